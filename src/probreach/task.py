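"""Random-target reach task simulation.

Simulates the sequential four-reach random-target paradigm in a
20 cm x 20 cm workspace: targets are drawn 5-15 cm from the current
target at a uniform angle, and out-of-workspace candidates are redrawn
by adding 90 degrees and fixing the distance at 5 cm until the candidate
falls inside. That rejection rule makes upcoming targets more likely
roughly opposite (and slightly clockwise of opposite) the current hand
position, which is the conditional probability structure every
downstream analysis interrogates.

The behavioral generative model plants two expectedness effects:
initial movement direction is blended toward the expected direction
phi_E = phi_P + phi_star, and reach latency grows with the angular
surprise |wrap_diff(phi_T, phi_E)|, more steeply for start positions
far from the center. Conventions: x rightward, y upward, angles in
degrees counterclockwise from +x, times in ms on a session clock
starting at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .circstats import canonical, wrap_diff

__all__ = [
    "Workspace",
    "TaskParams",
    "BehaviorParams",
    "SessionData",
    "draw_next_target",
    "apply_vr",
    "simulate_session",
]


@dataclass
class Workspace:
    half_width: float = 10.0  # cm; 20 x 20 cm workspace
    center: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    def contains(self, p) -> bool:
        cx, cy = self.center
        return (abs(p[0] - cx) < self.half_width) and (abs(p[1] - cy) < self.half_width)


@dataclass
class TaskParams:
    dist_min: float = 5.0      # cm
    dist_max: float = 15.0     # cm
    reject_angle_step: float = 90.0  # degrees added on rejection (+ = CCW step)
    reject_dist: float = 5.0   # cm, distance after first rejection
    hold_ms: float = 200.0
    display_delay_ms: float = 96.0
    targets_per_trial: int = 4
    intertrial_ms: float = 1000.0
    vr_rotation_deg: float = 0.0  # +30 for the visuomotor-rotation condition

    def __post_init__(self):
        if not (0 < self.dist_min <= self.reject_dist <= self.dist_max):
            raise ValueError("require 0 < dist_min <= reject_dist <= dist_max")
        if self.targets_per_trial < 1:
            raise ValueError("targets_per_trial must be >= 1")


@dataclass
class BehaviorParams:
    """Generative parameters for trajectories and latencies.

    ``phi_star_deg`` is the angular offset the simulated subject uses to
    form its expectation phi_E = phi_P + phi_star (the task's true
    conditional mean is near 150 degrees). ``initial_bias_weight`` in
    [0, 1] sets how strongly the initial movement direction points at
    phi_E; the blend decays with time constant ``bias_decay_ms`` and is
    scaled by distance from the center (peaked expectations far from the
    center produce stronger biases). Latency is
    base + slope_eff * |wrap_diff(phi_T, phi_E)| + noise, with
    slope_eff = slope * (0.5 + distance_gain * r / half_width).
    """

    latency_base_ms: float = 180.0
    latency_expectedness_slope: float = 0.4   # ms per degree of surprise
    latency_distance_gain: float = 1.0
    latency_noise_sd_ms: float = 20.0
    initial_bias_weight: float = 0.7
    bias_decay_ms: float = 150.0
    move_duration_base_ms: float = 250.0
    move_duration_per_cm_ms: float = 20.0
    hold_jitter_sd_cm: float = 0.1
    kinematic_noise_sd_cm: float = 0.02
    sample_period_ms: float = 10.0
    error_rate: float = 0.03
    phi_star_deg: float = 150.0

    def __post_init__(self):
        if not (0.0 <= self.initial_bias_weight <= 1.0):
            raise ValueError("initial_bias_weight must be in [0, 1]")
        for name in ("bias_decay_ms", "move_duration_base_ms", "sample_period_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class SessionData:
    """One simulated (or recorded) session.

    ``reaches`` has one row per reach with event times and angular
    quantities; ``kinematics`` is the continuous 2-D trajectory sampled
    on a regular grid (hand and screen coordinates; identical in the
    baseline condition); ``spikes`` (neuron_id, t_ms) and ``neurons``
    are filled by the neuron synthesis stage. ``truth`` carries
    ground-truth neuron attributes for test harnesses and is kept
    separate from observed metadata.
    """

    condition: str = "baseline"
    seed: int = 0
    workspace: Workspace = field(default_factory=Workspace)
    task_params: TaskParams = field(default_factory=TaskParams)
    behavior_params: BehaviorParams = field(default_factory=BehaviorParams)
    reaches: pd.DataFrame = None
    kinematics: pd.DataFrame = None
    spikes: pd.DataFrame = None
    neurons: pd.DataFrame = None
    truth: pd.DataFrame = None

    def manifest(self) -> dict:
        return {
            "condition": self.condition,
            "seed": int(self.seed),
            "workspace": asdict(self.workspace),
            "task_params": asdict(self.task_params),
            "behavior_params": asdict(self.behavior_params),
        }


def draw_next_target(current, ws: Workspace, tp: TaskParams, rng) -> np.ndarray:
    """Draw the next target location from the current one.

    Uniform distance in [dist_min, dist_max], uniform angle; if the
    candidate lands outside the workspace, add ``reject_angle_step`` to
    the angle and fix the distance at ``reject_dist``, repeating until
    inside. From any interior point at least one of the four 90
    degree-spaced directions at 5 cm stays inside a 20 x 20 cm square,
    so the loop terminates.
    """
    current = np.asarray(current, dtype=float)
    if not ws.contains(current):
        raise ValueError(f"current position {current} outside workspace")
    dist = rng.uniform(tp.dist_min, tp.dist_max)
    ang = rng.uniform(0.0, 360.0)
    while True:
        rad = np.radians(ang)
        cand = current + dist * np.array([np.cos(rad), np.sin(rad)])
        if ws.contains(cand):
            return cand
        ang += tp.reject_angle_step
        dist = tp.reject_dist


def simulate_phi_chain(n_reaches: int, ws: Workspace | None = None,
                       tp: TaskParams | None = None, rng=None,
                       seed: int | None = None) -> np.ndarray:
    """Phi for a long chain of target draws, hand position taken as the
    previous target location.

    Fast path for studying the task's statistics in isolation: no
    kinematics, no trial structure, just chained draws. Returns the
    signed Phi = phi_T - phi_P values in (-180, 180]; starts are at the
    workspace center (reaches from positions where phi_P is undefined
    are skipped).
    """
    ws = ws or Workspace()
    tp = tp or TaskParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    cur = np.array(ws.center, dtype=float)
    cx, cy = ws.center
    phis = np.empty(n_reaches)
    k = 0
    while k < n_reaches:
        tgt = draw_next_target(cur, ws, tp, rng)
        rel = cur - np.array([cx, cy])
        r = np.hypot(*rel)
        if r > 1e-9:
            phi_p = np.degrees(np.arctan2(rel[1], rel[0]))
            phi_t = np.degrees(np.arctan2(tgt[1] - cur[1], tgt[0] - cur[0]))
            phis[k] = wrap_diff(phi_t, phi_p)
            k += 1
        cur = tgt
    return phis


def apply_vr(hand_vector, rotation_deg: float = 30.0) -> np.ndarray:
    """Rotate a hand movement vector into screen coordinates (+ = CCW)."""
    v = np.asarray(hand_vector, dtype=float)
    r = np.radians(rotation_deg)
    rot = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
    return v @ rot.T


def _minjerk_profile(n):
    """Normalized min-jerk path fraction s(tau) and speed shape on n samples."""
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return tau, s


def simulate_session(n_trials: int,
                     ws: Workspace | None = None,
                     tp: TaskParams | None = None,
                     bp: BehaviorParams | None = None,
                     rng=None,
                     seed: int | None = None) -> SessionData:
    """Simulate the behavioral part of a session.

    Each trial chains ``targets_per_trial`` reaches; the hand holds on
    each target (with Gaussian jitter) until target onset plus the
    planted latency, then moves along a bell-speed trajectory whose
    direction is initially blended toward the expected direction. A
    fraction ``bp.error_rate`` of reaches is injected as errors (hold
    violation or timeout) and flagged.
    """
    ws = ws or Workspace()
    tp = tp or TaskParams()
    bp = bp or BehaviorParams()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    vr = tp.vr_rotation_deg != 0.0
    dt = bp.sample_period_ms
    hw = ws.half_width

    rows = []
    kin_t, kin_hx, kin_hy, kin_sx, kin_sy = [], [], [], [], []
    t = 0.0  # session clock, ms
    screen_pos = np.array(ws.center, dtype=float)  # cursor position on screen

    def screen_to_hand(vec):
        return apply_vr(vec, -tp.vr_rotation_deg) if vr else np.asarray(vec, float)

    def emit_hold(t_from, t_to, pos):
        """Hold samples at pos on the dt grid over [t_from, t_to).

        The jitter offset is constant per hold (the hand rests slightly
        off the target center), so holding produces no spurious speed."""
        nonlocal t
        times = np.arange(t_from, t_to, dt)
        for ti in times:
            sp = pos
            hp = screen_to_hand(sp - ws.center) + ws.center if vr else sp
            kin_t.append(ti)
            kin_sx.append(sp[0]); kin_sy.append(sp[1])
            kin_hx.append(hp[0]); kin_hy.append(hp[1])
        t = t_to

    reach_counter = 0
    for trial in range(n_trials):
        for idx in range(1, tp.targets_per_trial + 1):
            reach_counter += 1
            start = screen_pos.copy()
            held = start + rng.normal(0.0, bp.hold_jitter_sd_cm, size=2)
            target = draw_next_target(start, ws, tp, rng)

            # event times: land -> command (+100 ms) -> onset (+delay)
            land_time = t
            command_time = land_time + (tp.hold_ms - tp.display_delay_ms - 4.0)
            onset_time = command_time + tp.display_delay_ms

            # angular quantities (screen/workspace frame)
            rel = start - np.asarray(ws.center)
            phi_p = float(np.degrees(np.arctan2(rel[1], rel[0])) % 360.0)
            mvec = target - start
            phi_t = float(np.degrees(np.arctan2(mvec[1], mvec[0])) % 360.0)
            dist = float(np.hypot(*mvec))
            r_center = float(np.hypot(*rel))

            # subject's expectation and planted latency
            phi_e = canonical(phi_p + bp.phi_star_deg)
            surprise = abs(wrap_diff(phi_t, phi_e))
            slope_eff = bp.latency_expectedness_slope * (
                0.5 + bp.latency_distance_gain * r_center / hw)
            latency = (bp.latency_base_ms + slope_eff * surprise
                       + rng.normal(0.0, bp.latency_noise_sd_ms))
            latency = max(latency, 20.0)

            # error injection
            err = rng.uniform() < bp.error_rate
            err_kind = None
            hold_duration = tp.hold_ms
            move_T = bp.move_duration_base_ms + bp.move_duration_per_cm_ms * dist
            if err:
                if rng.uniform() < 0.5:
                    err_kind = "hold_violation"
                    hold_duration = rng.uniform(50.0, 180.0)
                else:
                    err_kind = "timeout"
                    move_T = 1500.0 - latency + rng.uniform(0.0, 300.0)
                    move_T = max(move_T, 1450.0 - latency)

            # hold phase: from landing until movement start (onset + latency)
            move_start = onset_time + latency
            if err_kind == "hold_violation":
                move_start = land_time + hold_duration + latency
                move_start = max(move_start, land_time + dt)
            emit_hold(land_time, move_start, held)

            # movement phase (screen frame): blended-direction bell trajectory
            n_samp = max(int(np.ceil(move_T / dt)), 4)
            tau, s_frac = _minjerk_profile(n_samp + 1)
            # expected direction in the frame the subject plans in (screen)
            w0 = bp.initial_bias_weight * min(1.0, r_center / hw)
            w_t = w0 * np.exp(-(tau * move_T) / bp.bias_decay_ms)
            # circular blend of directions phi_e (weight w) and phi_t
            d_et = wrap_diff(phi_e, phi_t)
            theta = np.radians(phi_t + w_t * d_et)
            arc = np.diff(s_frac) * dist
            steps = np.stack([np.cos(theta[1:]), np.sin(theta[1:])], axis=1) * arc[:, None]
            path = held + np.concatenate([[np.zeros(2)], np.cumsum(steps, axis=0)])
            # endpoint correction proportional to path fraction keeps the
            # initial direction intact while landing exactly on the target
            path = path + (target - path[-1]) * s_frac[:, None]
            samp_ms = move_T / n_samp
            v_max = float(np.max(np.hypot(*np.diff(path, axis=0).T)) / samp_ms * 1000.0)

            move_times = move_start + tau * move_T
            grid = np.arange(t, move_times[-1], dt)
            gx = np.interp(grid, move_times, path[:, 0])
            gy = np.interp(grid, move_times, path[:, 1])
            gx = gx + rng.normal(0.0, bp.kinematic_noise_sd_cm, size=gx.shape)
            gy = gy + rng.normal(0.0, bp.kinematic_noise_sd_cm, size=gy.shape)
            for ti, xi, yi in zip(grid, gx, gy):
                sp = np.array([xi, yi])
                hp = screen_to_hand(sp - ws.center) + ws.center if vr else sp
                kin_t.append(ti)
                kin_sx.append(sp[0]); kin_sy.append(sp[1])
                kin_hx.append(hp[0]); kin_hy.append(hp[1])
            t = move_times[-1]
            land_next = t

            hand_vec = screen_to_hand(mvec)
            phi_t_hand = float(np.degrees(np.arctan2(hand_vec[1], hand_vec[0])) % 360.0)

            rows.append({
                "reach_id": reach_counter,
                "trial_id": trial + 1,
                "index_in_trial": idx,
                "start_x": start[0], "start_y": start[1],
                "target_x": target[0], "target_y": target[1],
                "hold_start_time": land_time,
                "target_command_time": command_time,
                "target_onset_time": onset_time,
                "move_start_time": move_start,
                "land_time": land_next,
                "phi_p": phi_p,
                "phi_t": phi_t,
                "phi_t_hand": phi_t_hand,
                "dist": dist,
                "r_center": r_center,
                "hold_duration_ms": hold_duration,
                "move_duration_ms": land_next - onset_time,
                "v_max": v_max,
                "latency_planted_ms": latency,
                "valid": err_kind is None,
                "exclusion_reason": err_kind or "",
            })
            screen_pos = target
        t += tp.intertrial_ms

    reaches = pd.DataFrame(rows)
    kinematics = pd.DataFrame({
        "t_ms": kin_t,
        "hand_x": kin_hx, "hand_y": kin_hy,
        "screen_x": kin_sx, "screen_y": kin_sy,
    })
    # phase boundaries can occasionally coincide with a grid sample
    kinematics = kinematics.drop_duplicates("t_ms").reset_index(drop=True)
    return SessionData(
        condition="vr" if vr else "baseline",
        seed=-1 if seed is None else seed,
        workspace=ws, task_params=tp, behavior_params=bp,
        reaches=reaches, kinematics=kinematics,
    )
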