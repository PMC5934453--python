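"""Synthetic Poisson spiking populations with known ground truth.

Three neuron classes:

* ``PR`` (potential-response): pre-target rate scales with the
  conditional probability that the upcoming movement will fall within a
  window around the neuron's preferred direction, given the current
  hand position; post-target rate is von Mises tuned to the upcoming
  movement.
* ``SR`` (selected-response): baseline rate before target onset, von
  Mises movement tuning after.
* ``M1-like``: pre-target rate carries a decaying after-effect of the
  previous movement (tuned to the previous movement direction), which
  mimics position modulation without encoding upcoming probabilities.

The conditional probability ground truth is a Monte-Carlo map estimated
from the task's own target-drawing algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import Workspace, TaskParams, draw_next_target
from .circstats import wrap_diff

__all__ = ["NeuronSpec", "ProbabilityMap", "estimate_probability_map",
           "make_population", "synthesize_spikes"]

#: rate blend duration around target onset (ms), avoids PSTH discontinuities
BLEND_MS = 50.0
#: default angular window half-width for "movement near the PD" (degrees)
PD_WINDOW_HALFWIDTH = 60.0


@dataclass
class NeuronSpec:
    neuron_id: int
    klass: str                      # "PR" | "SR" | "M1-like"
    pd: float                       # ground-truth preferred direction, deg
    baseline_rate: float = 5.0      # sp/s
    movement_gain: float = 25.0     # sp/s at the PD (peak modulation)
    movement_concentration: float = 2.0   # von Mises beta
    prob_gain: float = 0.0          # sp/s per unit probability (PR only)
    m1_decay_ms: float = 0.0        # previous-movement decay (M1-like only)

    def __post_init__(self):
        if self.klass not in ("PR", "SR", "M1-like"):
            raise ValueError(f"unknown neuron class {self.klass!r}")
        if self.baseline_rate < 0 or self.movement_gain < 0:
            raise ValueError("rates must be nonnegative")
        if self.klass != "PR" and self.prob_gain != 0:
            raise ValueError("prob_gain is PR-only")
        if self.klass != "M1-like" and self.m1_decay_ms != 0:
            raise ValueError("m1_decay_ms is M1-like-only")


class ProbabilityMap:
    """p(next movement direction within +/- window of center | hand position).

    Estimated on a square grid of hand positions for a ring of direction-
    window centers. ``rotation_deg`` expresses the window centers in hand
    coordinates while positions and target draws live in screen
    coordinates (nonzero only for the visuomotor-rotation condition).
    Queries interpolate bilinearly in position and use the nearest
    direction center. Cells the task can never visit are NaN.
    """

    def __init__(self, xs, ys, centers, p, n_samples, window_halfwidth,
                 rotation_deg=0.0):
        self.xs = np.asarray(xs, dtype=float)
        self.ys = np.asarray(ys, dtype=float)
        self.centers = np.asarray(centers, dtype=float)
        self.p = np.asarray(p, dtype=float)   # shape (ny, nx, n_centers)
        self.n_samples = int(n_samples)
        self.window_halfwidth = float(window_halfwidth)
        self.rotation_deg = float(rotation_deg)

    @property
    def mc_se(self):
        """Monte-Carlo standard error of each cell's estimate."""
        return np.sqrt(self.p * (1 - self.p) / self.n_samples)

    def prob(self, positions, center_deg):
        """p for hand position(s) with the window centered at center_deg."""
        ci = int(np.argmin(np.abs(wrap_diff(self.centers, center_deg))))
        q = np.atleast_2d(np.asarray(positions, dtype=float))
        sheet = self.p[:, :, ci]
        ix = np.clip(np.searchsorted(self.xs, q[:, 0]) - 1, 0, len(self.xs) - 2)
        iy = np.clip(np.searchsorted(self.ys, q[:, 1]) - 1, 0, len(self.ys) - 2)
        x0, x1 = self.xs[ix], self.xs[ix + 1]
        y0, y1 = self.ys[iy], self.ys[iy + 1]
        tx = np.clip((q[:, 0] - x0) / (x1 - x0), 0, 1)
        ty = np.clip((q[:, 1] - y0) / (y1 - y0), 0, 1)
        z00 = sheet[iy, ix]
        z01 = sheet[iy, ix + 1]
        z10 = sheet[iy + 1, ix]
        z11 = sheet[iy + 1, ix + 1]
        out = (z00 * (1 - tx) * (1 - ty) + z01 * tx * (1 - ty)
               + z10 * (1 - tx) * ty + z11 * tx * ty)
        return out if out.size > 1 else float(out[0])


def _draw_targets_from(pos, ws, tp, rng, n):
    """Vectorized: n independent next-target draws from one position."""
    dist = rng.uniform(tp.dist_min, tp.dist_max, size=n)
    ang = rng.uniform(0.0, 360.0, size=n)
    pos = np.asarray(pos, dtype=float)
    for _ in range(8):
        rad = np.radians(ang)
        cand = pos + np.column_stack([dist * np.cos(rad), dist * np.sin(rad)])
        cx, cy = ws.center
        inside = ((np.abs(cand[:, 0] - cx) < ws.half_width)
                  & (np.abs(cand[:, 1] - cy) < ws.half_width))
        if inside.all():
            return cand
        ang = np.where(inside, ang, ang + tp.reject_angle_step)
        dist = np.where(inside, dist, tp.reject_dist)
    raise RuntimeError("rejection loop failed to terminate")  # pragma: no cover


def estimate_probability_map(tp=None, ws=None,
                             window_halfwidth=PD_WINDOW_HALFWIDTH,
                             grid_spacing=1.0, n_centers=24,
                             n_samples=10_000, rng=None,
                             rotation_deg=None):
    """Monte-Carlo conditional probability map of upcoming movements.

    For each grid hand position, ``n_samples`` next targets are drawn by
    the task algorithm; p for each direction-window center is the
    fraction of draws whose movement direction (in hand coordinates)
    falls within the window. With ``rotation_deg`` unset, the task
    params' own VR rotation is used.
    """
    ws = ws or Workspace()
    tp = tp or TaskParams()
    if n_samples < 1000:
        raise ValueError("n_samples too small for a stable map")
    rng = rng or np.random.default_rng(0)
    if rotation_deg is None:
        rotation_deg = tp.vr_rotation_deg
    margin = grid_spacing / 2
    xs = np.arange(-ws.half_width + margin, ws.half_width, grid_spacing)
    ys = xs.copy()
    centers = np.arange(0.0, 360.0, 360.0 / n_centers)
    p = np.full((len(ys), len(xs), len(centers)), np.nan)
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            pos = np.array([x, y])
            tgt = _draw_targets_from(pos, ws, tp, rng, n_samples)
            vec = tgt - pos
            dirs = np.degrees(np.arctan2(vec[:, 1], vec[:, 0]))
            # screen draw -> hand-frame direction
            dirs = dirs - rotation_deg
            for ic, c in enumerate(centers):
                p[iy, ix, ic] = np.mean(
                    np.abs(wrap_diff(dirs, c)) <= window_halfwidth)
    return ProbabilityMap(xs, ys, centers, p, n_samples, window_halfwidth,
                          rotation_deg)


def make_population(n_pr=40, n_sr=60, n_m1=50, rng=None,
                    baseline_rate=5.0, movement_gain=25.0,
                    movement_concentration=2.0, prob_gain=30.0,
                    m1_decay_ms=300.0):
    """Default synthetic population; PDs uniform on the circle per class."""
    rng = rng or np.random.default_rng(0)
    specs = []
    nid = 0
    for klass, n in (("PR", n_pr), ("SR", n_sr), ("M1-like", n_m1)):
        if n == 0:
            continue
        pds = (np.arange(n) * 360.0 / n + rng.uniform(0, 360.0 / n, size=n)) % 360.0
        for pd_ in pds:
            nid += 1
            specs.append(NeuronSpec(
                neuron_id=nid, klass=klass, pd=float(pd_),
                baseline_rate=baseline_rate, movement_gain=movement_gain,
                movement_concentration=movement_concentration,
                prob_gain=prob_gain if klass == "PR" else 0.0,
                m1_decay_ms=m1_decay_ms if klass == "M1-like" else 0.0,
            ))
    return specs


def _tuning_factor(direction_deg, pd, beta):
    """Normalized von Mises: 1 at the PD regardless of beta."""
    return np.exp(beta * (np.cos(np.radians(direction_deg - pd)) - 1.0))


def synthesize_spikes(specs, session, pmap: ProbabilityMap, rng=None,
                      max_rate=500.0):
    """Inhomogeneous-Poisson spike trains for the whole session (1 ms bins).

    Pre-target (hold) epochs use the class-specific rate; post-target
    (movement) epochs use baseline + gain * normalized von Mises tuning
    to the upcoming hand movement direction; the two blend linearly over
    50 ms around target onset. Writes ``spikes``, ``neurons`` and
    ``truth`` tables onto the session and returns it.
    """
    if session.reaches is None or len(session.reaches) == 0:
        raise ValueError("session behavioral part must be simulated first")
    rng = rng or np.random.default_rng(0)
    reaches = session.reaches
    t_end = float(reaches["land_time"].max()) + 500.0
    n_bins = int(np.ceil(t_end))
    tgrid = np.arange(n_bins, dtype=float)  # 1 ms bins

    # per-reach epoch bounds
    hold0 = reaches["hold_start_time"].to_numpy()
    onset = reaches["target_onset_time"].to_numpy()
    land = reaches["land_time"].to_numpy()
    start_pos = reaches[["start_x", "start_y"]].to_numpy()
    move_dir = reaches["phi_t_hand"].to_numpy()
    prev_dir = np.concatenate([[np.nan], move_dir[:-1]])
    same_trial = np.concatenate(
        [[False], reaches["trial_id"].to_numpy()[1:]
         == reaches["trial_id"].to_numpy()[:-1]])
    prev_dir[~same_trial] = np.nan

    spike_rows = []
    for spec in specs:
        rate = np.full(n_bins, spec.baseline_rate)
        # per-reach pre-target probability (PR only), vectorized over reaches
        if spec.klass == "PR":
            ci = int(np.argmin(np.abs(wrap_diff(pmap.centers, spec.pd))))
            p_pre = np.atleast_1d(pmap.prob(start_pos, pmap.centers[ci]))
        for i in range(len(reaches)):
            i0 = int(hold0[i])
            i_on = int(onset[i])
            i1 = min(int(land[i]), n_bins)
            if spec.klass == "PR":
                pre_rate = spec.baseline_rate + spec.prob_gain * p_pre[i]
                rate[i0:i_on] = pre_rate
            elif spec.klass == "M1-like" and np.isfinite(prev_dir[i]):
                tt = tgrid[i0:i_on] - hold0[i]
                rate[i0:i_on] = spec.baseline_rate + (
                    spec.movement_gain
                    * _tuning_factor(prev_dir[i], spec.pd,
                                     spec.movement_concentration)
                    * np.exp(-tt / spec.m1_decay_ms))
            post_rate = spec.baseline_rate + spec.movement_gain * _tuning_factor(
                move_dir[i], spec.pd, spec.movement_concentration)
            rate[i_on:i1] = post_rate
            # linear blend across onset
            b0 = max(int(i_on - BLEND_MS / 2), i0)
            b1 = min(int(i_on + BLEND_MS / 2), i1)
            if b1 > b0:
                u = np.linspace(0.0, 1.0, b1 - b0)
                pre_val = rate[b0 - 1] if b0 > i0 else rate[b0]
                rate[b0:b1] = (1 - u) * rate[max(b0 - 1, 0)] + u * post_rate
        np.clip(rate, 0.0, max_rate, out=rate)
        counts = rng.poisson(rate / 1000.0)
        idx = np.nonzero(counts)[0]
        times = np.repeat(idx, counts[idx]) + rng.uniform(size=int(counts[idx].sum()))
        spike_rows.append(pd.DataFrame(
            {"neuron_id": spec.neuron_id, "t_ms": np.sort(times)}))

    spikes = (pd.concat(spike_rows, ignore_index=True) if spike_rows
              else pd.DataFrame(columns=["neuron_id", "t_ms"]))
    spikes = spikes.sort_values(["neuron_id", "t_ms"]).reset_index(drop=True)
    session.spikes = spikes
    session.neurons = pd.DataFrame(
        [{"neuron_id": s.neuron_id, "area": "PMd" if s.klass != "M1-like" else "M1"}
         for s in specs])
    session.truth = pd.DataFrame(
        [{"neuron_id": s.neuron_id, "klass": s.klass, "pd": s.pd,
          "baseline_rate": s.baseline_rate, "movement_gain": s.movement_gain,
          "movement_concentration": s.movement_concentration,
          "prob_gain": s.prob_gain, "m1_decay_ms": s.m1_decay_ms}
         for s in specs])
    return session
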