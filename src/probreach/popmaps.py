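"""Trial-averaged population representations.

Condition-averaged PSTHs, profiles of pre-target activity against the
hand's angular position relative to each neuron's preferred direction,
rotated-and-summed position-activity maps compared against the task's
conditional probability of an upward movement, and the histogram of
preferred directions relative to preferred angular hand positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import canonical, circ_mean, wrap_diff
from .smoothing import SmoothedMap, MAP_SMOOTH
from .neurons import ProbabilityMap

__all__ = ["psth_by_condition", "relative_position_profile",
           "summed_rotated_maps", "pd_position_histogram",
           "RelativePositionProfile"]

NEAR_DEG = 60.0       # "near the PD": within 60 degrees
OPPOSITE_DEG = 120.0  # "opposite the PD": more than 120 degrees away
PSTH_SMOOTH_MS = 50.0
N_PROFILE_ANGLES = 20
N_BOOT = 1000


# ------------------------------------------------------------------ PSTHs

def _neuron_rate_matrix(spike_times, onsets, t_range, bin_ms):
    """(reaches x bins) spike rates (sp/s) around target onset."""
    edges = np.arange(t_range[0], t_range[1] + bin_ms / 2, bin_ms)
    mat = np.empty((len(onsets), len(edges) - 1))
    for i, on in enumerate(onsets):
        mat[i] = np.histogram(spike_times - on, bins=edges)[0]
    return mat / bin_ms * 1000.0, (edges[:-1] + edges[1:]) / 2


def _boxcar(trace, bin_ms, smooth_ms=PSTH_SMOOTH_MS):
    w = max(1, int(round(smooth_ms / bin_ms)))
    kernel = np.ones(w) / w
    return np.convolve(trace, kernel, mode="same")


def psth_by_condition(session, reaches, pds: dict, t_range=(-400.0, 400.0),
                      bin_ms: float = 10.0):
    """Normalized condition-averaged PSTHs.

    Conditions cross movement direction relative to the PD (near: <60
    deg; opposite: >120 deg) with starting angular hand position
    relative to the PD (near / opposite). Each neuron's traces are
    divided by the maximum of its across-condition average trace, then
    averaged across neurons; traces are smoothed with a 50 ms sliding
    window. ``pds`` maps neuron_id -> preferred direction (deg).

    Returns dict condition -> {"t", "mean", "sem", "n_neurons"}.
    """
    onsets = reaches["target_onset_time"].to_numpy()
    move_dir = reaches["phi_t_hand"].to_numpy()
    pos_ang = reaches["phi_p"].to_numpy()
    conds = {
        "move_near_pos_near": lambda d_m, d_p: (d_m < NEAR_DEG) & (d_p < NEAR_DEG),
        "move_near_pos_opp": lambda d_m, d_p: (d_m < NEAR_DEG) & (d_p > OPPOSITE_DEG),
        "move_opp_pos_near": lambda d_m, d_p: (d_m > OPPOSITE_DEG) & (d_p < NEAR_DEG),
        "move_opp_pos_opp": lambda d_m, d_p: (d_m > OPPOSITE_DEG) & (d_p > OPPOSITE_DEG),
    }
    per_neuron = {c: [] for c in conds}
    t_centers = None
    spikes = session.spikes
    for nid, pd_deg in pds.items():
        st = spikes.loc[spikes["neuron_id"] == nid, "t_ms"].to_numpy()
        mat, t_centers = _neuron_rate_matrix(st, onsets, t_range, bin_ms)
        d_m = np.abs(wrap_diff(move_dir, pd_deg))
        d_p = np.abs(wrap_diff(pos_ang, pd_deg))
        traces = {}
        for cname, fn in conds.items():
            sel = fn(d_m, d_p)
            traces[cname] = mat[sel].mean(axis=0) if sel.sum() else None
        peak = max((np.max(v) for v in traces.values() if v is not None),
                   default=0.0)
        if peak <= 0:
            continue
        for cname, v in traces.items():
            if v is not None:
                per_neuron[cname].append(_boxcar(v / peak, bin_ms))
    out = {}
    for cname, lst in per_neuron.items():
        if not lst:
            out[cname] = None
            continue
        arr = np.array(lst)
        out[cname] = {"t": t_centers, "mean": arr.mean(axis=0),
                      "sem": arr.std(axis=0, ddof=1) / np.sqrt(len(arr)),
                      "n_neurons": len(arr)}
    return out


# --------------------------------------------- relative-position profiles

@dataclass
class RelativePositionProfile:
    angles: np.ndarray              # the 20 relative angular positions, deg
    activity: np.ndarray            # across-neuron mean normalized rate
    sem: np.ndarray
    n_neurons: int
    peak_angle: float               # activity-weighted circular mean
    peak_ci: tuple                  # bootstrap 95% CI (lo, hi)
    resultant: float
    peak_defined: bool = True


def _profile_for_neuron(counts, rel_ang, angles, halfbin):
    prof = np.full(len(angles), np.nan)
    for j, a in enumerate(angles):
        sel = np.abs(wrap_diff(rel_ang, a)) <= halfbin
        if sel.sum():
            prof[j] = counts[sel].mean()
    mu = np.nanmean(prof)
    if not np.isfinite(mu) or mu <= 0:
        return None
    return prof / mu   # normalize by the neuron's mean rate

def _peak_of(activity, angles):
    w = np.clip(np.nan_to_num(activity), 0.0, None)
    if w.sum() <= 0:
        return np.nan, 0.0
    return circ_mean(angles, weights=w)


def relative_position_profile(session, reaches, pds: dict,
                              window=(-100.0, 0.0),
                              prev_upcoming_max_deg=None,
                              resample_to_180=False,
                              rng=None, n_boot: int = N_BOOT):
    """Pre-target activity vs angular hand position relative to the PD.

    For each neuron, reaches are binned at 20 evenly spaced relative
    angular positions (PD minus phi_P); rates are normalized by the
    neuron's mean and averaged across neurons. The peak is the
    activity-weighted circular mean of the 20 angles; its 95% CI comes
    from bootstrapping over neurons.

    ``prev_upcoming_max_deg`` restricts to reaches whose previous and
    upcoming movement directions differ by less than the given angle.
    ``resample_to_180`` importance-resamples reaches so the Phi
    distribution is recentered at 180 deg (weights from a unit-
    concentration von Mises at 180).
    """
    rng = rng or np.random.default_rng(0)
    angles = np.arange(N_PROFILE_ANGLES) * 360.0 / N_PROFILE_ANGLES
    halfbin = 180.0 / N_PROFILE_ANGLES

    r = reaches
    if prev_upcoming_max_deg is not None:
        full = session.reaches.set_index("reach_id")
        prev = full.reindex(r["reach_id"].to_numpy() - 1)
        dd = np.abs(wrap_diff(r["phi_t_hand"].to_numpy(),
                              prev["phi_t_hand"].to_numpy()))
        r = r[dd < prev_upcoming_max_deg]
    idx = np.arange(len(r))
    if resample_to_180:
        phi = wrap_diff(r["phi_t"].to_numpy(), r["phi_p"].to_numpy())
        w = np.exp(np.cos(np.radians(phi - 180.0)))
        w = w / w.sum()
        idx = rng.choice(len(r), size=len(r), replace=True, p=w)
    r = r.iloc[idx]

    onsets = r["target_onset_time"].to_numpy()
    pos_ang = r["phi_p"].to_numpy()
    spikes = session.spikes
    profiles = []
    for nid, pd_deg in pds.items():
        st = spikes.loc[spikes["neuron_id"] == nid, "t_ms"].to_numpy()
        lo = np.searchsorted(st, onsets + window[0])
        hi = np.searchsorted(st, onsets + window[1])
        counts = (hi - lo).astype(float)
        rel = canonical(pd_deg - pos_ang)
        prof = _profile_for_neuron(counts, rel, angles, halfbin)
        if prof is not None:
            profiles.append(prof)
    if len(profiles) < 2:
        raise ValueError("too few neurons with usable profiles")
    arr = np.array(profiles)
    mean_prof = np.nanmean(arr, axis=0)
    sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(len(arr))
    peak, res = _peak_of(mean_prof, angles)

    peaks = []
    for _ in range(n_boot):
        bi = rng.integers(0, len(arr), size=len(arr))
        p, rl = _peak_of(np.nanmean(arr[bi], axis=0), angles)
        if np.isfinite(p):
            peaks.append(p)
    if peaks and np.isfinite(peak):
        dev = wrap_diff(np.array(peaks), peak)
        ci = (canonical(peak + np.percentile(dev, 2.5)),
              canonical(peak + np.percentile(dev, 97.5)))
        defined = True
    else:
        ci, defined = (np.nan, np.nan), False
    return RelativePositionProfile(
        angles=angles, activity=mean_prof, sem=sem, n_neurons=len(arr),
        peak_angle=peak, peak_ci=ci, resultant=res, peak_defined=defined)


def peak_ci_contains(profile: RelativePositionProfile, angle: float) -> bool:
    """Whether the bootstrap peak CI covers the given angle (circular)."""
    lo, hi = profile.peak_ci
    if not profile.peak_defined:
        return False
    span = canonical(hi - lo)
    return canonical(angle - lo) <= span


# ------------------------------------------------- rotated position maps

def _quarter_rotation_for(pd_deg):
    """Multiple of 90 deg that puts the PD into [45, 135)."""
    for k in range(4):
        if 45.0 <= canonical(pd_deg + 90.0 * k) < 135.0:
            return 90.0 * k
    return 0.0  # pragma: no cover


def summed_rotated_maps(session, reaches, pds: dict, pmap: ProbabilityMap,
                        window=(-100.0, 50.0), grid_spacing: float = 0.5,
                        smooth=MAP_SMOOTH):
    """Sum of per-neuron position-activity maps rotated so each PD points
    up, compared with p(upward movement | position).

    Each neuron's map is a k-NN smoothed rate map (activity from -100 to
    +50 ms around target onset as a function of start position),
    evaluated on a square grid after rotating query coordinates by the
    multiple of 90 deg that puts the PD in [45, 135). Returns
    (xs, ys, summed map, probability grid, pearson_r).
    """
    hw = session.workspace.half_width
    xs = np.arange(-hw + grid_spacing, hw, grid_spacing)
    ys = xs.copy()
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])

    onsets = reaches["target_onset_time"].to_numpy()
    pos = reaches[["start_x", "start_y"]].to_numpy()
    spikes = session.spikes
    total = np.zeros(len(pts))
    n_used = 0
    for nid, pd_deg in pds.items():
        if not np.isfinite(pd_deg):
            continue
        st = spikes.loc[spikes["neuron_id"] == nid, "t_ms"].to_numpy()
        lo = np.searchsorted(st, onsets + window[0])
        hi = np.searchsorted(st, onsets + window[1])
        rates = (hi - lo) / (window[1] - window[0]) * 1000.0
        m = SmoothedMap(pos, rates, smooth, tag="position")
        rot = _quarter_rotation_for(pd_deg)
        # evaluate the unrotated map at coordinates rotated back by -rot
        rad = np.radians(-rot)
        R = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
        total += m.predict(pts @ R.T)
        n_used += 1
    if n_used == 0:
        raise ValueError("no neurons with reliable PDs")
    summed = total.reshape(gy.shape)

    p_up = np.asarray(pmap.prob(pts, 90.0)).reshape(gy.shape)
    ok = np.isfinite(p_up) & np.isfinite(summed)
    r = float(np.corrcoef(summed[ok].ravel(), p_up[ok].ravel())[0, 1])
    return xs, ys, summed, p_up, r


# ------------------------------------------------------- PD vs position

def pd_position_histogram(pds: dict, pref_positions: dict, phi_values=None,
                          n_bins: int = 18):
    """Distribution of (PD - preferred angular position) across neurons.

    Optionally compares against the behavioral Phi distribution
    (circular mean difference and dispersion ratio). Returns a dict with
    the per-neuron differences, histogram, circular mean/resultant, and
    the comparison when ``phi_values`` is given.
    """
    diffs = []
    for nid in pds:
        a, b = pds.get(nid), pref_positions.get(nid)
        if a is None or b is None or not (np.isfinite(a) and np.isfinite(b)):
            continue
        diffs.append(canonical(a - b))
    diffs = np.array(diffs)
    if diffs.size < 2:
        raise ValueError("need at least two neurons with both estimates")
    edges = np.arange(0.0, 360.0 + 1e-9, 360.0 / n_bins)
    hist, _ = np.histogram(diffs, bins=edges)
    m, res = circ_mean(diffs)
    out = {"diffs": diffs, "hist": hist, "bin_edges": edges,
           "circ_mean": m, "resultant": res,
           "dispersion": 1.0 - res}
    if phi_values is not None:
        pm, pres = circ_mean(np.asarray(phi_values))
        out["phi_circ_mean"] = pm
        out["mean_difference"] = float(wrap_diff(m, pm))
        out["dispersion_ratio"] = float((1.0 - res) / max(1.0 - pres, 1e-12))
    return out
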