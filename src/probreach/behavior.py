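"""Behavioral analysis: reach filtering, Phi statistics, trajectory bias,
latency measurement and expectedness effects.

Phi (the central behavioral quantity) is the angular difference between
the upcoming movement direction phi_T and the angular hand position
phi_P at target onset. Its conditional distribution given hand position
is what the neural analyses test for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .circstats import canonical, circ_mean, wrap_diff

__all__ = [
    "filter_reaches",
    "phi_statistics",
    "expected_direction",
    "trajectory_bias",
    "reach_latency",
    "measure_latencies",
    "latency_analyses",
    "PhiStats",
    "BiasValue",
]

SPEED_THRESHOLD_CM_S = 8.0      # latency = onset -> first crossing of this speed
MAX_REACH_DURATION_MS = 1400.0  # reaches slower than this are errors
HOLD_REQUIRED_MS = 200.0
LATENCY_OUTLIER_SD = 6.0
BIAS_DENOM_EPS_DEG = 1.0        # |phi_ref - phi_T| below this -> bias undefined
N_BOOT = 1000


@dataclass
class PhiStats:
    phi_values: np.ndarray          # signed, (-180, 180]
    phi_star: float                 # circular mean of Phi, [0, 360)
    resultant: float
    by_distance_quartile: pd.DataFrame   # circ mean + resultant per quartile
    by_position_bin: pd.DataFrame        # x/y quartile grid of conditional stats
    center_subset: dict = field(default_factory=dict)  # |pos| < 2 cm


@dataclass
class BiasValue:
    B: float
    reference: str
    t0_ms: float
    t1_ms: float
    defined: bool = True


def filter_reaches(session):
    """Valid-reach filter: drop reach 1 of each trial, hold violations,
    and reaches that took more than 1.4 s, returning the surviving rows
    and a per-reason exclusion log."""
    df = session.reaches
    if df is None or len(df) == 0:
        raise ValueError("session has no reaches")
    reasons = pd.Series("", index=df.index, dtype=object)
    first = df["index_in_trial"] == 1
    hold = (~first) & (df["hold_duration_ms"] < HOLD_REQUIRED_MS - 1e-9)
    slow = (~first) & (~hold) & (df["move_duration_ms"] > MAX_REACH_DURATION_MS)
    reasons[first] = "first_reach"
    reasons[hold] = "hold_violation"
    reasons[slow] = "timeout"
    valid = df[reasons == ""].copy()
    log = reasons[reasons != ""].value_counts().to_dict()
    log["n_valid"] = int(len(valid))
    log["n_total"] = int(len(df))
    if len(valid) == 0:
        raise ValueError("no valid reaches after filtering")
    return valid, log


def phi_statistics(reaches: pd.DataFrame, min_pos_cm: float = 1e-6,
                   center_cm: float = 2.0) -> PhiStats:
    """Phi per reach, its circular mean phi_star, and conditional summaries.

    Reaches with hand position closer than ``min_pos_cm`` to the center
    have undefined phi_P and are dropped from the Phi sample. Position
    bins are empirical x/y quartiles of the start positions; the
    ``center_subset`` uses starts within ``center_cm`` of the center.
    """
    r = reaches[reaches["r_center"] > min_pos_cm]
    phi = wrap_diff(r["phi_t"].to_numpy(), r["phi_p"].to_numpy())
    phi_star, res = circ_mean(phi)

    rc = r["r_center"].to_numpy()
    q = np.quantile(rc, [0.25, 0.5, 0.75])
    qidx = np.digitize(rc, q)
    rows = []
    for k in range(4):
        sub = phi[qidx == k]
        m, rl = circ_mean(sub) if sub.size else (np.nan, np.nan)
        rows.append({"quartile": k, "n": int(sub.size),
                     "circ_mean": m, "resultant": rl})
    by_q = pd.DataFrame(rows)

    xq = np.quantile(r["start_x"], [0.25, 0.5, 0.75])
    yq = np.quantile(r["start_y"], [0.25, 0.5, 0.75])
    xi = np.digitize(r["start_x"], xq)
    yi = np.digitize(r["start_y"], yq)
    cells = []
    for ix in range(4):
        for iy in range(4):
            sub = phi[(xi == ix) & (yi == iy)]
            m, rl = circ_mean(sub) if sub.size else (np.nan, np.nan)
            cells.append({"x_bin": ix, "y_bin": iy, "n": int(sub.size),
                          "circ_mean": m, "resultant": rl})
    by_pos = pd.DataFrame(cells)

    cen = phi[rc <= center_cm]
    if cen.size:
        cm, cr = circ_mean(cen)
        center = {"n": int(cen.size), "circ_mean": cm, "resultant": cr}
    else:
        center = {"n": 0, "circ_mean": np.nan, "resultant": np.nan}

    return PhiStats(phi_values=phi, phi_star=phi_star, resultant=res,
                    by_distance_quartile=by_q, by_position_bin=by_pos,
                    center_subset=center)


def expected_direction(phi_p, phi_star):
    """phi_E = phi_P + phi_star, canonical [0, 360)."""
    return canonical(np.asarray(phi_p, float) + phi_star)


def _window_direction(kin: pd.DataFrame, t0: float, t1: float, min_disp: float = 1e-3):
    seg = kin[(kin["t_ms"] >= t0) & (kin["t_ms"] <= t1)]
    if len(seg) < 2:
        return None
    dx = seg["screen_x"].iloc[-1] - seg["screen_x"].iloc[0]
    dy = seg["screen_y"].iloc[-1] - seg["screen_y"].iloc[0]
    if np.hypot(dx, dy) < min_disp:
        return None
    return float(np.degrees(np.arctan2(dy, dx)) % 360.0)


def trajectory_bias(kinematics: pd.DataFrame, t0: float, t1: float,
                    phi_t: float, reference_dir: float,
                    reference: str = "expected") -> BiasValue:
    """Bias B = wrap(phi_M - phi_T) / wrap(phi_ref - phi_T).

    phi_M is the net movement direction between the window's first and
    last hand samples. B = 1 means movement toward the reference
    direction, 0 toward the target, negative away from the reference.
    Undefined when the reference and target directions nearly coincide
    or the hand barely moved.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    denom = wrap_diff(reference_dir, phi_t)
    phi_m = _window_direction(kinematics, t0, t1)
    if phi_m is None or abs(denom) < BIAS_DENOM_EPS_DEG:
        return BiasValue(B=np.nan, reference=reference, t0_ms=t0, t1_ms=t1,
                         defined=False)
    return BiasValue(B=float(wrap_diff(phi_m, phi_t) / denom),
                     reference=reference, t0_ms=t0, t1_ms=t1)


def bias_summary(bias_values, rng=None, n_boot: int = N_BOOT):
    """Median bias with a bootstrap standard error of the median."""
    b = np.array([v.B for v in bias_values if v.defined and np.isfinite(v.B)])
    if b.size == 0:
        return {"n": 0, "median": np.nan, "se_median": np.nan}
    rng = rng or np.random.default_rng(0)
    meds = np.median(rng.choice(b, size=(n_boot, b.size), replace=True), axis=1)
    return {"n": int(b.size), "median": float(np.median(b)),
            "se_median": float(np.std(meds, ddof=1))}


def reach_latency(kinematics: pd.DataFrame, target_onset_time: float,
                  t_end: float | None = None):
    """Time from target onset to the hand speed first exceeding 8 cm/s.

    Speed comes from central differences of the sampled hand positions.
    Returns nan if the threshold is never crossed in the covered span.
    """
    kin = kinematics
    if t_end is not None:
        kin = kin[kin["t_ms"] <= t_end + 1e-9]
    kin = kin[kin["t_ms"] >= target_onset_time - 1e-9]
    kin = kin.drop_duplicates("t_ms")
    if len(kin) < 3:
        return float("nan")
    t = kin["t_ms"].to_numpy()
    x = kin["hand_x"].to_numpy()
    y = kin["hand_y"].to_numpy()
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy) * 1000.0  # cm/ms -> cm/s
    above = np.nonzero(speed > SPEED_THRESHOLD_CM_S)[0]
    if above.size == 0:
        return float("nan")
    return float(t[above[0]] - target_onset_time)


def measure_latencies(session, reaches: pd.DataFrame) -> pd.DataFrame:
    """Measured latency per reach, with the population-level 6-sd outlier
    rule applied (outliers and undefined latencies become NaN)."""
    kin = session.kinematics
    t = kin["t_ms"].to_numpy()
    lats = []
    for _, row in reaches.iterrows():
        i0 = np.searchsorted(t, row["target_onset_time"] - 1e-9)
        i1 = np.searchsorted(t, row["land_time"] + 1e-9)
        lats.append(reach_latency(kin.iloc[max(i0 - 1, 0):i1 + 1],
                                  row["target_onset_time"]))
    lats = np.asarray(lats, dtype=float)
    ok = np.isfinite(lats)
    if ok.sum() >= 3:
        mu, sd = lats[ok].mean(), lats[ok].std(ddof=1)
        if sd > 0:
            lats[ok & (np.abs(lats - mu) > LATENCY_OUTLIER_SD * sd)] = np.nan
    out = reaches.copy()
    out["latency_ms"] = lats
    return out


def latency_analyses(reaches: pd.DataFrame, phi_star: float,
                     expected_max_deg: float = 60.0,
                     unexpected_min_deg: float = 120.0) -> dict:
    """Expectedness effects on latency.

    Expectedness is |wrap_diff(phi_T, phi_E)| with phi_E = phi_P +
    phi_star. Reports the Pearson correlation (with its two-sided
    t-based p), per-class linear fits of latency against distance from
    the center, a Welch t-test comparing the expected-class slope with
    the unexpected-class slope, and mean latency differences in the
    0-20/20-40/40-60/60-100 percentile distance bins.
    """
    df = reaches.dropna(subset=["latency_ms"]).copy()
    phi_e = expected_direction(df["phi_p"].to_numpy(), phi_star)
    surprise = np.abs(wrap_diff(df["phi_t"].to_numpy(), phi_e))
    lat = df["latency_ms"].to_numpy()
    rc = df["r_center"].to_numpy()

    r, p = stats.pearsonr(surprise, lat) if len(df) >= 3 else (np.nan, np.nan)

    is_exp = surprise < expected_max_deg
    is_unexp = surprise > unexpected_min_deg
    out = {"r": float(r), "p": float(p), "n": int(len(df)),
           "n_expected": int(is_exp.sum()), "n_unexpected": int(is_unexp.sum())}

    def _slope(mask):
        if mask.sum() < 30:
            return None
        res = stats.linregress(rc[mask], lat[mask])
        return {"slope": float(res.slope), "se": float(res.stderr),
                "n": int(mask.sum())}
    fe, fu = _slope(is_exp), _slope(is_unexp)
    out["expected_fit"], out["unexpected_fit"] = fe, fu
    if fe and fu:
        t_stat = (fe["slope"] - fu["slope"]) / np.hypot(fe["se"], fu["se"])
        nu = (fe["se"] ** 2 + fu["se"] ** 2) ** 2 / (
            fe["se"] ** 4 / (fe["n"] - 2) + fu["se"] ** 4 / (fu["n"] - 2))
        p_slope = 2.0 * stats.t.sf(abs(t_stat), df=nu)
        out["slope_test"] = {"t": float(t_stat), "p": float(p_slope),
                             "expected_more_negative": bool(fe["slope"] < fu["slope"])}
    else:
        out["slope_test"] = None

    edges = np.percentile(rc, [0, 20, 40, 60, 100])
    bins = []
    for k in range(4):
        sel = (rc >= edges[k]) & (rc <= edges[k + 1] if k == 3 else rc < edges[k + 1])
        e_lat = lat[sel & is_exp]
        u_lat = lat[sel & is_unexp]
        bins.append({
            "bin": ["closest", "mid-close", "mid-far", "farthest"][k],
            "n_expected": int(e_lat.size), "n_unexpected": int(u_lat.size),
            "mean_diff_ms": float(e_lat.mean() - u_lat.mean())
            if e_lat.size and u_lat.size else np.nan,
        })
    out["distance_bins"] = bins
    return out
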