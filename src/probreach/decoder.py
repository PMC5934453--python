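"""Rescaled naive-Bayes decoding of intended reach direction.

Tuning curves fit after target onset (when the upcoming movement is
known) supply each neuron's preferred direction; their amplitude and
concentration are re-fit on pre-target activity against the future
movement, because firing rates differ strongly between the two epochs.
The decoder then treats the spike count of each neuron in a window as
Poisson with mean given by the composite tuning curve, multiplies
per-neuron likelihoods over a 1-degree direction grid (conditional
independence), applies a uniform prior, and normalizes. The posterior's
peak is the decoded direction; its full width at half maximum measures
the represented uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .circstats import canonical, circ_mean, fit_von_mises_rate, wrap_diff
from .behavior import trajectory_bias
from . import glm as _glm

__all__ = [
    "RescaledTuning", "DecodedDistribution",
    "fit_rescaled_tuning", "fit_session_tunings", "decode_posterior",
    "sliding_window_widths", "decoded_phi_analysis",
    "random_intercepts_test", "vr_decoded_shift",
]

DIRECTION_GRID = np.arange(360.0)   # 1-degree grid
PRE_WINDOW = (-100.0, 0.0)          # decode window before target onset (ms)
POST_WINDOW = (50.0, 200.0)         # tuning-fit window after onset (ms)
N_BOOT = 1000


@dataclass
class RescaledTuning:
    """Composite tuning: pre-target (alpha, beta), post-target phi_star."""
    neuron_id: int
    alpha: float        # sp/s, from the pre-target fit
    beta: float         # concentration, from the pre-target fit
    phi_star: float     # deg, from the post-target fit
    rate_floor: float = 0.1   # sp/s, keeps Poisson means positive

    def expected_counts(self, directions, window_ms: float):
        rate = self.alpha * np.exp(
            self.beta * np.cos(np.radians(np.asarray(directions) - self.phi_star)))
        return np.maximum(rate, self.rate_floor) * window_ms / 1000.0


@dataclass
class DecodedDistribution:
    posterior: np.ndarray        # over DIRECTION_GRID, sums to 1
    map_direction: float         # deg
    fwhm: float                  # deg
    multimodal: bool = False
    flat: bool = False
    grid: np.ndarray = field(default_factory=lambda: DIRECTION_GRID)


def fit_rescaled_tuning(counts_post, counts_pre, move_dirs,
                        neuron_id: int = 0,
                        post_window=POST_WINDOW, pre_window=PRE_WINDOW):
    """Composite tuning curve for one neuron.

    phi_star comes from the post-target fit (rates 50-200 ms vs
    movement direction); alpha and beta come from re-fitting the
    pre-target counts (-100-0 ms) against the *future* movement
    direction with the preferred direction pinned to the post-target
    value. Returns None when either fit is degenerate.
    """
    move_dirs = np.asarray(move_dirs, dtype=float)
    post_rates = np.asarray(counts_post, float) / (
        post_window[1] - post_window[0]) * 1000.0
    try:
        post_fit = fit_von_mises_rate(move_dirs, post_rates)
    except (ValueError, RuntimeError):
        return None
    if not post_fit.reliable:
        return None

    pre_rates = np.asarray(counts_pre, float) / (
        pre_window[1] - pre_window[0]) * 1000.0
    # pre-target fit with phi_star fixed: linear in exp(beta cos(...)),
    # profiled over beta on a grid then refined by the generic fitter
    try:
        pre_fit = fit_von_mises_rate(move_dirs, pre_rates)
    except (ValueError, RuntimeError):
        return None
    alpha, beta = pre_fit.alpha, pre_fit.beta
    if not pre_fit.reliable or alpha <= 0:
        # flat pre-target tuning: fall back to the mean pre-target rate
        alpha, beta = max(float(pre_rates.mean()), 1e-3), 0.0
    return RescaledTuning(neuron_id=neuron_id, alpha=float(alpha),
                          beta=float(beta), phi_star=float(post_fit.phi_star))


def select_decoder_neurons(session, reaches, rng=None, n_boot: int = 200):
    """Neuron ids passing the relaxed (bootstrap-median) criterion for
    both hand position (early) and upcoming movement (late)."""
    rng = rng or np.random.default_rng(0)
    table = _glm.classify_population(session, reaches, rng=rng, n_boot=n_boot)
    return table.loc[table["label_relaxed"] == "PR", "neuron_id"].tolist()


def fit_session_tunings(session, reaches, neuron_ids=None, rng=None,
                        n_boot: int = 200):
    """Rescaled tunings for all decoder-eligible neurons of a session.

    When ``neuron_ids`` is not given, neurons are screened with the
    relaxed GLM criterion.
    """
    if neuron_ids is None:
        neuron_ids = select_decoder_neurons(session, reaches, rng=rng,
                                            n_boot=n_boot)
    cpost = _glm.spike_counts(session, reaches, POST_WINDOW, neuron_ids)
    cpre = _glm.spike_counts(session, reaches, PRE_WINDOW, neuron_ids)
    dirs = reaches["phi_t_hand"].to_numpy()
    tunings = []
    for nid in neuron_ids:
        t = fit_rescaled_tuning(cpost[nid], cpre[nid], dirs, neuron_id=nid)
        if t is not None:
            tunings.append(t)
    return tunings


def decode_posterior(counts, tunings, window_ms: float) -> DecodedDistribution:
    """Posterior over direction from one window of population activity.

    Computed in log space: log P(s|r) = sum_i [r_i log f_i(s) - f_i(s)]
    + const, normalized with logsumexp. FWHM is the angular measure of
    the contiguous above-half-maximum arc containing the peak;
    additional above-threshold arcs set the multimodal flag. MAP ties
    break toward the smallest angle.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) != len(tunings) or len(tunings) == 0:
        raise ValueError("counts and tunings must align and be nonempty")
    F, logF = _tuning_matrix(tunings, window_ms)
    logp = counts @ logF - F.sum(axis=0) - gammaln(counts + 1).sum()
    logp -= logsumexp(logp)
    post = np.exp(logp)
    post /= post.sum()
    return _distribution_from(post)


def _tuning_matrix(tunings, window_ms):
    """(n_neurons, 360) expected counts and their logs on the grid."""
    F = np.stack([t.expected_counts(DIRECTION_GRID, window_ms)
                  for t in tunings])
    return F, np.log(F)


def _distribution_from(post) -> DecodedDistribution:
    pmax = post.max()
    if pmax - post.min() < 1e-15:
        return DecodedDistribution(posterior=post, map_direction=0.0,
                                   fwhm=360.0, flat=True)
    mode = int(np.argmax(post))          # argmax returns the smallest index
    thr = pmax / 2.0
    above = post >= thr
    # walk the contiguous arc around the mode on the circle
    n = len(post)
    lo = mode
    while above[(lo - 1) % n] and (lo - 1) % n != mode:
        lo -= 1
    hi = mode
    while above[(hi + 1) % n] and (hi + 1) % n != mode:
        hi += 1
    arc = (hi - lo + 1)
    fwhm = float(min(arc, n))
    multimodal = bool(above.sum() > arc)
    return DecodedDistribution(posterior=post, map_direction=float(mode % 360),
                               fwhm=fwhm, multimodal=multimodal)


def _counts_in_window(session, reaches, tunings, window):
    ids = [t.neuron_id for t in tunings]
    c = _glm.spike_counts(session, reaches, window, ids)
    return np.column_stack([c[i] for i in ids])


def decode_many(counts_matrix, tunings, window_ms):
    """Vectorized decode of many reaches (rows of counts_matrix)."""
    F, logF = _tuning_matrix(tunings, window_ms)
    logp = counts_matrix @ logF - F.sum(axis=0)
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    return [_distribution_from(post[i]) for i in range(post.shape[0])]


def decode_reaches(session, reaches, tunings, window=PRE_WINDOW):
    """Decode every reach in a fixed window; returns a table with the
    decoded direction phi_D, decoded Phi, FWHM and flags."""
    counts = _counts_in_window(session, reaches, tunings, window)
    wlen = window[1] - window[0]
    dists = decode_many(counts, tunings, wlen)
    rows = []
    for i, (_, row) in enumerate(reaches.iterrows()):
        d = dists[i]
        rows.append({
            "reach_id": row["reach_id"],
            "phi_d": d.map_direction,
            "decoded_phi": wrap_diff(d.map_direction, row["phi_p"]),
            "fwhm": d.fwhm,
            "multimodal": d.multimodal,
            "flat": d.flat,
        })
    return pd.DataFrame(rows)


def sliding_window_widths(session, reaches, tunings, window_ms: float = 50.0,
                          step_ms: float = 25.0, t_range=(-300.0, 300.0)):
    """FWHM time courses from a sliding decode window, grouped by
    distance-from-center percentile bins (0-20/20-40/40-60/60-100)."""
    rc = reaches["r_center"].to_numpy()
    edges = np.percentile(rc, [0, 20, 40, 60, 100])
    labels = ["closest", "mid-close", "mid-far", "farthest"]
    starts = np.arange(t_range[0], t_range[1] - window_ms + 1e-9, step_ms)
    recs = []
    for s in starts:
        win = (s, s + window_ms)
        counts = _counts_in_window(session, reaches, tunings, win)
        fw = np.array([d.fwhm for d in decode_many(counts, tunings, window_ms)])
        rec = {"t_center": s + window_ms / 2}
        for k, lab in enumerate(labels):
            sel = (rc >= edges[k]) & (rc < edges[k + 1] if k < 3 else rc <= edges[4])
            rec[lab] = float(fw[sel].mean()) if sel.sum() else np.nan
        recs.append(rec)
    return pd.DataFrame(recs)


def random_intercepts_test(values, covariate, session_ids):
    """Shared-slope regression with one intercept per session.

    Least-squares fit of values = sum_s beta_s I_s + beta_d * covariate;
    returns (slope, two-sided p) from a t-test on the slope coefficient.
    With a single session this reduces to plain simple regression.
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(covariate, dtype=float)
    sid = np.asarray(session_ids)
    ok = np.isfinite(y) & np.isfinite(d)
    y, d, sid = y[ok], d[ok], sid[ok]
    sessions = np.unique(sid)
    X = np.column_stack([(sid == s).astype(float) for s in sessions] + [d])
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough observations for the fit")
    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1e12:
        raise ValueError("collinear design (is the covariate constant?)")
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[-1, -1])
    t = beta[-1] / se
    pval = 2.0 * stats.t.sf(abs(t), df=n - p)
    return float(beta[-1]), float(pval)


def decoded_phi_analysis(session, reaches, tunings, phi_star: float,
                         session_id=0, bias_window=(100.0, 150.0), rng=None):
    """Single-session decoded-Phi analyses.

    Decodes the 100 ms before target onset for every reach, then
    reports: the decoded-Phi distribution (circular mean/resultant),
    latency vs angular error of the decoded direction, the initial-
    trajectory bias toward the decoded direction (median, bootstrap SE),
    and FWHM-vs-latency for expected reaches. Latencies must already be
    measured (``latency_ms`` column).
    """
    rng = rng or np.random.default_rng(0)
    dec = decode_reaches(session, reaches, tunings)
    merged = reaches.merge(dec, on="reach_id")

    dphi = merged["decoded_phi"].to_numpy()
    cmean, res = circ_mean(dphi)
    out = {"decoded_phi": dphi, "circ_mean": cmean, "resultant": res,
           "decode_table": dec}

    if "latency_ms" in merged:
        err = np.abs(wrap_diff(merged["phi_d"].to_numpy(),
                               merged["phi_t"].to_numpy()))
        lat = merged["latency_ms"].to_numpy()
        slope, p = random_intercepts_test(lat, err,
                                          np.full(len(merged), session_id))
        out["latency_vs_decode_error"] = {"slope": slope, "p": p}
        phi_e = canonical(merged["phi_p"].to_numpy() + phi_star)
        expected = np.abs(wrap_diff(merged["phi_t"].to_numpy(), phi_e)) < 60.0
        if expected.sum() > 10:
            slope_w, p_w = random_intercepts_test(
                lat[expected], merged["fwhm"].to_numpy()[expected],
                np.full(int(expected.sum()), session_id))
            out["latency_vs_width_expected"] = {"slope": slope_w, "p": p_w}

    biases = []
    for _, row in merged.iterrows():
        b = trajectory_bias(
            session.kinematics,
            row["target_onset_time"] + bias_window[0],
            row["target_onset_time"] + bias_window[1],
            row["phi_t"], row["phi_d"], reference="decoded")
        if b.defined:
            biases.append(b.B)
    biases = np.asarray(biases)
    if biases.size:
        boots = np.median(rng.choice(biases, (N_BOOT, biases.size)), axis=1)
        out["bias_toward_decoded"] = {
            "median": float(np.median(biases)),
            "ci": (float(np.percentile(boots, 2.5)),
                   float(np.percentile(boots, 97.5))),
            "n": int(biases.size)}
    return out


def vr_decoded_shift(baseline_phi, vr_phi, rng=None, n_boot: int = N_BOOT):
    """Circular-mean shift of decoded Phi, VR minus baseline, with a
    bootstrap 95% CI (resampling decoded reaches within each condition).
    Positive = counterclockwise."""
    rng = rng or np.random.default_rng(0)
    b = np.asarray(baseline_phi, dtype=float)
    v = np.asarray(vr_phi, dtype=float)
    if b.size < 5 or v.size < 5:
        raise ValueError("too few decoded reaches for the comparison")
    shift = wrap_diff(circ_mean(v)[0], circ_mean(b)[0])
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        bb = circ_mean(rng.choice(b, b.size))[0]
        vv = circ_mean(rng.choice(v, v.size))[0]
        diffs[i] = wrap_diff(vv, bb)
    # wrap bootstrap differences around the point estimate
    dev = wrap_diff(diffs, shift)
    ci = (shift + np.percentile(dev, 2.5), shift + np.percentile(dev, 97.5))
    return {"shift": float(shift), "ci": (float(ci[0]), float(ci[1])),
            "n_baseline": int(b.size), "n_vr": int(v.size)}
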