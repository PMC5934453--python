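"""Poisson GLM encoding analysis.

Spike counts per reach in a time window are modeled as
Y ~ Poisson(lambda), lambda = exp(X beta), where the design matrix
X = [1, theta_P, theta_UM, theta_PM, v_max] holds the expected rates
from k-NN smoothed maps of hand position, upcoming movement and
previous movement (each by itself), plus peak speed, z-scored per
training fold. Model value is the deviance-based pseudo-R^2, evaluated
with 5-fold cross-validation; covariate importance is the relative
pseudo-R^2 of the full model against the model with that covariate
removed. Neurons are classified as potential-response (PR: hand
position matters before target onset AND upcoming movement matters
after) or selected-response (SR: only upcoming movement matters) via
bootstrap confidence intervals on those quantities.

The IRLS fitter carries a tiny ridge penalty (1e-6, intercept excluded)
as a numerical stabilizer and uses step-halving; it is cross-checked
against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .circstats import fit_von_mises_rate, VonMisesTuning
from .smoothing import SmoothedMap, SmoothParams, GLM_SMOOTH, MAP_SMOOTH

__all__ = [
    "EARLY_WINDOW", "LATE_WINDOW", "MIN_RATE_SP_S",
    "spike_counts", "reach_covariates",
    "poisson_irls", "poisson_loglik", "pseudo_r2",
    "crossfit_covariates", "cv_pseudo_r2", "cv_relative_pseudo_r2",
    "GLMFit", "fit_poisson_glm",
    "estimate_pd", "estimate_preferred_position",
    "classify_neuron", "classify_population", "glm_timecourse",
]

EARLY_WINDOW = (-100.0, 50.0)   # ms relative to target onset (hand position)
LATE_WINDOW = (50.0, 200.0)     # ms relative to target onset (upcoming movement)
MIN_RATE_SP_S = 2.0             # inclusion: >= 2 sp/s in early OR late window
RIDGE = 1e-6
N_FOLDS = 5
N_BOOT = 1000


# ---------------------------------------------------------------- counts

def spike_counts(session, reaches: pd.DataFrame, window, neuron_ids=None):
    """Spike counts per (neuron, reach) in a window relative to target onset.

    Returns a dict neuron_id -> integer array aligned with ``reaches``.
    """
    t0, t1 = window
    onsets = reaches["target_onset_time"].to_numpy()
    spikes = session.spikes
    if neuron_ids is None:
        neuron_ids = session.neurons["neuron_id"].tolist()
    out = {}
    for nid, grp in spikes.groupby("neuron_id"):
        if nid not in set(neuron_ids):
            continue
        st = grp["t_ms"].to_numpy()
        lo = np.searchsorted(st, onsets + t0)
        hi = np.searchsorted(st, onsets + t1)
        out[nid] = (hi - lo).astype(int)
    for nid in neuron_ids:
        out.setdefault(nid, np.zeros(len(reaches), dtype=int))
    return out


def reach_covariates(session, reaches: pd.DataFrame):
    """Raw 2-D covariates per reach: hand position, upcoming movement
    vector, previous movement vector (hand frame), and peak speed.

    The previous movement is the preceding reach of the same trial;
    valid reaches (first-of-trial excluded) always have one.
    """
    full = session.reaches.set_index("reach_id")
    pos = reaches[["start_x", "start_y"]].to_numpy()
    ang = np.radians(reaches["phi_t_hand"].to_numpy())
    um = reaches["dist"].to_numpy()[:, None] * np.column_stack(
        [np.cos(ang), np.sin(ang)])
    prev_ids = reaches["reach_id"].to_numpy() - 1
    prev = full.reindex(prev_ids)
    pang = np.radians(prev["phi_t_hand"].to_numpy())
    pm = prev["dist"].to_numpy()[:, None] * np.column_stack(
        [np.cos(pang), np.sin(pang)])
    vmax = reaches["v_max"].to_numpy()
    return {"position": pos, "upcoming_movement": um,
            "previous_movement": pm, "v_max": vmax}


# ---------------------------------------------------------------- fitting

def poisson_loglik(y, lam):
    """Poisson log likelihood, summed (natural log)."""
    lam = np.clip(np.asarray(lam, dtype=float), 1e-12, None)
    y = np.asarray(y, dtype=float)
    return float(np.sum(y * np.log(lam) - lam - gammaln(y + 1)))


def poisson_irls(X, y, ridge: float = RIDGE, max_iter: int = 50,
                 tol: float = 1e-9):
    """Maximum-likelihood Poisson regression via Newton/IRLS.

    A ridge penalty on the non-intercept coefficients (the first column
    is assumed to be the intercept) stabilizes near-separable designs;
    step-halving guards against overshooting. Returns (beta, converged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    pen = np.full(p, ridge)
    pen[0] = 0.0
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8))

    def pll(b):
        eta = np.clip(X @ b, -30.0, 30.0)
        lam = np.exp(eta)
        return float(np.sum(y * eta - lam)) - 0.5 * float(np.sum(pen * b * b))

    ll = pll(beta)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        lam = np.exp(eta)
        grad = X.T @ (y - lam) - pen * beta
        H = (X * lam[:, None]).T @ X + np.diag(pen + 1e-12)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            ll_new = pll(beta + t * step)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return beta, converged


def pseudo_r2(y, lam, reference=None):
    """Deviance-based pseudo-R^2.

    1 - [logL(saturated) - logL(lam)] / [logL(saturated) - logL(ref)]
    with the mean model as the default reference. With a reduced-model
    lambda as the reference this is the relative pseudo-R^2 of the full
    model against the reduced one. Returns nan when the reference is
    itself saturated (zero denominator).
    """
    y = np.asarray(y, dtype=float)
    ll_sat = poisson_loglik(y, np.clip(y, 1e-12, None))
    ll_model = poisson_loglik(y, lam)
    if reference is None:
        reference = np.full_like(y, y.mean())
    ll_ref = poisson_loglik(y, reference)
    denom = ll_sat - ll_ref
    if abs(denom) < 1e-12:
        return float("nan")
    return 1.0 - (ll_sat - ll_model) / denom


# ------------------------------------------------------- cross-validation

def _fold_assignment(n, n_folds, rng):
    idx = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    for f, part in enumerate(np.array_split(idx, n_folds)):
        fold[part] = f
    return fold


def crossfit_covariates(counts, cov, fold, window_len_ms,
                        smooth: SmoothParams = GLM_SMOOTH):
    """Cross-fitted smoothed-map covariate columns.

    Each reach's theta_P / theta_UM / theta_PM is the k-NN map
    prediction using only reaches from the other folds (the map's
    neighbors come from the training folds only). Rates are counts
    scaled to sp/s. Returns the (n, 4) raw covariate matrix
    [theta_P, theta_UM, theta_PM, v_max].
    """
    n = len(counts)
    rates = np.asarray(counts, dtype=float) / window_len_ms * 1000.0
    theta = {k: np.empty(n) for k in
             ("position", "upcoming_movement", "previous_movement")}
    for f in np.unique(fold):
        tr = fold != f
        te = ~tr
        for key in theta:
            m = SmoothedMap(cov[key][tr], rates[tr], smooth, tag=key)
            theta[key][te] = m.predict(cov[key][te])
    return np.column_stack([theta["position"], theta["upcoming_movement"],
                            theta["previous_movement"], cov["v_max"]])


def _zscore_train(Xr, tr):
    mu = Xr[tr].mean(axis=0)
    sd = Xr[tr].std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (Xr - mu) / sd


def cv_lambda(Xraw, y, fold):
    """Held-out lambda-hat (and held-out mean-model reference) per row.

    Per fold: z-score with training statistics, fit by IRLS on the
    training rows, evaluate on the held-out rows.
    """
    n = len(y)
    lam = np.empty(n)
    ref = np.empty(n)
    for f in np.unique(fold):
        tr = fold != f
        te = ~tr
        Xz = _zscore_train(Xraw, tr)
        X = np.column_stack([np.ones(n), Xz])
        beta, _ = poisson_irls(X[tr], y[tr])
        lam[te] = np.exp(np.clip(X[te] @ beta, -30.0, 30.0))
        ref[te] = y[tr].mean()
    return lam, ref


def cv_pseudo_r2(Xraw, y, fold):
    lam, ref = cv_lambda(Xraw, y, fold)
    return pseudo_r2(y, lam, reference=np.clip(ref, 1e-12, None))


def cv_relative_pseudo_r2(Xfull, Xreduced, y, fold):
    lam_full, _ = cv_lambda(Xfull, y, fold)
    lam_red, _ = cv_lambda(Xreduced, y, fold)
    return pseudo_r2(y, lam_full, reference=lam_red)


@dataclass
class GLMFit:
    beta_full: np.ndarray
    lambda_hat: np.ndarray          # held-out, aligned with rows
    pseudo_r2_cv: float
    relative_r2: dict = field(default_factory=dict)   # covariate -> value
    single_r2: dict = field(default_factory=dict)     # covariate -> value
    converged: bool = True


COVARIATE_COLUMNS = {"position": 0, "upcoming_movement": 1,
                     "previous_movement": 2, "v_max": 3}


def fit_poisson_glm(Xraw, y, n_folds: int = N_FOLDS, rng=None) -> GLMFit:
    """Fit the full model plus its single-covariate and drop-one variants
    with cross-validated pseudo-R^2 values."""
    rng = rng or np.random.default_rng(0)
    y = np.asarray(y, dtype=float)
    fold = _fold_assignment(len(y), n_folds, rng)
    lam, ref = cv_lambda(Xraw, y, fold)
    fit = GLMFit(
        beta_full=poisson_irls(
            np.column_stack([np.ones(len(y)), _zscore_train(Xraw, np.ones(len(y), bool))]),
            y)[0],
        lambda_hat=lam,
        pseudo_r2_cv=pseudo_r2(y, lam, reference=np.clip(ref, 1e-12, None)),
    )
    for name, col in COVARIATE_COLUMNS.items():
        keep = [c for c in range(Xraw.shape[1]) if c != col]
        fit.relative_r2[name] = cv_relative_pseudo_r2(Xraw, Xraw[:, keep], y, fold)
        fit.single_r2[name] = cv_pseudo_r2(Xraw[:, [col]], y, fold)
    return fit


# ------------------------------------------------- tuning-curve estimates

def _mean_rates(counts, window):
    return np.asarray(counts, dtype=float) / (window[1] - window[0]) * 1000.0


def passes_inclusion(counts_early, counts_late):
    """At least two spikes per second in either the early or late window."""
    return (_mean_rates(counts_early, EARLY_WINDOW).mean() >= MIN_RATE_SP_S
            or _mean_rates(counts_late, LATE_WINDOW).mean() >= MIN_RATE_SP_S)


def estimate_pd(counts_late, cov, smooth: SmoothParams = GLM_SMOOTH,
                window=LATE_WINDOW) -> VonMisesTuning:
    """Position-corrected preferred direction.

    Rates in the late window have the position-related signal (a k-NN
    position map prediction in the same window) subtracted before the
    von Mises fit against movement direction.
    """
    rates = _mean_rates(counts_late, window)
    pos_map = SmoothedMap(cov["position"], rates, smooth, tag="position")
    theta_p = pos_map.predict(cov["position"])
    um = cov["upcoming_movement"]
    dirs = np.degrees(np.arctan2(um[:, 1], um[:, 0])) % 360.0
    return fit_von_mises_rate(dirs, rates - theta_p)


def estimate_preferred_position(counts_early, cov,
                                smooth: SmoothParams = GLM_SMOOTH,
                                window=EARLY_WINDOW) -> VonMisesTuning:
    """Preferred angular hand position in the early window, with the
    movement-related signal subtracted first."""
    rates = _mean_rates(counts_early, window)
    um_map = SmoothedMap(cov["upcoming_movement"], rates, smooth,
                         tag="upcoming_movement")
    theta_um = um_map.predict(cov["upcoming_movement"])
    pos = cov["position"]
    ang = np.degrees(np.arctan2(pos[:, 1], pos[:, 0])) % 360.0
    return fit_von_mises_rate(ang, rates - theta_um)


# ------------------------------------------------ batched bootstrap engine

def _batched_irls(X, y, w, ridge: float = RIDGE, iters: int = 15):
    """Newton/IRLS for many weighted Poisson regressions at once.

    X is (B, n, p) with the intercept in column 0, y and the 0/1 training
    weights w are (B, n). Step magnitudes are capped for stability (no
    per-system step-halving in the batched path). Returns beta (B, p).
    """
    B, n, p = X.shape
    pen = np.full(p, ridge)
    pen[0] = 0.0
    beta = np.zeros((B, p))
    beta[:, 0] = np.log(np.clip((w * y).sum(1) / w.sum(1), 1e-8, None))
    eye_pen = np.diag(pen + 1e-9)
    for _ in range(iters):
        eta = np.clip(np.einsum("bnp,bp->bn", X, beta, optimize=True), -30, 30)
        lam = np.exp(eta)
        grad = np.einsum("bnp,bn->bp", X, w * (y - lam), optimize=True) - pen * beta
        H = np.einsum("bnp,bn,bnq->bpq", X, w * lam, X, optimize=True) + eye_pen
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - singular batch
            step = np.stack([np.linalg.lstsq(H[b], grad[b], rcond=None)[0]
                             for b in range(B)])
        nrm = np.linalg.norm(step, axis=1, keepdims=True)
        step *= np.minimum(1.0, 5.0 / np.maximum(nrm, 1e-12))
        beta = beta + step
    return beta


def _batched_cv_lambda(Xraw, y, fold, n_folds):
    """Held-out lambda and mean-model reference for a batch of data sets.

    Xraw (B, n, j) raw covariates, y (B, n), fold (B, n) assignments.
    """
    B, n, _ = Xraw.shape
    lam = np.empty((B, n))
    ref = np.empty((B, n))
    for f in range(n_folds):
        w = (fold != f).astype(float)
        wsum = w.sum(1, keepdims=True)
        mu = (w[..., None] * Xraw).sum(1, keepdims=True) / wsum[..., None]
        var = (w[..., None] * (Xraw - mu) ** 2).sum(1, keepdims=True) / wsum[..., None]
        sd = np.sqrt(var)
        sd = np.where(sd < 1e-12, 1.0, sd)
        Xz = (Xraw - mu) / sd
        X = np.concatenate([np.ones((B, n, 1)), Xz], axis=2)
        beta = _batched_irls(X, y, w)
        eta = np.clip(np.einsum("bnp,bp->bn", X, beta, optimize=True), -30, 30)
        te = fold == f
        lam[te] = np.exp(eta)[te]
        ref_b = (w * y).sum(1) / w.sum(1)
        ref[te] = np.broadcast_to(ref_b[:, None], (B, n))[te]
    return lam, np.clip(ref, 1e-12, None)


def _batched_pseudo_r2(y, lam, ref):
    """Row-wise pseudo-R^2 for (B, n) batches; ref may be reduced-model lam."""
    ys = np.clip(y, 1e-12, None)
    ll_sat = (y * np.log(ys) - y).sum(1)
    ll_mod = (y * np.log(np.clip(lam, 1e-12, None)) - lam).sum(1)
    ll_ref = (y * np.log(np.clip(ref, 1e-12, None)) - ref).sum(1)
    denom = ll_sat - ll_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - (ll_sat - ll_mod) / denom
    out[np.abs(denom) < 1e-12] = np.nan
    return out


def _boot_window_quantities(Xkey, y, n_boot, rng, n_folds=N_FOLDS,
                            batch: int = 250):
    """Bootstrap (single-covariate R^2, relative R^2) for one window.

    Resamples reaches with replacement; each replicate gets a fresh
    5-fold split. Xkey has the window's key covariate in column 0.
    Returns an (n_boot, 2) array.
    """
    n = len(y)
    out = np.empty((n_boot, 2))
    done = 0
    while done < n_boot:
        B = min(batch, n_boot - done)
        idx = rng.integers(0, n, size=(B, n))
        r = rng.random((B, n))
        order = np.argsort(r, axis=1)
        fold = np.empty((B, n), dtype=int)
        np.put_along_axis(fold, order,
                          np.broadcast_to(np.arange(n) * n_folds // n, (B, n)),
                          axis=1)
        Xb = Xkey[idx]
        yb = y[idx]
        lam_s, ref_s = _batched_cv_lambda(Xb[:, :, [0]], yb, fold, n_folds)
        lam_f, _ = _batched_cv_lambda(Xb, yb, fold, n_folds)
        lam_r, _ = _batched_cv_lambda(Xb[:, :, 1:], yb, fold, n_folds)
        out[done:done + B, 0] = _batched_pseudo_r2(yb, lam_s, ref_s)
        out[done:done + B, 1] = _batched_pseudo_r2(yb, lam_f, lam_r)
        done += B
    return out


# ----------------------------------------------------------- classification

def _window_quantities(Xraw, y, fold):
    """(single-covariate R^2, relative R^2) for one window's key covariate.

    Xraw columns: [theta_key, theta_other..., v_max]; the key covariate
    is column 0 by construction in classify_neuron.
    """
    single = cv_pseudo_r2(Xraw[:, [0]], y, fold)
    rel = cv_relative_pseudo_r2(Xraw, Xraw[:, 1:], y, fold)
    return single, rel


def classify_neuron(counts_early, counts_late, cov, rng=None,
                    n_boot: int = N_BOOT, n_folds: int = N_FOLDS):
    """PR / SR / neither classification with bootstrap significance.

    A covariate "matters" in a window when (a) the single-covariate
    model has significant cross-validated predictive power and (b) the
    full model beats the model without it — both judged by the lower
    bound of a bootstrap 95% CI being above zero (reaches resampled with
    replacement). The relaxed variant requires only the bootstrap median
    to be positive. PR = position matters early AND movement matters
    late; SR = movement matters late AND position does not matter early.
    """
    rng = rng or np.random.default_rng(0)
    y_e = np.asarray(counts_early, dtype=float)
    y_l = np.asarray(counts_late, dtype=float)
    n = len(y_e)
    fold = _fold_assignment(n, n_folds, rng)

    Xe = crossfit_covariates(counts_early, cov, fold,
                             EARLY_WINDOW[1] - EARLY_WINDOW[0])
    Xl = crossfit_covariates(counts_late, cov, fold,
                             LATE_WINDOW[1] - LATE_WINDOW[0])
    # reorder so the window's key covariate is column 0
    Xe_key = Xe[:, [0, 1, 2, 3]]                   # position first (early)
    Xl_key = Xl[:, [1, 0, 2, 3]]                   # upcoming movement first (late)

    boots = np.concatenate([
        _boot_window_quantities(Xe_key, y_e, n_boot, rng, n_folds),
        _boot_window_quantities(Xl_key, y_l, n_boot, rng, n_folds),
    ], axis=1)   # columns: single_e, rel_e, single_l, rel_l

    lo = np.nanpercentile(boots, 2.5, axis=0)
    med = np.nanmedian(boots, axis=0)
    pos_early_95 = bool(lo[0] > 0 and lo[1] > 0)
    mov_late_95 = bool(lo[2] > 0 and lo[3] > 0)
    pos_early_50 = bool(med[0] > 0 and med[1] > 0)
    mov_late_50 = bool(med[2] > 0 and med[3] > 0)

    def label(pos_e, mov_l):
        if mov_l and pos_e:
            return "PR"
        if mov_l:
            return "SR"
        return "neither"

    point_e = _window_quantities(Xe_key, y_e, fold)
    point_l = _window_quantities(Xl_key, y_l, fold)
    return {
        "label": label(pos_early_95, mov_late_95),
        "label_relaxed": label(pos_early_50, mov_late_50),
        "position_early": {"single_r2": point_e[0], "relative_r2": point_e[1],
                           "ci_lower": (lo[0], lo[1]), "median": (med[0], med[1])},
        "movement_late": {"single_r2": point_l[0], "relative_r2": point_l[1],
                          "ci_lower": (lo[2], lo[3]), "median": (med[2], med[3])},
    }


def classify_population(session, reaches, rng=None, n_boot: int = N_BOOT,
                        neuron_ids=None):
    """Run inclusion + classification for every neuron; returns a table."""
    rng = rng or np.random.default_rng(0)
    cov = reach_covariates(session, reaches)
    ce = spike_counts(session, reaches, EARLY_WINDOW, neuron_ids)
    cl = spike_counts(session, reaches, LATE_WINDOW, neuron_ids)
    rows = []
    for nid in ce:
        if not passes_inclusion(ce[nid], cl[nid]):
            rows.append({"neuron_id": nid, "included": False,
                         "label": "excluded", "label_relaxed": "excluded"})
            continue
        res = classify_neuron(ce[nid], cl[nid], cov, rng=rng, n_boot=n_boot)
        rows.append({"neuron_id": nid, "included": True,
                     "label": res["label"],
                     "label_relaxed": res["label_relaxed"],
                     "pos_early_rel_r2": res["position_early"]["relative_r2"],
                     "mov_late_rel_r2": res["movement_late"]["relative_r2"]})
    return pd.DataFrame(rows).sort_values("neuron_id").reset_index(drop=True)


# --------------------------------------------------------------- timecourse

def glm_timecourse(session, reaches, neuron_id, t_range=(-400.0, 400.0),
                   window_len: float = 150.0, step: float = 25.0, rng=None):
    """Relative pseudo-R^2 traces for the position and upcoming-movement
    covariates over sliding windows around target onset (maps refit per
    window)."""
    rng = rng or np.random.default_rng(0)
    cov = reach_covariates(session, reaches)
    starts = np.arange(t_range[0], t_range[1] - window_len + 1e-9, step)
    rows = []
    n = len(reaches)
    fold = _fold_assignment(n, N_FOLDS, rng)
    for s in starts:
        win = (s, s + window_len)
        y = spike_counts(session, reaches, win, [neuron_id])[neuron_id].astype(float)
        if y.sum() < 5:
            rows.append({"t_center": s + window_len / 2,
                         "position": np.nan, "upcoming_movement": np.nan})
            continue
        X = crossfit_covariates(y, cov, fold, window_len)
        rel_pos = cv_relative_pseudo_r2(X, X[:, [1, 2, 3]], y, fold)
        rel_um = cv_relative_pseudo_r2(X, X[:, [0, 2, 3]], y, fold)
        rows.append({"t_center": s + window_len / 2,
                     "position": rel_pos, "upcoming_movement": rel_um})
    return pd.DataFrame(rows)
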