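"""Naive-Bayes decoder: posteriors, FWHM, regressions, VR shift."""

import numpy as np
import pytest
from scipy.special import gammaln

from probreach import decoder
from probreach.decoder import (DIRECTION_GRID, RescaledTuning,
                               decode_posterior, random_intercepts_test,
                               vr_decoded_shift)


def brute_force_posterior(counts, tunings, window_ms):
    """Direct product of Poisson pmfs at every 1-degree direction."""
    post = np.ones(360)
    for s in range(360):
        p = 1.0
        for r, tun in zip(counts, tunings):
            f = tun.expected_counts(np.array([float(s)]), window_ms)[0]
            p *= np.exp(-f) * f ** r / np.exp(gammaln(r + 1))
        post[s] = p
    return post / post.sum()


def make_tuning(nid, alpha, beta, phi):
    return RescaledTuning(neuron_id=nid, alpha=alpha, beta=beta, phi_star=phi)


class TestDecodePosterior:
    def test_single_neuron_zero_spikes_closed_form(self):
        tun = make_tuning(1, alpha=20.0, beta=2.0, phi=90.0)
        d = decode_posterior([0], [tun], window_ms=100.0)
        f = tun.expected_counts(DIRECTION_GRID, 100.0)
        expected = np.exp(-f) / np.exp(-f).sum()
        assert d.posterior == pytest.approx(expected, abs=1e-12)
        # with zero spikes the posterior is minimized at the PD
        assert np.argmin(d.posterior) == 90

    def test_three_neuron_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            tunings = [make_tuning(i, rng.uniform(5, 30),
                                   rng.uniform(0.5, 3.0),
                                   rng.uniform(0, 360)) for i in range(3)]
            counts = rng.poisson(2.0, 3)
            d = decode_posterior(counts, tunings, window_ms=100.0)
            oracle = brute_force_posterior(counts, tunings, 100.0)
            assert np.max(np.abs(d.posterior - oracle)) < 1e-10

    def test_posterior_normalized(self):
        rng = np.random.default_rng(1)
        tunings = [make_tuning(i, 10.0, 1.0, i * 36.0) for i in range(10)]
        for _ in range(10):
            counts = rng.poisson(1.0, 10)
            d = decode_posterior(counts, tunings, 50.0)
            assert d.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_flat_tunings_give_flat_posterior(self):
        tunings = [make_tuning(i, 10.0, 0.0, 0.0) for i in range(5)]
        d = decode_posterior([1, 2, 0, 1, 3], tunings, 100.0)
        assert d.flat
        assert d.fwhm == 360.0

    def test_fwhm_decreases_with_concentration(self):
        widths = []
        for beta in (0.5, 1.0, 2.0, 4.0):
            tun = make_tuning(1, 20.0, beta, 180.0)
            counts = [int(tun.expected_counts(np.array([180.0]), 100.0)[0])]
            widths.append(decode_posterior(counts, [tun], 100.0).fwhm)
        assert widths == sorted(widths, reverse=True)

    def test_fwhm_shrinks_with_population_size(self):
        rng = np.random.default_rng(2)
        med = []
        for n in (10, 50, 200):
            widths = []
            for _ in range(20):
                pds = rng.uniform(0, 360, n)
                tunings = [make_tuning(i, 10.0, 1.5, p)
                           for i, p in enumerate(pds)]
                lam = np.array([t.expected_counts(np.array([45.0]), 100.0)[0]
                                for t in tunings])
                counts = rng.poisson(lam)
                widths.append(decode_posterior(counts, tunings, 100.0).fwhm)
            med.append(np.median(widths))
        assert med[0] >= med[1] >= med[2]

    def test_map_attains_maximum_and_ties_break_low(self):
        tun = make_tuning(1, 20.0, 2.0, 90.0)
        d = decode_posterior([5], [tun], 100.0)
        assert d.posterior[int(d.map_direction)] == d.posterior.max()


class TestRescaledTuning:
    def test_identical_pre_post_recovers_same_curve(self):
        rng = np.random.default_rng(3)
        dirs = rng.uniform(0, 360, 2000)
        lam = 6.0 * np.exp(1.2 * np.cos(np.radians(dirs - 200.0)))
        counts = rng.poisson(lam * 0.15)   # identical tuning both epochs
        tun = decoder.fit_rescaled_tuning(counts, counts, dirs,
                                          post_window=(50.0, 200.0),
                                          pre_window=(-150.0, 0.0))
        assert tun is not None
        assert abs(tun.phi_star - 200.0) < 5.0
        assert tun.beta == pytest.approx(1.2, abs=0.3)
        assert tun.alpha == pytest.approx(6.0, rel=0.2)

    def test_pr_composite_peak_below_posttarget_peak(self, pr_session):
        from probreach import glm
        s, valid = pr_session["session"], pr_session["valid"]
        sp = pr_session["specs"][0]
        cpost = glm.spike_counts(s, valid, decoder.POST_WINDOW,
                                 [sp.neuron_id])[sp.neuron_id]
        cpre = glm.spike_counts(s, valid, decoder.PRE_WINDOW,
                                [sp.neuron_id])[sp.neuron_id]
        dirs = valid["phi_t_hand"].to_numpy()
        tun = decoder.fit_rescaled_tuning(cpost, cpre, dirs,
                                          neuron_id=sp.neuron_id)
        assert tun is not None
        from probreach.circstats import fit_von_mises_rate
        post_fit = fit_von_mises_rate(dirs, cpost / 0.15)
        peak_pre = tun.alpha * np.exp(tun.beta)
        peak_post = post_fit.alpha * np.exp(post_fit.beta)
        assert peak_pre < peak_post


class TestRandomInterceptsModel:
    def test_exact_recovery_two_sessions(self):
        d = np.concatenate([np.linspace(0, 10, 50), np.linspace(0, 10, 50)])
        sid = np.repeat([0, 1], 50)
        y = 2.0 * d + np.where(sid == 0, 5.0, 11.0)
        slope, p = random_intercepts_test(y, d, sid)
        assert slope == pytest.approx(2.0, abs=1e-10)
        assert p < 1e-12

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        n = 120
        d = rng.normal(size=n)
        sid = rng.integers(0, 3, n)
        y = 0.7 * d + sid * 2.0 + rng.normal(size=n)
        slope, p = random_intercepts_test(y, d, sid)
        X = np.column_stack([(sid == s).astype(float) for s in range(3)] + [d])
        ref = sm.OLS(y, X).fit()
        assert slope == pytest.approx(ref.params[-1], abs=1e-10)
        assert p == pytest.approx(ref.pvalues[-1], rel=1e-6)

    def test_null_slope_type_i_error_calibrated(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 1000
        for _ in range(reps):
            d = rng.normal(size=60)
            sid = rng.integers(0, 2, 60)
            y = sid * 3.0 + rng.normal(size=60)
            _, p = random_intercepts_test(y, d, sid)
            hits += p < 0.05
        assert 0.03 < hits / reps < 0.07

    def test_collinear_covariate_rejected(self):
        with pytest.raises(ValueError):
            random_intercepts_test(np.arange(10.0), np.ones(10),
                                   np.zeros(10))


class TestVrShift:
    def test_identical_distributions_ci_straddles_zero(self):
        rng = np.random.default_rng(6)
        base = np.degrees(rng.vonmises(np.radians(150), 2.0, 400))
        vr = np.degrees(rng.vonmises(np.radians(150), 2.0, 400))
        res = vr_decoded_shift(base, vr, rng=np.random.default_rng(0))
        assert res["ci"][0] < 0 < res["ci"][1]

    def test_planted_rotation_recovered(self):
        rng = np.random.default_rng(7)
        base = np.degrees(rng.vonmises(np.radians(150), 2.0, 400))
        vr = np.degrees(rng.vonmises(np.radians(120), 2.0, 400))
        res = vr_decoded_shift(base, vr, rng=np.random.default_rng(0))
        assert res["shift"] == pytest.approx(-30.0, abs=8.0)
        assert res["ci"][1] < 0


class TestEndToEndDecoding:
    def test_decoded_phi_matches_behavioral_phi(self, pr_session):
        s, valid = pr_session["session"], pr_session["valid"]
        ids = [sp.neuron_id for sp in pr_session["specs"]]
        tunings = decoder.fit_session_tunings(s, valid, neuron_ids=ids)
        assert len(tunings) >= 20
        dec = decoder.decode_reaches(s, valid, tunings)
        from probreach.circstats import circ_mean, wrap_diff
        from probreach.behavior import phi_statistics
        m, _ = circ_mean(dec["decoded_phi"].to_numpy())
        stats = phi_statistics(valid)
        assert abs(wrap_diff(m, stats.phi_star)) < 15.0

    def test_pretarget_width_narrower_far_from_center(self, pr_session):
        s, valid = pr_session["session"], pr_session["valid"]
        ids = [sp.neuron_id for sp in pr_session["specs"]]
        tunings = decoder.fit_session_tunings(s, valid, neuron_ids=ids)
        dec = decoder.decode_reaches(s, valid, tunings)
        merged = valid.merge(dec, on="reach_id")
        rc = merged["r_center"].to_numpy()
        fw = merged["fwhm"].to_numpy()
        close = fw[rc <= np.percentile(rc, 20)]
        far = fw[rc >= np.percentile(rc, 60)]
        assert np.median(far) < np.median(close)

    def test_sliding_widths_shrink_after_onset(self, pr_session):
        s, valid = pr_session["session"], pr_session["valid"]
        ids = [sp.neuron_id for sp in pr_session["specs"]]
        tunings = decoder.fit_session_tunings(s, valid, neuron_ids=ids)
        sw = decoder.sliding_window_widths(s, valid.head(150), tunings)
        pre = sw[(sw["t_center"] > -150) & (sw["t_center"] < 0)]
        post = sw[sw["t_center"] > 100]
        # target information collapses the position dependence: the
        # closest-bin width shrinks after onset and the distance bins
        # converge (the farthest bin was already narrow before onset)
        assert post["closest"].mean() < pre["closest"].mean()
        gap_pre = (pre["closest"] - pre["farthest"]).mean()
        gap_post = (post["closest"] - post["farthest"]).mean()
        assert gap_post < 0.5 * gap_pre
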