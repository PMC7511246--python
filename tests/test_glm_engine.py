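"""Design construction, OLS / AR-IRLS / mixed-effects solvers, joint test."""
import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox

from nirsglm.glm_engine import (
    DesignMatrix,
    StimulusDesign,
    ar_irls_fit,
    build_ss_design,
    build_task_design,
    canonical_hrf,
    hotelling_joint,
    me_ar_irls_fit,
    ols_fit,
    _whiten,
)
from nirsglm.probe_signal import HemoScan
from nirsglm.synthetic_data import generate_noise_scan, make_events, NoiseSpec

FS = 7.8125


def _block_stim():
    onsets = 30.0 + np.arange(5) * 55.0
    return StimulusDesign(onsets=onsets, durations=np.full(5, 25.0))


def _ar1(rng, n, phi, innov_sd=1.0):
    e = rng.normal(0, innov_sd, n)
    x = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = phi * acc + e[i]
        x[i] = acc
    return x


class TestTaskDesign:
    def test_empty_condition_rejected(self):
        stim = StimulusDesign(onsets=np.zeros(0), durations=np.zeros(0))
        with pytest.raises(ValueError, match="empty condition"):
            build_task_design(stim, 1000, FS)

    def test_events_beyond_scan_rejected(self):
        stim = StimulusDesign(onsets=[290.0], durations=[25.0])
        with pytest.raises(ValueError, match="beyond scan end"):
            build_task_design(stim, int(300 * FS), FS)

    def test_five_blocks_give_five_lobes_with_unit_peak(self):
        n = int(300 * FS)
        x, labels = build_task_design(_block_stim(), n, FS)
        assert labels == ["task"]
        col = x[:, 0]
        assert col.max() == pytest.approx(1.0)
        # five distinct response lobes: five upward crossings of half max
        up = np.sum((col[1:] >= 0.5) & (col[:-1] < 0.5))
        assert up == 5

    def test_convolution_matches_bruteforce_sum(self):
        n = 100
        stim = StimulusDesign(onsets=[2.0], durations=[3.0])
        x, _ = build_task_design(stim, n, FS)
        box = np.zeros(n)
        i0, i1 = int(round(2.0 * FS)), int(round(5.0 * FS))
        box[i0:i1] = 1.0
        t_kernel = np.arange(0, 40.0, 1.0 / FS)
        hrf = canonical_hrf(t_kernel)
        brute = np.zeros(n)
        for i in range(n):  # direct convolution sum
            for j in range(len(hrf)):
                if 0 <= i - j < n:
                    brute[i] += hrf[j] * box[i - j]
        brute /= np.abs(brute).max()
        np.testing.assert_allclose(x[:, 0], brute, atol=1e-10)


@pytest.fixture(scope="module")
def noise_scan(geometry):
    events = make_events("rest", 300.0, 11)
    return generate_noise_scan(NoiseSpec(), events, 11, geometry)


class TestSSDesign:
    @pytest.fixture()
    def scan(self, noise_scan):
        return noise_scan

    def test_both_mode_all_channels_gives_16_raw_columns(self, scan, geometry):
        x, labels = build_ss_design(scan, geometry, mode="both", decorrelate=False)
        assert x.shape[1] == 16
        assert len(labels) == 16

    def test_hbo_mode_single_nearest_gives_one_column(self, scan, geometry):
        ld = int(geometry.ld_indices()[0])
        x, _ = build_ss_design(
            scan, geometry, ld_channel=ld, mode="HbO2", n_nearest=1, decorrelate=False
        )
        assert x.shape[1] == 1

    def test_decorrelated_block_orthonormal_with_same_span(self, scan, geometry):
        raw, _ = build_ss_design(scan, geometry, mode="both", decorrelate=False)
        dec, _ = build_ss_design(scan, geometry, mode="both", decorrelate=True)
        gram = dec.T @ dec
        np.testing.assert_allclose(gram, np.eye(dec.shape[1]), atol=1e-8)
        # span equality: projecting raw onto dec leaves no residual
        resid = raw - dec @ (dec.T @ raw)
        assert np.abs(resid).max() < 1e-8 * np.abs(raw).max()

    def test_too_many_nearest_rejected(self, scan, geometry):
        with pytest.raises(ValueError, match="only 8"):
            build_ss_design(
                scan, geometry, ld_channel=int(geometry.ld_indices()[0]),
                mode="HbO2", n_nearest=9,
            )


class TestOLS:
    def _design(self, n=400):
        x, labels = build_task_design(
            StimulusDesign(onsets=[5.0, 25.0], durations=[5.0, 5.0]), n, FS
        )
        return DesignMatrix(xtask=x, task_labels=labels, fs=FS)

    def test_noiseless_recovery_is_exact(self):
        dm = self._design()
        x, _ = dm.full()
        beta0 = np.array([2.0, 0.5])
        y = x @ beta0
        scan = HemoScan(y[:, None], y[:, None], fs=FS)
        res = ols_fit(scan, dm)["HbO2"][0]
        np.testing.assert_allclose(res.beta, beta0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        dm = self._design()
        x, _ = dm.full()
        y = rng.standard_normal(400)
        scan = HemoScan(y[:, None], y[:, None], fs=FS)
        res = ols_fit(scan, dm)["HbO2"][0]
        oracle = np.linalg.inv(x.T @ x) @ x.T @ y
        np.testing.assert_allclose(res.beta, oracle, atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal((100, 1))
        dm = DesignMatrix(
            xtask=np.hstack([x, x]), task_labels=["a", "b"], fs=FS
        )
        scan = HemoScan(rng.standard_normal((100, 1)), rng.standard_normal((100, 1)), fs=FS)
        with pytest.raises(ValueError, match="rank deficient"):
            ols_fit(scan, dm)


class TestARIRLS:
    def test_white_noise_behaves_like_ols(self, rng):
        dm = TestOLS()._design(n=600)
        y = rng.standard_normal(600)
        scan = HemoScan(y[:, None], y[:, None], fs=FS)
        res_ar = ar_irls_fit(scan, dm)["HbO2"][0]
        res_ols = ols_fit(scan, dm)["HbO2"][0]
        # small selected order, near-identity whitening
        assert len(res_ar.ar_coefficients) <= 3
        se = np.sqrt(np.diag(res_ols.cov)[:2])
        assert np.all(np.abs(res_ar.beta_task - res_ols.beta_task) < 2 * se)

    def test_ar1_coefficient_recovered_and_beta_unbiased(self, rng):
        n = 2000
        x, labels = build_task_design(
            StimulusDesign(onsets=30 + np.arange(4) * 60.0, durations=np.full(4, 25.0)),
            n, FS,
        )
        dm = DesignMatrix(xtask=x, task_labels=labels, fs=FS)
        beta0 = 1.5
        noise = _ar1(rng, n, 0.8, innov_sd=0.6)
        y = beta0 * x[:, 0] + noise
        scan = HemoScan(y[:, None], y[:, None], fs=FS)
        res = ar_irls_fit(scan, dm)["HbO2"][0]
        assert res.ar_coefficients[0] == pytest.approx(0.8, abs=0.05)
        se = np.sqrt(res.cov[0, 0])
        assert abs(res.beta_task[0] - beta0) < 3 * se

    def test_whitened_residuals_pass_ljung_box(self):
        # exactly-AR(2) noise: whitening by the fitted model leaves residuals
        # that Ljung-Box accepts at the 1% level in >= 95% of simulations
        n = 1500
        phi = np.array([0.7, 0.2])
        x, labels = build_task_design(
            StimulusDesign(onsets=[30.0, 90.0], durations=[25.0, 25.0]), n, FS
        )
        dm = DesignMatrix(xtask=x, task_labels=labels, fs=FS)
        xf, _ = dm.full()
        passes = 0
        n_sim = 40
        for s in range(n_sim):
            rng = np.random.default_rng(500 + s)
            e = rng.standard_normal(n)
            noise = np.empty(n)
            a1 = a2 = 0.0
            for i in range(n):
                v = phi[0] * a1 + phi[1] * a2 + e[i]
                noise[i] = v
                a2, a1 = a1, v
            y = 0.5 * x[:, 0] + noise
            scan = HemoScan(y[:, None], y[:, None], fs=FS)
            res = ar_irls_fit(scan, dm)["HbO2"][0]
            resid = y - xf @ res.beta
            white = _whiten(resid, res.ar_coefficients)
            lb = acorr_ljungbox(white, lags=[20], return_df=True)
            if float(lb.lb_pvalue.iloc[0]) > 0.01:
                passes += 1
        assert passes / n_sim >= 0.95

    def test_scale_equivariance_all_solvers(self, rng):
        n = 500
        x, labels = build_task_design(
            StimulusDesign(onsets=[20.0, 45.0], durations=[10.0, 10.0]), n, FS
        )
        z = np.linalg.qr(rng.standard_normal((n, 2)))[0]
        y = rng.standard_normal((n, 3)) + 0.3 * _ar1(rng, n, 0.9)[:, None]
        c = 7.3
        for solver in ("ols", "ar_irls", "me"):
            if solver == "me":
                res1, _ = me_ar_irls_fit(
                    HemoScan(y, y.copy(), fs=FS), x, z, fs=FS, task_labels=labels
                )
                res2, _ = me_ar_irls_fit(
                    HemoScan(c * y, c * y.copy(), fs=FS), x, z, fs=FS, task_labels=labels
                )
                r1, r2 = res1["HbO2"][0], res2["HbO2"][0]
            else:
                dm = DesignMatrix(xtask=x, task_labels=labels, fs=FS)
                fit = ols_fit if solver == "ols" else ar_irls_fit
                r1 = fit(HemoScan(y, y.copy(), fs=FS), dm)["HbO2"][0]
                r2 = fit(HemoScan(c * y, c * y.copy(), fs=FS), dm)["HbO2"][0]
            np.testing.assert_allclose(r2.beta_task, c * r1.beta_task, rtol=1e-6)
            np.testing.assert_allclose(r2.t, r1.t, rtol=1e-6)
            np.testing.assert_allclose(r2.p, r1.p, rtol=1e-6)

    def test_null_p_uniform_under_white_noise(self, rng):
        # pooled over 2000 independent channels, p is U(0,1) for OLS and AR-IRLS
        n = 600
        x, labels = build_task_design(
            StimulusDesign(onsets=[10.0, 40.0], durations=[5.0, 5.0]), n, FS
        )
        dm = DesignMatrix(xtask=x[:, :1], task_labels=[labels[0]], fs=FS)
        y = rng.standard_normal((n, 2000))
        scan = HemoScan(y, y.copy(), fs=FS)
        for fit in (ols_fit, ar_irls_fit):
            res = fit(scan, dm, chromophores=("HbO2",))["HbO2"]
            p = np.array([r.p[0] for r in res])
            assert stats.kstest(p, "uniform").pvalue > 0.01
        # mixed-effects solver: pooled over 50 independent 20-channel probes
        z = np.linalg.qr(rng.standard_normal((n, 3)))[0]
        ps = []
        for probe in range(50):
            yb = rng.standard_normal((n, 20))
            sub = HemoScan(yb, yb.copy(), fs=FS)
            res, _ = me_ar_irls_fit(
                sub, x[:, :1], z, fs=FS, task_labels=[labels[0]],
                chromophores=("HbO2",),
            )
            ps += [r.p[0] for r in res["HbO2"]]
        assert stats.kstest(np.array(ps), "uniform").pvalue > 0.01


class TestMixedEffects:
    def _setup(self, rng, n=300, n_ch=6, m=3, sigma_gamma=0.5, noise_sd=0.1,
               shared_gamma=None):
        x, labels = build_task_design(
            StimulusDesign(onsets=[8.0, 22.0], durations=[5.0, 5.0]), n, FS
        )
        z = np.linalg.qr(rng.standard_normal((n, m)))[0]
        ys = np.empty((n, n_ch))
        gammas = np.empty((n_ch, m))
        for ch in range(n_ch):
            g = shared_gamma if shared_gamma is not None else rng.normal(0, sigma_gamma, m)
            gammas[ch] = g
            ys[:, ch] = 0.8 * x[:, 0] + z @ g + rng.normal(0, noise_sd, n)
        scan = HemoScan(ys, ys.copy(), fs=FS)
        return scan, x, z, labels, gammas

    def test_no_penalty_limit_equals_ar_irls_with_appended_columns(self, rng):
        scan, x, z, labels, _ = self._setup(rng)
        me_res, states = me_ar_irls_fit(
            scan, x, z, fs=FS, task_labels=labels, max_outer=0
        )
        dm = DesignMatrix(
            xtask=x, task_labels=labels, fs=FS,
            xshort=z, short_labels=["SS0", "SS1", "SS2"],
        )
        ar_res = ar_irls_fit(scan, dm)
        assert not np.isfinite(states["HbO2"].sigma)
        for chrom in ("HbO2", "Hb"):
            for a, b in zip(me_res[chrom], ar_res[chrom]):
                np.testing.assert_allclose(a.beta, b.beta, atol=1e-6)

    def test_sigma_recovery_within_35pct(self):
        # Gamma ~ N(0, 0.25) across 22 channels; median recovered sigma over
        # 50 replicates lands within 35% of the true 0.5
        sigmas = []
        for rep in range(50):
            rng = np.random.default_rng(900 + rep)
            scan, x, z, labels, _ = self._setup(rng, n_ch=22, sigma_gamma=0.5)
            _, states = me_ar_irls_fit(scan, x, z, fs=FS, task_labels=labels,
                                       chromophores=("HbO2",))
            sigmas.append(states["HbO2"].sigma)
        assert abs(np.median(sigmas) - 0.5) < 0.35 * 0.5

    def test_global_physiology_gives_lower_gamma_variance_than_unpooled(self):
        # identical Gamma in every channel: pooling shrinks the spread of
        # per-channel estimates below the unpooled AR-IRLS spread
        me_spread, plain_spread = [], []
        for rep in range(10):
            rng = np.random.default_rng(40 + rep)
            shared = np.array([0.15, -0.1, 0.05])
            scan, x, z, labels, _ = self._setup(
                rng, n_ch=12, shared_gamma=shared, noise_sd=0.4
            )
            me_res, _ = me_ar_irls_fit(scan, x, z, fs=FS, task_labels=labels,
                                       chromophores=("HbO2",))
            dm = DesignMatrix(xtask=x, task_labels=labels, fs=FS,
                              xshort=z, short_labels=["a", "b", "c"])
            ar_res = ar_irls_fit(scan, dm, chromophores=("HbO2",))
            me_g = np.array([r.beta_short for r in me_res["HbO2"]])
            ar_g = np.array([r.beta_short for r in ar_res["HbO2"]])
            me_spread.append(me_g.var(axis=0).mean())
            plain_spread.append(ar_g.var(axis=0).mean())
        assert np.mean(me_spread) < np.mean(plain_spread)

    def test_shrinkage_monotone_in_prior_scale(self, rng):
        from nirsglm.glm_engine import _ar_irls_single

        scan, x, z, labels, _ = self._setup(rng, n_ch=2)
        xfull = np.hstack([x, z, np.ones((len(x), 1))])
        st = _ar_irls_single(scan.hbo[:, 0], xfull, max_ar_order=16)
        mask = np.zeros(xfull.shape[1])
        mask[x.shape[1]: x.shape[1] + z.shape[1]] = 1.0
        norms = []
        for sigma in (10.0, 1.0, 0.3, 0.1, 0.03):
            pen = np.diag(mask / sigma)
            a = np.vstack([st["aw"], pen])
            b = np.concatenate([st["bw"], np.zeros(xfull.shape[1])])
            beta, *_ = np.linalg.lstsq(a, b, rcond=None)
            norms.append(np.linalg.norm(beta[x.shape[1]: x.shape[1] + z.shape[1]]))
        assert all(n2 <= n1 + 1e-12 for n1, n2 in zip(norms, norms[1:]))

    def test_fewer_than_two_ss_regressors_rejected(self, rng):
        scan, x, z, labels, _ = self._setup(rng)
        with pytest.raises(ValueError, match="at least 2 SS"):
            me_ar_irls_fit(scan, x, z[:, :1], fs=FS, task_labels=labels)


class TestHotellingJoint:
    def _null_results(self, rng, n_draws=2000, n=80):
        x, labels = build_task_design(
            StimulusDesign(onsets=[2.0, 6.0], durations=[1.5, 1.5]), n, FS
        )
        dm = DesignMatrix(xtask=x[:, :1], task_labels=[labels[0]], fs=FS)
        scan = HemoScan(
            rng.standard_normal((n, n_draws)), rng.standard_normal((n, n_draws)), fs=FS
        )
        return ols_fit(scan, dm)

    def test_diagonal_case_is_sum_of_squared_ts(self, rng):
        res = self._null_results(rng, n_draws=5)
        for hbo, hbr in zip(res["HbO2"], res["Hb"]):
            t2, _ = hotelling_joint(hbo, hbr)
            assert t2 == pytest.approx(hbo.t[0] ** 2 + hbr.t[0] ** 2, rel=1e-10)

    def test_matches_direct_quadratic_form(self, rng):
        res = self._null_results(rng, n_draws=3)
        hbo, hbr = res["HbO2"][0], res["Hb"][0]
        b = np.array([hbo.beta_task[0], hbr.beta_task[0]])
        c = np.diag([hbo.cov[0, 0], hbr.cov[0, 0]])
        t2, _ = hotelling_joint(hbo, hbr)
        assert t2 == pytest.approx(float(b @ np.linalg.inv(c) @ b), rel=1e-10)

    def test_null_joint_p_uniform(self, rng):
        res = self._null_results(rng)
        ps = np.array(
            [hotelling_joint(a, b)[1] for a, b in zip(res["HbO2"], res["Hb"])]
        )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_singular_covariance_rejected(self, rng):
        res = self._null_results(rng, n_draws=1)
        hbo = res["HbO2"][0]
        bad = res["Hb"][0]
        bad.cov = bad.cov * 0.0
        with pytest.raises(ValueError, match="singular"):
            hotelling_joint(hbo, bad)
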