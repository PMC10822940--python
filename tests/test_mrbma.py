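import numpy as np
import pytest
from scipy import integrate, stats

from mrcluster.gwas_io import LDReference
from mrcluster.mrbma import (
    BMAConfig,
    InsufficientJointInstrumentsError,
    JointInstrumentMatrix,
    _log_ml,
    build_joint_matrix,
    diagnose,
    mip_and_mace,
    model_posteriors,
    run_bma,
)
from mrcluster.synthdata import ScenarioConfig, simulate_multivariable
from mrcluster.calibration import _matrix_from_panels
from conftest import panel, variant


def toy_matrix(seed=0, J=20, d=3, theta=(0.5, 0.0, 0.0), noise=0.1):
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.2, 0.05, size=(J, d))
    by = bx @ np.array(theta) + rng.normal(0, noise, J)
    return JointInstrumentMatrix(
        [f"rs{i}" for i in range(J)], [f"e{j}" for j in range(d)],
        bx, np.full((J, d), 0.02), by, np.full(J, noise),
    )


class TestModelPosteriors:
    def test_normalization_and_mip_identities(self):
        m = toy_matrix()
        post, est = model_posteriors(m, BMAConfig())
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)
        mip, mace = mip_and_mace(post, est, m.d)
        for j in range(m.d):
            expected_mip = sum(pp for s, pp in post.items() if j in s)
            assert mip[j] == pytest.approx(expected_mip, abs=1e-12)
            expected_mace = sum(
                pp * est[s][sorted(s).index(j)] for s, pp in post.items() if j in s
            )
            assert mace[j] == pytest.approx(expected_mace, abs=1e-12)
        assert np.all((mip >= 0) & (mip <= 1))

    def test_sigma_to_zero_limit_recovers_prior(self):
        """As σ² → 0 every model's marginal likelihood coincides, so the
        posterior is proportional to the inclusion prior alone."""
        m = toy_matrix()
        cfg = BMAConfig(prior_sigma2=1e-12, prior_p=0.1)
        post, _ = model_posteriors(m, cfg)
        d = m.d
        p = 0.1
        prior = {s: p ** len(s) * (1 - p) ** (d - len(s)) for s in post}
        z = sum(prior.values())
        for s, pp in post.items():
            assert pp == pytest.approx(prior[s] / z, rel=1e-4)

    def test_one_dimensional_bayes_factor_quadrature_oracle(self):
        """For d=1 the closed-form marginal likelihood matches numeric
        integration of the Gaussian likelihood against the N(0, σ²) prior."""
        rng = np.random.default_rng(7)
        J, sigma2 = 12, 0.5
        x = rng.normal(0.3, 0.1, J)
        y = 0.4 * x + rng.normal(0, 0.2, J)
        xs = (x / np.linalg.norm(x))[:, None]

        def integrand(theta):
            return np.exp(-0.5 * np.sum((y - xs[:, 0] * theta) ** 2) + 0.5 * y @ y) \
                * stats.norm.pdf(theta, 0, np.sqrt(sigma2))

        bf_quad, _ = integrate.quad(integrand, -20, 20)
        log_bf = _log_ml(y, xs, sigma2) - (-0.5 * y @ y)
        assert np.exp(log_bf) == pytest.approx(bf_quad, rel=1e-8)

    def test_relabeling_permutes_pp(self):
        m = toy_matrix(seed=3)
        post1, _ = model_posteriors(m, BMAConfig())
        perm = [2, 0, 1]  # new column j is old column perm[j]
        m2 = JointInstrumentMatrix(
            m.variant_ids, [m.exposure_ids[p] for p in perm],
            m.beta_x[:, perm], m.se_x[:, perm], m.beta_y, m.se_y,
        )
        post2, _ = model_posteriors(m2, BMAConfig())
        inverse = {old: new for new, old in enumerate(perm)}
        for s, pp in post1.items():
            mapped = frozenset(inverse[j] for j in s)
            assert post2[mapped] == pytest.approx(pp, rel=1e-9)

    def test_max_model_size_respected(self):
        m = toy_matrix()
        post, _ = model_posteriors(m, BMAConfig(max_model_size=1))
        assert all(len(s) == 1 for s in post)

    def test_exhaustive_vs_stochastic_mip_agreement(self):
        cfg_s = ScenarioConfig(seed=21, J=60, n_exposures=8, true_subset=(0, 1),
                               exposure_corr=0.5, theta_subset=0.3)
        panels, outcome, _ = simulate_multivariable(cfg_s)
        m = _matrix_from_panels(panels, outcome)
        post_e, est_e = model_posteriors(m, BMAConfig(search="exhaustive"))
        post_s, est_s = model_posteriors(
            m, BMAConfig(search="stochastic", n_iter=30_000, seed=5))
        mip_e, _ = mip_and_mace(post_e, est_e, 8)
        mip_s, _ = mip_and_mace(post_s, est_s, 8)
        assert np.max(np.abs(mip_e - mip_s)) < 0.02


class TestMipMaceDefinition:
    def test_worked_example(self):
        post = {frozenset({0}): 0.6, frozenset({1}): 0.1,
                frozenset({0, 1}): 0.2, frozenset(): 0.1}
        est = {frozenset({0}): np.array([0.5]), frozenset({1}): np.array([0.3]),
               frozenset({0, 1}): np.array([0.4, 0.1]), frozenset(): np.array([])}
        mip, mace = mip_and_mace(post, est, 2)
        assert mip[0] == pytest.approx(0.8) and mip[1] == pytest.approx(0.3)
        assert mace[0] == pytest.approx(0.6 * 0.5 + 0.2 * 0.4)

    def test_excluded_exposure_zero(self):
        post = {frozenset({0}): 1.0}
        est = {frozenset({0}): np.array([0.5])}
        mip, mace = mip_and_mace(post, est, 2)
        assert mip[1] == 0.0 and mace[1] == 0.0


class TestDiagnostics:
    def test_perfect_fit_no_removals(self):
        m = toy_matrix(noise=1e-8)
        res = run_bma(m, BMAConfig())
        assert res.removed_variants == [] and res.rerun is None

    def test_planted_outlier_flagged_and_rerun(self):
        m = toy_matrix(seed=5, J=30, noise=0.05)
        m.beta_y[4] += 8 * m.se_y[4]
        res = run_bma(m, BMAConfig())
        assert "rs4" in res.removed_variants
        assert res.rerun is not None
        assert len(res.rerun.posteriors) > 0

    def test_infinite_threshold_removes_nothing(self):
        m = toy_matrix(seed=5, J=30, noise=0.05)
        m.beta_y[4] += 8 * m.se_y[4]
        post, _ = model_posteriors(m, BMAConfig())
        diag = diagnose(m, post, BMAConfig(q_outlier_threshold=np.inf))
        # Cook's-distance flags may remain; the q rule itself fires nowhere
        assert all((q <= np.inf).all() for q in diag["q"].values())
        cfg = BMAConfig(q_outlier_threshold=np.inf)
        # with both rules disabled nothing is flagged
        diag2 = diagnose(m, post, cfg)
        q_flagged = {i for model, q in diag2["q"].items()
                     for i in np.flatnonzero(q > cfg.q_outlier_threshold)}
        assert q_flagged == set()


class TestBuildJointMatrix:
    @staticmethod
    def make_panels():
        e1 = panel("e1", [variant("rs1", pval=1e-8),
                          variant("rs2", pval=1e-7, pos=30_000_000),
                          variant("rs3", pval=0.5, pos=60_000_000),
                          variant("rs4", pval=1e-6, pos=90_000_000),
                          variant("rs5", pval=1e-6, pos=120_000_000)])
        e2 = panel("e2", [variant("rs1", pval=0.3, beta=0.05),
                          variant("rs2", pval=1e-9),
                          variant("rs3", pval=1e-8, pos=60_000_000),
                          variant("rs4", pval=0.2, beta=0.04, pos=90_000_000),
                          variant("rs5", pval=0.4, beta=0.03, pos=120_000_000)])
        out = panel("out", [variant(f"rs{i}", beta=0.02, pval=0.01,
                                    pos=(1 + 30 * (i - 1)) * 10**6)
                            for i in range(1, 6)])
        return e1, e2, out

    def test_union_and_fill(self):
        e1, e2, out = self.make_panels()
        m = build_joint_matrix([e1, e2], out, LDReference(), p_thresholds=1e-5)
        # union: rs1,rs2,rs4,rs5 from e1; rs2,rs3 from e2 -> all five
        assert sorted(m.variant_ids) == ["rs1", "rs2", "rs3", "rs4", "rs5"]
        assert m.beta_x.shape == (5, 2)
        # each variant appears once even when selected for both exposures
        assert len(set(m.variant_ids)) == len(m.variant_ids)

    def test_variant_missing_from_exposure_dropped(self):
        e1, e2, out = self.make_panels()
        e2_short = panel("e2", [v for v in e2.variants if v.variant_id != "rs4"])
        m = build_joint_matrix([e1, e2_short], out, LDReference(), p_thresholds=1e-5)
        assert "rs4" not in m.variant_ids
        assert ("rs4", "missing from an exposure panel") in m.dropped

    def test_insufficient_instruments(self):
        e1, e2, out = self.make_panels()
        out_short = panel("out", out.variants[:3])
        with pytest.raises(InsufficientJointInstrumentsError):
            build_joint_matrix([e1, e2], out_short, LDReference(), p_thresholds=1e-5)
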