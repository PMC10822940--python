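import numpy as np
import pytest

from mrcluster.estimators import MRFit, ivw_mre
from mrcluster.sensitivity import (
    LooResult,
    PressoRecord,
    SensitivityReport,
    SteigerRecord,
    cochran_q,
    leave_one_out,
    presso,
    robustness_verdict,
    steiger_filter,
)
from mrcluster.synthdata import ScenarioConfig, simulate_tsmr_pair
from mrcluster.calibration import harmonized_from_truth
from conftest import hi


class TestCochranQ:
    def test_homogeneous_ratios(self):
        hs = [hi(f"v{i}", bx, 0.01, 0.5 * bx, 0.05) for i, bx in enumerate([0.1, 0.2, 0.3])]
        q, df, p = cochran_q(hs, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_hand_arithmetic(self):
        hs = [hi("a", 1, 0.1, 1, 1), hi("b", 1, 0.1, 3, 1)]
        q, df, _ = cochran_q(hs, 2.0)
        assert q == pytest.approx(2.0) and df == 1

    def test_duplication_doubles_q(self, random_instruments):
        hs = random_instruments(J=6, seed=1)
        theta = ivw_mre(hs).estimate
        q1, _, _ = cochran_q(hs, theta)
        q2, _, _ = cochran_q(hs + hs, theta)
        assert q2 == pytest.approx(2 * q1)

    def test_order_invariance(self, random_instruments):
        hs = random_instruments(J=6, seed=2)
        assert cochran_q(hs, 0.4)[0] == pytest.approx(cochran_q(hs[::-1], 0.4)[0])

    def test_needs_two(self):
        with pytest.raises(ValueError):
            cochran_q([hi()], 0.5)


class TestLeaveOneOut:
    def test_identical_instruments_stable(self):
        hs = [hi(f"v{i}", 0.2, 0.01, 0.1, 0.02) for i in range(5)]
        res = leave_one_out(hs)
        assert not res.unstable
        assert all(v == pytest.approx(0.5) for v in res.estimates.values())

    def test_dominating_outlier_flips_sign(self):
        # one huge-|bx| instrument with opposite-direction effect dominates the
        # weighted fit; dropping it flips the estimate's sign
        hs = [hi(f"v{i}", 0.1, 0.01, 0.05, 0.5) for i in range(4)]
        hs.append(hi("dom", 5.0, 0.01, -5.0, 0.05))
        full = ivw_mre(hs)
        res = leave_one_out(hs)
        assert np.sign(res.estimates["dom"]) != np.sign(full.estimate)
        assert res.unstable

    def test_too_few_marked_not_applicable(self):
        res = leave_one_out([hi("a"), hi("b", bx=0.3)])
        assert res.reason.startswith("not applicable")
        assert not res.unstable

    def test_permutation_only_permutes_rows(self, random_instruments):
        hs = random_instruments(J=5, seed=3)
        a = leave_one_out(hs).estimates
        b = leave_one_out(hs[::-1]).estimates
        assert set(a) == set(b)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)


class TestSteiger:
    def test_formula_arithmetic(self):
        # t = 10 on exposure, t = 1 on outcome, n = 10,000 each
        h = hi("rs1", bx=0.1, sx=0.01, by=0.01, sy=0.01)
        rec, kept = steiger_filter([h], n_exp=10_000, n_out=10_000)
        assert rec.r2_exp["rs1"] == pytest.approx(100 / (100 + 9998), rel=1e-12)
        assert rec.r2_out["rs1"] == pytest.approx(1 / (1 + 9998), rel=1e-12)
        assert rec.direction == "forward" and kept and not rec.removed_ids

    def test_swapping_panels_flips_direction(self, random_instruments):
        hs = random_instruments(J=6, seed=4)
        fwd, _ = steiger_filter(hs, 50_000, 50_000)
        swapped = [hi(h.variant_id, h.beta_out, h.se_out, h.beta_exp, h.se_exp)
                   for h in hs]
        rev, _ = steiger_filter(swapped, 50_000, 50_000)
        assert {fwd.direction, rev.direction} == {"forward", "reverse"}

    def test_reverse_variant_removed_and_idempotent(self):
        good = hi("g", bx=0.2, sx=0.01, by=0.01, sy=0.01)
        bad = hi("b", bx=0.01, sx=0.01, by=0.2, sy=0.01)
        rec, kept = steiger_filter([good, bad], 10_000, 10_000)
        assert rec.removed_ids == ["b"]
        rec2, kept2 = steiger_filter(kept, 10_000, 10_000)
        assert rec2.removed_ids == [] and kept2 == kept

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            steiger_filter([hi()], n_exp=2, n_out=100)


class TestPresso:
    @staticmethod
    def null_instruments(seed=11, J=20, theta=0.3):
        e, o, _ = simulate_tsmr_pair(ScenarioConfig(seed=seed, J=J, theta=theta))
        return harmonized_from_truth(e, o)

    def test_null_data_global_p_large(self):
        rec = presso(self.null_instruments(), n_sim=500, seed=1)
        assert rec.global_pval > 0.05
        assert rec.outlier_ids == []

    def test_shifted_instrument_detected(self):
        hs = self.null_instruments()
        h = hs[3]
        hs[3] = hi(h.variant_id, h.beta_exp, h.se_exp,
                   h.beta_out + 10 * h.se_out, h.se_out)
        rec = presso(hs, n_sim=500, seed=2)
        assert h.variant_id in rec.outlier_ids
        assert rec.global_pval < 0.05
        assert rec.corrected_estimate is not None
        assert rec.distortion_pval is not None

    def test_too_few_instruments(self):
        with pytest.raises(ValueError):
            presso(self.null_instruments()[:3], n_sim=10, seed=0)


def fit(method, estimate, pval=0.01):
    return MRFit(method, estimate, abs(estimate) / 2 + 0.01, pval, 5)


def fits_with_signs(primary=0.5, egger_est=0.4, wm=0.45, wmode=0.42):
    return {
        "ivw_mre": fit("ivw_mre", primary),
        "egger": fit("egger", egger_est),
        "weighted_median": fit("weighted_median", wm),
        "weighted_mode": fit("weighted_mode", wmode),
    }


class TestVerdict:
    def test_all_consistent_is_robust(self):
        v, _ = robustness_verdict(fits_with_signs(), SensitivityReport(), "significant")
        assert v == "robust"

    def test_potential_tier_sign_flip_rejected(self):
        v, reason = robustness_verdict(fits_with_signs(egger_est=-0.1),
                                       SensitivityReport(), "potential")
        assert v == "rejected" and "sign" in reason

    def test_significant_tier_sign_flip_downgraded_to_caution(self):
        v, _ = robustness_verdict(fits_with_signs(egger_est=-0.1),
                                  SensitivityReport(), "significant")
        assert v == "caution"

    def test_loo_instability_rejects(self):
        rep = SensitivityReport(loo=LooResult({}, {}, True))
        v, reason = robustness_verdict(fits_with_signs(), rep, "significant")
        assert v == "rejected" and "leave-one-out" in reason

    def test_outlier_corrected_sign_change_rejects(self):
        rep = SensitivityReport(
            presso=PressoRecord(10.0, 0.001, ["rs9"], {}, -0.2, 0.01))
        v, _ = robustness_verdict(fits_with_signs(), rep, "significant")
        assert v == "rejected"

    def test_steiger_reverse_rejects(self):
        rep = SensitivityReport(
            steiger=SteigerRecord("reverse", 0.2, {}, {}, []))
        v, _ = robustness_verdict(fits_with_signs(), rep, "potential")
        assert v == "rejected"

    def test_egger_intercept_only_cautions(self):
        rep = SensitivityReport(egger_intercept={"estimate": 0.1, "se": 0.01,
                                                 "pval": 0.001})
        v, reason = robustness_verdict(fits_with_signs(), rep, "significant")
        assert v == "caution" and "intercept" in reason

    def test_pure_function(self):
        rep = SensitivityReport()
        fits = fits_with_signs()
        assert robustness_verdict(fits, rep, "potential") == \
            robustness_verdict(fits, rep, "potential")
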