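import numpy as np
import pytest

from mrcluster.gwas_io import LDReference
from mrcluster.instruments import (
    HarmonizedInstrument,
    clump,
    f_statistic,
    harmonize,
    select_instruments,
    usable,
)
from conftest import panel, variant


class TestFStatistic:
    @pytest.mark.parametrize("beta,se,expected", [(0.1, 0.01, 100.0), (0.0, 0.05, 0.0),
                                                  (0.03, 0.01, 9.0)])
    def test_values(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


class TestSelectInstruments:
    def test_all_criteria_met(self):
        p = panel("x", [variant("rs1", pval=1e-6, beta=0.2, se=0.02, eaf=0.3)])
        [rec] = select_instruments(p, 1e-5)
        assert rec.selected and rec.f_stat == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "kwargs,threshold,reason",
        [
            # metabolite threshold is stricter than microbiota's
            (dict(pval=1e-6), 5e-8, "p-threshold"),
            (dict(eaf=0.005), 1e-5, "MAF"),
            (dict(beta=0.05, se=0.02), 1e-5, "weak instrument (F)"),
        ],
    )
    def test_first_failing_criterion_recorded(self, kwargs, threshold, reason):
        p = panel("x", [variant("rs1", **{**dict(pval=1e-8, beta=0.2, se=0.02, eaf=0.3),
                                          **kwargs})])
        [rec] = select_instruments(p, threshold)
        assert not rec.selected and rec.rejection_reason == reason

    def test_criterion_order_is_p_then_maf_then_f(self):
        # fails all three; p-threshold is reported because it is checked first
        p = panel("x", [variant("rs1", pval=0.5, eaf=0.001, beta=0.01, se=0.02)])
        [rec] = select_instruments(p, 1e-5)
        assert rec.rejection_reason == "p-threshold"

    def test_missing_eaf_skips_maf_check(self):
        p = panel("x", [variant("rs1", pval=1e-8, eaf=None)])
        [rec] = select_instruments(p, 1e-5)
        assert rec.selected

    def test_bad_threshold(self):
        p = panel("x", [variant("rs1")])
        with pytest.raises(ValueError):
            select_instruments(p, 1.5)


def selected(panel_obj, thr=1e-4):
    return [r for r in select_instruments(panel_obj, thr) if r.selected]


class TestClump:
    def test_greedy_rule(self):
        p = panel("x", [
            variant("rsA", pval=1e-8, pos=1_000_000),
            variant("rsB", pval=1e-6, pos=1_050_000),  # 50 kb from A, r2 0.5
            variant("rsC", pval=1e-5, pos=1_100_000),  # r2 below threshold
        ])
        ld = LDReference({("rsA", "rsB"): 0.5, ("rsA", "rsC"): 0.0005})
        kept = clump(selected(p, 1e-4), ld)
        assert kept == ["rsA", "rsC"]

    def test_window_checked_before_ld(self):
        p = panel("x", [variant("rsA", pval=1e-8, chrom="1"),
                        variant("rsB", pval=1e-6, chrom="2")])
        ld = LDReference({("rsA", "rsB"): 0.9})
        assert clump(selected(p), ld) == ["rsA", "rsB"]

    def test_tie_break_lexicographic(self):
        p = panel("x", [variant("rsB", pval=1e-8, pos=1_000_000),
                        variant("rsA", pval=1e-8, pos=1_010_000)])
        ld = LDReference({("rsA", "rsB"): 0.9})
        assert clump(selected(p), ld) == ["rsA"]

    def test_single_variant_unchanged(self):
        p = panel("x", [variant("rsA")])
        assert clump(selected(p), LDReference()) == ["rsA"]

    def test_empty_input(self):
        assert clump([], LDReference()) == []

    def test_output_independence_certified(self, rng):
        """Every retained same-chromosome pair within the window has r2 < r2_max."""
        J = 40
        variants = [variant(f"rs{i:02d}", pval=float(rng.uniform(1e-9, 1e-5)),
                            chrom=str(1 + i % 3), pos=1_000_000 + 500_000 * (i // 3))
                    for i in range(J)]
        pairs = {}
        ids = [v.variant_id for v in variants]
        for i in range(J):
            for j in range(i + 1, J):
                if rng.random() < 0.3:
                    pairs[(ids[i], ids[j])] = float(rng.uniform(0, 1))
        ld = LDReference(pairs)
        p = panel("x", variants)
        kept = clump(selected(p), ld)
        lookup = {v.variant_id: v for v in variants}
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                va, vb = lookup[a], lookup[b]
                if va.chrom == vb.chrom and abs(va.pos - vb.pos) <= 10_000_000:
                    assert ld.r2(a, b) < 0.001


class TestHarmonize:
    def make(self, exp_alleles=("A", "G"), out_alleles=("A", "G"),
             beta_exp=0.1, beta_out=-0.05, eaf_out=0.4):
        exp = panel("e", [variant("rs1", *exp_alleles, beta=beta_exp)])
        out = panel("o", [variant("rs1", *out_alleles, beta=beta_out, eaf=eaf_out)])
        return harmonize(selected(exp), out)

    def test_aligned(self):
        [h] = self.make()
        assert h.action == "aligned" and h.beta_out == -0.05

    def test_flipped_negates_beta_and_reflects_eaf(self):
        [h] = self.make(out_alleles=("G", "A"))
        assert h.action == "flipped"
        assert h.beta_out == pytest.approx(0.05)
        assert h.eaf_out == pytest.approx(0.6)

    def test_palindromic_dropped(self):
        [h] = self.make(exp_alleles=("A", "T"), out_alleles=("A", "T"))
        assert h.action == "dropped_palindromic"

    def test_palindromic_outcome_side_dropped(self):
        [h] = self.make(out_alleles=("C", "G"), exp_alleles=("C", "A"))
        assert h.action == "dropped_palindromic"

    def test_incompatible_alleles_dropped(self):
        [h] = self.make(out_alleles=("A", "C"))
        assert h.action == "dropped_incompatible"

    def test_missing_dropped(self):
        exp = panel("e", [variant("rs1"), variant("rs2", pos=2_000_000)])
        out = panel("o", [variant("rs1")])
        actions = {h.variant_id: h.action for h in harmonize(selected(exp), out)}
        assert actions == {"rs1": "aligned", "rs2": "dropped_missing"}

    def test_dropped_records_excluded_from_usable(self):
        exp = panel("e", [variant("rs1", "A", "T")])
        out = panel("o", [variant("rs1", "A", "T")])
        assert usable(harmonize(selected(exp), out)) == []

    def test_involution(self, rng):
        """Flipping every outcome record's alleles and beta sign leaves the
        harmonized beta_out values unchanged."""
        flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
        exp_vs, out_vs, out_flipped = [], [], []
        for i in range(12):
            ea, oa = ("A", "G") if i % 2 else ("T", "C")
            b_out = float(rng.normal(0, 0.1))
            exp_vs.append(variant(f"rs{i}", ea, oa, pos=(i + 1) * 10**6))
            out_vs.append(variant(f"rs{i}", ea, oa, beta=b_out, pos=(i + 1) * 10**6))
            out_flipped.append(variant(f"rs{i}", oa, ea, beta=-b_out, pos=(i + 1) * 10**6))
        ivs = selected(panel("e", exp_vs))
        h1 = harmonize(ivs, panel("o", out_vs))
        h2 = harmonize(ivs, panel("o", out_flipped))
        assert [h.beta_out for h in h1] == pytest.approx([h.beta_out for h in h2])
        assert {h.action for h in h2} == {"flipped"}
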