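import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import prscox as px
from prscox.prs import ValidationError


def _gm(dosages, rsids=None, counted=None, other=None):
    dosages = np.atleast_2d(np.asarray(dosages, float))
    rsids = rsids or [f"rs{j}" for j in range(dosages.shape[1])]
    return px.GenotypeMatrix(
        [f"S{i}" for i in range(dosages.shape[0])], rsids, dosages, counted, other
    )


def _vw(rsid="rs0", weight=0.1, eaf=0.3, ea="A", oa="G", **kw):
    return px.VariantWeight(rsid, "1", 100, ea, oa, weight, eaf, **kw)


class TestSelectVariants:
    def test_rare_variant_filtered_out(self, five_variant_catalog):
        only_rare = [five_variant_catalog[2]]  # MAF 0.005
        assert px.select_variants(only_rare) == []

    def test_larger_development_cohort_wins_within_locus(self):
        a = _vw("rsA", eaf=0.3, locus="L", source_n=50_000, source_p=1e-20)
        b = _vw("rsB", eaf=0.3, locus="L", source_n=80_000, source_p=1e-5)
        assert [v.rsid for v in px.select_variants([a, b])] == ["rsB"]

    def test_matches_exhaustive_rule_application(self, five_variant_catalog):
        # independent oracle: apply MAF filter then per-locus (max n, min p,
        # min rsid) by brute force
        eligible = [v for v in five_variant_catalog if min(v.eaf, 1 - v.eaf) > 0.01]
        expected = set()
        for locus in {v.locus for v in eligible}:
            group = [v for v in eligible if v.locus == locus]
            best = sorted(group, key=lambda v: (-v.source_n, v.source_p, v.rsid))[0]
            expected.add(best.rsid)
        got = px.select_variants(five_variant_catalog)
        assert {v.rsid for v in got} == expected == {"rs2", "rs4", "rs5"}
        # sorted by chromosome and position
        assert [(v.chrom, v.pos) for v in got] == sorted((v.chrom, v.pos) for v in got)

    def test_unavailable_variants_dropped(self):
        v = _vw("rsA", available=False)
        assert px.select_variants([v]) == []

    def test_tie_breaks_by_p_then_rsid(self):
        a = _vw("rsB", locus="L", source_n=10, source_p=1e-5)
        b = _vw("rsA", locus="L", source_n=10, source_p=1e-5)
        assert [v.rsid for v in px.select_variants([a, b])] == ["rsA"]

    def test_duplicate_rsids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            px.select_variants([_vw("rsX"), _vw("rsX")])


class TestVariantValidation:
    @pytest.mark.parametrize("eaf", [0.0, 1.0, -0.1, 1.5])
    def test_frequency_outside_open_interval_rejected(self, eaf):
        with pytest.raises(ValidationError, match="rs0"):
            _vw(eaf=eaf)

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValidationError):
            _vw(ea="A", oa="A")


class TestHarmonize:
    def test_other_allele_counting_is_flipped(self):
        panel = [_vw("rs0", ea="A", oa="G")]
        gm = _gm([[2.0], [0.0]], counted=["G"], other=["A"])
        out, kept = px.harmonize_genotypes(gm, panel)
        assert kept == panel
        assert out.dosages[:, 0].tolist() == [0.0, 2.0]

    def test_strand_complement_resolved(self):
        panel = [_vw("rs0", ea="A", oa="G")]
        # file reports on the opposite strand: T/C complements A/G
        gm = _gm([[1.0]], counted=["T"], other=["C"])
        out, _ = px.harmonize_genotypes(gm, panel)
        assert out.dosages[0, 0] == 1.0

    def test_palindromic_excluded_by_default_kept_by_flag(self):
        panel = [_vw("rs0", ea="A", oa="T"), _vw("rs1", ea="C", oa="A")]
        gm = _gm([[1.0, 2.0]], rsids=["rs0", "rs1"], counted=["A", "C"], other=["T", "A"])
        out, kept = px.harmonize_genotypes(gm, panel)
        assert [v.rsid for v in kept] == ["rs1"]
        out2, kept2 = px.harmonize_genotypes(gm, panel, keep_palindromic=True)
        assert [v.rsid for v in kept2] == ["rs0", "rs1"]

    def test_missing_imputed_as_twice_eaf(self):
        panel = [_vw("rs0", eaf=0.3)]
        gm = _gm([[np.nan]], counted=["A"], other=["G"])
        out, _ = px.harmonize_genotypes(gm, panel)
        assert out.dosages[0, 0] == pytest.approx(0.6)
        out2, _ = px.harmonize_genotypes(gm, panel, impute_missing=False)
        assert np.isnan(out2.dosages[0, 0])

    def test_incompatible_alleles_dropped(self):
        panel = [_vw("rs0", ea="A", oa="G")]
        gm = _gm([[1.0]], counted=["C"], other=["G"])
        out, kept = px.harmonize_genotypes(gm, panel)
        assert kept == [] and out.n_variants == 0

    def test_no_overlap_is_an_error(self):
        panel = [_vw("rsZ")]
        with pytest.raises(ValidationError, match="overlap"):
            px.harmonize_genotypes(_gm([[1.0]], rsids=["rsOther"]), panel)


class TestComputePrs:
    def test_hand_computed_dot_product(self):
        panel = [
            _vw("rs0", weight=0.1), _vw("rs1", weight=-0.2), _vw("rs2", weight=0.3),
        ]
        gm = _gm([[2.0, 1.0, 0.0]], rsids=["rs0", "rs1", "rs2"])
        assert px.compute_prs(gm, panel).iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_zero_weights_and_single_variant(self):
        gm = _gm([[2.0], [1.0]])
        assert px.compute_prs(gm, [_vw(weight=0.0)]).tolist() == [0.0, 0.0]
        assert px.compute_prs(gm, [_vw(weight=0.5)]).tolist() == [1.0, 0.5]

    def test_misaligned_columns_rejected(self):
        gm = _gm([[1.0]], rsids=["rsX"])
        with pytest.raises(ValidationError, match="aligned"):
            px.compute_prs(gm, [_vw("rs0")])

    @given(alpha=st.floats(-5, 5, allow_nan=False))
    def test_scoring_is_linear_in_weights(self, alpha):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(20, 3)).astype(float)
        base = [_vw(f"rs{j}", weight=w) for j, w in enumerate((0.1, -0.2, 0.3))]
        scaled = [
            px.VariantWeight(v.rsid, v.chrom, v.pos, v.effect_allele, v.other_allele,
                             alpha * v.weight, v.eaf)
            for v in base
        ]
        s1 = px.compute_prs(_gm(g), base)
        s2 = px.compute_prs(_gm(g), scaled)
        np.testing.assert_allclose(s2, alpha * s1, atol=1e-9)

    def test_flip_invariance(self):
        """Scoring a flipped-orientation file equals applying weight to 2-g."""
        panel = [_vw("rs0", weight=0.4, ea="A", oa="G")]
        g = np.array([[0.0], [1.0], [2.0]])
        flipped_file = _gm(2.0 - g, counted=["G"], other=["A"])
        out, kept = px.harmonize_genotypes(flipped_file, panel)
        s_flip = px.compute_prs(out, kept)
        np.testing.assert_allclose(s_flip, 0.4 * g[:, 0], atol=1e-12)


class TestStandardize:
    def test_three_point_example(self):
        z = px.standardize_prs(pd.Series([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            px.standardize_prs(pd.Series([2.0, 2.0, 2.0]))

    def test_mean_zero_unit_sd(self):
        rng = np.random.default_rng(1)
        z = px.standardize_prs(pd.Series(rng.gamma(2, size=500)))
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0)


class TestCategorize:
    def test_five_point_quintiles(self):
        z = pd.Series([-2.0, -1.0, 0.0, 1.0, 2.0])
        cats = px.categorize_prs(z)["genetic_risk"].tolist()
        assert cats == ["low", "intermediate", "intermediate", "intermediate", "high"]

    def test_group_sizes_at_n_1000(self):
        rng = np.random.default_rng(2)
        counts = px.categorize_prs(pd.Series(rng.normal(size=1000)))["genetic_risk"].value_counts()
        assert counts["low"] == 200 and counts["intermediate"] == 600 and counts["high"] == 200

    @given(n=st.integers(5, 400))
    def test_quintile_conservation(self, n):
        rng = np.random.default_rng(n)
        # ties on purpose: rounded values
        z = pd.Series(np.round(rng.normal(size=n), 1))
        cats = px.categorize_prs(z)
        counts = cats["genetic_risk"].value_counts()
        assert int(counts.sum()) == n
        for q in (1, 5):
            size = int((cats["quintile"] == q).sum())
            assert abs(size - n / 5) <= 1

    def test_too_few_participants(self):
        with pytest.raises(ValidationError):
            px.categorize_prs(pd.Series([0.0, 1.0]))


class TestCategorizeSmoking:
    @pytest.mark.parametrize(
        "py,expected",
        [(0.0, "no"), (0.1, "light"), (19.9, "light"), (20.0, "intermediate"),
         (39.9, "intermediate"), (40.0, "heavy"), (75.0, "heavy")],
    )
    def test_packyear_bins(self, py, expected):
        out = px.categorize_smoking(["former"], [py])
        assert out["packyear_category"].iloc[0] == expected

    def test_mismatch_flag(self):
        out = px.categorize_smoking(["never", "never"], [5.0, 0.0])
        assert out["smoking_mismatch"].tolist() == [True, False]

    def test_negative_packyears_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            px.categorize_smoking(["current"], [-1.0])

    def test_unknown_status_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            px.categorize_smoking(["sometimes"], [1.0])


def test_end_to_end_scores_standardised(sim_cohort):
    assert abs(sim_cohort["prs_z"].mean()) < 1e-10
    assert sim_cohort["prs_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
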