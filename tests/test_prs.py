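import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conformalprs.cohort import iamdgc_disease_model, simulate_genotypes, simulate_phenotypes
from conformalprs.prs import (
    AMD_RISK_THRESHOLDS,
    QuintileThresholds,
    assign_risk_group,
    assign_risk_groups,
    compute_prs,
    derive_quintile_thresholds,
    extract_dosages,
    qc_strong_effect,
)

from conftest import make_matrix, make_panel, panel_from_weights

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI0\tI1\n"
)


def write_vcf_text(tmp_path, body):
    path = tmp_path / "g.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestExtractDosages:
    def test_het_with_alt_risk_counts_one(self, tmp_path):
        panel = make_panel([1.2])  # rs1 at 1:1000, risk allele = alt G
        path = write_vcf_text(tmp_path, "1\t1000\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n")
        dm = extract_dosages(path, panel)
        assert dm.dosage[:, 0].tolist() == [1, 2]
        assert not dm.missing_mask.any()

    def test_hom_alt_with_ref_risk_counts_zero(self, tmp_path):
        from dataclasses import replace

        from conformalprs.panel import VariantPanel

        base = make_panel([1.2])
        panel = VariantPanel(variants=(replace(base.variants[0], risk_allele="A"),))
        path = write_vcf_text(tmp_path, "1\t1000\trs1\tA\tG\t.\t.\t.\tGT\t1/1\t0/1\n")
        dm = extract_dosages(path, panel)
        assert dm.dosage[:, 0].tolist() == [0, 1]

    def test_absent_variant_is_masked(self, tmp_path):
        panel = make_panel([1.2, 1.3])  # rs2 at 1:1100 not in the VCF
        path = write_vcf_text(tmp_path, "1\t1000\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n")
        dm = extract_dosages(path, panel)
        assert dm.missing_mask[:, 1].all()
        assert not dm.missing_mask[:, 0].any()

    def test_uncalled_genotype_is_masked(self, tmp_path):
        panel = make_panel([1.2])
        path = write_vcf_text(tmp_path, "1\t1000\trs1\tA\tG\t.\t.\t.\tGT\t./.\t0/1\n")
        dm = extract_dosages(path, panel)
        assert dm.missing_mask[0, 0] and not dm.missing_mask[1, 0]

    def test_allele_mismatch_is_hard_error(self, tmp_path):
        panel = make_panel([1.2])
        path = write_vcf_text(tmp_path, "1\t1000\trs1\tA\tT\t.\t.\t.\tGT\t0/1\t0/0\n")
        with pytest.raises(ValueError, match="rs1"):
            extract_dosages(path, panel)


class TestQC:
    def test_no_missing_passes(self):
        panel = make_panel([1.5, 1.1])
        report = qc_strong_effect(make_matrix([[1, 0], [2, 1]], panel=panel), panel)
        assert report.passed and not report.strong_effect_flags

    def test_strong_variant_with_half_missing_fails(self):
        panel = make_panel([1.47, 1.05])
        missing = [[True, True], [False, True]]  # rs1 50%, rs2 100% missing
        report = qc_strong_effect(make_matrix([[0, 0], [1, 0]], missing, panel=panel), panel)
        assert report.strong_effect_flags == ("rs1",)
        assert not report.passed

    def test_weak_variant_with_half_missing_only_warns(self):
        panel = make_panel([1.05, 1.06])
        missing = [[True, False], [False, False]]
        report = qc_strong_effect(make_matrix([[0, 1], [1, 0]], missing, panel=panel), panel)
        assert report.passed
        assert report.missing_fraction["rs1"] == pytest.approx(0.5)


class TestComputePRS:
    def test_zero_dosages_give_zero(self):
        panel = panel_from_weights([0.5, 1.0, 1.5])
        recs = compute_prs(make_matrix([[0, 0, 0]], panel=panel), panel)
        assert recs[0].prs == 0.0

    def test_equal_weights_reduce_to_allele_count(self):
        panel = panel_from_weights([0.7, 0.7, 0.7])
        recs = compute_prs(make_matrix([[2, 1, 0], [1, 1, 1]], panel=panel), panel)
        assert [r.prs for r in recs] == pytest.approx([3.0, 3.0])

    def test_hand_example(self):
        panel = panel_from_weights([0.5, 1.0, 1.5])  # mean weight exactly 1.0
        recs = compute_prs(make_matrix([[2, 1, 0]], panel=panel), panel)
        assert recs[0].prs == pytest.approx(2.0, abs=1e-12)

    def test_zero_mean_weight_rejected(self):
        panel = make_panel([1.0, 1.0])
        with pytest.raises(ValueError, match="mean effect weight"):
            compute_prs(make_matrix([[1, 1]], panel=panel), panel)

    def test_impute_freq_without_freqs_rejected(self):
        panel = panel_from_weights([0.5, 1.0])
        matrix = make_matrix([[1, 0]], [[False, True]], panel=panel)
        with pytest.raises(ValueError, match="frequencies"):
            compute_prs(matrix, panel, missing_policy="impute_freq")

    def test_impute_freq_substitutes_expectation(self):
        panel = panel_from_weights([0.5, 1.0], freqs=[0.2, 0.4])
        matrix = make_matrix([[1, 0]], [[False, True]], panel=panel)
        recs = compute_prs(matrix, panel, missing_policy="impute_freq")
        expected = (1 * 0.5 + 2 * 0.4 * 1.0) / 0.75
        assert recs[0].prs == pytest.approx(expected, abs=1e-12)
        assert recs[0].n_missing == 1

    def test_zero_policy_ignores_missing(self):
        panel = panel_from_weights([0.5, 1.0], freqs=[0.2, 0.4])
        matrix = make_matrix([[1, 2]], [[False, True]], panel=panel)
        recs = compute_prs(matrix, panel, missing_policy="zero")
        assert recs[0].prs == pytest.approx(0.5 / 0.75, abs=1e-12)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = 47
            weights = rng.uniform(0.02, 1.0, m)
            freqs = rng.uniform(0.05, 0.95, m)
            panel = panel_from_weights(weights, freqs=freqs)
            dosage = rng.integers(0, 3, size=(200, m))
            missing = rng.random((200, m)) < 0.05
            matrix = make_matrix(dosage, missing, panel=panel)
            recs = compute_prs(matrix, panel, missing_policy="impute_freq")
            w = panel.weights
            wbar = panel.mean_effect_weight
            for i in range(200):
                total = 0.0
                for j in range(m):
                    total += (2 * freqs[j] if missing[i, j] else dosage[i, j]) * w[j]
                assert abs(recs[i].prs - total / wbar) < 1e-9

    @given(st.integers(min_value=0, max_value=199), st.integers(min_value=0, max_value=9))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_dosage(self, i, j):
        rng = np.random.default_rng(123)
        panel = panel_from_weights(rng.uniform(0.05, 1.0, 10))
        dosage = rng.integers(0, 2, size=(200, 10))  # leave headroom to increment
        matrix = make_matrix(dosage, panel=panel)
        base = compute_prs(matrix, panel)[i].prs
        bumped = dosage.copy()
        bumped[i, j] += 1
        higher = compute_prs(make_matrix(bumped, panel=panel), panel)[i].prs
        assert higher >= base


class TestThresholds:
    def test_even_reference_matches_sorting_oracle(self):
        ref = list(range(1, 101))
        cuts = derive_quintile_thresholds(ref).cuts
        # independent oracle: linear interpolation between order statistics
        values = sorted(ref)
        expected = []
        for q in (0.2, 0.4, 0.6, 0.8):
            pos = q * (len(values) - 1)
            lo, hi = int(math.floor(pos)), int(math.ceil(pos))
            expected.append(values[lo] + (pos - lo) * (values[hi] - values[lo]))
        assert cuts == pytest.approx(expected)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            derive_quintile_thresholds([3.0] * 50)

    def test_fewer_than_five_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            derive_quintile_thresholds([1.0, 2.0, 3.0, 4.0])

    def test_shipped_preset_constants(self):
        assert AMD_RISK_THRESHOLDS.cuts == (25.3, 29.9, 34.5, 39.1)

    def test_non_ascending_cuts_rejected(self):
        with pytest.raises(ValueError):
            QuintileThresholds(cuts=(1.0, 1.0, 2.0, 3.0))


class TestRiskGroups:
    @pytest.mark.parametrize(
        "prs,group",
        [(25.3, 1), (25.31, 2), (29.9, 2), (29.91, 3), (34.5, 3), (34.51, 4), (39.1, 4), (40.0, 5), (0.0, 1)],
    )
    def test_published_boundaries(self, prs, group):
        assert assign_risk_group(prs, AMD_RISK_THRESHOLDS) == group

    @given(
        st.lists(st.floats(min_value=-100, max_value=100), min_size=4, max_size=4, unique=True),
        st.floats(min_value=-150, max_value=150, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_of_real_line(self, cuts, value):
        t = QuintileThresholds(cuts=tuple(sorted(cuts)))
        g = assign_risk_group(value, t)
        assert 1 <= g <= 5
        c = t.cuts
        if g == 1:
            assert value <= c[0]
        elif g == 5:
            assert value > c[3]
        else:
            assert c[g - 2] < value <= c[g - 1]

    def test_vectorised_matches_scalar(self):
        values = np.linspace(20, 45, 37)
        vec = assign_risk_groups(values, AMD_RISK_THRESHOLDS)
        assert vec.tolist() == [assign_risk_group(v, AMD_RISK_THRESHOLDS) for v in values]

    def test_preset_cases_concentrate_in_upper_groups(self, curated_panel):
        model = iamdgc_disease_model(curated_panel)
        dm = simulate_genotypes(curated_panel, 10_000, seed=31)
        cohort = simulate_phenotypes(dm, curated_panel, model, seed=32)
        recs = compute_prs(dm, curated_panel, thresholds=AMD_RISK_THRESHOLDS)
        groups = np.array([r.risk_group for r in recs])
        cases = cohort.phenotypes["status"].to_numpy() == "case"
        assert np.isin(groups[cases], (3, 4, 5)).mean() > 0.6
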