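import numpy as np
import pandas as pd
import pytest

from orthoflow import (
    aggregate_species,
    gc_family_contrasts,
    kruskal_wallis,
    pairwise_mann_whitney_bonferroni,
    pearson_test,
    sex_differences,
)
from orthoflow.datasets import (
    load_measured_species,
    measured_species_summaries,
    sex_pair_summaries,
)
from orthoflow.errors import DegenerateInputError, InsufficientGroupsError
from orthoflow.stats import (
    Provenance,
    SpeciesSummary,
    mann_whitney_p,
    summaries_to_frame,
)
from oracles import (
    kruskal_h_oracle,
    mannwhitney_exact_p_oracle,
    pearson_permutation_p_oracle,
)


class TestAggregation:
    def _rows(self, values, species="Bryodemella tuberculata", sex="F"):
        return pd.DataFrame([
            {"specimen_id": f"s{i}", "species": species, "sex": sex,
             "c1_pg": v, "gc_percent": 42.0} for i, v in enumerate(values)])

    def test_two_specimen_female_mean(self):
        # 21.96 and 21.88 pg females average to the species mean 21.92 pg
        out = aggregate_species(self._rows([21.96, 21.88]))
        assert len(out) == 1
        assert out[0].mean_1C_female_pg == pytest.approx(21.92)
        assert out[0].n_female == 2
        assert out[0].mean_1C_male_pg is None

    def test_single_specimen_mean_is_value(self):
        out = aggregate_species(self._rows([18.51]))
        assert out[0].mean_1C_female_pg == pytest.approx(18.51)

    def test_missing_karyotype_leaves_field_absent(self):
        out = aggregate_species(self._rows([10.0]), karyotype={"other": 22})
        assert out[0].male_2n is None

    def test_order_invariance(self):
        rows = pd.concat([self._rows([21.96, 21.88]),
                          self._rows([10.66, 10.47], species="Ab c", sex="M")])
        fwd = summaries_to_frame(aggregate_species(rows))
        rev = summaries_to_frame(aggregate_species(rows.iloc[::-1]))
        pd.testing.assert_frame_equal(fwd, rev)

    def test_dye_replicates_average_within_specimen_first(self):
        rows = pd.DataFrame([
            {"specimen_id": "s1", "species": "x", "sex": "F", "c1_pg": 10.0},
            {"specimen_id": "s1", "species": "x", "sex": "F", "c1_pg": 12.0},
            {"specimen_id": "s2", "species": "x", "sex": "F", "c1_pg": 20.0},
        ])
        out = aggregate_species(rows)
        # specimen means 11 and 20 -> species mean 15.5 (not the row mean 14)
        assert out[0].mean_1C_female_pg == pytest.approx(15.5)


class TestSexDifferences:
    def test_reproduces_printed_worked_values(self):
        summaries, prov = sex_pair_summaries()
        deltas = {d.species: d.delta_pg
                  for d in sex_differences(summaries, prov)}
        expected = {
            "Gomphocerippus rufus": 2.52,
            "Chorthippus vagans": 2.43,
            "Pseudochorthippus parallelus": 2.25,
            "Schistocerca gregaria": 2.13,
            "Chorthippus dorsatus": -0.21,
            "Myrmeleotettix maculatus": -0.31,
        }
        for sp, val in expected.items():
            assert deltas[sp] == pytest.approx(val, abs=1e-9)

    def test_antisymmetric_under_sex_swap(self):
        s = SpeciesSummary("x", mean_1C_female_pg=13.18, mean_1C_male_pg=10.66)
        swapped = SpeciesSummary("x", mean_1C_female_pg=10.66,
                                 mean_1C_male_pg=13.18)
        d1 = sex_differences([s])[0].delta_pg
        d2 = sex_differences([swapped])[0].delta_pg
        assert d1 == pytest.approx(-d2)

    def test_species_without_male_mean_skipped(self):
        s = SpeciesSummary("x", mean_1C_female_pg=13.18)
        assert sex_differences([s]) == []

    def test_provenance_tagging(self):
        _, prov = sex_pair_summaries()
        assert prov["Chorthippus dorsatus"] is Provenance.SAME_STUDY
        assert prov["Myrmeleotettix maculatus"] is Provenance.CROSS_METHOD


class TestKruskalWallis:
    def test_identical_groups_give_zero_h_unit_p(self):
        res = kruskal_wallis([("A", 1), ("A", 2), ("A", 3),
                              ("B", 1), ("B", 2), ("B", 3)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_explicit_rank_formula_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 6, size=3)
        groups = [list(rng.integers(0, 6, size=s).astype(float))
                  for s in sizes]
        values = [(k, v) for k, g in enumerate(groups) for v in g]
        res = kruskal_wallis(values)
        if np.ptp([v for _, v in values]) == 0:
            assert res.statistic == 0.0
        else:
            assert res.statistic == pytest.approx(kruskal_h_oracle(groups),
                                                  rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientGroupsError):
            kruskal_wallis([("A", 1), ("A", 2)])


class TestMannWhitney:
    def test_exact_p_for_complete_separation_3v3(self):
        # two tie-free groups of 3 with complete separation: p = 2/20
        assert mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        pooled = rng.permutation(np.arange(10.0))
        n = int(rng.integers(2, 6))
        x, y = pooled[:n], pooled[n:n + int(rng.integers(2, 6))]
        assert mann_whitney_p(x, y) == pytest.approx(
            mannwhitney_exact_p_oracle(x, y), abs=1e-12)

    def test_identical_groups_corrected_p_is_one(self):
        mat = pairwise_mann_whitney_bonferroni(
            [("A", v) for v in (1, 2, 3)] + [("B", v) for v in (1, 2, 3)])
        assert mat.loc["A", "B"] == pytest.approx(1.0)

    def test_bonferroni_multiplies_by_pairs_tested(self):
        data = ([("A", v) for v in (1.0, 2.0, 3.0)]
                + [("B", v) for v in (4.0, 5.0, 6.0)]
                + [("C", v) for v in (7.0, 8.0, 9.0)])
        mat = pairwise_mann_whitney_bonferroni(data)
        # 3 pairs tested; raw exact p for 3v3 separation is 0.1
        assert mat.loc["A", "B"] == pytest.approx(0.3)
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)

    def test_min_group_size_filter(self):
        data = [("A", 1.0), ("B", 2.0)]
        with pytest.raises(InsufficientGroupsError):
            pairwise_mann_whitney_bonferroni(data, min_group_size=2)

    def test_corrected_p_capped_at_one(self):
        rng = np.random.default_rng(0)
        data = [(k, float(v)) for k in "ABCDE"
                for v in rng.normal(0, 1, size=4)]
        mat = pairwise_mann_whitney_bonferroni(data)
        assert np.nanmax(mat.values) <= 1.0


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(5.0)
        res = pearson_test(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert pearson_test(x, -x).statistic == pytest.approx(-1.0)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=12)
        y = 0.8 * x + rng.normal(size=12)
        res = pearson_test(x, y)
        p_perm = pearson_permutation_p_oracle(x, y, n_perm=20000, seed=1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / 20000) + 1e-4
        assert abs(res.p_value - p_perm) < max(mc_err, 0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFamilyContrasts:
    def test_identical_families_show_no_contrast(self):
        per = [(fam, "F", gc) for fam in ("A", "B", "C")
               for gc in (40.0, 41.0, 42.0)]
        res = gc_family_contrasts(per)
        assert res.anova.statistic == pytest.approx(0.0, abs=1e-12)
        assert np.nanmin(res.pairwise.values) == pytest.approx(1.0)

    def test_shifted_family_detected(self):
        rng = np.random.default_rng(5)
        per = []
        for fam, shift in (("A", 0.0), ("B", 0.0), ("C", 3.0)):
            per += [(fam, "F", float(40 + shift + rng.normal(0, 0.5)))
                    for _ in range(8)]
        res = gc_family_contrasts(per)
        assert res.anova.p_value < 1e-6
        assert res.pairwise.loc["A", "C"] < 0.05

    def test_summary_table_columns(self):
        per = [("A", "F", 40.0), ("A", "F", 41.0), ("B", "M", 39.0),
               ("B", "F", 38.0)]
        res = gc_family_contrasts(per)
        assert list(res.summary.columns) == ["family", "n", "max", "min",
                                             "mean", "sd"]
        assert res.summary.set_index("family").loc["A", "n"] == 2


class TestSurveyDataset:
    """Structural checks on the bundled species-level survey table."""

    def test_fifty_species_four_families(self):
        df = load_measured_species()
        assert len(df) == 50
        assert set(df["family"]) == {"Acrididae", "Gryllidae", "Tetrigidae",
                                     "Tettigoniidae"}

    def test_largest_genome_is_bryodemella(self):
        df = load_measured_species()
        top = df.loc[df["c1_female_pg"].idxmax()]
        assert top["species"] == "Bryodemella tuberculata"
        assert top["c1_female_pg"] == pytest.approx(21.92)

    def test_pairwise_matrix_covers_eligible_chromosome_groups(self):
        df = load_measured_species().dropna(subset=["c1_male_pg"])
        counts = df.groupby("male_2n").size()
        eligible = sorted(int(k) for k, n in counts.items() if n >= 2)
        mat = pairwise_mann_whitney_bonferroni(
            zip(df["male_2n"].astype(int), df["c1_male_pg"]))
        assert list(mat.index) == eligible
        assert list(mat.columns) == eligible

    def test_t_test_on_identical_samples(self):
        from orthoflow.stats import t_test
        res = t_test([40.1, 41.0, 42.3], [40.1, 41.0, 42.3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_sex_difference_trends_with_male_size(self):
        # the trend of larger sex differences in larger male genomes points
        # the right way even on this survey subset (the reported significance
        # needs the full multi-study compilation, which is not bundled)
        summaries = measured_species_summaries()
        deltas = sex_differences(summaries)
        males = {s.species: s.mean_1C_male_pg for s in summaries}
        x = [males[d.species] for d in deltas]
        y = [d.delta_pg for d in deltas]
        res = pearson_test(x, y)
        assert res.statistic > 0
        assert 0 <= res.p_value <= 1
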