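"""Phenotype-plate QC, profile clustering, LSD letters, delta-Cq, conidiation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from clonotyper.phenotype import (
    QCConfig,
    cluster_profiles,
    conidiation_summary,
    delta_cq,
    delta_cq_summary,
    lsd_compare,
    profile_matrix,
    qc_filter,
)


def plate(rows):
    return pd.DataFrame(rows, columns=["strain", "replicate", "well", "compound",
                                       "timepoint_h", "od490", "od750",
                                       "conidia_present"])


class TestQCFilter:
    def test_reading_at_ceiling_retained_above_excluded(self):
        wells = plate([
            ("s1", 1, "A1", "glucose", 48, 0.5, 2.0, False),
            ("s1", 1, "A2", "glucose", 48, 0.5, 2.1, False),
            ("s1", 1, "A3", "glucose", 48, 0.5, 0.8, False),
        ])
        kept = qc_filter(wells)
        assert sorted(kept["well"]) == ["A1", "A3"]

    def test_grid_of_absorbances_max_retained_is_ceiling(self):
        values = [round(0.1 * i, 1) for i in range(31)]  # 0.0 .. 3.0
        wells = plate([("s1", 1, f"A{i}", "c", 48, 0.1, v, False)
                       for i, v in enumerate(values)])
        kept = qc_filter(wells)
        assert kept["od750"].max() == 2.0
        assert len(kept) == 21

    def test_conidia_wells_excluded_by_default_kept_when_disabled(self):
        wells = plate([
            ("s1", 1, "A1", "c", 48, 0.5, 1.0, True),
            ("s1", 1, "A2", "c", 48, 0.5, 1.0, False),
        ])
        assert list(qc_filter(wells)["well"]) == ["A2"]
        relaxed = qc_filter(wells, QCConfig(exclude_conidia_wells=False))
        assert sorted(relaxed["well"]) == ["A1", "A2"]

    def test_other_wavelength_filtered_independently(self):
        wells = plate([("s1", 1, "A1", "c", 48, 2.5, 1.0, False)])
        assert len(qc_filter(wells, wavelength="od750")) == 1
        assert len(qc_filter(wells, wavelength="od490")) == 0


class TestProfileMatrix:
    def test_replicate_means_and_missing_cells(self):
        wells = plate([
            ("s1", 1, "A1", "glucose", 48, 0.1, 1.0, False),
            ("s1", 2, "A1", "glucose", 48, 0.1, 2.0, False),
            ("s2", 1, "A1", "glucose", 48, 0.1, 0.4, False),
        ])
        m = profile_matrix(wells, timepoint=48)
        assert m.loc["s1", "glucose"] == 1.5
        assert m.loc["s2", "glucose"] == 0.4

    def test_empty_cell_is_nan_not_zero(self):
        wells = plate([
            ("s1", 1, "A1", "glucose", 48, 0.1, 1.0, False),
            ("s1", 1, "A2", "xylose", 48, 0.1, 0.7, False),
            ("s2", 1, "A1", "glucose", 48, 0.1, 0.4, False),
        ])
        m = profile_matrix(wells, timepoint=48)
        assert math.isnan(m.loc["s2", "xylose"])


class TestClustering:
    @staticmethod
    def _matrix(rows: dict) -> pd.DataFrame:
        return pd.DataFrame(rows).T

    def test_identical_profiles_merge_at_similarity_one(self):
        m = self._matrix({"a": [1.0, 2.0, 3.0, 1.5], "b": [1.0, 2.0, 3.0, 1.5],
                          "c": [3.0, 0.5, 0.1, 2.0]})
        res = cluster_profiles(m)
        assert res.merge_similarities[0] == pytest.approx(1.0)

    def test_anticorrelated_profiles_merge_at_similarity_zero(self):
        m = self._matrix({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        res = cluster_profiles(m)
        assert res.merge_similarities[0] == pytest.approx(0.0)

    def test_similarities_bounded_zero_one(self, rng):
        m = self._matrix({f"s{i}": list(rng.normal(size=8)) for i in range(6)})
        res = cluster_profiles(m)
        for s in res.merge_similarities:
            assert 0.0 <= s <= 1.0 + 1e-12

    def test_row_order_does_not_change_tree_heights(self, rng):
        data = {f"s{i}": list(rng.normal(size=6)) for i in range(5)}
        m1 = self._matrix(data)
        m2 = m1.iloc[::-1]
        r1, r2 = cluster_profiles(m1), cluster_profiles(m2)
        assert np.allclose(sorted(r1.merge_similarities), sorted(r2.merge_similarities))

    def test_newick_contains_all_labels(self):
        m = self._matrix({"a": [1, 2, 3], "b": [1, 2, 4], "c": [5, 1, 0]})
        tree = cluster_profiles(m).to_newick()
        assert tree.endswith(";")
        for label in "abc":
            assert label in tree

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(self._matrix({"a": [1, 2, 3]}))

    def test_insufficient_shared_compounds_rejected(self):
        m = pd.DataFrame({"x": [1.0, np.nan], "y": [2.0, np.nan], "z": [np.nan, 3.0]},
                         index=["a", "b"])
        with pytest.raises(ValueError):
            cluster_profiles(m)


class TestLSD:
    def test_balanced_design_matches_textbook_formula(self):
        groups = {"g1": [10.0, 11.0, 9.0, 10.0], "g2": [14.0, 15.0, 13.0, 14.0]}
        res = lsd_compare(groups, alpha=0.05)
        sse = sum((x - 10.0) ** 2 for x in groups["g1"]) + \
              sum((x - 14.0) ** 2 for x in groups["g2"])
        mse = sse / 6
        expected = t_dist.ppf(0.975, 6) * math.sqrt(2 * mse / 4)
        assert res.lsd == pytest.approx(expected)
        assert res.df_error == 6 and res.n_harmonic == 4

    def test_unbalanced_design_uses_harmonic_mean(self):
        groups = {"g1": [1.0, 2.0], "g2": [1.5, 2.5, 3.5, 4.5]}
        res = lsd_compare(groups)
        assert res.n_harmonic == pytest.approx(2 / (1 / 2 + 1 / 4))

    def test_separated_groups_get_distinct_letters(self):
        groups = {"low": [1.0, 1.1, 0.9], "high": [9.0, 9.1, 8.9]}
        letters = lsd_compare(groups).letters
        assert letters["low"] != letters["high"]
        assert set(letters.values()) == {"a", "b"}

    def test_indistinguishable_groups_share_a_letter(self):
        groups = {"g1": [5.0, 6.0, 4.0], "g2": [5.5, 6.5, 4.5]}
        letters = lsd_compare(groups).letters
        assert set(letters["g1"]) & set(letters["g2"])

    def test_letter_assignment_consistent_with_lsd(self):
        """Sharing a letter if and only if the mean difference is within the
        l.s.d. holds pairwise for a graded three-group design."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            centers = sorted(rng.uniform(0, 10, size=3))
            groups = {f"g{i}": list(c + rng.normal(0, 0.5, size=4))
                      for i, c in enumerate(centers)}
            res = lsd_compare(groups)
            for a, b in itertools.combinations(groups, 2):
                shares = bool(set(res.letters[a]) & set(res.letters[b]))
                within = abs(res.means[a] - res.means[b]) <= res.lsd
                assert shares == within

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            lsd_compare({"only": [1.0, 2.0]})
        with pytest.raises(ValueError):
            lsd_compare({"g1": [1.0], "g2": [2.0, 3.0]})


class TestDeltaCq:
    def test_delta_is_target_minus_reference(self):
        df = pd.DataFrame({"Cq_target": [25.0, 30.0], "Cq_ref": [20.0, 20.0]})
        out = delta_cq(df)
        assert list(out["delta_cq"]) == [5.0, 10.0]
        # lower delta-Cq = higher expression: the 5.0 sample expresses more

    def test_missing_values_dropped_with_warning(self):
        df = pd.DataFrame({"Cq_target": [25.0, np.nan], "Cq_ref": [20.0, 21.0]})
        with pytest.warns(UserWarning):
            out = delta_cq(df)
        assert len(out) == 1

    def test_shift_of_reference_shifts_delta_linearly(self):
        df = pd.DataFrame({"Cq_target": [25.0, 26.0], "Cq_ref": [20.0, 20.0]})
        shifted = df.assign(Cq_ref=df["Cq_ref"] + 2.0)
        d0, d1 = delta_cq(df)["delta_cq"], delta_cq(shifted)["delta_cq"]
        assert list(d1) == [x - 2.0 for x in d0]

    def test_summary_contrasts_two_conditions(self):
        df = pd.DataFrame({
            "strain": ["s1"] * 4, "target_gene": ["gene1"] * 4,
            "condition": ["ctrl", "ctrl", "induced", "induced"],
            "Cq_target": [25.0, 25.2, 22.0, 22.2], "Cq_ref": [20.0] * 4,
        })
        out = delta_cq_summary(df)
        assert set(out["condition"]) == {"ctrl", "induced"}
        # induced - ctrl contrast: (2.1 - 5.1) = -3.0 (more expressed when induced)
        assert out["difference"].iloc[0] == pytest.approx(-3.0)


class TestConidiation:
    def test_replicate_then_strain_averaging(self):
        wells = pd.DataFrame({
            "strain": ["s1"] * 4, "timepoint_h": [48] * 4,
            "replicate": [1, 1, 2, 2], "score": [0, 4, 2, 2],
        })
        out = conidiation_summary(wells)
        assert out["mean_score"].iloc[0] == pytest.approx(2.0)  # mean(2.0, 2.0)
        assert out["wells_with_conidia"].iloc[0] == pytest.approx(1.5)  # mean(1, 2)

    def test_out_of_range_score_rejected(self):
        wells = pd.DataFrame({"strain": ["s1"], "timepoint_h": [48],
                              "replicate": [1], "score": [6]})
        with pytest.raises(ValueError):
            conidiation_summary(wells)
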