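"""Glycopeptide filtering cascade, adaptive statistics, and overlay."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycodiff.glyco import (
    GlycopeptideMatrix,
    adaptive_test,
    bh_adjust,
    differential_expression,
    filter_by_scores,
    fold_change_overlay,
    merge_samples,
    per_sample_overall_metrics,
    presence_filter,
    render_site,
    singleton_fraction,
)
from glycodiff.glycan import glycan_metrics, parse_composition

from conftest import make_matrix


def bh_oracle(p):
    """Independent step-up BH: walk ranks from largest p down."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def records_table(rows):
    return pd.DataFrame(
        rows, columns=["protein", "site", "glycan", "abundance", "ms1_score", "ms2_score"]
    )


class TestRenderSite:
    def test_forms(self):
        assert render_site(197) == "197"
        assert render_site({553, 197}) == "197/553"
        assert render_site("553/197") == "197/553"

    def test_invalid(self):
        with pytest.raises(ValueError):
            render_site(0)
        with pytest.raises(ValueError):
            render_site([])


class TestScoreFilter:
    def test_inclusive_boundary(self):
        t = records_table(
            [
                ("P1", "100", "H5N2", 1.0, 3.0, 5.0),   # exactly at both cutoffs
                ("P1", "100", "H5N2", 1.0, 10.0, 4.9),  # fails MS2
                ("P1", "100", "H5N2", 1.0, 2.9, 50.0),  # fails MS1
            ]
        )
        kept = filter_by_scores(t)
        assert list(kept.index) == [0]

    def test_matches_loop_oracle(self, rng):
        t = records_table(
            [
                ("P1", "1", "H5N2", 1.0, rng.uniform(0, 10), rng.uniform(0, 10))
                for _ in range(100)
            ]
        )
        kept = filter_by_scores(t, ms1_min=3.0, ms2_min=5.0)
        expected = sum(
            1 for _, r in t.iterrows() if r.ms1_score >= 3.0 and r.ms2_score >= 5.0
        )
        assert len(kept) == expected
        assert list(kept.index) == sorted(kept.index)  # order preserved

    def test_idempotent(self, rng):
        t = records_table(
            [("P1", "1", "H5N2", 1.0, rng.uniform(0, 10), rng.uniform(0, 10))
             for _ in range(50)]
        )
        once = filter_by_scores(t)
        assert filter_by_scores(once).equals(once)

    def test_missing_score_raises(self):
        t = records_table([("P1", "1", "H5N2", 1.0, np.nan, 5.0)])
        with pytest.raises(ValueError, match="ms1_score"):
            filter_by_scores(t)
        t2 = records_table([("P1", "1", "H5N2", 1.0, 4.0, 6.0)])
        with pytest.raises(ValueError, match="ms2_score"):
            filter_by_scores(t2.drop(columns="ms2_score"))


class TestMerge:
    def test_shared_key_and_within_sample_duplicates(self):
        t1 = records_table(
            [("P1", "100", "H5N2", 2.0, 5, 10), ("P1", "100", "H5N2", 3.0, 5, 10)]
        )
        t2 = records_table([("P1", "100", "H5N2", 7.0, 5, 10)])
        m = merge_samples({"T01": t1, "A01": t2}, {"T01": "tumor", "A01": "adjacent"})
        assert m.n_glycopeptides == 1
        assert m.abundance.loc[("P1", "100", "H5N2"), "T01"] == 5.0  # duplicates summed
        assert m.abundance.loc[("P1", "100", "H5N2"), "A01"] == 7.0

    def test_disjoint_keys_union(self, rng):
        tables = {}
        groups = {}
        expected_keys = set()
        for i in range(4):
            rows = [
                (f"P{i}", str(100 + j), "H5N2", 1.0, 5, 10)
                for j in range(rng.integers(1, 6))
            ]
            tables[f"S{i}"] = records_table(rows)
            groups[f"S{i}"] = "tumor" if i < 2 else "adjacent"
            expected_keys |= {(r[0], r[1], r[2]) for r in rows}
        m = merge_samples(tables, groups)
        assert m.n_glycopeptides == len(expected_keys)

    def test_absent_observations_are_missing_not_zero(self):
        t1 = records_table([("P1", "100", "H5N2", 2.0, 5, 10)])
        t2 = records_table([("P2", "200", "H5N4", 3.0, 5, 10)])
        m = merge_samples({"T01": t1, "A01": t2}, {"T01": "tumor", "A01": "adjacent"})
        assert np.isnan(m.abundance.loc[("P1", "100", "H5N2"), "A01"])

    def test_unknown_group_label_rejected(self):
        t = records_table([("P1", "100", "H5N2", 2.0, 5, 10)])
        with pytest.raises(ValueError):
            merge_samples({"S1": t}, {"S1": "treated"})

    def test_glycan_strings_canonicalized(self):
        t = records_table([("P1", "100", "S1N4H5", 2.0, 5, 10)])
        m = merge_samples({"S1": t}, {"S1": "tumor"})
        assert m.abundance.index[0][2] == "H5N4S1"


class TestPresenceFilter:
    def test_boundary(self):
        m = make_matrix(
            {
                ("P1", "1", "H5N2"): {f"T{i}": 1.0 for i in range(5)},
                ("P2", "1", "H5N2"): {
                    **{f"T{i}": 1.0 for i in range(4)},
                    **{f"A{i}": 1.0 for i in range(4)},
                },
            },
            {**{f"T{i}": "tumor" for i in range(6)}, **{f"A{i}": "adjacent" for i in range(6)}},
        )
        kept = presence_filter(m, min_per_group=5)
        assert kept.abundance.index.get_level_values("protein").tolist() == ["P1"]

    def test_min_exceeding_group_sizes_raises(self):
        m = make_matrix(
            {("P1", "1", "H5N2"): {"T0": 1.0, "A0": 1.0}},
            {"T0": "tumor", "A0": "adjacent"},
        )
        with pytest.raises(ValueError):
            presence_filter(m, min_per_group=2)

    def test_random_mask_matches_loop_oracle_and_idempotence(self, rng):
        samples = [f"T{i}" for i in range(6)] + [f"A{i}" for i in range(6)]
        groups = {s: ("tumor" if s.startswith("T") else "adjacent") for s in samples}
        values = {}
        for r in range(60):
            mask = rng.random(12) < 0.4
            values[("P%d" % r, "1", "H5N2")] = {
                s: (1.0 if mask[i] else np.nan) for i, s in enumerate(samples)
            }
        m = make_matrix(values, groups)
        kept = presence_filter(m, min_per_group=3)
        expected = set()
        for key, row in values.items():
            nt = sum(not np.isnan(row[s]) for s in samples if s.startswith("T"))
            na = sum(not np.isnan(row[s]) for s in samples if s.startswith("A"))
            if nt >= 3 or na >= 3:
                expected.add(key)
        assert set(kept.abundance.index) == expected
        again = presence_filter(kept, min_per_group=3)
        assert again.abundance.equals(kept.abundance)


class TestSingletonFraction:
    def test_all_singletons(self):
        m = make_matrix(
            {
                ("P1", "1", "H5N2"): {"T0": 1.0, "A0": np.nan},
                ("P2", "1", "H5N2"): {"T0": np.nan, "A0": 2.0},
            },
            {"T0": "tumor", "A0": "adjacent"},
        )
        count, frac = singleton_fraction(m)
        assert (count, frac) == (2, 1.0)

    def test_known_mask(self):
        m = make_matrix(
            {
                ("P1", "1", "H5N2"): {"T0": 1.0, "T1": 1.0, "A0": np.nan},
                ("P2", "1", "H5N2"): {"T0": np.nan, "T1": 1.0, "A0": np.nan},
                ("P3", "1", "H5N2"): {"T0": 1.0, "T1": 1.0, "A0": 1.0},
            },
            {"T0": "tumor", "T1": "tumor", "A0": "adjacent"},
        )
        count, frac = singleton_fraction(m)
        assert count == 1 and frac == pytest.approx(1 / 3)


class TestPerSampleMetrics:
    def test_single_glycopeptide_sample(self):
        m = make_matrix(
            {("P1", "1", "H5N4S1"): {"T0": 10.0, "A0": np.nan}},
            {"T0": "tumor", "A0": "adjacent"},
        )
        out = per_sample_overall_metrics(m)
        assert out.loc["T0", "sialylation"] == pytest.approx(0.5)
        assert np.isnan(out.loc["A0", "sialylation"])  # no observations: flagged

    def test_identical_columns_identical_metrics(self):
        col = {"T0": 3.0, "T1": 3.0}
        m = make_matrix(
            {
                ("P1", "1", "F1H5N4S1"): col,
                ("P1", "1", "H5N2"): {"T0": 1.0, "T1": 1.0},
            },
            {"T0": "tumor", "T1": "tumor"},
        )
        out = per_sample_overall_metrics(m)
        assert out.loc["T0"].drop("group").equals(out.loc["T1"].drop("group"))

    def test_matches_loop_recomputation(self, rng):
        glycans = ["H5N2", "H5N4S1", "F1H5N4", "H6N5S2", "H3N2"]
        samples = ["T0", "T1", "A0"]
        values = {}
        for i, g in enumerate(glycans):
            values[(f"P{i}", "1", g)] = {
                s: (rng.uniform(1, 100) if rng.random() < 0.8 else np.nan)
                for s in samples
            }
        m = make_matrix(values, {"T0": "tumor", "T1": "tumor", "A0": "adjacent"})
        out = per_sample_overall_metrics(m)
        for s in samples:
            num = den = 0.0
            for (_, _, g), row in values.items():
                ab = row[s]
                if np.isnan(ab):
                    continue
                v = glycan_metrics(parse_composition(g)).sialylation
                if v is not None:
                    num += ab * v
                    den += ab
            expected = num / den if den else np.nan
            got = out.loc[s, "sialylation"]
            assert got == pytest.approx(expected, abs=1e-12) or (
                np.isnan(expected) and np.isnan(got)
            )


class TestAdaptiveTest:
    def test_identical_vectors_student_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = adaptive_test(x, x.copy())
        assert res.test_used == "student"
        assert res.p == pytest.approx(1.0)

    def test_unequal_variances_select_welch(self, rng):
        # grossly different spreads with clean Gaussian shapes
        picks = []
        for _ in range(50):
            x = rng.normal(0, 1, 15)
            y = rng.normal(0, 6, 15)
            picks.append(adaptive_test(x, y).test_used)
        assert picks.count("welch") > len(picks) / 2
        assert "student" not in picks or picks.count("student") < 10

    def test_heavy_tails_select_wilcoxon(self, rng):
        picks = []
        for _ in range(100):
            x = rng.lognormal(0, 2, 12)
            y = rng.lognormal(0, 2, 12)
            picks.append(adaptive_test(x, y).test_used)
        assert picks.count("wilcoxon") > 50

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError):
            adaptive_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_wilcoxon_matches_mannwhitney(self, rng):
        x = rng.lognormal(0, 2, 8)
        y = rng.lognormal(1, 2, 8)
        res = adaptive_test(x, y)
        if res.test_used == "wilcoxon":
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            assert res.p == pytest.approx(ref.pvalue)


class TestBHAdjust:
    def test_hand_computed(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_matches_step_up_oracle(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_p_rank(self, rng):
        p = rng.random(30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestDifferentialExpression:
    @pytest.fixture
    def matrix(self, rng):
        samples = [f"T{i}" for i in range(6)] + [f"A{i}" for i in range(6)]
        groups = {s: ("tumor" if s.startswith("T") else "adjacent") for s in samples}
        values = {}
        for r in range(30):
            shift = 2.0 if r < 5 else 0.0
            values[(f"P{r}", "1", "H5N4S1")] = {
                s: float(
                    2 ** (10 + (shift if s.startswith("T") else 0) + rng.normal(0, 0.4))
                )
                for s in samples
            }
        # one row with too few observations in a group
        values[("P99", "1", "H5N2")] = {
            **{f"T{i}": 2.0**10 for i in range(6)},
            **{f"A{i}": (2.0**10 if i < 2 else np.nan) for i in range(6)},
        }
        return make_matrix(values, groups)

    def test_fold_change_is_ratio_of_group_means(self, matrix):
        out = differential_expression(matrix)
        key = ("P0", "1", "H5N4S1")
        row = matrix.abundance.loc[key]
        expected = row[[c for c in row.index if c.startswith("T")]].mean() / row[
            [c for c in row.index if c.startswith("A")]
        ].mean()
        assert out.loc[key, "fold_change"] == pytest.approx(expected)

    def test_insufficient_rows_flagged_and_excluded_from_bh(self, matrix):
        out = differential_expression(matrix)
        row = out.loc[("P99", "1", "H5N2")]
        assert row["test_used"] == "insufficient"
        assert np.isnan(row["p"]) and np.isnan(row["q"])
        tested = out["p"].notna()
        np.testing.assert_allclose(
            out.loc[tested, "q"].to_numpy(),
            bh_oracle(out.loc[tested, "p"].to_numpy()),
            atol=1e-12,
        )

    def test_planted_shifts_detected(self, matrix):
        out = differential_expression(matrix)
        planted = [(f"P{r}", "1", "H5N4S1") for r in range(5)]
        assert (out.loc[planted, "q"] < 0.05).all()


class TestFoldChangeOverlay:
    def make_results(self):
        idx = pd.MultiIndex.from_tuples(
            [("P1", "10", "H5N4"), ("P2", "20", "F1H5N4S1"), ("P3", "30", "H5N2")],
            names=["protein", "site", "glycan"],
        )
        return pd.DataFrame(
            {
                "mean_tumor": [8.0, 1.0, 6.0],
                "mean_adjacent": [2.0, 5.0, 2.0],
                "fold_change": [4.0, 0.2, 3.0],
                "test_used": ["student"] * 3,
                "statistic": [5.0, -4.0, 4.0],
                "p": [0.001, 0.001, 0.001],
                "q": [0.003, 0.003, 0.003],
            },
            index=idx,
        )

    def test_attribution_flags(self):
        overlay = fold_change_overlay(
            self.make_results(), {"P1": 4.0, "P2": 1.0}
        )
        flags = overlay["attribution"]
        assert flags[("P1", "10", "H5N4")] == "expression-driven"
        assert flags[("P2", "20", "F1H5N4S1")] == "glycosylation-driven"
        assert flags[("P3", "30", "H5N2")] == "unattributed"
        assert np.isnan(overlay.loc[("P3", "30", "H5N2"), "protein_fold_change"])

    def test_opposite_direction_is_glycosylation_driven(self):
        overlay = fold_change_overlay(self.make_results(), {"P2": 3.0})
        assert overlay.loc[("P2", "20", "F1H5N4S1"), "attribution"] == "glycosylation-driven"

    def test_only_significant_rows_included(self):
        res = self.make_results()
        res.loc[("P3", "30", "H5N2"), "q"] = 0.5
        overlay = fold_change_overlay(res, {})
        assert ("P3", "30", "H5N2") not in overlay.index
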