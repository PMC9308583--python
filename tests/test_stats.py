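"""Lesion classification, reliability filtering, preference tables, and tests."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import medastac as m
from medastac.stats import LesionClass, T1Class, model_preference


def _desc(flair=True, t1="iso_to_NAWM", gd=False, v1=0.1, vf=0.1, diam=5.0):
    return m.LesionDescriptor("L", flair, t1, gd, v1, vf, diam)


class TestClassifyLesion:
    def test_remyelinated_rule(self):
        assert m.classify_lesion(_desc(flair=True, t1="iso_to_NAWM", gd=False)) \
            is LesionClass.REMYELINATED

    def test_partially_myelinated_rule(self):
        d = _desc(t1="hypointense", v1=0.05, vf=0.10)
        assert m.classify_lesion(d) is LesionClass.PARTIALLY_MYELINATED

    def test_gadolinium_enhancement_wins(self):
        for t1 in T1Class:
            assert m.classify_lesion(_desc(t1=t1.value, gd=True)) is LesionClass.ACTIVE

    def test_size_exclusion_is_strict(self):
        assert m.classify_lesion(_desc(diam=3.0)) is LesionClass.EXCLUDED
        assert m.classify_lesion(_desc(diam=3.001)) is not LesionClass.EXCLUDED

    def test_exhaustive_descriptor_grid(self):
        """The rule table partitions the full descriptor space."""
        tol = 0.2

        def expected(flair, t1, gd, v1, vf, diam):
            if diam <= 3.0:
                return LesionClass.EXCLUDED
            if gd:
                return LesionClass.ACTIVE
            if t1 == "iso_to_CSF":
                return LesionClass.BLACK_HOLE
            if t1 == "hypointense":
                return (LesionClass.PARTIALLY_MYELINATED
                        if v1 < (1 - tol) * vf else LesionClass.DEMYELINATED)
            return LesionClass.REMYELINATED

        grid = itertools.product(
            [True, False], [c.value for c in T1Class], [True, False],
            [0.05, 0.09, 0.1, 0.15], [0.1], [2.0, 5.0])
        n = 0
        for flair, t1, gd, v1, vf, diam in grid:
            got = m.classify_lesion(_desc(flair, t1, gd, v1, vf, diam), volume_equal_tol=tol)
            assert got is expected(flair, t1, gd, v1, vf, diam), (flair, t1, gd, v1, vf, diam)
            n += 1
        assert n == 2 * 3 * 2 * 4 * 1 * 2


class TestFilterReliable:
    def test_no_removal(self):
        df = pd.DataFrame({"se_percent": [10.0] * 4, "Ki": range(4)})
        kept, removed = m.filter_reliable(df)
        assert removed == 0.0 and len(kept) == 4

    def test_half_removed(self):
        df = pd.DataFrame({"se_percent": [10.0, 30.0, 20.0, 40.0]})
        kept, removed = m.filter_reliable(df)
        assert removed == pytest.approx(0.5)
        assert list(kept["se_percent"]) == [10.0, 20.0]

    def test_nonfinite_counts_as_unreliable(self):
        df = pd.DataFrame({"se_percent": [np.inf, 5.0]})
        _, removed = m.filter_reliable(df)
        assert removed == pytest.approx(0.5)


class TestModelPreference:
    def test_unanimous(self):
        rows = [{"region": f"r{i}", "model": mod, "aic": 1.0 if mod == "2T4k" else 2.0}
                for i in range(3) for mod in ("1T2k", "2T3k", "2T4k")]
        pref = model_preference(pd.DataFrame(rows))
        assert pref.percentages.loc["all", "2T4k"] == pytest.approx(100.0)
        assert pref.preferred("all") == "2T4k"

    def test_tie_splits_vote(self):
        rows = [
            {"region": "r1", "model": "1T2k", "aic": 5.0},
            {"region": "r1", "model": "2T3k", "aic": 5.0},
        ]
        pref = model_preference(pd.DataFrame(rows))
        assert pref.counts.loc["all", "1T2k"] == pytest.approx(0.5)
        assert pref.counts.loc["all"].sum() == pytest.approx(1.0)

    def test_missing_aic_skipped(self):
        rows = [
            {"region": "r1", "model": "1T2k", "aic": np.nan},
            {"region": "r1", "model": "2T3k", "aic": 5.0},
            {"region": "r2", "model": "1T2k", "aic": 1.0},
            {"region": "r2", "model": "2T3k", "aic": 5.0},
        ]
        pref = model_preference(pd.DataFrame(rows))
        assert pref.counts.loc["all"].sum() == pytest.approx(1.0)


class TestCompareMethods:
    def test_identity_and_affine(self):
        x = np.array([0.05, 0.08, 0.11, 0.02, 0.07])
        res = m.compare_methods(x, x)
        assert (res.r, res.slope, res.intercept) == (pytest.approx(1.0), pytest.approx(1.0),
                                                     pytest.approx(0.0, abs=1e-15))
        res2 = m.compare_methods(x, 0.9 * x + 0.01)
        assert res2.r == pytest.approx(1.0)
        assert res2.slope == pytest.approx(0.9)
        assert res2.intercept == pytest.approx(0.01)

    def test_hand_computed_four_points(self):
        # x=(1,2,3,4), y=(2,3,5,6): Sxy=7, Sxx=5 -> slope 1.4,
        # intercept 4-1.4*2.5=0.5, r = 7/sqrt(5*10)
        res = m.compare_methods([1, 2, 3, 4], [2, 3, 5, 6])
        assert res.slope == pytest.approx(1.4)
        assert res.intercept == pytest.approx(0.5)
        assert res.r == pytest.approx(7 / np.sqrt(50))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            m.compare_methods([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            m.compare_methods([1, 2], [1, 2])


class TestGroupDifference:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = m.group_difference(x, x)
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)
        assert res["df"] == 6

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        gm = 1.0 + 1e-3 * rng.standard_normal(5)
        wm = 2.0 + 1e-3 * rng.standard_normal(5)
        res = m.group_difference(gm, wm)
        assert res["p"] < 0.01

    def test_unequal_variance_triggers_welch(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, 20)
        b = rng.normal(0, 5.0, 20)
        res = m.group_difference(a, b)
        assert res["levene_p"] < 0.05
        assert res["test_used"] == "welch_t"
        assert res["df"] < 38  # Welch df below the pooled value


def _brute_force_u(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    gt = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return gt + 0.5 * ties


class TestMannWhitney:
    def test_complete_separation(self):
        res = m.lesion_vs_nawm([1, 2], [3, 4])
        assert res["U"] == 0.0

    def test_identical_samples_symmetric(self):
        res = m.lesion_vs_nawm([1.0, 2.0], [1.0, 2.0])
        assert res["U"] == pytest.approx(2.0)  # n1*n2/2

    def test_enumerated_example(self):
        x, y = [3, 5, 6], [4, 7, 8, 9]
        res = m.lesion_vs_nawm(x, y)
        assert res["U"] == _brute_force_u(x, y) == 2.0
        # exact p by enumeration over all C(7,3)=35 rank assignments
        pooled = np.array(x + y, dtype=float)
        stats = []
        for comb in itertools.combinations(range(7), 3):
            mask = np.zeros(7, bool)
            mask[list(comb)] = True
            stats.append(_brute_force_u(pooled[mask], pooled[~mask]))
        stats = np.asarray(stats)
        u = res["U"]
        p_exact = np.mean(np.minimum(stats, 12 - stats) <= min(u, 12 - u))
        assert res["p"] == pytest.approx(p_exact)

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=5),
           st.lists(st.integers(0, 50), min_size=1, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_statistic_matches_brute_force(self, x, y):
        res = m.lesion_vs_nawm(x, y)
        assert res["U"] == pytest.approx(_brute_force_u(x, y))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            m.lesion_vs_nawm([], [1.0])
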