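import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from salmap.twopoint import (
    CODE_AMBIGUOUS,
    CODE_MISSING,
    TransmissionVector,
    classify_marker,
    estimate_two_point,
    g_test_2x2,
    infer_transmissions,
    lod_score,
    map_function,
    recomdif,
    two_point_matrices,
)

from conftest import make_dataset


class TestClassify:
    @pytest.mark.parametrize(
        "dam,sire,expected",
        [
            ((212, 216), (224, 228), "both_fully_informative"),
            ((212, 216), (212, 224), "both_fully_informative"),
            ((212, 216), (212, 212), "dam_only"),
            ((212, 212), (212, 216), "sire_only"),
            ((212, 216), (212, 216), "intercross_shared"),
            ((212, 212), (216, 216), "uninformative"),
            ((0, 0), (212, 216), "uninformative"),
        ],
    )
    def test_parental_genotype_classes(self, dam, sire, expected):
        assert classify_marker(dam, sire) == expected


class TestTransmissions:
    def test_forced_assignment_codes_transmitted_allele(self):
        ds = make_dataset(
            {"m": {"dam": (212, 216), "sire": (224, 228), "off": [(212, 224), (216, 228)]}}
        )
        tv = infer_transmissions(ds, "m", "dam")
        assert list(tv.codes) == [0, 1]  # 212 = haplotype 0 (sorted order)

    def test_shared_heterozygote_offspring_is_ambiguous_for_both(self):
        ds = make_dataset(
            {"m": {"dam": (212, 216), "sire": (212, 216), "off": [(212, 216)]}}
        )
        for parent in ("dam", "sire"):
            assert infer_transmissions(ds, "m", parent).codes[0] == CODE_AMBIGUOUS

    def test_shared_homozygote_offspring_is_unambiguous_for_both(self):
        ds = make_dataset(
            {"m": {"dam": (212, 216), "sire": (212, 216), "off": [(212, 212)]}}
        )
        for parent in ("dam", "sire"):
            assert infer_transmissions(ds, "m", parent).codes[0] == 0

    def test_incompatible_offspring_coded_missing_with_warning(self):
        ds = make_dataset(
            {"m": {"dam": (212, 216), "sire": (224, 228), "off": [(300, 301)]}}
        )
        with pytest.warns(UserWarning, match="incompatible"):
            tv = infer_transmissions(ds, "m", "dam")
        assert tv.codes[0] == CODE_MISSING

    def test_grandparents_orient_haplotype_zero(self):
        ds = make_dataset(
            {
                "m": {
                    "gs1": (216, 216),
                    "gd1": (212, 212),
                    "gs2": (224, 224),
                    "gd2": (228, 228),
                    "dam": (212, 216),
                    "sire": (224, 228),
                    "off": [(216, 224)],
                }
            },
            grandparents=True,
        )
        tv = infer_transmissions(ds, "m", "dam")
        assert tv.phase_known
        assert tv.codes[0] == 0  # 216 came from the grandsire -> haplotype 0

    def test_homozygous_parent_has_no_meioses(self):
        ds = make_dataset({"m": {"dam": (212, 212), "sire": (212, 216), "off": [(212, 212)]}})
        with pytest.raises(ValueError, match="not heterozygous"):
            infer_transmissions(ds, "m", "dam")


def _tv(codes, parent="dam", marker="m"):
    return TransmissionVector(parent=parent, marker=marker, codes=np.asarray(codes, dtype=np.int8))


class TestTwoPoint:
    def test_perfect_cosegregation(self):
        a = _tv([0, 1] * 5)
        res = estimate_two_point(a, _tv([0, 1] * 5))
        assert res.theta == 0.0
        assert res.lod == pytest.approx(10 * math.log10(2), abs=1e-12)
        assert not res.phase_flipped

    def test_two_recombinants_in_twenty(self):
        a = _tv([0] * 10 + [1] * 10)
        b = _tv([0] * 8 + [1, 1] + [1] * 10)
        res = estimate_two_point(a, b)
        assert res.theta == pytest.approx(0.10)
        assert res.lod == pytest.approx(
            2 * math.log10(0.2) + 18 * math.log10(1.8), abs=1e-12
        )  # = 3.19697 at the ML estimate

    def test_phase_symmetry(self):
        a = _tv([0] * 10 + [1] * 10)
        b = _tv([0] * 8 + [1, 1] + [1] * 10)
        flipped = estimate_two_point(a, _tv(1 - b.codes))
        direct = estimate_two_point(a, b)
        assert flipped.theta == pytest.approx(direct.theta)
        assert flipped.lod == pytest.approx(direct.lod)
        assert flipped.phase_flipped != direct.phase_flipped

    def test_ambiguous_and_missing_excluded_pairwise(self):
        a = _tv([0, 1, CODE_AMBIGUOUS, 0, CODE_MISSING])
        b = _tv([0, 1, 0, CODE_AMBIGUOUS, 1])
        res = estimate_two_point(a, b)
        assert res.n == 2 and res.r == 0

    def test_no_shared_meioses_returns_none(self):
        assert estimate_two_point(_tv([CODE_MISSING]), _tv([0])) is None

    def test_boundary_theta_half_has_zero_lod(self):
        a = _tv([0, 0, 1, 1])
        b = _tv([0, 1, 0, 1])
        res = estimate_two_point(a, b)
        assert res.theta == 0.5 and res.lod == 0.0

    @given(st.integers(2, 48), st.data())
    @settings(max_examples=200, derandomize=True)
    def test_matches_grid_search_ml(self, n, data):
        """The closed-form estimate equals exhaustive likelihood search."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        a = _tv(rng.integers(0, 2, n))
        b = _tv(rng.integers(0, 2, n))
        res = estimate_two_point(a, b)
        grid = np.arange(0.0, 0.5 + 1e-9, 1e-4)
        d = int(np.sum(a.codes != b.codes))
        d = min(d, n - d)
        with np.errstate(divide="ignore"):
            loglik = d * np.log10(np.maximum(grid, 1e-300)) + (n - d) * np.log10(1 - grid)
        best = grid[int(np.argmax(loglik))]
        assert res.theta == pytest.approx(best, abs=5.1e-5)
        assert res.lod == pytest.approx(
            float(np.max(loglik) - (n * np.log10(0.5))), abs=1e-6
        )

    def test_matrix_path_agrees_with_scalar_path(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(-2, 2, size=(6, 40)).astype(np.int8)
        mats = two_point_matrices(codes)
        for i in range(6):
            for j in range(i + 1, 6):
                res = estimate_two_point(_tv(codes[i]), _tv(codes[j]))
                if res is None:
                    assert mats["n"][i, j] == 0
                else:
                    assert mats["n"][i, j] == res.n
                    assert mats["r"][i, j] == res.r
                    assert mats["lod"][i, j] == pytest.approx(res.lod)


class TestMapFunctions:
    def test_zero_theta_is_zero_distance(self):
        for kind in ("morgan", "haldane", "kosambi"):
            assert map_function(0.0, kind) == 0.0

    def test_closed_forms(self):
        assert map_function(0.2, "haldane") == pytest.approx(-50 * math.log(0.6), abs=1e-12)
        assert map_function(0.2, "kosambi") == pytest.approx(
            25 * math.log(1.4 / 0.6), abs=1e-12
        )
        assert map_function(0.2, "morgan") == pytest.approx(20.0)

    def test_kosambi_below_haldane_on_open_interval(self):
        grid = np.linspace(0.001, 0.499, 200)
        assert np.all(map_function(grid, "kosambi") < map_function(grid, "haldane"))

    def test_small_theta_limit_is_morgan(self):
        # exact relative deviations at theta = 0.01: Haldane 1.013%,
        # Kosambi 0.013% — both shrink linearly/quadratically toward 0
        for kind, rel in (("haldane", 0.011), ("kosambi", 0.001)):
            assert map_function(0.01, kind) == pytest.approx(1.0, rel=rel)
        for kind in ("haldane", "kosambi"):
            assert map_function(0.005, kind) == pytest.approx(0.5, rel=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            map_function(0.6, "haldane")
        with pytest.raises(ValueError):
            map_function(-0.1, "morgan")
        with pytest.raises(ValueError):
            map_function(0.1, "carter")

    def test_theta_half_capped(self):
        assert map_function(0.5, "morgan") == 50.0
        assert map_function(0.5, "haldane", cap_cm=75.0) == 75.0

    def test_lod_monotone_in_recombinants(self):
        lods = [lod_score(r, 40) for r in range(0, 21)]
        assert all(a > b for a, b in zip(lods, lods[1:]))


class TestRecomDif:
    def _table(self, rows):
        import pandas as pd

        return pd.DataFrame(
            rows, columns=["marker_a", "marker_b", "r_female", "n_female", "r_male", "n_male"]
        )

    def test_ratio_of_mean_recombinant_counts(self):
        res = recomdif(
            self._table([("a", "b", 4, 40, 1, 40), ("c", "d", 6, 40, 1, 40)])
        )
        assert res.ratio == pytest.approx(5.0)
        assert res.n_pairs == 2

    def test_equal_proportions_give_zero_g(self):
        res = recomdif(self._table([("a", "b", 5, 50, 5, 50)]))
        assert res.g == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_g_statistic_closed_form(self):
        """Pooled table F:(10 rec, 90 non) vs M:(50 rec, 50 non)."""
        res = recomdif(self._table([("a", "b", 10, 100, 50, 100)]))
        obs = np.array([[10, 90], [50, 50]])
        expected = 2 * sum(
            o * math.log(o / e)
            for o, e in zip(
                obs.ravel(),
                (obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()).ravel(),
            )
        )
        assert res.g == pytest.approx(expected, abs=1e-9)
        assert res.g == pytest.approx(40.70, abs=0.01)
        g_scipy, p_scipy, dof, _ = chi2_contingency(
            obs, correction=False, lambda_="log-likelihood"
        )
        assert res.g == pytest.approx(g_scipy, abs=1e-9)
        assert res.p_value == pytest.approx(p_scipy, abs=1e-12)
        assert res.df == dof == 1

    def test_zero_male_recombinants_leaves_ratio_undefined(self):
        res = recomdif(self._table([("a", "b", 5, 40, 0, 40)]))
        assert math.isnan(res.ratio)
        assert res.g > 0

    def test_empty_pair_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            recomdif(self._table([]))

    def test_degenerate_table_returns_zero_g(self):
        assert g_test_2x2(np.array([[0, 0], [0, 0]])) == (0.0, 1.0)
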