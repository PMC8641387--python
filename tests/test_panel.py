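"""Homogenization, orientation/normalization, assembly and correlations."""

import numpy as np
import pandas as pd
import pytest

from devwild import (
    HomogenizationError,
    HomogenizationParams,
    assemble,
    correlations,
    homogenize,
    normalize_and_orient,
)
from devwild.panel import availability_table


def _avail(data, countries, indicators):
    return pd.DataFrame(data, index=countries, columns=indicators, dtype=bool)


class TestHomogenize:
    def test_complete_panel_is_a_no_op(self):
        avail = _avail(np.ones((3, 4)), ["A", "B", "C"], list("wxyz"))
        res = homogenize(avail, {"A": 5, "B": 5, "C": 5}, HomogenizationParams(0.5, 10))
        assert res.countries == ["A", "B", "C"]
        assert res.indicators == list("wxyz")
        assert len(res.audit) == 0

    def test_country_with_20_of_42_indicators_removed_at_step_one(self):
        # half of 42 rounds to 21; a country holding 20 falls below the cut
        cols = [f"i{k}" for k in range(42)]
        rows = np.ones((3, 42), dtype=bool)
        rows[0, 20:] = False  # country A holds exactly 20
        avail = _avail(rows, ["A", "B", "C"], cols)
        res = homogenize(avail, {c: 500 for c in "ABC"}, HomogenizationParams(0.5, 1))
        assert "A" not in res.countries
        step1 = res.audit[res.audit["step"] == 1]
        assert list(step1["entity"]) == ["A"]
        assert int(step1["threshold"].iloc[0]) == 21

    def test_hand_enumerated_three_step_example(self):
        # countries A..D, indicators x,y,z; one gap at (B, z).
        avail = _avail(
            [[1, 1, 1], [1, 1, 0], [1, 1, 1], [0, 1, 1]], list("ABCD"), list("xyz")
        )
        pops = {"A": 10, "B": 10, "C": 4, "D": 3}
        # step 1 (need >= 2 of 3): all countries keep >= 2 -> none removed.
        # step 2 (min 20 pops): x has A,B,C -> 24 keep; y has all -> 27 keep;
        #   z has A,C,D -> 17 < 20 drop.
        # step 3: all remaining countries have x and y -> D lacks x -> drop D.
        res = homogenize(avail, pops, HomogenizationParams(0.5, 20))
        assert res.indicators == ["x", "y"]
        assert res.countries == ["A", "B", "C"]
        reasons = set(zip(res.audit["step"], res.audit["entity"]))
        assert reasons == {(2, "z"), (3, "D")}

    def test_step_order_is_fixed(self):
        # 'poor' holds only y (1 of 4 indicators -> dropped at step 1), and y
        # then loses poor's 100 populations and falls below the step-2 cut.
        # Had indicator pruning run first, y (105 populations) would survive.
        avail = _avail(
            [[0, 1, 0, 0], [1, 1, 1, 1], [1, 0, 1, 1]],
            ["poor", "R1", "R2"],
            list("xyzw"),
        )
        res = homogenize(
            avail, {"poor": 100, "R1": 5, "R2": 5}, HomogenizationParams(0.5, 10)
        )
        assert "poor" not in res.countries
        assert "y" not in res.indicators
        assert res.countries == ["R1", "R2"]
        assert res.indicators == ["x", "z", "w"]  # input column order preserved

    def test_homogenization_is_idempotent(self):
        rng = np.random.default_rng(13)  # seed chosen to prune both axes
        avail = _avail(rng.random((6, 5)) < 0.7, list("ABCDEF"), list("vwxyz"))
        pops = {c: int(n) for c, n in zip("ABCDEF", rng.integers(1, 30, 6))}
        params = HomogenizationParams(0.5, 25)
        first = homogenize(avail, pops, params)
        assert first.countries and len(first.indicators) < 5  # non-trivial prune
        again = homogenize(
            avail.loc[first.countries, first.indicators], pops, params
        )
        assert again.countries == first.countries
        assert again.indicators == first.indicators

    def test_emptied_panel_raises_with_binding_constraint(self):
        avail = _avail([[1, 1]], ["A"], ["x", "y"])
        with pytest.raises(HomogenizationError, match="step 2"):
            homogenize(avail, {"A": 1}, HomogenizationParams(0.5, 99))


class TestNormalizeAndOrient:
    def _trends(self, values, invert=False, code="9.3."):
        return pd.DataFrame(
            {
                "country": [f"C{i}" for i in range(len(values))],
                "indicator_code": code,
                "mean_trend": values,
                "retained": True,
                "invert": invert,
            }
        )

    def test_sample_sd_z_scores(self):
        out, audit = normalize_and_orient(self._trends([1.0, 2.0, 3.0]))
        assert np.allclose(out["z"], [-1.0, 0.0, 1.0])
        assert len(audit) == 0

    def test_inversion_flips_z_exactly(self):
        plain, _ = normalize_and_orient(self._trends([1.0, 2.0, 3.0], invert=False))
        flipped, _ = normalize_and_orient(self._trends([1.0, 2.0, 3.0], invert=True))
        assert np.array_equal(flipped["z"].to_numpy(), -plain["z"].to_numpy())

    def test_normalized_moments(self):
        rng = np.random.default_rng(0)
        out, _ = normalize_and_orient(self._trends(rng.normal(size=25)))
        assert abs(out["z"].mean()) < 1e-12
        assert abs(out["z"].std(ddof=1) - 1.0) < 1e-12

    def test_degenerate_sd_excluded_with_reason(self):
        out, audit = normalize_and_orient(self._trends([2.0, 2.0, 2.0]))
        assert len(out) == 0
        assert audit["reason"].iloc[0] == "zero_cross_country_sd"

    def test_population_sd_convention_available(self):
        out, _ = normalize_and_orient(self._trends([1.0, 2.0, 3.0]), ddof=0)
        assert np.allclose(out["z"], np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5))


def _meta(countries, income="low"):
    return pd.DataFrame(
        {
            "country": countries,
            "region": "region_1",
            "land_area_km2": 1e5,
            "hpd_1996": 50.0,
            "income_class_1995": income,
        }
    )


def _wildlife(pids, country):
    return pd.DataFrame(
        {
            "population_id": pids,
            "species": [f"sp{p}" for p in pids],
            "order": "aves_1",
            "region": "region_1",
            "country": country,
            "mean_trend": 0.01,
        }
    )


def _oriented(country, codes):
    return pd.DataFrame(
        {
            "country": country,
            "indicator_code": codes,
            "oriented_trend": 0.1,
            "z": 0.5,
            "inverted": False,
        }
    )


class TestAssemble:
    def test_cross_join_row_count(self):
        rows, audit = assemble(
            _wildlife(["p1", "p2"], "A"), _oriented("A", ["x", "y", "z"]), _meta(["A"])
        )
        assert len(rows["bird"]) == 6
        assert len(audit) == 0
        assert np.allclose(rows["bird"]["log_land_area"], 5.0)

    def test_population_in_excluded_country_dropped_with_audit(self):
        rows, audit = assemble(
            _wildlife(["p1"], "B"), _oriented("A", ["x"]), _meta(["A", "B"])
        )
        assert rows == {}
        assert audit["reason"].iloc[0] == "country_not_homogenized"

    def test_income_filter_applies(self):
        rows, audit = assemble(
            _wildlife(["p1"], "A"),
            _oriented("A", ["x"]),
            _meta(["A"], income="upper_middle"),
        )
        assert rows == {}
        assert audit["reason"].iloc[0] == "income_class_excluded"


class TestCorrelations:
    def test_diagonal_and_inverted_copy(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=10)
        frame = pd.concat(
            [
                pd.DataFrame(
                    {
                        "country": [f"C{i}" for i in range(10)],
                        "indicator_code": code,
                        "oriented_trend": v,
                    }
                )
                for code, v in [("a", vals), ("b", -vals)]
            ]
        )
        table = correlations(frame).set_index(["indicator_a", "indicator_b"])
        assert table.loc[("a", "a"), "r"] == 1.0
        assert table.loc[("a", "b"), "r"] == pytest.approx(-1.0)
        assert table.loc[("b", "a"), "r"] == pytest.approx(-1.0)

    def test_pairs_below_minimum_overlap_are_undefined(self):
        frame = pd.DataFrame(
            {
                "country": ["C1", "C2", "C1", "C2"],
                "indicator_code": ["a", "a", "b", "b"],
                "oriented_trend": [0.1, 0.2, 0.3, 0.4],
            }
        )
        table = correlations(frame, min_n=3).set_index(["indicator_a", "indicator_b"])
        assert np.isnan(table.loc[("a", "b"), "r"])


def test_availability_table_pivots_retained_only():
    trends = pd.DataFrame(
        {
            "country": ["A", "A", "B"],
            "indicator_code": ["x", "y", "x"],
            "mean_trend": [0.1, 0.2, 0.3],
            "retained": [True, False, True],
            "invert": False,
        }
    )
    table = availability_table(trends)
    assert bool(table.loc["A", "x"]) and bool(table.loc["B", "x"])
    assert "y" not in table.columns or not table["y"].any()
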