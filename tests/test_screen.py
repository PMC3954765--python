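"""Aggregation, normalization, hit calling and screen-level statistics."""

import numpy as np
import pandas as pd
import pytest

from synaptoquant.pairing import PARAMETERS
from synaptoquant.screen import (
    PlateMap,
    aggregate_shrna,
    aggregate_shrnas,
    aggregate_well,
    aggregate_wells,
    call_hits,
    cross_readout_regression,
    normalize_to_controls,
    population_comparison,
)
from tests.conftest import make_layout


def site_rows(plate, well, values_by_param, low_flags=None):
    n = len(next(iter(values_by_param.values())))
    low_flags = low_flags or [False] * n
    rows = []
    for i in range(n):
        row = {"plate": plate, "well": well, "site": i + 1,
               "low_dendrite_flag": low_flags[i]}
        for p in PARAMETERS:
            row[p] = values_by_param.get(p, [1.0] * n)[i]
        rows.append(row)
    return pd.DataFrame(rows)


class TestAggregateWell:
    def test_odd_median(self):
        df = site_rows("P1", "A01", {"psd95_count": [1.0, 2.0, 3.0]})
        out = aggregate_well(df)
        assert out[out.parameter == "psd95_count"].value.iloc[0] == 2.0

    def test_even_median_mean_of_middle(self):
        df = site_rows("P1", "A01", {"psd95_count": [1.0, 2.0, 3.0, 4.0]})
        out = aggregate_well(df)
        assert out[out.parameter == "psd95_count"].value.iloc[0] == 2.5

    def test_constant_sites(self):
        df = site_rows("P1", "A01", {"psd95_count": [7.0] * 9})
        row = aggregate_well(df).set_index("parameter").loc["psd95_count"]
        assert row.value == 7.0 and row.n_sites == 9

    def test_low_dendrite_sites_excluded_from_densities_only(self):
        df = site_rows(
            "P1", "A01",
            {"psd95_count": [10.0, 20.0, 30.0],
             "psd95_density_per_um": [0.1, 0.2, 0.9]},
            low_flags=[False, False, True],
        )
        out = aggregate_well(df).set_index("parameter")
        assert out.loc["psd95_count"].value == 20.0          # all 3 sites
        assert out.loc["psd95_density_per_um"].value == pytest.approx(0.15)
        assert out.loc["psd95_density_per_um"].n_sites == 2

    def test_mixed_wells_rejected(self):
        df = pd.concat([site_rows("P1", "A01", {"psd95_count": [1.0]}),
                        site_rows("P1", "A02", {"psd95_count": [2.0]})])
        with pytest.raises(ValueError):
            aggregate_well(df)


class TestAggregateShrna:
    def _well_values(self, vals, param="psd95_count"):
        return pd.DataFrame(
            [{"plate": "P1", "well": f"A{i:02d}", "parameter": param, "value": v,
              "n_sites": 9} for i, v in enumerate(vals)]
        )

    def test_median_and_mad_closed_form(self):
        out = aggregate_shrna(self._well_values([1.0, 2.0, 3.0]), "sh1")
        row = out.set_index("parameter").loc["psd95_count"]
        assert row["median"] == 2.0 and row["mad"] == 1.0
        assert row["n_replicates"] == 3

    def test_identical_replicates_zero_cv(self):
        out = aggregate_shrna(self._well_values([5.0] * 4), "sh1")
        assert out.pct_cv.iloc[0] == 0.0

    def test_zero_mean_cv_flagged(self):
        with pytest.warns(UserWarning):
            out = aggregate_shrna(self._well_values([-1.0, 1.0]), "sh1")
        assert np.isnan(out.pct_cv.iloc[0])

    def test_lognormal_against_independent_recomputation(self, rng):
        import statistics

        draws = rng.lognormal(mean=0.0, sigma=0.5, size=1000)
        out = aggregate_shrna(self._well_values(list(draws)), "sh1")
        row = out.iloc[0]
        med = statistics.median(draws)
        mad = statistics.median([abs(x - med) for x in draws])
        cv = 100.0 * statistics.stdev(draws) / statistics.fmean(draws)
        assert row["median"] == pytest.approx(med, rel=1e-12)
        assert row["mad"] == pytest.approx(mad, rel=1e-12)
        assert row["pct_cv"] == pytest.approx(cv, rel=1e-9)


def _screen_fixture():
    """Two library hairpins + three negative controls, 2 wells each, on P1."""
    rows = []

    def add(shrna, gene, role, wells, value):
        for w, v in zip(wells, value):
            rows.append({"plate": "P1", "well": w, "shrna_id": shrna,
                         "gene": gene, "role": role, "value": v})

    add("shA", "geneA", "library", ["A01", "A02"], [4.0, 6.0])      # median 5
    add("shB", "geneB", "library", ["B01", "B02"], [9.0, 11.0])     # median 10
    add("neg1", "g1", "negative_control", ["C01", "C02"], [9.0, 10.0])
    add("neg2", "g2", "negative_control", ["D01", "D02"], [10.0, 11.0])
    add("neg3", "g3", "negative_control", ["E01", "E02"], [10.0, 10.0])
    df = pd.DataFrame(rows)
    platemap = PlateMap(df[["plate", "well", "shrna_id", "gene", "role"]])
    wells = df.rename(columns={"value": "value"})[["plate", "well", "value"]]
    wells["parameter"] = "pair_psd95_syn1_density_per_um"
    wells["n_sites"] = 9
    return wells, platemap


class TestNormalize:
    def test_control_matched_shrna_normalizes_to_one(self):
        wells, pm = _screen_fixture()
        summ = aggregate_shrnas(wells, pm)
        out = normalize_to_controls(summ, wells, pm)
        b = out[out.shrna_id == "shB"].iloc[0]
        assert b.normalized == pytest.approx(1.0)  # ctrl median is 10
        a = out[out.shrna_id == "shA"].iloc[0]
        assert a.normalized == pytest.approx(0.5)

    def test_missing_negative_controls_names_plate(self):
        wells, pm = _screen_fixture()
        lib_only = PlateMap(pm.table[pm.table.role == "library"])
        summ = aggregate_shrnas(wells, lib_only)
        with pytest.raises(ValueError, match="P1"):
            normalize_to_controls(summ, wells, lib_only)

    def test_welch_ttest_matches_closed_form(self):
        from scipy.special import stdtr

        wells, pm = _screen_fixture()
        # replace shA's replicate values with {1,2,3}; controls {4,5,6}
        rows = []
        for w, v in zip(["A01", "A02", "A03"], [1.0, 2.0, 3.0]):
            rows.append({"plate": "P1", "well": w, "shrna_id": "shA",
                         "gene": "geneA", "role": "library", "value": v})
        for w, v in zip(["C01", "C02", "C03"], [4.0, 5.0, 6.0]):
            rows.append({"plate": "P1", "well": w, "shrna_id": "neg1",
                         "gene": "g1", "role": "negative_control", "value": v})
        df = pd.DataFrame(rows)
        pm = PlateMap(df[["plate", "well", "shrna_id", "gene", "role"]])
        wells = df[["plate", "well", "value"]].copy()
        wells["parameter"] = "x"
        wells["n_sites"] = 1
        out = normalize_to_controls(aggregate_shrnas(wells, pm), wells, pm)
        p = out[out.shrna_id == "shA"].p_value.iloc[0]
        # textbook Welch: t = -3/sqrt(2/3), df = 4
        t_stat = -3.0 / np.sqrt(2.0 / 3.0)
        p_expected = 2.0 * stdtr(4.0, t_stat)
        assert p == pytest.approx(p_expected, rel=1e-9)

    def test_identical_samples_give_p_one(self):
        from scipy import stats

        t = stats.ttest_ind([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], equal_var=False)
        assert t.pvalue == pytest.approx(1.0)


class TestCallHits:
    def _summary(self, normalized_by_shrna, parameter="p"):
        rows = []
        for shrna, norm in normalized_by_shrna.items():
            rows.append({"shrna_id": shrna, "gene": "geneX", "role": "library",
                         "parameter": parameter, "median": norm, "mad": 0.0,
                         "pct_cv": 0.0, "n_replicates": 3, "normalized": norm,
                         "p_value": 0.5})
        return pd.DataFrame(rows)

    def test_two_of_five_at_forty_percent(self):
        s = self._summary({f"h{i}": v for i, v in
                           enumerate([0.55, 0.58, 0.90, 1.00, 1.05])})
        (call,) = call_hits(s, parameter="p")
        assert call.n_hairpins_passing == 2
        assert call.is_hit

    def test_no_effect_no_hit(self):
        s = self._summary({f"h{i}": 1.0 for i in range(5)})
        (call,) = call_hits(s, parameter="p")
        assert call.n_hairpins_passing == 0 and not call.is_hit

    def test_boundary_forty_percent_reduction_is_inclusive(self):
        s = self._summary({"h0": 0.60, "h1": 0.60, "h2": 1.0})
        (call,) = call_hits(s, parameter="p")
        assert call.n_hairpins_passing == 2 and call.is_hit

    def test_stricter_sixty_percent_rule(self):
        s = self._summary({"h0": 0.55, "h1": 0.58, "h2": 0.35, "h3": 0.39})
        (call,) = call_hits(s, parameter="p", threshold_fraction=0.60)
        assert call.n_hairpins_passing == 2 and call.is_hit

    def test_single_passing_hairpin_is_not_a_hit(self):
        s = self._summary({"h0": 0.2, "h1": 1.0, "h2": 1.0})
        (call,) = call_hits(s, parameter="p")
        assert call.n_hairpins_passing == 1 and not call.is_hit


class TestRegression:
    def _summary(self, xs, ys):
        rows = []
        for i, (x, y) in enumerate(zip(xs, ys)):
            for param, v in (("px", x), ("py", y)):
                rows.append({"shrna_id": f"s{i}", "gene": f"g{i}",
                             "role": "library", "parameter": param,
                             "median": v, "mad": 0.0, "pct_cv": 0.0,
                             "n_replicates": 3, "normalized": v, "p_value": 0.5})
        return pd.DataFrame(rows)

    def test_perfect_linear_relation(self):
        xs = [0.2, 0.5, 0.8, 1.0, 1.3]
        s = self._summary(xs, [2 * x for x in xs])
        fit = cross_readout_regression(s, "px", "py")
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_independent_noise_low_r_squared(self, rng):
        xs = rng.normal(1, 0.2, 200)
        ys = rng.normal(1, 0.2, 200)
        fit = cross_readout_regression(self._summary(xs, ys), "px", "py")
        assert fit.r_squared < 0.05

    def test_matches_normal_equations(self, rng):
        xs = [0.3, 0.7, 0.9, 1.1, 1.6]
        ys = [0.5, 0.6, 1.0, 0.9, 1.7]
        fit = cross_readout_regression(self._summary(xs, ys), "px", "py")
        X = np.column_stack([np.ones(5), xs])
        beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(ys))
        resid = ys - X @ beta
        r2 = 1 - resid @ resid / np.sum((ys - np.mean(ys)) ** 2)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
        assert fit.slope == pytest.approx(beta[1], rel=1e-9)
        assert fit.r_squared == pytest.approx(r2, rel=1e-9)

    def test_too_few_points_or_zero_variance(self):
        s = self._summary([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            cross_readout_regression(self._summary([1.0], [2.0]), "px", "py")
        with pytest.raises(ValueError, match="variance"):
            cross_readout_regression(s, "px", "py")


class TestPopulationComparison:
    def test_identical_groups_p_one(self):
        p, _, _ = population_comparison(
            pd.DataFrame(), "p",
            values_a=np.array([1.0, 2.0, 3.0]),
            values_b=np.array([1.0, 2.0, 3.0]),
        )
        assert p == pytest.approx(1.0)

    def test_strongly_shifted_groups(self, rng):
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(3.0, 1.0, 50)
        p, _, _ = population_comparison(pd.DataFrame(), "p",
                                        values_a=a, values_b=b)
        assert p < 0.001

    def test_ecdf_reaches_one(self, rng):
        p, (xa, fa), (xb, fb) = population_comparison(
            pd.DataFrame(), "p",
            values_a=rng.random(10), values_b=rng.random(12),
        )
        assert fa[-1] == 1.0 and fb[-1] == 1.0
        assert np.all(np.diff(xa) >= 0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            population_comparison(pd.DataFrame(), "p",
                                  values_a=np.array([1.0]),
                                  values_b=np.array([1.0, 2.0]))


def test_aggregation_invariant_to_site_and_well_order(rng):
    layout = make_layout(n_genes=1, hairpins_per_gene=2, n_negative=2)
    frames = []
    for _, row in layout.iterrows():
        vals = {p: list(rng.random(4) + 1) for p in PARAMETERS}
        frames.append(site_rows(row.plate, row.well, vals))
    sites = pd.concat(frames, ignore_index=True)
    shuffled = sites.sample(frac=1.0, random_state=0).reset_index(drop=True)
    w1 = aggregate_wells(sites).sort_values(["well", "parameter"]).reset_index(drop=True)
    w2 = aggregate_wells(shuffled).sort_values(["well", "parameter"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(w1, w2)


def test_platemap_validation():
    bad = pd.DataFrame([
        {"plate": "P1", "well": "A01", "shrna_id": "s1", "gene": "g1",
         "role": "library"},
        {"plate": "P1", "well": "A01", "shrna_id": "s2", "gene": "g2",
         "role": "library"},
    ])
    with pytest.raises(ValueError, match="duplicate"):
        PlateMap(bad)
    bad2 = pd.DataFrame([
        {"plate": "P1", "well": "A01", "shrna_id": "s1", "gene": "g1",
         "role": "library"},
        {"plate": "P1", "well": "A02", "shrna_id": "s1", "gene": "g2",
         "role": "library"},
    ])
    with pytest.raises(ValueError, match="multiple genes"):
        PlateMap(bad2)
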