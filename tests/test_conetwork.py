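import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from placeframes.conetwork import (
    CANONICAL_REGIONS,
    average_replicates,
    build_graph,
    compare_groups,
    correlation_matrix,
    fdr_select,
    fisher_z_compare,
    normalize_to_standards,
    proportion_test,
)


def synthetic_table(n_subjects=10, rho=0.0, seed=0, regions=CANONICAL_REGIONS):
    rng = np.random.default_rng(seed)
    k = len(regions)
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    data = rng.multivariate_normal(np.zeros(k), cov, size=n_subjects,
                                   method="cholesky")
    return pd.DataFrame(data, columns=list(regions))


class TestAverageReplicates:
    def test_mean_of_readings(self):
        df = pd.DataFrame({"subject": ["s1"] * 3, "region": ["RE"] * 3,
                           "od": [1.0, 2.0, 3.0]})
        assert average_replicates(df).loc["s1", "RE"] == pytest.approx(2.0)

    def test_single_reading(self):
        df = pd.DataFrame({"subject": ["s1"], "region": ["RE"], "od": [1.7]})
        assert average_replicates(df).loc["s1", "RE"] == pytest.approx(1.7)

    def test_missing_stays_nan(self):
        df = pd.DataFrame({"subject": ["s1", "s2"], "region": ["RE", "DS"],
                           "od": [1.0, 2.0]})
        wide = average_replicates(df)
        assert np.isnan(wide.loc["s1", "DS"])

    def test_hemispheres_pooled(self):
        df = pd.DataFrame({"subject": ["s1"] * 4, "region": ["RE"] * 4,
                           "hemisphere": ["L", "L", "R", "R"],
                           "od": [1.0, 1.0, 3.0, 3.0]})
        assert average_replicates(df).loc["s1", "RE"] == pytest.approx(2.0)


class TestNormalization:
    def test_known_slope(self):
        standards = pd.DataFrame({"batch": ["b1"] * 4,
                                  "thickness_um": [20, 40, 60, 80],
                                  "od": [0.2, 0.4, 0.6, 0.8]})  # slope 0.01/um
        raw = pd.DataFrame({"batch": ["b1"], "od": [0.5]})
        out = normalize_to_standards(raw, standards)
        assert out.iloc[0] == pytest.approx(50.0)

    def test_common_rescaling_preserves_r(self):
        table = synthetic_table(12, rho=0.4, seed=1)
        edges_raw = correlation_matrix(table)
        edges_scaled = correlation_matrix(table / 0.01)
        assert np.allclose(edges_raw["r"], edges_scaled["r"])

    def test_degenerate_standards(self):
        standards = pd.DataFrame({"batch": ["b1"] * 2, "thickness_um": [40, 40],
                                  "od": [0.2, 0.4]})
        with pytest.raises(ValueError, match="degenerate"):
            normalize_to_standards(pd.DataFrame({"batch": ["b1"], "od": [0.5]}),
                                   standards)

    def test_zero_slope(self):
        standards = pd.DataFrame({"batch": ["b1"] * 2, "thickness_um": [20, 80],
                                  "od": [0.3, 0.3]})
        with pytest.raises(ValueError, match="zero"):
            normalize_to_standards(pd.DataFrame({"batch": ["b1"], "od": [0.5]}),
                                   standards)


class TestCorrelationMatrix:
    def test_canonical_pair_count(self):
        edges = correlation_matrix(synthetic_table(8, seed=2))
        assert len(edges) == 91   # C(14, 2)

    def test_duplicated_region_perfect_r(self):
        table = synthetic_table(8, seed=3, regions=("A", "B"))
        table["A2"] = table["A"]
        edges = correlation_matrix(table)
        row = edges[(edges.region_a == "A") & (edges.region_b == "A2")]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_known_sigma_recovery(self):
        table = synthetic_table(200, rho=0.5, seed=4, regions=("A", "B", "C"))
        edges = correlation_matrix(table)
        assert np.all(np.abs(edges["r"] - 0.5) < 0.1)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="subjects"):
            correlation_matrix(synthetic_table(3, seed=5))


class TestFdr:
    def test_all_ones_empty(self):
        assert not fdr_select(np.ones(91)).any()

    def test_single_tiny_p_selected(self):
        p = np.ones(91)
        p[40] = 1e-6
        sel = fdr_select(p)
        assert sel[40] and sel.sum() == 1

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_q(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 91) ** 2
        sel_small = fdr_select(p, q=0.01)
        sel_large = fdr_select(p, q=0.05)
        assert np.all(sel_large[sel_small])   # lowering q never adds edges


class TestFisherZ:
    def test_equal_r_is_zero(self):
        z, p = fisher_z_compare(0.5, 10, 0.5, 12)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_closed_form(self):
        z, _ = fisher_z_compare(0.9, 8, 0.0, 8)
        assert z == pytest.approx(np.arctanh(0.9) / np.sqrt(2 / 5), abs=1e-9)
        assert z == pytest.approx(2.328, abs=0.001)

    def test_perfect_correlation_error(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 8, 0.0, 8)


class TestProportionTest:
    def test_equal_proportions(self):
        z, p = proportion_test(5, 10, 10, 20)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_pooled_formula(self):
        z, _ = proportion_test(15, 91, 7, 91)
        pool = 22 / 182
        expect = (15 / 91 - 7 / 91) / np.sqrt(pool * (1 - pool) * (2 / 91))
        assert z == pytest.approx(expect)

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            proportion_test(12, 10, 1, 10)


class TestGraph:
    def test_tiers_nested(self):
        table = synthetic_table(20, rho=0.6, seed=6)
        edges = correlation_matrix(table)
        assert np.all(edges.loc[edges.significant_fdr, "significant_p05"])
        G = build_graph(edges, regions=CANONICAL_REGIONS)
        assert set(G.nodes) == set(CANONICAL_REGIONS)
        for _, _, d in G.edges(data=True):
            assert d["p"] < 0.05

    def test_no_edges_nodes_only(self):
        edges = correlation_matrix(synthetic_table(8, rho=0.0, seed=12345))
        edges["significant_p05"] = False
        edges["significant_fdr"] = False
        G = build_graph(edges)
        assert G.number_of_edges() == 0 and G.number_of_nodes() == 14


def test_compare_groups_row_per_pair():
    a = correlation_matrix(synthetic_table(8, seed=7))
    b = correlation_matrix(synthetic_table(8, seed=8))
    out = compare_groups(a, b)
    assert len(out) == 91
    assert np.isfinite(out["fisher_z"]).all()
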