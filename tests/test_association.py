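"""Association indices, quadrant assignment and coherent-pair selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lncmodnet.association import (
    AreaError,
    CoherenceConfig,
    INDICES,
    UndefinedIndexError,
    assign_areas,
    association_index,
    combine_contexts,
    pairwise_profile_similarity,
    select_coherent_pairs,
)
from lncmodnet.bipartite import BipartiteNetwork


def brute_force_index(na, nb, method, n_y=None):
    """Independent set-arithmetic/incidence-vector computation."""
    inter = sum(1 for e in na if e in nb)
    ka, kb = len(na), len(nb)
    if method == "jaccard":
        union = len(set(na) | set(nb))
        return inter / union
    if method == "simpson":
        return inter / min(ka, kb)
    if method == "geometric":
        return inter * inter / (ka * kb)
    if method == "cosine":
        return inter / (ka * kb) ** 0.5
    if method == "pcc":
        universe = sorted(set(range(n_y)))
        va = np.array([1.0 if u in na else 0.0 for u in universe])
        vb = np.array([1.0 if u in nb else 0.0 for u in universe])
        return float(np.corrcoef(va, vb)[0, 1])
    raise AssertionError(method)


def make_network(neighborhoods, n_y):
    """Bipartite network with given x-side neighborhoods over 0..n_y-1."""
    rows = [
        {"x": x, "y": f"y{y}", "z": 4.0}
        for x, ys in neighborhoods.items()
        for y in ys
    ]
    # make sure all Y nodes exist by attaching a dummy hub if needed
    present = {r["y"] for r in rows}
    for y in range(n_y):
        if f"y{y}" not in present:
            rows.append({"x": "_hub", "y": f"y{y}", "z": 4.0})
    return BipartiteNetwork(
        edges=pd.DataFrame(rows), x_class="lncRNA", y_class="mRNA"
    )


class TestAssociationIndex:
    def test_worked_example_all_set_indices(self):
        na, nb = {"m1", "m2", "m3"}, {"m2", "m3", "m4"}
        assert association_index(na, nb, "jaccard") == pytest.approx(0.5)
        assert association_index(na, nb, "simpson") == pytest.approx(2 / 3)
        assert association_index(na, nb, "geometric") == pytest.approx(4 / 9)
        assert association_index(na, nb, "cosine") == pytest.approx(2 / 3)

    def test_identical_neighborhoods_give_unity(self):
        na = {"a", "b"}
        for method in ("jaccard", "simpson", "geometric", "cosine"):
            assert association_index(na, na, method) == pytest.approx(1.0)
        assert association_index(na, na, "pcc", n_y=5) == pytest.approx(1.0)

    def test_pcc_zero_case_matches_incidence_pearson(self):
        # numerator 1*4 - 2*2 = 0
        na, nb = {0, 1}, {1, 2}
        value = association_index(na, nb, "pcc", n_y=4)
        assert value == pytest.approx(0.0, abs=1e-12)
        assert value == pytest.approx(
            brute_force_index(na, nb, "pcc", n_y=4), abs=1e-12
        )

    def test_empty_neighborhood_signals(self):
        with pytest.raises(UndefinedIndexError):
            association_index(set(), {"a"}, "simpson")
        with pytest.raises(UndefinedIndexError):
            association_index(set(), set(), "jaccard")
        with pytest.raises(UndefinedIndexError):
            association_index({"a"}, set(), "cosine")

    def test_jaccard_with_one_empty_side_is_zero(self):
        assert association_index(set(), {"a"}, "jaccard") == 0.0

    def test_pcc_full_profile_signals(self):
        with pytest.raises(UndefinedIndexError):
            association_index({0, 1}, {0}, "pcc", n_y=2)

    def test_sampled_neighborhood_pairs_match_brute_force(self):
        """All five indices agree with direct set/vector computation."""
        n_y = 12
        universe = list(range(n_y))
        rng = np.random.default_rng(0)
        for _ in range(2000):
            na = frozenset(rng.choice(universe, rng.integers(1, n_y), replace=False))
            nb = frozenset(rng.choice(universe, rng.integers(1, n_y), replace=False))
            for method in INDICES:
                if method == "pcc" and (len(na) == n_y or len(nb) == n_y):
                    continue
                got = association_index(na, nb, method, n_y=n_y)
                want = brute_force_index(na, nb, method, n_y=n_y)
                assert got == pytest.approx(want, abs=1e-12), (na, nb, method)

    def test_index_ordering_exhaustive_small_universe(self):
        """geometric <= cosine <= simpson and jaccard <= cosine, all pairs."""
        universe = list(range(6))
        subsets = [
            frozenset(c)
            for r in range(1, 7)
            for c in itertools.combinations(universe, r)
        ]
        for na in subsets:
            for nb in subsets:
                geo = association_index(na, nb, "geometric")
                cos = association_index(na, nb, "cosine")
                simp = association_index(na, nb, "simpson")
                jac = association_index(na, nb, "jaccard")
                assert geo <= cos + 1e-12
                assert cos <= simp + 1e-12
                assert jac <= cos + 1e-12


class TestPairwiseProfileSimilarity:
    def test_matches_scalar_on_small_network(self):
        rng = np.random.default_rng(1)
        neigh = {
            f"l{i}": set(rng.choice(8, rng.integers(1, 8), replace=False))
            for i in range(10)
        }
        net = make_network(neigh, 8)
        table = pairwise_profile_similarity(net, "x")
        n_y = net.n_y
        for row in table.itertuples():
            na = net.neighbors(row.node_a, "x")
            nb = net.neighbors(row.node_b, "x")
            for method in INDICES:
                got = getattr(row, method)
                try:
                    want = association_index(na, nb, method, n_y=n_y)
                except UndefinedIndexError:
                    assert np.isnan(got)
                    continue
                assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_in_pair_order(self):
        net = make_network({"l0": {0, 1}, "l1": {1, 2}, "l2": {0, 2}}, 4)
        t1 = pairwise_profile_similarity(net, "x").set_index(["node_a", "node_b"])
        # the table enumerates each unordered pair once; symmetry follows
        # from the index definition, checked via the scalar operation
        for (a, b), row in t1.iterrows():
            for method in ("jaccard", "cosine"):
                assert row[method] == pytest.approx(
                    association_index(
                        net.neighbors(b, "x"), net.neighbors(a, "x"), method
                    )
                )

    def test_disjoint_singleton_all_zero(self):
        net = make_network({"l0": {0}, "l1": {1, 2}, "l2": {2, 3}}, 5)
        table = pairwise_profile_similarity(net, "x")
        rows = table[(table["node_a"] == "l0") | (table["node_b"] == "l0")]
        for method in ("jaccard", "simpson", "geometric", "cosine"):
            assert (rows[method] == 0).all()

    def test_single_node_side_errors(self):
        net = make_network({"l0": {0, 1}}, 2)
        net_single = BipartiteNetwork(
            edges=net.edges[net.edges["x"] == "l0"],
            x_class="lncRNA", y_class="mRNA",
        )
        with pytest.raises(ValueError):
            pairwise_profile_similarity(net_single, "x")


def make_records(v1, v2, index="jaccard"):
    k = len(v1)
    return pd.DataFrame(
        {
            "node_a": [f"a{i}" for i in range(k)],
            "node_b": [f"b{i}" for i in range(k)],
            "index": index,
            "value_c1": v1,
            "value_c2": v2,
        }
    )


class TestAssignAreas:
    def test_quadrants(self):
        rec = make_records([0.1, 0.9, 0.1, 0.9], [0.1, 0.1, 0.9, 0.9])
        out = assign_areas(rec, area_quantile=0.5)
        assert list(out["area"]) == ["A", "B", "C", "D"]

    def test_labels_partition_records(self):
        rng = np.random.default_rng(2)
        rec = make_records(rng.random(50), rng.random(50))
        out = assign_areas(rec, 0.95)
        assert out["area"].notna().all()
        assert set(out["area"]) <= {"A", "B", "C", "D"}

    def test_median_split_marks_top_half_high(self):
        v1 = np.arange(10) / 10
        rng = np.random.default_rng(3)
        v2 = rng.permutation(10) / 10
        out = assign_areas(make_records(v1, v2), area_quantile=0.5)
        high1 = set(out.loc[out["area"].isin(["B", "D"]), "node_a"])
        assert high1 == {f"a{i}" for i in range(5, 10)}
        high2 = set(out.loc[out["area"].isin(["C", "D"]), "node_a"])
        assert high2 == {f"a{i}" for i in np.argsort(v2)[5:]}

    def test_degenerate_axis_errors(self):
        rec = make_records([0.5] * 10, np.arange(10) / 10)
        with pytest.raises(AreaError):
            assign_areas(rec)

    def test_missing_values_get_missing_label(self):
        rec = make_records([0.1, np.nan, 0.9], [0.2, 0.3, 0.8])
        out = assign_areas(rec, 0.5)
        assert pd.isna(out.loc[1, "area"])


class TestSelectCoherentPairs:
    def records_with_top_pair(self, n_indices):
        """One pair at the extreme of both axes for ``n_indices`` indices."""
        frames = []
        rng = np.random.default_rng(4)
        for j, index in enumerate(INDICES):
            v1 = list(rng.uniform(0.0, 0.5, 40))
            v2 = list(rng.uniform(0.0, 0.5, 40))
            if j < n_indices:
                v1[0], v2[0] = 1.0, 1.0
            frames.append(make_records(v1, v2, index))
        return pd.concat(frames, ignore_index=True)

    def test_pair_supported_by_three_indices_selected(self):
        rec = assign_areas(self.records_with_top_pair(3), 0.95)
        out = select_coherent_pairs(rec, CoherenceConfig(top_frac=0.05))
        selected = out.set_index(["node_a", "node_b"])["n_supporting"]
        assert selected.get(("a0", "b0")) == 3

    def test_pair_supported_by_two_indices_rejected(self):
        rec = assign_areas(self.records_with_top_pair(2), 0.95)
        out = select_coherent_pairs(rec, CoherenceConfig(top_frac=0.05))
        assert len(out) == 0

    def test_coherent_subset_of_area_d(self):
        rng = np.random.default_rng(5)
        frames = [
            make_records(rng.random(60), rng.random(60), index)
            for index in INDICES
        ]
        rec = assign_areas(pd.concat(frames, ignore_index=True), 0.9)
        out = select_coherent_pairs(
            rec, CoherenceConfig(min_indices=1, top_frac=0.2, area_quantile=0.9)
        )
        d_pairs = set(
            rec.loc[rec["area"] == "D", ["node_a", "node_b"]]
            .itertuples(index=False, name=None)
        )
        for pair in out[["node_a", "node_b"]].itertuples(index=False, name=None):
            assert pair in d_pairs

    def test_undefined_values_never_qualify(self):
        frames = []
        for index in INDICES:
            v1 = [np.nan] + list(np.linspace(0.1, 0.9, 20))
            v2 = [np.nan] + list(np.linspace(0.1, 0.9, 20))
            frames.append(make_records(v1, v2, index))
        rec = assign_areas(pd.concat(frames, ignore_index=True), 0.5)
        out = select_coherent_pairs(
            rec, CoherenceConfig(min_indices=1, top_frac=0.3)
        )
        assert "a0" not in set(out["node_a"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CoherenceConfig(min_indices=6).validate()
        with pytest.raises(ValueError):
            CoherenceConfig(top_frac=0.0).validate()


def test_cross_context_concordance_on_default_cohort(default_run):
    """High similarity via shared mRNAs co-occurs with high via miRNAs."""
    rec = pd.read_csv(
        default_run["rundir"] / "similarity_lncRNA.tsv", sep="\t"
    )
    sub = rec[rec["index"] == "jaccard"].dropna(subset=["value_c1", "value_c2"])
    from scipy.stats import spearmanr

    rho = spearmanr(sub["value_c1"], sub["value_c2"]).statistic
    assert rho > 0


def test_planted_pairs_enriched_in_area_d(default_run):
    """Same-group lncRNA pairs concentrate in area D, not area A."""
    truth = default_run["cohort"].truth
    rec = pd.read_csv(
        default_run["rundir"] / "similarity_lncRNA.tsv", sep="\t"
    )
    rec = rec.dropna(subset=["area"])

    def is_planted(row):
        ga = truth.group_of.get(row.node_a, 0)
        return ga > 0 and ga == truth.group_of.get(row.node_b, 0)

    rates = {}
    for area in ("A", "D"):
        sub = rec[rec["area"] == area]
        hits = sum(is_planted(r) for r in sub.itertuples())
        rates[area] = hits / len(sub)
    assert rates["D"] > rates["A"]
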