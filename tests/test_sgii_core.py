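import itertools

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from sgii import (
    GICResult,
    LPPINetwork,
    MOUSE_PARAMS,
    SGIIParams,
    build_rank_table,
    classify,
    compute_centralities,
    configure_subset,
    indicator,
    rank_descending,
)
from sgii.errors import ConfigError, MissingScoreError
from sgii.sgii_core import MEASURES
from oracles import brute_sgii_calls


class TestRankDescending:
    def test_highest_score_gets_rank_one(self):
        assert rank_descending({"a": 3.0, "b": 1.0, "c": 2.0}) == {
            "a": 1, "c": 2, "b": 3}

    def test_ties_break_lexicographically(self):
        assert rank_descending({"b": 2.0, "a": 2.0}) == {"a": 1, "b": 2}

    def test_singleton(self):
        assert rank_descending({"x": 0.0}) == {"x": 1}

    def test_nan_rejected(self):
        with pytest.raises(ConfigError, match="non-finite"):
            rank_descending({"a": float("nan")})

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            rank_descending({})

    @settings(max_examples=100, derandomize=True)
    @given(st.dictionaries(
        st.text("abcdefgh", min_size=1, max_size=4),
        st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=20))
    def test_ranks_are_a_permutation(self, scores):
        ranks = rank_descending(scores)
        assert sorted(ranks.values()) == list(range(1, len(scores) + 1))
        # descending order respected
        ordered = sorted(scores, key=lambda v: ranks[v])
        values = [scores[v] for v in ordered]
        assert values == sorted(values, reverse=True)


class TestIndicator:
    @pytest.mark.parametrize("rank,n,pct,expected", [
        (4, 100, 5, 1),    # 0.04 < 0.05
        (5, 100, 5, 0),    # strict inequality at the boundary
        (1, 1, 100, 0),    # degenerate universe: 1/1 < 1 is false
        (1, 10, 100, 1),
        (10, 10, 100, 0),
    ])
    def test_strict_threshold(self, rank, n, pct, expected):
        assert indicator(rank, n, pct) == expected


class TestConfigureSubset:
    def test_subset_canonical_order_and_dedup(self):
        params = configure_subset(SGIIParams(), ["DC", "BC", "DC"])
        assert params.centrality_subset == ("BC", "DC")

    def test_empty_subset_means_gic_only(self):
        params = configure_subset(SGIIParams(), [])
        assert params.centrality_subset == ()

    def test_unknown_measure_rejected(self):
        with pytest.raises(ConfigError, match="unknown centrality"):
            configure_subset(SGIIParams(), ["BC", "XX"])

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            SGIIParams(k=0)
        with pytest.raises(ConfigError):
            SGIIParams(t=150)
        with pytest.raises(ConfigError):
            SGIIParams(z=-1)


def constructed_network(n_lnc=20, n_prot=6, seed=0):
    """A 20-lncRNA network with a controlled spread of degrees."""
    g = nx.Graph()
    prots = [f"P{j}" for j in range(n_prot)]
    for p in prots:
        g.add_node(p, kind="protein")
    for a, b in itertools.combinations(prots[:4], 2):
        g.add_edge(a, b)
    for i in range(n_lnc):
        v = f"L{i:02d}"
        g.add_node(v, kind="lncRNA", dummy=False)
        for j in range(1 + i % n_prot):  # degrees 1..6 cycling
            g.add_edge(v, prots[(i + j) % n_prot])
    return LPPINetwork(g)


@pytest.fixture(scope="module")
def constructed():
    net = constructed_network()
    centralities = compute_centralities(net)
    gic = {v: GICResult(theta=((i * 37) % 20) / 10.0 - 1.0, score=0.5)
           for i, v in enumerate(sorted(net.scoreable_lncrnas))}
    return net, centralities, gic


class TestClassify:
    def test_high_degree_top_ranked_is_essential(self, constructed):
        net, centralities, gic = constructed
        params = SGIIParams(z=2, k=40.0, t=1.0)
        calls = classify(net, centralities, gic, params)
        # the best-connected lncRNAs sit in the top 40% of every centrality
        top = [v for v, c in calls.items()
               if c.branch == "centrality" and all(
                   c.indicators[f"I_{m[0].lower()}"] for m in MEASURES)]
        assert top
        assert all(calls[v].essential for v in top)

    def test_low_degree_routes_to_gic_branch(self, constructed):
        net, centralities, gic = constructed
        params = SGIIParams(z=4, k=5.0, t=30.0)
        calls = classify(net, centralities, gic, params)
        low = [v for v in calls if net.degree(v) < 4]
        assert low
        for v in low:
            assert calls[v].branch == "GIC"
            assert calls[v].essential == bool(calls[v].indicators["I_g"])

    def test_one_failing_indicator_blocks_the_call(self, constructed):
        net, centralities, gic = constructed
        params = SGIIParams(z=1, k=30.0, t=1.0)
        calls = classify(net, centralities, gic, params)
        for v, c in calls.items():
            if c.branch != "centrality":
                continue
            inds = [c.indicators[f"I_{m[0].lower()}"] for m in MEASURES]
            if 0 in inds:
                assert not c.essential
            else:
                assert c.essential

    def test_partition_into_exactly_one_branch(self, constructed):
        net, centralities, gic = constructed
        calls = classify(net, centralities, gic, SGIIParams(z=3, k=10, t=10))
        n_cent = sum(c.branch == "centrality" for c in calls.values())
        n_gic = sum(c.branch == "GIC" for c in calls.values())
        assert n_cent + n_gic == len(net.scoreable_lncrnas)

    def test_empty_subset_equals_gic_thresholding(self, constructed):
        net, centralities, gic = constructed
        params = configure_subset(SGIIParams(z=3, k=10, t=25.0), [])
        calls = classify(net, centralities, gic, params)
        table = build_rank_table(centralities, gic, net.scoreable_lncrnas)
        for v, c in calls.items():
            assert c.branch == "GIC"
            expected = indicator(int(table.ranks.at[v, "r_g"]), table.n, 25.0)
            assert c.essential == bool(expected)

    @pytest.mark.parametrize("tighter,looser", [(5.0, 10.0), (1.0, 50.0)])
    def test_lowering_thresholds_never_adds_calls(self, constructed, tighter, looser):
        net, centralities, gic = constructed
        for attr in ("k", "t"):
            loose = classify(net, centralities, gic,
                             SGIIParams(z=3, **{attr: looser}))
            tight = classify(net, centralities, gic,
                             SGIIParams(z=3, **{attr: tighter}))
            loose_set = {v for v, c in loose.items() if c.essential}
            tight_set = {v for v, c in tight.items() if c.essential}
            assert tight_set <= loose_set

    def test_missing_gic_score_is_named(self, constructed):
        net, centralities, gic = constructed
        partial = dict(gic)
        partial.pop("L00")
        with pytest.raises(MissingScoreError, match="L00"):
            classify(net, centralities, partial, SGIIParams())

    def test_determinism(self, constructed):
        net, centralities, gic = constructed
        a = classify(net, centralities, gic, MOUSE_PARAMS)
        b = classify(net, centralities, dict(reversed(list(gic.items()))),
                     MOUSE_PARAMS)
        assert a == b


class TestAgainstBruteForce:
    @pytest.mark.parametrize("z", [0, 2, 4, 7])
    @pytest.mark.parametrize("k,t", [(10.0, 10.0), (35.0, 20.0)])
    def test_all_subsets_match_independent_reimplementation(
            self, constructed, z, k, t):
        net, centralities, gic = constructed
        ids = net.scoreable_lncrnas
        degrees = {v: net.degree(v) for v in ids}
        cent_scores = {
            m: {v: float(centralities.at[v, m.lower()]) for v in ids}
            for m in MEASURES
        }
        gic_scores = {v: gic[v].theta for v in ids}
        for r in range(5):
            for subset in itertools.combinations(MEASURES, r):
                params = SGIIParams(z=z, k=k, t=t, centrality_subset=subset)
                calls = classify(net, centralities, gic, params)
                expected = brute_sgii_calls(
                    degrees, cent_scores, gic_scores, z, k, t, subset)
                got = {v: c.essential for v, c in calls.items()}
                assert got == expected
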