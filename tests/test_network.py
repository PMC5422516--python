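"""Median-joining networks: recoding, the star-median case, oracle equality."""

import random
from itertools import combinations, product

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree

from hybdiag.alignments import AlignmentError
from hybdiag.network import (
    IndelEvent,
    NetworkCharacterMatrix,
    build_mj_network,
    export_network,
    recode_matrix,
)


def mk(haps):
    names = tuple(sorted(haps))
    k = len(next(iter(haps.values())))
    return NetworkCharacterMatrix(names, dict(haps), tuple(range(1, k + 1)))


# ---------------------------------------------------------------- recoding

def test_recode_drops_constant_and_collapses_indel():
    haps = {"h1": "AC----GA", "h2": "ACTTTTGA", "h3": "ACTTTTGC"}
    m = recode_matrix(haps, [IndelEvent("L", 3, 6)])
    assert m.n_characters == 2  # indel presence/absence + final column
    assert m.matrix["h1"][0] == "0" and m.matrix["h2"][0] == "1"


def test_recode_identical_haplotypes_zero_characters():
    m = recode_matrix({"a": "ACGT", "b": "ACGT"})
    assert m.n_characters == 0


def test_recode_gap_is_fifth_state():
    m = recode_matrix({"a": "A-G", "b": "AAG"})
    assert m.n_characters == 1
    assert {m.matrix["a"], m.matrix["b"]} == {"-", "A"}


def test_recode_rejects_overlap_and_partial_gaps():
    haps = {"a": "AAAA", "b": "TTTT"}
    with pytest.raises(AlignmentError, match="overlap"):
        recode_matrix(haps, [IndelEvent("L", 1, 2), IndelEvent("L", 2, 3)])
    with pytest.raises(AlignmentError, match="partially gapped"):
        recode_matrix({"a": "A--A", "b": "A-AA"}, [IndelEvent("L", 2, 3)])


def test_indel_event_counts_one_step():
    haps = {"h1": "AC------GT", "h2": "ACTCACATGT"}
    m = recode_matrix(haps, [IndelEvent("WD", 3, 8)])
    assert m.n_characters == 1
    net = build_mj_network(m)
    assert net.edges == [("h1", "h2", 1)]


# ------------------------------------------------------------ construction

def test_three_haplotype_star_gains_median():
    net = build_mj_network(mk({"h1": "AAT", "h2": "ATA", "h3": "TAA"}))
    assert len(net.medians) == 1
    mid = net.medians[0]
    assert net.graph.nodes[mid]["state"] == "AAA"
    assert sorted(w for _, _, w in net.edges) == [1, 1, 1]
    assert net.spanning_cost() == 3


def test_star_median_is_brute_force_steiner_optimum():
    """Exhaustive Steiner-point search confirms AAA is the unique improver."""
    obs = ["AAT", "ATA", "TAA"]

    def mst_cost(points):
        n = len(points)
        mat = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            mat[i, j] = sum(a != b for a, b in zip(points[i], points[j]))
        return int(minimum_spanning_tree(mat).sum())

    base = mst_cost(obs)  # 4
    best = {}
    for cand in map("".join, product("AT", repeat=3)):
        if cand in obs:
            continue
        cost = mst_cost(obs + [cand])
        if cost < base:
            best[cand] = cost
    assert best == {"AAA": 3}


def test_two_and_one_haplotype_networks():
    net2 = build_mj_network(mk({"a": "AACC", "b": "TTCC"}))
    assert net2.edges == [("a", "b", 2)] and net2.medians == ()
    net1 = build_mj_network(mk({"a": "A"}))
    assert net1.nodes == ["a"] and net1.edges == []
    with pytest.raises(AlignmentError):
        build_mj_network(NetworkCharacterMatrix((), {}, ()))


def test_network_contains_all_observed_and_an_mst():
    rng = random.Random(3)
    for _ in range(40):
        haps = _random_instance(rng)
        net = build_mj_network(mk(haps))
        assert set(haps) <= set(net.graph.nodes)
        assert nx.is_connected(net.graph)
        # every edge weight >= 1
        assert all(w >= 1 for _, _, w in net.edges)
        # the MSN keeps every MST of the final node set: check one
        g = nx.Graph()
        states = {n: net.graph.nodes[n]["state"] for n in net.graph.nodes}
        for u, v in combinations(states, 2):
            g.add_edge(u, v, weight=sum(a != b for a, b in
                                        zip(states[u], states[v])))
        mst_w = sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
        net_w = {(min(u, v), max(u, v)): w for u, v, w in net.edges}
        # greedily rebuild an MST restricted to network edges; it must reach
        # the unrestricted MST weight (MSN => contains some MST)
        sub = nx.Graph()
        sub.add_nodes_from(states)
        for (u, v), w in net_w.items():
            sub.add_edge(u, v, weight=w)
        sub_w = sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(sub, data=True))
        assert sub_w == mst_w
        # medians only ever reduce the spanning cost over observed haplotypes
        obs_only = {n: s for n, s in states.items() if n in haps}
        base = _prim(list(obs_only.values()))
        assert net.spanning_cost() <= base


def _prim(seqs):
    n = len(seqs)
    if n <= 1:
        return 0
    in_tree = [False] * n
    best = [10**9] * n
    best[0] = 0
    total = 0
    for _ in range(n):
        u = min((i for i in range(n) if not in_tree[i]), key=best.__getitem__)
        in_tree[u] = True
        total += best[u]
        for v in range(n):
            if not in_tree[v]:
                d = sum(a != b for a, b in zip(seqs[u], seqs[v]))
                best[v] = min(best[v], d)
    return total


def _random_instance(rng, max_haps=5, max_chars=8):
    n = rng.randint(2, max_haps)
    k = rng.randint(1, max_chars)
    haps = {}
    tries = 0
    while len(haps) < n and tries < 100:
        tries += 1
        seq = "".join(rng.choice("ACT"[: rng.choice((2, 2, 3))]) for _ in range(k))
        if seq not in haps.values():
            haps[f"h{len(haps)}"] = seq
    return haps


# ------------------------------------------------- naive oracle comparison

def naive_mj(haps, epsilon=0):
    """Independent re-implementation: exhaustive loops, scipy MST costs.

    Same construction rule, written naively: full single-linkage matrix per
    sweep, every triple enumerated, every quasi-median candidate scored by a
    from-scratch MST, greedy addition of the (cost, state)-smallest improver,
    then exhaustive removal and minimum-subset cleaning.
    """
    def dist(a, b):
        return sum(x != y for x, y in zip(a, b))

    def mst_cost(vectors):
        names = sorted(vectors)
        n = len(names)
        if n <= 1:
            return 0
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = dist(vectors[names[i]], vectors[names[j]])
        return int(minimum_spanning_tree(mat).sum())

    def msn(vectors):
        names = sorted(vectors)
        clusters = [{x} for x in names]
        level = {}
        for d, u, v in sorted((dist(vectors[u], vectors[v]), u, v)
                              for u, v in combinations(names, 2)):
            cu = next(c for c in clusters if u in c)
            cv = next(c for c in clusters if v in c)
            if cu is not cv:
                for x in cu:
                    for y in cv:
                        level[frozenset((x, y))] = d
                clusters.remove(cu)
                clusters.remove(cv)
                clusters.append(cu | cv)
        return [(u, v, dist(vectors[u], vectors[v]))
                for u, v in combinations(names, 2)
                if dist(vectors[u], vectors[v]) <= level[frozenset((u, v))] + epsilon]

    def quasi_medians(a, b, c):
        per = []
        for x, y, z in zip(a, b, c):
            if x == y or x == z:
                per.append([x])
            elif y == z:
                per.append([y])
            else:
                per.append(sorted({x, y, z}))
        return sorted("".join(t) for t in product(*per))

    vectors = dict(haps)
    observed = dict(haps)
    seq = 0
    while True:
        progressed = False
        while True:
            edges = msn(vectors)
            adj = {}
            for u, v, _ in edges:
                adj.setdefault(u, set()).add(v)
                adj.setdefault(v, set()).add(u)
            base = mst_cost(vectors)
            best = None
            for u, v, _ in sorted((tuple(sorted((u, v))) + (w,)) for u, v, w in edges):
                for t in sorted(vectors):
                    if t in (u, v):
                        continue
                    if t not in adj.get(u, set()) and t not in adj.get(v, set()):
                        continue
                    for cand in quasi_medians(vectors[u], vectors[v], vectors[t]):
                        if cand in vectors.values():
                            continue
                        cost = mst_cost({**vectors, "__x__": cand})
                        if cost < base and (best is None or (cost, cand) < best):
                            best = (cost, cand)
            if best is None:
                break
            seq += 1
            vectors[f"mv{seq}"] = best[1]
            progressed = True
        while True:
            cost = mst_cost(vectors)
            removed = False
            for name in sorted(n for n in vectors if n not in observed):
                if mst_cost({k: v for k, v in vectors.items() if k != name}) <= cost:
                    del vectors[name]
                    removed = progressed = True
                    break
            if not removed:
                break
        if not progressed:
            break
    # minimum-subset cleaning (exhaustive)
    medians = sorted(n for n in vectors if n not in observed)
    best_cost, best_subsets = None, []
    for r in range(len(medians) + 1):
        for subset in combinations(medians, r):
            trial = dict(observed, **{m: vectors[m] for m in subset})
            cost = mst_cost(trial)
            if best_cost is None or cost < best_cost:
                best_cost, best_subsets = cost, [subset]
            elif cost == best_cost:
                best_subsets.append(subset)
    minimal = [s for s in best_subsets
               if not any(set(t) < set(s) for t in best_subsets)]
    keep = set().union(*minimal) if minimal else set()
    final = dict(observed, **{m: vectors[m] for m in medians if m in keep})
    return sorted(final.values()), sorted(
        tuple(sorted((final[u], final[v]))) + (w,) for u, v, w in msn(final))


def test_mj_matches_naive_oracle_on_random_instances():
    rng = random.Random(2024)
    for _ in range(150):
        haps = _random_instance(rng)
        net = build_mj_network(mk(haps))
        states = sorted(net.graph.nodes[n]["state"] for n in net.graph.nodes)
        edges = sorted(
            tuple(sorted((net.graph.nodes[u]["state"], net.graph.nodes[v]["state"])))
            + (int(d["weight"]),)
            for u, v, d in net.graph.edges(data=True))
        o_states, o_edges = naive_mj(haps)
        assert states == o_states
        assert edges == o_edges


def test_determinism():
    rng = random.Random(7)
    haps = _random_instance(rng)
    a = build_mj_network(mk(haps))
    b = build_mj_network(mk(haps))
    assert a.edges == b.edges and a.nodes == b.nodes


# ----------------------------------------------------------------- export

def test_export_tsv_and_dot(tmp_path):
    net = build_mj_network(mk({"a": "AACC", "b": "TTCC"}))
    tsv = tmp_path / "net.tsv"
    export_network(net, tsv, "tsv")
    assert tsv.read_text().splitlines() == ["node1\tnode2\tsteps", "a\tb\t2"]
    dot = tmp_path / "net.dot"
    export_network(net, dot, "dot")
    text = dot.read_text()
    assert text.startswith("graph") and '"a" -- "b"' in text
    with pytest.raises(AlignmentError, match="format"):
        export_network(net, tmp_path / "x", "gml")


def test_infer_indel_events_splits_on_pattern_change():
    from hybdiag.network import infer_indel_events

    haps = {"a": "AC------GT", "b": "ACTCACATGT", "c": "AC--------"}
    evs = infer_indel_events(haps, "L")
    assert [(e.start, e.end) for e in evs] == [(3, 8), (9, 10)]
    assert infer_indel_events({"a": "ACGT", "b": "ACCT"}) == []


def test_reference_cp_network_separates_parents(case_study, case_result):
    """Parental chloroplast clusters sit >= 14 mutational steps apart (the
    fixed substitutions plus single-step indel events)."""
    from hybdiag.fixtures import DIELSIANUS, GLAUCOPHYLLUS
    from hybdiag.pipeline import locus_network

    cp_id = case_result.cp_concat.locus_id
    net = locus_network(case_result, cp_id, case_study.taxa)
    # min path cost between any dielsianus node and any glaucophyllus node
    own = {}
    for n in net.nodes:
        taxa = net.graph.nodes[n].get("taxa") or {}
        own[n] = set(taxa)
    import networkx as nx
    dist = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
    sep = min(dist[u][v] for u in net.nodes for v in net.nodes
              if DIELSIANUS in own[u] and GLAUCOPHYLLUS in own[v])
    assert sep >= 14
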