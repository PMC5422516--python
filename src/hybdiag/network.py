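"""Median-joining haplotype networks with fifth-state gap coding.

Characters are the variable columns of the haplotype alignment, with the gap
treated as a fifth character state, and every registered multi-column indel
collapsed to a single binary presence/absence character so that a long indel
counts as one mutational step.

The network construction iterates: build the minimum-spanning network (all
links within ``epsilon`` of the minimal connection cost between components);
propose median (consensus) vectors for connected triplets; greedily add the
median that most reduces the spanning cost; drop medians that no longer pay
for themselves; repeat to a fixed point.  All tie-breaks are deterministic
(lexicographic), so identical inputs give byte-identical networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import networkx as nx

from .alignments import GAP, AlignmentError


@dataclass(frozen=True)
class IndelEvent:
    """Registry entry: columns [start..end] (1-based) form one indel event."""

    locus_id: str
    start: int
    end: int


@dataclass
class NetworkCharacterMatrix:
    """Distinct haplotypes recoded to network characters.

    ``matrix`` maps haplotype name -> state string; substitution characters
    keep their nucleotide/gap state, indel characters are '1' (bases present)
    or '0' (gapped).  ``columns`` records, per character, either the original
    1-based column or the indel event it encodes (invertible recoding).
    """

    names: tuple[str, ...]
    matrix: dict[str, str]
    columns: tuple[object, ...]  # int (original column) or IndelEvent

    @property
    def n_characters(self) -> int:
        return len(self.columns)


def recode_matrix(haplotypes: dict[str, str],
                  indel_events: list[IndelEvent] | None = None,
                  ) -> NetworkCharacterMatrix:
    """Recode aligned haplotypes: drop constant columns, collapse indels.

    ``haplotypes`` maps name -> aligned sequence.  Indel event ranges must not
    overlap; inside a range a haplotype must be entirely gapped or entirely
    ungapped (anything else is not a presence/absence state).
    """
    if not haplotypes:
        raise AlignmentError("no haplotypes to recode")
    names = tuple(sorted(haplotypes))
    length = len(haplotypes[names[0]])
    for n in names:
        if len(haplotypes[n]) != length:
            raise AlignmentError("haplotypes are not aligned to equal length")
    events = sorted(indel_events or [], key=lambda e: e.start)
    for e1, e2 in zip(events, events[1:]):
        if e2.start <= e1.end:
            raise AlignmentError(
                f"overlapping indel events {e1} and {e2} in network recoding")
    in_event = {}
    for ev in events:
        if not (1 <= ev.start <= ev.end <= length):
            raise AlignmentError(f"indel event {ev} outside alignment 1..{length}")
        for pos in range(ev.start, ev.end + 1):
            in_event[pos] = ev

    states: dict[str, list[str]] = {n: [] for n in names}
    columns: list[object] = []
    for ev in events:
        chars = {}
        for n in names:
            seg = haplotypes[n][ev.start - 1:ev.end]
            if set(seg) == {GAP}:
                chars[n] = "0"
            elif GAP not in seg:
                chars[n] = "1"
            else:
                raise AlignmentError(
                    f"haplotype {n!r} is partially gapped inside indel event {ev}")
        if len(set(chars.values())) > 1:
            columns.append(ev)
            for n in names:
                states[n].append(chars[n])
    for pos in range(1, length + 1):
        if pos in in_event:
            continue
        col = {n: haplotypes[n][pos - 1] for n in names}
        if len(set(col.values())) > 1:
            columns.append(pos)
            for n in names:
                states[n].append(col[n])
    # characters in ascending column order, indel events sorting at their start
    order = sorted(range(len(columns)),
                   key=lambda i: columns[i].start if isinstance(columns[i], IndelEvent)
                   else columns[i])
    matrix = {n: "".join(states[n][i] for i in order) for n in names}
    return NetworkCharacterMatrix(names, matrix,
                                  tuple(columns[i] for i in order))


def infer_indel_events(haplotypes: dict[str, str], locus_id: str = "",
                       ) -> list[IndelEvent]:
    """Gap runs shared across haplotypes, one event per run.

    A run is a maximal block of consecutive columns with an identical
    gapped-haplotype pattern (and at least one gapped haplotype).  Inside such
    a block every haplotype is either fully gapped or fully ungapped, so the
    block recodes cleanly to one presence/absence character.
    """
    names = sorted(haplotypes)
    if not names:
        return []
    length = len(haplotypes[names[0]])
    events: list[IndelEvent] = []
    run_start = None
    run_pattern: tuple[bool, ...] | None = None
    for pos in range(1, length + 2):
        pattern = (tuple(haplotypes[n][pos - 1] == GAP for n in names)
                   if pos <= length else None)
        if pattern is not None and any(pattern):
            if run_pattern == pattern:
                continue
            if run_start is not None:
                events.append(IndelEvent(locus_id, run_start, pos - 1))
            run_start, run_pattern = pos, pattern
        else:
            if run_start is not None:
                events.append(IndelEvent(locus_id, run_start, pos - 1))
            run_start = run_pattern = None
    return events


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph
    observed: tuple[str, ...]
    medians: tuple[str, ...]
    epsilon: int

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return sorted((min(u, v), max(u, v), int(d["weight"]))
                      for u, v, d in self.graph.edges(data=True))

    def spanning_cost(self) -> int:
        """Weight of an MST over all current nodes (observed + medians)."""
        return _mst_cost({n: self.graph.nodes[n]["state"] for n in self.graph.nodes})


def _dist(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _mst_cost(vectors: dict[str, str]) -> int:
    # Prim over the complete distance graph; called in the inner loop of the
    # median search, so kept allocation-light
    seqs = list(vectors.values())
    n = len(seqs)
    if n <= 1:
        return 0
    in_tree = [False] * n
    best = [len(seqs[0]) + 1] * n
    best[0] = 0
    total = 0
    for _ in range(n):
        u = min((i for i in range(n) if not in_tree[i]), key=best.__getitem__)
        in_tree[u] = True
        total += best[u]
        su = seqs[u]
        for v in range(n):
            if not in_tree[v]:
                d = _dist(su, seqs[v])
                if d < best[v]:
                    best[v] = d
    return total


def _msn_edges(vectors: dict[str, str], epsilon: int) -> list[tuple[str, str, int]]:
    """Minimum-spanning-network links.

    A pair (u, v) is linked when its distance is within ``epsilon`` of the
    cost level at which the single-linkage components of u and v merge, i.e.
    the network keeps every edge belonging to some MST (ties included) plus
    relaxed links for epsilon > 0.
    """
    names = sorted(vectors)
    if len(names) <= 1:
        return []
    pairs = sorted(((_dist(vectors[u], vectors[v]), u, v)
                    for u, v in combinations(names, 2)))
    merge = _single_linkage_levels(vectors)
    edges = []
    for d, u, v in pairs:
        if d <= merge[frozenset((u, v))] + epsilon:
            edges.append((u, v, d))
    return edges


def _single_linkage_levels(vectors: dict[str, str]) -> dict[frozenset[str], int]:
    """For every pair, the distance level at which their clusters merge."""
    names = sorted(vectors)
    clusters: list[set[str]] = [{n} for n in names]
    levels: dict[frozenset[str], int] = {}
    pairs = sorted(((_dist(vectors[u], vectors[v]), u, v)
                    for u, v in combinations(names, 2)))
    for d, u, v in pairs:
        cu = next(c for c in clusters if u in c)
        cv = next(c for c in clusters if v in c)
        if cu is not cv:
            for x in cu:
                for y in cv:
                    levels[frozenset((x, y))] = d
            clusters.remove(cu)
            clusters.remove(cv)
            clusters.append(cu | cv)
    return levels


def _median_candidates(a: str, b: str, c: str) -> list[str]:
    """Quasi-median (consensus) vectors of a triplet.

    Per character the majority state wins; where all three states differ the
    character branches over the three observed states.
    """
    per_char: list[list[str]] = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            per_char.append([x])
        elif y == z:
            per_char.append([y])
        else:
            per_char.append(sorted({x, y, z}))
    out = ["".join(choice) for choice in product(*per_char)]
    return sorted(out)


def build_mj_network(matrix: NetworkCharacterMatrix, epsilon: int = 0,
                     mp_cleaning: bool | None = None) -> HaplotypeNetwork:
    """Median-joining network over recoded haplotypes.

    ``mp_cleaning`` prunes median vectors that do not lie on any minimum-cost
    subtree spanning the observed haplotypes; it is exponential in the number
    of medians and defaults to on for networks of at most 12 nodes.
    """
    if not matrix.names:
        raise AlignmentError("cannot build a network over zero haplotypes")
    observed = {n: matrix.matrix[n] for n in matrix.names}
    vectors = dict(observed)
    median_seq = 0

    def current_medians() -> list[str]:
        return [n for n in vectors if n not in observed]

    changed = True
    while changed:
        changed = False
        # greedy median addition to a local fixed point
        while True:
            edges = _msn_edges(vectors, epsilon)
            g = nx.Graph()
            g.add_nodes_from(vectors)
            g.add_weighted_edges_from(edges)
            base_cost = _mst_cost(vectors)
            best: tuple[int, str] | None = None  # (new_cost, state)
            seen_states = set(vectors.values())
            for u, v, w in sorted((tuple(sorted((u, v))) + (w,)) for u, v, w in edges):
                for t in sorted(g.nodes):
                    if t in (u, v):
                        continue
                    if not (g.has_edge(t, u) or g.has_edge(t, v)):
                        continue
                    for cand in _median_candidates(vectors[u], vectors[v], vectors[t]):
                        if cand in seen_states:
                            continue
                        trial = dict(vectors)
                        trial["__cand__"] = cand
                        cost = _mst_cost(trial)
                        if cost < base_cost and (best is None or (cost, cand) < best):
                            best = (cost, cand)
            if best is None:
                break
            median_seq += 1
            vectors[f"mv{median_seq}"] = best[1]
            changed = True
        # drop medians whose removal does not increase the spanning cost
        pruned = True
        while pruned:
            pruned = False
            cost = _mst_cost(vectors)
            for name in sorted(current_medians()):
                trial = {k: v for k, v in vectors.items() if k != name}
                if _mst_cost(trial) <= cost:
                    del vectors[name]
                    pruned = True
                    changed = True
                    break
        if not changed:
            break

    medians = sorted(current_medians())
    if mp_cleaning is None:
        mp_cleaning = len(vectors) <= 12
    if mp_cleaning and medians:
        vectors = _mp_clean(vectors, observed)
        medians = [n for n in vectors if n not in observed]

    edges = _msn_edges(vectors, epsilon)
    g = nx.Graph()
    for name, state in vectors.items():
        g.add_node(name, state=state, median=name not in observed)
    g.add_weighted_edges_from(edges)
    return HaplotypeNetwork(g, tuple(sorted(observed)), tuple(sorted(medians)), epsilon)


def _mp_clean(vectors: dict[str, str], observed: dict[str, str]) -> dict[str, str]:
    """Keep only medians appearing in some minimum-cost spanning solution.

    Exhaustive over median subsets; the minimum cost is the smallest MST
    weight over observed + subset among subsets whose medians all have degree
    >= 3 worth of savings (checked implicitly by cost minimality with
    smallest subset preferred).
    """
    medians = sorted(n for n in vectors if n not in observed)
    best_cost = None
    best_subsets: list[tuple[str, ...]] = []
    for r in range(len(medians) + 1):
        for subset in combinations(medians, r):
            trial = dict(observed)
            for m in subset:
                trial[m] = vectors[m]
            cost = _mst_cost(trial)
            if best_cost is None or cost < best_cost:
                best_cost, best_subsets = cost, [subset]
            elif cost == best_cost:
                best_subsets.append(subset)
    keep = set()
    minimal = [s for s in best_subsets
               if not any(set(t) < set(s) for t in best_subsets)]
    for subset in minimal:
        keep.update(subset)
    out = dict(observed)
    for m in medians:
        if m in keep:
            out[m] = vectors[m]
    return out


def annotate_network(net: HaplotypeNetwork,
                     carrier_counts: dict[str, int] | None = None,
                     taxon_composition: dict[str, dict[str, int]] | None = None,
                     ) -> None:
    for n in net.graph.nodes:
        net.graph.nodes[n]["carriers"] = (carrier_counts or {}).get(n, 0)
        net.graph.nodes[n]["taxa"] = dict((taxon_composition or {}).get(n, {}))


def export_network(net: HaplotypeNetwork, path: str | Path, fmt: str = "tsv") -> None:
    """Write the network as an edge-list TSV or DOT text."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("node1\tnode2\tsteps\n")
            for u, v, w in net.edges:
                fh.write(f"{u}\t{v}\t{w}\n")
    elif fmt == "dot":
        lines = ["graph haplotype_network {"]
        for n in net.nodes:
            data = net.graph.nodes[n]
            attrs = []
            taxa = data.get("taxa") or {}
            label_bits = [n]
            if data.get("carriers"):
                label_bits.append(f"n={data['carriers']}")
            if taxa:
                label_bits.append(",".join(f"{t}:{c}" for t, c in sorted(taxa.items())))
            attrs.append(f'label="{" ".join(label_bits)}"')
            if data.get("median"):
                attrs.append("shape=point")
            lines.append(f'  "{n}" [{", ".join(attrs)}];')
        for u, v, w in net.edges:
            lines.append(f'  "{u}" -- "{v}" [label="{w}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise AlignmentError(f"unknown network export format {fmt!r}")


def node_table(net: HaplotypeNetwork):
    import pandas as pd

    rows = []
    for n in net.nodes:
        d = net.graph.nodes[n]
        rows.append({"node": n, "state": d.get("state", ""),
                     "median": bool(d.get("median")),
                     "carriers": d.get("carriers", 0),
                     "taxa": ";".join(f"{t}:{c}"
                                      for t, c in sorted((d.get("taxa") or {}).items()))})
    return pd.DataFrame(rows, columns=["node", "state", "median", "carriers", "taxa"])
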