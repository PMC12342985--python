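"""Topology weighting of window genealogies over taxon groups.

Given per-window trees whose tips map onto a small number of groups
(lineages), the weight of a candidate group topology is the fraction of
one-tip-per-group combinations whose induced unrooted subtree matches it.
Windows where topologies consistent with gene flow carry a combined weight
above a threshold are merged into candidate introgression intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

_MAX_EXACT_COMBINATIONS = 10_000_000


def double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


@dataclass(frozen=True)
class Topology:
    """An unrooted leaf-labeled binary topology on group labels.

    ``splits`` is the set of non-trivial bipartitions; each bipartition is a
    frozenset of the two frozenset sides.
    """

    labels: tuple[str, ...]
    splits: frozenset
    newick: str


def _rooted_trees(labels: tuple[str, ...]):
    """All rooted binary leaf-labeled shapes on ``labels`` as nested tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    # the subtree containing `first` is generated once per unordered split
    for k in range(len(rest) + 1):
        for combo in itertools.combinations(rest, k):
            left_labels = (first,) + combo
            right_labels = tuple(x for x in rest if x not in combo)
            if not right_labels:
                continue
            for left in _rooted_trees(left_labels):
                for right in _rooted_trees(right_labels):
                    yield (left, right)


def _leafset(node) -> frozenset:
    if isinstance(node, str):
        return frozenset([node])
    return _leafset(node[0]) | _leafset(node[1])


def _collect_splits(node, universe: frozenset, out: set) -> None:
    if isinstance(node, str):
        return
    for child in node:
        ls = _leafset(child)
        if 2 <= len(ls) <= len(universe) - 2:
            out.add(frozenset([ls, universe - ls]))
        _collect_splits(child, universe, out)


def _node_newick(node) -> str:
    if isinstance(node, str):
        return node
    parts = sorted((_node_newick(c) for c in node), key=lambda s: min(_token_labels(s)))
    return "(" + ",".join(parts) + ")"


def _token_labels(newick_fragment: str) -> list[str]:
    return [t for t in newick_fragment.replace("(", ",").replace(")", ",").split(",") if t]


def _split_sort_key(split: frozenset):
    sides = sorted(tuple(sorted(side)) for side in split)
    return tuple(sides)


def enumerate_topologies(groups) -> list[Topology]:
    """All distinct unrooted binary topologies on the group labels.

    Count is the double factorial (2g-5)!!; order is deterministic
    (lexicographic on the sorted bipartition sets).
    """
    labels = tuple(sorted(groups))
    g = len(labels)
    if not 3 <= g <= 7:
        raise ValueError(f"number of groups must be in [3, 7], got {g}")
    anchor, rest = labels[0], labels[1:]
    universe = frozenset(labels)
    topologies = []
    for shape in _rooted_trees(rest):
        splits: set = set()
        if not isinstance(shape, str):
            # the root edge of the subtree carries the anchor on the far side
            for child in shape:
                ls = _leafset(child)
                if 2 <= len(ls) <= g - 2:
                    splits.add(frozenset([ls, universe - ls]))
            _collect_splits(shape, universe, splits)
        newick = f"({anchor},{_node_newick(shape)});" if not isinstance(shape, str) \
            else f"({anchor},{shape});"
        topologies.append(Topology(labels, frozenset(splits), newick))
    topologies.sort(key=lambda t: tuple(sorted(_split_sort_key(s) for s in t.splits)))
    expected = double_factorial(2 * g - 5)
    assert len(topologies) == expected and len({t.splits for t in topologies}) == expected
    return topologies


# ---------------------------------------------------------------------------
# window trees and weighting
# ---------------------------------------------------------------------------

@dataclass
class WindowTree:
    """A genealogy for a genomic window (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    newick: str


@dataclass
class TopologyWeights:
    chrom: str
    start: int
    end: int
    weights: np.ndarray
    method: str
    n_combinations: int


def _edge_tipsets(tree: dendropy.Tree) -> tuple[list[frozenset], frozenset]:
    """Tip-label sets below each internal edge, plus the full tip set."""
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    sets = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        ls = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(ls) <= len(all_tips) - 2:
            sets.append(ls)
    return sets, all_tips


def _induced_splits(combo: tuple[str, ...], tip_to_group: dict[str, str],
                    edge_sets: list[frozenset]) -> frozenset:
    cset = frozenset(combo)
    g = len(combo)
    groups_all = frozenset(tip_to_group[t] for t in combo)
    out = set()
    for es in edge_sets:
        a = es & cset
        if 2 <= len(a) <= g - 2:
            ga = frozenset(tip_to_group[t] for t in a)
            out.add(frozenset([ga, groups_all - ga]))
    return frozenset(out)


def _tally(induced: frozenset, key_to_index: dict, topologies: list[Topology],
           weights: np.ndarray) -> None:
    idx = key_to_index.get(induced)
    if idx is not None:
        weights[idx] += 1.0
        return
    # unresolved (polytomy): distribute equally among compatible topologies
    compatible = [i for i, t in enumerate(topologies) if induced <= t.splits]
    if not compatible:  # pragma: no cover - cannot happen for valid splits
        raise RuntimeError("induced splits match no topology")
    for i in compatible:
        weights[i] += 1.0 / len(compatible)


def weight_tree(tree, groups: dict[str, str], method: str = "exact",
                n_samples: int = 1000, seed: int | None = None,
                topologies: list[Topology] | None = None,
                window: tuple[str, int, int] = ("", 0, 0)) -> TopologyWeights:
    """Topology weights for one tree.

    ``groups`` maps tip label -> group label.  ``method`` is ``"exact"``
    (all one-tip-per-group combinations) or ``"sampled"`` (``n_samples``
    uniform draws).  Weights sum to 1.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    edge_sets, all_tips = _edge_tipsets(tree)
    unmapped = sorted(all_tips - set(groups))
    if unmapped:
        raise ValueError(f"tips not mapped to any group: {unmapped}")
    by_group: dict[str, list[str]] = {}
    for tip in sorted(all_tips):
        by_group.setdefault(groups[tip], []).append(tip)
    group_labels = sorted(by_group)
    if topologies is None:
        topologies = enumerate_topologies(group_labels)
    key_to_index = {t.splits: i for i, t in enumerate(topologies)}
    weights = np.zeros(len(topologies))
    tip_lists = [by_group[g] for g in group_labels]
    n_total = int(np.prod([len(t) for t in tip_lists]))
    if method == "exact":
        if n_total > _MAX_EXACT_COMBINATIONS:
            raise ValueError(
                f"{n_total} combinations exceed the exact-mode limit; "
                "use method='sampled'")
        for combo in itertools.product(*tip_lists):
            _tally(_induced_splits(combo, groups, edge_sets),
                   key_to_index, topologies, weights)
        n_eval = n_total
    elif method == "sampled":
        rng = np.random.default_rng(seed)
        sizes = [len(t) for t in tip_lists]
        for _ in range(n_samples):
            combo = tuple(tip_lists[k][rng.integers(sizes[k])]
                          for k in range(len(tip_lists)))
            _tally(_induced_splits(combo, groups, edge_sets),
                   key_to_index, topologies, weights)
        n_eval = n_samples
    else:
        raise ValueError(f"unknown method {method!r}")
    weights /= weights.sum()
    return TopologyWeights(window[0], window[1], window[2], weights,
                           method, n_eval)


def weight_series(trees: list[WindowTree], groups: dict[str, str],
                  method: str = "exact", n_samples: int = 1000,
                  seed: int | None = None) -> pd.DataFrame:
    """Weight every window tree; one row per window, one column per topology.

    Columns: chrom, start, end, topo1..topoT (canonical order); the topology
    newick strings are attached as ``frame.attrs["topologies"]``.
    """
    group_labels = sorted(set(groups.values()))
    topologies = enumerate_topologies(group_labels)
    rows = []
    for k, wt in enumerate(trees):
        try:
            res = weight_tree(wt.newick, groups, method=method,
                              n_samples=n_samples,
                              seed=None if seed is None else seed + k,
                              topologies=topologies,
                              window=(wt.chrom, wt.start, wt.end))
        except ValueError as exc:
            raise ValueError(f"window tree {k} ({wt.chrom}:{wt.start}-{wt.end}): "
                             f"{exc}") from exc
        rows.append([wt.chrom, wt.start, wt.end, *res.weights])
    cols = ["chrom", "start", "end"] + [f"topo{i + 1}" for i in range(len(topologies))]
    frame = pd.DataFrame(rows, columns=cols)
    frame.attrs["topologies"] = [t.newick for t in topologies]
    return frame


# ---------------------------------------------------------------------------
# introgression windows
# ---------------------------------------------------------------------------

def call_introgression_windows(weights: pd.DataFrame, topo_set: list[int],
                               threshold: float = 0.5) -> pd.DataFrame:
    """Merge windows whose combined weight over ``topo_set`` exceeds threshold.

    ``topo_set``: 1-based indices into the canonical topology order (matching
    the ``topoN`` column names).  The rule is strictly ``>``; adjacent or
    overlapping flagged windows merge, single-window gaps are not bridged.
    Returns (chrom, start, end, peak_weight) with disjoint sorted intervals.
    """
    if not topo_set:
        raise ValueError("empty introgression topology set")
    cols = [f"topo{i}" for i in topo_set]
    for c in cols:
        if c not in weights.columns:
            raise ValueError(f"no column {c} in weight table")
    combined = weights[cols].sum(axis=1)
    flagged = weights.loc[combined > threshold, ["chrom", "start", "end"]].copy()
    flagged["weight"] = combined[combined > threshold]
    flagged = flagged.sort_values(["chrom", "start"]).reset_index(drop=True)
    out = []
    for row in flagged.itertuples(index=False):
        if out and out[-1][0] == row.chrom and row.start <= out[-1][2]:
            out[-1][2] = max(out[-1][2], row.end)
            out[-1][3] = max(out[-1][3], row.weight)
        else:
            out.append([row.chrom, row.start, row.end, row.weight])
    return pd.DataFrame(out, columns=["chrom", "start", "end", "peak_weight"])


def genes_in_windows(intervals: pd.DataFrame, gene_intervals: pd.DataFrame) -> list[str]:
    """Gene ids overlapping any interval by >= 1 bp (half-open arithmetic).

    ``gene_intervals``: columns gene_id, chrom, start, end (0-based
    half-open; see :meth:`GeneAnnotation.gene_intervals_halfopen`).  Each
    gene is listed once, in annotation order.
    """
    hits = []
    for gene in gene_intervals.itertuples(index=False):
        sub = intervals[intervals["chrom"] == gene.chrom]
        if ((gene.start < sub["end"]) & (sub["start"] < gene.end)).any():
            hits.append(gene.gene_id)
    return hits


def clade_test(tree, labels) -> tuple[bool, frozenset]:
    """Do the labeled tips form a clade (evaluated as an unrooted bipartition)?

    Returns (monophyletic, tip set of the smallest containing clade).
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    want = frozenset(labels)
    absent = sorted(want - all_tips)
    if absent:
        raise ValueError(f"labels not in tree: {absent}")
    if want == all_tips or len(want) == 1:
        return True, want
    best = all_tips
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        ls = frozenset(l.taxon.label for l in node.leaf_iter())
        for side in (ls, all_tips - ls):
            if want <= side and len(side) < len(best):
                best = side
    return best == want, best
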