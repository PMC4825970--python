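"""Exact dispersal–vicariance (DIVA) optimisation and S-DIVA averaging.

The event-parsimony model: an ancestral range splits at every cladogenesis
either by *vicariance* (two disjoint, non-empty subsets, free) or — for a
single-area range — by *duplication* (both daughters inherit the area,
free).  Along a branch the inherited subset may then gain areas (dispersal,
cost 1 per area) or lose areas (local extinction, cost 1 per area) before
reaching the daughter's range.  ``diva_optimize`` finds, for every internal
node, every ancestral range attainable in a globally minimal-cost history.

S-DIVA extends this to a sample of trees: per clade, the uniform tie-weights
from each tree containing the clade are averaged, which is how reconstruction
uncertainty across topologies is usually summarised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from .areas import TipDistribution
from .reconstruction import AncestralReconstruction
from .trees import CladeKey, DatedTree, TreeSample, TreeValidationError

__all__ = ["diva_optimize", "sdiva", "SDivaClade", "EXACT_MODE_MAX_AREAS"]

#: exact enumeration over all subsets is capped here (3^n split growth)
EXACT_MODE_MAX_AREAS = 8

_INF = float("inf")


def _popcount(x: int) -> int:
    return bin(x).count("1")


def _transition_cost(inherited: int, child_range: int) -> int:
    """Dispersals (areas gained) plus extinctions (areas lost) on a branch."""
    return _popcount(child_range & ~inherited) + _popcount(inherited & ~child_range)


def _ordered_splits(mask: int) -> Iterable[Tuple[int, int]]:
    """All ordered cladogenetic inheritances of a parent range.

    Vicariance: every ordered pair of disjoint non-empty submasks covering
    the range.  Duplication: allowed only for single-area ranges.
    """
    if mask & (mask - 1) == 0:  # single area
        yield mask, mask
        return
    sub = (mask - 1) & mask
    while sub:
        other = mask ^ sub
        if other:
            yield sub, other
        sub = (sub - 1) & mask


def _candidate_ranges(tips: TipDistribution, tree: DatedTree, max_areas: int) -> List[int]:
    n_areas = len(tips.alphabet)
    if n_areas <= EXACT_MODE_MAX_AREAS:
        return [m for m in range(1, 1 << n_areas) if _popcount(m) <= max_areas]
    # above the exact cap: restrict candidates to unions of observed tip ranges
    observed = {tips[t] for t in tree.tip_labels}
    closure = set(observed)
    frontier = set(observed)
    while frontier:
        new = set()
        for a in frontier:
            for b in observed:
                u = a | b
                if u not in closure and _popcount(u) <= max_areas:
                    new.add(u)
        closure |= new
        frontier = new
    warnings.warn(
        f"{n_areas} areas exceed the exact-mode cap of {EXACT_MODE_MAX_AREAS}; "
        "candidate ancestral ranges restricted to unions of observed tip ranges",
        stacklevel=3,
    )
    return sorted(closure)


def diva_optimize(
    tree: DatedTree, tips: TipDistribution, max_areas: int = 12
) -> AncestralReconstruction:
    """Minimal-cost ancestral ranges for every internal node of one tree.

    Returns an :class:`AncestralReconstruction` whose per-node weights are
    uniform over all ranges attainable at that node in some globally optimal
    history; ``optimal_cost`` is the global minimum number of
    dispersal+extinction events.
    """
    tips.require_cover(tree.tip_labels)
    if max_areas < 1:
        raise ValueError("max_areas must be ≥ 1")
    candidates = _candidate_ranges(tips, tree, max_areas)

    # upward pass: up[node][R] = min cost of node's subtree given node has R
    up: Dict[int, Dict[int, float]] = {}
    # best[child][S] = min over child ranges C of trans(S, C) + up[child][C]
    best: Dict[int, Dict[int, float]] = {}

    order = list(tree.nodes())
    for node in reversed(order):
        if node.is_leaf:
            up[id(node)] = {tips[node.label]: 0.0}
        else:
            c1, c2 = node.children
            table: Dict[int, float] = {}
            for r in candidates:
                cost = _INF
                for s1, s2 in _ordered_splits(r):
                    c = _best(best, up, c1, s1, candidates) + _best(
                        best, up, c2, s2, candidates
                    )
                    if c < cost:
                        cost = c
                if cost < _INF:
                    table[r] = cost
            up[id(node)] = table

    root = tree.root
    optimal = min(up[id(root)].values())

    # downward pass: down[node][R] = min cost of everything outside node's
    # subtree given node has range R
    down: Dict[int, Dict[int, float]] = {id(root): {r: 0.0 for r in up[id(root)]}}
    for node in order:
        if node.is_leaf:
            continue
        c1, c2 = node.children
        for child, sib in ((c1, c2), (c2, c1)):
            # cheapest way for `child` to inherit subset S from any parent range
            inherit: Dict[int, float] = {}
            for r, dcost in down[id(node)].items():
                for s_child, s_sib in _ordered_splits(r):
                    total = dcost + _best(best, up, sib, s_sib, candidates)
                    if total < inherit.get(s_child, _INF):
                        inherit[s_child] = total
            table: Dict[int, float] = {}
            domain = up[id(child)].keys()
            for c in domain:
                cost = min(
                    (v + _transition_cost(s, c) for s, v in inherit.items()),
                    default=_INF,
                )
                table[c] = cost
            down[id(child)] = table

    node_weights: Dict[CladeKey, Dict[int, float]] = {}
    for node in order:
        utab, dtab = up[id(node)], down[id(node)]
        opt = [r for r in utab if utab[r] + dtab.get(r, _INF) <= optimal + 1e-9]
        w = 1.0 / len(opt)
        node_weights[node.clade] = {r: w for r in opt}

    return AncestralReconstruction(
        method="S-DIVA",
        topology="",
        alphabet=tips.alphabet,
        node_weights=node_weights,
        optimal_cost=int(round(optimal)),
    )


def _best(best, up, child, s: int, candidates) -> float:
    """Memoised min over child ranges C of trans(S,C) + up[child][C]."""
    table = best.setdefault(id(child), {})
    if s in table:
        return table[s]
    val = min(
        (_transition_cost(s, c) + uc for c, uc in up[id(child)].items()),
        default=_INF,
    )
    table[s] = val
    return val


@dataclass
class SDivaClade:
    """Averaged range frequencies for one clade across a tree sample."""

    frequencies: Dict[int, float]
    occupancy: float  # fraction of post-burn-in trees containing the clade


def sdiva(
    sample: Union[TreeSample, Sequence[DatedTree]],
    tips: TipDistribution,
    max_areas: int = 12,
) -> Dict[CladeKey, SDivaClade]:
    """Average per-tree optimal-range weights over a sample of trees.

    For each clade seen in at least one tree, the candidate-range frequency
    is the mean (over trees containing that clade) of that tree's uniform
    tie-weights; clades absent from some trees are flagged by occupancy < 1.
    """
    trees = sample.trees if isinstance(sample, TreeSample) else list(sample)
    if not trees:
        raise TreeValidationError("empty tree list")
    per_clade: Dict[CladeKey, List[Dict[int, float]]] = {}
    for tree in trees:
        recon = diva_optimize(tree, tips, max_areas=max_areas)
        for clade, weights in recon.node_weights.items():
            per_clade.setdefault(clade, []).append(weights)
    out: Dict[CladeKey, SDivaClade] = {}
    n = len(trees)
    for clade, weight_list in per_clade.items():
        freqs: Dict[int, float] = {}
        for weights in weight_list:
            for r, w in weights.items():
                freqs[r] = freqs.get(r, 0.0) + w
        k = len(weight_list)
        out[clade] = SDivaClade(
            frequencies={r: v / k for r, v in freqs.items()},
            occupancy=k / n,
        )
    return out
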