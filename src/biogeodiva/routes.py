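"""Event annotation and the textual route grammar.

Each internal node's cladogenetic outcome is summarised as a *route string*::

    <parent-range> ( "|" <left> "^" <right> | "->" <gained-areas> )*

where ranges are concatenated area letters, ``|`` marks a vicariant split of
the parent range into the two disjoint inherited subsets (written
``left^right``), and ``->`` marks areas gained by dispersal on a daughter
branch.  ``AB|A^B`` therefore reads "ancestor in AB, vicariance leaving one
daughter in A and the other in B"; ``A->B`` reads "ancestor in A, a daughter
dispersed into B".
"""

from __future__ import annotations

import re
from typing import Dict, List, Tuple

from .areas import AreaAlphabet
from .reconstruction import AncestralReconstruction
from .trees import CladeKey, DatedTree

__all__ = ["annotate_events", "serialize_route", "parse_route", "RouteParseError"]


class RouteParseError(ValueError):
    pass


# event token forms: ("vic", left_mask, right_mask) | ("disp", gained_mask)
RouteEvent = Tuple


def serialize_route(parent_mask: int, events: List[RouteEvent], alphabet: AreaAlphabet) -> str:
    parts = [alphabet.unmask(parent_mask)]
    for ev in events:
        if ev[0] == "vic":
            parts.append(f"|{alphabet.unmask(ev[1])}^{alphabet.unmask(ev[2])}")
        elif ev[0] == "disp":
            parts.append(f"->{alphabet.unmask(ev[1])}")
        else:
            raise ValueError(f"unknown event token {ev[0]!r}")
    return "".join(parts)


_TOKEN = re.compile(r"\|([A-Za-z]+)\^([A-Za-z]+)|->([A-Za-z]+)")


def parse_route(text: str, alphabet: AreaAlphabet) -> Tuple[int, List[RouteEvent]]:
    """Inverse of :func:`serialize_route`; round-trips exactly."""
    m = re.match(r"[A-Za-z]+", text)
    if not m:
        raise RouteParseError(f"route must open with a parent range: {text!r}")
    parent = alphabet.mask(m.group(0))
    events: List[RouteEvent] = []
    pos = m.end()
    while pos < len(text):
        tok = _TOKEN.match(text, pos)
        if not tok:
            raise RouteParseError(f"unparseable route token at offset {pos} in {text!r}")
        if tok.group(1) is not None:
            events.append(("vic", alphabet.mask(tok.group(1)), alphabet.mask(tok.group(2))))
        else:
            events.append(("disp", alphabet.mask(tok.group(3))))
        pos = tok.end()
    return parent, events


def _popcount(x: int) -> int:
    return bin(x).count("1")


def _branch_cost(inherited: int, child: int) -> int:
    return _popcount(child & ~inherited) + _popcount(inherited & ~child)


def _best_bipartition(p: int, m1: int, m2: int):
    """Ordered bipartition of p minimising the two branch event counts."""
    best = None
    best_cost = None
    sub = (p - 1) & p
    while sub:
        other = p ^ sub
        if other:
            cost = _branch_cost(sub, m1) + _branch_cost(other, m2)
            if best_cost is None or cost < best_cost or (
                cost == best_cost and sub < best[0]
            ):
                best, best_cost = (sub, other), cost
        sub = (sub - 1) & p
    return best, best_cost


def annotate_events(
    recon: AncestralReconstruction, tree: DatedTree
) -> Dict[CladeKey, str]:
    """Call per-node events from modal ranges and emit route strings.

    For each internal node the modal (highest-weight, smallest-bitmask on
    ties) parent range P and child ranges decide the called history.  The
    two *inherited* subsets are inferred by minimal-event reasoning: among
    all ordered disjoint bipartitions of P the one needing the fewest
    subsequent branch gains/losses to reach the child ranges is compared
    with plain full inheritance (both daughters start with P); the node is
    called vicariant when the bipartition explains the children more
    cheaply.  (Judging vicariance from the raw child∩parent intersections
    instead fails as soon as a daughter branch re-gains an area from the
    sibling's half, which is common whenever dispersal continues after the
    split.)  Dispersal is called for areas gained on a daughter branch,
    extinction for areas lost, and duplication for a single-area range
    passed intact to both daughters.  Fills ``recon.events`` and returns
    the route strings.
    """
    alphabet = recon.alphabet
    routes: Dict[CladeKey, str] = {}
    for node in tree.internal_nodes():
        p = recon.modal_range(node.clade)
        c1, c2 = node.children
        m1 = recon.modal_range(c1.clade)
        m2 = recon.modal_range(c2.clade)
        events: List[RouteEvent] = []
        kinds: List[str] = []
        inherited = (p, p)
        if p != (p & -p):  # widespread parent: is a vicariant split cheaper?
            split, split_cost = _best_bipartition(p, m1, m2)
            full_cost = _branch_cost(p, m1) + _branch_cost(p, m2)
            if split is not None and split_cost < full_cost:
                events.append(("vic", split[0], split[1]))
                kinds.append("vicariance")
                inherited = split
        elif m1 & p and m2 & p:
            kinds.append("duplication")
        for child_mask, inh in ((m1, inherited[0]), (m2, inherited[1])):
            gained = child_mask & ~inh
            lost = inh & ~child_mask
            if gained:
                events.append(("disp", gained))
                if "dispersal" not in kinds:
                    kinds.append("dispersal")
            if lost and "extinction" not in kinds:
                kinds.append("extinction")
        recon.events[node.clade] = tuple(kinds)
        routes[node.clade] = serialize_route(p, events, alphabet)
    return routes
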