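"""Shared container for ancestral-range reconstructions.

Both the event-parsimony (DIVA) and Bayesian binary MCMC reconstructions
produce the same shape of answer: for every clade of a tree, a probability
distribution over candidate ancestral ranges, optionally decorated with the
cladogenetic event class inferred at that node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from .areas import AreaAlphabet
from .trees import CladeKey

__all__ = ["AncestralReconstruction", "EVENT_KINDS"]

EVENT_KINDS = ("vicariance", "dispersal", "extinction", "duplication")


@dataclass
class AncestralReconstruction:
    """Per-clade distributions over ancestral ranges plus event calls.

    Attributes
    ----------
    method : str
        ``"S-DIVA"``, ``"BBM-null"``, ``"BBM-wide"`` or ``"BBM-custom"``.
    topology : str
        Label of the topology reconstructed on (e.g. ``"ML"``, ``"B1"``).
    alphabet : AreaAlphabet
    node_weights : dict
        CladeKey → {range bitmask → weight}; weights per clade sum to 1.
    events : dict
        CladeKey → tuple of event kinds called at that node (filled by
        route annotation).
    optimal_cost : int or None
        Global minimum event cost (parsimony reconstructions only).
    """

    method: str
    topology: str
    alphabet: AreaAlphabet
    node_weights: Dict[CladeKey, Dict[int, float]]
    events: Dict[CladeKey, tuple] = field(default_factory=dict)
    optimal_cost: Optional[int] = None

    def modal_range(self, clade: CladeKey) -> int:
        """Highest-weight range at a clade; ties go to the smallest bitmask."""
        weights = self.node_weights[clade]
        best = max(weights.values())
        return min(m for m, w in weights.items() if w >= best - 1e-12)

    def is_vicariant(self, clade: CladeKey) -> bool:
        return "vicariance" in self.events.get(clade, ())

    def vicariant_clades(self) -> set:
        return {c for c, ev in self.events.items() if "vicariance" in ev}
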