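"""Decision layer: HPD intervals, vicariance consensus, temporal congruence
with geological windows, and the calibration-sensitivity regression.

The congruence question is: could a dated geological or climatic window
(say, the Pebas system at 23–10 Ma) have caused a given cladogenetic event?
The null hypothesis (the event influenced diversification) is kept whenever
the window intersects the node-age 95% interval; under the default
``all-runs-overlap`` rule it is *rejected* as soon as the window is disjoint
from the interval in at least one of the dating analyses (B1/B2/B3), so a
rejection is a robust, analysis-independent incompatibility.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .reconstruction import AncestralReconstruction
from .trees import CladeKey, DatedTree

__all__ = [
    "HPDInterval",
    "AgePosterior",
    "GeoEventWindow",
    "HypothesisRow",
    "VicarianceCall",
    "CongruenceDecision",
    "hpd_interval",
    "congruence_test",
    "run_hypothesis_table",
    "read_hypothesis_table",
    "consensus_vicariance",
    "precision_regression",
    "RULES",
]

RULES = ("all-runs-overlap", "any-run-overlap", "mean-in-window")


@dataclass(frozen=True)
class HPDInterval:
    """Shortest interval holding ≥ ``mass`` of the samples (Ma)."""

    lower: float
    upper: float
    mass: float = 0.95

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class AgePosterior:
    """Node-age samples (Ma) per clade for one dating analysis."""

    label: str
    samples: Dict[CladeKey, np.ndarray]

    def hpd(self, clade: CladeKey, mass: float = 0.95) -> HPDInterval:
        return hpd_interval(self.samples[clade], mass)

    def summaries(self, mass: float = 0.95) -> Dict[CladeKey, Tuple[float, float]]:
        """Per-clade (mean age, interval width) pairs for the regression."""
        out = {}
        for clade, s in self.samples.items():
            iv = hpd_interval(s, mass)
            out[clade] = (float(np.mean(s)), iv.width)
        return out


def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> HPDInterval:
    """Shortest window over the sorted samples containing ≥ mass of them.

    With n samples the window spans k = ceil(mass·n) − 1 order-statistic
    steps; among equal-width windows the one with the smaller lower bound
    wins.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("hpd_interval needs at least one sample")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    if x.size == 1:
        return HPDInterval(float(x[0]), float(x[0]), mass)
    x = np.sort(x)
    n = x.size
    k = int(np.ceil(mass * n)) - 1
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))  # first minimum → smallest lower bound
    return HPDInterval(float(x[i]), float(x[i + k]), mass)


@dataclass(frozen=True)
class GeoEventWindow:
    """A dated geological or biotic window, stored older ≥ younger (Ma)."""

    name: str
    older: float
    younger: float
    kind: str = "geological"

    def __post_init__(self):
        if self.older < self.younger:
            raise ValueError(
                f"window {self.name!r}: older bound {self.older} < younger "
                f"bound {self.younger} (enter bounds older-first)"
            )
        if self.younger < 0:
            raise ValueError(f"window {self.name!r}: negative age")

    @classmethod
    def from_printed(cls, name: str, a: float, b: float, kind: str = "geological"):
        """Accept bounds in either printed order and normalise."""
        return cls(name, max(a, b), min(a, b), kind)

    def overlaps(self, lower: float, upper: float) -> bool:
        """Closed-interval intersection; a shared endpoint counts."""
        return lower <= self.older and self.younger <= upper


@dataclass
class CongruenceDecision:
    decision: str  # "rejected" | "not_rejected"
    rule: str
    flags: Dict[str, bool]  # per-analysis overlap (or mean-in-window) flag


def congruence_test(
    intervals: Mapping[str, Tuple[float, float]],
    window: GeoEventWindow,
    rule: str = "all-runs-overlap",
) -> CongruenceDecision:
    """Test one geological window against per-analysis node-age intervals.

    Rules
    -----
    ``all-runs-overlap`` (default)
        rejected iff the window is disjoint from the interval in ≥ 1 analysis.
    ``any-run-overlap``
        rejected iff the window is disjoint from every analysis interval.
    ``mean-in-window``
        per-analysis flag is "interval midpoint lies inside the window";
        rejected iff any flag is false.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {RULES}")
    if not intervals:
        raise ValueError("at least one analysis interval is required")
    flags: Dict[str, bool] = {}
    for label, (lo, hi) in intervals.items():
        if not lo < hi:
            raise ValueError(f"analysis {label!r}: interval ({lo}, {hi}) needs lower < upper")
        if rule == "mean-in-window":
            mid = 0.5 * (lo + hi)
            flags[label] = window.younger <= mid <= window.older
        else:
            flags[label] = window.overlaps(lo, hi)
    if rule == "any-run-overlap":
        ok = any(flags.values())
    else:
        ok = all(flags.values())
    return CongruenceDecision(
        decision="not_rejected" if ok else "rejected", rule=rule, flags=flags
    )


@dataclass
class HypothesisRow:
    """One line of the hypothesis table: a cladogenetic event × a window."""

    cladogenetic_event: str
    window: GeoEventWindow
    intervals: Dict[str, Tuple[float, float]]  # analysis label → (lower, upper)
    recorded_decision: Optional[str] = None
    clade: Optional[CladeKey] = None


@dataclass
class HypothesisReport:
    decisions: List[CongruenceDecision]
    n_cladogenetic_events: int
    n_geological_hypotheses: int
    n_rejected: int
    mismatches: List[int]  # row indices disagreeing with the recorded decision
    rule: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "rule": self.rule,
                "n_cladogenetic_events": self.n_cladogenetic_events,
                "n_geological_hypotheses": self.n_geological_hypotheses,
                "n_rejected": self.n_rejected,
                "n_rows": len(self.decisions),
                "mismatch_rows": self.mismatches,
                "multiple_testing_correction": "none",
            },
            indent=2,
        )


def run_hypothesis_table(
    rows: Sequence[HypothesisRow], rule: str = "all-runs-overlap"
) -> HypothesisReport:
    """Apply the congruence test to every row and tally the outcomes.

    Counts unique cladogenetic-event labels, geological-kind rows (biotic
    hypotheses are tested but excluded from the geological tally), and
    rejections; rows whose computed decision disagrees with the transcribed
    one are reported as mismatches.  No multiple-testing correction is
    applied.
    """
    seen = set()
    for row in rows:
        key = (row.cladogenetic_event, row.window.name)
        if key in seen:
            raise ValueError(f"duplicate hypothesis row: {key}")
        seen.add(key)
    decisions = [congruence_test(r.intervals, r.window, rule) for r in rows]
    mismatches = [
        i
        for i, (r, d) in enumerate(zip(rows, decisions))
        if r.recorded_decision is not None and r.recorded_decision != d.decision
    ]
    return HypothesisReport(
        decisions=decisions,
        n_cladogenetic_events=len({r.cladogenetic_event for r in rows}),
        n_geological_hypotheses=sum(1 for r in rows if r.window.kind == "geological"),
        n_rejected=sum(1 for d in decisions if d.decision == "rejected"),
        mismatches=mismatches,
        rule=rule,
    )


_HYP_COLUMNS = [
    "cladogenetic_event",
    "geological_event",
    "kind",
    "older_Ma",
    "younger_Ma",
    "B1_lower",
    "B1_upper",
    "B2_lower",
    "B2_upper",
    "B3_lower",
    "B3_upper",
    "recorded_decision",
]


def read_hypothesis_table(source) -> List[HypothesisRow]:
    """Read the tab-separated hypothesis-table format."""
    df = pd.read_csv(source, sep="\t", comment="#")
    missing = [c for c in _HYP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hypothesis table missing columns: {missing}")
    rows: List[HypothesisRow] = []
    for _, r in df.iterrows():
        window = GeoEventWindow.from_printed(
            str(r["geological_event"]),
            float(r["older_Ma"]),
            float(r["younger_Ma"]),
            kind=str(r["kind"]),
        )
        intervals = {
            lab: (float(r[f"{lab}_lower"]), float(r[f"{lab}_upper"]))
            for lab in ("B1", "B2", "B3")
        }
        rows.append(
            HypothesisRow(
                cladogenetic_event=str(r["cladogenetic_event"]),
                window=window,
                intervals=intervals,
                recorded_decision=str(r["recorded_decision"]),
            )
        )
    return rows


def write_decision_table(
    rows: Sequence[HypothesisRow], report: HypothesisReport, path
) -> None:
    records = []
    for i, (row, dec) in enumerate(zip(rows, report.decisions)):
        rec = {
            "cladogenetic_event": row.cladogenetic_event,
            "geological_event": row.window.name,
            "kind": row.window.kind,
            "older_Ma": row.window.older,
            "younger_Ma": row.window.younger,
            "decision": dec.decision,
            "recorded_decision": row.recorded_decision or "",
            "mismatch": i in report.mismatches,
        }
        for lab, flag in dec.flags.items():
            rec[f"{lab}_overlap"] = flag
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


# -- consensus vicariance --------------------------------------------------


@dataclass
class VicarianceCall:
    clade: CladeKey
    support: float  # fraction of grid reconstructions calling vicariance
    topology_presence: int  # number of topologies containing the clade


def consensus_vicariance(
    grid: Sequence[AncestralReconstruction],
    topologies: Mapping[str, DatedTree],
    min_support: float = 0.5,
    per_topology: bool = False,
) -> List[VicarianceCall]:
    """Clades called vicariant across a reconstruction grid.

    A clade is retained when (1) it is annotated vicariant in at least
    ``min_support`` (inclusive) of the reconstructions — over the full grid
    by default, or within every topology when ``per_topology`` — and (2) it
    occurs in every supplied topology.
    """
    if not grid:
        raise ValueError("empty reconstruction grid")
    labels = set(topologies)
    for recon in grid:
        if recon.topology not in labels:
            raise ValueError(
                f"reconstruction tagged with unknown topology {recon.topology!r}; "
                f"known: {sorted(labels)}"
            )
    candidates = set()
    for recon in grid:
        candidates |= recon.vicariant_clades()
    calls: List[VicarianceCall] = []
    for clade in sorted(candidates):
        presence = sum(1 for t in topologies.values() if t.has_clade(clade))
        if presence < len(topologies):
            continue
        hits = sum(1 for r in grid if r.is_vicariant(clade))
        support = hits / len(grid)
        if per_topology:
            ok = True
            for lab in labels:
                sub = [r for r in grid if r.topology == lab]
                if not sub or sum(1 for r in sub if r.is_vicariant(clade)) < min_support * len(sub):
                    ok = False
                    break
            if not ok:
                continue
        elif support < min_support:
            continue
        calls.append(
            VicarianceCall(clade=clade, support=support, topology_presence=presence)
        )
    return calls


# -- calibration-sensitivity regression ------------------------------------


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    residual_se: float
    n: int


def precision_regression(
    summaries: Mapping[str, Mapping[CladeKey, Tuple[float, float]]],
) -> Dict[str, RegressionFit]:
    """OLS of interval width *w* on mean node age *m*, per analysis label.

    Only nodes present in every label enter the fit (so slopes are
    comparable); nodes missing from some label are dropped with a warning.
    """
    labels = list(summaries)
    if not labels:
        raise ValueError("no analyses supplied")
    shared = set.intersection(*(set(summaries[l]) for l in labels))
    dropped = set.union(*(set(summaries[l]) for l in labels)) - shared
    if dropped:
        warnings.warn(
            f"{len(dropped)} node(s) missing from some analysis were dropped",
            stacklevel=2,
        )
    if len(shared) < 3:
        raise ValueError(
            f"need ≥ 3 nodes shared by all analyses, got {len(shared)}"
        )
    order = sorted(shared)
    out: Dict[str, RegressionFit] = {}
    for lab in labels:
        m = np.array([summaries[lab][c][0] for c in order])
        w = np.array([summaries[lab][c][1] for c in order])
        X = np.column_stack([m, np.ones_like(m)])
        coef, *_ = np.linalg.lstsq(X, w, rcond=None)
        resid = w - X @ coef
        dof = max(len(order) - 2, 1)
        out[lab] = RegressionFit(
            slope=float(coef[0]),
            intercept=float(coef[1]),
            residual_se=float(np.sqrt(resid @ resid / dof)),
            n=len(order),
        )
    return out
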