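"""Fossil calibration priors and the B1/B2/B3 configuration bookkeeping.

A calibration prior ties a fossil to the age of a clade: either a normal
distribution (mean Ma, sd Myr) or an exponential distribution (mean Myr)
shifted by a hard minimum ``offset`` in Ma.  The three dating
configurations nest: B1 uses the single deep root calibration, B2 six
calibrations (with the Emesinae fossil as an exponential with a 25 Ma hard
minimum), and B3 all seven (switching that fossil to its normal variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

__all__ = ["CalibrationPrior", "load_calibrations"]

KINDS = ("normal", "exponential")
CONFIGURATIONS = ("B1", "B2", "B3")


@dataclass
class CalibrationPrior:
    name: str  # fossil species
    taxa: Tuple[str, ...]  # ingroup whose MRCA the prior constrains
    kind: str  # "normal" | "exponential"
    mean: float  # Ma (normal) or Myr above the offset (exponential)
    sd: Optional[float] = None  # Myr, normal only
    offset: Optional[float] = None  # Ma hard minimum, exponential only
    configurations: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown prior distribution kind {self.kind!r}")
        if self.kind == "normal":
            if self.sd is None or self.sd <= 0:
                raise ValueError(f"{self.name}: normal prior needs sd > 0")
        else:
            if self.offset is None or self.offset < 0 or self.mean <= 0:
                raise ValueError(
                    f"{self.name}: exponential prior needs offset ≥ 0 and mean > 0"
                )
        bad = [c for c in self.configurations if c not in CONFIGURATIONS]
        if bad:
            raise ValueError(f"{self.name}: unknown configurations {bad}")

    @property
    def hard_minimum(self) -> Optional[float]:
        return self.offset if self.kind == "exponential" else None


def _num(value) -> float:
    """Parse a number, tolerating European decimal commas ('10,5' → 10.5)."""
    return float(str(value).strip().replace(",", "."))


def load_calibrations(source) -> Tuple[List[CalibrationPrior], Dict[str, int]]:
    """Read the tab-separated calibration table.

    Columns: name, clade_taxa (semicolon list), kind, mean, sd_or_offset,
    configurations (semicolon list of B1/B2/B3).  A fossil may appear on
    several rows when different configurations use different distribution
    variants.  Returns the priors plus per-configuration membership counts.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    required = ["name", "clade_taxa", "kind", "mean", "sd_or_offset", "configurations"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"calibration table missing columns: {missing}")
    if df.empty:
        raise ValueError("calibration table holds no priors")
    priors: List[CalibrationPrior] = []
    for _, r in df.iterrows():
        kind = str(r["kind"]).strip().lower()
        mean = _num(r["mean"])
        aux = _num(r["sd_or_offset"])
        priors.append(
            CalibrationPrior(
                name=str(r["name"]).strip(),
                taxa=tuple(t.strip() for t in str(r["clade_taxa"]).split(";") if t.strip()),
                kind=kind,
                mean=mean,
                sd=aux if kind == "normal" else None,
                offset=aux if kind == "exponential" else None,
                configurations=tuple(
                    c.strip() for c in str(r["configurations"]).split(";") if c.strip()
                ),
            )
        )
    counts = {
        cfg: sum(1 for p in priors if cfg in p.configurations) for cfg in CONFIGURATIONS
    }
    return priors, counts
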