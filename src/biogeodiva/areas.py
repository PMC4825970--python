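"""Area alphabets, range bitmasks, and tip presence/absence distributions.

Ranges are subsets of a small ordered area alphabet (at most 12 areas) and
are carried as integer bitmasks: bit *i* set means the lineage occupies the
*i*-th area.  The default alphabet is the 12-area Neotropical coding A–L
(Mexican Transition Zone through North America) used throughout the
package's worked analyses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

import pandas as pd

__all__ = [
    "AreaAlphabet",
    "TipDistribution",
    "DEFAULT_AREAS",
    "read_distribution_matrix",
    "write_distribution_matrix",
]

MAX_AREAS = 12

#: the default 12-area Neotropical biogeographic coding
DEFAULT_AREA_NAMES = {
    "A": "Mexican Transition Zone",
    "B": "Antillean subregion, Brazilian subregion",
    "C": "Mesoamerican Dominion",
    "D": "Pacific Dominion",
    "E": "Boreal Brazilian Dominion",
    "F": "South Brazilian Dominion, Chacoan subregion",
    "G": "South-eastern Amazonian Dominion",
    "H": "Chacoan Dominion",
    "I": "Parana Dominion",
    "J": "South American transition zone",
    "K": "Old World",
    "L": "North America (except Mexico)",
}


class AreaAlphabet:
    """Ordered collection of unique single-letter area codes (≤ 12)."""

    def __init__(self, codes: Iterable[str]):
        codes = list(codes)
        if len(codes) == 0 or len(codes) > MAX_AREAS:
            raise ValueError(f"alphabet must hold 1..{MAX_AREAS} areas, got {len(codes)}")
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate area codes in {codes}")
        self.codes = tuple(codes)
        self._index = {c: i for i, c in enumerate(self.codes)}

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(self.codes)

    def __eq__(self, other) -> bool:
        return isinstance(other, AreaAlphabet) and self.codes == other.codes

    def index(self, code: str) -> int:
        try:
            return self._index[code]
        except KeyError:
            raise KeyError(f"unknown area code {code!r}; alphabet is {self.codes}") from None

    def mask(self, areas: Iterable[str]) -> int:
        """Bitmask for a set of area codes."""
        m = 0
        for a in areas:
            m |= 1 << self.index(a)
        return m

    def unmask(self, mask: int) -> str:
        """Concatenated area letters for a bitmask, in alphabet order."""
        return "".join(c for i, c in enumerate(self.codes) if mask >> i & 1)

    def full_mask(self) -> int:
        return (1 << len(self.codes)) - 1

    def __repr__(self) -> str:  # pragma: no cover
        return f"AreaAlphabet({''.join(self.codes)})"


DEFAULT_AREAS = AreaAlphabet(DEFAULT_AREA_NAMES)


@dataclass
class TipDistribution:
    """Map from tip label to occupied-range bitmask over one alphabet."""

    alphabet: AreaAlphabet
    ranges: Dict[str, int]

    def __post_init__(self):
        full = self.alphabet.full_mask()
        for taxon, mask in self.ranges.items():
            if mask == 0:
                raise ValueError(f"tip {taxon!r} has an empty observed range")
            if mask & ~full:
                raise ValueError(f"tip {taxon!r} range exceeds the alphabet")

    def __getitem__(self, taxon: str) -> int:
        return self.ranges[taxon]

    def covers(self, tip_labels: Iterable[str]) -> bool:
        return set(tip_labels) <= set(self.ranges)

    def require_cover(self, tip_labels: Iterable[str]) -> None:
        missing = set(tip_labels) - set(self.ranges)
        if missing:
            raise ValueError(f"no range recorded for tips: {sorted(missing)}")

    def as_sets(self) -> Dict[str, str]:
        return {t: self.alphabet.unmask(m) for t, m in self.ranges.items()}


def read_distribution_matrix(source) -> TipDistribution:
    """Read a tab-separated taxon × area presence/absence matrix.

    First column holds the taxon label; the header row names one area code
    per remaining column; cells are 0/1.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("distribution matrix needs a taxon column plus ≥1 area column")
    area_codes = list(df.columns[1:])
    alphabet = AreaAlphabet(area_codes)
    ranges: Dict[str, int] = {}
    for _, row in df.iterrows():
        taxon = str(row.iloc[0])
        present = [c for c in area_codes if str(row[c]).strip() == "1"]
        bad = [c for c in area_codes if str(row[c]).strip() not in ("0", "1")]
        if bad:
            raise ValueError(f"non-binary cells for taxon {taxon!r} in columns {bad}")
        ranges[taxon] = alphabet.mask(present)
    return TipDistribution(alphabet, ranges)


def write_distribution_matrix(tips: TipDistribution, path) -> None:
    rows = []
    for taxon in sorted(tips.ranges):
        mask = tips.ranges[taxon]
        rows.append(
            [taxon] + [(mask >> i) & 1 for i in range(len(tips.alphabet))]
        )
    df = pd.DataFrame(rows, columns=["taxon", *tips.alphabet.codes])
    df.to_csv(path, sep="\t", index=False)
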