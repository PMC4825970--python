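"""Packaged reference tables: calibration priors, the hypothesis table, and
the 12-area Neotropical coding."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .areas import AreaAlphabet
from .calibrations import load_calibrations
from .congruence import read_hypothesis_table

__all__ = ["load_fixture", "FIXTURES"]

FIXTURES = ("table1", "table3", "areas")


def _open(name: str):
    return resources.files("biogeodiva.data").joinpath(name).open("r")


def load_fixture(name: str):
    """Return a packaged fixture in its parsed, pipeline-ready form.

    ``table1`` → (list of CalibrationPrior, per-configuration counts);
    ``table3`` → list of HypothesisRow;
    ``areas``  → (AreaAlphabet, {code → description}).
    """
    if name == "table1":
        with _open("table1.tsv") as fh:
            return load_calibrations(fh)
    if name == "table3":
        with _open("table3.tsv") as fh:
            return read_hypothesis_table(fh)
    if name == "areas":
        with _open("areas.tsv") as fh:
            df = pd.read_csv(fh, sep="\t")
        names = dict(zip(df["code"], df["name"]))
        return AreaAlphabet(df["code"]), names
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
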