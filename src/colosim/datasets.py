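"""Packaged data: synthetic fixtures and published reference outcomes."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibration import BenchmarkSet
from .demography import LifeTable
from .natural_history import NHParams

_DATA = resources.files("colosim") / "data"


def load_life_table() -> LifeTable:
    """Synthetic china-2020-like life table (e0 ~ 78 y; see synthetic.py)."""
    with resources.as_file(_DATA / "life_table.csv") as p:
        return LifeTable.from_csv(p)


def load_benchmarks() -> BenchmarkSet:
    """Synthetic china-like calibration benchmarks (lifetime CRC risk 4.6%)."""
    with resources.as_file(_DATA / "benchmarks.csv") as p:
        return BenchmarkSet.from_csv(p)


def load_calibrated_params() -> NHParams:
    """Natural-history parameters calibrated against the packaged benchmarks
    (produced with ``colosim calibrate``; see docs/methods.md)."""
    with resources.as_file(_DATA / "params_calibrated.yaml") as p:
        return NHParams.from_yaml(p)


def load_reference_strategies() -> pd.DataFrame:
    """Externally reported per-1000 outcomes of efficient organized CRC
    screening strategies (FIT / NCPCS / RS categories), used for arithmetic
    cross-checks and as oracles for the efficiency analysis."""
    with resources.as_file(_DATA / "reference_strategies.csv") as p:
        return pd.read_csv(p, comment="#")
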