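"""Loaders for the packaged reference tables.

The package ships the published summary tables for the western/central
Mediterranean sporadic-nesting record: the 40-event nesting inventory, the
18-clutch genetic summary, the six-temperature demographic grid, and the
named mtDNA haplotype metadata (with synthetic stand-in sequences; the real
control-region sequences live in public accessions).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .assignment import HaplotypeReference, load_haplotype_reference
from .tsd import TemperatureGrid, default_grid

__all__ = [
    "sporadic_nesting_events",
    "genotyped_nests",
    "haplotype_reference",
    "default_grid",
]


def _data_path(name: str):
    return resources.as_file(resources.files("caretta") / "data" / name)


def sporadic_nesting_events() -> pd.DataFrame:
    """The 40 recorded sporadic nesting events (one row each)."""
    with _data_path("sporadic_nests.csv") as p:
        return pd.read_csv(p, comment="#")


def genotyped_nests() -> pd.DataFrame:
    """Genetic summary of the 18 clutches with samples assayed
    (121 samples in total, incl. one nesting female)."""
    with _data_path("genotyped_nests.csv") as p:
        return pd.read_csv(p, comment="#")


def haplotype_reference() -> HaplotypeReference:
    """Named haplotypes with origin classes; sequences are synthetic
    stand-ins carrying the published names/accessions."""
    with _data_path("haplotypes_synthetic.fasta") as fp, _data_path(
        "haplotype_origins.tsv"
    ) as op:
        return load_haplotype_reference(fp, op)
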