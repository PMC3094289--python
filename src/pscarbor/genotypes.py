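"""Packaged genotype configurations (one per studied cohort)."""

from __future__ import annotations

from importlib import resources

from .io import read_genotype_config
from .types import GenotypeConfig

__all__ = ["GENOTYPE_ORDER", "load_genotype_config", "load_all_genotype_configs"]

#: Summary-table row order.
GENOTYPE_ORDER = [
    "wildtype",
    "driver_control",
    "plexa_lof_het",
    "plexa_rnai",
    "plexa_rnai_lof",
    "plexb_lof_het",
    "plexb_rnai",
    "plexb_rnai_lof",
    "double_rnai",
]


def load_genotype_config(name: str) -> GenotypeConfig:
    ref = resources.files("pscarbor").joinpath(f"data/genotypes/{name}.cfg")
    with resources.as_file(ref) as path:
        return read_genotype_config(path)


def load_all_genotype_configs() -> dict[str, GenotypeConfig]:
    return {name: load_genotype_config(name) for name in GENOTYPE_ORDER}
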