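"""Loaders for the packaged reference data.

The package ships small TSV fixtures transcribed from the published
rat-louse study: the arrangement catalogs of *Polyplax asiatica* (Pa) and
*Polyplax spinulosa* (Ps), the reconstructed ancestral arrangement, the
per-minichromosome coding-region sizes and read counts, the tRNA T-arm
table, the life-history table, the seven diagnostic junction characters,
and the fixed louse phylogeny.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .model import ArrangementCatalog, LifeHistoryRecord, Phylogeny, load_catalog


def _data_path(name: str):
    return resources.files("minimt.data").joinpath(name)


@lru_cache(maxsize=None)
def _catalogs() -> dict[str, ArrangementCatalog]:
    with resources.as_file(_data_path("catalogs.tsv")) as p:
        return load_catalog(p)  # type: ignore[return-value]


def pa_catalog() -> ArrangementCatalog:
    """Arrangement catalog of *Polyplax asiatica* (11 minichromosomes, 37 genes)."""
    return _catalogs()["Polyplax_asiatica"]


def ps_catalog() -> ArrangementCatalog:
    """Arrangement catalog of *Polyplax spinulosa* (11 minichromosomes, 37 genes)."""
    return _catalogs()["Polyplax_spinulosa"]


@lru_cache(maxsize=None)
def ancestral_catalog() -> ArrangementCatalog:
    """Reconstructed arrangement of the *Polyplax* MRCA.

    Junctions shared between one *Polyplax* species and the pig lice (and,
    where stated, the human lice) are taken as ancestral; the catalog is the
    Pa arrangement with trnP restored between nad4L and cox3 and trnF
    restored downstream of nad5.
    """
    with resources.as_file(_data_path("ancestral_catalog.tsv")) as p:
        return load_catalog(p, species="Polyplax_MRCA")  # type: ignore[return-value]


@lru_cache(maxsize=None)
def coding_sizes() -> pd.DataFrame:
    """Coding-region sizes (bp) and Illumina read counts per minichromosome."""
    with resources.as_file(_data_path("coding_sizes.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


@lru_cache(maxsize=None)
def trna_arm_values() -> pd.DataFrame:
    """T-stem pairs and T-loop nt of the 22 mt tRNAs of Pa and Ps."""
    with resources.as_file(_data_path("trna_arms.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


@lru_cache(maxsize=None)
def life_history_table() -> pd.DataFrame:
    with resources.as_file(_data_path("life_history.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def life_history_records() -> list[LifeHistoryRecord]:
    """Life-history ranges for the five species with complete data."""
    return [
        LifeHistoryRecord(
            species=r.species,
            body_length_mm=(r.body_lo, r.body_hi),
            life_cycle_days=(r.cycle_lo, r.cycle_hi),
            genes_per_minichromosome=r.genes_per_mc,
        )
        for r in life_history_table().itertuples()
    ]


@lru_cache(maxsize=None)
def junction_table() -> pd.DataFrame:
    """The seven diagnostic junction / whole-minichromosome characters."""
    with resources.as_file(_data_path("junctions.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


@lru_cache(maxsize=None)
def louse_tree() -> Phylogeny:
    """Fixed rooted phylogeny of the seven louse species (pig lice outermost)."""
    with resources.as_file(_data_path("louse_tree.nwk")) as p:
        return Phylogeny.from_newick(p)
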