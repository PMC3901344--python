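"""Fragmentation metrics and their relation to life-history traits.

The extent of mt genome fragmentation is summarised as the mean number of
genes per minichromosome (lower = more fragmented).  Against life-history
ranges (converted to midpoints) the association is described by a Spearman
rank correlation with average ranks for ties, plus a strict weak-
monotonicity check; with five species and tied metrics no p-value is
attached — the output is descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .model import ArrangementCatalog, LifeHistoryRecord
from .util import round_half_up


@dataclass
class FragmentationRecord:
    species: str
    n_genes: int
    n_minichromosomes: int
    genes_per_minichromosome: float
    source: str = "computed"  # computed | catalog_constant

    def __post_init__(self) -> None:
        if self.source == "computed":
            expected = round_half_up(self.n_genes / self.n_minichromosomes, 1)
            if self.genes_per_minichromosome != expected:
                raise ValueError(
                    f"{self.species}: metric {self.genes_per_minichromosome} "
                    f"!= {self.n_genes}/{self.n_minichromosomes} rounded ({expected})")


def genes_per_minichromosome(
    source: ArrangementCatalog | tuple[int, int],
    species: str | None = None,
) -> FragmentationRecord:
    """Mean genes per minichromosome, rounded half-up to one decimal.

    Accepts an arrangement catalog or a raw ``(n_genes,
    n_minichromosomes)`` pair.
    """
    if isinstance(source, ArrangementCatalog):
        n_genes = len(source.gene_names())
        n_mc = source.n_minichromosomes
        species = species or source.species
    else:
        n_genes, n_mc = source
        species = species or "unnamed"
    if n_mc < 1:
        raise ValueError("need at least one minichromosome")
    return FragmentationRecord(
        species=species, n_genes=n_genes, n_minichromosomes=n_mc,
        genes_per_minichromosome=round_half_up(n_genes / n_mc, 1))


def _midpoint(rng: tuple[float, float]) -> float:
    return (rng[0] + rng[1]) / 2


def life_history_association(
    records: Sequence[tuple[FragmentationRecord, LifeHistoryRecord]],
    trait: str,
) -> tuple[float, bool]:
    """(Spearman rho, concordant ordering) of fragmentation vs a trait.

    ``trait`` is ``'life_cycle'`` or ``'body_length'``; ranges become
    midpoints.  ``concordant_ordering`` is True iff genes-per-
    minichromosome is weakly monotone in the trait midpoint across all
    records (either direction).
    """
    if trait not in ("life_cycle", "body_length"):
        raise ValueError(f"unknown trait {trait!r}")
    if len(records) < 4:
        raise ValueError("need at least 4 records")
    xs, ys = [], []
    for frag, life in records:
        rng = life.life_cycle_days if trait == "life_cycle" else life.body_length_mm
        if rng is None:
            raise ValueError(f"{life.species}: no {trait} data")
        xs.append(_midpoint(rng))
        ys.append(frag.genes_per_minichromosome)
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("zero variance in trait or metric")
    rho = float(stats.spearmanr(xs, ys).statistic)

    order = np.argsort(np.asarray(xs), kind="stable")
    sorted_y = [ys[i] for i in order]
    non_dec = all(a <= b for a, b in zip(sorted_y, sorted_y[1:]))
    non_inc = all(a >= b for a, b in zip(sorted_y, sorted_y[1:]))
    return rho, bool(non_dec or non_inc)


def fragmentation_records_from_table(df) -> list[tuple[FragmentationRecord, LifeHistoryRecord]]:
    """Pair fragmentation and life-history records from the packaged table."""
    out = []
    for r in df.itertuples():
        frag = FragmentationRecord(
            species=r.species, n_genes=int(r.n_genes),
            n_minichromosomes=int(r.n_minichromosomes),
            genes_per_minichromosome=float(r.genes_per_mc),
            source=r.source)
        life = LifeHistoryRecord(
            species=r.species,
            body_length_mm=(float(r.body_lo), float(r.body_hi)),
            life_cycle_days=(float(r.cycle_lo), float(r.cycle_hi)),
            genes_per_minichromosome=float(r.genes_per_mc))
        out.append((frag, life))
    return out
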