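"""Pipeline configuration and stage orchestration.

Stages run in a fixed order (simulate, assemble, annotate, stretches,
compare, fragstats); each writes its standard artifacts under the output
directory, and the run ends with a machine-readable ``summary.json``
carrying the tool version, a hash of the configuration, the seed, and the
headline counts.  A catalog-only run (``catalog_a``/``catalog_b`` set,
stages ``compare,fragstats``) needs no sequence data at all.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__, fixtures
from .annotate import contigs_to_catalog
from .assembly import assemble_circular
from .compare import compare_catalogs
from .fragstats import (fragmentation_records_from_table, genes_per_minichromosome,
                        life_history_association)
from .model import load_catalog, write_catalog, write_genome_fasta
from .simulate import (SimulationConfig, generate_genome, read_fastq,
                       simulate_reads, write_fastq)
from .stretches import scan_gene_pairs, write_report_tsv

log = logging.getLogger("minimt")

_DEFAULT_STAGES = ("simulate", "assemble", "annotate", "stretches",
                   "compare", "fragstats")


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = _DEFAULT_STAGES
    out_dir: str = "minimt_out"
    seed: int = 0
    # read simulation
    coverage: float = 30.0
    error_rate: float = 0.0
    read_length: int = 90
    read_region: str = "coding"
    # assembly
    min_overlap: int = 50
    min_identity: float = 0.98
    # shared stretches
    stretch_reps: int = 200
    stretch_revcomp: bool = False
    # motif thresholds
    at_threshold: float = 0.60
    gc_threshold: float = 0.55
    # catalog-only comparison inputs
    catalog_a: str | None = None
    catalog_b: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        cfg = cls(**d)
        bad = set(cfg.stages) - set(_DEFAULT_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and return the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    banner = f"minimt {__version__} | config {config.hash()} | seed {config.seed}"
    counts: dict = {}
    state: dict = {}

    def stage_on(name: str) -> bool:
        return name in config.stages

    t0 = time.perf_counter()
    if stage_on("simulate"):
        log.info("stage simulate")
        genome, truth = generate_genome(SimulationConfig(seed=config.seed))
        write_genome_fasta(genome, out / "genome.fasta")
        write_catalog(truth.catalog, out / "truth_catalog.tsv", header=banner)
        with open(out / "reference_genes.fasta", "w") as fh:
            for name, seq in sorted(truth.gene_sequences.items()):
                fh.write(f">{name}\n{seq}\n")
        reads = simulate_reads(
            genome, read_length=config.read_length, coverage=config.coverage,
            error_rate=config.error_rate, seed=config.seed,
            region=config.read_region)
        write_fastq(reads, out / "reads.fastq")
        state.update(genome=genome, truth=truth, reads=reads)
        counts["minichromosomes"] = len(genome)
        counts["genes"] = len(genome.gene_names())

    if stage_on("assemble"):
        log.info("stage assemble")
        reads = state.get("reads")
        if reads is None:
            fq = out / "reads.fastq"
            if not fq.exists():
                raise ValueError("assemble stage needs reads.fastq (run simulate)")
            reads = read_fastq(fq)
        contigs = assemble_circular(reads, config.min_overlap, config.min_identity)
        with open(out / "contigs.fasta", "w") as fh:
            for i, c in enumerate(contigs):
                fh.write(f">contig{i}|circular={'true' if c.circular else 'false'}"
                         f"|reads={c.n_reads}\n{c.sequence}\n")
        state["contigs"] = contigs
        counts["contigs"] = len(contigs)

    if stage_on("annotate"):
        log.info("stage annotate")
        if "contigs" not in state or "truth" not in state:
            raise ValueError("annotate stage needs contigs and reference_genes.fasta")
        catalog = contigs_to_catalog(state["contigs"],
                                     state["truth"].gene_sequences,
                                     species="assembly")
        write_catalog(catalog, out / "assembled_catalog.tsv", header=banner)
        state["assembled"] = catalog
        counts["annotated_genes"] = len(catalog.gene_names())

    if stage_on("stretches"):
        log.info("stage stretches")
        if "genome" not in state:
            raise ValueError("stretches stage needs the simulated genome")
        reports = scan_gene_pairs(state["genome"], reps=config.stretch_reps,
                                  seed=config.seed,
                                  search_revcomp=config.stretch_revcomp)
        write_report_tsv(reports, out / "stretches.tsv")
        counts["flagged_pairs"] = sum(r.flagged for r in reports)

    if stage_on("compare"):
        log.info("stage compare")
        if config.catalog_a and config.catalog_b:
            cat_a = _load_single(config.catalog_a)
            cat_b = _load_single(config.catalog_b)
        elif "truth" in state and "assembled" in state:
            cat_a, cat_b = state["truth"].catalog, state["assembled"]
        else:
            raise ValueError("compare stage needs two catalogs "
                             "(catalog_a/catalog_b or a simulate+annotate run)")
        cmp = compare_catalogs(cat_a, cat_b)
        counts["minichromosomes_a"] = cat_a.n_minichromosomes
        counts["minichromosomes_b"] = cat_b.n_minichromosomes
        counts["identical_minichromosomes"] = cmp.n_identical
        counts["differing_trnas"] = len(cmp.differing_trnas)
        counts["differing_pcg_rrna"] = len(cmp.differing_pcg_rrna)
        state["cmp"] = cmp
        state["cats"] = (cat_a, cat_b)

    if stage_on("fragstats"):
        log.info("stage fragstats")
        metrics: dict[str, float] = {}
        if "cats" in state:
            for cat in state["cats"]:
                rec = genes_per_minichromosome(cat)
                metrics[cat.species] = rec.genes_per_minichromosome
        pairs = fragmentation_records_from_table(fixtures.life_history_table())
        rho, concordant = life_history_association(pairs, "life_cycle")
        metrics["life_cycle_spearman_rho"] = round(rho, 4)
        metrics["life_cycle_concordant"] = concordant
        counts["fragmentation"] = metrics

    summary = {
        "tool": "minimt",
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "counts": counts,
    }
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    log.info("done in %.1fs", time.perf_counter() - t0)
    return summary


def _load_single(path: str):
    cat = load_catalog(path)
    if isinstance(cat, dict):
        raise ValueError(f"{path}: expected a single-species catalog")
    return cat
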