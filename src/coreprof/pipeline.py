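"""End-to-end profiling pipeline and fixture generation.

``run_profile`` chains the two-pass profiler stage by stage — k-mer screen,
restricted mapping, breadth-of-coverage, coverage filter, quantification —
and is tested to equal the manual composition of those stages.  All
randomness derives from one global seed; stage outputs can be written to
documented on-disk formats so each stage is independently inspectable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import synthetic
from .db import CoreGeneDB, KmerIndex, build_kmer_index
from .mapper import build_restricted_reference, compute_coverage, map_reads
from .quantify import AbundanceTable, QuantifierConfig, apply_coverage_filter, quantify
from .screen import screen_sample


@dataclass
class RunConfig:
    k: int = 35
    min_reads: int = 1
    seed_length: int = 31
    max_mismatches: int = 5
    quantifier: QuantifierConfig = field(default_factory=QuantifierConfig)
    seed: int | None = None


def run_profile(
    reads,
    db: CoreGeneDB,
    config: RunConfig = RunConfig(),
    index: KmerIndex | None = None,
    sample_id: str = "sample",
):
    """Profile one sample: screen -> map -> coverage -> filter -> quantify.

    Returns ``(AbundanceTable, CoverageProfile, manifest)`` where the manifest
    records per-stage row counts and the configuration hash.
    """
    if index is None:
        index = build_kmer_index(db, k=config.k)
    candidates = screen_sample(index, reads, min_reads=config.min_reads, sample_id=sample_id)
    reference = build_restricted_reference(db, candidates.species, seed_length=config.seed_length)
    alignments = map_reads(reference, reads, max_mismatches=config.max_mismatches)
    coverage = compute_coverage(alignments, db, sample_id=sample_id)
    retained = apply_coverage_filter(coverage, config.quantifier)
    if len(reads) == 0:
        warnings.warn("empty read set: abundance table is empty")
    table = quantify(alignments, retained, db, sample_id=sample_id)
    cfg_repr = json.dumps(
        {
            "k": config.k,
            "min_reads": config.min_reads,
            "seed_length": config.seed_length,
            "max_mismatches": config.max_mismatches,
            "coverage_threshold": config.quantifier.coverage_threshold,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    manifest = {
        "sample_id": sample_id,
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        "n_reads": len(reads),
        "n_candidates": len(candidates.species),
        "n_alignments": len(alignments),
        "n_retained_species": len(retained),
    }
    return table, coverage, manifest


# ---------------------------------------------------------------------------
# Fixture presets
# ---------------------------------------------------------------------------

PRESETS = {
    "tiny3": dict(
        n_phyla=1,
        genera_per_phylum=1,
        species_per_genus=3,
        genes_per_species=92,
        gene_length_range=(500, 1000),
        divergence=0.05,
        proportions=(0.5, 0.3, 0.2),
        n_reads=5000,
        error_rate=0.0,
        off_target_fraction=0.0,
    ),
    "decoy6": dict(
        n_phyla=1,
        genera_per_phylum=2,
        species_per_genus=3,
        genes_per_species=92,
        gene_length_range=(500, 1000),
        divergence=0.05,
        proportions=(0.5, 0.3, 0.2),
        n_reads=5000,
        error_rate=0.0,
        off_target_fraction=0.1,
    ),
}


def make_fixture(preset: str, seed: int, outdir: str | Path) -> dict:
    """Write a complete on-disk fixture bundle for a named preset.

    Produces reference FASTA, taxonomy TSV, reads FASTQ, per-read truth TSV
    and a JSON manifest; the first species of the taxonomy carry the
    community proportions.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    p = PRESETS[preset]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tax = synthetic.make_taxonomy(p["n_phyla"], p["genera_per_phylum"], p["species_per_genus"])
    db = synthetic.generate_core_genes(
        tax,
        genes_per_species=p["genes_per_species"],
        gene_length_range=p["gene_length_range"],
        divergence=p["divergence"],
        seed=seed,
    )
    species = tax.species_ids()[: len(p["proportions"])]
    community = synthetic.simulate_community(species, p["proportions"], seed=seed)
    reads = synthetic.simulate_reads(
        community,
        db,
        synthetic.ReadSimConfig(
            n_reads=p["n_reads"],
            substitution_error_rate=p["error_rate"],
            off_target_fraction=p["off_target_fraction"],
            seed=seed,
        ),
    )
    db.to_fasta(out / "core_genes.fasta")
    tax.to_tsv(out / "taxonomy.tsv")
    reads.to_fastq(out / "reads.fastq")
    reads.truth_to_tsv(out / "truth.tsv")
    manifest = {
        "preset": preset,
        "seed": seed,
        "community_species": list(community.species_ids),
        "proportions": list(community.proportions),
        "n_reads": len(reads),
        "files": ["core_genes.fasta", "taxonomy.tsv", "reads.fastq", "truth.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
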