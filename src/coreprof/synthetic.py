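"""Synthetic communities with known ground truth.

Everything downstream of the profiler is tested against data produced here:
a small rooted taxonomy, per-species panels of homologous core genes with a
controllable inter-species divergence, shotgun read sets with substitution
errors and off-target decoys, and two-group abundance studies with planted
effect taxa for the statistics layer.

Design choices (documented in the methods note):

* Reads are single-end 150 bp; the profiler logic is strictly per-read, so
  pairing would add no tested behavior.
* The error model is substitution-only; the mapper performs ungapped
  end-to-end extension.
* Off-target decoys are i.i.d. random sequence with the reference's GC
  content: they exercise the coverage filter's false-positive rejection.
* Homologous genes are generated by mutating a per-gene ancestor along the
  taxonomy, so k-mers shared between relatives have genuine LCA structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .db import CoreGeneDB, Taxon, Taxonomy, encode_bases
from .quantify import AbundanceTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Taxonomy generation
# ---------------------------------------------------------------------------


def make_taxonomy(n_phyla: int = 1, genera_per_phylum: int = 1, species_per_genus: int = 3) -> Taxonomy:
    """Balanced root/phylum/genus/species taxonomy with sequential numeric ids."""
    taxa = [Taxon(1, 0, "root", "root")]
    nid = 1
    for p in range(n_phyla):
        nid += 1
        pid = nid
        taxa.append(Taxon(pid, 1, "phylum", f"phylum_{p + 1}"))
        for g in range(genera_per_phylum):
            nid += 1
            gid = nid
            taxa.append(Taxon(gid, pid, "genus", f"genus_{p + 1}_{g + 1}"))
            for s in range(species_per_genus):
                nid += 1
                taxa.append(Taxon(nid, gid, "species", f"species_{p + 1}_{g + 1}_{s + 1}"))
    return Taxonomy(taxa)


# ---------------------------------------------------------------------------
# Core-gene generation
# ---------------------------------------------------------------------------


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a uniform other base."""
    if rate <= 0:
        return codes.copy()
    mask = rng.random(codes.shape) < rate
    shift = rng.integers(1, 4, size=codes.shape)
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def generate_core_genes(
    taxonomy: Taxonomy,
    genes_per_species: int = 92,
    gene_length_range: tuple[int, int] = (500, 1000),
    divergence: float = 0.05,
    seed: int | None = None,
) -> CoreGeneDB:
    """Generate homologous core-gene panels for every species of a taxonomy.

    Each gene has a random ancestral sequence at the root which is mutated
    independently along every taxonomy edge.  Edges above the species rank
    accumulate substitutions at ``divergence`` per site and the terminal
    species edges at ``divergence / 2``, so two sibling species differ at
    ~``divergence`` of sites while species from different genera are more
    distant.  Substitution-only, hence all orthologs share their length.

    Returns a ready :class:`~coreprof.db.CoreGeneDB` (use ``to_fasta`` /
    ``taxonomy.to_tsv`` for the on-disk FASTA + taxonomy-table form).
    """
    species = taxonomy.species_ids()
    if not species:
        raise ValueError("taxonomy contains no species")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if genes_per_species < 1:
        raise ValueError("genes_per_species must be >= 1")
    lo, hi = gene_length_range
    rng = np.random.default_rng(seed)
    width = max(3, len(str(genes_per_species)))
    genes: dict[int, dict[str, str]] = {sp: {} for sp in species}
    decode = np.frombuffer(b"ACGT", dtype=np.uint8)
    for j in range(genes_per_species):
        gid = f"g{j + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        node_seq = {taxonomy.root_id: rng.integers(0, 4, size=length).astype(np.uint8)}
        # walk nodes in id order: parents precede children by construction
        for tid in sorted(taxonomy.nodes):
            if tid == taxonomy.root_id:
                continue
            node = taxonomy.nodes[tid]
            rate = divergence / 2 if node.rank == "species" else divergence
            node_seq[tid] = _mutate(node_seq[node.parent_id], rate, rng)
        for sp in species:
            genes[sp][gid] = decode[node_seq[sp]].tobytes().decode()
    return CoreGeneDB(taxonomy=taxonomy, genes=genes)


# ---------------------------------------------------------------------------
# Communities and reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunityProfile:
    """Ground-truth community: species ids and their relative proportions."""

    species_ids: tuple[int, ...]
    proportions: tuple[float, ...]
    seed: int | None = None

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


def simulate_community(species_ids, proportions, seed: int | None = None) -> CommunityProfile:
    """Normalize ``proportions`` and freeze them with their species ids."""
    species_ids = tuple(int(s) for s in species_ids)
    props = np.asarray(proportions, dtype=float)
    if len(species_ids) != len(props):
        raise ValueError("species_ids and proportions must have equal length")
    if (props < 0).any():
        raise ValueError("proportions must be non-negative")
    total = props.sum()
    if total <= 0:
        raise ValueError("proportions must not all be zero")
    props = props / total
    props = props / props.sum()  # exact renormalization
    return CommunityProfile(species_ids, tuple(float(p) for p in props), seed)


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 150
    substitution_error_rate: float = 0.0
    n_reads: int = 10_000
    off_target_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.substitution_error_rate < 1:
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if not 0 <= self.off_target_fraction <= 1:
            raise ValueError("off_target_fraction must be in [0, 1]")
        if self.read_length < 1 or self.n_reads < 0:
            raise ValueError("read_length and n_reads must be positive")


DECOY_LABEL = 0  # truth label for off-target reads


@dataclass
class ReadSet:
    """Fixed-length read set with per-read ground-truth source labels.

    ``codes`` holds 2-bit base codes (N x read_length); ``truth`` is the
    source species id per read, with 0 marking off-target decoys (``truth``
    is None for reads loaded from plain FASTQ).
    """

    ids: list[str]
    codes: np.ndarray
    truth: np.ndarray | None = None
    _seqs: list[str] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> list[str]:
        if self._seqs is None:
            chars = _BASES[self.codes]
            self._seqs = [row.tobytes().decode() for row in chars]
        return self._seqs

    def to_fastq(self, path: str | Path) -> None:
        qual = "I" * self.read_length  # phred+33 Q40
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.sequences()):
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    def truth_to_tsv(self, path: str | Path) -> None:
        if self.truth is None:
            raise ValueError("read set has no truth labels")
        with open(path, "w") as fh:
            fh.write("read_id\tsource_species\n")
            for rid, t in zip(self.ids, self.truth):
                fh.write(f"{rid}\t{int(t)}\n")

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        from Bio import SeqIO

        ids, seqs = [], []
        try:
            for rec in SeqIO.parse(str(path), "fastq"):
                ids.append(rec.id)
                seqs.append(str(rec.seq).upper())
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ near record {len(ids) + 1}: {exc}") from exc
        if not seqs:
            return cls(ids=[], codes=np.zeros((0, 0), dtype=np.uint8), truth=None)
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("mixed read lengths are not supported")
        codes = np.vstack([encode_bases(s) for s in seqs])
        return cls(ids=ids, codes=codes, truth=None, _seqs=seqs)


def simulate_reads(community: CommunityProfile, db: CoreGeneDB, config: ReadSimConfig) -> ReadSet:
    """Draw shotgun reads from a community's core genes.

    A read's source species is drawn with probability proportional to
    (proportion x total core-gene length), emulating the DNA yield of a
    shotgun library; its position is uniform over valid start positions on a
    uniformly-random strand.  ``off_target_fraction`` of reads are GC-matched
    random decoys labelled 0 in the truth vector.
    """
    for sp in community.species_ids:
        if sp not in db.genes:
            raise ValueError(f"community species {sp} not in database")
    rl = config.read_length
    shortest = min(len(s) for sp in community.species_ids for s in db.genes[sp].values())
    if rl > shortest:
        raise ValueError(f"read_length {rl} exceeds shortest gene length {shortest}")
    rng = np.random.default_rng(config.seed)

    weights = np.array(
        [p * db.total_core_length(sp) for sp, p in zip(community.species_ids, community.proportions)]
    )
    weights = weights / weights.sum()
    probs = np.concatenate([[config.off_target_fraction], (1 - config.off_target_fraction) * weights])
    counts = rng.multinomial(config.n_reads, probs)

    blocks: list[np.ndarray] = []
    truth: list[np.ndarray] = []

    # off-target decoys, GC matched to the reference
    n_off = counts[0]
    if n_off:
        allc = np.concatenate([encode_bases(s) for sp in db.genes for s in db.genes[sp].values()])
        gc = float(np.mean((allc == 1) | (allc == 2)))
        base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        blocks.append(rng.choice(4, size=(n_off, rl), p=base_p).astype(np.uint8))
        truth.append(np.zeros(n_off, dtype=np.int64))

    for sp, n_sp in zip(community.species_ids, counts[1:]):
        if n_sp == 0:
            continue
        gene_codes = [encode_bases(db.genes[sp][g]) for g in sorted(db.genes[sp])]
        starts_per_gene = np.array([len(c) - rl + 1 for c in gene_codes])
        cum = np.concatenate([[0], np.cumsum(starts_per_gene)])
        flat = rng.integers(0, cum[-1], size=n_sp)
        gi = np.searchsorted(cum, flat, side="right") - 1
        pos = flat - cum[gi]
        reads = np.empty((n_sp, rl), dtype=np.uint8)
        for i in range(n_sp):
            reads[i] = gene_codes[gi[i]][pos[i] : pos[i] + rl]
        rc = rng.integers(0, 2, size=n_sp).astype(bool)
        reads[rc] = (3 - reads[rc])[:, ::-1]
        blocks.append(reads)
        truth.append(np.full(n_sp, sp, dtype=np.int64))

    if blocks:
        codes = np.vstack(blocks)
        labels = np.concatenate(truth)
    else:
        codes = np.zeros((0, rl), dtype=np.uint8)
        labels = np.zeros(0, dtype=np.int64)

    if config.substitution_error_rate > 0 and len(codes):
        mask = rng.random(codes.shape) < config.substitution_error_rate
        shift = rng.integers(1, 4, size=codes.shape).astype(np.uint8)
        codes = np.where(mask, (codes + shift) % 4, codes)

    order = rng.permutation(len(codes))
    codes, labels = codes[order], labels[order]
    ids = [f"read{i + 1:07d}" for i in range(len(codes))]
    return ReadSet(ids=ids, codes=codes, truth=labels)


# ---------------------------------------------------------------------------
# Two-group abundance studies for the statistics layer
# ---------------------------------------------------------------------------


def simulate_abundance_study(
    n_per_group: int = 30,
    n_features: int = 100,
    effect_features: tuple[int, ...] = (),
    fold_changes: float | tuple[float, ...] = (),
    dispersion: float = 0.5,
    seed: int | None = None,
    depth: int = 50_000,
    baseline_sigma: float = 1.0,
) -> tuple[AbundanceTable, pd.Series]:
    """Two-group compositional count table with planted effect features.

    Baseline feature means are log-normal; per-sample expected abundances get
    gamma noise with squared coefficient of variation ``dispersion``; counts
    are multinomial at ``depth`` reads.  ``effect_features`` (column indices)
    are multiplied by ``fold_changes`` in group B only.  With all folds at 1
    the two groups are exchangeable, which is what the type-I-error tests
    rely on.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    effect_features = tuple(int(f) for f in np.atleast_1d(np.asarray(effect_features, dtype=int)))
    if any(f < 0 or f >= n_features for f in effect_features):
        raise ValueError("effect_features must be valid feature indices")
    folds = np.asarray(fold_changes, dtype=float)
    if folds.ndim == 0:
        folds = np.full(len(effect_features), float(folds))
    if len(folds) != len(effect_features):
        raise ValueError("fold_changes must match effect_features")
    rng = np.random.default_rng(seed)

    base = rng.lognormal(mean=0.0, sigma=baseline_sigma, size=n_features)
    base /= base.sum()
    mean_b = base.copy()
    for f, fc in zip(effect_features, folds):
        mean_b[f] *= fc

    shape = 1.0 / dispersion if dispersion > 0 else None
    rows, labels, names = [], [], []
    for gname, mean in (("A", base), ("B", mean_b)):
        for i in range(n_per_group):
            lam = rng.gamma(shape, mean / shape) if shape else mean.copy()
            lam = np.where(lam <= 0, 1e-12, lam)
            rows.append(rng.multinomial(depth, lam / lam.sum()))
            labels.append(gname)
            names.append(f"S_{gname}{i + 1:03d}")
    features = [f"feat{j + 1:04d}" for j in range(n_features)]
    counts = pd.DataFrame(np.vstack(rows), index=names, columns=features)
    if (counts.sum(axis=1) <= 0).any():
        warnings.warn("sample with zero total count generated")
    table = AbundanceTable.from_counts(counts)
    return table, pd.Series(labels, index=names, name="group")
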