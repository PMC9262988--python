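"""Core-gene reference database: taxonomy, per-species gene sets, k-mer LCA index.

The database holds, for every species, a fixed panel of single-copy core genes
and the summed length of that panel (used downstream to length-normalize read
counts).  A k-mer index maps every canonical 35-mer occurring in any core gene
to the lowest common ancestor (LCA) of all species that contain it; the index
drives the first, high-recall screening pass of the profiler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS = ("root", "phylum", "genus", "species")

# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Taxon:
    taxon_id: int
    parent_id: int  # 0 for the root
    rank: str
    name: str


class Taxonomy:
    """Rooted taxonomy with numeric node ids; species are the leaves.

    Invariants enforced at construction: exactly one root, every non-root node
    has an existing parent, and every ``species``-rank node is a leaf.
    """

    def __init__(self, taxa: list[Taxon]):
        self.nodes: dict[int, Taxon] = {t.taxon_id: t for t in taxa}
        if len(self.nodes) != len(taxa):
            raise ValueError("duplicate taxon ids")
        roots = [t for t in taxa if t.rank == "root"]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root_id = roots[0].taxon_id
        self._children: dict[int, list[int]] = {t.taxon_id: [] for t in taxa}
        for t in taxa:
            if t.taxon_id == self.root_id:
                continue
            if t.parent_id not in self.nodes:
                raise ValueError(f"taxon {t.taxon_id} has unknown parent {t.parent_id}")
            self._children[t.parent_id].append(t.taxon_id)
        for t in taxa:
            if t.rank == "species" and self._children[t.taxon_id]:
                raise ValueError(f"species {t.taxon_id} is not a leaf")
        # caches
        self._path: dict[int, tuple[int, ...]] = {}
        self._path_sets: dict[int, frozenset[int]] = {}
        self._species_under: dict[int, tuple[int, ...]] = {}

    # -- navigation ---------------------------------------------------------

    def path_to_root(self, taxon_id: int) -> tuple[int, ...]:
        """Path root -> ... -> taxon_id (root first)."""
        cached = self._path.get(taxon_id)
        if cached is not None:
            return cached
        path = []
        t = taxon_id
        while True:
            path.append(t)
            if t == self.root_id:
                break
            t = self.nodes[t].parent_id
        out = tuple(reversed(path))
        self._path[taxon_id] = out
        return out

    def _path_set(self, taxon_id: int) -> frozenset[int]:
        out = self._path_sets.get(taxon_id)
        if out is None:
            out = frozenset(self.path_to_root(taxon_id))
            self._path_sets[taxon_id] = out
        return out

    def lca(self, a: int, b: int) -> int:
        pa, pb = self.path_to_root(a), self.path_to_root(b)
        out = self.root_id
        for x, y in zip(pa, pb):
            if x != y:
                break
            out = x
        return out

    def species_ids(self) -> list[int]:
        return sorted(t.taxon_id for t in self.nodes.values() if t.rank == "species")

    def species_under(self, taxon_id: int) -> tuple[int, ...]:
        cached = self._species_under.get(taxon_id)
        if cached is not None:
            return cached
        if self.nodes[taxon_id].rank == "species":
            out: tuple[int, ...] = (taxon_id,)
        else:
            acc: list[int] = []
            for c in self._children[taxon_id]:
                acc.extend(self.species_under(c))
            out = tuple(sorted(acc))
        self._species_under[taxon_id] = out
        return out

    def is_species(self, taxon_id: int) -> bool:
        return self.nodes[taxon_id].rank == "species"

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_id\tparent_id\trank\tname\n")
            for tid in sorted(self.nodes):
                t = self.nodes[tid]
                fh.write(f"{t.taxon_id}\t{t.parent_id}\t{t.rank}\t{t.name}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        taxa = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("taxon_id"):
                raise ValueError("taxonomy TSV must have a taxon_id header line")
            for line in fh:
                if not line.strip():
                    continue
                tid, pid, rank, name = line.rstrip("\n").split("\t")
                taxa.append(Taxon(int(tid), int(pid), rank, name))
        return cls(taxa)


# ---------------------------------------------------------------------------
# Core-gene database
# ---------------------------------------------------------------------------


@dataclass
class CoreGeneDB:
    """Per-species core-gene sequences plus taxonomy.

    ``genes[species_id][gene_id]`` is an upper-case DNA string.  The summed
    core-gene length per species is the normalization constant for abundance.
    """

    taxonomy: Taxonomy
    genes: dict[int, dict[str, str]]

    def __post_init__(self) -> None:
        for sp in self.genes:
            if sp not in self.taxonomy.nodes or not self.taxonomy.is_species(sp):
                raise ValueError(f"gene species id {sp} is not a species in the taxonomy")
            if not self.genes[sp]:
                raise ValueError(f"species {sp} has zero genes")

    def species_ids(self) -> list[int]:
        return sorted(self.genes)

    def total_core_length(self, species_id: int) -> int:
        return sum(len(s) for s in self.genes[species_id].values())

    def gene_length(self, species_id: int, gene_id: str) -> int:
        return len(self.genes[species_id][gene_id])

    def n_genes(self, species_id: int) -> int:
        return len(self.genes[species_id])

    # -- I/O ----------------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        """Headers are ``<species_id>|<gene_id>`` (numeric id first)."""
        records = []
        for sp in sorted(self.genes):
            for gid in sorted(self.genes[sp]):
                records.append(
                    SeqRecord(Seq(self.genes[sp][gid]), id=f"{sp}|{gid}", description="")
                )
        SeqIO.write(records, str(path), "fasta")

    def save(self, directory: str | Path) -> None:
        """Serialize as a JSON + FASTA + TSV bundle."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_fasta(d / "core_genes.fasta")
        self.taxonomy.to_tsv(d / "taxonomy.tsv")
        manifest = {
            "format": "coreprof-db",
            "version": 1,
            "n_species": len(self.genes),
            "total_core_length": {str(sp): self.total_core_length(sp) for sp in self.genes},
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "CoreGeneDB":
        d = Path(directory)
        taxonomy = Taxonomy.from_tsv(d / "taxonomy.tsv")
        return build_database(d / "core_genes.fasta", taxonomy)


def build_database(core_gene_fasta, taxonomy: Taxonomy | str | Path) -> CoreGeneDB:
    """Build a :class:`CoreGeneDB` from a FASTA of core genes and a taxonomy.

    FASTA headers must be ``<species_id>|<gene_id>``; the species id must be a
    species-rank node of the taxonomy.  Duplicate gene ids within a species are
    rejected.
    """
    if not isinstance(taxonomy, Taxonomy):
        taxonomy = Taxonomy.from_tsv(taxonomy)
    genes: dict[int, dict[str, str]] = {}
    for rec in SeqIO.parse(str(core_gene_fasta), "fasta"):
        parts = rec.id.split("|", 1)
        if len(parts) != 2 or not parts[0].isdigit():
            raise ValueError(f"FASTA header {rec.id!r} lacks a parseable '<species>|<gene>' id")
        sp, gid = int(parts[0]), parts[1]
        per = genes.setdefault(sp, {})
        if gid in per:
            raise ValueError(f"duplicate gene id {gid!r} for species {sp}")
        per[gid] = str(rec.seq).upper()
    if not genes:
        raise ValueError("no sequences in core-gene FASTA")
    return CoreGeneDB(taxonomy=taxonomy, genes=genes)


# ---------------------------------------------------------------------------
# 2-bit k-mer encoding (shared by index build and read screening)
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case


def encode_bases(seq: str | bytes) -> np.ndarray:
    """DNA string -> uint8 codes (A=0 C=1 G=2 T=3, 255 for non-ACGT)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _BASE_CODE[np.frombuffer(seq, dtype=np.uint8)]


def _rolling_codes(codes: np.ndarray, k: int):
    """Per-window (hi, lo, valid) for all k-mers of a (N, L) code matrix.

    A k-mer is split big-endian into ``hi`` (the first max(k-32, 0) bases) and
    ``lo`` (the last min(k, 32) bases), each packed 2 bits/base into uint64.
    Windows containing a non-ACGT base are flagged invalid.
    """
    n, length = codes.shape
    w = length - k + 1
    if w <= 0:
        z = np.zeros((n, 0), dtype=np.uint64)
        return z, z, np.zeros((n, 0), dtype=bool)
    bad = codes > 3
    # transpose so the per-position loop touches contiguous rows
    safe_t = np.ascontiguousarray(np.where(bad, 0, codes).T).astype(np.uint64)
    badcum = np.zeros((n, length + 1), dtype=np.int32)
    np.cumsum(bad, axis=1, out=badcum[:, 1:])

    lo = np.zeros(n, dtype=np.uint64)
    hi = np.zeros(n, dtype=np.uint64)
    lo_mask = np.uint64((1 << (2 * min(k, 32))) - 1)
    hi_bits = 2 * max(k - 32, 0)
    hi_mask = np.uint64((1 << hi_bits) - 1) if hi_bits else np.uint64(0)
    four = np.uint64(4)
    his_t = np.empty((w, n), dtype=np.uint64)
    los_t = np.empty((w, n), dtype=np.uint64)
    for p in range(length):
        lo = (lo * four + safe_t[p]) & lo_mask
        if hi_bits and p >= 32:
            hi = (hi * four + safe_t[p - 32]) & hi_mask
        if p >= k - 1:
            his_t[p - k + 1] = hi
            los_t[p - k + 1] = lo
    valid = (badcum[:, k:] - badcum[:, :-k]) == 0
    return his_t.T, los_t.T, valid


def canonical_kmer_codes(codes: np.ndarray, k: int):
    """Canonical (strand-min) packed k-mer codes for every window.

    Returns (hi, lo, valid) of shape (N, L-k+1); canonical = lexicographic min
    of the forward k-mer and its reverse complement, compared base-wise, which
    equals numeric comparison of the packed big-endian codes.
    """
    fh, fl, fv = _rolling_codes(codes, k)
    rc = np.where(codes == 255, 255, 3 - codes).astype(np.uint8)[:, ::-1]
    rh, rl, _ = _rolling_codes(rc, k)
    rh, rl = rh[:, ::-1], rl[:, ::-1]
    fwd_min = (fh < rh) | ((fh == rh) & (fl <= rl))
    hi = np.where(fwd_min, fh, rh)
    lo = np.where(fwd_min, fl, rl)
    return hi, lo, fv


def pack_key(hi: int, lo: int) -> int:
    return (int(hi) << 64) | int(lo)


def kmer_to_key(kmer: str, k: int) -> int | None:
    """Canonical integer key of a single k-mer string (None if non-ACGT)."""
    codes = encode_bases(kmer)[None, :]
    if codes.shape[1] != k:
        raise ValueError(f"expected a {k}-mer, got length {codes.shape[1]}")
    hi, lo, valid = canonical_kmer_codes(codes, k)
    if not valid[0, 0]:
        return None
    return pack_key(hi[0, 0], lo[0, 0])


# ---------------------------------------------------------------------------
# k-mer LCA index
# ---------------------------------------------------------------------------


@dataclass
class KmerIndex:
    """Map canonical k-mer -> LCA taxon over all species whose core genes
    contain that k-mer.  k is fixed at build time (default 35)."""

    k: int
    taxonomy: Taxonomy
    index: dict[int, int] = field(repr=False, default_factory=dict)
    _groups: dict | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.index)

    def _sorted_groups(self) -> dict:
        """Index keys bucketed by the high word, each bucket's low words sorted.

        Enables vectorized batch lookup via searchsorted: the high word of a
        packed k-mer takes few distinct values (2*(k-32) bits), so queries are
        resolved with one binary search per bucket.
        """
        if self._groups is None:
            groups: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            by_hi: dict[int, list[tuple[int, int]]] = {}
            for key, taxon in self.index.items():
                by_hi.setdefault(key >> 64, []).append((key & 0xFFFFFFFFFFFFFFFF, taxon))
            for h, pairs in by_hi.items():
                pairs.sort()
                lo = np.array([p[0] for p in pairs], dtype=np.uint64)
                taxa = np.array([p[1] for p in pairs], dtype=np.int64)
                groups[h] = (lo, taxa)
            self._groups = groups
        return self._groups

    def lookup(self, kmer: str) -> int | None:
        """Taxon id for one k-mer string, or None if absent/ambiguous-base."""
        key = kmer_to_key(kmer, self.k)
        if key is None:
            return None
        return self.index.get(key)

    def lookup_batch(self, codes: np.ndarray) -> np.ndarray:
        """Per-window taxon ids (-1 where unindexed) for a (N, L) code matrix.

        De-duplicates windows before the dict lookups so the Python-level cost
        scales with the number of *distinct* k-mers in the batch.
        """
        hi, lo, valid = canonical_kmer_codes(codes, self.k)
        n, w = hi.shape
        if w == 0:
            return np.zeros((n, 0), dtype=np.int64)
        q_hi, q_lo = hi.ravel(), lo.ravel()
        out = np.full(n * w, -1, dtype=np.int64)
        # bucket queries by high word (radix argsort when it fits in uint8/16),
        # then one binary search per bucket against the sorted index arrays
        if self.k <= 36:
            q_hi_small = q_hi.astype(np.uint8)
        elif self.k <= 40:
            q_hi_small = q_hi.astype(np.uint16)
        else:
            q_hi_small = q_hi
        order = np.argsort(q_hi_small, kind="stable")
        sorted_hi = q_hi[order]
        for h, (lo_arr, taxa) in self._sorted_groups().items():
            h64 = np.uint64(h)
            a = np.searchsorted(sorted_hi, h64, side="left")
            b = np.searchsorted(sorted_hi, h64, side="right")
            if a == b:
                continue
            idxs = order[a:b]
            ql = q_lo[idxs]
            pos = np.searchsorted(lo_arr, ql)
            pos_c = np.minimum(pos, len(lo_arr) - 1)
            found = lo_arr[pos_c] == ql
            out[idxs] = np.where(found, taxa[pos_c], -1)
        out = out.reshape(n, w)
        out[~valid] = -1
        return out


def build_kmer_index(db: CoreGeneDB, k: int = 35) -> KmerIndex:
    """Index every canonical k-mer of every core gene to its species LCA.

    Genes shorter than k are an error (they would contribute no k-mers and
    silently degrade screening sensitivity for that species).
    """
    tax = db.taxonomy
    index: dict[int, int] = {}
    lca_cache: dict[tuple[int, int], int] = {}

    def lca2(a: int, b: int) -> int:
        if a == b:
            return a
        key = (a, b) if a < b else (b, a)
        out = lca_cache.get(key)
        if out is None:
            out = tax.lca(a, b)
            lca_cache[key] = out
        return out

    for sp in db.species_ids():
        for gid, seq in sorted(db.genes[sp].items()):
            if len(seq) < k:
                raise ValueError(
                    f"gene {gid!r} of species {sp} is shorter ({len(seq)} bp) than k={k}"
                )
            hi, lo, valid = canonical_kmer_codes(encode_bases(seq)[None, :], k)
            hi, lo, valid = hi[0], lo[0], valid[0]
            for i in np.nonzero(valid)[0]:
                key = (int(hi[i]) << 64) | int(lo[i])
                cur = index.get(key)
                index[key] = sp if cur is None else lca2(cur, sp)
    return KmerIndex(k=k, taxonomy=tax, index=index)
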