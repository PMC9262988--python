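"""Second profiler pass: ungapped mapping against candidate core genes and
breadth-of-coverage computation.

The reference is restricted to the candidate species found by the k-mer
screen.  Mapping is exact-seed lookup (default 31 bp seeds placed every
floor(read_length/4) bp plus one flush with the read end) followed by
full-read Hamming extension on both strands; the best-scoring end-to-end hit
is kept, with ties broken deterministically by lowest (taxon, gene,
position).  With seeds every floor(L/4) bp a 150 bp read has four disjoint
seed windows, so every alignment with at most three mismatches is guaranteed
to be found; alignments with more mismatches (up to ``max_mismatches``) are
found on a best-effort basis, as in any seeded mapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .db import CoreGeneDB, encode_bases

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    taxon_id: int
    gene_id: str
    start: int  # 0-based, half-open [start, end)
    end: int
    mismatches: int
    score: int  # matched bases (read_length - mismatches)
    strand: str = "+"


class RestrictedReference:
    """Candidate species' core genes with an exact-seed position index."""

    def __init__(self, genes: dict[tuple[int, str], np.ndarray], seed_length: int = 31):
        self.genes = genes  # (species, gene) -> uint8 base codes
        self.seed_length = seed_length
        self.seed_index: dict[bytes, list[tuple[int, str, int]]] = {}
        for (sp, gid), codes in sorted(genes.items()):
            buf = codes.tobytes()
            for p in range(len(buf) - seed_length + 1):
                self.seed_index.setdefault(buf[p : p + seed_length], []).append((sp, gid, p))

    @property
    def species(self) -> list[int]:
        return sorted({sp for sp, _ in self.genes})

    def n_genes(self) -> int:
        return len(self.genes)


def build_restricted_reference(db: CoreGeneDB, candidates, seed_length: int = 31) -> RestrictedReference:
    """Reference holding exactly the candidate species' core genes."""
    candidates = sorted(set(int(c) for c in candidates))
    unknown = [c for c in candidates if c not in db.genes]
    if unknown:
        raise ValueError(f"unknown candidate species ids: {unknown}")
    if not candidates:
        warnings.warn("empty candidate list: restricted reference is empty")
    genes = {
        (sp, gid): encode_bases(db.genes[sp][gid])
        for sp in candidates
        for gid in sorted(db.genes[sp])
    }
    return RestrictedReference(genes, seed_length=seed_length)


def _seed_offsets(read_length: int, seed_length: int) -> list[int]:
    step = max(1, read_length // 4)
    offsets = list(range(0, read_length - seed_length + 1, step))
    last = read_length - seed_length
    if last not in offsets:
        offsets.append(last)
    return offsets


def map_reads(reference: RestrictedReference, reads, max_mismatches: int = 5) -> list[AlignmentRecord]:
    """Best end-to-end ungapped hit per read; unmapped reads are omitted.

    ``reads`` is a ReadSet or list of (id, sequence) pairs.  A hit needs at
    most ``max_mismatches`` substitutions over the full read; among hits the
    one with fewest mismatches wins and exact ties resolve to the lowest
    (taxon id, gene id, start position, strand).
    """
    if hasattr(reads, "codes"):
        ids = reads.ids
        code_rows = reads.codes
    else:
        ids = [r[0] for r in reads]
        code_rows = [encode_bases(r[1]) for r in reads]

    sl = reference.seed_length
    seed_index = reference.seed_index
    genes = reference.genes
    out: list[AlignmentRecord] = []
    offsets_cache: dict[int, list[int]] = {}

    for rid, codes in zip(ids, code_rows):
        rl = len(codes)
        if rl < sl or not seed_index:
            continue
        offsets = offsets_cache.get(rl)
        if offsets is None:
            offsets = offsets_cache[rl] = _seed_offsets(rl, sl)
        fwd = np.ascontiguousarray(codes)
        rev = np.ascontiguousarray((3 - codes)[::-1])
        best: tuple[int, int, str, int, str] | None = None  # (mm, sp, gid, start, strand)
        seen: set[tuple[int, str, int, str]] = set()
        for strand, arr in (("+", fwd), ("-", rev)):
            buf = arr.tobytes()
            for off in offsets:
                hits = seed_index.get(buf[off : off + sl])
                if not hits:
                    continue
                for sp, gid, pos in hits:
                    start = pos - off
                    gene = genes[(sp, gid)]
                    if start < 0 or start + rl > len(gene):
                        continue
                    key = (sp, gid, start, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    mm = int(np.count_nonzero(gene[start : start + rl] != arr))
                    if mm > max_mismatches:
                        continue
                    cand = (mm, sp, gid, start, strand)
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            mm, sp, gid, start, strand = best
            out.append(
                AlignmentRecord(
                    read_id=rid,
                    taxon_id=sp,
                    gene_id=gid,
                    start=start,
                    end=start + rl,
                    mismatches=mm,
                    score=rl - mm,
                    strand=strand,
                )
            )
    return out


@dataclass
class CoverageProfile:
    """Per-species breadth of coverage over concatenated core genes."""

    sample_id: str
    covered_positions: dict[int, int]
    total_core_length: dict[int, int]
    breadth: dict[int, float]


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    total, cur_s, cur_e = 0, *intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def compute_coverage(alignments, db: CoreGeneDB, sample_id: str = "sample") -> CoverageProfile:
    """Breadth = fraction of core-gene positions covered by >=1 read.

    Each position counts at most once regardless of depth (interval union
    per gene, summed over the species' gene panel).
    """
    per_gene: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for rec in alignments:
        per_gene.setdefault((rec.taxon_id, rec.gene_id), []).append((rec.start, rec.end))
    covered: dict[int, int] = {}
    for (sp, _gid), ivals in per_gene.items():
        covered[sp] = covered.get(sp, 0) + _union_length(ivals)
    totals = {sp: db.total_core_length(sp) for sp in covered}
    breadth = {sp: covered[sp] / totals[sp] for sp in covered}
    return CoverageProfile(
        sample_id=sample_id,
        covered_positions=covered,
        total_core_length=totals,
        breadth=breadth,
    )


def write_sam(alignments, db: CoreGeneDB, path) -> None:
    """Minimal SAM writer (header + 11 mandatory columns, ungapped CIGAR)."""
    refs = sorted({(rec.taxon_id, rec.gene_id) for rec in alignments})
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for sp, gid in refs:
            fh.write(f"@SQ\tSN:{sp}|{gid}\tLN:{db.gene_length(sp, gid)}\n")
        for rec in alignments:
            flag = 0 if rec.strand == "+" else 16
            rl = rec.end - rec.start
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.taxon_id}|{rec.gene_id}\t{rec.start + 1}\t255\t"
                f"{rl}M\t*\t0\t0\t*\t*\n"
            )


def write_coverage_bed(coverage_intervals: dict, path) -> None:
    """BED-like per-gene covered intervals (species, gene, start, end)."""
    with open(path, "w") as fh:
        for (sp, gid), ivals in sorted(coverage_intervals.items()):
            for s, e in sorted(ivals):
                fh.write(f"{sp}|{gid}\t{s}\t{e}\n")
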