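"""First profiler pass: per-read k-mer classification and candidate listing.

Each read's k-mers are looked up in the core-gene LCA index; the read is
assigned to the deepest supported node on the root-to-leaf path that
maximizes the cumulative k-mer hit weight (classic k-mer-classifier scoring).
Per sample, species reaching ``min_reads`` classified reads become candidates
for the second, alignment-based pass; classifications at internal ranks
expand to all descendant species so that screening errs on the side of
recall — the downstream coverage filter removes false positives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .db import KmerIndex, Taxonomy, encode_bases

UNCLASSIFIED = -1


@dataclass
class CandidateList:
    """Candidate species for one sample with their supporting read counts."""

    sample_id: str
    counts: dict[int, int]  # species id -> classified-read count (incl. ancestors)
    min_reads: int

    @property
    def species(self) -> list[int]:
        return sorted(self.counts)


def _codes_matrix(reads) -> np.ndarray:
    """Accept a ReadSet or a list of equal-length strings."""
    if hasattr(reads, "codes"):
        return reads.codes
    if not reads:
        return np.zeros((0, 0), dtype=np.uint8)
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        raise ValueError("reads must have equal length for batch classification")
    return np.vstack([encode_bases(r) for r in reads])


def _resolve_taxon(tax: Taxonomy, hit_taxa: np.ndarray) -> int:
    """Deepest supported node on the maximal-weight root-to-leaf path.

    Ties between leaves are broken toward the lowest taxon id; the chosen
    path is then trimmed to its deepest node with a nonzero hit count, so a
    read whose hits all sit at a genus resolves to that genus.
    """
    counts = Counter(int(t) for t in hit_taxa)
    # fast path: all hits on a single root-to-leaf lineage -> deepest hit wins
    deepest_hit = max(counts, key=lambda t: len(tax.path_to_root(t)))
    if all(t in tax._path_set(deepest_hit) for t in counts):
        return deepest_hit
    leaves: set[int] = set()
    for t in counts:
        leaves.update(tax.species_under(t))
    best_leaf, best_score = None, -1
    for leaf in sorted(leaves):
        score = sum(counts.get(t, 0) for t in tax.path_to_root(leaf))
        if score > best_score:
            best_leaf, best_score = leaf, score
    if best_leaf is None:
        return UNCLASSIFIED
    deepest = UNCLASSIFIED
    for t in tax.path_to_root(best_leaf):
        if counts.get(t, 0) > 0:
            deepest = t
    return deepest


def classify_reads(index: KmerIndex, reads) -> np.ndarray:
    """Vectorized classification of a batch; returns taxon ids (-1 unclassified)."""
    codes = _codes_matrix(reads)
    n = codes.shape[0]
    out = np.full(n, UNCLASSIFIED, dtype=np.int64)
    if n == 0 or codes.shape[1] < index.k:
        return out
    taxa = index.lookup_batch(codes)
    hit_rows = np.nonzero((taxa >= 0).any(axis=1))[0]
    for i in hit_rows:
        row = taxa[i]
        out[i] = _resolve_taxon(index.taxonomy, row[row >= 0])
    return out


def classify_read(index: KmerIndex, read: str) -> int:
    """Classify a single read; reads shorter than k are UNCLASSIFIED."""
    if len(read) < index.k:
        return UNCLASSIFIED
    return int(classify_reads(index, [read])[0])


def screen_sample(index: KmerIndex, reads, min_reads: int = 1, sample_id: str = "sample") -> CandidateList:
    """List candidate species with at least ``min_reads`` supporting reads.

    A read classified to a species supports that species; a read classified
    to an internal node supports every species beneath it (recall-oriented
    expansion).  Raising ``min_reads`` can only shrink the list.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    assignments = classify_reads(index, reads)
    tax = index.taxonomy
    taxon_counts = Counter(int(t) for t in assignments if t != UNCLASSIFIED)
    species_counts: Counter[int] = Counter()
    for t, c in taxon_counts.items():
        for sp in tax.species_under(t):
            species_counts[sp] += c
    counts = {sp: c for sp, c in species_counts.items() if c >= min_reads}
    return CandidateList(sample_id=sample_id, counts=counts, min_reads=min_reads)
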