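"""Read-level functional profiling: six-frame translation, top-hit ortholog
assignment, and parsimony (minimal set cover) pathway inference.

Reads are translated in all six frames and scored against a reference of
ortholog peptide sequences by shared amino-acid k-mers (default k=5); the
highest-scoring ortholog is the read's assignment, with score 0 or a tie
yielding UNASSIGNED.  Observed orthologs are then explained by the smallest
set of pathways whose member orthologs cover them — solved exactly by
branch-and-bound for maps of up to 20 pathways and by greedy set cover
beyond that, with the solver flagged in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

UNASSIGNED = None


def six_frame_translate(read: str) -> list[str]:
    """All six reading frames (3 forward, 3 reverse-complement), '*' at stops,
    'X' at codons with ambiguous bases."""
    seq = Seq(read.upper())
    rc = seq.reverse_complement()
    frames = []
    for s in (seq, rc):
        for off in range(3):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            frames.append(str(sub.translate(table=1)))
    return frames


class OrthologReference:
    """Ortholog peptide sequences with a shared-k-mer lookup table."""

    def __init__(self, peptides: dict[str, str], k_aa: int = 5):
        if not peptides:
            raise ValueError("empty ortholog reference")
        self.k_aa = k_aa
        self.peptides = {k: v.upper() for k, v in peptides.items()}
        self._kmer_map: dict[str, set[str]] = {}
        for ko, pep in self.peptides.items():
            for i in range(len(pep) - k_aa + 1):
                kmer = pep[i : i + k_aa]
                if "*" in kmer or "X" in kmer:
                    continue
                self._kmer_map.setdefault(kmer, set()).add(ko)

    @classmethod
    def from_fasta(cls, path, k_aa: int = 5) -> "OrthologReference":
        from Bio import SeqIO

        peptides = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(peptides, k_aa=k_aa)


def assign_ortholog(read: str, reference: OrthologReference) -> str | None:
    """Top-hit ortholog by shared amino-acid k-mer count over all six frames.

    The score of an ortholog is the number of k-mer positions (across all
    frames) whose k-mer occurs in that ortholog's peptide.  Score 0 or a tie
    for the top score returns UNASSIGNED.
    """
    k = reference.k_aa
    scores: dict[str, int] = {}
    for frame in six_frame_translate(read):
        for i in range(len(frame) - k + 1):
            hit = reference._kmer_map.get(frame[i : i + k])
            if hit:
                for ko in hit:
                    scores[ko] = scores.get(ko, 0) + 1
    if not scores:
        return UNASSIGNED
    top = max(scores.values())
    winners = [ko for ko, s in scores.items() if s == top]
    if len(winners) != 1:
        return UNASSIGNED
    return winners[0]


def count_orthologs(reads, reference: OrthologReference, sample_id: str = "sample") -> pd.Series:
    """Per-sample ortholog read counts (one ortholog per assigned read)."""
    seqs = reads.sequences() if hasattr(reads, "sequences") else list(reads)
    counts: dict[str, int] = {}
    for seq in seqs:
        ko = assign_ortholog(seq, reference)
        if ko is not UNASSIGNED:
            counts[ko] = counts.get(ko, 0) + 1
    out = pd.Series(counts, dtype=int).sort_index()
    out.name = sample_id
    return out


# ---------------------------------------------------------------------------
# Parsimony pathway inference
# ---------------------------------------------------------------------------


@dataclass
class PathwayInference:
    pathways: frozenset[str]
    exact: bool  # True = branch-and-bound optimum, False = greedy set cover
    covered_orthologs: frozenset[str]
    dropped_orthologs: frozenset[str]  # observed but in no pathway


def _greedy_cover(universe: set[str], sets: dict[str, set[str]]) -> set[str]:
    remaining = set(universe)
    chosen: set[str] = set()
    while remaining:
        best = max(sorted(sets), key=lambda p: len(sets[p] & remaining))
        gain = sets[best] & remaining
        if not gain:
            break
        chosen.add(best)
        remaining -= gain
    return chosen


def _exact_cover(universe: set[str], sets: dict[str, set[str]]) -> set[str]:
    """Branch-and-bound minimal set cover, seeded with the greedy bound."""
    names = sorted(sets, key=lambda p: -len(sets[p]))
    best = _greedy_cover(universe, sets)

    def recurse(remaining: frozenset[str], chosen: tuple[str, ...]):
        nonlocal best
        if not remaining:
            if len(chosen) < len(best):
                best = set(chosen)
            return
        if len(chosen) + 1 >= len(best):
            return
        # branch on an arbitrary uncovered element: only sets containing it help
        elem = min(remaining)
        for p in names:
            if elem in sets[p]:
                recurse(remaining - frozenset(sets[p]), chosen + (p,))

    recurse(frozenset(universe), ())
    return best


def infer_pathways(observed_orthologs, pathway_map: dict[str, set[str]]) -> PathwayInference:
    """Smallest pathway set covering all coverable observed orthologs.

    Orthologs absent from every pathway are dropped with a warning.  Exact
    for maps of <= 20 pathways, greedy otherwise (flagged via ``exact``).
    Ties between equally small covers resolve deterministically.
    """
    for p, members in pathway_map.items():
        if not members:
            raise ValueError(f"pathway {p!r} has no member orthologs")
    observed = set(observed_orthologs)
    coverable = {ko for ko in observed if any(ko in m for m in pathway_map.values())}
    dropped = observed - coverable
    if dropped:
        warnings.warn(f"{len(dropped)} observed ortholog(s) belong to no pathway; dropped")
    if not coverable:
        return PathwayInference(frozenset(), True, frozenset(), frozenset(dropped))
    sets = {p: set(m) & coverable for p, m in pathway_map.items() if set(m) & coverable}
    if len(pathway_map) <= 20:
        chosen = _exact_cover(coverable, sets)
        exact = True
    else:
        chosen = _greedy_cover(coverable, sets)
        exact = False
    return PathwayInference(frozenset(chosen), exact, frozenset(coverable), frozenset(dropped))


def pathway_abundance(
    ortholog_counts: pd.Series, kept_pathways, pathway_map: dict[str, set[str]]
) -> pd.Series:
    """Pathway count = sum of member-ortholog counts; an ortholog belonging to
    two kept pathways contributes to both."""
    out = {}
    for p in sorted(kept_pathways):
        members = pathway_map[p]
        out[p] = int(sum(ortholog_counts.get(ko, 0) for ko in members))
    s = pd.Series(out, dtype=int)
    s.name = ortholog_counts.name
    return s
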