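"""Coverage filtering and abundance quantification.

This is the profiler's bespoke final step: a species is only quantified in a
sample if the breadth of coverage over its concatenated core genes is at
least 25% — the filter that suppresses false positives from stray or
off-target alignments — and retained read counts are normalized by each
species' total core-gene length before relative abundances are formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QuantifierConfig:
    coverage_threshold: float = 0.25  # "at least 25%": inclusive boundary

    def __post_init__(self):
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")


class AbundanceTable:
    """Samples x features table with raw, length-normalized and relative layers.

    ``normalized = raw_count / total_core_length`` (reads per bp of core
    genes) and ``relative`` renormalizes each sample's normalized row to sum
    to 1; rows with no retained feature stay all-zero.
    """

    LAYERS = ("raw_count", "normalized", "relative")

    def __init__(self, raw_count: pd.DataFrame, total_core_length: pd.Series | None = None):
        raw_count = raw_count.astype(float)
        if total_core_length is None:
            total_core_length = pd.Series(1.0, index=raw_count.columns)
        total_core_length = total_core_length.reindex(raw_count.columns).astype(float)
        if total_core_length.isna().any() or (total_core_length <= 0).any():
            raise ValueError("every feature needs a positive total_core_length")
        normalized = raw_count.div(total_core_length, axis=1)
        row_sums = normalized.sum(axis=1)
        relative = normalized.div(row_sums.where(row_sums > 0, np.inf), axis=0)
        self.layers: dict[str, pd.DataFrame] = {
            "raw_count": raw_count,
            "normalized": normalized,
            "relative": relative,
        }
        self.feature_meta = pd.DataFrame({"total_core_length": total_core_length})

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, total_core_length: pd.Series | None = None):
        return cls(counts, total_core_length)

    @property
    def raw_count(self) -> pd.DataFrame:
        return self.layers["raw_count"]

    @property
    def normalized(self) -> pd.DataFrame:
        return self.layers["normalized"]

    @property
    def relative(self) -> pd.DataFrame:
        return self.layers["relative"]

    @property
    def samples(self) -> list:
        return list(self.raw_count.index)

    @property
    def features(self) -> list:
        return list(self.raw_count.columns)

    def to_tsv(self, directory, prefix: str = "abundance") -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for layer, df in self.layers.items():
            df.to_csv(d / f"{prefix}.{layer}.tsv", sep="\t")

    @staticmethod
    def concat(tables: list["AbundanceTable"]) -> "AbundanceTable":
        """Stack single-sample tables; missing features fill with zero counts."""
        raw = pd.concat([t.raw_count for t in tables]).fillna(0.0)
        lengths = pd.concat([t.feature_meta["total_core_length"] for t in tables])
        lengths = lengths[~lengths.index.duplicated()]
        # features absent from a table's metadata keep length 1 only if never seen
        return AbundanceTable(raw, lengths.reindex(raw.columns).fillna(1.0))


def apply_coverage_filter(coverage, config: QuantifierConfig = QuantifierConfig()) -> set[int]:
    """Species whose core-gene breadth of coverage is >= the threshold.

    The boundary is inclusive: breadth exactly at the threshold is retained.
    """
    return {sp for sp, breadth in coverage.breadth.items() if breadth >= config.coverage_threshold}


def quantify(alignments, retained: set[int], db, sample_id: str = "sample") -> AbundanceTable:
    """One-sample abundance table over the retained species.

    Raw counts are best-hit read counts per species (reads mapped to
    filtered-out species are dropped, not reassigned); the normalized layer
    divides by total core-gene length and the relative layer renormalizes it.
    """
    counts: dict[int, int] = {sp: 0 for sp in retained}
    for rec in alignments:
        if rec.taxon_id in counts:
            counts[rec.taxon_id] += 1
    if not retained:
        warnings.warn(f"sample {sample_id}: no species passed the coverage filter")
        raw = pd.DataFrame(0.0, index=[sample_id], columns=pd.Index([], dtype=object))
        return AbundanceTable(raw)
    species = sorted(retained)
    raw = pd.DataFrame([[float(counts[sp]) for sp in species]], index=[sample_id], columns=species)
    lengths = pd.Series({sp: float(db.total_core_length(sp)) for sp in species})
    return AbundanceTable(raw, lengths)
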