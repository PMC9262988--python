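"""Community statistics: alpha diversity, Bray-Curtis/PERMANOVA, CLR,
two-group testing with BH control, linear association, and contingency
summaries.

Conventions: Shannon uses the natural logarithm by default (switchable),
Chao1 is the bias-corrected estimator by default (the classic form is
available and falls back to bias-corrected when no doubletons exist), and
PERMANOVA permutes raw group labels with a seeded generator so p-values are
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class StatsConfig:
    permutations: int = 999
    bh_q: float = 0.05
    alpha: float = 0.05
    clr_pseudocount: float | None = None  # None: half the smallest nonzero value
    seed: int | None = None

    def __post_init__(self):
        if self.permutations < 99:
            raise ValueError("permutations must be >= 99")
        if not 0 < self.bh_q < 1:
            raise ValueError("bh_q must be in (0, 1)")


@dataclass
class TestResult:
    feature: str
    statistic: float
    p: float
    q: float
    direction: str  # label of the group with the larger central tendency


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)) (bias-corrected form).

    The classic form S_obs + F1^2 / (2 F2) is used when ``bias_corrected`` is
    False and both singletons and doubletons exist; otherwise it falls back
    to the bias-corrected estimator.  An all-zero sample has richness 0.
    """
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(c, np.round(c)):
        raise ValueError("Chao1 requires integer counts")
    c = np.round(c).astype(np.int64)
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        return 0.0
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if not bias_corrected and f1 and f2:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts, base: float = np.e) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log by default)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon diversity needs a positive total count")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


# ---------------------------------------------------------------------------
# Beta diversity and PERMANOVA
# ---------------------------------------------------------------------------


def bray_curtis(abundance) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1].

    A pair of all-zero samples has no defined dissimilarity; it is set to 0
    with a warning.
    """
    df = pd.DataFrame(abundance)
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    with np.errstate(invalid="ignore"):
        dm = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(dm).any():
        warnings.warn("all-zero sample pair: Bray-Curtis distance set to 0")
        dm = np.nan_to_num(dm, nan=0.0)
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=df.index, columns=df.index)


def permanova(distance_matrix, labels, config: StatsConfig = StatsConfig()) -> tuple[float, float]:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = (SS_among / (a-1)) / (SS_within / (n-a)) with sums of squared
    distances; p = (#{permuted F >= observed} + 1) / (permutations + 1).
    Label permutations are vectorized and driven by ``config.seed``.
    """
    dm = pd.DataFrame(distance_matrix).to_numpy(dtype=float)
    labels = np.asarray(pd.Series(labels))
    n = len(labels)
    if dm.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    groups, g = np.unique(labels, return_inverse=True)
    a = len(groups)
    if a < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(g)
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 samples")
    d2 = dm**2
    ss_total = d2.sum() / (2.0 * n)

    def ss_within_for(code_matrix: np.ndarray) -> np.ndarray:
        # code_matrix: (B, n) integer group codes
        out = np.zeros(code_matrix.shape[0])
        for k in range(a):
            m = (code_matrix == k).astype(float)
            out += np.einsum("bi,ij,bj->b", m, d2, m) / (2.0 * sizes[k])
        return out

    ss_w = float(ss_within_for(g[None, :])[0])
    ss_a = ss_total - ss_w
    f_obs = (ss_a / (a - 1)) / (ss_w / (n - a))

    rng = np.random.default_rng(config.seed)
    perm = np.array([rng.permutation(g) for _ in range(config.permutations)])
    ss_w_perm = ss_within_for(perm)
    f_perm = ((ss_total - ss_w_perm) / (a - 1)) / (ss_w_perm / (n - a))
    p = (np.count_nonzero(f_perm >= f_obs) + 1) / (config.permutations + 1)
    return float(f_obs), float(p)


# ---------------------------------------------------------------------------
# CLR transform
# ---------------------------------------------------------------------------


def clr_transform(table, pseudocount: float | None = None) -> pd.DataFrame:
    """Centered log-ratio per sample: log(x + delta) minus its row mean.

    ``pseudocount`` defaults to half the smallest nonzero value in the table
    (only needed when zeros are present); each output row sums to 0.
    """
    df = pd.DataFrame(table).astype(float)
    x = df.to_numpy()
    if (x < 0).any():
        raise ValueError("CLR requires non-negative abundances")
    has_zero = (x == 0).any()
    if pseudocount is None:
        pseudocount = x[x > 0].min() / 2.0 if has_zero else 0.0
    if has_zero and pseudocount <= 0:
        raise ValueError("a positive pseudocount is required when zeros are present")
    logx = np.log(x + pseudocount)
    out = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# Group testing with BH control
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1] if len(p) else p


def groupwise_mwu(table, labels, config: StatsConfig = StatsConfig()) -> list[TestResult]:
    """Per-feature two-sided Mann-Whitney U (normal approximation with tie
    correction) across two groups, with BH-adjusted q-values.

    A feature constant across both groups gets p = 1.  ``direction`` is the
    label of the group with the larger mean rank.
    """
    df = pd.DataFrame(table)
    labels = pd.Series(labels, index=df.index if len(labels) == len(df) else None)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("groupwise_mwu needs exactly two groups")
    ga, gb = groups
    ia, ib = labels == ga, labels == gb
    stats_, ps, dirs = [], [], []
    for col in df.columns:
        x, y = df.loc[ia, col].to_numpy(), df.loc[ib, col].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            u, p = len(x) * len(y) / 2.0, 1.0
            direction = "none"
        else:
            u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            direction = str(ga) if u > len(x) * len(y) / 2.0 else str(gb)
        stats_.append(float(u))
        ps.append(float(p))
        dirs.append(direction)
    qs = bh_adjust(ps)
    return [
        TestResult(feature=str(c), statistic=s, p=p, q=float(q), direction=d)
        for c, s, p, q, d in zip(df.columns, stats_, ps, qs, dirs)
    ]


def pairwise_linear_association(x_feature, y_table, config: StatsConfig = StatsConfig()) -> pd.DataFrame:
    """OLS of every y feature on x (paired samples): slope, t-test p, BH q."""
    y = pd.DataFrame(y_table)
    x = pd.Series(x_feature)
    if not x.index.equals(y.index):
        x = x.reindex(y.index)
        if x.isna().any():
            raise ValueError("x and y tables must share sample ids")
    if len(x) < 3:
        raise ValueError("need >= 3 paired samples")
    rows = []
    for col in y.columns:
        res = sps.linregress(x.to_numpy(), y[col].to_numpy())
        rows.append((str(col), res.slope, res.rvalue, res.pvalue))
    out = pd.DataFrame(rows, columns=["feature", "slope", "r", "p"]).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Contingency summaries (cohort-table style)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoProportionResult:
    pct1: float  # percentage, rounded to 1 decimal
    pct2: float
    p: float
    test: str  # "chi2" or "fisher"


def two_proportion_summary(a: int, n1: int, b: int, n2: int) -> TwoProportionResult:
    """Percentages (1 decimal) and a 2x2 test of a/n1 vs b/n2.

    Chi-square with continuity correction by default; Fisher's exact test
    when any table margin is zero.
    """
    if not (0 <= a <= n1 and 0 <= b <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= a <= n1 and 0 <= b <= n2 with positive n")
    table = np.array([[a, n1 - a], [b, n2 - b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        _, p = sps.fisher_exact(table)
        test = "fisher"
    else:
        _, p, _, _ = sps.chi2_contingency(table, correction=True)
        test = "chi2"
    return TwoProportionResult(
        pct1=round(100.0 * a / n1, 1), pct2=round(100.0 * b / n2, 1), p=float(p), test=test
    )
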