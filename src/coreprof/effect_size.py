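"""LDA effect-size biomarker discovery (two-class LEfSe-style path).

Features below a minimum mean relative abundance (default 0.01%) are removed;
the survivors are screened with a Kruskal-Wallis test and, for those passing,
an effect size is computed from bootstrapped linear-discriminant fits on
abundances rescaled to [0, 1e6].  A feature is selected as a biomarker when
its Kruskal-Wallis p is below ``kw_alpha`` and its averaged log10 effect size
reaches ``lda_cutoff`` (default 2.0).

Per-feature scoring: within each bootstrap round a two-class LDA is fit
jointly on all screened features; with w the unit-norm discriminant
direction, feature f's effect is the mean of (a) its raw class-mean
difference and (b) |w_f| times the class-mean difference of the projected
data — i.e. the feature's abundance shift averaged with its share of the
discriminant separation, the canonical LDA-effect-size combination.  The
score is log10(max(effect, 1)), averaged over rounds; the 1e6 rescaling puts
scores on the familiar 2-5 range that makes a cutoff of 2.0 meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


@dataclass(frozen=True)
class EffectSizeConfig:
    min_relative_abundance: float = 1e-4  # 0.01%
    kw_alpha: float = 0.05
    lda_cutoff: float = 2.0
    bootstrap_rounds: int = 30
    subsample_fraction: float = 2.0 / 3.0
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.min_relative_abundance < 1:
            raise ValueError("min_relative_abundance must be in [0, 1)")
        if self.lda_cutoff < 0:
            raise ValueError("lda_cutoff must be >= 0")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclass
class EffectSizeResult:
    feature: str
    kw_p: float
    enriched: str  # group label with the larger mean abundance
    lda_score: float  # log10 scale; NaN if the feature failed the KW screen
    selected: bool


def abundance_filter(
    relative_table, config: EffectSizeConfig = EffectSizeConfig(), per_sample_max: bool = False
) -> pd.DataFrame:
    """Drop features with mean relative abundance below the threshold.

    "Below" is strict: a feature exactly at the threshold is kept.  With
    ``per_sample_max`` the per-sample maximum is compared instead of the mean.
    """
    df = pd.DataFrame(relative_table).astype(float)
    stat = df.max(axis=0) if per_sample_max else df.mean(axis=0)
    kept = df.loc[:, stat >= config.min_relative_abundance]
    if kept.shape[1] == 0:
        raise ValueError("abundance filter removed every feature")
    return kept


def lda_effect_size(
    table, labels, config: EffectSizeConfig = EffectSizeConfig()
) -> list[EffectSizeResult]:
    """Kruskal-Wallis screen followed by bootstrapped LDA effect sizes.

    Deterministic for a fixed ``config.seed``.  Groups need >= 3 samples each.
    """
    df = pd.DataFrame(table).astype(float)
    labels = pd.Series(labels)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("effect-size analysis needs exactly two groups")
    ga, gb = groups
    ia = (labels == ga).to_numpy()
    ib = (labels == gb).to_numpy()
    if ia.sum() < 3 or ib.sum() < 3:
        raise ValueError("each group needs >= 3 samples")

    x = df.to_numpy() * 1e6  # rescale to [0, 1e6], the canonical LDA scale
    features = [str(c) for c in df.columns]
    kw_p = np.empty(len(features))
    for j in range(len(features)):
        xa, xb = x[ia, j], x[ib, j]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            kw_p[j] = 1.0
        else:
            kw_p[j] = sps.kruskal(xa, xb).pvalue
    passing = np.nonzero(kw_p < config.kw_alpha)[0]

    scores = np.full(len(features), np.nan)
    if len(passing):
        rng = np.random.default_rng(config.seed)
        xs = x[:, passing]
        a_idx, b_idx = np.nonzero(ia)[0], np.nonzero(ib)[0]
        na = max(2, int(np.ceil(config.subsample_fraction * len(a_idx))))
        nb = max(2, int(np.ceil(config.subsample_fraction * len(b_idx))))
        acc = np.zeros(len(passing))
        for _ in range(config.bootstrap_rounds):
            sel = np.concatenate(
                [rng.choice(a_idx, na, replace=False), rng.choice(b_idx, nb, replace=False)]
            )
            xi, yi = xs[sel], labels.to_numpy()[sel]
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(xi, yi)
            w = lda.coef_[0]
            norm = np.linalg.norm(w)
            w_unit = w / norm if norm > 0 else w
            dmean = xi[yi == ga].mean(axis=0) - xi[yi == gb].mean(axis=0)
            proj = xi @ w_unit
            d_proj = abs(proj[yi == ga].mean() - proj[yi == gb].mean())
            effect = 0.5 * (np.abs(dmean) + np.abs(w_unit) * d_proj)
            acc += np.log10(np.maximum(effect, 1.0))
        scores[passing] = acc / config.bootstrap_rounds

    results = []
    for j, feat in enumerate(features):
        mean_a, mean_b = x[ia, j].mean(), x[ib, j].mean()
        enriched = str(ga) if mean_a >= mean_b else str(gb)
        selected = bool(kw_p[j] < config.kw_alpha and scores[j] >= config.lda_cutoff)
        results.append(
            EffectSizeResult(
                feature=feat,
                kw_p=float(kw_p[j]),
                enriched=enriched,
                lda_score=float(scores[j]),
                selected=selected,
            )
        )
    return results


def results_to_frame(results: list[EffectSizeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature, r.kw_p, r.enriched, r.lda_score, r.selected) for r in results],
        columns=["feature", "kw_p", "enriched", "lda_score", "selected"],
    ).set_index("feature")
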