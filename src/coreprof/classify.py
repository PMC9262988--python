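"""Repeated cross-validated discrimination of sample groups.

The protocol mirrors common microbiome classifier evaluations: a random
forest (pluggable via a learner factory) trained with stratified k-fold
cross-validation repeated ``n_repeats`` times, reporting the ROC AUC of every
held-out fold, per-repeat means, a grand mean, and a percentile 95% CI over
repeat means.  Two classifier runs are compared with a two-sided
Mann-Whitney U test on their repeat-level AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ClassifierConfig:
    n_repeats: int = 20
    n_folds: int = 5
    n_trees: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CvResult:
    fold_aucs: np.ndarray = field(repr=False)  # (n_repeats, n_folds)
    repeat_means: np.ndarray
    grand_mean: float
    ci: tuple[float, float]  # 2.5 / 97.5 percentiles of repeat means

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_means)

    def to_dict(self) -> dict:
        return {
            "fold_aucs": self.fold_aucs.tolist(),
            "repeat_means": self.repeat_means.tolist(),
            "grand_mean": self.grand_mean,
            "ci": list(self.ci),
        }


def _default_learner(n_trees: int):
    def factory(random_state: int):
        return RandomForestClassifier(n_estimators=n_trees, random_state=random_state)

    return factory


def cross_validated_auc(
    features, labels, config: ClassifierConfig = ClassifierConfig(), learner_factory=None
) -> CvResult:
    """Stratified repeated-CV ROC AUC.

    Folds are re-randomized each repeat from sub-seeds of ``config.seed``;
    exactly ``n_repeats x n_folds`` fold-AUCs are recorded.  Requires two
    classes with at least ``n_folds`` samples each.
    """
    x = pd.DataFrame(features).to_numpy(dtype=float)
    y = np.asarray(pd.Series(labels))
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if np.bincount(y_enc).min() < config.n_folds:
        raise ValueError("each class needs >= n_folds samples")
    if learner_factory is None:
        learner_factory = _default_learner(config.n_trees)

    ss = np.random.SeedSequence(config.seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_repeats)]
    fold_aucs = np.empty((config.n_repeats, config.n_folds))
    for r, rseed in enumerate(repeat_seeds):
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=rseed)
        for f, (train, test) in enumerate(skf.split(x, y_enc)):
            clf = learner_factory(rseed + f)
            clf.fit(x[train], y_enc[train])
            prob = clf.predict_proba(x[test])[:, 1]
            fold_aucs[r, f] = roc_auc_score(y_enc[test], prob)
    repeat_means = fold_aucs.mean(axis=1)
    ci = (float(np.percentile(repeat_means, 2.5)), float(np.percentile(repeat_means, 97.5)))
    return CvResult(
        fold_aucs=fold_aucs,
        repeat_means=repeat_means,
        grand_mean=float(repeat_means.mean()),
        ci=ci,
    )


def compare_classifiers(cv_a: CvResult, cv_b: CvResult) -> float:
    """Two-sided Mann-Whitney U p-value on repeat-level AUCs."""
    if cv_a.n_repeats != cv_b.n_repeats:
        raise ValueError("results have different numbers of repeats")
    a, b = cv_a.repeat_means, cv_b.repeat_means
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
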