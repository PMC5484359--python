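"""Imbalance-aware metrics and synthetic-free pooled cross-validation.

Raw accuracy on a 42/38/10 cohort mostly reflects the majority classes, so
performance is summarized per class by one-vs-rest precision, sensitivity
(recall), specificity, the F-measure ``2ps/(p+s)`` and the G-mean
``sqrt(sensitivity * specificity)``, plus the balanced accuracy rate (BAR),
the unweighted mean of per-class sensitivities.

:func:`pooled_cv` implements the pool-rotation scheme: the *original*
cohort is stratified into ``z`` pools; for each held-out pool, borderline-
SMOTE is applied only to the minority cases of the remaining ``z - 1``
pools, the learner (with fold-local PCA) is trained on the augmented
training partition and scored on the untouched held-out pool.  Synthetic
cases therefore never appear in any test set, and every original sample is
tested exactly once per repeat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort
from .errors import ValidationError
from .learners import LearnerConfig
from .preprocessing import pca_fit_transform
from .resampling import SmoteConfig, oversample

logger = logging.getLogger(__name__)

METRIC_NAMES = ("precision", "sensitivity", "specificity", "f_measure", "g_mean")


@dataclass
class ConfusionSummary:
    """Counts matrix with rows = truth and columns = prediction."""

    matrix: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.class_names),) * 2:
            raise ValidationError("confusion matrix must be square over class_names")
        if np.any(self.matrix < 0):
            raise ValidationError("confusion counts must be >= 0")

    @classmethod
    def from_labels(
        cls,
        truth: Sequence[str],
        predicted: Sequence[str],
        class_names: Sequence[str] | None = None,
    ) -> "ConfusionSummary":
        truth = [str(t) for t in truth]
        predicted = [str(p) for p in predicted]
        if len(truth) != len(predicted):
            raise ValidationError("truth and prediction lengths differ")
        names = sorted(set(truth) | set(predicted)) if class_names is None else list(class_names)
        index = {c: i for i, c in enumerate(names)}
        matrix = np.zeros((len(names), len(names)))
        for t, p in zip(truth, predicted):
            matrix[index[t], index[p]] += 1
        return cls(matrix=matrix, class_names=names)

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        if self.class_names != other.class_names:
            raise ValidationError("cannot add confusions over different classes")
        return ConfusionSummary(self.matrix + other.matrix, list(self.class_names))


def per_class_rates(confusion: ConfusionSummary, target: str) -> dict[str, float]:
    """One-vs-rest precision, sensitivity and specificity for ``target``.

    Empty denominators yield 0 with a logged warning.
    """
    if target not in confusion.class_names:
        raise ValidationError(f"class {target!r} not in confusion matrix")
    m = confusion.matrix
    if m.sum() == 0:
        raise ValidationError("confusion matrix is all zeros")
    i = confusion.class_names.index(target)
    tp = m[i, i]
    row = m[i].sum()
    col = m[:, i].sum()
    fp = col - tp
    tn = m.sum() - row - col + tp

    def ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            logger.warning("empty denominator for %s of class %r; returning 0", what, target)
            return 0.0
        return float(num / den)

    return {
        "precision": ratio(tp, col, "precision"),
        "sensitivity": ratio(tp, row, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
    }


def g_mean(sensitivity: float, specificity: float, sqrt: bool = True) -> float:
    """Geometric mean of sensitivity and specificity.

    ``sqrt=False`` gives the bare product (the literal printed form of the
    formula, which omits the radical).
    """
    for v in (sensitivity, specificity):
        if not (0.0 <= v <= 1.0):
            raise ValidationError("rates must lie in [0, 1]")
    product = sensitivity * specificity
    return math.sqrt(product) if sqrt else product


def f_measure(precision: float, sensitivity: float) -> float:
    """Harmonic mean ``2ps / (p + s)``; 0 when both rates are 0."""
    for v in (precision, sensitivity):
        if not (0.0 <= v <= 1.0):
            raise ValidationError("rates must lie in [0, 1]")
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def bar(confusion: ConfusionSummary) -> float:
    """Balanced accuracy rate: mean per-class sensitivity over classes in truth."""
    row_sums = confusion.matrix.sum(axis=1)
    present = row_sums > 0
    if not present.any():
        raise ValidationError("no class has truth counts > 0")
    sens = np.diag(confusion.matrix)[present] / row_sums[present]
    return float(sens.mean())


def _metrics_from_confusion(confusion: ConfusionSummary) -> dict[str, dict[str, float]]:
    out = {}
    for cls in confusion.class_names:
        rates = per_class_rates(confusion, cls)
        rates["f_measure"] = f_measure(rates["precision"], rates["sensitivity"])
        rates["g_mean"] = g_mean(rates["sensitivity"], rates["specificity"])
        out[cls] = rates
    return out


@dataclass
class EvaluationReport:
    """Repeat-averaged per-class metrics plus per-repeat detail."""

    per_class: dict[str, dict[str, float]]
    bar: float
    n_folds: int
    n_repeats: int
    rate: float
    per_repeat: list[dict] = field(default_factory=list)
    audit: list[dict] = field(default_factory=list)

    @property
    def per_repeat_bars(self) -> list[float]:
        return [r["bar"] for r in self.per_repeat]

    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "bar": self.bar,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "per_class": self.per_class,
            "per_repeat_bars": self.per_repeat_bars,
        }


def _stratified_pools(
    cohort: Cohort, z: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random stratified partition into z pools (minority spread ~1 per pool)."""
    pools: list[list[int]] = [[] for _ in range(z)]
    for cls in cohort.class_names:
        idx = rng.permutation(cohort.class_indices(cls))
        offset = int(rng.integers(z))
        for j, i in enumerate(idx):
            pools[(offset + j) % z].append(int(i))
    if any(len(p) == 0 for p in pools):
        raise ValidationError(f"cannot form {z} nonempty pools from {cohort.n_samples} samples")
    return [np.array(sorted(p)) for p in pools]


def pooled_cv(
    cohort: Cohort,
    config: SmoteConfig,
    learner: LearnerConfig,
    z: int = 10,
    repeats: int = 100,
    seed: int = 0,
    use_pca: bool = True,
    variance_threshold: float = 0.95,
    collect_audit: bool = False,
) -> EvaluationReport:
    """Pool-rotation cross-validation with synthetic-free test sets.

    Per repeat: stratify the original cohort into ``z`` pools; for each
    held-out pool, oversample the minority cases of the remaining pools,
    fit fold-local PCA on the augmented training block (when ``use_pca``),
    train the learner and score the untouched held-out pool.  Fold
    confusions accumulate into one per-repeat confusion; metric values are
    averaged across repeats.  With ``config.rate == 0`` this reduces to
    plain stratified z-fold cross-validation.
    """
    if cohort.is_synthetic.any():
        raise ValidationError("input cohort must contain no synthetic rows")
    if z < 2 or z > cohort.n_samples:
        raise ValidationError("z must lie in [2, n_samples]")
    class_names = cohort.class_names
    master = np.random.default_rng(seed)
    per_repeat: list[dict] = []
    audit: list[dict] = []
    for rep in range(repeats):
        rep_rng = np.random.default_rng(int(master.integers(2**31 - 1)))
        pools = _stratified_pools(cohort, z, rep_rng)
        confusion = ConfusionSummary(np.zeros((len(class_names),) * 2), list(class_names))
        for fold, test_idx in enumerate(pools):
            train_idx = np.setdiff1d(np.arange(cohort.n_samples), test_idx)
            train = cohort.subset(train_idx)
            test = cohort.subset(test_idx)
            if config.rate > 0:
                fold_cfg = SmoteConfig(
                    minority_class=config.minority_class,
                    rate=config.rate,
                    k=config.k,
                    seed=int(rep_rng.integers(2**31 - 1)),
                    metric=config.metric,
                )
                train = oversample(train, fold_cfg)
            x_train, x_test = train.features, test.features
            if use_pca:
                _, x_train, x_test = pca_fit_transform(x_train, x_test, variance_threshold)
            model = learner.fit(x_train, train.labels, seed=int(rep_rng.integers(2**31 - 1)))
            predicted = np.asarray(model.predict(x_test), dtype=object)
            confusion = confusion + ConfusionSummary.from_labels(
                test.labels, predicted, class_names
            )
            if collect_audit:
                audit.append(
                    {
                        "repeat": rep,
                        "fold": fold,
                        "test_ids": tuple(map(str, test.sample_ids)),
                        "n_synthetic_in_test": int(test.is_synthetic.sum()),
                        "n_synthetic_in_train": int(train.is_synthetic.sum()),
                    }
                )
        per_repeat.append(
            {
                "bar": bar(confusion),
                "per_class": _metrics_from_confusion(confusion),
                "total_scored": float(confusion.matrix.sum()),
            }
        )
    averaged = {
        cls: {
            metric: float(np.mean([r["per_class"][cls][metric] for r in per_repeat]))
            for metric in METRIC_NAMES
        }
        for cls in class_names
    }
    return EvaluationReport(
        per_class=averaged,
        bar=float(np.mean([r["bar"] for r in per_repeat])),
        n_folds=z,
        n_repeats=repeats,
        rate=config.rate,
        per_repeat=per_repeat,
        audit=audit,
    )


def rate_comparison(
    reports: Mapping[float, Sequence[float]], method: str = "kruskal"
) -> tuple[float, float]:
    """Compare per-repeat BARs across oversampling rates.

    Kruskal–Wallis rank test by default (``method="anova"`` for one-way
    ANOVA), alpha 0.05 by convention.  Groups that are all identical
    constants return (0.0, 1.0): no evidence of any difference.
    """
    groups = [np.asarray(v, dtype=float) for v in reports.values()]
    if len(groups) < 2:
        raise ValidationError("need >= 2 rate groups")
    if any(g.size < 2 for g in groups):
        raise ValidationError("every rate group needs >= 2 values")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if method == "kruskal":
        stat, p = stats.kruskal(*groups)
    elif method == "anova":
        stat, p = stats.f_oneway(*groups)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(stat), float(p)
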