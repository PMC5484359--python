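"""Borderline synthetic minority oversampling (borderline-SMOTE).

The minority class is partitioned by the composition of each member's
k-nearest neighborhood over *all* other samples:

* **noise** — every neighbor belongs to a non-minority class;
* **danger** (borderline) — non-minority neighbors strictly outnumber
  minority neighbors, but not all k are non-minority;
* **safe** — otherwise.

Synthetic samples are generated only from the danger set: each new case is
``x_i + (x_hat - x_i) * delta`` with ``x_hat`` one of the seed's k nearest
*minority* neighbors and ``delta ~ Uniform[0, 1]``, i.e. a point on the
segment joining the two parents.  All non-minority classes are treated as
one pooled majority when classifying neighborhoods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .cohort import Cohort
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SmoteConfig:
    """Oversampling parameters.

    rate is the fraction of the minority size to add (0.5 adds 5 cases to a
    10-case class); k is the neighbor count (default 5).
    """

    minority_class: str
    rate: float = 1.0
    k: int = 5
    seed: int = 0
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError("oversampling rate must be >= 0")
        if self.k < 1:
            raise ValidationError("neighbor count k must be >= 1")


@dataclass
class MinorityTaxonomy:
    """Disjoint partition of the minority class by neighborhood composition."""

    safe_ids: list[str] = field(default_factory=list)
    danger_ids: list[str] = field(default_factory=list)
    noise_ids: list[str] = field(default_factory=list)


def _neighbor_order(distances: np.ndarray) -> np.ndarray:
    """Indices sorted by distance, ties broken by row order (deterministic)."""
    return np.lexsort((np.arange(distances.size), distances))


def classify_minority(cohort: Cohort, config: SmoteConfig) -> MinorityTaxonomy:
    """Partition the minority class into safe / danger / noise subsets.

    Each minority sample's k nearest neighbors are found among all *other*
    samples (any class, self excluded) under the configured metric.
    """
    minority_idx = cohort.class_indices(config.minority_class)
    if minority_idx.size == 0:
        raise ValidationError(f"minority class {config.minority_class!r} has no samples")
    if config.k >= cohort.n_samples:
        raise ValidationError("k must be smaller than the total sample count")
    dist = cdist(cohort.features[minority_idx], cohort.features, metric=config.metric)
    is_minor = cohort.labels == config.minority_class
    taxonomy = MinorityTaxonomy()
    for row, i in enumerate(minority_idx):
        d = dist[row].copy()
        d[i] = np.inf  # exclude self
        neighbors = _neighbor_order(d)[: config.k]
        n_minor = int(is_minor[neighbors].sum())
        sid = str(cohort.sample_ids[i])
        if n_minor == 0:
            taxonomy.noise_ids.append(sid)
        elif config.k - n_minor > n_minor:
            taxonomy.danger_ids.append(sid)
        else:
            taxonomy.safe_ids.append(sid)
    return taxonomy


def smote_interpolate(
    xi: np.ndarray, neighbor: np.ndarray, delta: float
) -> np.ndarray:
    """Convex interpolation ``xi + (neighbor - xi) * delta``, delta in [0, 1]."""
    xi = np.asarray(xi, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    if xi.shape != neighbor.shape:
        raise ValidationError("parent vectors must share a shape")
    if not (0.0 <= delta <= 1.0):
        raise ValidationError("delta must lie in [0, 1]")
    return xi + (neighbor - xi) * delta


def oversample(cohort: Cohort, config: SmoteConfig) -> Cohort:
    """Append ``round(rate * n_minority)`` synthetic minority samples.

    Seeds cycle through the danger set in a random order, one synthetic
    sample per visit, until the quota is met; each synthetic case
    interpolates between its seed and one of the seed's k nearest
    minority-class neighbors.  When the danger set is empty, the full
    minority set minus the noise points serves as the seed pool (with a
    logged warning).  Original rows are returned unchanged; synthetic rows
    carry the minority label, fresh ids and ``is_synthetic=True``.
    """
    minority_idx = cohort.class_indices(config.minority_class)
    n_min = minority_idx.size
    n_new = math.floor(config.rate * n_min + 0.5)  # round half up
    if n_new == 0:
        return cohort.copy()
    if n_min < 2:
        raise ValidationError("minority class needs >= 2 samples to interpolate")

    taxonomy = classify_minority(cohort, config)
    id_to_idx = {str(s): i for i, s in enumerate(cohort.sample_ids)}
    seed_ids = taxonomy.danger_ids
    if not seed_ids:
        seed_ids = [s for s in map(str, cohort.sample_ids[minority_idx])
                    if s not in set(taxonomy.noise_ids)]
        if not seed_ids:
            seed_ids = [str(s) for s in cohort.sample_ids[minority_idx]]
        logger.warning(
            "danger set empty for minority class %r; seeding from %d non-noise minority samples",
            config.minority_class, len(seed_ids),
        )
    seed_idx = np.array([id_to_idx[s] for s in seed_ids])

    # k nearest minority neighbors of each seed (second, minority-only search)
    minority_feats = cohort.features[minority_idx]
    dist = cdist(cohort.features[seed_idx], minority_feats, metric=config.metric)
    neighbor_lists = []
    for row, i in enumerate(seed_idx):
        d = dist[row].copy()
        d[minority_idx == i] = np.inf  # exclude self
        order = _neighbor_order(d)
        avail = min(config.k, n_min - 1)
        neighbor_lists.append(minority_idx[order[:avail]])

    rng = np.random.default_rng(config.seed)
    visit_order = rng.permutation(len(seed_idx))
    new_rows, new_ids = [], []
    produced = 0
    while produced < n_new:
        for pos in visit_order:
            if produced >= n_new:
                break
            xi = cohort.features[seed_idx[pos]]
            neighbors = neighbor_lists[pos]
            x_hat = cohort.features[neighbors[rng.integers(len(neighbors))]]
            delta = rng.uniform(0.0, 1.0)
            new_rows.append(smote_interpolate(xi, x_hat, delta))
            new_ids.append(f"SYN-{config.minority_class}-{produced + 1:03d}")
            produced += 1
        visit_order = rng.permutation(len(seed_idx))

    return Cohort(
        features=np.vstack([cohort.features, np.array(new_rows)]),
        feature_names=list(cohort.feature_names),
        labels=np.concatenate([cohort.labels, np.array([config.minority_class] * n_new, dtype=object)]),
        sample_ids=np.concatenate([cohort.sample_ids, np.array(new_ids, dtype=object)]),
        is_synthetic=np.concatenate([cohort.is_synthetic, np.ones(n_new, dtype=bool)]),
    )
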