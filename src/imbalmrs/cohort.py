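"""Labelled sample containers and their delimited-text representations.

A :class:`Cohort` is the package's in-memory feature table: one row per
patient (or synthetic case), a class label, a stable sample id and a flag
marking rows created by oversampling.  A :class:`SpectrumSet` holds the
"complete spectra" representation: a shared chemical-shift (ppm) axis plus
one intensity vector per sample.  Both round-trip through tab-delimited
text so every artefact of a run is inspectable with standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ID_COLUMN = "sample_id"
LABEL_COLUMN = "label"
SYNTHETIC_COLUMN = "is_synthetic"


@dataclass
class Cohort:
    """Samples × features matrix with labels, ids and synthetic flags.

    Parameters
    ----------
    features
        Array of shape ``(n_samples, n_features)``.
    feature_names
        Ordered feature (metabolite or spectral-point) names.
    labels
        Class name per sample.
    sample_ids
        Unique id per sample.
    is_synthetic
        True for rows created by oversampling; all False at generation time.
    """

    features: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    sample_ids: np.ndarray
    is_synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        self.feature_names = [str(f) for f in self.feature_names]
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.is_synthetic is None:
            self.is_synthetic = np.zeros(self.features.shape[0], dtype=bool)
        self.is_synthetic = np.asarray(self.is_synthetic, dtype=bool)
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.sample_ids) == len(self.is_synthetic) == n):
            raise ValidationError("row count, labels, ids and synthetic flags must align")
        if self.features.shape[1] != len(self.feature_names):
            raise ValidationError("feature count must match feature_names")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids must be unique")

    # -- basic queries -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def class_names(self) -> list[str]:
        return sorted(set(self.labels))

    def class_counts(self) -> dict[str, int]:
        names, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))

    def class_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.labels == name)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "Cohort":
        idx = np.asarray(indices, dtype=int)
        return Cohort(
            features=self.features[idx],
            feature_names=list(self.feature_names),
            labels=self.labels[idx],
            sample_ids=self.sample_ids[idx],
            is_synthetic=self.is_synthetic[idx],
        )

    def copy(self) -> "Cohort":
        return replace(
            self,
            features=self.features.copy(),
            feature_names=list(self.feature_names),
            labels=self.labels.copy(),
            sample_ids=self.sample_ids.copy(),
            is_synthetic=self.is_synthetic.copy(),
        )

    # -- I/O -----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=self.feature_names)
        frame.insert(0, SYNTHETIC_COLUMN, self.is_synthetic)
        frame.insert(0, LABEL_COLUMN, self.labels)
        frame.insert(0, ID_COLUMN, self.sample_ids)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Cohort":
        missing = {ID_COLUMN, LABEL_COLUMN} - set(frame.columns)
        if missing:
            raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
        synth = (
            frame[SYNTHETIC_COLUMN].astype(bool).to_numpy()
            if SYNTHETIC_COLUMN in frame.columns
            else np.zeros(len(frame), dtype=bool)
        )
        feature_cols = [
            c for c in frame.columns if c not in (ID_COLUMN, LABEL_COLUMN, SYNTHETIC_COLUMN)
        ]
        return cls(
            features=frame[feature_cols].to_numpy(dtype=float),
            feature_names=list(feature_cols),
            labels=frame[LABEL_COLUMN].to_numpy(dtype=object),
            sample_ids=frame[ID_COLUMN].astype(str).to_numpy(dtype=object),
            is_synthetic=synth,
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class SpectrumSet:
    """Shared ppm axis plus per-sample intensity vectors."""

    ppm: np.ndarray
    intensities: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != self.intensities.shape[0]:
                raise ValidationError("labels must align with spectra")
        if self.intensities.shape[1] != self.ppm.size:
            raise ValidationError("intensity columns must match the ppm axis")
        if len(self.sample_ids) != self.intensities.shape[0]:
            raise ValidationError("sample ids must align with spectra")
        if np.any(np.diff(self.ppm) <= 0):
            raise ValidationError("ppm axis must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def to_cohort(self, prefix: str = "ppm_") -> Cohort:
        """Expose the spectra as a feature table for classification."""
        if self.labels is None:
            raise ValidationError("spectra carry no labels; cannot build a cohort")
        names = [f"{prefix}{v:.4f}" for v in self.ppm]
        return Cohort(
            features=self.intensities.copy(),
            feature_names=names,
            labels=self.labels,
            sample_ids=self.sample_ids,
        )

    def write_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.intensities, columns=[f"{v:.6f}" for v in self.ppm])
        if self.labels is not None:
            frame.insert(0, LABEL_COLUMN, self.labels)
        frame.insert(0, ID_COLUMN, self.sample_ids)
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SpectrumSet":
        frame = pd.read_csv(path, sep="\t")
        labels = frame[LABEL_COLUMN].to_numpy(object) if LABEL_COLUMN in frame else None
        axis_cols = [c for c in frame.columns if c not in (ID_COLUMN, LABEL_COLUMN)]
        return cls(
            ppm=np.array([float(c) for c in axis_cols]),
            intensities=frame[axis_cols].to_numpy(dtype=float),
            sample_ids=frame[ID_COLUMN].astype(str).to_numpy(dtype=object),
            labels=labels,
        )
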