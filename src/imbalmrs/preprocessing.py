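"""Quality control, metabolite filtering, profile assembly and PCA.

Implements the standard preparation steps of the classification pipeline:

* spectral SNR per the quality-control definition
  ``(max(spectrum - baseline)) / (2 * RMS noise)`` with inclusive
  thresholds SNR >= 4 and FWHM <= 0.15 ppm;
* the Cramér–Rao lower-bound inclusion rule (a metabolite is kept when at
  least ``min_patients`` samples have CRLB strictly below the bound);
* assembly of the 17-variable profile (14 classification metabolites plus
  the grouped lipid/macromolecule resonances TLM09/TLM13/TLM20) with
  composite sums (total NAA = NAA + NAAG, total creatine = creatine +
  phosphocreatine, total choline = GPC + PC on request);
* windowing of spectra to the 0.5-4.0 ppm analysis range;
* leakage-free PCA retaining the smallest number of leading components
  whose cumulative explained variance reaches the threshold (default 95%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort import SpectrumSet
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Canonical 17-variable profile order: 14 metabolites, then the TLM group.
CLASSIFICATION_METABOLITES = [
    "citrate",
    "glycerophosphocholine",
    "glucose",
    "glutamine",
    "glutathione",
    "glutamate",
    "glycine",
    "myo_inositol",
    "lactate",
    "phosphocholine",
    "scyllo_inositol",
    "taurine",
    "total_creatine",
    "total_naa",
]
TLM_VARIABLES = ["TLM09", "TLM13", "TLM20"]
PROFILE_VARIABLES = CLASSIFICATION_METABOLITES + TLM_VARIABLES

#: Default grouping of the nine lipid/macromolecule basis components onto
#: the three broad resonances (names follow common spectral-fitting bases).
DEFAULT_TLM_COMPONENTS: dict[str, list[str]] = {
    "0.9": ["MM09", "Lip09"],
    "1.3": ["MM12", "MM14", "Lip13a", "Lip13b"],
    "2.0": ["MM17", "MM20", "Lip20"],
}

_TLM_NAME = {"0.9": "TLM09", "1.3": "TLM13", "2.0": "TLM20"}

_COMPOSITES = {
    "total_naa": ("naa", "naag"),
    "total_creatine": ("creatine", "phosphocreatine"),
    "total_choline": ("glycerophosphocholine", "phosphocholine"),
}


@dataclass
class QCThresholds:
    """Inclusive spectral quality-control limits."""

    min_snr: float = 4.0
    max_fwhm_ppm: float = 0.15

    def __post_init__(self) -> None:
        if self.min_snr <= 0 or self.max_fwhm_ppm <= 0:
            raise ValidationError("QC thresholds must be positive")


def snr(
    spectrum: np.ndarray,
    baseline: np.ndarray | float = 0.0,
    noise_rms: float = 1.0,
) -> float:
    """Signal-to-noise ratio: max(spectrum - baseline) / (2 * noise RMS)."""
    if noise_rms <= 0:
        raise ValidationError("noise_rms must be > 0")
    signal = np.asarray(spectrum, dtype=float) - np.asarray(baseline, dtype=float)
    return float(np.max(signal) / (2.0 * noise_rms))


def estimate_noise_rms(
    spectra: SpectrumSet, region: tuple[float, float] = (3.75, 4.0)
) -> np.ndarray:
    """Per-sample noise RMS from a signal-free ppm region (mean-detrended)."""
    lo, hi = region
    mask = (spectra.ppm >= lo) & (spectra.ppm <= hi)
    if mask.sum() < 2:
        raise ValidationError("noise region contains fewer than 2 axis points")
    seg = spectra.intensities[:, mask]
    return np.sqrt(np.mean((seg - seg.mean(axis=1, keepdims=True)) ** 2, axis=1))


def qc_filter(
    spectra: SpectrumSet,
    fwhm_per_sample: Sequence[float],
    thresholds: QCThresholds | None = None,
    noise_rms: float | Sequence[float] | None = None,
    baseline: np.ndarray | float = 0.0,
) -> list[str]:
    """Ids of samples passing SNR >= min_snr and FWHM <= max_fwhm_ppm.

    FWHM is taken as a per-sample input (it comes from the spectral-fitting
    software, not from the spectrum itself).  ``noise_rms`` may be a scalar,
    per-sample, or None to estimate it from the 3.75-4.0 ppm region.
    """
    thresholds = thresholds or QCThresholds()
    fwhm = np.asarray(fwhm_per_sample, dtype=float)
    if fwhm.size != spectra.n_samples:
        raise ValidationError("fwhm_per_sample must align with spectra")
    if noise_rms is None:
        noise = estimate_noise_rms(spectra)
    else:
        noise = np.broadcast_to(np.asarray(noise_rms, dtype=float), (spectra.n_samples,))
    kept = []
    for i, sid in enumerate(spectra.sample_ids):
        s = snr(spectra.intensities[i], baseline, float(noise[i]))
        if s >= thresholds.min_snr and fwhm[i] <= thresholds.max_fwhm_ppm:
            kept.append(str(sid))
    return kept


def crlb_filter(
    crlb: pd.DataFrame,
    bound: float = 50.0,
    min_patients: int = 2,
    metabolites: Sequence[str] | None = None,
) -> list[str]:
    """Metabolites with CRLB < bound (strict) in at least ``min_patients`` samples.

    ``crlb`` is samples x metabolites, in percent; NaN marks a missing
    estimate and never counts toward inclusion.
    """
    if min_patients < 1:
        raise ValidationError("min_patients must be >= 1")
    cols = list(crlb.columns) if metabolites is None else list(metabolites)
    unknown = set(cols) - set(crlb.columns)
    if unknown:
        raise ValidationError(f"unknown metabolites in CRLB table: {sorted(unknown)}")
    values = crlb[cols].to_numpy(dtype=float)
    counts = np.sum(np.nan_to_num(values, nan=np.inf) < bound, axis=0)
    return [m for m, c in zip(cols, counts) if c >= min_patients]


def assemble_profile(
    metabolites: pd.DataFrame,
    tlm_components: Mapping[str, Sequence[str]] | None = None,
    include_total_choline: bool = False,
) -> pd.DataFrame:
    """Build the canonical 17-variable profile from a per-sample table.

    Columns are matched case-insensitively.  Composites (total NAA, total
    creatine and, on request, total choline) are taken as-is when present
    and otherwise computed as sums of their components; the nine
    lipid/macromolecule components are grouped onto the 0.9 / 1.3 / 2.0 ppm
    resonances.  Output order is the 14 classification metabolites followed
    by TLM09, TLM13, TLM20 (+ total_choline last when requested).
    """
    tlm_components = dict(tlm_components) if tlm_components is not None else DEFAULT_TLM_COMPONENTS
    lower = {c.lower(): c for c in metabolites.columns}

    def col(name: str) -> pd.Series | None:
        key = name.lower()
        return metabolites[lower[key]] if key in lower else None

    def composite(name: str) -> pd.Series:
        existing = col(name)
        if existing is not None:
            return existing.astype(float)
        parts = []
        for part in _COMPOSITES[name]:
            series = col(part)
            if series is None:
                raise ValidationError(
                    f"cannot build {name!r}: component {part!r} missing from the table"
                )
            parts.append(series.astype(float))
        return sum(parts)

    out = pd.DataFrame(index=metabolites.index)
    for name in CLASSIFICATION_METABOLITES:
        if name in _COMPOSITES:
            out[name] = composite(name)
        else:
            series = col(name)
            if series is None:
                raise ValidationError(f"metabolite {name!r} missing from the table")
            out[name] = series.astype(float)
    for resonance, components in tlm_components.items():
        tlm_name = _TLM_NAME.get(str(resonance), f"TLM{str(resonance).replace('.', '')}")
        existing = col(tlm_name)
        if existing is not None:
            out[tlm_name] = existing.astype(float)
            continue
        parts = []
        for part in components:
            series = col(part)
            if series is None:
                raise ValidationError(
                    f"cannot build {tlm_name}: component {part!r} missing from the table"
                )
            parts.append(series.astype(float))
        out[tlm_name] = sum(parts)
    if include_total_choline:
        out["total_choline"] = composite("total_choline")
    return out


def window_spectrum(
    spectra: SpectrumSet, lo_ppm: float = 0.5, hi_ppm: float = 4.0
) -> SpectrumSet:
    """Restrict spectra to axis points within [lo, hi] ppm, inclusive."""
    if lo_ppm >= hi_ppm:
        raise ValidationError("window bounds must satisfy lo < hi")
    mask = (spectra.ppm >= lo_ppm) & (spectra.ppm <= hi_ppm)
    if not mask.any():
        raise ValidationError("window does not intersect the ppm axis")
    return SpectrumSet(
        ppm=spectra.ppm[mask],
        intensities=spectra.intensities[:, mask],
        sample_ids=spectra.sample_ids.copy(),
        labels=None if spectra.labels is None else spectra.labels.copy(),
    )


@dataclass
class PcaModel:
    """Fitted PCA rotation retaining a cumulative-variance fraction."""

    component_loadings: np.ndarray  # features x components
    component_variances: np.ndarray  # explained-variance fractions
    feature_means: np.ndarray
    n_components: int
    variance_threshold: float

    def transform(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        return (x - self.feature_means) @ self.component_loadings

    def write_text(self, path: str | Path) -> None:
        lines = [
            f"# pca_model threshold={self.variance_threshold} n_components={self.n_components}",
            "# feature_means\t" + "\t".join(f"{v:.10g}" for v in self.feature_means),
            "# component_variances\t" + "\t".join(f"{v:.10g}" for v in self.component_variances),
        ]
        for row in self.component_loadings:
            lines.append("\t".join(f"{v:.10g}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_text(cls, path: str | Path) -> "PcaModel":
        lines = Path(path).read_text().strip().splitlines()
        header = dict(kv.split("=") for kv in lines[0].removeprefix("# pca_model ").split())
        means = np.array([float(v) for v in lines[1].split("\t")[1:]])
        variances = np.array([float(v) for v in lines[2].split("\t")[1:]])
        loadings = np.array([[float(v) for v in line.split("\t")] for line in lines[3:]])
        return cls(
            component_loadings=loadings,
            component_variances=variances,
            feature_means=means,
            n_components=int(header["n_components"]),
            variance_threshold=float(header["threshold"]),
        )


def pca_fit_transform(
    train_features: np.ndarray,
    apply_features: np.ndarray,
    variance_threshold: float = 0.95,
) -> tuple[PcaModel, np.ndarray, np.ndarray]:
    """Fit PCA on the training block only and project both blocks.

    Retains the smallest leading component count whose cumulative
    explained-variance fraction reaches ``variance_threshold``; the apply
    block is centered with the training means and projected with the
    training loadings, so no information leaks from it into the model.
    """
    if not (0.0 < variance_threshold <= 1.0):
        raise ValidationError("variance threshold must lie in (0, 1]")
    train = np.asarray(train_features, dtype=float)
    apply = np.asarray(apply_features, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValidationError("training block needs at least 2 rows")
    if apply.shape[1] != train.shape[1]:
        raise ValidationError("apply block feature count differs from training")
    pca = PCA(svd_solver="full")
    pca.fit(train)
    ratios = pca.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    k = int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    model = PcaModel(
        component_loadings=pca.components_[:k].T.copy(),
        component_variances=ratios[:k].copy(),
        feature_means=pca.mean_.copy(),
        n_components=k,
        variance_threshold=variance_threshold,
    )
    return model, model.transform(train), model.transform(apply)
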