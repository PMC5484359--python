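"""Synthetic imbalanced MRS cohorts: metabolite profiles and matching spectra.

The generator emulates the study cohort the downstream analysis assumes: a
three-class pediatric brain-tumor population (pilocytic astrocytoma n=42,
medulloblastoma n=38, ependymoma n=10) whose per-class metabolite
concentration means and standard deviations are shipped as an editable
parameter file (``data/class_profiles.yaml``).  Within a class each metabolite is
drawn from an independent truncated normal (clipped at zero); a matching
"complete spectrum" is synthesized per sample from a peak library of
Lorentzian lineshapes on the 0.5-4.0 ppm window.

Real MRS metabolites covary and carry multiplet structure; the generator
deliberately ignores both (no covariance is published for the cohort and
the spectral lineshape parameters are labelled stand-ins).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import Cohort, SpectrumSet
from .errors import ConfigurationError, ValidationError

PPM_LO = 0.5
PPM_HI = 4.0

_CLASS_ID_PREFIXES = {
    "pilocytic_astrocytoma": "PA",
    "medulloblastoma": "MB",
    "ependymoma": "EP",
}


@dataclass
class ClassSpec:
    """Sampling specification for one tumor class.

    ``metabolite_means``/``metabolite_sds`` map metabolite name to the
    class mean / standard deviation in mM-like arbitrary units.
    """

    name: str
    n: int
    metabolite_means: dict[str, float]
    metabolite_sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError(f"class {self.name!r}: n must be >= 0")
        extra = set(self.metabolite_sds) - set(self.metabolite_means)
        if extra:
            raise ValidationError(
                f"class {self.name!r}: SDs given for unknown metabolites {sorted(extra)}"
            )
        for met, sd in self.metabolite_sds.items():
            if sd < 0:
                raise ValidationError(f"class {self.name!r}: SD of {met!r} is negative")

    @property
    def metabolites(self) -> list[str]:
        return list(self.metabolite_means)


@dataclass
class PeakEntry:
    metabolite: str
    ppm: float
    fwhm: float
    amplitude: float = 1.0


@dataclass
class PeakLibrary:
    """Lorentzian lineshape parameters used to synthesize spectra.

    A synthetic stand-in: single unit-area Lorentzians at canonical
    chemical shifts, not fitted in-vivo lineshapes.
    """

    entries: list[PeakEntry]
    baseline_level: float = 0.0
    noise_sd: float = 0.0
    axis_points: int = 457

    def __post_init__(self) -> None:
        for e in self.entries:
            if not (PPM_LO <= e.ppm <= PPM_HI):
                raise ValidationError(
                    f"peak {e.metabolite!r} at {e.ppm} ppm lies outside [{PPM_LO}, {PPM_HI}]"
                )
            if e.fwhm <= 0:
                raise ValidationError(f"peak {e.metabolite!r}: linewidth must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.axis_points < 2:
            raise ValidationError("axis_points must be >= 2")

    @property
    def metabolites(self) -> set[str]:
        return {e.metabolite for e in self.entries}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PeakLibrary":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            entries=[PeakEntry(**p) for p in raw["peaks"]],
            baseline_level=float(raw.get("baseline_level", 0.0)),
            noise_sd=float(raw.get("noise_sd", 0.0)),
            axis_points=int(raw.get("axis_points", 457)),
        )


def _packaged(name: str) -> Path:
    return Path(str(importlib.resources.files("imbalmrs").joinpath("data", name)))


def load_peak_library(path: str | Path | None = None) -> PeakLibrary:
    """Load a peak library; defaults to the packaged stand-in library."""
    return PeakLibrary.from_yaml(path if path is not None else _packaged("peak_library.yaml"))


def load_class_specs(
    path: str | Path | None = None,
    sizes: Mapping[str, int] | None = None,
) -> list[ClassSpec]:
    """Load per-class generator parameters (defaults to the shipped table).

    ``sizes`` overrides the per-class sample counts, e.g. for large-n
    convergence checks.
    """
    raw = yaml.safe_load(Path(path if path is not None else _packaged("class_profiles.yaml")).read_text())
    specs = []
    for name, block in raw["classes"].items():
        mets = block["metabolites"]
        n = int(sizes[name]) if sizes is not None and name in sizes else int(block["n"])
        specs.append(
            ClassSpec(
                name=name,
                n=n,
                metabolite_means={m: float(v["mean"]) for m, v in mets.items()},
                metabolite_sds={m: float(v["sd"]) for m, v in mets.items()},
            )
        )
    return specs


def generate_cohort(specs: Sequence[ClassSpec], seed: int) -> Cohort:
    """Draw an imbalanced cohort of metabolite profiles.

    Per class, each metabolite is drawn independently from
    ``Normal(mean, sd)`` and clipped at zero (concentrations are
    nonnegative; clipping rather than rejection keeps the draw count, and
    hence reproducibility, independent of the parameters).  Deterministic
    given ``seed``.
    """
    if not specs:
        raise ConfigurationError("at least one class spec is required")
    names = specs[0].metabolites
    for spec in specs[1:]:
        if set(spec.metabolites) != set(names):
            raise ConfigurationError(
                "all class specs must share one metabolite name set; "
                f"{spec.name!r} differs from {specs[0].name!r}"
            )
    rng = np.random.default_rng(seed)
    blocks, labels, ids = [], [], []
    for spec in specs:
        means = np.array([spec.metabolite_means[m] for m in names])
        sds = np.array([spec.metabolite_sds.get(m, 0.0) for m in names])
        draws = rng.normal(loc=means, scale=sds, size=(spec.n, len(names)))
        blocks.append(np.clip(draws, 0.0, None))
        labels.extend([spec.name] * spec.n)
        prefix = _CLASS_ID_PREFIXES.get(spec.name, spec.name[:2].upper())
        ids.extend(f"{prefix}-{i + 1:03d}" for i in range(spec.n))
    return Cohort(
        features=np.vstack(blocks) if blocks else np.empty((0, len(names))),
        feature_names=list(names),
        labels=np.array(labels, dtype=object),
        sample_ids=np.array(ids, dtype=object),
    )


def _lorentzian(axis: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzian lineshape; peak height = 2 / (pi * fwhm)."""
    hwhm = fwhm / 2.0
    return (hwhm / np.pi) / ((axis - center) ** 2 + hwhm**2)


def make_axis(
    axis_step_ppm: float | None = None,
    n_points: int | None = None,
    lo_ppm: float = PPM_LO,
    hi_ppm: float = PPM_HI,
) -> np.ndarray:
    """Chemical-shift axis covering exactly [lo, hi], endpoints included."""
    if lo_ppm >= hi_ppm:
        raise ValidationError("lo_ppm must be < hi_ppm")
    if axis_step_ppm is not None:
        if axis_step_ppm <= 0:
            raise ValidationError("axis step must be > 0")
        n_points = int(round((hi_ppm - lo_ppm) / axis_step_ppm)) + 1
    if n_points is None or n_points < 2:
        raise ValidationError("axis needs at least 2 points")
    return np.linspace(lo_ppm, hi_ppm, n_points)


def synthesize_spectra(
    cohort: Cohort,
    library: PeakLibrary,
    axis_step_ppm: float | None = None,
    seed: int = 0,
    skip_missing: bool = False,
) -> SpectrumSet:
    """Synthesize one spectrum per cohort sample.

    Each spectrum is ``baseline + sum_m conc_m * amplitude_m *
    Lorentzian(ppm_m, fwhm_m) + N(0, noise_sd)`` on a shared axis covering
    exactly [0.5, 4.0] ppm.  The synthesis is linear in the concentrations.
    Metabolites absent from the library raise unless ``skip_missing``.
    """
    missing = set(cohort.feature_names) - library.metabolites
    if missing and not skip_missing:
        raise ConfigurationError(
            f"no peak entry for metabolites {sorted(missing)}; "
            "pass skip_missing=True to leave them out of the spectra"
        )
    axis = make_axis(axis_step_ppm, n_points=None if axis_step_ppm else library.axis_points)
    shapes = np.zeros((cohort.n_features, axis.size))
    for entry in library.entries:
        if entry.metabolite in cohort.feature_names:
            j = cohort.feature_names.index(entry.metabolite)
            shapes[j] += entry.amplitude * _lorentzian(axis, entry.ppm, entry.fwhm)
    rng = np.random.default_rng(seed)
    intensities = library.baseline_level + cohort.features @ shapes
    if library.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, library.noise_sd, size=intensities.shape)
    return SpectrumSet(
        ppm=axis,
        intensities=intensities,
        sample_ids=cohort.sample_ids.copy(),
        labels=cohort.labels.copy(),
    )
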