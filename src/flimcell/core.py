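"""Core data containers shared across the pipeline.

A FLIM field of view is a photon-count histogram cube: for every pixel a
TCSPC histogram of photon arrival times relative to the laser sync pulse.
The containers here carry that cube (:class:`FLIMStack`), the time-axis
bookkeeping (:class:`AcquisitionConfig`), ground-truth or segmented ROIs
(:class:`LabelMask`), per-ROI aggregated kinetics (:class:`DecayCurve`) and
the exponential-mixture ground truth used by the phantom generator
(:class:`DecaySpec`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidConfigError, ShapeMismatchError

__all__ = [
    "AcquisitionConfig",
    "DecaySpec",
    "FLIMStack",
    "LabelMask",
    "DecayCurve",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """TCSPC acquisition geometry and photon budget.

    Parameters
    ----------
    repetition_period
        Laser sync period in ns. An 80 MHz Ti:Sa oscillator gives 12.5 ns.
    n_bins
        Number of TCSPC time bins spanning one period.
    irf_fwhm
        Full width at half maximum of the (Gaussian) instrument response, ns.
        Detector-limited; the femtosecond pulse itself is negligible.
    irf_offset_fraction
        Position of the IRF centre as a fraction of the period (the usual
        pre-trigger dead zone before the rising edge).
    photon_rate
        Detected photon rate, photons/s.
    collection_time
        Frame integration time, s. ``photon_rate * collection_time`` is the
        photon budget of one field of view.
    dark_count_fraction
        Uniform-in-time background counts as a fraction of the photon budget.
    seed
        Seed for every stochastic step deriving from this configuration.
    """

    repetition_period: float = 12.5
    n_bins: int = 256
    irf_fwhm: float = 0.2
    irf_offset_fraction: float = 0.10
    photon_rate: float = 1.5e5
    collection_time: float = 60.0
    dark_count_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetition_period <= 0:
            raise InvalidConfigError("repetition_period must be positive")
        if self.n_bins < 16:
            raise InvalidConfigError("n_bins must be at least 16")
        if self.irf_fwhm <= 0:
            raise InvalidConfigError("irf_fwhm must be positive")
        if self.irf_fwhm >= self.repetition_period / 4:
            raise InvalidConfigError(
                "irf_fwhm must be below a quarter of the repetition period"
            )
        if not 0 <= self.dark_count_fraction <= 0.05:
            raise InvalidConfigError("dark_count_fraction must lie in [0, 0.05]")
        if self.photon_rate < 0 or self.collection_time < 0:
            raise InvalidConfigError("photon budget terms must be nonnegative")

    @property
    def bin_width(self) -> float:
        """Width of one TCSPC bin in ns."""
        return self.repetition_period / self.n_bins

    @property
    def time_edges(self) -> np.ndarray:
        """Bin edges ``t_0 .. t_n`` in ns; bins are half-open ``[t, t+dt)``."""
        return np.linspace(0.0, self.repetition_period, self.n_bins + 1)

    @property
    def time_centers(self) -> np.ndarray:
        edges = self.time_edges
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def photon_budget(self) -> float:
        """Expected signal photons in one field of view."""
        return self.photon_rate * self.collection_time

    def to_dict(self) -> dict:
        return {
            "repetition_period": self.repetition_period,
            "n_bins": self.n_bins,
            "irf_fwhm": self.irf_fwhm,
            "irf_offset_fraction": self.irf_offset_fraction,
            "photon_rate": self.photon_rate,
            "collection_time": self.collection_time,
            "dark_count_fraction": self.dark_count_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class DecaySpec:
    """Exponential-mixture ground truth for one fluorophore population.

    ``amplitudes`` are the relative amplitudes of the decay components (the
    a1/a2 of the biexponential model, as fractions summing to 1, not photon
    shares). One component models a DOX-like fluorophore, two components the
    free/bound NAD(P)H mixture.
    """

    lifetimes: tuple
    amplitudes: tuple
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "lifetimes", tuple(float(t) for t in self.lifetimes))
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        k = len(self.lifetimes)
        if not 1 <= k <= 2:
            raise InvalidConfigError("1 or 2 decay components supported")
        if len(self.amplitudes) != k:
            raise InvalidConfigError("lifetimes and amplitudes must pair up")
        if any(t <= 0 for t in self.lifetimes):
            raise InvalidConfigError("lifetimes must be strictly positive")
        if list(self.lifetimes) != sorted(set(self.lifetimes)):
            raise InvalidConfigError("lifetimes must be strictly increasing")
        if any(a < 0 for a in self.amplitudes):
            raise InvalidConfigError("amplitudes must be nonnegative")
        if abs(sum(self.amplitudes) - 1.0) > 1e-9:
            raise InvalidConfigError("amplitudes must sum to 1 within 1e-9")

    @property
    def n_components(self) -> int:
        return len(self.lifetimes)

    def to_dict(self) -> dict:
        return {
            "lifetimes": list(self.lifetimes),
            "amplitudes": list(self.amplitudes),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DecaySpec":
        return cls(
            lifetimes=tuple(d["lifetimes"]),
            amplitudes=tuple(d["amplitudes"]),
            label=d.get("label", ""),
        )


@dataclass
class FLIMStack:
    """Photon-count histogram cube of one channel: (y, x, time-bin)."""

    data: np.ndarray
    config: AcquisitionConfig
    channel: str = "main"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeMismatchError("FLIMStack data must be 3-D (y, x, t)")
        if self.data.shape[2] != self.config.n_bins:
            raise ShapeMismatchError(
                f"stack has {self.data.shape[2]} time bins, "
                f"config says {self.config.n_bins}"
            )

    @property
    def frame_shape(self) -> tuple:
        return self.data.shape[:2]

    def intensity(self) -> np.ndarray:
        """Photon-sum (time-integrated) image."""
        return self.data.sum(axis=2)


@dataclass
class LabelMask:
    """Integer ROI image; 0 is background, labels are unique per object."""

    labels: np.ndarray
    kind: str = "cell"  # cell | nucleus | cytoplasm
    provenance: str = "external"  # external | classical-fallback | ground-truth
    border_labels: tuple = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ShapeMismatchError("LabelMask must be 2-D")
        if self.labels.min(initial=0) < 0:
            raise InvalidConfigError("labels must be nonnegative")
        if self.kind not in ("cell", "nucleus", "cytoplasm"):
            raise InvalidConfigError(f"unknown mask kind {self.kind!r}")

    @property
    def object_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs > 0]

    @property
    def n_objects(self) -> int:
        return int(self.object_labels.size)

    def object_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class DecayCurve:
    """Per-ROI aggregated TCSPC histogram on the shared time axis."""

    counts: np.ndarray
    config: AcquisitionConfig
    roi_id: tuple = ("", "")  # (cell label, compartment)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size != self.config.n_bins:
            raise ShapeMismatchError("counts must be 1-D of length n_bins")
        if np.any(self.counts < 0):
            raise InvalidConfigError("counts must be nonnegative")

    @property
    def axis(self) -> np.ndarray:
        return self.config.time_centers

    @property
    def total_photons(self) -> float:
        return float(self.counts.sum())


def require_same_grid(shape_a: Sequence[int], shape_b: Sequence[int]) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ShapeMismatchError(f"pixel grids differ: {tuple(shape_a)} vs {tuple(shape_b)}")
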