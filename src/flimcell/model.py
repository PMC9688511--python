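"""Shared forward model for TCSPC decay curves.

The measured histogram is modelled as a discrete convolution of a
discretized instrument response (IRF) with per-bin integrals of an
exponential mixture, optionally wrapped around the laser period to account
for incomplete decay. The phantom generator and the fitters both call this
module, so a fit of simulated data is exact up to photon noise.

Conventions
-----------
* Time axis: ``n_bins`` half-open bins over one repetition period, bin 0
  starting at the laser sync.
* The IRF is a nonnegative vector summing to 1.
* ``decay_shape`` returns a probability vector (sums to 1); multiplying by
  the photon budget gives expected counts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr

from .core import AcquisitionConfig, DecaySpec
from .errors import InvalidConfigError

__all__ = ["make_irf", "exp_bin_integrals", "convolve_irf", "decay_shape", "expected_counts"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def make_irf(
    cfg: AcquisitionConfig,
    fwhm: Optional[float] = None,
    offset: Optional[float] = None,
) -> np.ndarray:
    """Discretized Gaussian instrument response on the TCSPC time axis.

    Parameters
    ----------
    cfg
        Acquisition geometry; supplies the time axis and default FWHM.
    fwhm
        Override of ``cfg.irf_fwhm`` in ns. Must be positive; in the
        ``fwhm -> 0`` limit the vector tends to a single-bin unit impulse.
    offset
        Centre of the IRF in ns. Defaults to
        ``cfg.irf_offset_fraction * repetition_period``.

    Returns
    -------
    numpy.ndarray
        Length ``n_bins`` nonnegative vector summing to 1, unimodal, with
        each entry the Gaussian mass falling inside that bin.
    """
    if fwhm is None:
        fwhm = cfg.irf_fwhm
    if fwhm <= 0:
        raise InvalidConfigError("IRF FWHM must be positive")
    if offset is None:
        offset = cfg.irf_offset_fraction * cfg.repetition_period
    sigma = fwhm * _FWHM_TO_SIGMA
    edges = cfg.time_edges
    with np.errstate(over="ignore", invalid="ignore"):
        z = (edges - offset) / sigma
    cdf = ndtr(z)
    irf = np.diff(cdf)
    total = irf.sum()
    if total <= 0:
        raise InvalidConfigError("IRF mass falls entirely outside the time window")
    return irf / total


def exp_bin_integrals(
    tau: float,
    cfg: AcquisitionConfig,
    wrap: bool = False,
) -> np.ndarray:
    """Per-bin integrals of a unit-amplitude exponential ``exp(-t/tau)``.

    Bin ``k`` holds ``tau * (exp(-t_k/tau) - exp(-t_{k+1}/tau))``. With
    ``wrap=True`` the geometric pile-up of previous excitation periods is
    included (factor ``1/(1 - exp(-T/tau))``), modelling incomplete decay.
    """
    if tau <= 0:
        raise InvalidConfigError("lifetime must be positive")
    edges = cfg.time_edges
    e = np.exp(-edges / tau)
    g = tau * (e[:-1] - e[1:])
    if wrap:
        g = g / (1.0 - np.exp(-cfg.repetition_period / tau))
    return g


def convolve_irf(irf: np.ndarray, decay: np.ndarray, wrap: bool = False) -> np.ndarray:
    """Discrete (linear or circular) convolution truncated to the window."""
    n = decay.size
    full = np.convolve(irf, decay)
    out = full[:n].copy()
    if wrap:
        out[: n - 1] += full[n:]
    return out


def decay_shape(
    lifetimes: Sequence[float],
    amplitudes: Sequence[float],
    irf: np.ndarray,
    cfg: AcquisitionConfig,
    wrap: bool = False,
) -> np.ndarray:
    """Normalized expected-count profile of an exponential mixture.

    ``amplitudes`` weight the decay amplitudes (not photon shares): the
    photon share of component ``i`` is proportional to ``a_i * tau_i``.
    The returned vector sums to 1 exactly, so scaling by a photon budget
    conserves photons irrespective of window truncation.
    """
    mix = np.zeros(cfg.n_bins)
    for tau, a in zip(lifetimes, amplitudes):
        if a > 0:
            mix += a * exp_bin_integrals(tau, cfg, wrap=wrap)
    conv = convolve_irf(irf, mix, wrap=wrap)
    total = conv.sum()
    if total <= 0:
        raise InvalidConfigError("decay shape has no mass in the window")
    return conv / total


def expected_counts(
    spec: DecaySpec,
    cfg: AcquisitionConfig,
    photons: float,
    irf: Optional[np.ndarray] = None,
    wrap: bool = False,
) -> np.ndarray:
    """Expected per-bin counts: signal shape times budget plus dark floor.

    Dark counts are uniform in time at ``cfg.dark_count_fraction`` of the
    budget, so the total expectation is ``photons * (1 + dark_fraction)``.
    """
    if photons < 0:
        raise InvalidConfigError("photon budget must be nonnegative")
    if irf is None:
        irf = make_irf(cfg)
    lam = photons * decay_shape(spec.lifetimes, spec.amplitudes, irf, cfg, wrap=wrap)
    if cfg.dark_count_fraction > 0:
        lam = lam + photons * cfg.dark_count_fraction / cfg.n_bins
    return lam
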