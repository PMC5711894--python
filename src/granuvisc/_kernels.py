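"""Shared decay-kernel math: bin-integrated (IRF-convolved) exponentials.

The instantaneous decay of a fluorophore excited at ``t0`` is
``I(t) = A exp(-(t - t0)/tau)``.  A Gaussian instrument response of standard
deviation ``sigma`` turns the photon-arrival density into an exponentially
modified Gaussian (EMG).  TCSPC electronics integrate that density over finite
time bins, so both the simulator and the fitter work with bin integrals, never
point samples.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def emg_cdf(t: np.ndarray, tau: float, t0: float, sigma: float) -> np.ndarray:
    """CDF of the exponential (lifetime ``tau``, start ``t0``) convolved with a
    zero-mean Gaussian of standard deviation ``sigma``.

    Evaluated in log space for the exponential term so the pre-pulse tail does
    not overflow.
    """
    t = np.asarray(t, dtype=float)
    if sigma <= 0.0:
        u = np.maximum(t - t0, 0.0)
        return -np.expm1(-u / tau)
    z = (t - t0) / sigma
    with np.errstate(over="ignore", invalid="ignore"):
        k = sigma * sigma / (2.0 * tau * tau) - (t - t0) / tau
        ex = k + log_ndtr(z - sigma / tau)
    # the subtracted term is bounded by Phi(z) <= 1, so its log exponent is
    # analytically <= 0; clamp rounding noise and inf-inf artifacts
    ex = np.where(np.isnan(ex), -np.inf, np.minimum(ex, 0.0))
    return ndtr(z) - np.exp(ex)


def bin_fractions(edges: np.ndarray, tau: float, t0: float, irf_fwhm: float) -> np.ndarray:
    """Probability mass of the arrival-time distribution in each bin.

    ``edges`` are the ``n+1`` bin edges in ns.  Returns ``n`` nonnegative
    values; their sum is the fraction of all emitted photons that land inside
    the acquisition window (close to 1 when the window spans many lifetimes).
    """
    sigma = irf_fwhm * FWHM_TO_SIGMA
    cdf = emg_cdf(edges, tau, t0, sigma)
    return np.maximum(np.diff(cdf), 0.0)


def unit_amplitude_basis(edges: np.ndarray, tau: float, t0: float, irf_fwhm: float) -> np.ndarray:
    """Expected counts per bin for a component of unit initial intensity.

    "Initial intensity" means counts per bin at the excitation instant, i.e.
    the amplitude A_i of the multi-exponential decay model, so the basis peaks
    near 1.  Total counts of a component are ``A * tau / bin_width`` (up to
    window truncation).
    """
    dt = edges[1] - edges[0]
    return (tau / dt) * bin_fractions(edges, tau, t0, irf_fwhm)
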