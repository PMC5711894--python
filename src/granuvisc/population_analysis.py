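"""Granule viscosity distributions and Gaussian-mixture population analysis.

Per-granule lifetimes are converted to viscosities through the calibration
curve, pooled into a distribution per study group, and modelled as a k-component
univariate Gaussian mixture.  The number of populations is selected by BIC
(k = 1..k_max, ties toward fewer components):

    BIC = -2 log L + (3k - 1) ln n.

Healthy (non-CF) granule sets are expected to select k = 1 near 521 cP; CF
sets select k = 2 with a dominant low-viscosity population near 164 cP and a
minority population near 501 cP.

Standard errors of the fitted component means come from the observed
information approximated by the outer product of per-observation scores
(exact sd/sqrt(n) in the single-component case); a bootstrap fallback is used
and flagged if that matrix is singular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import ks_2samp, norm
from sklearn.mixture import GaussianMixture

from .decay_fit import LifetimeImage
from .granule_segmentation import GranuleRecord
from .rotor_calibration import CalibrationCurve

__all__ = [
    "ViscosityDistribution",
    "MixtureFit",
    "granule_viscosities",
    "fit_mixture",
    "select_k",
    "compare_groups",
]

MIN_DEFINED_PIXELS = 5
_SD_FLOOR_REL = 1e-6


@dataclass
class ViscosityDistribution:
    """Per-granule viscosities (cP) for one group of granules."""

    values: np.ndarray
    group: str = ""
    n_excluded: int = 0  # granules dropped (few defined pixels / out of domain)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def histogram(self) -> Tuple[np.ndarray, np.ndarray]:
        """Freedman-Diaconis histogram for display; fits use raw values."""
        bins = "fd" if np.ptp(self.values) > 0 else 1
        counts, edges = np.histogram(self.values, bins=bins)
        return counts, edges


@dataclass
class MixtureFit:
    """k-component univariate Gaussian mixture, components sorted by mean."""

    k: int
    means: np.ndarray  # cP
    sds: np.ndarray  # cP
    weights: np.ndarray  # sum to 1
    log_likelihood: float
    bic: float
    n: int
    mean_standard_errors: np.ndarray  # cP
    converged: bool = True
    flagged: bool = False
    se_method: str = "observed_information"


def granule_viscosities(
    records: Sequence[GranuleRecord],
    lifetime_img: LifetimeImage,
    curve: CalibrationCurve,
    method: str = "viscosity_of_mean",
    group: str = "",
) -> ViscosityDistribution:
    """Summarise each granule to one viscosity and pool into a distribution.

    ``"viscosity_of_mean"`` (default) averages the granule's defined pixel
    lifetimes and converts once; ``"mean_of_pixels"`` converts every pixel and
    averages the viscosities.  Granules with fewer than 5 defined pixels, and
    granules whose summary falls outside the calibration domain, are excluded
    and counted in ``n_excluded``.  Records are annotated in place.
    """
    if method not in ("viscosity_of_mean", "mean_of_pixels"):
        raise ValueError("method must be 'viscosity_of_mean' or 'mean_of_pixels'")
    lt = lifetime_img.mean_lifetime
    values = []
    n_excluded = 0
    for rec in records:
        pix = lt[rec.coords[:, 0], rec.coords[:, 1]]
        defined = pix[np.isfinite(pix)]
        rec.n_defined_pixels = int(defined.size)
        if defined.size < MIN_DEFINED_PIXELS:
            n_excluded += 1
            continue
        rec.summary_lifetime = float(defined.mean())
        if method == "viscosity_of_mean":
            visc, flag = curve.viscosity(rec.summary_lifetime, return_flag=True)
        else:
            per_pix, flags = curve.viscosity(defined, return_flag=True)
            visc, flag = float(per_pix.mean()), bool(flags.all())
        rec.summary_viscosity = float(visc)
        if flag:
            n_excluded += 1
            continue
        values.append(float(visc))
    if not values:
        raise ValueError("no eligible granules: every record was excluded")
    return ViscosityDistribution(
        values=np.array(values), group=group, n_excluded=n_excluded
    )


# ---------------------------------------------------------------------------
# Gaussian mixture fitting
# ---------------------------------------------------------------------------
def _mixture_loglik(x, means, sds, weights) -> float:
    dens = np.sum(
        weights[None, :] * norm.pdf(x[:, None], means[None, :], sds[None, :]), axis=1
    )
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def _mean_ses_opg(x, means, sds, weights) -> Optional[np.ndarray]:
    """SEs of component means from the outer-product-of-scores information.

    Scores are taken with respect to the full parameter vector (k means,
    k log-sds, k-1 weights); the mean block of the inverted information gives
    the standard errors.
    """
    k = len(means)
    comp = weights[None, :] * norm.pdf(x[:, None], means[None, :], sds[None, :])
    resp = comp / np.maximum(comp.sum(axis=1, keepdims=True), 1e-300)
    z = (x[:, None] - means[None, :]) / sds[None, :]
    s_mean = resp * z / sds[None, :]
    s_lsd = resp * (z**2 - 1.0)
    s_w = resp[:, :-1] / weights[None, :-1] - resp[:, [-1]] / weights[-1]
    S = np.concatenate([s_mean, s_lsd, s_w], axis=1)
    info = S.T @ S
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)[:k]
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        return None
    return np.sqrt(var)


def _mean_ses_bootstrap(x, k, seed, n_boot=200) -> np.ndarray:
    rng = np.random.default_rng(seed)
    means_b = []
    for _ in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        gm = GaussianMixture(n_components=k, n_init=3, random_state=seed).fit(
            xb[:, None]
        )
        order = np.argsort(gm.means_.ravel())
        means_b.append(gm.means_.ravel()[order])
    return np.std(np.array(means_b), axis=0, ddof=1)


def fit_mixture(
    dist: ViscosityDistribution, k: int, seed: int = 0
) -> MixtureFit:
    """Fit a k-component Gaussian mixture by EM (10 seeded restarts).

    ``k = 1`` is the closed-form maximum likelihood fit (sample mean, MLE sd,
    SE = sd/sqrt(n)), exactly.  Degenerate inputs (vanishing spread) return a
    floored-sd single component with ``flagged=True``.
    """
    x_raw = np.asarray(dist.values, dtype=float)
    # EM sees sorted values so fits are invariant to input permutation;
    # k=1 closed-form statistics use the original order (bitwise exact)
    x = np.sort(x_raw)
    n = x.size
    if n < 10 * k:
        raise ValueError(f"need n >= 10*k observations for k={k}, got {n}")
    sd_floor = _SD_FLOOR_REL * max(1.0, abs(float(np.mean(x))))
    degenerate = float(np.std(x)) <= sd_floor

    if k == 1 or degenerate:
        mu, sd = float(np.mean(x_raw)), float(np.std(x_raw))
        flagged = False
        if sd <= sd_floor:
            sd, flagged = sd_floor, True
        ll = _mixture_loglik(x, np.array([mu]), np.array([sd]), np.array([1.0]))
        return MixtureFit(
            k=1,
            means=np.array([mu]),
            sds=np.array([sd]),
            weights=np.array([1.0]),
            log_likelihood=ll,
            bic=-2.0 * ll + 2.0 * np.log(n),
            n=n,
            mean_standard_errors=np.array([sd / np.sqrt(n)]),
            converged=True,
            flagged=flagged,
        )

    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=10,
        random_state=seed,
        reg_covar=1e-6,
    ).fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    weights = weights / weights.sum()
    ll = _mixture_loglik(x, means, sds, weights)
    bic = -2.0 * ll + (3.0 * k - 1.0) * np.log(n)
    ses = _mean_ses_opg(x, means, sds, weights)
    se_method = "observed_information"
    flagged = False
    if ses is None:
        ses = _mean_ses_bootstrap(x, k, seed)
        se_method, flagged = "bootstrap", True
    return MixtureFit(
        k=k,
        means=means,
        sds=sds,
        weights=weights,
        log_likelihood=ll,
        bic=bic,
        n=n,
        mean_standard_errors=ses,
        converged=bool(gm.converged_),
        flagged=flagged,
        se_method=se_method,
    )


def select_k(
    dist: ViscosityDistribution, k_max: int = 3, seed: int = 0
) -> MixtureFit:
    """Minimum-BIC mixture over k = 1..k_max; BIC ties break toward smaller k."""
    if not 1 <= k_max <= 3:
        raise ValueError("k_max must be between 1 and 3")
    best = None
    for k in range(1, k_max + 1):
        if dist.n < 10 * k:
            break
        fit = fit_mixture(dist, k, seed=seed)
        if best is None or fit.bic < best.bic:
            best = fit
    return best


def compare_groups(
    a: ViscosityDistribution,
    b: ViscosityDistribution,
    k_max: int = 3,
    seed: int = 0,
) -> dict:
    """Descriptive comparison of two viscosity distributions.

    Selects k per group, matches components of the smaller-k fit to the
    nearest means of the other, and reports mean differences with combined
    standard errors plus the two-sample Kolmogorov-Smirnov distance.  No
    p-values are claimed.
    """
    if a.n == 0 or b.n == 0:
        raise ValueError("both distributions must be non-empty")
    fit_a = select_k(a, k_max=k_max, seed=seed)
    fit_b = select_k(b, k_max=k_max, seed=seed)
    if fit_a.k <= fit_b.k:
        small, large, swapped = fit_a, fit_b, False
    else:
        small, large, swapped = fit_b, fit_a, True
    matches = []
    for i, m in enumerate(small.means):
        j = int(np.argmin(np.abs(large.means - m)))
        diff = float(m - large.means[j]) * (1.0 if not swapped else -1.0)
        comb_se = float(
            np.hypot(small.mean_standard_errors[i], large.mean_standard_errors[j])
        )
        matches.append(
            {
                "mean_a": float(m if not swapped else large.means[j]),
                "mean_b": float(large.means[j] if not swapped else m),
                "difference": diff,
                "combined_se": comb_se,
            }
        )
    ks = ks_2samp(a.values, b.values)
    return {
        "group_a": a.group,
        "group_b": b.group,
        "fit_a": fit_a,
        "fit_b": fit_b,
        "matched_components": matches,
        "ks_distance": float(ks.statistic),
        "n_a": a.n,
        "n_b": b.n,
    }
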