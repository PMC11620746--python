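"""Clone-size spectrum, discrete power-law MLE, clonality statistics."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .io import RepertoireSample

logger = logging.getLogger(__name__)

__all__ = [
    "PowerLawFit",
    "ClonalityStats",
    "clone_size_spectrum",
    "power_law_loglik",
    "fit_power_law",
    "estimate_xmin",
    "clonality_stats",
]

_ALPHA_LO = 1.01
_ALPHA_HI = 30.0


@dataclass(frozen=True)
class PowerLawFit:
    """MLE fit of the discrete power law f(k) = C k^-alpha."""

    alpha: float
    xmin: int
    n_tail: int
    log_likelihood: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class ClonalityStats:
    """Top-percentile clonal expansion summary."""

    top_share: float
    threshold: int
    mean_top_abundance: float
    n_top: int


def clone_size_spectrum(sample: RepertoireSample) -> list[tuple[int, float]]:
    """(clone size k, proportion of total molecules in clones of size k)."""
    if not sample.clonotypes:
        raise ValueError("empty sample")
    abundances = sample.abundances()
    total = abundances.sum()
    ks, counts = np.unique(abundances, return_counts=True)
    return [(int(k), float(k * c / total)) for k, c in zip(ks, counts)]


def power_law_loglik(alpha: float, abundances: np.ndarray, xmin: int = 1) -> float:
    """Log likelihood of the zeta distribution truncated at xmin."""
    tail = abundances[abundances >= xmin]
    return float(
        -alpha * np.log(tail).sum() - len(tail) * math.log(special.zeta(alpha, xmin))
    )


def fit_power_law(abundances, xmin: int = 1) -> PowerLawFit:
    """Maximum-likelihood discrete power-law fit of a clone-size vector.

    Maximises the Hurwitz-zeta-normalised log likelihood over
    alpha in (1.01, 30] by bounded scalar optimisation.  The fit is
    reported non-converged when the data carry no tail information (all
    observations equal xmin) or the optimiser runs into a bound.
    """
    abundances = np.asarray(abundances, dtype=np.int64)
    tail = abundances[abundances >= xmin]
    if len(tail) < 10:
        raise ValueError("need at least 10 observations >= xmin")
    if (tail == xmin).all():
        return PowerLawFit(
            alpha=math.inf,
            xmin=xmin,
            n_tail=len(tail),
            log_likelihood=math.nan,
            converged=False,
            message="all observations equal xmin; likelihood unbounded",
        )
    res = optimize.minimize_scalar(
        lambda a: -power_law_loglik(a, tail, xmin),
        bounds=(_ALPHA_LO, _ALPHA_HI),
        method="bounded",
        options={"xatol": 1e-8},
    )
    alpha = float(res.x)
    at_bound = alpha > _ALPHA_HI - 1e-3 or alpha < _ALPHA_LO + 1e-3
    return PowerLawFit(
        alpha=alpha,
        xmin=xmin,
        n_tail=len(tail),
        log_likelihood=float(-res.fun),
        converged=bool(res.success) and not at_bound,
        message="optimiser hit parameter bound" if at_bound else "",
    )


def estimate_xmin(abundances, xmin_max: int | None = None) -> PowerLawFit:
    """Clauset-style xmin scan: minimise the KS distance of tail fits.

    Off by default in all analyses (xmin is fixed at 1 unless this mode
    is requested explicitly).
    """
    abundances = np.asarray(abundances, dtype=np.int64)
    candidates = np.unique(abundances)
    if xmin_max is not None:
        candidates = candidates[candidates <= xmin_max]
    best: tuple[float, PowerLawFit] | None = None
    for xmin in candidates:
        tail = abundances[abundances >= xmin]
        if len(tail) < 10 or (tail == xmin).all():
            continue
        fit = fit_power_law(abundances, int(xmin))
        if not fit.converged:
            continue
        ks, counts = np.unique(tail, return_counts=True)
        emp_cdf = np.cumsum(counts) / len(tail)
        z = special.zeta(fit.alpha, xmin)
        pmf = ks.astype(float) ** -fit.alpha / z
        # model CDF at the observed support points
        mod_cdf = np.cumsum(pmf)
        # account for support gaps: add mass of skipped integers
        full_k = np.arange(xmin, ks[-1] + 1)
        full_cdf = np.cumsum(full_k.astype(float) ** -fit.alpha / z)
        mod_cdf = full_cdf[ks - xmin]
        dist = float(np.abs(emp_cdf - mod_cdf).max())
        if best is None or dist < best[0]:
            best = (dist, fit)
    if best is None:
        raise ValueError("no feasible xmin candidate")
    return best[1]


def clonality_stats(
    sample: RepertoireSample, top_fraction: float = 0.01
) -> ClonalityStats:
    """Share of the repertoire held by the top-percentile expanded clones.

    The threshold is the nearest-rank (1 - top_fraction) percentile of
    the unique-clonotype abundance vector; the top set is clonotypes
    strictly above it.  If no clonotype exceeds the threshold (all
    abundances tied), the ceil(top_fraction * n) largest clonotypes are
    used instead.
    """
    n = len(sample.clonotypes)
    if n * top_fraction < 1:
        raise ValueError(
            f"need at least {math.ceil(1 / top_fraction)} unique clonotypes"
        )
    abundances = np.sort(sample.abundances())
    # nearest-rank percentile: value at rank ceil(q * n), 1-based
    rank = math.ceil((1.0 - top_fraction) * n)
    threshold = int(abundances[rank - 1])
    top = abundances[abundances > threshold]
    if len(top) == 0:
        k = math.ceil(top_fraction * n)
        top = abundances[-k:]
        logger.info(
            "no abundance strictly above the percentile threshold; "
            "falling back to the %d largest clonotypes", k
        )
    total = abundances.sum()
    return ClonalityStats(
        top_share=float(top.sum() / total),
        threshold=threshold,
        mean_top_abundance=float(top.mean()),
        n_top=len(top),
    )
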