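"""Classic and asymptotic McDonald-Kreitman estimation of alpha.

alpha is the proportion of non-synonymous fixed differences driven by
positive selection. The classic estimator,

    alpha = 1 - (DS * pN) / (DN * pS),

is biased downward by segregating slightly deleterious non-synonymous
variants. The asymptotic variant computes alpha separately in derived-allele
frequency bins and extrapolates a fitted curve, y = a + b*ln(x+c) or
y = a + b*exp(-x/c), to x = 1 (fixation). The fit is restricted to bins
wholly below DAF 0.5, where mispolarization distortion of the unfolded SFS
is negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .divergence_polymorphism import MkCounts, SfsTable, VariantSite, build_sfs
from .errors import EstimationError, ParameterError, UndefinedAlphaError

logger = logging.getLogger(__name__)

LOGARITHMIC = "logarithmic"
EXPONENTIAL = "exponential"


@dataclass
class BinnedAlpha:
    """Per-frequency-bin alpha estimates with the bin bookkeeping."""

    midpoints: np.ndarray
    upper_edges: np.ndarray
    alphas: np.ndarray
    pN: np.ndarray
    pS: np.ndarray
    n_dropped: int = 0


@dataclass
class AsymptoticFit:
    form: str
    fit_a: float
    fit_b: float
    fit_c: float
    x_bins: np.ndarray
    alpha_per_bin: np.ndarray
    alpha_hat: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    converged: bool = True


def classic_mk(counts: MkCounts) -> float:
    """Classic MK alpha = 1 - (DS*pN)/(DN*pS). May be negative."""
    if counts.DN == 0 or counts.pS == 0:
        raise UndefinedAlphaError(
            f"alpha undefined for DN={counts.DN}, pS={counts.pS} "
            f"(DS={counts.DS}, pN={counts.pN})"
        )
    return 1.0 - (counts.DS * counts.pN) / (counts.DN * counts.pS)


def binned_alpha(
    sfs: SfsTable,
    DN: int,
    DS: int,
    min_total: int = 5,
) -> BinnedAlpha:
    """Classic-MK alpha computed bin by bin from an SFS.

    A bin is usable when it has pS >= 1 and at least ``min_total`` variants;
    degenerate bins are dropped and logged.
    """
    if DN <= 0:
        raise ParameterError("DN must be > 0 for binned alpha")
    mids, uppers, alphas, pns, pss = [], [], [], [], []
    dropped = 0
    edges = sfs.bin_edges
    for i, mid in enumerate(sfs.midpoints):
        pn = sfs.counts_nonsyn[i]
        ps = sfs.counts_syn[i]
        if ps < 1 or (pn + ps) < min_total:
            dropped += 1
            logger.debug("bin %.3f dropped (pN=%g pS=%g)", mid, pn, ps)
            continue
        mids.append(mid)
        uppers.append(edges[i + 1])
        alphas.append(1.0 - (DS * pn) / (DN * ps))
        pns.append(pn)
        pss.append(ps)
    if not mids:
        raise EstimationError("all frequency bins are degenerate")
    return BinnedAlpha(
        midpoints=np.array(mids),
        upper_edges=np.array(uppers),
        alphas=np.array(alphas),
        pN=np.array(pns),
        pS=np.array(pss),
        n_dropped=dropped,
    )


def _curve(form: str, x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    if form == LOGARITHMIC:
        return a + b * np.log(x + c)
    return a + b * np.exp(-x / c)


def _profile_ls(form: str, x: np.ndarray, y: np.ndarray, w: np.ndarray, c: float):
    """Linear least squares for (a, b) at fixed curve parameter c."""
    t = np.log(x + c) if form == LOGARITHMIC else np.exp(-x / c)
    A = np.column_stack([np.ones_like(x), t]) * np.sqrt(w)[:, None]
    coef, *_ = np.linalg.lstsq(A, y * np.sqrt(w), rcond=None)
    resid = y - (coef[0] + coef[1] * t)
    return coef[0], coef[1], float(np.sum(w * resid**2))


def fit_asymptotic(
    binned: BinnedAlpha,
    form: str = EXPONENTIAL,
    max_x: float = 0.5,
    weights: str = "none",
) -> AsymptoticFit:
    """Fit the alpha(x) curve on low-frequency bins and extrapolate to x=1.

    Only bins whose upper edge is <= ``max_x`` enter the fit (strict reading
    of "frequencies lower than 0.5"). The curve parameter c is profiled by a
    bounded 1-D search with (a, b) solved linearly at each c; the exponential
    form falls back to the logarithmic fit when it fails to converge, and if
    both fail the last usable bin's alpha is reported with converged=False.

    ``weights``: "none" (default, unweighted) or "counts" (inverse-variance
    proxy weights pN*pS/(pN+pS) from per-bin counts).
    """
    if form not in (LOGARITHMIC, EXPONENTIAL):
        raise ParameterError(f"unknown fit form {form!r}")
    keep = binned.upper_edges <= max_x + 1e-12
    x = binned.midpoints[keep]
    y = binned.alphas[keep]
    if len(x) < 3:
        raise EstimationError(
            f"need >= 3 usable bins below {max_x}, have {len(x)}"
        )
    if weights == "counts":
        pn, ps = binned.pN[keep], binned.pS[keep]
        w = (pn * ps) / np.maximum(pn + ps, 1.0)
        w = np.where(w > 0, w, 1e-6)
    else:
        w = np.ones_like(x)

    def attempt(f: str) -> AsymptoticFit | None:
        lo = 1e-3 if f == LOGARITHMIC else 1e-2
        hi = 5.0 if f == LOGARITHMIC else 10.0
        try:
            res = minimize_scalar(
                lambda c: _profile_ls(f, x, y, w, c)[2],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-8},
            )
        except (ValueError, np.linalg.LinAlgError):
            return None
        if not res.success or not np.isfinite(res.x):
            return None
        c = float(res.x)
        a, b, _ = _profile_ls(f, x, y, w, c)
        if not (np.isfinite(a) and np.isfinite(b)):
            return None
        alpha_hat = float(_curve(f, np.array([1.0]), a, b, c)[0])
        if not np.isfinite(alpha_hat):
            return None
        return AsymptoticFit(
            form=f, fit_a=float(a), fit_b=float(b), fit_c=c,
            x_bins=x.copy(), alpha_per_bin=y.copy(),
            alpha_hat=min(alpha_hat, 1.0), converged=True,
        )

    fit = attempt(form)
    if fit is None and form == EXPONENTIAL:
        logger.warning("exponential fit failed to converge; falling back to logarithmic")
        fit = attempt(LOGARITHMIC)
    if fit is None:
        logger.warning("asymptotic fit failed; reporting last-bin alpha")
        return AsymptoticFit(
            form=form, fit_a=float("nan"), fit_b=float("nan"), fit_c=float("nan"),
            x_bins=x.copy(), alpha_per_bin=y.copy(),
            alpha_hat=float(y[-1]), converged=False,
        )
    return fit


def asymptotic_alpha(
    variants: Sequence[VariantSite],
    DN: int,
    DS: int,
    bin_edges: Sequence[float] | None = None,
    form: str = EXPONENTIAL,
    max_x: float = 0.5,
    min_total: int = 5,
    exclude_singletons_flag: bool = False,
) -> AsymptoticFit:
    """Pipeline convenience: SFS -> binned alpha -> asymptotic fit."""
    sfs = build_sfs(variants, bin_edges, exclude_singletons_flag)
    return fit_asymptotic(binned_alpha(sfs, DN, DS, min_total), form, max_x)


def bootstrap_alpha(
    genes: Sequence,
    estimator: Callable[[Sequence], float],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """Percentile bootstrap over genes.

    ``estimator`` maps a list of per-gene units (whatever the caller pools,
    e.g. (MkCounts, variants) tuples) to a point estimate of alpha. Genes are
    resampled with replacement n_boot times; replicates where the estimator
    fails are discarded, erroring if more than half fail.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    genes = list(genes)
    if not genes:
        raise ParameterError("no genes to bootstrap")
    rng = np.random.default_rng(seed)
    point = estimator(genes)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(genes), size=len(genes))
        try:
            reps.append(estimator([genes[i] for i in idx]))
        except EstimationError:
            continue
    if len(reps) < n_boot / 2:
        raise EstimationError(
            f"estimator failed in {n_boot - len(reps)}/{n_boot} bootstrap replicates"
        )
    lo = (1.0 - ci) / 2.0
    ci_low, ci_high = np.quantile(reps, [lo, 1.0 - lo])
    return float(point), float(ci_low), float(ci_high)
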