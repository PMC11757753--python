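"""Beta-distribution fits and summary statistics for Jacobian elements.

Empirical distributions of Jacobian matrix elements from Hill-model
screening are summarised by location-scale beta fits: the data are mapped
affinely onto the unit interval (the beta's support is bounded while
Jacobian elements are not, so the support is part of the fit) and the shape
parameters (alpha, beta) are estimated by the method of moments, optionally
refined by maximum likelihood with the moment fit as the starting point.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BetaFit",
    "InvalidMomentsError",
    "fit_moments",
    "fit_mle",
    "element_summary",
    "ElementSummary",
]

_SUPPORT_PAD = 1e-6  # fraction of the data range padded on each side


class InvalidMomentsError(ValueError):
    """No beta distribution matches the sample's mean/variance."""


@dataclasses.dataclass(frozen=True)
class BetaFit:
    """Fitted beta shapes with the affine support mapping used.

    Data value x maps to (x - support_lo) / (support_hi - support_lo); all
    mapped data lie strictly inside (0, 1).  ``log_likelihood`` is reported
    on the mapped scale.  ``converged`` is False when the likelihood
    optimisation failed and the moment estimate was returned instead.
    """

    alpha: float
    beta: float
    support_lo: float
    support_hi: float
    log_likelihood: float
    method: str
    n: int
    converged: bool = True

    def mapped(self, sample: np.ndarray) -> np.ndarray:
        return (np.asarray(sample, float) - self.support_lo) / (
            self.support_hi - self.support_lo
        )

    def mean_variance(self) -> tuple[float, float]:
        """Moments (on the mapped scale) implied by the fitted shapes."""
        a, b = self.alpha, self.beta
        m = a / (a + b)
        v = a * b / ((a + b) ** 2 * (a + b + 1.0))
        return m, v

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _map_support(sample: np.ndarray, support: tuple[float, float] | None):
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if support is None:
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise InvalidMomentsError("degenerate sample: zero range")
        pad = _SUPPORT_PAD * (hi - lo)
        lo, hi = lo - pad, hi + pad
    else:
        lo, hi = map(float, support)
        if hi <= lo:
            raise ValueError("support_lo must be < support_hi")
        if x.min() <= lo or x.max() >= hi:
            raise ValueError("all data must lie strictly inside the support")
    return (x - lo) / (hi - lo), lo, hi


def _loglik(a: float, b: float, u: np.ndarray) -> float:
    return float(np.sum(stats.beta.logpdf(u, a, b)))


def fit_moments(
    sample: np.ndarray, support: tuple[float, float] | None = None
) -> BetaFit:
    """Method-of-moments beta fit on the affinely mapped sample.

    With mapped mean m and variance v, the shapes are
    alpha = m (m(1-m)/v - 1) and beta = (1-m)(m(1-m)/v - 1); they
    reproduce (m, v) exactly.  Raises :class:`InvalidMomentsError` when
    v >= m(1-m), where no beta distribution exists.
    """
    u, lo, hi = _map_support(sample, support)
    m = float(u.mean())
    v = float(u.var(ddof=0))
    bound = m * (1.0 - m)
    if v <= 0 or v >= bound:
        raise InvalidMomentsError(
            f"mapped variance {v:.3g} not in (0, m(1-m)={bound:.3g})"
        )
    c = bound / v - 1.0
    a, b = m * c, (1.0 - m) * c
    return BetaFit(
        alpha=a, beta=b, support_lo=lo, support_hi=hi,
        log_likelihood=_loglik(a, b, u), method="moments", n=u.size,
    )


def fit_mle(
    sample: np.ndarray,
    init: BetaFit | None = None,
    support: tuple[float, float] | None = None,
) -> BetaFit:
    """Maximum-likelihood beta fit started from the method-of-moments shapes.

    The support mapping is taken from ``init`` (or computed as in
    :func:`fit_moments`).  If the optimiser fails to improve on the moment
    fit, that fit is returned with ``converged=False``.
    """
    if init is None:
        init = fit_moments(sample, support)
    u = init.mapped(np.asarray(sample, dtype=float).ravel())
    log_u = np.log(u)
    log_1mu = np.log1p(-u)

    def negll(theta):
        a, b = np.exp(theta)
        from scipy.special import betaln

        return -(float((a - 1) * log_u.sum() + (b - 1) * log_1mu.sum())
                 - u.size * betaln(a, b))

    res = optimize.minimize(
        negll, np.log([init.alpha, init.beta]), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if res.success:
        a, b = np.exp(res.x)
        ll = _loglik(a, b, u)
        if np.isfinite(ll) and ll >= init.log_likelihood - 1e-9:
            return BetaFit(
                alpha=float(a), beta=float(b), support_lo=init.support_lo,
                support_hi=init.support_hi, log_likelihood=ll, method="mle",
                n=u.size,
            )
    return dataclasses.replace(init, converged=False)


@dataclasses.dataclass
class ElementSummary:
    """Per-element statistics and off-diagonal-sum shape measures."""

    element_table: pd.DataFrame   # i, j, class, n, mean, variance
    sum_table: pd.DataFrame       # class, n, mean, variance, skewness, excess_kurtosis
    sums: pd.DataFrame            # set_id, state_id, class, offdiag_sum


def element_summary(
    records: pd.DataFrame, nonturing: str = "all_non_turing"
) -> ElementSummary:
    """Summarise screening records by element and by instability class.

    ``records`` must have columns set_id, state_id, i, j, value, klass (as
    produced by the Hill-model screen).  Classes are collapsed to
    ``turing_I`` versus ``non_turing``; with ``nonturing="stable_only"``
    the non-Turing group keeps only systems that are stable without
    diffusion, with ``"all_non_turing"`` it includes every non-Turing-I
    outcome.  Per (i, j) element the mean and variance are reported per
    class; per record set the sum over off-diagonal elements is formed and
    its skewness and excess kurtosis summarise how Gaussian the sum has
    become.
    """
    if nonturing not in ("all_non_turing", "stable_only"):
        raise ValueError("nonturing must be 'all_non_turing' or 'stable_only'")
    rec = records.copy()
    if nonturing == "stable_only":
        rec = rec[rec["klass"].isin(["turing_I", "stable"])]
    rec["group"] = np.where(rec["klass"] == "turing_I", "turing_I", "non_turing")

    el = (
        rec.groupby(["i", "j", "group"])["value"]
        .agg(n="count", mean="mean", variance=lambda s: s.var(ddof=0))
        .reset_index()
    )

    off = rec[rec["i"] != rec["j"]]
    sums = (
        off.groupby(["set_id", "state_id", "group"])["value"]
        .sum()
        .rename("offdiag_sum")
        .reset_index()
    )
    rows = []
    for group, s in sums.groupby("group")["offdiag_sum"]:
        x = s.to_numpy()
        if x.size > 3:
            q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])
            # quantile (Bowley) skewness: robust to the heavy tails that
            # Hill-model Jacobian elements produce at small concentrations
            qskew = (q3 + q1 - 2 * q2) / (q3 - q1) if q3 > q1 else np.nan
        else:
            qskew = np.nan
        rows.append(
            {
                "group": group,
                "n": x.size,
                "mean": x.mean() if x.size else np.nan,
                "variance": x.var(ddof=0) if x.size else np.nan,
                "skewness": stats.skew(x) if x.size > 2 and x.var() > 0 else np.nan,
                "quantile_skewness": qskew,
                "excess_kurtosis": stats.kurtosis(x)
                if x.size > 3 and x.var() > 0 else np.nan,
            }
        )
    return ElementSummary(
        element_table=el, sum_table=pd.DataFrame(rows), sums=sums
    )
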