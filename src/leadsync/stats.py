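"""Default Bayesian t-tests and directional posterior summaries.

The Bayes factor follows the Jeffreys–Zellner–Siow (JZS) setup: a Cauchy
prior with scale ``r`` on the standardized effect size, equivalently an
inverse-gamma(1/2, r^2/2) mixing density on the variance ratio ``g``.  The
marginal likelihood ratio is

    BF10 = ∫_0^∞ (1 + N g)^{-1/2}
           [ (1 + t^2 / ((1 + N g) ν)) / (1 + t^2 / ν) ]^{-(ν+1)/2}
           π(g) dg,

where ``N`` is the effective sample size and ``ν`` the degrees of freedom of
the t statistic.  The integral is evaluated by adaptive quadrature with the
null density factored out for numerical stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = ["BayesFactorResult", "HypothesisSummary", "jzs_bf", "directional_hypothesis"]

DEFAULT_RSCALE = math.sqrt(2) / 2


@dataclass(frozen=True)
class BayesFactorResult:
    """JZS Bayes factor for a t statistic.

    ``bf10`` is evidence for the alternative over the null; ``1/bf10`` is
    the evidence for the null.
    """

    bf10: float
    t: float
    n: int
    n2: int | None
    rscale: float
    kind: str

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass(frozen=True)
class HypothesisSummary:
    """Directional summary of a posterior sample vector.

    ``posterior_probability`` is the fraction of draws on the hypothesized
    side of zero; ``evidence_ratio`` is its odds p/(1-p), capped at the
    number of draws when p = 1 (finite sampling cannot distinguish p = 1
    from p > 1 - 1/n).
    """

    estimate: float
    ci_low: float
    ci_high: float
    posterior_probability: float
    evidence_ratio: float
    direction: str
    credible: bool
    capped: bool = False


def _effective(kind: str, n: int, n2: int | None) -> tuple[float, float]:
    """(effective N, degrees of freedom) for the test kind."""
    if kind in ("one-sample", "paired"):
        return float(n), float(n - 1)
    if kind == "independent":
        if n2 is None:
            raise ValueError("independent test requires n2")
        return n * n2 / (n + n2), float(n + n2 - 2)
    raise ValueError(f"unknown test kind {kind!r}")


def jzs_bf(
    t: float,
    n: int,
    n2: int | None = None,
    rscale: float = DEFAULT_RSCALE,
    kind: str = "one-sample",
) -> BayesFactorResult:
    """JZS Bayes factor BF10 for a one-sample, paired or independent t test.

    Parameters
    ----------
    t : float
        Observed t statistic.
    n, n2 : int
        Sample size(s); ``n2`` only for ``kind="independent"``.
    rscale : float
        Cauchy prior scale on effect size (default sqrt(2)/2, the
        conventional "medium" prior).
    kind : {"one-sample", "paired", "independent"}
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if rscale <= 0:
        raise ValueError("rscale must be positive")
    if kind == "independent" and n2 is None:
        raise ValueError("independent test requires n2")
    if n < 2 or (n2 is not None and n2 < 2):
        raise ValueError("need at least 2 observations per group")
    N, nu = _effective(kind, n, n2)

    t2 = t * t
    null_factor = 1.0 + t2 / nu
    r2 = rscale * rscale

    def integrand(g: float) -> float:
        # ratio of alternative to null likelihood at fixed g, times the
        # inverse-gamma(1/2, r^2/2) prior density
        ong = 1.0 + N * g
        log_lik = -0.5 * math.log(ong) - 0.5 * (nu + 1.0) * (
            math.log1p(t2 / (ong * nu)) - math.log(null_factor)
        )
        log_prior = (
            0.5 * math.log(r2 / 2.0)
            - math.lgamma(0.5)
            - 1.5 * math.log(g)
            - r2 / (2.0 * g)
        )
        return math.exp(log_lik + log_prior)

    bf10, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(bf10) or (bf10 > 0 and err / bf10 > 1e-4):
        raise RuntimeError(
            f"quadrature did not converge (value={bf10:.3g}, abs err={err:.3g})"
        )
    return BayesFactorResult(bf10=bf10, t=t, n=n, n2=n2, rscale=rscale, kind=kind)


def directional_hypothesis(
    draws: np.ndarray, direction: str = ">0", threshold: float = 0.975
) -> HypothesisSummary:
    """Evaluate a one-sided hypothesis about a coefficient from its draws.

    ``posterior_probability`` is the fraction of posterior draws that are
    positive (``direction=">0"``) or negative (``"<0"``); the hypothesis is
    ``credible`` when that probability exceeds ``threshold``.  The default
    threshold 0.975 corresponds to a two-sided alpha of 5% remapped to
    one-sided testing; a priori directional hypotheses use 0.95.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty posterior sample")
    if draws.size < 100:
        raise ValueError("need at least 100 posterior draws")
    if direction not in (">0", "<0"):
        raise ValueError(f"direction must be '>0' or '<0', got {direction!r}")

    p = float(np.mean(draws > 0) if direction == ">0" else np.mean(draws < 0))
    capped = p >= 1.0
    evidence_ratio = float(draws.size) if capped else p / (1.0 - p)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return HypothesisSummary(
        estimate=float(np.mean(draws)),
        ci_low=float(lo),
        ci_high=float(hi),
        posterior_probability=p,
        evidence_ratio=evidence_ratio,
        direction=direction,
        credible=p > threshold,
        capped=capped,
    )
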