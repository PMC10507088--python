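"""Bayesian linear mixed model of trial-level impression scores.

The model regresses the composite impression score (or one named rating) on
the diagnostic status of the target interactant, the two (log, scaled)
leading scores and their interactions, with overall motion of both
interactants and video source as nuisance terms:

    score ~ diagnosis * green_leading * white_leading
            + motion_green + motion_white + source
            + (1 + diagnosis + source | participant) + (1 | stimulus)

Treatment coding: non-autistic targets and source study A are the reference
levels.  Continuous predictors are z-scored across the modelling set so
coefficients are comparable.

Posterior inference uses a blocked Gibbs sampler over the conjugate
conditional posteriors of the Gaussian LMM: one joint multivariate-normal
step for all location parameters (fixed effects and every random intercept
and slope together, which avoids the slow mixing of alternating beta/u
updates when predictors vary only at the group level), and inverse-gamma
steps for all variance components.  Random-slope covariance is diagonal —
intercepts and slopes are a priori independent — which keeps every
conditional conjugate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from leadsync.stats import HypothesisSummary, directional_hypothesis

__all__ = [
    "TrialRecord",
    "DesignBundle",
    "PosteriorSamples",
    "MAIN_COEFFICIENTS",
    "build_design",
    "fit_bayes_lmm",
    "evaluate_hypotheses",
]

MAIN_COEFFICIENTS = (
    "intercept",
    "diagnosis",
    "green_leading",
    "white_leading",
    "green_x_white",
    "diagnosis_x_green",
    "diagnosis_x_white",
    "diagnosis_x_green_x_white",
    "motion_green",
    "motion_white",
    "source",
)

_CONTINUOUS = ("green_leading_log", "white_leading_log", "motion_green", "motion_white")


@dataclass
class TrialRecord:
    """One rating trial with its predictors.

    ``diagnosis``: 0 = non-autistic target (reference), 1 = autistic.
    ``source``: 0 = study A (reference), 1 = study B.
    ``aq_group``: 0 = low autism-like traits, 1 = high (exploratory models).
    """

    participant_id: str
    stimulus_id: str
    score: float
    diagnosis: int
    green_leading_log: float
    white_leading_log: float
    motion_green: float
    motion_white: float
    source: int
    aq_group: int = 0


@dataclass
class DesignBundle:
    """Fixed-effect matrix plus grouping structure for the sampler."""

    X: np.ndarray
    y: np.ndarray
    coef_names: list[str]
    participant_idx: np.ndarray
    stimulus_idx: np.ndarray
    n_participants: int
    n_stimuli: int
    diagnosis_code: np.ndarray
    source_code: np.ndarray
    formula_variant: str


@dataclass
class PosteriorSamples:
    """Post-warmup draws from the Gibbs sampler, tagged by chain.

    ``beta`` has shape (chains, kept_iterations, n_coefficients);
    ``variances`` maps each variance component (residual, participant
    intercept/slopes, stimulus intercept) to draws of the same leading
    shape.  ``rhat`` holds the split-chain potential-scale-reduction
    statistic per parameter.
    """

    beta: np.ndarray
    coef_names: list[str]
    variances: dict[str, np.ndarray]
    warmup: int
    seed: int
    rhat: dict[str, float] = field(default_factory=dict)

    def draws(self, name: str) -> np.ndarray:
        """Flattened (all chains) draws for one fixed-effect coefficient."""
        if name not in self.coef_names:
            raise KeyError(f"unknown coefficient {name!r}; have {self.coef_names}")
        return self.beta[:, :, self.coef_names.index(name)].ravel()

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, iteration, parameter, value."""
        rows = []
        chains, kept, _ = self.beta.shape
        for c in range(chains):
            for j, name in enumerate(self.coef_names):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(kept),
                            "parameter": name,
                            "value": self.beta[c, :, j],
                        }
                    )
                )
            for name, v in self.variances.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(kept),
                            "parameter": name,
                            "value": v[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _zscore(col: np.ndarray, name: str) -> np.ndarray:
    sd = col.std(ddof=1)
    if sd == 0:
        raise ValueError(f"predictor {name!r} is constant; cannot scale")
    return (col - col.mean()) / sd


def build_design(
    trials: Sequence[TrialRecord] | pd.DataFrame,
    formula_variant: str = "main",
) -> DesignBundle:
    """Assemble the fixed-effect matrix and grouping indices.

    ``formula_variant`` is ``"main"`` (the confirmatory model),
    ``"aq_exploratory"`` (adds the binarised AQ-10 group and its interaction
    with diagnosis) or ``"per_rating"`` (identical design; the caller swaps
    the outcome column).  Continuous predictors are z-scored here, within
    the modelling set.
    """
    if formula_variant not in ("main", "aq_exploratory", "per_rating"):
        raise ValueError(f"unknown formula variant {formula_variant!r}")
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
    else:
        df = pd.DataFrame([t.__dict__ for t in trials])
    if df["participant_id"].nunique() < 2 or df["stimulus_id"].nunique() < 2:
        raise ValueError("need at least 2 participants and 2 stimuli")

    g = _zscore(df["green_leading_log"].to_numpy(float), "green_leading_log")
    w = _zscore(df["white_leading_log"].to_numpy(float), "white_leading_log")
    mg = _zscore(df["motion_green"].to_numpy(float), "motion_green")
    mw = _zscore(df["motion_white"].to_numpy(float), "motion_white")
    d = df["diagnosis"].to_numpy(float)
    s = df["source"].to_numpy(float)
    n = len(df)

    cols = [
        np.ones(n), d, g, w, g * w, d * g, d * w, d * g * w, mg, mw, s,
    ]
    names = list(MAIN_COEFFICIENTS)
    if formula_variant == "aq_exploratory":
        aq = df["aq_group"].to_numpy(float)
        cols += [aq, aq * d]
        names += ["aq_group", "aq_group_x_diagnosis"]
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        aliased = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    participants = pd.Categorical(df["participant_id"])
    stimuli = pd.Categorical(df["stimulus_id"])
    return DesignBundle(
        X=X,
        y=df["score"].to_numpy(float),
        coef_names=names,
        participant_idx=np.asarray(participants.codes, dtype=int),
        stimulus_idx=np.asarray(stimuli.codes, dtype=int),
        n_participants=len(participants.categories),
        n_stimuli=len(stimuli.categories),
        diagnosis_code=d,
        source_code=s,
        formula_variant=formula_variant,
    )


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction (R-hat).

    ``draws`` has shape (chains, iterations); each chain is split in half,
    then the classic between/within variance ratio is computed.
    """
    chains, iters = draws.shape
    half = iters // 2
    if half < 2:
        return np.nan
    splits = np.vstack([draws[:, :half], draws[:, half : 2 * half]])
    m, nit = splits.shape
    chain_means = splits.mean(axis=1)
    chain_vars = splits.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = nit * chain_means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (nit - 1) / nit * W + B / nit
    return float(np.sqrt(var_plus / W))


def fit_bayes_lmm(
    design: DesignBundle,
    chains: int = 4,
    iterations: int = 10000,
    warmup_fraction: float = 0.5,
    seed: int = 0,
    prior_beta_sd: float = 50.0,
    prior_ig_shape: float = 0.01,
    prior_ig_rate: float = 0.01,
    rhat_threshold: float = 1.05,
) -> PosteriorSamples:
    """Gibbs sampler for the crossed-random-effects Gaussian LMM.

    Priors: fixed effects N(0, ``prior_beta_sd``^2) — weakly informative on
    the 0–100 outcome scale; all variance components inverse-gamma
    (``prior_ig_shape``, ``prior_ig_rate``).  ``iterations`` is the total
    per-chain count with the first ``warmup_fraction`` discarded.  A
    convergence warning (via ``warnings``) is issued when any split-chain
    R-hat exceeds ``rhat_threshold``.
    """
    import warnings

    warmup = int(iterations * warmup_fraction)
    kept = iterations - warmup
    if kept < 500:
        raise ValueError("need at least 500 post-warmup iterations per chain")

    X, y = design.X, design.y
    n, p = X.shape
    prior_prec_beta = 1.0 / prior_beta_sd**2

    # random-effect terms: (group index, per-row weight, n_levels, label)
    terms = [
        (design.participant_idx, np.ones(n), design.n_participants, "participant_intercept"),
        (design.participant_idx, design.diagnosis_code, design.n_participants, "participant_diagnosis"),
        (design.participant_idx, design.source_code, design.n_participants, "participant_source"),
        (design.stimulus_idx, np.ones(n), design.n_stimuli, "stimulus_intercept"),
    ]
    # drop slope terms whose covariate is all zero within the data
    terms = [t for t in terms if np.any(t[1] != 0)]

    # sparse random-effect design Z, materialized densely once: the joint
    # location step samples (beta, u) in one Gaussian block, which avoids
    # the slow beta <-> u random walk when groups and predictors overlap
    blocks = []
    slices = []
    offset = 0
    for idx, wgt, nlev, _ in terms:
        Zk = np.zeros((n, nlev))
        Zk[np.arange(n), idx] = wgt
        blocks.append(Zk)
        slices.append(slice(offset, offset + nlev))
        offset += nlev
    Z = np.hstack(blocks) if blocks else np.zeros((n, 0))
    q = Z.shape[1]
    W = np.hstack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ y
    dim = p + q

    beta_out = np.empty((chains, kept, p))
    var_out = {"sigma2_residual": np.empty((chains, kept))}
    for _, _, _, label in terms:
        var_out[f"var_{label}"] = np.empty((chains, kept))

    for c in range(chains):
        rng = np.random.default_rng([seed, c])
        var_u = [1.0 for _ in terms]
        sigma2 = max(float(np.var(y)), 1e-6)

        for it in range(iterations):
            # joint location step: (beta, u) | variances
            prec = WtW / sigma2
            diag = prec.ravel()[:: dim + 1]
            diag[:p] += prior_prec_beta
            for k, sl in enumerate(slices):
                diag[p + sl.start : p + sl.stop] += 1.0 / var_u[k]
            L = np.linalg.cholesky(prec)
            half = solve_triangular(L, Wty / sigma2, lower=True)
            mean = solve_triangular(L.T, half, lower=False)
            theta = mean + solve_triangular(L.T, rng.standard_normal(dim), lower=False)
            beta = theta[:p]
            u = theta[p:]

            # variance components | u
            for k, ((_, _, nlev, label), sl) in enumerate(zip(terms, slices)):
                uk = u[sl]
                var_u[k] = 1.0 / rng.gamma(
                    prior_ig_shape + nlev / 2.0,
                    1.0 / (prior_ig_rate + 0.5 * float(uk @ uk)),
                )
                if not np.isfinite(var_u[k]) or var_u[k] <= 0:
                    raise RuntimeError(f"divergent variance draw for {label}")

            # residual variance | everything
            resid = y - W @ theta
            sigma2 = 1.0 / rng.gamma(
                prior_ig_shape + n / 2.0,
                1.0 / (prior_ig_rate + 0.5 * float(resid @ resid)),
            )
            if not np.isfinite(sigma2) or sigma2 <= 0:
                raise RuntimeError("divergent residual variance draw")

            if it >= warmup:
                j = it - warmup
                beta_out[c, j] = beta
                var_out["sigma2_residual"][c, j] = sigma2
                for k, (_, _, _, label) in enumerate(terms):
                    var_out[f"var_{label}"][c, j] = var_u[k]

    rhat = {
        name: _split_rhat(beta_out[:, :, j])
        for j, name in enumerate(design.coef_names)
    }
    for name, v in var_out.items():
        rhat[name] = _split_rhat(np.log(v))
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > rhat_threshold}
    if bad:
        warnings.warn(f"R-hat above {rhat_threshold}: {bad}", stacklevel=2)

    return PosteriorSamples(
        beta=beta_out,
        coef_names=list(design.coef_names),
        variances=var_out,
        warmup=warmup,
        seed=seed,
        rhat=rhat,
    )


def evaluate_hypotheses(
    fit: PosteriorSamples,
    hypotheses: Sequence[tuple[str, str | None]] | None = None,
    threshold: float = 0.975,
) -> dict[str, HypothesisSummary]:
    """Directional hypothesis summaries for fixed-effect coefficients.

    ``hypotheses`` is a list of (coefficient, direction) pairs where
    direction is ``">0"``, ``"<0"`` or None; None tests in the direction of
    the posterior mean (the one-sided scheme).  Defaults to all fixed
    effects except the intercept.
    """
    if hypotheses is None:
        hypotheses = [(n, None) for n in fit.coef_names if n != "intercept"]
    out = {}
    for name, direction in hypotheses:
        draws = fit.draws(name)
        if direction is None:
            direction = ">0" if np.mean(draws) > 0 else "<0"
        out[name] = directional_hypothesis(draws, direction=direction, threshold=threshold)
    return out
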