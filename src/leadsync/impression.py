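"""Composite impression scoring, unidimensionality and participant filtering.

Raters judge the target interactant on six 0–100 scales: intelligent,
awkward, likeable, trustworthy, conversation ("would you start a
conversation?") and friends ("do you think they have many friends?").
Awkwardness is reverse-coded (higher = worse impression) before the six
values are averaged into a single composite impression score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RATING_COLUMNS",
    "RatingRecord",
    "ParticipantRecord",
    "composite_impression",
    "reverse_awkward",
    "unidimensionality_fit",
    "filter_participants",
]

RATING_COLUMNS = (
    "intelligent",
    "awkward",
    "likeable",
    "trustworthy",
    "conversation",
    "friends",
)


@dataclass(frozen=True)
class RatingRecord:
    """Six forced 0–100 ratings of one stimulus by one participant."""

    participant_id: str
    stimulus_id: str
    intelligent: float
    awkward: float
    likeable: float
    trustworthy: float
    conversation: float
    friends: float

    def __post_init__(self) -> None:
        for name in RATING_COLUMNS:
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing rating {name!r} (responses are forced)")
            if not 0 <= v <= 100:
                raise ValueError(f"rating {name!r}={v} outside [0, 100]")

    def ratings(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in RATING_COLUMNS], dtype=float)


@dataclass(frozen=True)
class ParticipantRecord:
    """Screening data for one rater.

    ``aq10`` is the 10-item autism-traits screener (0–10, exclusion above
    5); ``wst`` the verbal-IQ vocabulary test (0–42, exclusion below 6);
    ``conscientious`` whether the participant endorsed use of their data.
    """

    participant_id: str
    age: float
    gender: str
    aq10: int
    wst: int
    conscientious: bool

    def __post_init__(self) -> None:
        if not 0 <= self.aq10 <= 10:
            raise ValueError(f"aq10={self.aq10} outside [0, 10]")
        if not 0 <= self.wst <= 42:
            raise ValueError(f"wst={self.wst} outside [0, 42]")


def reverse_awkward(value: float | np.ndarray) -> float | np.ndarray:
    """Reverse-code an awkwardness rating on the 0–100 scale."""
    return 100.0 - value


def composite_impression(record: RatingRecord) -> float:
    """Mean of the six ratings with awkwardness reverse-coded.

    Higher scores mean a more favourable impression throughout.
    """
    vals = record.ratings()
    vals[RATING_COLUMNS.index("awkward")] = reverse_awkward(vals[RATING_COLUMNS.index("awkward")])
    return float(vals.mean())


def _principal_factor_loadings(R: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """First-factor loadings by iterated principal-factor extraction.

    Starts from squared multiple correlations as communality estimates and
    iterates eigendecomposition of the reduced correlation matrix until the
    communalities stabilize.
    """
    p = R.shape[0]
    # SMC initial communalities; guard near-singular R
    try:
        Rinv = np.linalg.inv(R)
        h2 = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.0, 1.0)
    loadings = np.zeros(p)
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        eigval, eigvec = np.linalg.eigh(Rr)
        lam = eigvec[:, -1] * np.sqrt(max(eigval[-1], 0.0))
        new_h2 = np.clip(lam**2, 0.0, 1.0)
        if np.max(np.abs(new_h2 - h2)) < tol:
            loadings = lam
            break
        h2 = new_h2
        loadings = lam
    # sign convention: majority-positive loadings
    if loadings.sum() < 0:
        loadings = -loadings
    return loadings


def unidimensionality_fit(ratings_matrix: np.ndarray | pd.DataFrame) -> float:
    """One-factor fit of the six ratings (awkwardness reverse-coded first).

    Computes ``1 - SS_offdiag(R - λλᵀ) / SS_offdiag(R)`` where ``R`` is the
    6x6 Pearson correlation matrix of the ratings and ``λ`` the first-factor
    loadings from an iterated principal-factor fit.  A value near 1 means a
    single latent dimension reproduces the observed correlations, justifying
    the composite score.
    """
    if isinstance(ratings_matrix, pd.DataFrame):
        cols = [c for c in RATING_COLUMNS if c in ratings_matrix.columns]
        if len(cols) == len(RATING_COLUMNS):
            X = ratings_matrix[list(RATING_COLUMNS)].to_numpy(dtype=float)
        else:
            X = ratings_matrix.to_numpy(dtype=float)
        names = list(ratings_matrix.columns)
    else:
        X = np.asarray(ratings_matrix, dtype=float)
        names = [f"col{i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need a trials x items matrix with at least 10 rows")
    X = X.copy()
    if X.shape[1] == len(RATING_COLUMNS):
        X[:, RATING_COLUMNS.index("awkward")] = reverse_awkward(
            X[:, RATING_COLUMNS.index("awkward")]
        )

    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = names[int(np.argmin(sds))]
        raise ValueError(f"constant column {bad!r}: correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    lam = _principal_factor_loadings(R)
    resid = R - np.outer(lam, lam)
    off = ~np.eye(R.shape[0], dtype=bool)
    denom = float((R[off] ** 2).sum())
    if denom == 0.0:
        return 1.0
    return float(1.0 - (resid[off] ** 2).sum() / denom)


def filter_participants(
    records: list[ParticipantRecord],
) -> tuple[list[ParticipantRecord], list[tuple[ParticipantRecord, str]]]:
    """Apply the inclusion rules; returns (included, excluded-with-reason).

    A participant is excluded if they flagged their data as not usable, if
    ``wst < 6``, or if ``aq10 > 5`` — the first matching reason, checked in
    that order, is recorded.  Boundary scores (aq10 = 5, wst = 6) are
    included.
    """
    included, excluded = [], []
    for rec in records:
        if not rec.conscientious:
            excluded.append((rec, "not-conscientious"))
        elif rec.wst < 6:
            excluded.append((rec, "low-wst"))
        elif rec.aq10 > 5:
            excluded.append((rec, "high-aq10"))
        else:
            included.append(rec)
    return included, excluded
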