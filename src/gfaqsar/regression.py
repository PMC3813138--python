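"""Ordinary least squares and the QSAR statistic suite.

A fitted equation is a :class:`LinearModel` (intercept plus named slopes);
its quality is summarised by :class:`FitStats`: R^2, adjusted R^2, the
overall F statistic, the Friedman lack-of-fit score used as the selection
criterion in genetic function approximation, and the leave-one-out
cross-validated q^2 = 1 - PRESS/SST.

Conventions
-----------
* Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1) for k non-intercept terms.
* F = (R^2/k) / ((1 - R^2)/(n - k - 1)).
* Friedman LOF = SSE / (n (1 - (c + d p)/n)^2) with c the number of
  non-intercept basis functions, p = c + 1 the number of estimated
  parameters, and smoothing factor d (default 0.5).  This is the convention
  of the GFA literature; it is isolated in :func:`friedman_lof` so it can be
  swapped.
* q^2 uses PRESS from leave-one-out folds and SST about the full-sample
  mean — the standard QSAR definition.
* Standardized coefficients are b_j * s(x_j)/s(y) with n-1 denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datasets import DescriptorTable, LigandRecord
from .errors import (
    DegenerateDescriptorError,
    DegeneratePenaltyError,
    EvaluationError,
    FoldSingularError,
    InsufficientDataError,
    SingularDesignError,
)

#: Relative condition number above which a design matrix is declared
#: rank deficient.
CONDITION_LIMIT = 1e10


@dataclass
class LinearModel:
    """Intercept + named linear terms.

    ``provenance`` records how the model was obtained: ``"ols"``,
    ``"pls(k)"`` for a k-component partial-least-squares fit, or
    ``"fixed"`` for coefficients taken verbatim from a publication.
    """

    intercept: float
    coefficients: dict[str, float]
    provenance: str = "ols"

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def predict_record(self, record: LigandRecord | Mapping[str, float]) -> float:
        desc = record.descriptors if isinstance(record, LigandRecord) else record
        total = self.intercept
        for name, coef in self.coefficients.items():
            if name not in desc:
                raise EvaluationError(f"record lacks descriptor {name!r}")
            total += coef * desc[name]
        return total

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict from a matrix whose columns follow ``self.terms`` order."""
        beta = np.array([self.coefficients[t] for t in self.terms])
        return self.intercept + np.asarray(X, dtype=float) @ beta


@dataclass
class FitStats:
    """The full statistic suite of one fitted equation."""

    n: int
    k: int
    sse: float
    sst: float
    r2: float
    r2_adj: float
    f_stat: float
    lof: float
    press: float | None = None
    q2: float | None = None
    std_coefficients: dict[str, float] = field(default_factory=dict)

    def summary_line(self) -> str:
        """The statistics line in the layout of the source publication."""

        def num(v: float | None) -> str:
            return "   n/a" if v is None else f"{v:6.3f}"

        return (
            f"N = {self.n:3d}  LOF = {num(self.lof)}  R^2 = {num(self.r2)}  "
            f"R^2_adj = {num(self.r2_adj)}  R^2_cv = {num(self.q2)}  "
            f"F = {self.f_stat:7.2f}"
        )


# ---------------------------------------------------------------------------
# Closed-form statistics


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted R^2 for n samples and k non-intercept terms."""
    if n <= k + 1:
        raise InsufficientDataError(f"adjusted R^2 undefined for n={n}, k={k}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def f_statistic(r2: float, n: int, k: int) -> float:
    """Overall regression F with (k, n-k-1) degrees of freedom.

    A saturated fit (R^2 == 1) returns ``math.inf``.
    """
    if n <= k + 1:
        raise InsufficientDataError(f"F undefined for n={n}, k={k}")
    if not (0.0 <= r2 <= 1.0):
        raise ValueError(f"R^2 must lie in [0, 1], got {r2}")
    if r2 == 1.0:
        return math.inf
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def friedman_lof(sse: float, n: int, c: int, p: int, d: float = 0.5) -> float:
    """Friedman lack-of-fit: SSE penalised by model size.

    Parameters
    ----------
    sse : residual sum of squares of the candidate equation.
    n : number of training samples.
    c : number of non-intercept basis functions.
    p : total number of estimated parameters (``c + 1`` for linear models
        with intercept).
    d : smoothing factor; larger d punishes extra terms harder.
    """
    if sse < 0:
        raise ValueError(f"SSE must be non-negative, got {sse}")
    penalty = (c + d * p) / n
    if penalty >= 1.0:
        raise DegeneratePenaltyError(
            f"LOF penalty (c + d*p)/n = {penalty:.3f} >= 1 for n={n}, c={c}, p={p}, d={d}"
        )
    return sse / (n * (1.0 - penalty) ** 2)


# ---------------------------------------------------------------------------
# Fitting


def _design(table: DescriptorTable, terms: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list]:
    recs = table.training_records
    X = table.matrix(terms, recs)
    y = table.response(recs)
    return X, y, recs


def _check_rank(Xd: np.ndarray, terms: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the design; raises SingularDesignError naming collinear terms."""
    U, s, Vt = np.linalg.svd(Xd, full_matrices=False)
    if s[-1] == 0 or s[0] / s[-1] > CONDITION_LIMIT:
        null = Vt[-1]
        # the intercept is column 0; name the descriptor columns that load
        # on the (near-)null direction
        guilty = [
            terms[j - 1]
            for j in range(1, len(null))
            if abs(null[j]) > 0.1 * np.max(np.abs(null))
        ]
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear terms: {guilty}",
            collinear_terms=guilty,
        )
    return U, s, Vt


def fit_ols(
    table: DescriptorTable,
    terms: Sequence[str],
    response: str = "pIC50_obs",
    *,
    smoothing_d: float = 0.5,
    compute_loo: bool = True,
) -> tuple[LinearModel, FitStats]:
    """Least-squares fit of ``response`` on ``terms`` over the training rows.

    Returns the fitted :class:`LinearModel` and a fully populated
    :class:`FitStats`.  PRESS/q^2 come from the exact hat-matrix identity
    e_i/(1 - h_ii) and can be skipped with ``compute_loo=False`` (used by
    the genetic search, whose fitness needs only SSE/LOF).
    """
    terms = list(terms)
    X, y, _ = _design(table, terms)
    n, k = X.shape
    if n <= k + 1:
        raise InsufficientDataError(
            f"n={n} training records cannot support k={k} terms plus intercept"
        )
    Xd = np.column_stack([np.ones(n), X])
    U, s, Vt = _check_rank(Xd, terms)
    beta = Vt.T @ ((U.T @ y) / s)
    yhat = Xd @ beta
    resid = y - yhat
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    model = LinearModel(
        intercept=float(beta[0]),
        coefficients={t: float(b) for t, b in zip(terms, beta[1:])},
        provenance="ols",
    )
    press = q2 = None
    if compute_loo:
        h = np.sum(U**2, axis=1)
        press = float(np.sum((resid / (1.0 - h)) ** 2))
        q2 = 1.0 - press / sst if sst > 0 else None
    stats = FitStats(
        n=n,
        k=k,
        sse=sse,
        sst=sst,
        r2=r2,
        r2_adj=adjusted_r2(r2, n, k),
        f_stat=f_statistic(min(r2, 1.0), n, k) if r2 < 1.0 else math.inf,
        lof=friedman_lof(sse, n, c=k, p=k + 1, d=smoothing_d),
        press=press,
        q2=q2,
        std_coefficients=standardized_coefficients(model, table, response),
    )
    return model, stats


def loo_q2(
    table: DescriptorTable,
    terms: Sequence[str],
    response: str = "pIC50_obs",
) -> float:
    """Leave-one-out cross-validated q^2 by explicit refitting.

    Each training record is predicted by the OLS model fitted to the other
    n-1 records; q^2 = 1 - PRESS/SST with SST about the full-sample mean.
    """
    terms = list(terms)
    X, y, recs = _design(table, terms)
    n, k = X.shape
    if n <= k + 2:
        raise InsufficientDataError(
            f"LOO needs n > k+2 (got n={n}, k={k}) so every fold is solvable"
        )
    Xd = np.column_stack([np.ones(n), X])
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = Xd[mask], y[mask]
        beta, _, rank, _ = np.linalg.lstsq(Xi, yi, rcond=None)
        if rank < Xd.shape[1]:
            raise FoldSingularError(
                f"singular design when ligand {recs[i].ligand_id!r} is left out",
                ligand_id=recs[i].ligand_id,
            )
        press += float((y[i] - Xd[i] @ beta) ** 2)
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sst


def standardized_coefficients(
    model: LinearModel,
    table: DescriptorTable,
    response: str = "pIC50_obs",
) -> dict[str, float]:
    """Slopes rescaled to b_j * s(x_j)/s(y); the basis of importance ranking."""
    recs = table.training_records
    X = table.matrix(model.terms, recs)
    y = table.response(recs)
    sy = float(np.std(y, ddof=1))
    if sy == 0:
        raise DegenerateDescriptorError("response has zero variance")
    out: dict[str, float] = {}
    for j, name in enumerate(model.terms):
        sx = float(np.std(X[:, j], ddof=1))
        # scale-relative test: a constant column's std is O(eps), not 0
        if sx <= 1e-12 * max(1.0, float(np.abs(X[:, j]).max())):
            raise DegenerateDescriptorError(f"descriptor {name!r} has zero variance")
        out[name] = model.coefficients[name] * sx / sy
    return out


def evaluate_equation(model: LinearModel, record: LigandRecord | Mapping[str, float]) -> float:
    """Evaluate a (possibly fixed, published) equation on one record."""
    return model.predict_record(record)


def rank_importance(std_coefficients: Mapping[str, float]) -> list[str]:
    """Descriptor names by decreasing |standardized coefficient|.

    Ties broken lexicographically so the ordering is deterministic.
    """
    if not std_coefficients:
        raise ValueError("empty standardized-coefficient map")
    return [
        name
        for name, _ in sorted(
            std_coefficients.items(), key=lambda kv: (-abs(kv[1]), kv[0])
        )
    ]
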