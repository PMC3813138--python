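"""Single-response partial least squares (NIPALS), for G/PLS fitting.

Components are extracted sequentially on centered, unit-variance data; each
weight vector maximises covariance between the X scores and the (deflated)
response.  The latent model is collapsed to an ordinary regression vector
and returned as a :class:`~gfaqsar.regression.LinearModel` on the raw
descriptor scale, so downstream evaluation, reporting and prediction are
identical for OLS and PLS fits.  With as many components as the rank of the
centered design, PLS reproduces the OLS solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import DescriptorTable
from .errors import (
    ComponentCountError,
    DegenerateDescriptorError,
    InsufficientDataError,
)
from .regression import (
    FitStats,
    LinearModel,
    adjusted_r2,
    f_statistic,
    friedman_lof,
    standardized_coefficients,
)

_EPS = 1e-12


@dataclass
class PLSModel:
    """Internal latent structure of a PLS fit (autoscaled space)."""

    n_components: int
    terms: tuple[str, ...]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    weights: np.ndarray      # (p, A) X-weights, unit norm
    loadings: np.ndarray     # (p, A) X-loadings
    y_loadings: np.ndarray   # (A,)
    regression_vector: dict[str, float] | None = None
    intercept: float | None = None

    def coefficients_scaled(self) -> np.ndarray:
        """Regression vector in autoscaled space: W (P'W)^-1 q."""
        W, P, q = self.weights, self.loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)


def _nipals(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sequential component extraction on (already autoscaled) X, y."""
    n, p = X.shape
    Xk = X.copy()
    yk = y.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = Xk.T @ yk
        norm = np.linalg.norm(w)
        if norm < _EPS:
            raise ComponentCountError(
                f"component {a + 1} exceeds the rank of the deflated design"
            )
        w /= norm
        t = Xk @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise ComponentCountError(
                f"component {a + 1} has a degenerate score vector"
            )
        P[:, a] = Xk.T @ t / tt
        q[a] = float(yk @ t) / tt
        W[:, a] = w
        Xk -= np.outer(t, P[:, a])
        yk = yk - q[a] * t
    return W, P, q


def fit_pls(
    table: DescriptorTable,
    terms: Sequence[str],
    response: str = "pIC50_obs",
    n_components: int = 2,
    *,
    smoothing_d: float = 0.5,
    compute_loo: bool = True,
) -> tuple[LinearModel, FitStats]:
    """PLS fit of ``response`` on ``terms``; returns raw-scale model + stats.

    ``n_components`` must not exceed the rank of the centered design.
    PRESS/q^2 are obtained by explicit leave-one-out refits (there is no
    hat-matrix shortcut for PLS); skip with ``compute_loo=False``.
    """
    terms = list(terms)
    recs = table.training_records
    X = table.matrix(terms, recs)
    y = table.response(recs)
    n, k = X.shape
    if n <= k + 1:
        raise InsufficientDataError(
            f"n={n} training records cannot support k={k} terms plus intercept"
        )
    model, pls = _fit_raw(X, y, terms, n_components)
    yhat = model.predict(X)
    resid = y - yhat
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    press = q2 = None
    if compute_loo:
        press = 0.0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            m_i, _ = _fit_raw(X[mask], y[mask], terms, n_components)
            press += float((y[i] - m_i.predict(X[i : i + 1])[0]) ** 2)
        q2 = 1.0 - press / sst if sst > 0 else None
    stats = FitStats(
        n=n,
        k=k,
        sse=sse,
        sst=sst,
        r2=min(r2, 1.0),
        r2_adj=adjusted_r2(r2, n, k),
        f_stat=f_statistic(min(max(r2, 0.0), 1.0), n, k),
        lof=friedman_lof(sse, n, c=k, p=k + 1, d=smoothing_d),
        press=press,
        q2=q2,
        std_coefficients=standardized_coefficients(model, table, response),
    )
    return model, stats


def _fit_raw(
    X: np.ndarray, y: np.ndarray, terms: list[str], n_components: int
) -> tuple[LinearModel, PLSModel]:
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    col_mag = np.maximum(1.0, np.abs(X).max(axis=0))
    dead = [terms[j] for j in np.flatnonzero(x_scale <= 1e-12 * col_mag)]
    if dead:
        raise DegenerateDescriptorError(f"zero-variance descriptor(s): {dead}")
    Xs = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    y_scale = float(y.std(ddof=1))
    if y_scale < _EPS:
        raise DegenerateDescriptorError("response has zero variance")
    ys = (y - y_mean) / y_scale
    rank = int(np.linalg.matrix_rank(Xs))
    if not (1 <= n_components <= rank):
        raise ComponentCountError(
            f"n_components={n_components} outside [1, rank={rank}]"
        )
    W, P, q = _nipals(Xs, ys, n_components)
    pls = PLSModel(
        n_components=n_components,
        terms=tuple(terms),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        weights=W,
        loadings=P,
        y_loadings=q,
    )
    b_scaled = pls.coefficients_scaled()
    b_raw = y_scale * b_scaled / x_scale
    intercept = y_mean - float(b_raw @ x_mean)
    coefficients = {t: float(b) for t, b in zip(terms, b_raw)}
    pls.regression_vector = coefficients
    pls.intercept = intercept
    model = LinearModel(
        intercept=intercept,
        coefficients=coefficients,
        provenance=f"pls({n_components})",
    )
    return model, pls
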