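"""Whitening/coloring transform: impose an exact genetic correlation matrix.

Let Y be the n x t matrix of genetic values. Each column is centred and
scaled; Sigma, the *sample* correlation matrix of the scaled columns, is
Cholesky-factored Sigma = L L^T. Whitening X = L^-1 Y_s^T makes the trait
columns exactly uncorrelated in-sample; coloring Y' = L' X with
Sigma' = L' L'^T imposes the target correlation Sigma' exactly (to machine
precision, not just in expectation, because Sigma is the sample matrix).
Finally each column's original mean and standard deviation are restored.
"""

from __future__ import annotations

import numpy as np


class TransformError(ValueError):
    """Cholesky failure: collinear genetic values or an infeasible target."""


def validate_correlation_matrix(mat, name: str = "correlation matrix") -> np.ndarray:
    """Check symmetry, unit diagonal, positive definiteness; return Cholesky factor's input."""
    m = np.asarray(mat, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise TransformError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise TransformError(f"{name} is not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise TransformError(f"{name} does not have a unit diagonal")
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        raise TransformError(f"{name} is not positive definite") from None
    return m


def whiten_color(Y, sigma_prime) -> np.ndarray:
    """Return genetic values whose sample correlation equals ``sigma_prime``.

    Per-trait means and variances are preserved; with one trait the transform
    is the identity. Raises :class:`TransformError` naming the offending
    matrix if either the sample correlation of Y or the target fails the
    Cholesky factorisation.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise TransformError("genetic values must be an n x t matrix")
    n, t = Y.shape
    if t == 1:
        return Y.copy()
    target = validate_correlation_matrix(sigma_prime, "target correlation matrix Sigma'")
    if target.shape[0] != t:
        raise TransformError(
            f"target correlation is {target.shape[0]}x{target.shape[0]} "
            f"but there are {t} traits")
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise TransformError(
            "sample correlation matrix Sigma is undefined: a trait has zero "
            "genetic variance")
    Ys = (Y - mu) / sd
    sigma = (Ys.T @ Ys) / (n - 1)  # sample correlation of scaled columns
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise TransformError(
            "sample correlation matrix Sigma of the genetic values is not "
            "positive definite (collinear trait columns)") from None
    Lp = np.linalg.cholesky(target)
    X = np.linalg.solve(L, Ys.T)   # whiten: cor(X rows) = I exactly
    Yp = (Lp @ X).T                # color: cor = Sigma' exactly, zero mean, unit sd
    return Yp * sd + mu
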