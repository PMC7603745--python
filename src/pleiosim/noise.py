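"""Heritability-calibrated non-genetic error terms.

Trait variance is dichotomised into the variance of the genetic values and
the variance of normally distributed random errors. Given a target
narrow-sense-style heritability h2 = var_g / (var_g + var_e), the residual
variance is var_e = var_g (1 - h2) / h2, with var_g the *sample* variance of
that replicate's genetic-value column so the calibration tracks each
replicate's realised genetic variance. Errors are independent across traits
by default; an optional residual correlation matrix (cor_res) correlates
them.
"""

from __future__ import annotations

import numpy as np

from .correlate import validate_correlation_matrix


def residual_variance(var_g: float, h2: float) -> float:
    """var_e such that var_g / (var_g + var_e) = h2."""
    if not (0 < h2 <= 1):
        raise ValueError(f"heritability must be in (0, 1], got {h2}")
    if var_g < 0:
        raise ValueError("genetic variance must be >= 0")
    return var_g * (1.0 - h2) / h2


def simulate_errors(n: int, var_e, cor_res=None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """n x t multivariate-normal errors with marginal variances ``var_e``.

    Cross-trait correlation is ``cor_res`` when given, identity otherwise.
    A zero variance yields an exactly-zero error column (the h2 = 1 case).
    """
    var_e = np.atleast_1d(np.asarray(var_e, dtype=float))
    if (var_e < 0).any():
        raise ValueError("residual variances must be >= 0")
    t = var_e.size
    if rng is None:
        rng = np.random.default_rng()
    Z = rng.standard_normal((n, t))
    if cor_res is not None:
        R = validate_correlation_matrix(cor_res, "residual correlation matrix cor_res")
        if R.shape[0] != t:
            raise ValueError("cor_res dimension does not match the number of traits")
        Z = Z @ np.linalg.cholesky(R).T
    return Z * np.sqrt(var_e)


def assemble_phenotypes(G, E) -> np.ndarray:
    """Phenotype = genetic value + error, elementwise."""
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float)
    if G.shape != E.shape:
        raise ValueError(f"shape mismatch: genetic {G.shape} vs error {E.shape}")
    return G + E


def realized_h2(G, E) -> np.ndarray:
    """Per-trait realised sample heritability var(G) / (var(G) + var(E))."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    E = np.atleast_2d(np.asarray(E, dtype=float))
    vg = G.var(axis=0, ddof=1)
    ve = E.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return vg / (vg + ve)
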