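"""Per-QTN effect models and genetic-value aggregation.

Genotype coding g in {-1, 0, +1} (0 = heterozygote). Effect of one QTN on
one individual:

* additive, size a:   a * g           (-a / 0 / +a)
* dominance, size d:  d * (1 - |g|)   (0 / d / 0)
* additive x additive epistasis, size e, for a marker pair (g1, g2):
  e * g1 * g2 — both homozygotes matching in direction give +e, opposite
  homozygotes -e, any heterozygote 0.

A trait's genetic value is the exact sum of its per-QTN contributions;
the contributions are retained so the variance explained by each QTN can be
reported on the pre-transform scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker_io import GenotypeMatrix
from .qtn import ArchitectureSpec, ConfigurationError, ReplicateAssignment


def geometric_effects(base: float, n: int) -> list[float]:
    """Effect sizes base^1, base^2, ..., base^n (largest first for |base|<1)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n and base == 0:
        raise ValueError("geometric base must be nonzero")
    return [base ** i for i in range(1, n + 1)]


def additive_value(column, a: float) -> np.ndarray:
    return a * np.asarray(column, dtype=float)


def dominance_value(column, d: float) -> np.ndarray:
    col = np.asarray(column, dtype=float)
    return d * (1.0 - np.abs(col))


def epistatic_value(col_1, col_2, e: float) -> np.ndarray:
    c1 = np.asarray(col_1, dtype=float)
    c2 = np.asarray(col_2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("epistatic marker columns have unequal length")
    return e * c1 * c2


@dataclass
class EffectSpec:
    """Effect sizes per trait: ``additive[t]``, ``dominance[t]`` are lists of
    per-QTN sizes, ``epistatic[t]`` one size per QTN pair.

    Alternatively build from geometric bases with :meth:`from_geometric`:
    the i-th ranked QTN of a trait gets base^i, so the first-sampled QTN
    carries the largest effect.
    """

    additive: list
    dominance: list
    epistatic: list

    @classmethod
    def from_geometric(cls, spec: ArchitectureSpec, add_base=None, dom_base=None,
                       epi_base=None) -> "EffectSpec":
        def series(bases, which):
            out = []
            for t in range(spec.n_traits):
                n = spec.trait_counts(t)[which]
                if n == 0:
                    out.append([])
                    continue
                if bases is None:
                    raise ConfigurationError(
                        f"trait {t + 1} has {n} QTNs of a model with no "
                        "effect base given")
                b = bases[t] if isinstance(bases, (list, tuple)) else bases
                out.append(geometric_effects(float(b), n))
            return out
        return cls(series(add_base, 0), series(dom_base, 1), series(epi_base, 2))

    def validate(self, spec: ArchitectureSpec) -> None:
        for t in range(spec.n_traits):
            n_add, n_dom, n_epi = spec.trait_counts(t)
            got = (len(self.additive[t]), len(self.dominance[t]), len(self.epistatic[t]))
            if got != (n_add, n_dom, n_epi):
                raise ConfigurationError(
                    f"trait {t + 1}: effect list lengths {got} do not match "
                    f"QTN counts {(n_add, n_dom, n_epi)}")


@dataclass
class GeneticValues:
    """n_individuals x n_traits genetic values plus per-QTN contributions.

    ``contributions[t]`` is a list of (kind, marker indices, vector) with the
    vectors summing exactly to column t of ``values``.
    """

    values: np.ndarray
    contributions: list

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]


def aggregate_genetic_values(geno: GenotypeMatrix, assignment: ReplicateAssignment,
                             effects: EffectSpec) -> GeneticValues:
    """Sum additive + dominance + epistatic contributions per trait.

    Missing genotypes are imputed to 0 (heterozygote) before the effect
    computation so genetic values are defined for every individual.
    """
    X, _ = geno.imputed()
    n_traits = len(assignment.traits)
    values = np.zeros((geno.n_individuals, n_traits))
    contributions = []
    for t, tq in enumerate(assignment.traits):
        if (len(effects.additive[t]) != len(tq.additive)
                or len(effects.dominance[t]) != len(tq.dominance)
                or len(effects.epistatic[t]) != len(tq.epistatic_pairs)):
            raise ConfigurationError(
                f"trait {t + 1}: effect lists and QTN assignment have "
                "mismatched shapes")
        per_qtn = []
        for a, j in zip(effects.additive[t], tq.additive):
            per_qtn.append(("additive", (int(j),), additive_value(X[:, j], a)))
        for d, j in zip(effects.dominance[t], tq.dominance):
            per_qtn.append(("dominance", (int(j),), dominance_value(X[:, j], d)))
        for e, (j, k) in zip(effects.epistatic[t], tq.epistatic_pairs):
            per_qtn.append(("epistatic", (int(j), int(k)),
                            epistatic_value(X[:, j], X[:, k], e)))
        for _, _, v in per_qtn:
            values[:, t] += v
        contributions.append(per_qtn)
    return GeneticValues(values, contributions)


def variance_explained(gv: GeneticValues, var_phenotype) -> pd.DataFrame:
    """Fraction of phenotypic variance explained by each QTN, per trait.

    ``var_phenotype`` gives the per-trait denominator (the implied
    phenotypic variance on the pre-transform scale, var_g / h2). A zero
    denominator yields NaN rather than an error.
    """
    var_p = np.atleast_1d(np.asarray(var_phenotype, dtype=float))
    rows = []
    for t, per_qtn in enumerate(gv.contributions):
        for kind, idx, vec in per_qtn:
            v = float(np.var(vec, ddof=1)) if vec.size > 1 else 0.0
            frac = v / var_p[t] if var_p[t] > 0 else np.nan
            rows.append({"trait": t + 1, "model": kind,
                         "marker_index": "+".join(str(i) for i in idx),
                         "var_qtn": v, "var_phenotype": var_p[t],
                         "fraction_explained": frac})
    return pd.DataFrame(rows, columns=["trait", "model", "marker_index",
                                       "var_qtn", "var_phenotype", "fraction_explained"])
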