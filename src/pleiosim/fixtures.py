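"""Synthetic genotype panels with controllable MAF spectrum and block LD.

The generator emulates a diversity-panel genotype matrix (hundreds of
inbred-or-not individuals by thousands of SNPs) via a latent-haplotype
mosaic: inside each LD block every gamete carries a latent 0/1 haplotype
indicator, and marker alleles copy that indicator with per-site noise. With
constant decay the per-site flip rate eps gives pairwise correlation
r = (1 - 2 eps)^2 between block markers (at haplotype frequency 0.5), so a
target within-block r maps to eps = (1 - sqrt(r)) / 2. With exponential
decay the indicator follows a Markov chain along the block and adjacent-pair
correlation r decays as r^distance. Markers outside blocks are independent
binomial draws.

This is deliberately not population-genetic realism — no coalescent,
selection or demography — just tunable MAF and LD so every architecture
(especially spurious pleiotropy) is testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rand import derive_rng
from .marker_io import MAP_COLUMNS, GenotypeMatrix

_LETTERS = np.array(list("ACGT"))
_MAX_MAF_ROUNDS = 50
_N_CHROM = 10


class FixtureError(ValueError):
    """The fixture specification is infeasible."""


@dataclass
class LDBlock:
    """One block of consecutive markers in mutual LD.

    ``decay='constant'`` targets a flat pairwise r inside the block;
    ``'exponential'`` targets r between adjacent markers, decaying as
    r^distance.
    """

    n_markers: int
    target_r: float
    decay: str = "constant"

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise FixtureError("an LD block needs at least 2 markers")
        if not (0 < self.target_r < 1):
            raise FixtureError("block target r must be in (0, 1)")
        if self.decay not in ("constant", "exponential"):
            raise FixtureError("decay must be 'constant' or 'exponential'")


@dataclass
class FixtureSpec:
    """Shape, MAF spectrum and LD structure of a synthetic panel.

    Defaults emulate a maize-style diversity panel of inbred lines: 280
    individuals, 5,000 SNPs, no heterozygous calls. ``inbred_fraction`` is
    the fraction of individuals whose two gametes are identical copies;
    lowering it introduces heterozygotes so dominance/epistasis paths are
    exercisable.
    """

    n_individuals: int = 280
    n_markers: int = 5000
    maf_distribution: str = "uniform"  # or "u_shaped"
    maf_bounds: tuple = (0.05, 0.5)
    ld_blocks: tuple = ()
    inbred_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_markers < 1:
            raise FixtureError("need at least 2 individuals and 1 marker")
        lo, hi = self.maf_bounds
        if not (0 <= lo < hi <= 0.5):
            raise FixtureError(f"need 0 <= lo < hi <= 0.5 in maf_bounds, got {self.maf_bounds}")
        if self.maf_distribution not in ("uniform", "u_shaped"):
            raise FixtureError("maf_distribution must be 'uniform' or 'u_shaped'")
        if not (0 <= self.inbred_fraction <= 1):
            raise FixtureError("inbred_fraction must be in [0, 1]")
        self.ld_blocks = tuple(b if isinstance(b, LDBlock) else LDBlock(*b)
                               for b in self.ld_blocks)
        if sum(b.n_markers for b in self.ld_blocks) > self.n_markers:
            raise FixtureError("LD block lengths exceed n_markers")


def _layout(spec: FixtureSpec):
    """Interleave blocks with runs of independent markers; return block id
    per marker (-1 = independent)."""
    n_single = spec.n_markers - sum(b.n_markers for b in spec.ld_blocks)
    n_gaps = len(spec.ld_blocks) + 1
    gap_sizes = [n_single // n_gaps + (1 if g < n_single % n_gaps else 0)
                 for g in range(n_gaps)]
    block_id = []
    for g, b in enumerate(spec.ld_blocks):
        block_id += [-1] * gap_sizes[g] + [g] * b.n_markers
    block_id += [-1] * gap_sizes[-1]
    return np.asarray(block_id)


def _draw_p(spec: FixtureSpec, size: int, rng: np.random.Generator,
            lo: float, hi: float) -> np.ndarray:
    if spec.maf_distribution == "u_shaped":
        u = rng.beta(0.5, 0.5, size=size)
        return lo + u * (hi - lo)
    return rng.uniform(lo, hi, size=size)


def _gametes_single(n: int, p: float, inbred: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    a1 = rng.random(n) < p
    a2 = rng.random(n) < p
    a2[inbred] = a1[inbred]
    return (a1.astype(int) + a2.astype(int)) - 1


def _block_gamete(n: int, L: int, f: float, eps: float, switch: float,
                  rng: np.random.Generator) -> np.ndarray:
    """One gamete's alleles across a block: latent Markov indicator + flips."""
    H = np.empty((n, L), dtype=bool)
    H[:, 0] = rng.random(n) < f
    for j in range(1, L):
        resample = rng.random(n) < switch
        H[:, j] = np.where(resample, rng.random(n) < f, H[:, j - 1])
    if eps > 0:
        H = H ^ (rng.random((n, L)) < eps)
    return H


def _block_genotypes(spec: FixtureSpec, b: LDBlock, f: float, inbred: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    n, L = spec.n_individuals, b.n_markers
    if b.decay == "constant":
        eps, switch = (1 - np.sqrt(b.target_r)) / 2, 0.0
    else:
        eps, switch = 0.0, 1 - b.target_r
    g1 = _block_gamete(n, L, f, eps, switch, rng)
    g2 = _block_gamete(n, L, f, eps, switch, rng)
    g2[inbred] = g1[inbred]
    return (g1.astype(int) + g2.astype(int)) - 1


def make_fixture(spec: FixtureSpec) -> GenotypeMatrix:
    """Generate a deterministic synthetic panel for the given spec.

    Realised per-marker MAFs are enforced inside ``maf_bounds`` (closed
    interval) by resampling violating markers, up to a bounded number of
    rounds; an infeasible spec raises :class:`FixtureError` with the count
    of markers still violating.
    """
    rng = derive_rng(spec.seed, 0, "fixture")
    n, m = spec.n_individuals, spec.n_markers
    lo, hi = spec.maf_bounds
    # sampling margin keeps realised MAF inside the requested window
    margin = min((hi - lo) / 4, 2.0 / np.sqrt(2 * n))
    p_lo = lo + margin
    p_hi = hi if hi == 0.5 else hi - margin

    n_inbred = int(round(spec.inbred_fraction * n))
    inbred = np.zeros(n, dtype=bool)
    inbred[rng.permutation(n)[:n_inbred]] = True

    block_id = _layout(spec)
    values = np.empty((n, m), dtype=float)
    # haplotype frequency per block: keep f near 0.5 so the target r is achievable
    f_lo = max(p_lo, min(0.3, p_hi - 0.01))
    block_f = {g: rng.uniform(f_lo, p_hi) for g in range(len(spec.ld_blocks))}
    for g, b in enumerate(spec.ld_blocks):
        cols = np.flatnonzero(block_id == g)
        values[:, cols] = _block_genotypes(spec, b, block_f[g], inbred, rng)
    singles = np.flatnonzero(block_id == -1)
    p_single = _draw_p(spec, singles.size, rng, p_lo, p_hi)
    for k, j in enumerate(singles):
        values[:, j] = _gametes_single(n, p_single[k], inbred, rng)

    # enforce realised MAF within bounds (and polymorphism)
    for _round in range(_MAX_MAF_ROUNDS):
        maf = _maf(values)
        mono = np.array([np.unique(values[:, j]).size < 2 for j in range(m)])
        bad = np.flatnonzero((maf < lo) | (maf > hi) | mono)
        if bad.size == 0:
            break
        for j in bad:
            g = block_id[j]
            if g == -1:
                values[:, j] = _gametes_single(n, float(_draw_p(spec, 1, rng, p_lo, p_hi)[0]),
                                               inbred, rng)
            else:
                # redraw this block column alone (loses some LD for that site
                # but keeps the bulk of the block structure)
                b = spec.ld_blocks[g]
                eps = (1 - np.sqrt(b.target_r)) / 2 if b.decay == "constant" else 0.05
                cols = np.flatnonzero(block_id == g)
                anchor = cols[0] if j != cols[0] else cols[1]
                base = (values[:, anchor] + 1) / 2  # crude haplotype proxy
                a1 = (rng.random(n) < base / 1.0) ^ (rng.random(n) < eps)
                a2 = (rng.random(n) < base / 1.0) ^ (rng.random(n) < eps)
                a2[inbred] = a1[inbred]
                values[:, j] = a1.astype(int) + a2.astype(int) - 1
    else:
        maf = _maf(values)
        bad = np.flatnonzero((maf < lo) | (maf > hi))
        raise FixtureError(
            f"could not realise MAFs inside {spec.maf_bounds} for {bad.size} "
            "markers; widen the bounds or increase n_individuals")

    marker_map = _make_map(spec, values, block_id, rng)
    ids = [f"ind_{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(values, marker_map, ids)


def _maf(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    p = (2 * (values == 1).sum(axis=0) + (values == 0).sum(axis=0)) / (2 * n)
    return np.minimum(p, 1 - p)


def _make_map(spec: FixtureSpec, values: np.ndarray, block_id: np.ndarray,
              rng: np.random.Generator) -> pd.DataFrame:
    m = spec.n_markers
    chrom = np.arange(m) * _N_CHROM // m + 1
    # keep each block on one chromosome (assign the whole block to its start's)
    for g in range(len(spec.ld_blocks)):
        cols = np.flatnonzero(block_id == g)
        chrom[cols] = chrom[cols[0]]
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        pos[cols] = np.arange(cols.size) * 2500 + 1
    rows = []
    for j in range(m):
        pair = sorted(rng.choice(_LETTERS, size=2, replace=False))
        plus = pair[1]  # alphabetically second: survives HapMap round-trips
        p_plus = ((values[:, j] == 1).sum() * 2 + (values[:, j] == 0).sum()) \
            / (2 * values.shape[0])
        major, minor = (pair[0], pair[1]) if p_plus <= 0.5 else (pair[1], pair[0])
        rows.append([f"snp_{j + 1:06d}", str(chrom[j]), int(pos[j]),
                     major, minor, plus, np.nan])
    return pd.DataFrame(rows, columns=MAP_COLUMNS)
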