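"""QTN selection under single-trait, pleiotropy, partial-pleiotropy and
spurious-pleiotropy architectures.

Multi-trait architectures for a pool of causal markers:

* **pleiotropy** — one QTN set controls every trait;
* **partial pleiotropy** — a shared set controls all traits, plus disjoint
  trait-specific sets (e.g. 4 shared, 7 only trait 1, 9 only trait 2);
* **spurious pleiotropy** — the traits share *no* QTNs; instead each of a set
  of randomly chosen linking markers is in LD with one QTN of each trait, so
  an association scan sees an apparently pleiotropic signal at the link.

LD is measured as the Pearson correlation r of the coded genotype scores
(composite LD — inbred-panel data carry no phase). The user's ``ld`` value
is an upper bound on |r|, not a target; the search takes the qualifying
candidate whose |r| is closest to the bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rand import derive_rng
from .marker_io import GenotypeMatrix

ARCHITECTURES = ("single_trait", "pleiotropy", "partial_pleiotropy", "spurious_pleiotropy")

#: markers scanned on each side of a candidate when searching for LD partners
SCAN_WINDOW = 50
#: linking-marker draws attempted before giving up on a spurious replicate
MAX_LINK_TRIES = 500


class ConfigurationError(ValueError):
    """The architecture specification is infeasible or inconsistent."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Which markers become QTNs, for how many traits, under what constraints.

    ``add_qtn_num`` / ``dom_qtn_num`` / ``epi_qtn_num`` are the per-trait
    counts (``epi_qtn_num`` counts QTN *pairs*). Under partial pleiotropy
    they are the *shared* counts and the ``*_qtn_specific`` tuples give each
    trait's private counts. ``ld_ceiling`` bounds |r| in spurious mode;
    ``maf_above < MAF < maf_below`` (strict) restricts eligible markers.
    """

    architecture: str
    n_traits: int = 1
    add_qtn_num: int = 0
    dom_qtn_num: int = 0
    epi_qtn_num: int = 0
    add_qtn_specific: tuple | None = None
    dom_qtn_specific: tuple | None = None
    epi_qtn_specific: tuple | None = None
    ld_ceiling: float = 0.7
    type_of_ld: str = "indirect"
    maf_above: float = 0.0
    maf_below: float = 0.5
    vary_qtn: bool = False
    seed: int = 0
    n_experiments: int = 1

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}")
        if self.architecture == "single_trait":
            if self.n_traits != 1:
                raise ConfigurationError("single_trait architecture requires n_traits = 1")
        elif self.n_traits < 2:
            raise ConfigurationError("multi-trait architectures require n_traits >= 2")
        for name in ("add_qtn_num", "dom_qtn_num", "epi_qtn_num"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0 <= self.maf_above < self.maf_below <= 0.5):
            raise ConfigurationError(
                f"need 0 <= maf_above < maf_below <= 0.5, got "
                f"({self.maf_above}, {self.maf_below})")
        if not (0 < self.ld_ceiling <= 1):
            raise ConfigurationError("ld_ceiling must be in (0, 1]")
        if self.type_of_ld not in ("indirect", "direct"):
            raise ConfigurationError("type_of_ld must be 'indirect' or 'direct'")
        if self.n_experiments < 1:
            raise ConfigurationError("n_experiments must be >= 1")
        if self.architecture == "partial_pleiotropy":
            for name in ("add_qtn_specific", "dom_qtn_specific", "epi_qtn_specific"):
                val = getattr(self, name)
                if val is None:
                    val = (0,) * self.n_traits
                val = tuple(int(x) for x in val)
                if len(val) != self.n_traits or any(x < 0 for x in val):
                    raise ConfigurationError(
                        f"{name} must give one count >= 0 per trait")
                object.__setattr__(self, name, val)
        if self.architecture == "spurious_pleiotropy":
            if self.n_traits != 2:
                raise ConfigurationError(
                    "spurious pleiotropy is defined for exactly 2 traits")
            if self.dom_qtn_num or self.epi_qtn_num:
                raise ConfigurationError(
                    "spurious pleiotropy supports additive QTNs only")
            if self.add_qtn_num < 1:
                raise ConfigurationError("spurious pleiotropy needs add_qtn_num >= 1")

    def trait_counts(self, trait: int) -> tuple[int, int, int]:
        """(n_additive, n_dominance, n_epistatic_pairs) for one trait."""
        if self.architecture == "partial_pleiotropy":
            return (self.add_qtn_num + self.add_qtn_specific[trait],
                    self.dom_qtn_num + self.dom_qtn_specific[trait],
                    self.epi_qtn_num + self.epi_qtn_specific[trait])
        return (self.add_qtn_num, self.dom_qtn_num, self.epi_qtn_num)


@dataclass
class TraitQTNs:
    """QTN marker indices of one trait in one replicate."""

    additive: np.ndarray
    dominance: np.ndarray
    epistatic_pairs: list  # list[(i, j)]

    @property
    def all_markers(self) -> np.ndarray:
        flat = [self.additive, self.dominance]
        flat += [np.asarray(p) for p in self.epistatic_pairs]
        out = np.concatenate([np.atleast_1d(np.asarray(a, dtype=int)) for a in flat]) \
            if flat else np.array([], dtype=int)
        return out


@dataclass
class LDRecord:
    """Realised LD around one linking slot in spurious mode.

    ``link_idx`` is None in direct mode (QTN pairs constrained directly).
    """

    link_idx: int | None
    qtn_idx: tuple  # one QTN index per trait
    r_link_qtn: tuple  # r(link, QTN_t) per trait; empty in direct mode
    r_qtn_qtn: float
    input_ld: float


@dataclass
class ReplicateAssignment:
    """All QTNs of one replicate: one :class:`TraitQTNs` per trait."""

    traits: list
    ld_records: list = field(default_factory=list)

    def distinct_markers(self, include_links: bool = False) -> np.ndarray:
        idx = [t.all_markers for t in self.traits]
        if include_links:
            idx.append(np.array([r.link_idx for r in self.ld_records
                                 if r.link_idx is not None], dtype=int))
        return np.unique(np.concatenate(idx)) if idx else np.array([], dtype=int)


@dataclass
class QTNAssignment:
    """Per-replicate assignments plus the architecture spec that made them."""

    spec: ArchitectureSpec
    replicates: list

    def distinct_markers(self, include_links: bool = False) -> np.ndarray:
        parts = [r.distinct_markers(include_links) for r in self.replicates]
        return np.unique(np.concatenate(parts)) if parts else np.array([], dtype=int)


# --------------------------------------------------------------------------
# MAF and LD primitives
# --------------------------------------------------------------------------

def compute_maf(column) -> float:
    """MAF = min(p, 1-p) with p the +1-allele frequency, missing excluded."""
    col = np.asarray(column, dtype=float)
    finite = col[np.isfinite(col)]
    if finite.size == 0:
        raise ValueError("all-missing genotype column")
    p = (2 * (finite == 1).sum() + (finite == 0).sum()) / (2 * finite.size)
    return float(min(p, 1 - p))


def maf_filter(geno: GenotypeMatrix, maf_above: float, maf_below: float) -> np.ndarray:
    """Indices of markers with maf_above < MAF < maf_below.

    Bounds are strict, except that maf_below = 0.5 (the maximum possible
    MAF) is inclusive so the (0, 0.5) window is vacuous on polymorphic data.
    """
    if not (0 <= maf_above < maf_below <= 0.5):
        raise ConfigurationError(
            f"need 0 <= maf_above < maf_below <= 0.5, got ({maf_above}, {maf_below})")
    maf = geno.maf()
    below = (maf <= 0.5) if maf_below == 0.5 else (maf < maf_below)
    eligible = np.flatnonzero((maf > maf_above) & below)
    if eligible.size == 0:
        raise ConfigurationError(
            f"no marker has MAF strictly inside ({maf_above}, {maf_below})")
    return eligible


def ld_r(col_a, col_b) -> float:
    """Pearson r of two coded genotype columns (composite LD), pairwise-complete."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("columns of unequal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance column in LD computation")
    return float(np.corrcoef(a, b)[0, 1])


# --------------------------------------------------------------------------
# per-replicate selection
# --------------------------------------------------------------------------

def _sample(rng: np.random.Generator, eligible: np.ndarray, k: int, what: str) -> np.ndarray:
    if k > eligible.size:
        raise ConfigurationError(
            f"{what}: need {k} markers but only {eligible.size} are eligible "
            f"under the MAF window")
    return rng.choice(eligible, size=k, replace=False)


def _split_trait(idx: np.ndarray, n_add: int, n_dom: int, n_epi: int) -> TraitQTNs:
    add = idx[:n_add]
    dom = idx[n_add:n_add + n_dom]
    epi = idx[n_add + n_dom:]
    pairs = [(int(epi[2 * k]), int(epi[2 * k + 1])) for k in range(n_epi)]
    return TraitQTNs(np.asarray(add, int), np.asarray(dom, int), pairs)


def select_pleiotropic(spec: ArchitectureSpec, eligible: np.ndarray,
                       rng: np.random.Generator) -> ReplicateAssignment:
    """One QTN set, identical for every trait (also serves single_trait)."""
    n_add, n_dom, n_epi = spec.add_qtn_num, spec.dom_qtn_num, spec.epi_qtn_num
    idx = _sample(rng, np.asarray(eligible), n_add + n_dom + 2 * n_epi, "pleiotropy")
    tq = _split_trait(idx, n_add, n_dom, n_epi)
    return ReplicateAssignment([replace(tq) for _ in range(spec.n_traits)])


def select_partial(spec: ArchitectureSpec, eligible: np.ndarray,
                   rng: np.random.Generator) -> ReplicateAssignment:
    """Shared QTNs for all traits plus disjoint trait-specific QTNs."""
    n_shared = spec.add_qtn_num + spec.dom_qtn_num + 2 * spec.epi_qtn_num
    per_trait = [spec.add_qtn_specific[t] + spec.dom_qtn_specific[t]
                 + 2 * spec.epi_qtn_specific[t] for t in range(spec.n_traits)]
    idx = _sample(rng, np.asarray(eligible), n_shared + sum(per_trait), "partial pleiotropy")
    shared, rest = idx[:n_shared], idx[n_shared:]
    traits, off = [], 0
    for t in range(spec.n_traits):
        own = rest[off:off + per_trait[t]]
        off += per_trait[t]
        # order: shared first (add, dom, epi), then trait-specific
        add = np.concatenate([shared[:spec.add_qtn_num], own[:spec.add_qtn_specific[t]]])
        dom = np.concatenate([
            shared[spec.add_qtn_num:spec.add_qtn_num + spec.dom_qtn_num],
            own[spec.add_qtn_specific[t]:spec.add_qtn_specific[t] + spec.dom_qtn_specific[t]],
        ])
        epi_flat = np.concatenate([
            shared[spec.add_qtn_num + spec.dom_qtn_num:],
            own[spec.add_qtn_specific[t] + spec.dom_qtn_specific[t]:],
        ])
        n_epi = spec.epi_qtn_num + spec.epi_qtn_specific[t]
        pairs = [(int(epi_flat[2 * k]), int(epi_flat[2 * k + 1])) for k in range(n_epi)]
        traits.append(TraitQTNs(add.astype(int), dom.astype(int), pairs))
    return ReplicateAssignment(traits)


def _scan_candidates(geno: GenotypeMatrix, anchor: int, eligible_set: set,
                     used: set, ceiling: float, side: str):
    """Qualifying (|r| <= ceiling) markers near ``anchor`` on one side.

    Scans up to :data:`SCAN_WINDOW` markers in map order on the same
    chromosome; returns (index, |r|, r) triples.
    """
    chrom = geno.marker_map["chrom"].to_numpy()
    step = -1 if side == "up" else 1
    out = []
    j = anchor + step
    scanned = 0
    while 0 <= j < geno.n_markers and scanned < SCAN_WINDOW:
        if chrom[j] != chrom[anchor]:
            break
        scanned += 1
        if j in eligible_set and j not in used:
            try:
                r = ld_r(geno.values[:, anchor], geno.values[:, j])
            except ValueError:
                j += step
                continue
            if abs(r) <= ceiling:
                out.append((j, abs(r), r))
        j += step
    return out


def _best(cands, ceiling: float):
    """Qualifying candidate with |r| closest to (but below) the ceiling."""
    return max(cands, key=lambda c: c[1]) if cands else None


def select_spurious(spec: ArchitectureSpec, geno: GenotypeMatrix,
                    eligible: np.ndarray, rng: np.random.Generator) -> ReplicateAssignment:
    """Disjoint per-trait QTNs tied together by LD.

    ``indirect`` mode: for each of ``add_qtn_num`` slots, draw a linking
    marker and take its nearest qualifying upstream marker as the trait-1 QTN
    and nearest qualifying downstream marker as the trait-2 QTN, each with
    |r(link, QTN)| <= ld_ceiling. ``direct`` mode: constrain the QTN pair
    itself, |r(QTN_1, QTN_2)| <= ld_ceiling. Realised r values are recorded.
    """
    eligible = np.asarray(eligible)
    eligible_set = set(int(i) for i in eligible)
    used: set[int] = set()
    q1, q2, records = [], [], []
    for _ in range(spec.add_qtn_num):
        found = False
        for _try in range(MAX_LINK_TRIES):
            anchor = int(rng.choice(eligible))
            if anchor in used:
                continue
            if spec.type_of_ld == "indirect":
                up = _best(_scan_candidates(geno, anchor, eligible_set, used | {anchor},
                                            spec.ld_ceiling, "up"), spec.ld_ceiling)
                down = _best(_scan_candidates(geno, anchor, eligible_set, used | {anchor},
                                              spec.ld_ceiling, "down"), spec.ld_ceiling)
                if up is None or down is None:
                    continue
                a, b = up[0], down[0]
                try:
                    r_ab = ld_r(geno.values[:, a], geno.values[:, b])
                except ValueError:
                    continue
                used.update({anchor, a, b})
                q1.append(a)
                q2.append(b)
                records.append(LDRecord(anchor, (a, b), (up[2], down[2]), r_ab,
                                        spec.ld_ceiling))
                found = True
                break
            else:  # direct: anchor is the trait-1 QTN, partner the trait-2 QTN
                cands = (_scan_candidates(geno, anchor, eligible_set, used | {anchor},
                                          spec.ld_ceiling, "up")
                         + _scan_candidates(geno, anchor, eligible_set, used | {anchor},
                                            spec.ld_ceiling, "down"))
                best = _best(cands, spec.ld_ceiling)
                if best is None:
                    continue
                b = best[0]
                used.update({anchor, b})
                q1.append(anchor)
                q2.append(b)
                records.append(LDRecord(None, (anchor, b), (), best[2], spec.ld_ceiling))
                found = True
                break
        if not found:
            raise ConfigurationError(
                "could not find a qualifying linking triple under "
                f"|r| <= {spec.ld_ceiling}; consider a larger ld ceiling or a "
                "panel with more LD")
    empty: list = []
    traits = [TraitQTNs(np.asarray(q1, int), np.array([], int), list(empty)),
              TraitQTNs(np.asarray(q2, int), np.array([], int), list(empty))]
    return ReplicateAssignment(traits, records)


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def assign_qtns(spec: ArchitectureSpec, geno: GenotypeMatrix) -> QTNAssignment:
    """Select QTNs for every replicate.

    With ``vary_qtn`` false the replicate-0 assignment is reused across all
    experiments; otherwise each replicate resamples from its own stream.
    Identical (spec, genotype, seed) give identical assignments.
    """
    eligible = maf_filter(geno, spec.maf_above, spec.maf_below)
    replicates = []
    for rep in range(spec.n_experiments):
        if rep > 0 and not spec.vary_qtn:
            replicates.append(replicates[0])
            continue
        rng = derive_rng(spec.seed, rep, "qtn")
        if spec.architecture in ("single_trait", "pleiotropy"):
            a = select_pleiotropic(spec, eligible, rng)
        elif spec.architecture == "partial_pleiotropy":
            a = select_partial(spec, eligible, rng)
        else:
            a = select_spurious(spec, geno, eligible, rng)
        _check_assignment(spec, geno, a)
        replicates.append(a)
    return QTNAssignment(spec, replicates)


def _check_assignment(spec: ArchitectureSpec, geno: GenotypeMatrix,
                      a: ReplicateAssignment) -> None:
    """Post-selection invariants: MAF window, no within-trait duplicates."""
    maf = geno.maf()
    for tq in a.traits:
        idx = tq.all_markers
        if idx.size != np.unique(idx).size:
            raise ConfigurationError("marker selected twice for one trait")
        below = (maf[idx] <= 0.5) if spec.maf_below == 0.5 else (maf[idx] < spec.maf_below)
        if idx.size and not ((maf[idx] > spec.maf_above) & below).all():
            raise ConfigurationError("selected QTN violates the MAF window")
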