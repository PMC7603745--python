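"""Reading, numericalising and writing biallelic marker data.

Supported input formats: numeric (-1/0/1 matrix with a map sidecar), HapMap
(tab-separated, 11 metadata columns), VCF 4.x (GT field only, via pysam) and
Plink ped/map text. Writers: numeric, HapMap and minimal VCF.

Numeric coding convention: for each biallelic marker one allele is designated
the "+1 direction" allele; +1 = homozygous for it, 0 = heterozygote, -1 = the
other homozygote. VCF carries ref/alt, so +1 = alt/alt there; for letter
formats without a reference direction (HapMap, ped) the alphabetically second
allele is +1, which makes the coding deterministic for a given file. The
direction is recorded per marker in the map (``allele_plus``) and all
simulated architectures are symmetric under flipping it.

Missing genotypes stay ``NaN`` in :class:`GenotypeMatrix.values`; the effect
engine mean-imputes them to 0 via :meth:`GenotypeMatrix.imputed`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["marker_id", "chrom", "pos", "allele_major", "allele_minor", "allele_plus", "cm"]

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

#: single-letter IUPAC heterozygote codes occasionally used in HapMap files
_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}

_MISSING_CALLS = {"NN", "N", "--", "00", "0", "", "??"}


class MarkerDataError(ValueError):
    """A marker file violated the format or biallelic contract."""


class MonomorphicMarkerError(MarkerDataError):
    """Marker has a single observed allele (cannot be coded or be a QTN)."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers in {-1, 0, 1, NaN} coding plus a marker map.

    ``marker_map`` is a DataFrame with columns :data:`MAP_COLUMNS`, one row
    per matrix column, in column order.
    """

    values: np.ndarray
    marker_map: pd.DataFrame
    individual_ids: list[str]
    n_dropped: int = 0  # multiallelic / monomorphic / all-missing markers dropped at read

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MarkerDataError("genotype values must be a 2-D matrix")
        self.individual_ids = [str(i) for i in self.individual_ids]
        if len(self.individual_ids) != self.values.shape[0]:
            raise MarkerDataError("individual_ids length does not match row count")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise MarkerDataError("individual ids are not unique")
        m = self.marker_map
        missing_cols = [c for c in MAP_COLUMNS if c not in m.columns]
        if missing_cols:
            raise MarkerDataError(f"marker map lacks columns {missing_cols}")
        if len(m) != self.values.shape[1]:
            raise MarkerDataError("marker map length does not match column count")
        if m["marker_id"].duplicated().any():
            dup = m.loc[m["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise MarkerDataError(f"duplicate marker id {dup!r}")
        if len(m) and (m["pos"].to_numpy() < 1).any():
            raise MarkerDataError("positions must be 1-based (>= 1)")
        if len(m) and (m["allele_major"] == m["allele_minor"]).any():
            bad = m.loc[m["allele_major"] == m["allele_minor"], "marker_id"].iloc[0]
            raise MarkerDataError(f"marker {bad!r} has identical major and minor alleles")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (-1.0, 0.0, 1.0)).all():
            raise MarkerDataError("genotype values outside {-1, 0, 1, NaN}")
        # positions must increase within each chromosome run (map order = file order)
        if len(m) > 1:
            chrom = m["chrom"].to_numpy()
            pos = m["pos"].to_numpy()
            same = chrom[1:] == chrom[:-1]
            if (pos[1:][same] < pos[:-1][same]).any():
                raise MarkerDataError("marker map not sorted by position within chromosome")

    # ------------------------------------------------------------------ basic
    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def imputed(self) -> tuple[np.ndarray, int]:
        """Values with missing genotypes imputed to 0 (heterozygote/mean).

        Returns the imputed matrix and the number of imputed calls.
        """
        miss = ~np.isfinite(self.values)
        out = np.where(miss, 0.0, self.values)
        n = int(miss.sum())
        if n:
            logger.info("imputed %d missing genotype calls to 0", n)
        return out, n

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker, missing calls excluded."""
        v = self.values
        nonmiss = np.isfinite(v).sum(axis=0)
        if (nonmiss == 0).any():
            raise MarkerDataError("all-missing marker column")
        p = (2 * np.nansum(v == 1, axis=0) + np.nansum(v == 0, axis=0)) / (2 * nonmiss)
        return np.minimum(p, 1 - p)

    def drop_markers(self, indices) -> "GenotypeMatrix":
        """New matrix without the given marker columns (map kept in sync)."""
        indices = sorted(set(int(i) for i in indices))
        if indices and (indices[0] < 0 or indices[-1] >= self.n_markers):
            raise MarkerDataError("marker index out of range")
        keep = np.setdiff1d(np.arange(self.n_markers), indices)
        if keep.size == 0:
            raise MarkerDataError("cannot drop every marker (empty marker set)")
        return GenotypeMatrix(
            self.values[:, keep],
            self.marker_map.iloc[keep].reset_index(drop=True),
            list(self.individual_ids),
        )


# --------------------------------------------------------------------------
# numericalisation
# --------------------------------------------------------------------------

def numericalize(calls, plus_allele: str | None = None):
    """Code diploid allele calls to {-1, 0, +1, NaN}.

    ``calls`` is a sequence of two-character strings (one letter per allele,
    e.g. ``"AG"``); entries in :data:`_MISSING_CALLS` become NaN. With no
    ``plus_allele`` given, the alphabetically second observed allele codes +1.

    Returns ``(codes, minus_allele, plus_allele)``. Raises
    :class:`MonomorphicMarkerError` for a single observed allele and
    :class:`MarkerDataError` if a third allele is observed.
    """
    pairs: list[str | None] = []
    observed: set[str] = set()
    for c in calls:
        c = str(c).strip().upper()
        if c in _MISSING_CALLS:
            pairs.append(None)
            continue
        if len(c) == 1:
            c = _IUPAC_HET.get(c, c * 2)
        if len(c) != 2:
            raise MarkerDataError(f"unparseable genotype call {c!r}")
        pairs.append(c)
        observed.update(c)
    if len(observed) > 2:
        raise MarkerDataError(f"more than two alleles observed: {sorted(observed)}")
    if len(observed) < 2:
        raise MonomorphicMarkerError(f"monomorphic marker (alleles {sorted(observed)})")
    a, b = sorted(observed)
    if plus_allele is None:
        plus_allele = b
    elif plus_allele not in observed:
        raise MarkerDataError(f"designated +1 allele {plus_allele!r} not observed")
    minus_allele = a if plus_allele == b else b
    codes = np.full(len(pairs), np.nan)
    for i, pr in enumerate(pairs):
        if pr is None:
            continue
        codes[i] = pr.count(plus_allele) - 1
    return codes, minus_allele, plus_allele


def _major_minor(codes: np.ndarray, minus: str, plus: str) -> tuple[str, str]:
    """Assign (major, minor) labels from realised frequency (ties: sort order)."""
    nonmiss = np.isfinite(codes).sum()
    p_plus = (2 * (codes == 1).sum() + (codes == 0).sum()) / (2 * nonmiss)
    if p_plus < 0.5:
        return minus, plus
    if p_plus > 0.5:
        return plus, minus
    a, b = sorted((minus, plus))
    return a, b


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

def read_genotypes(path, format: str | None = None, map_path=None) -> GenotypeMatrix:
    """Read biallelic marker data and numericalise to -1/0/1 coding.

    ``format`` is one of ``numeric``, ``hapmap``, ``vcf``, ``plink_ped``;
    when omitted it is inferred from the file name. Multiallelic,
    monomorphic and all-missing markers are dropped (count in
    ``result.n_dropped``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        name = path.name.lower()
        if name.endswith(".vcf") or name.endswith(".vcf.gz"):
            format = "vcf"
        elif ".hmp" in name or "hapmap" in name:
            format = "hapmap"
        elif name.endswith(".ped"):
            format = "plink_ped"
        else:
            format = "numeric"
    readers = {
        "numeric": _read_numeric,
        "hapmap": _read_hapmap,
        "vcf": _read_vcf,
        "plink_ped": _read_ped,
    }
    if format not in readers:
        raise MarkerDataError(f"unknown genotype format {format!r}")
    if format == "numeric":
        return _read_numeric(path, map_path)
    return readers[format](path)


def _finish(columns, rows_map, individual_ids, n_dropped) -> GenotypeMatrix:
    if not columns:
        raise MarkerDataError("no usable biallelic markers in file")
    values = np.column_stack(columns)
    mm = pd.DataFrame(rows_map, columns=MAP_COLUMNS)
    if n_dropped:
        logger.info("dropped %d multiallelic/monomorphic/all-missing markers", n_dropped)
    return GenotypeMatrix(values, mm, individual_ids, n_dropped=n_dropped)


def _read_numeric(path: Path, map_path=None) -> GenotypeMatrix:
    map_path = Path(map_path) if map_path is not None else Path(str(path) + ".map")
    if not map_path.exists():
        raise FileNotFoundError(f"numeric map sidecar not found: {map_path}")
    geno = pd.read_csv(path, sep="\t", dtype={0: str})
    mm = pd.read_csv(map_path, sep="\t", dtype={"marker_id": str, "chrom": str})
    ids = geno.iloc[:, 0].tolist()
    vals = geno.iloc[:, 1:]
    if list(vals.columns) != list(mm["marker_id"].astype(str)):
        raise MarkerDataError("numeric file marker columns do not match map sidecar order")
    arr = vals.to_numpy(dtype=float)
    bad = np.isfinite(arr) & ~np.isin(arr, (-1.0, 0.0, 1.0))
    if bad.any():
        j = int(np.argwhere(bad.any(axis=0))[0][0])
        raise MarkerDataError(
            f"non-biallelic coding in numeric input at marker {vals.columns[j]!r}"
        )
    for col in ("allele_major", "allele_minor", "allele_plus"):
        if col not in mm.columns:  # bare map: synthesise placeholder letters
            mm[col] = {"allele_major": "A", "allele_minor": "T", "allele_plus": "T"}[col]
    if "cm" not in mm.columns:
        mm["cm"] = np.nan
    # drop monomorphic / all-missing columns
    keep, n_dropped = [], 0
    for j in range(arr.shape[1]):
        col = arr[:, j]
        finite = col[np.isfinite(col)]
        if finite.size == 0 or np.unique(finite).size < 2:
            n_dropped += 1
        else:
            keep.append(j)
    if not keep:
        raise MarkerDataError("no polymorphic markers in numeric file")
    gm = GenotypeMatrix(
        arr[:, keep], mm.iloc[keep].reset_index(drop=True)[MAP_COLUMNS], ids, n_dropped=n_dropped
    )
    return gm


def _read_hapmap(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 12:
        raise MarkerDataError(f"{path}: HapMap file needs 11 metadata columns plus genotypes")
    ids = list(df.columns[11:])
    columns, rows, n_dropped = [], [], 0
    for i, row in df.iterrows():
        calls = [row.iloc[11 + k] for k in range(len(ids))]
        try:
            codes, minus, plus = numericalize(calls)
        except MonomorphicMarkerError:
            n_dropped += 1
            continue
        except MarkerDataError:
            n_dropped += 1
            continue
        major, minor = _major_minor(codes, minus, plus)
        try:
            pos = int(row.iloc[3])
        except (TypeError, ValueError):
            raise MarkerDataError(f"{path}: bad position on data line {i + 2}")
        columns.append(codes)
        rows.append([str(row.iloc[0]), str(row.iloc[2]), pos, major, minor, plus, np.nan])
    return _finish(columns, rows, ids, n_dropped)


def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        ids = list(vf.header.samples)
        columns, rows, n_dropped = [], [], 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_dropped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            codes = np.full(len(ids), np.nan)
            for k, sample in enumerate(ids):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                codes[k] = sum(gt) - 1  # alt/alt -> +1
            finite = codes[np.isfinite(codes)]
            if finite.size == 0 or np.unique(finite).size < 2:
                n_dropped += 1
                continue
            major, minor = _major_minor(codes, ref, alt)
            marker_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
            columns.append(codes)
            rows.append([marker_id, str(rec.chrom), int(rec.pos), major, minor, alt, np.nan])
    return _finish(columns, rows, ids, n_dropped)


def _read_ped(path: Path) -> GenotypeMatrix:
    map_path = path.with_suffix(".map")
    if not map_path.exists():
        raise FileNotFoundError(f"Plink map file not found: {map_path}")
    mm = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if mm.shape[1] < 4:
        raise MarkerDataError(f"{map_path}: Plink map needs 4 columns (chrom id cm pos)")
    ids, call_rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(mm):
                raise MarkerDataError(f"{path}: line {lineno} has wrong field count")
            ids.append(parts[1])
            call_rows.append(parts[6:])
    columns, rows, n_dropped = [], [], 0
    for j in range(len(mm)):
        calls = [call_rows[i][2 * j] + call_rows[i][2 * j + 1] for i in range(len(ids))]
        try:
            codes, minus, plus = numericalize(calls)
        except MarkerDataError:
            n_dropped += 1
            continue
        major, minor = _major_minor(codes, minus, plus)
        cm = float(mm.iloc[j, 2]) if float(mm.iloc[j, 2]) != 0 else np.nan
        columns.append(codes)
        rows.append([str(mm.iloc[j, 1]), str(mm.iloc[j, 0]), int(mm.iloc[j, 3]),
                     major, minor, plus, cm])
    return _finish(columns, rows, ids, n_dropped)


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def write_markers(geno: GenotypeMatrix, path, format: str = "numeric",
                  exclude=(), map_path=None):
    """Write marker data, optionally excluding columns (e.g. QTN markers).

    Formats: ``numeric`` (with map sidecar), ``hapmap``, ``vcf``. The written
    file round-trips through :func:`read_genotypes` to the same matrix minus
    the excluded columns (for HapMap this requires the +1 allele to sort
    alphabetically second, which fixture data guarantees).
    """
    exclude = sorted(set(int(i) for i in exclude))
    if exclude:
        if exclude[0] < 0 or exclude[-1] >= geno.n_markers:
            raise MarkerDataError("exclude index out of range")
        if len(exclude) == geno.n_markers:
            raise MarkerDataError("cannot exclude every marker (empty marker set)")
        geno = geno.drop_markers(exclude)
    path = Path(path)
    if format == "numeric":
        _write_numeric(geno, path, map_path)
    elif format == "hapmap":
        _write_hapmap(geno, path)
    elif format == "vcf":
        _write_vcf(geno, path)
    else:
        raise MarkerDataError(f"unknown marker output format {format!r}")
    return path


def _fmt_code(v: float) -> str:
    return "NA" if not np.isfinite(v) else str(int(v))


def _write_numeric(geno: GenotypeMatrix, path: Path, map_path=None) -> None:
    map_path = Path(map_path) if map_path is not None else Path(str(path) + ".map")
    with open(path, "w") as fh:
        fh.write("taxa\t" + "\t".join(geno.marker_map["marker_id"]) + "\n")
        for i, ind in enumerate(geno.individual_ids):
            fh.write(ind + "\t" + "\t".join(_fmt_code(v) for v in geno.values[i]) + "\n")
    geno.marker_map[MAP_COLUMNS].to_csv(map_path, sep="\t", index=False)


def _calls_for(geno: GenotypeMatrix, j: int) -> list[str]:
    row = geno.marker_map.iloc[j]
    plus = row["allele_plus"]
    minus = row["allele_major"] if row["allele_minor"] == plus else row["allele_minor"]
    out = []
    for v in geno.values[:, j]:
        if not np.isfinite(v):
            out.append(None)
        elif v == 1:
            out.append(plus + plus)
        elif v == -1:
            out.append(minus + minus)
        else:
            a, b = sorted((minus, plus))
            out.append(a + b)
    return out


def _write_hapmap(geno: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + list(geno.individual_ids)) + "\n")
        for j in range(geno.n_markers):
            row = geno.marker_map.iloc[j]
            a, b = sorted((row["allele_major"], row["allele_minor"]))
            calls = ["NN" if c is None else c for c in _calls_for(geno, j)]
            fields = [row["marker_id"], f"{a}/{b}", str(row["chrom"]), str(int(row["pos"])),
                      "+", "NA", "NA", "NA", "NA", "NA", "NA"] + calls
            fh.write("\t".join(fields) + "\n")


def _write_vcf(geno: GenotypeMatrix, path: Path) -> None:
    chroms = list(dict.fromkeys(geno.marker_map["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pleiosim\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.individual_ids) + "\n")
        gtmap = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}
        for j in range(geno.n_markers):
            row = geno.marker_map.iloc[j]
            plus = row["allele_plus"]
            ref = row["allele_major"] if row["allele_minor"] == plus else row["allele_minor"]
            gts = ["./." if not np.isfinite(v) else gtmap[v] for v in geno.values[:, j]]
            fh.write("\t".join([str(row["chrom"]), str(int(row["pos"])), row["marker_id"],
                                ref, plus, ".", "PASS", ".", "GT"] + gts) + "\n")
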