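"""Phenotype writers and provenance tables.

Phenotype formats:

* ``gemma`` — whitespace-separated trait columns, no header, rows in
  genotype-file individual order, ``NA`` for missing (GEMMA's -p input);
* ``tassel`` — TASSEL v5 trait-format text: ``<Phenotype>`` directive,
  a ``taxa/data`` type line, a header row, then one row per individual;
* ``wide_table`` — tab-separated, taxa column plus one column per trait;
* ``long_table`` — tidy table (taxa, replicate, trait, value).

Provenance: a QTN map table (replication, marker type, marker, alleles,
chromosome, position, cM, MAF) and, for spurious pleiotropy, an LD summary
(linking marker, input LD bound, realised LD with each trait's QTN, the QTN
ids, and the QTN-QTN LD).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .marker_io import GenotypeMatrix
from .qtn import QTNAssignment

PHENOTYPE_FORMATS = ("gemma", "tassel", "wide_table", "long_table")

_FLOAT_FMT = "%.17g"  # round-trips doubles exactly: realised statistics in the
# tables stay recomputable from the emitted phenotype files to machine precision


def _fmt(v: float) -> str:
    return "NA" if not np.isfinite(v) else _FLOAT_FMT % v


def write_phenotypes(P, format: str, path, individual_ids, trait_names=None):
    """Write one replicate's individuals x traits phenotype matrix."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if trait_names is None:
        trait_names = [f"trait_{t + 1}" for t in range(P.shape[1])]
    path = Path(path)
    if format == "gemma":
        with open(path, "w") as fh:
            for row in P:
                fh.write(" ".join(_fmt(v) for v in row) + "\n")
    elif format == "tassel":
        with open(path, "w") as fh:
            fh.write("<Phenotype>\n")
            fh.write("taxa\t" + "\t".join(["data"] * P.shape[1]) + "\n")
            fh.write("Taxa\t" + "\t".join(trait_names) + "\n")
            for ind, row in zip(individual_ids, P):
                fh.write(str(ind) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    elif format == "wide_table":
        with open(path, "w") as fh:
            fh.write("taxa\t" + "\t".join(trait_names) + "\n")
            for ind, row in zip(individual_ids, P):
                fh.write(str(ind) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    else:
        raise ValueError(f"unknown phenotype format {format!r} "
                         f"(choose from {PHENOTYPE_FORMATS})")
    return path


def read_tassel_phenotypes(path) -> pd.DataFrame:
    """Parse a TASSEL trait-format file back to a taxa-indexed DataFrame."""
    with open(path) as fh:
        first = fh.readline().strip()
        if first != "<Phenotype>":
            raise ValueError(f"{path}: not a TASSEL phenotype file")
        fh.readline()  # type line
        header = fh.readline().rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", names=header, na_values=["NA"])
    return df.set_index("Taxa")


def write_long_table(records: list, path) -> Path:
    """Tidy phenotype table across replicates: taxa, replicate, trait, value."""
    rows = []
    for rep, (ids, P, trait_names) in enumerate(records, start=1):
        for t, name in enumerate(trait_names):
            for ind, v in zip(ids, P[:, t]):
                rows.append((ind, rep, name, v))
    df = pd.DataFrame(rows, columns=["taxa", "replicate", "trait", "value"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return Path(path)


# --------------------------------------------------------------------------
# provenance tables
# --------------------------------------------------------------------------

QTN_MAP_COLUMNS = ["Replication", "Marker type", "Marker", "Allele",
                   "Chromosome", "Position", "cM", "MAF"]

LD_SUMMARY_COLUMNS = ["Replication", "Marker causing LD", "input LD (absolute value)",
                      "Actual LD with QTN of Trait 1", "Actual LD with QTN of Trait 2",
                      "QTN for Trait 1", "QTN for Trait 2", "LD between QTNs"]


def _map_row(geno: GenotypeMatrix, maf: np.ndarray, rep: int, kind: str, j: int) -> dict:
    row = geno.marker_map.iloc[j]
    cm = row["cm"]
    return {
        "Replication": rep,
        "Marker type": kind,
        "Marker": row["marker_id"],
        "Allele": f"{row['allele_major']}/{row['allele_minor']}",
        "Chromosome": row["chrom"],
        "Position": int(row["pos"]),
        "cM": float(cm) if np.isfinite(cm) else np.nan,
        "MAF": round(float(maf[j]), 4),
    }


def qtn_map_table(assignment: QTNAssignment, geno: GenotypeMatrix) -> pd.DataFrame:
    """Map and MAF of every selected marker, per replicate (QTN map schema)."""
    maf = geno.maf()
    spec = assignment.spec
    rows = []
    for rep, a in enumerate(assignment.replicates, start=1):
        if spec.architecture == "spurious_pleiotropy":
            for rec in a.ld_records:
                if rec.link_idx is not None:
                    rows.append(_map_row(geno, maf, rep, "cause_of_LD", rec.link_idx))
            for rec in a.ld_records:
                rows.append(_map_row(geno, maf, rep, "QTN_upstream", rec.qtn_idx[0]))
            for rec in a.ld_records:
                rows.append(_map_row(geno, maf, rep, "QTN_downstream", rec.qtn_idx[1]))
        elif spec.architecture == "partial_pleiotropy":
            shared_seen: set[int] = set()
            for t, tq in enumerate(a.traits, start=1):
                for kind, idx in (("additive", tq.additive), ("dominance", tq.dominance)):
                    n_shared = {"additive": spec.add_qtn_num,
                                "dominance": spec.dom_qtn_num}[kind]
                    for k, j in enumerate(idx):
                        if k < n_shared:
                            if j in shared_seen:
                                continue
                            shared_seen.add(int(j))
                            rows.append(_map_row(geno, maf, rep, f"QTN_{kind}_shared", j))
                        else:
                            rows.append(_map_row(geno, maf, rep, f"QTN_{kind}_trait_{t}", j))
                for k, (j1, j2) in enumerate(tq.epistatic_pairs):
                    shared = k < spec.epi_qtn_num
                    for j in (j1, j2):
                        if shared:
                            if j in shared_seen:
                                continue
                            shared_seen.add(int(j))
                        kind2 = "QTN_epistatic_shared" if shared else f"QTN_epistatic_trait_{t}"
                        rows.append(_map_row(geno, maf, rep, kind2, j))
        else:  # single trait / full pleiotropy: one shared set
            tq = a.traits[0]
            for j in tq.additive:
                rows.append(_map_row(geno, maf, rep, "QTN_additive", j))
            for j in tq.dominance:
                rows.append(_map_row(geno, maf, rep, "QTN_dominance", j))
            for j1, j2 in tq.epistatic_pairs:
                rows.append(_map_row(geno, maf, rep, "QTN_epistatic", j1))
                rows.append(_map_row(geno, maf, rep, "QTN_epistatic", j2))
    return pd.DataFrame(rows, columns=QTN_MAP_COLUMNS)


def ld_summary_table(assignment: QTNAssignment, geno: GenotypeMatrix) -> pd.DataFrame:
    """Realised LD around each linking slot (spurious pleiotropy only)."""
    ids = geno.marker_map["marker_id"]
    rows = []
    for rep, a in enumerate(assignment.replicates, start=1):
        for rec in a.ld_records:
            link = ids.iloc[rec.link_idx] if rec.link_idx is not None else "NA"
            r1 = round(rec.r_link_qtn[0], 2) if rec.r_link_qtn else np.nan
            r2 = round(rec.r_link_qtn[1], 2) if rec.r_link_qtn else np.nan
            rows.append({
                "Replication": rep,
                "Marker causing LD": link,
                "input LD (absolute value)": round(rec.input_ld, 2),
                "Actual LD with QTN of Trait 1": r1,
                "Actual LD with QTN of Trait 2": r2,
                "QTN for Trait 1": ids.iloc[rec.qtn_idx[0]],
                "QTN for Trait 2": ids.iloc[rec.qtn_idx[1]],
                "LD between QTNs": round(rec.r_qtn_qtn, 2),
            })
    return pd.DataFrame(rows, columns=LD_SUMMARY_COLUMNS)


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
    return Path(path)
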