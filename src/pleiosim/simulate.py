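"""The simulation driver: validate a configuration, run replicates, write
phenotypes, provenance and the log.

Pipeline per replicate: select QTNs -> genetic values -> optional
whitening/coloring (when a target genetic correlation is given) -> residual
variance from the target heritabilities -> correlated-or-independent normal
errors -> phenotype = genetic value + error. Everything downstream of the
root seed is deterministic, including output bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import outputs
from ._rand import derive_rng, spawn_key
from .correlate import validate_correlation_matrix, whiten_color
from .effects import EffectSpec, aggregate_genetic_values, variance_explained
from .marker_io import GenotypeMatrix, read_genotypes, write_markers
from .noise import assemble_phenotypes, realized_h2, residual_variance, simulate_errors
from .qtn import ArchitectureSpec, ConfigurationError, assign_qtns


@dataclass
class SimulationConfig:
    """Full user configuration for one run of the simulator."""

    arch: ArchitectureSpec
    effects: EffectSpec
    h2: list
    cor: np.ndarray | None = None          # target genetic correlation Sigma'
    cor_res: np.ndarray | None = None      # residual correlation
    remove_qtn: bool = False
    output_formats: tuple = ("wide_table",)
    marker_out_format: str = "numeric"
    prefix: str = "sim"

    def __post_init__(self) -> None:
        self.h2 = [float(h) for h in np.atleast_1d(self.h2)]
        if len(self.h2) == 1 and self.arch.n_traits > 1:
            self.h2 = self.h2 * self.arch.n_traits
        if len(self.h2) != self.arch.n_traits:
            raise ConfigurationError(
                f"h2 has {len(self.h2)} entries for {self.arch.n_traits} traits")
        for h in self.h2:
            if not (0 < h <= 1):
                raise ConfigurationError(f"heritability must be in (0, 1], got {h}")
        self.effects.validate(self.arch)
        if self.cor is not None:
            self.cor = validate_correlation_matrix(self.cor, "cor (Sigma')")
            if self.cor.shape[0] != self.arch.n_traits:
                raise ConfigurationError("cor dimension does not match ntraits")
        if self.cor_res is not None:
            self.cor_res = validate_correlation_matrix(self.cor_res, "cor_res")
            if self.cor_res.shape[0] != self.arch.n_traits:
                raise ConfigurationError("cor_res dimension does not match ntraits")
        bad = [f for f in self.output_formats if f not in outputs.PHENOTYPE_FORMATS]
        if bad:
            raise ConfigurationError(
                f"unknown output formats {bad}; choose from {outputs.PHENOTYPE_FORMATS}")

    def echo(self) -> dict:
        """Plain-dict configuration echo for the log."""
        d = {
            "architecture": self.arch.architecture,
            "ntraits": self.arch.n_traits,
            "rep": self.arch.n_experiments,
            "vary_QTN": self.arch.vary_qtn,
            "seed": self.arch.seed,
            "add_QTN_num": self.arch.add_qtn_num,
            "dom_QTN_num": self.arch.dom_qtn_num,
            "epi_QTN_num": self.arch.epi_qtn_num,
            "maf_above": self.arch.maf_above,
            "maf_below": self.arch.maf_below,
            "ld": self.arch.ld_ceiling,
            "type_of_ld": self.arch.type_of_ld,
            "h2": list(self.h2),
            "add_effect": [list(map(float, e)) for e in self.effects.additive],
            "dom_effect": [list(map(float, e)) for e in self.effects.dominance],
            "epi_effect": [list(map(float, e)) for e in self.effects.epistatic],
            "cor": None if self.cor is None else self.cor.tolist(),
            "cor_res": None if self.cor_res is None else self.cor_res.tolist(),
            "remove_QTN": self.remove_qtn,
            "output_format": list(self.output_formats),
        }
        if self.arch.architecture == "partial_pleiotropy":
            d["add_QTN_specific"] = list(self.arch.add_qtn_specific)
            d["dom_QTN_specific"] = list(self.arch.dom_qtn_specific)
            d["epi_QTN_specific"] = list(self.arch.epi_qtn_specific)
        return d


@dataclass
class SimulationResult:
    """In-memory results of every replicate plus realised statistics."""

    config: SimulationConfig
    assignment: object
    genetic_values: list        # per replicate, n x t (post-transform)
    errors: list                # per replicate, n x t
    phenotypes: list            # per replicate, n x t
    realized_h2: np.ndarray     # reps x traits
    realized_gen_corr: list     # per replicate t x t (or None)
    realized_res_corr: list
    variance_explained: object  # DataFrame across replicates
    individual_ids: list
    files: list = field(default_factory=list)
    out_dir: Path | None = None


def simulate_traits(geno: GenotypeMatrix, config: SimulationConfig) -> SimulationResult:
    """Run all replicates in memory (no files written)."""
    arch = config.arch
    assignment = assign_qtns(arch, geno)
    G_list, E_list, P_list = [], [], []
    h2_rows, gc_list, rc_list, ve_frames = [], [], [], []
    for rep in range(arch.n_experiments):
        gv = aggregate_genetic_values(geno, assignment.replicates[rep], config.effects)
        var_g_pre = gv.values.var(axis=0, ddof=1)
        var_p_implied = np.where(np.asarray(config.h2) > 0,
                                 var_g_pre / np.asarray(config.h2), np.nan)
        ve = variance_explained(gv, var_p_implied)
        ve.insert(0, "replicate", rep + 1)
        ve_frames.append(ve)
        if config.cor is not None and arch.n_traits > 1:
            G = whiten_color(gv.values, config.cor)
        else:
            G = gv.values
        var_g = G.var(axis=0, ddof=1)
        var_e = [residual_variance(var_g[t], config.h2[t]) for t in range(arch.n_traits)]
        E = simulate_errors(geno.n_individuals, var_e, config.cor_res,
                            derive_rng(arch.seed, rep, "noise"))
        P = assemble_phenotypes(G, E)
        G_list.append(G)
        E_list.append(E)
        P_list.append(P)
        h2_rows.append(realized_h2(G, E))
        if arch.n_traits > 1:
            gc_list.append(np.corrcoef(G, rowvar=False))
            rc_list.append(np.corrcoef(E, rowvar=False)
                           if all(v > 0 for v in var_e) else None)
        else:
            gc_list.append(None)
            rc_list.append(None)
    import pandas as pd
    return SimulationResult(
        config=config,
        assignment=assignment,
        genetic_values=G_list,
        errors=E_list,
        phenotypes=P_list,
        realized_h2=np.vstack(h2_rows),
        realized_gen_corr=gc_list,
        realized_res_corr=rc_list,
        variance_explained=pd.concat(ve_frames, ignore_index=True),
        individual_ids=list(geno.individual_ids),
    )


def create_phenotypes(geno, config: SimulationConfig, out_dir) -> SimulationResult:
    """Run the simulation and write phenotypes, provenance, seeds and log.

    ``geno`` is a :class:`GenotypeMatrix` or a marker file path. The output
    directory is byte-identical across reruns with the same config and seed.
    """
    if not isinstance(geno, GenotypeMatrix):
        geno = read_genotypes(geno)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = simulate_traits(geno, config)
    res.out_dir = out_dir
    arch, prefix = config.arch, config.prefix
    trait_names = [f"trait_{t + 1}" for t in range(arch.n_traits)]
    ext = {"gemma": "gemma.txt", "tassel": "tassel.txt", "wide_table": "tsv"}
    files: list[Path] = []
    long_records = []
    for rep, P in enumerate(res.phenotypes, start=1):
        for fmt in config.output_formats:
            if fmt == "long_table":
                continue
            path = out_dir / f"{prefix}_rep{rep}.{ext[fmt]}"
            outputs.write_phenotypes(P, fmt, path, res.individual_ids, trait_names)
            files.append(path)
        long_records.append((res.individual_ids, P, trait_names))
    if "long_table" in config.output_formats:
        files.append(outputs.write_long_table(long_records,
                                              out_dir / f"{prefix}_long.tsv"))
    # provenance
    files.append(outputs.write_table(outputs.qtn_map_table(res.assignment, geno),
                                     out_dir / f"{prefix}_qtn_map.tsv"))
    if arch.architecture == "spurious_pleiotropy":
        files.append(outputs.write_table(outputs.ld_summary_table(res.assignment, geno),
                                         out_dir / f"{prefix}_ld_summary.tsv"))
    files.append(outputs.write_table(res.variance_explained,
                                     out_dir / f"{prefix}_variance_explained.tsv"))
    files.append(_write_summary(res, out_dir / f"{prefix}_summary.tsv"))
    files.append(_write_seeds(arch, out_dir / f"{prefix}_seeds.txt"))
    if config.remove_qtn:
        # QTNs removed; linking markers kept (they are the discoverable signal)
        qtn_idx = res.assignment.distinct_markers(include_links=False)
        ext2 = {"numeric": "num.txt", "hapmap": "hmp.txt", "vcf": "vcf"}
        path = out_dir / f"{prefix}_markers_no_qtn.{ext2[config.marker_out_format]}"
        write_markers(geno, path, config.marker_out_format, exclude=qtn_idx)
        files.append(path)
        if config.marker_out_format == "numeric":
            files.append(Path(str(path) + ".map"))
    files.append(_write_log(res, files, out_dir / f"{prefix}.log"))
    res.files = files
    return res


def _write_summary(res: SimulationResult, path: Path) -> Path:
    import pandas as pd
    rows = []
    for rep in range(len(res.phenotypes)):
        for t in range(res.config.arch.n_traits):
            rows.append({
                "replicate": rep + 1,
                "trait": t + 1,
                "target_h2": res.config.h2[t],
                "realized_h2": res.realized_h2[rep, t],
                "var_g": res.genetic_values[rep][:, t].var(ddof=1),
                "var_e": res.errors[rep][:, t].var(ddof=1),
            })
    # %.17g: realised h2 must be recomputable from the files to ~1e-12
    return outputs.write_table(pd.DataFrame(rows), path, float_format="%.17g")


def _write_seeds(arch: ArchitectureSpec, path: Path) -> Path:
    """Persist the root seed and per-replicate stream spawn keys."""
    with open(path, "w") as fh:
        fh.write(f"root_seed\t{arch.seed}\n")
        fh.write("replicate\tqtn_spawn_key\tnoise_spawn_key\n")
        for rep in range(arch.n_experiments):
            qrep = rep if arch.vary_qtn else 0
            fh.write(f"{rep + 1}\t{spawn_key(qrep, 'qtn')}\t{spawn_key(rep, 'noise')}\n")
    return path


def _matrix_lines(name: str, mat) -> list[str]:
    out = [f"{name}:"]
    for row in np.atleast_2d(mat):
        out.append("  " + "  ".join(f"{v: .6f}" for v in row))
    return out


def _write_log(res: SimulationResult, files: list, path: Path) -> Path:
    cfg = res.config
    lines = ["# pleiosim simulation log", "", "## configuration", ""]
    lines += yaml.safe_dump(cfg.echo(), sort_keys=True).rstrip().splitlines()
    lines += ["", "## realised statistics", ""]
    lines.append("mean realised h2 per trait (target in parentheses):")
    mean_h2 = res.realized_h2.mean(axis=0)
    for t in range(cfg.arch.n_traits):
        lines.append(f"  trait {t + 1}: {mean_h2[t]:.6f} (target {cfg.h2[t]})")
    if cfg.arch.n_traits > 1:
        mean_gc = np.mean([g for g in res.realized_gen_corr if g is not None], axis=0)
        lines += _matrix_lines("mean realised genetic correlation", mean_gc)
        if cfg.cor is not None:
            lines += _matrix_lines("target genetic correlation (cor)", cfg.cor)
        rcs = [r for r in res.realized_res_corr if r is not None]
        if rcs:
            lines += _matrix_lines("mean realised residual correlation", np.mean(rcs, axis=0))
        if cfg.cor_res is not None:
            lines += _matrix_lines("target residual correlation (cor_res)", cfg.cor_res)
    lines += ["", "## files written", ""]
    lines += sorted(f"  {Path(f).name}" for f in files)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
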