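"""Declarative YAML configuration.

One file describes a whole run; keys use the argument names conventional
for trait simulators in this field (``add_QTN_num``, ``maf_above``,
``maf_below``, ``ld``, ``type_of_ld``, ``vary_QTN``, ``remove_QTN``,
``cor``, ``cor_res``, ``rep``, ``h2``) for discoverability, plus a
genotype source: either ``geno_file``/``geno_format`` or a ``fixture``
mapping for a synthetic panel.

Effect sizes: ``add_effect`` (and ``dom_effect``/``epi_effect``) are either
one list of per-QTN sizes per trait, or — with ``sim_method: geometric`` —
one base value per trait from which the geometric series base^1..base^n is
built.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .effects import EffectSpec
from .fixtures import FixtureSpec, LDBlock, make_fixture
from .marker_io import GenotypeMatrix, read_genotypes
from .qtn import ArchitectureSpec, ConfigurationError
from .simulate import SimulationConfig


def _per_trait_lists(value, n_traits: int, name: str):
    if value is None:
        return [[] for _ in range(n_traits)]
    if not isinstance(value, (list, tuple)) or (value and not
                                                isinstance(value[0], (list, tuple))):
        raise ConfigurationError(
            f"{name} must be a list with one list of effect sizes per trait "
            "(or use sim_method: geometric with one base per trait)")
    if len(value) != n_traits:
        raise ConfigurationError(f"{name} has {len(value)} entries for {n_traits} traits")
    return [[float(x) for x in v] for v in value]


def parse_config(raw: dict) -> tuple[dict, SimulationConfig]:
    """Validate a raw config mapping; returns (genotype source, SimulationConfig)."""
    known = {
        "geno_file", "geno_format", "fixture", "architecture", "ntraits", "rep",
        "vary_QTN", "seed", "add_QTN_num", "dom_QTN_num", "epi_QTN_num",
        "add_QTN_specific", "dom_QTN_specific", "epi_QTN_specific",
        "sim_method", "add_effect", "dom_effect", "epi_effect", "h2",
        "cor", "cor_res", "ld", "type_of_ld", "maf_above", "maf_below",
        "remove_QTN", "output_format", "marker_out_format", "prefix",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    if ("geno_file" in raw) == ("fixture" in raw):
        raise ConfigurationError("give exactly one of geno_file or fixture")

    arch = ArchitectureSpec(
        architecture=raw.get("architecture", "single_trait"),
        n_traits=int(raw.get("ntraits", 1)),
        add_qtn_num=int(raw.get("add_QTN_num", 0)),
        dom_qtn_num=int(raw.get("dom_QTN_num", 0)),
        epi_qtn_num=int(raw.get("epi_QTN_num", 0)),
        add_qtn_specific=raw.get("add_QTN_specific"),
        dom_qtn_specific=raw.get("dom_QTN_specific"),
        epi_qtn_specific=raw.get("epi_QTN_specific"),
        ld_ceiling=float(raw.get("ld", 0.7)),
        type_of_ld=raw.get("type_of_ld", "indirect"),
        maf_above=float(raw.get("maf_above", 0.0)),
        maf_below=float(raw.get("maf_below", 0.5)),
        vary_qtn=bool(raw.get("vary_QTN", False)),
        seed=int(raw.get("seed", 0)),
        n_experiments=int(raw.get("rep", 1)),
    )
    if raw.get("sim_method", "custom") == "geometric":
        effects = EffectSpec.from_geometric(
            arch, raw.get("add_effect"), raw.get("dom_effect"), raw.get("epi_effect"))
    else:
        effects = EffectSpec(
            _per_trait_lists(raw.get("add_effect"), arch.n_traits, "add_effect"),
            _per_trait_lists(raw.get("dom_effect"), arch.n_traits, "dom_effect"),
            _per_trait_lists(raw.get("epi_effect"), arch.n_traits, "epi_effect"),
        )
    if "h2" not in raw:
        raise ConfigurationError("h2 is required")
    fmts = raw.get("output_format", ["wide_table"])
    if isinstance(fmts, str):
        fmts = [fmts]
    cfg = SimulationConfig(
        arch=arch,
        effects=effects,
        h2=raw["h2"],
        cor=None if raw.get("cor") is None else np.asarray(raw["cor"], dtype=float),
        cor_res=None if raw.get("cor_res") is None
        else np.asarray(raw["cor_res"], dtype=float),
        remove_qtn=bool(raw.get("remove_QTN", False)),
        output_formats=tuple(fmts),
        marker_out_format=raw.get("marker_out_format", "numeric"),
        prefix=raw.get("prefix", "sim"),
    )
    source = {k: raw[k] for k in ("geno_file", "geno_format", "fixture") if k in raw}
    return source, cfg


def load_config(path) -> tuple[dict, SimulationConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: configuration must be a mapping")
    return parse_config(raw)


def load_genotypes(source: dict, base_dir=None) -> GenotypeMatrix:
    """Materialise the genotype source named in a config."""
    if "geno_file" in source:
        path = Path(source["geno_file"])
        if base_dir is not None and not path.is_absolute():
            path = Path(base_dir) / path
        return read_genotypes(path, source.get("geno_format"))
    fx = dict(source["fixture"])
    blocks = tuple(
        LDBlock(int(b["n_markers"]), float(b["target_r"]), b.get("decay", "constant"))
        for b in fx.pop("ld_blocks", [])
    )
    if "maf_bounds" in fx:
        fx["maf_bounds"] = tuple(float(x) for x in fx["maf_bounds"])
    return make_fixture(FixtureSpec(ld_blocks=blocks, **fx))
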