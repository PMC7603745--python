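import hashlib

import numpy as np
import pandas as pd
import pytest
import yaml

from pleiosim.config import load_config, load_genotypes, parse_config
from pleiosim.effects import EffectSpec
from pleiosim.marker_io import read_genotypes
from pleiosim.outputs import read_tassel_phenotypes, write_phenotypes
from pleiosim.qtn import ArchitectureSpec, ConfigurationError
from pleiosim.simulate import SimulationConfig, create_phenotypes, simulate_traits


def canonical_spurious_config(seed=5, n_experiments=2, **kw):
    """Spurious-indirect two-trait run: 3 additive QTNs, h2 = 0.5 both,
    effects (0.2, 0.1, 0.05) / (0.3, 0.2, 0.1), LD ceiling 0.7."""
    arch = ArchitectureSpec("spurious_pleiotropy", n_traits=2, add_qtn_num=3,
                            ld_ceiling=0.7, type_of_ld="indirect",
                            maf_above=0.05, maf_below=0.45, seed=seed,
                            n_experiments=n_experiments, vary_qtn=True)
    eff = EffectSpec([[0.2, 0.1, 0.05], [0.3, 0.2, 0.1]], [[], []], [[], []])
    base = dict(arch=arch, effects=eff, h2=[0.5, 0.5])
    base.update(kw)
    return SimulationConfig(**base)


def dir_digest(path):
    h = hashlib.sha256()
    for f in sorted(p for p in path.rglob("*") if p.is_file()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


# ------------------------------------------------------------ end to end

def test_spurious_run_outputs_and_marker_removal(ld_panel, tmp_path):
    cfg = canonical_spurious_config(remove_qtn=True,
                               output_formats=("gemma", "tassel", "wide_table"))
    res = create_phenotypes(ld_panel, cfg, tmp_path)
    # two-trait phenotype file in every format, per replicate
    gemma = np.loadtxt(tmp_path / "sim_rep1.gemma.txt")
    assert gemma.shape == (ld_panel.n_individuals, 2)
    # QTN map and LD summary provenance exist with the expected schemas
    qtn = pd.read_csv(tmp_path / "sim_qtn_map.tsv", sep="\t")
    assert list(qtn.columns) == ["Replication", "Marker type", "Marker", "Allele",
                                 "Chromosome", "Position", "cM", "MAF"]
    assert set(qtn["Marker type"]) == {"cause_of_LD", "QTN_upstream", "QTN_downstream"}
    ld = pd.read_csv(tmp_path / "sim_ld_summary.tsv", sep="\t")
    assert (ld["input LD (absolute value)"] == 0.7).all()
    assert (ld["Actual LD with QTN of Trait 1"].abs() <= 0.7).all()
    # marker file: QTNs removed, linking markers kept
    back = read_genotypes(tmp_path / "sim_markers_no_qtn.num.txt", "numeric")
    qtn_idx = res.assignment.distinct_markers(include_links=False)
    assert back.n_markers == ld_panel.n_markers - qtn_idx.size
    removed_ids = set(ld_panel.marker_map["marker_id"].iloc[qtn_idx])
    assert removed_ids.isdisjoint(back.marker_map["marker_id"])
    link_ids = {ld_panel.marker_map["marker_id"].iloc[r.link_idx]
                for a in res.assignment.replicates for r in a.ld_records}
    assert link_ids <= set(back.marker_map["marker_id"])


def test_end_to_end_determinism_byte_identical(ld_panel, tmp_path):
    cfg = canonical_spurious_config(output_formats=("gemma", "tassel", "wide_table",
                                               "long_table"), remove_qtn=True)
    create_phenotypes(ld_panel, cfg, tmp_path / "a")
    create_phenotypes(ld_panel, cfg, tmp_path / "b")
    assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")
    cfg2 = canonical_spurious_config(seed=6, output_formats=("gemma", "tassel",
                                                        "wide_table", "long_table"),
                                remove_qtn=True)
    create_phenotypes(ld_panel, cfg2, tmp_path / "c")
    assert dir_digest(tmp_path / "a") != dir_digest(tmp_path / "c")


def test_log_statistics_match_emitted_files(ld_panel, tmp_path):
    cfg = canonical_spurious_config()
    res = create_phenotypes(ld_panel, cfg, tmp_path)
    summary = pd.read_csv(tmp_path / "sim_summary.tsv", sep="\t")
    for rep in range(2):
        P = np.loadtxt(tmp_path / f"sim_rep{rep + 1}.tsv", skiprows=1,
                       usecols=(1, 2), delimiter="\t")
        G, E = res.genetic_values[rep], res.errors[rep]
        np.testing.assert_allclose(P, G + E, atol=1e-9)  # file precision
        for t in range(2):
            row = summary[(summary.replicate == rep + 1) & (summary.trait == t + 1)]
            h2_file = float(row["realized_h2"].iloc[0])
            vg = G[:, t].var(ddof=1)
            ve = E[:, t].var(ddof=1)
            assert h2_file == pytest.approx(vg / (vg + ve), abs=1e-12)


def test_h2_one_phenotypes_equal_genetic_values(panel, tmp_path):
    """Zero-noise degeneracy: phenotype is the genetic value, bit for bit."""
    arch = ArchitectureSpec("pleiotropy", n_traits=2, add_qtn_num=2, seed=3)
    eff = EffectSpec([[0.10, 0.01], [0.40, 0.16]], [[], []], [[], []])
    cfg = SimulationConfig(arch, eff, h2=[1.0, 1.0])
    res = simulate_traits(panel, cfg)
    assert np.array_equal(res.phenotypes[0], res.genetic_values[0])
    np.testing.assert_array_equal(res.realized_h2, 1.0)


def test_h2_one_with_target_correlation_is_exact(panel):
    arch = ArchitectureSpec("pleiotropy", n_traits=2, add_qtn_num=3, seed=4)
    eff = EffectSpec([[0.2, 0.1, 0.05], [0.3, 0.2, 0.1]], [[], []], [[], []])
    cor = np.array([[1.0, 0.6], [0.6, 1.0]])
    cfg = SimulationConfig(arch, eff, h2=[1.0, 1.0], cor=cor)
    res = simulate_traits(panel, cfg)
    realized = np.corrcoef(res.phenotypes[0], rowvar=False)
    np.testing.assert_allclose(realized, cor, atol=1e-10)


def test_residual_correlation_flows_into_errors(panel):
    arch = ArchitectureSpec("pleiotropy", n_traits=2, add_qtn_num=3, seed=8,
                            n_experiments=50, vary_qtn=False)
    eff = EffectSpec([[0.2, 0.1, 0.05], [0.3, 0.2, 0.1]], [[], []], [[], []])
    cor_res = np.array([[1.0, 0.8], [0.8, 1.0]])
    cfg = SimulationConfig(arch, eff, h2=[0.5, 0.5], cor_res=cor_res)
    res = simulate_traits(panel, cfg)
    mean_r = np.mean([r[0, 1] for r in res.realized_res_corr])
    assert mean_r == pytest.approx(0.8, abs=0.05)


def test_config_validation_errors_are_named():
    arch = ArchitectureSpec("pleiotropy", n_traits=2, add_qtn_num=2, seed=0)
    eff = EffectSpec([[0.1, 0.2], [0.1, 0.2]], [[], []], [[], []])
    with pytest.raises(ConfigurationError, match="h2"):
        SimulationConfig(arch, eff, h2=[0.5, 0.5, 0.5])
    with pytest.raises(ConfigurationError, match="heritability"):
        SimulationConfig(arch, eff, h2=[0.0, 0.5])
    with pytest.raises(ConfigurationError, match="effect list"):
        SimulationConfig(arch, EffectSpec([[0.1], [0.1]], [[], []], [[], []]),
                         h2=[0.5, 0.5])
    with pytest.raises(ConfigurationError, match="cor"):
        SimulationConfig(arch, eff, h2=[0.5, 0.5], cor=np.eye(3))


# ------------------------------------------------------------ writers

def test_gemma_writer_contract(tmp_path):
    P = np.array([[1.5, np.nan], [2.0, 3.0]])
    path = write_phenotypes(P, "gemma", tmp_path / "p.txt", ["a", "b"])
    lines = path.read_text().splitlines()
    assert lines == ["1.5 NA", "2 3"]  # no header, NA for missing


def test_tassel_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    P = rng.standard_normal((5, 2))
    ids = [f"tx{k}" for k in range(5)]
    path = write_phenotypes(P, "tassel", tmp_path / "p.txt", ids)
    back = read_tassel_phenotypes(path)
    assert list(back.index) == ids
    np.testing.assert_allclose(back.to_numpy(), P, atol=1e-9)


def test_long_table_has_trait_replicate_groups(panel, tmp_path):
    arch = ArchitectureSpec("pleiotropy", n_traits=2, add_qtn_num=2, seed=1,
                            n_experiments=3)
    eff = EffectSpec([[0.1, 0.2], [0.1, 0.2]], [[], []], [[], []])
    cfg = SimulationConfig(arch, eff, h2=[0.5, 0.5], output_formats=("long_table",))
    create_phenotypes(panel, cfg, tmp_path)
    df = pd.read_csv(tmp_path / "sim_long.tsv", sep="\t")
    assert df.groupby(["replicate", "trait"]).ngroups == 6
    assert len(df) == 6 * panel.n_individuals


# ------------------------------------------------------------ YAML config

def test_yaml_config_round_trip(tmp_path):
    raw = {
        "fixture": {"n_individuals": 80, "n_markers": 200, "seed": 3},
        "architecture": "pleiotropy",
        "ntraits": 2,
        "add_QTN_num": 2,
        "sim_method": "geometric",
        "add_effect": [0.1, 0.4],
        "h2": [0.5, 0.7],
        "rep": 2,
        "seed": 9,
        "output_format": "wide_table",
    }
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(raw))
    source, cfg = load_config(path)
    assert cfg.effects.additive == [[0.1, 0.010000000000000002], [0.4, 0.16000000000000003]]
    geno = load_genotypes(source)
    assert geno.n_individuals == 80
    res = simulate_traits(geno, cfg)
    assert len(res.phenotypes) == 2


def test_unknown_config_key_rejected():
    with pytest.raises(ConfigurationError, match="unknown"):
        parse_config({"fixture": {}, "h2": 0.5, "typo_key": 1})
    with pytest.raises(ConfigurationError, match="geno_file"):
        parse_config({"h2": 0.5})
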