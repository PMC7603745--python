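import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleiosim._rand import derive_rng
from pleiosim.effects import (EffectSpec, additive_value, aggregate_genetic_values,
                              dominance_value, epistatic_value, geometric_effects,
                              variance_explained)
from pleiosim.qtn import (ArchitectureSpec, ConfigurationError, assign_qtns,
                          maf_filter, select_pleiotropic)

# effect of one QTN on one individual, by model and genotype(s):
# hand-transcribed lookup used as the oracle for the engine
ADDITIVE_TABLE = {-1: "-a", 0: "0", 1: "a"}
DOMINANCE_TABLE = {-1: "0", 0: "d", 1: "0"}
EPISTATIC_TABLE = {(-1, -1): "e", (-1, 0): "0", (-1, 1): "-e",
                   (0, -1): "0", (0, 0): "0", (0, 1): "0",
                   (1, -1): "-e", (1, 0): "0", (1, 1): "e"}


def test_effect_coding_matches_lookup_table():
    """Full 3 x 3 x 3 enumeration against the literal lookup tables."""
    a, d, e = 0.2, 0.5, 0.3
    sym = {"a": a, "-a": -a, "d": d, "e": e, "-e": -e, "0": 0.0}
    for g1, g2 in itertools.product((-1, 0, 1), repeat=2):
        assert additive_value([g1], a)[0] == sym[ADDITIVE_TABLE[g1]]
        assert dominance_value([g1], d)[0] == sym[DOMINANCE_TABLE[g1]]
        assert epistatic_value([g1], [g2], e)[0] == sym[EPISTATIC_TABLE[(g1, g2)]]


@pytest.mark.parametrize(
    "base, n, expected",
    [
        (0.4, 2, [0.40, 0.16]),
        (0.1, 2, [0.10, 0.01]),
        (1.0, 5, [1, 1, 1, 1, 1]),
        (0.5, 0, []),
    ],
)
def test_geometric_effect_series(base, n, expected):
    assert geometric_effects(base, n) == pytest.approx(expected)


def test_geometric_series_rejects_zero_base():
    with pytest.raises(ValueError):
        geometric_effects(0.0, 3)


def test_dominance_inert_in_fully_inbred_data():
    col = np.array([-1.0, 1.0, 1.0, -1.0])
    np.testing.assert_array_equal(dominance_value(col, 0.7), np.zeros(4))


def test_epistatic_unequal_lengths_error():
    with pytest.raises(ValueError):
        epistatic_value([1, -1], [1], 0.3)


# ----------------------------------------------------------- aggregation

def pleio_spec(n_add, seed=3, n_traits=2):
    return ArchitectureSpec("pleiotropy", n_traits=n_traits, add_qtn_num=n_add,
                            seed=seed)


def test_single_additive_qtn_identity(panel):
    """One QTN with a = 1: the genetic value IS the coded genotype column."""
    spec = pleio_spec(1)
    a = assign_qtns(spec, panel)
    eff = EffectSpec([[1.0], [1.0]], [[], []], [[], []])
    gv = aggregate_genetic_values(panel, a.replicates[0], eff)
    j = a.replicates[0].traits[0].additive[0]
    np.testing.assert_array_equal(gv.values[:, 0], panel.values[:, j])


def test_genetic_values_sum_of_contributions_exactly(outbred_panel):
    spec = ArchitectureSpec("pleiotropy", n_traits=2, add_qtn_num=3,
                            dom_qtn_num=2, epi_qtn_num=1, seed=9)
    a = assign_qtns(spec, outbred_panel)
    eff = EffectSpec([[0.2, 0.1, 0.05], [0.3, 0.2, 0.1]],
                     [[0.4, 0.2], [0.1, 0.05]], [[0.3], [0.2]])
    gv = aggregate_genetic_values(outbred_panel, a.replicates[0], eff)
    for t in range(2):
        total = np.sum([v for _, _, v in gv.contributions[t]], axis=0)
        np.testing.assert_array_equal(gv.values[:, t], total)


def test_shared_qtns_different_effects_are_correlated(panel):
    spec = pleio_spec(2)
    a = assign_qtns(spec, panel)
    eff = EffectSpec([[0.10, 0.01], [0.40, 0.16]], [[], []], [[], []])
    gv = aggregate_genetic_values(panel, a.replicates[0], eff)
    r = np.corrcoef(gv.values, rowvar=False)[0, 1]
    assert 0 < r < 1


def test_all_zero_effects_give_zero_matrix(panel):
    spec = pleio_spec(2)
    a = assign_qtns(spec, panel)
    eff = EffectSpec([[0.0, 0.0], [0.0, 0.0]], [[], []], [[], []])
    gv = aggregate_genetic_values(panel, a.replicates[0], eff)
    assert not gv.values.any()


def test_effect_shape_mismatch_errors(panel):
    spec = pleio_spec(3)
    a = assign_qtns(spec, panel)
    eff = EffectSpec([[0.1], [0.2]], [[], []], [[], []])
    with pytest.raises(ConfigurationError):
        aggregate_genetic_values(panel, a.replicates[0], eff)


@settings(deadline=None, derandomize=True)
@given(c=st.floats(min_value=-4, max_value=4).filter(lambda x: x != 0))
def test_linearity_scaling_effects_scales_values(c):
    rng = derive_rng(17, 0, "qtn")
    X = rng.choice([-1.0, 0.0, 1.0], size=(50, 6))
    from conftest import toy_map
    from pleiosim.marker_io import GenotypeMatrix
    geno = GenotypeMatrix(X, toy_map(6), [f"i{k}" for k in range(50)])
    spec = ArchitectureSpec("pleiotropy", n_traits=2, add_qtn_num=2,
                            dom_qtn_num=1, epi_qtn_num=1, seed=1)
    a = select_pleiotropic(spec, np.arange(6), derive_rng(1, 0, "qtn"))
    base = EffectSpec([[0.2, 0.1], [0.3, 0.2]], [[0.4], [0.1]], [[0.3], [0.2]])
    scaled = EffectSpec([[c * x for x in t] for t in base.additive],
                        [[c * x for x in t] for t in base.dominance],
                        [[c * x for x in t] for t in base.epistatic])
    g1 = aggregate_genetic_values(geno, a, base).values
    g2 = aggregate_genetic_values(geno, a, scaled).values
    np.testing.assert_allclose(g2, c * g1, atol=1e-12)


# ------------------------------------------------------ variance explained

def test_variance_explained_single_qtn_equals_h2(panel):
    """With one QTN the genetic variance is all of var_g, so the fraction of
    phenotypic variance (var_g / h2) explained equals h2."""
    spec = pleio_spec(1)
    a = assign_qtns(spec, panel)
    eff = EffectSpec([[0.5], [0.2]], [[], []], [[], []])
    gv = aggregate_genetic_values(panel, a.replicates[0], eff)
    h2 = np.array([0.5, 0.8])
    var_p = gv.values.var(axis=0, ddof=1) / h2
    ve = variance_explained(gv, var_p)
    np.testing.assert_allclose(ve["fraction_explained"].to_numpy(), h2, rtol=1e-12)


def test_variance_explained_zero_effect_qtn_is_zero(panel):
    spec = pleio_spec(2)
    a = assign_qtns(spec, panel)
    eff = EffectSpec([[0.5, 0.0], [0.2, 0.0]], [[], []], [[], []])
    gv = aggregate_genetic_values(panel, a.replicates[0], eff)
    ve = variance_explained(gv, [1.0, 1.0])
    zero_rows = ve.iloc[[1, 3]]
    assert (zero_rows["fraction_explained"] == 0).all()


def test_variance_explained_equal_maf_equal_effects():
    """Two independent equal-MAF additive QTNs with equal effects explain
    equal fractions; verified against exact enumeration of genotype classes."""
    from conftest import toy_map
    from pleiosim.marker_io import GenotypeMatrix

    # balanced inbred design: every (g1, g2) homozygote combination once
    g1 = np.array([-1.0, -1.0, 1.0, 1.0])
    g2 = np.array([-1.0, 1.0, -1.0, 1.0])
    geno = GenotypeMatrix(np.column_stack([g1, g2]), toy_map(2), list("abcd"))
    spec = ArchitectureSpec("pleiotropy", n_traits=2, add_qtn_num=2, seed=0)
    a = select_pleiotropic(spec, np.arange(2), derive_rng(0, 0, "qtn"))
    eff = EffectSpec([[1.0, 1.0], [1.0, 1.0]], [[], []], [[], []])
    gv = aggregate_genetic_values(geno, a, eff)
    # exact decomposition: var(g1)=var(g2)=4/3 (ddof=1), total var = 8/3
    var_p = gv.values.var(axis=0, ddof=1)
    ve = variance_explained(gv, var_p)
    np.testing.assert_allclose(ve["var_qtn"], 4 / 3)
    np.testing.assert_allclose(ve["fraction_explained"], 0.5)


def test_variance_explained_degenerate_denominator_is_nan(panel):
    spec = pleio_spec(1)
    a = assign_qtns(spec, panel)
    eff = EffectSpec([[0.5], [0.2]], [[], []], [[], []])
    gv = aggregate_genetic_values(panel, a.replicates[0], eff)
    ve = variance_explained(gv, [0.0, 0.0])
    assert ve["fraction_explained"].isna().all()
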