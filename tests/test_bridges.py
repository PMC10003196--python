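"""Salt-bridge proxy distances and state-comparison statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatemap.bridges import (
    MIN_OVER_CHAIN_PAIRS,
    ResiduePairSpec,
    charged_pair_distance,
    classify_contact,
    delta_table,
    distance_stats,
    ensemble_distance_stats,
    state_comparison_table,
)
from gatemap.model import TERMINAL_CHARGED_ATOMS, ResidueRef, StructureEnsemble
from gatemap.synth import (
    BridgeEnsembleSpec,
    PlantedPair,
    canonical_pairs,
    gen_bridge_ensemble,
)

from conftest import make_residue, rigid_transform


def _pair(a_chain="A", b_chain="A", mode="intra"):
    return ResiduePairSpec(
        "p", ResidueRef(a_chain, 10, "ASP"), ResidueRef(b_chain, 20, "LYS"), chain_mode=mode
    )


def test_minimum_over_terminal_atom_cross_product():
    """ASP with OD1/OD2 against LYS NZ: the closer oxygen defines the distance."""
    model = make_residue("ASP", 10, {"CA": (0, -3, 0), "OD1": (0, 0, 0), "OD2": (4, 0, 0)})
    model += make_residue("LYS", 20, {"CA": (3, -3, 0), "NZ": (3, 0, 0)})
    assert charged_pair_distance(model, _pair()) == pytest.approx(1.0)


def test_single_atom_residues_345_triangle():
    model = make_residue("GLU", 10, {"CA": (9, 9, 9), "OE1": (0, 0, 0)})
    model += make_residue("ARG", 20, {"CA": (9, 9, 0), "NH1": (0, 3, 4)})
    p = ResiduePairSpec("p", ResidueRef("A", 10, "GLU"), ResidueRef("A", 20, "ARG"))
    assert charged_pair_distance(model, p) == pytest.approx(5.0)


@pytest.mark.parametrize("seed", range(10))
def test_matches_brute_force_on_random_geometries(seed):
    """Vectorized minimum equals exhaustive loop over every listed atom pair."""
    rng = np.random.default_rng(seed)
    a_pos = {n: rng.uniform(-10, 10, 3) for n in TERMINAL_CHARGED_ATOMS["ASP"]}
    b_pos = {n: rng.uniform(-10, 10, 3) for n in TERMINAL_CHARGED_ATOMS["ARG"]}
    model = make_residue("ASP", 10, {"CA": rng.uniform(-10, 10, 3), **a_pos})
    model += make_residue("ARG", 20, {"CA": rng.uniform(-10, 10, 3), **b_pos})
    p = ResiduePairSpec("p", ResidueRef("A", 10, "ASP"), ResidueRef("A", 20, "ARG"))
    brute = min(
        np.linalg.norm(np.asarray(pa) - np.asarray(pb))
        for pa, pb in itertools.product(a_pos.values(), b_pos.values())
    )
    assert charged_pair_distance(model, p) == pytest.approx(brute, abs=1e-12)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_distance_symmetric_and_rigid_invariant(seed):
    """d(a,b) = d(b,a) and the distance survives rotation + translation."""
    rng = np.random.default_rng(seed)
    model = make_residue(
        "GLU", 10, {"CA": rng.uniform(-5, 5, 3), "OE1": rng.uniform(-5, 5, 3), "OE2": rng.uniform(-5, 5, 3)}
    )
    model += make_residue("LYS", 20, {"CA": rng.uniform(-5, 5, 3), "NZ": rng.uniform(-5, 5, 3)})
    p = ResiduePairSpec("p", ResidueRef("A", 10, "GLU"), ResidueRef("A", 20, "LYS"))
    p_rev = ResiduePairSpec("p", ResidueRef("A", 20, "LYS"), ResidueRef("A", 10, "GLU"))
    d = charged_pair_distance(model, p)
    assert charged_pair_distance(model, p_rev) == pytest.approx(d)
    move = rigid_transform(rng)
    from dataclasses import replace

    moved = [replace(a, xyz=move(a.xyz)) for a in model]
    assert charged_pair_distance(moved, p) == pytest.approx(d, abs=1e-9)


def test_min_over_chain_pairs_not_larger_than_intra():
    model = make_residue("ASP", 10, {"OD1": (0, 0, 0)}, chain="A")
    model += make_residue("LYS", 20, {"NZ": (8, 0, 0)}, chain="A")
    model += make_residue("ASP", 10, {"OD1": (20, 0, 0)}, chain="B")
    model += make_residue("LYS", 20, {"NZ": (21, 0, 0)}, chain="B")
    intra = charged_pair_distance(model, _pair("A", "A"))
    cross = charged_pair_distance(model, _pair("A", "A", MIN_OVER_CHAIN_PAIRS))
    assert cross <= intra
    assert cross == pytest.approx(1.0)


def test_non_acid_base_pair_warns_but_computes(caplog):
    model = make_residue("LYS", 10, {"NZ": (0, 0, 0)})
    model += make_residue("ARG", 20, {"NH1": (2, 0, 0)})
    p = ResiduePairSpec("p", ResidueRef("A", 10, "LYS"), ResidueRef("A", 20, "ARG"))
    with caplog.at_level("WARNING", logger="gatemap.bridges"):
        assert charged_pair_distance(model, p) == pytest.approx(2.0)
    assert any("generic terminal-atom rule" in r.message for r in caplog.records)


# -- ensemble statistics ----------------------------------------------------

def test_single_model_stats_are_degenerate(glu_lys_pair):
    model = make_residue("GLU", 10, {"OE1": (0, 0, 0)})
    model += make_residue("LYS", 20, {"NZ": (3.2, 0, 0)})
    e = StructureEnsemble(models=[model], source_label="apo")
    stat = ensemble_distance_stats(e, glu_lys_pair)
    assert (stat.mean_A, stat.sd_A, stat.n) == (pytest.approx(3.2), 0.0, 1)


def test_planted_normal_mean_recovered(bridge_ensemble_20):
    """Normal(8.0, 0.5) over 20 models: mean within 3 sigma / sqrt(n)."""
    pair, ensemble, truth = bridge_ensemble_20
    stat = ensemble_distance_stats(ensemble, pair)
    assert stat.n == 20
    assert abs(stat.mean_A - 8.0) < 3 * 0.5 / np.sqrt(20)
    # and the measured per-model distances equal the generator's ground truth
    np.testing.assert_allclose(
        [stat.mean_A], [truth["distance_A"].mean()], atol=1e-9
    )


def test_mean_equals_naive_loop(bridge_ensemble_20):
    pair, ensemble, _ = bridge_ensemble_20
    total = 0.0
    for model in ensemble.models:
        total += charged_pair_distance(model, pair)
    stat = ensemble_distance_stats(ensemble, pair)
    assert stat.mean_A == pytest.approx(total / ensemble.n_models, abs=1e-12)


def test_pooled_mean_is_weighted_mean_of_ensemble_means():
    pair = canonical_pairs()[0]
    e1, _ = gen_bridge_ensemble(BridgeEnsembleSpec(pairs=(PlantedPair(pair, 8.0, 0.5),), n_models=5, seed=1))
    e2, _ = gen_bridge_ensemble(BridgeEnsembleSpec(pairs=(PlantedPair(pair, 10.0, 0.5),), n_models=15, seed=2))
    s1 = ensemble_distance_stats(e1, pair)
    s2 = ensemble_distance_stats(e2, pair)
    pooled = state_comparison_table({"c": [e1, e2]}, [pair])
    expected = (s1.mean_A * s1.n + s2.mean_A * s2.n) / (s1.n + s2.n)
    assert pooled["mean_A"].iloc[0] == pytest.approx(expected, abs=1e-12)
    assert pooled["n"].iloc[0] == 20


# -- state comparison table -------------------------------------------------

def test_table_recovers_planted_means_per_condition():
    pairs = canonical_pairs()
    means_apo = {"HLH-TDhC": 12.0, "HLH-TDhN": 11.0, "ARD6-HLH": 15.0, "S2S3-TDh": 5.0}
    means_bound = {"HLH-TDhC": 4.0, "HLH-TDhN": 4.5, "ARD6-HLH": 14.0, "S2S3-TDh": 10.0}
    conditions = {}
    for cond, means, seed in (("apo", means_apo, 1), ("bound", means_bound, 2)):
        spec = BridgeEnsembleSpec(
            pairs=tuple(PlantedPair(p, means[p.label], 0.5) for p in pairs),
            n_models=20,
            seed=seed,
        )
        e, _ = gen_bridge_ensemble(spec)
        conditions[cond] = [e]
    table = state_comparison_table(conditions, pairs)
    assert len(table) == 8
    tol = 3 * 0.5 / np.sqrt(20)
    for row in table.itertuples():
        planted = (means_apo if row.condition == "apo" else means_bound)[row.pair_label]
        assert abs(row.mean_A - planted) < tol


def test_degenerate_table_equals_ensemble_stats(glu_lys_pair):
    model = make_residue("GLU", 10, {"OE1": (0, 0, 0)})
    model += make_residue("LYS", 20, {"NZ": (4.4, 0, 0)})
    e = StructureEnsemble(models=[model], source_label="apo")
    table = state_comparison_table({"apo": [e]}, [glu_lys_pair])
    stat = ensemble_distance_stats(e, glu_lys_pair)
    row = table.iloc[0]
    assert (row["mean_A"], row["sd_A"], row["n"]) == (stat.mean_A, stat.sd_A, stat.n)


def test_delta_is_antisymmetric(bridge_ensemble_20):
    pair, e, _ = bridge_ensemble_20
    e2, _ = gen_bridge_ensemble(
        BridgeEnsembleSpec(pairs=(PlantedPair(pair, 4.0, 0.5),), n_models=20, seed=5)
    )
    table = state_comparison_table({"a": [e], "b": [e2]}, [pair])
    ab = delta_table(table, "a", "b")["delta_mean_A"].to_numpy()
    ba = delta_table(table, "b", "a")["delta_mean_A"].to_numpy()
    np.testing.assert_allclose(ab, -ba)


@pytest.mark.parametrize(
    "d,expected", [(3.9, "formed"), (4.0, "formed"), (4.01, "broken")]
)
def test_contact_classification_boundary_inclusive(d, expected):
    assert classify_contact(d) == expected


def test_distance_stats_sample_sd():
    stat = distance_stats([1.0, 2.0, 3.0], "p", "c")
    assert stat.sd_A == pytest.approx(1.0)  # ddof=1
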