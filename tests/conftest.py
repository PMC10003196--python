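"""Shared fixtures: small generated ensembles, trajectories and traces."""

import numpy as np
import pytest

from gatemap.bridges import ResiduePairSpec
from gatemap.model import AtomRecord, ResidueRef, StructureEnsemble
from gatemap.synth import (
    BridgeEnsembleSpec,
    PairProcess,
    PlantedPair,
    TrajectorySpec,
    canonical_pairs,
    gen_bridge_ensemble,
    gen_trajectory,
)


def make_atom(
    name: str,
    xyz,
    *,
    resname: str = "GLY",
    chain: str = "A",
    resid: int = 1,
    model_id: int = 1,
    element: str | None = None,
    hetero: bool = False,
) -> AtomRecord:
    return AtomRecord(
        model_id=model_id,
        chain_id=chain,
        resid=resid,
        icode="",
        resname=resname,
        atom_name=name,
        element=element if element is not None else name[0],
        altloc="",
        xyz=tuple(float(v) for v in xyz),
        is_hetero=hetero,
    )


def make_residue(resname: str, resid: int, atom_positions: dict, chain: str = "A"):
    """Residue as a list of atoms from {atom_name: xyz}."""
    return [
        make_atom(n, p, resname=resname, chain=chain, resid=resid)
        for n, p in atom_positions.items()
    ]


@pytest.fixture
def glu_lys_pair():
    """GLU 10 / LYS 20 pair spec with full side-chain terminal atoms."""
    return ResiduePairSpec(
        "test",
        ResidueRef("A", 10, "GLU"),
        ResidueRef("A", 20, "LYS"),
    )


@pytest.fixture
def bridge_ensemble_20():
    """20-model ensemble, one pair planted at Normal(8.0, 0.5)."""
    pair = canonical_pairs()[0]
    spec = BridgeEnsembleSpec(
        pairs=(PlantedPair(pair, 8.0, 0.5),), n_models=20, seed=11
    )
    ensemble, truth = gen_bridge_ensemble(spec)
    return pair, ensemble, truth


@pytest.fixture
def planted_trajectory():
    """500-frame trajectory, changepoint 150, one fluctuating pair."""
    pair = canonical_pairs()[0]
    spec = TrajectorySpec(
        pairs=(PairProcess(pair, 6.0, fluct_sd_A=0.2, pre_onset_drift_A=2.0),),
        n_frames=500,
        changepoint=150,
        seed=7,
    )
    traj, truth = gen_trajectory(spec)
    return pair, spec, traj, truth


def rigid_transform(rng: np.random.Generator):
    """A random proper rotation + translation as a coordinate function."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return lambda xyz: tuple(rot @ np.asarray(xyz) + t)
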