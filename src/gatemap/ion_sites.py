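"""Geometric detection of Ca2+ coordination sites.

A site qualifies when the ion has four to eight coordinating oxygens within
2.5 A — the generic first-shell geometry of protein-bound calcium.  Oxygens
are counted by element only (carboxylate, carbonyl, hydroxyl and water all
count); waters can be excluded by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import TopologyError
from .model import AtomRecord, StructureEnsemble

logger = logging.getLogger(__name__)

WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL"})


@dataclass(frozen=True)
class CoordinationConfig:
    """Counting rule for the oxygen shell of an ion.

    Defaults encode the 4–8 oxygens / 2.5 A first-shell criterion.
    """

    distance_cutoff: float = 2.5
    min_oxygens: int = 4
    max_oxygens: int = 8
    ion_names: frozenset[str] = frozenset({"CA"})
    include_water: bool = True

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if not (1 <= self.min_oxygens <= self.max_oxygens):
            raise ValueError("require 1 <= min_oxygens <= max_oxygens")


@dataclass(frozen=True)
class CoordinationSite:
    """One ion with its counted oxygen shell in one model."""

    ion: AtomRecord
    oxygens: tuple[AtomRecord, ...]
    count: int
    mean_distance: float
    qualifies: bool
    model_id: int


def _is_candidate_oxygen(atom: AtomRecord, cfg: CoordinationConfig) -> bool:
    if atom.element != "O":
        return False
    if not cfg.include_water and atom.resname in WATER_RESNAMES:
        return False
    return True


def find_coordination_sites(
    model: list[AtomRecord], cfg: CoordinationConfig = CoordinationConfig()
) -> list[CoordinationSite]:
    """One :class:`CoordinationSite` per matching ion, qualifying or not.

    Ions are HETATM atoms whose atom name is in ``cfg.ion_names``; an empty
    result (no ions present) is a logged notice, not an error.
    """
    ions = [a for a in model if a.is_hetero and a.atom_name in cfg.ion_names]
    if not ions:
        logger.info("no ions matching %s in model", sorted(cfg.ion_names))
        return []
    oxygens = [a for a in model if _is_candidate_oxygen(a, cfg)]
    ox_xyz = np.array([a.xyz for a in oxygens]) if oxygens else np.empty((0, 3))
    sites = []
    for ion in ions:
        if ox_xyz.size:
            d = np.linalg.norm(ox_xyz - np.array(ion.xyz), axis=1)
            within = d <= cfg.distance_cutoff
        else:
            d = np.empty(0)
            within = np.zeros(0, dtype=bool)
        shell = tuple(o for o, w in zip(oxygens, within) if w)
        count = len(shell)
        mean_d = float(d[within].mean()) if count else float("nan")
        qualifies = (
            cfg.min_oxygens <= count <= cfg.max_oxygens
            and mean_d <= cfg.distance_cutoff
        )
        sites.append(
            CoordinationSite(
                ion=ion,
                oxygens=shell,
                count=count,
                mean_distance=mean_d,
                qualifies=qualifies,
                model_id=ion.model_id,
            )
        )
    return sites


def site_occupancy(
    traj: StructureEnsemble,
    ion_ref: tuple[str, int, str, str],
    cfg: CoordinationConfig = CoordinationConfig(),
    *,
    start_index: int = 0,
) -> float:
    """Fraction of frames (from ``start_index`` on) in which the ion's site qualifies.

    ``ion_ref`` identifies the ion by (chain_id, resid, icode, atom_name);
    topology constancy guarantees the same atom exists in every frame.
    """
    chain, resid, icode, name = ion_ref
    n_qual = 0
    frames = traj.models[start_index:]
    if not frames:
        raise ValueError("start_index leaves no frames to analyse")
    for i, model in enumerate(frames, start=start_index + 1):
        sites = find_coordination_sites(model, cfg)
        match = [
            s
            for s in sites
            if s.ion.chain_id == chain
            and s.ion.resid == resid
            and s.ion.icode == icode
            and s.ion.atom_name == name
        ]
        if not match:
            raise TopologyError(f"ion {ion_ref} missing from frame {i}")
        if match[0].qualifies:
            n_qual += 1
    return n_qual / len(frames)
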