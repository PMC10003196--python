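"""Salt-bridge proxy distances and state-comparison tables.

The proxy for an interdomain salt bridge between an acidic and a basic
residue is the minimum Euclidean distance over all pairs of their side-chain
terminal charged atoms (carboxylate oxygens vs amine/guanidinium nitrogens).
Per-model distances are averaged over every model of every structure of a
condition, and conditions are compared through signed differences of the
per-condition means — the numbers behind apo-vs-Ca2+/CaM heat maps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ResidueLookupError
from .model import (
    ACIDIC_RESNAMES,
    BASIC_RESNAMES,
    AtomRecord,
    ResidueRef,
    StructureEnsemble,
    terminal_charged_atoms,
)

logger = logging.getLogger(__name__)

INTRA = "intra"
MIN_OVER_CHAIN_PAIRS = "min_over_chain_pairs"


@dataclass(frozen=True)
class ResiduePairSpec:
    """A labelled residue pair, e.g. HLH-TDh as E294-R606.

    ``chain_mode`` selects whether the distance uses exactly the chains given
    in the refs (``intra``) or the global minimum over all chain combinations
    in which both residues resolve (``min_over_chain_pairs``) — the latter
    matters for homotetramers where the contact may be inter-subunit.
    """

    label: str
    a: ResidueRef
    b: ResidueRef
    chain_mode: str = INTRA

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"pair {self.label!r}: residues must differ")
        if self.chain_mode not in (INTRA, MIN_OVER_CHAIN_PAIRS):
            raise ValueError(f"unknown chain_mode {self.chain_mode!r}")


@dataclass(frozen=True)
class PairDistanceStat:
    """Mean/sd/n of one pair's distance under one condition (one heat-map cell)."""

    pair_label: str
    condition: str
    mean_A: float
    sd_A: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_A < 0 or self.mean_A <= 0:
            raise ValueError("require sd_A >= 0 and mean_A > 0")


def _min_cross_distance(a_atoms: Sequence[AtomRecord], b_atoms: Sequence[AtomRecord]) -> float:
    a = np.array([at.xyz for at in a_atoms])
    b = np.array([bt.xyz for bt in b_atoms])
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def _check_charge_pairing(p: ResiduePairSpec) -> None:
    names = {p.a.resname, p.b.resname}
    acidic = names & ACIDIC_RESNAMES
    basic = names & BASIC_RESNAMES
    if not (len(acidic) == 1 and len(basic) == 1 and acidic != basic):
        logger.warning(
            "pair %s is not one acidic + one basic residue (%s-%s); "
            "falling back on the generic terminal-atom rule",
            p.label,
            p.a.resname,
            p.b.resname,
        )


def _chains_with_residue(model: Iterable[AtomRecord], ref: ResidueRef) -> list[str]:
    chains = sorted(
        {
            a.chain_id
            for a in model
            if a.resid == ref.resid and a.icode == ref.icode and a.resname == ref.resname
        }
    )
    return chains


def charged_pair_distance(model: Sequence[AtomRecord], p: ResiduePairSpec) -> float:
    """Minimum terminal-charged-atom distance of a residue pair, in angstroms."""
    _check_charge_pairing(p)
    if p.chain_mode == INTRA:
        return _min_cross_distance(
            terminal_charged_atoms(model, p.a), terminal_charged_atoms(model, p.b)
        )
    chains_a = _chains_with_residue(model, p.a)
    chains_b = _chains_with_residue(model, p.b)
    if not chains_a or not chains_b:
        raise ResidueLookupError(
            f"pair {p.label}: no chain contains {p.a if not chains_a else p.b}"
        )
    best = math.inf
    for ca in chains_a:
        a_atoms = terminal_charged_atoms(model, replace(p.a, chain_id=ca))
        for cb in chains_b:
            b_atoms = terminal_charged_atoms(model, replace(p.b, chain_id=cb))
            best = min(best, _min_cross_distance(a_atoms, b_atoms))
    return best


def distance_stats(
    values: Sequence[float], pair_label: str, condition: str
) -> PairDistanceStat:
    """Mean, sample sd (ddof=1, 0 when n=1) and n of a distance collection."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return PairDistanceStat(
        pair_label=pair_label,
        condition=condition,
        mean_A=float(arr.mean()),
        sd_A=sd,
        n=n,
    )


def ensemble_distance_stats(
    e: StructureEnsemble, p: ResiduePairSpec, *, condition: str | None = None
) -> PairDistanceStat:
    """Per-model distances of one pair aggregated over an ensemble."""
    values = []
    for i, model in enumerate(e.models, start=1):
        try:
            values.append(charged_pair_distance(model, p))
        except Exception as exc:
            raise type(exc)(f"model {i}: {exc}") from exc
    return distance_stats(values, p.label, condition if condition is not None else e.source_label)


def state_comparison_table(
    conditions: Mapping[str, Sequence[StructureEnsemble]],
    pairs: Sequence[ResiduePairSpec],
) -> pd.DataFrame:
    """Long-format table of PairDistanceStat cells: one row per (pair, condition).

    All models of all ensembles of one condition are pooled with equal weight
    per model.  Conditions in which a pair resolves in no model are dropped
    for that pair with a logged warning.
    """
    if not conditions or not pairs:
        raise ValueError("need at least one condition and one pair")
    rows = []
    for p in pairs:
        for cond, ensembles in conditions.items():
            values: list[float] = []
            for e in ensembles:
                for model in e.models:
                    values.append(charged_pair_distance(model, p))
            if not values:
                logger.warning("condition %r: pair %s resolvable in no model; dropped", cond, p.label)
                continue
            stat = distance_stats(values, p.label, cond)
            rows.append(
                {
                    "pair_label": stat.pair_label,
                    "condition": stat.condition,
                    "mean_A": stat.mean_A,
                    "sd_A": stat.sd_A,
                    "n": stat.n,
                }
            )
    return pd.DataFrame(rows, columns=["pair_label", "condition", "mean_A", "sd_A", "n"])


def wide_table(long: pd.DataFrame) -> pd.DataFrame:
    """Pairs x conditions table with "mean±sd (n)" cells, heat-map style."""
    cells = long.assign(
        cell=[
            f"{r.mean_A:.2f}±{r.sd_A:.2f} ({r.n})"
            for r in long.itertuples()
        ]
    )
    return cells.pivot(index="pair_label", columns="condition", values="cell")


def delta_table(long: pd.DataFrame, cond_a: str, cond_b: str) -> pd.DataFrame:
    """Signed per-pair difference of condition means: mean(cond_a) - mean(cond_b)."""
    means = long.pivot(index="pair_label", columns="condition", values="mean_A")
    for c in (cond_a, cond_b):
        if c not in means.columns:
            raise KeyError(f"condition {c!r} absent from table")
    out = pd.DataFrame(
        {
            "pair_label": means.index,
            "cond_a": cond_a,
            "cond_b": cond_b,
            "delta_mean_A": (means[cond_a] - means[cond_b]).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def classify_contact(d: float, cutoff: float = 4.0) -> str:
    """'formed' iff the distance is at or below the salt-bridge cutoff."""
    if d <= 0:
        raise ValueError("distance must be positive")
    return "formed" if d <= cutoff else "broken"
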