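"""Seeded generators for every input class, with known ground truth.

Each generator is a pure function of its spec (seed included): the same spec
produces byte-identical output.  Geometry is idealized — minimal residues
(backbone CA plus the terminal charged atoms), axis-aligned placement — but
sufficient for every consumer operation, and coordinates are quantized to
0.001 A (the PDB field precision) at generation time so that written files
round-trip exactly and planted values are realized exactly in the emitted
coordinates.

Distance planting controls the MINIMUM over terminal-atom pairs (the measured
quantity): the designated primary atoms sit exactly the planted distance
apart along x, and every other terminal atom is placed strictly farther from
the opposing residue's atoms.

RMSD planting uses a construction that keeps the optimal superposition
rotation exactly the identity: two mirror clusters of k CA atoms at +/-x are
displaced by +/-u(t) along x inside a static anchor frame, so the net
translation is zero, the cross-covariance stays symmetric positive definite,
and the aligned RMSD equals sqrt(2k/N) * u(t) exactly.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError
from .model import (
    TERMINAL_CHARGED_ATOMS,
    AtomRecord,
    ResidueRef,
    StructureEnsemble,
)
from .bridges import ResiduePairSpec

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _q(x: float) -> float:
    """Quantize to the 0.001-A grid of the PDB coordinate field."""
    return round(float(x), 3)


def _qv(v: Sequence[float]) -> tuple[float, float, float]:
    return (_q(v[0]), _q(v[1]), _q(v[2]))


# ---------------------------------------------------------------------------
# Bridge ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPair:
    """One residue pair with the target minimum-distance distribution."""

    pair: ResiduePairSpec
    mean_A: float
    sd_A: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_A <= 0 or self.sd_A < 0:
            raise ValueError("require mean_A > 0 and sd_A >= 0")


@dataclass(frozen=True)
class BridgeEnsembleSpec:
    """Multi-model ensemble with charged pairs at planted distances."""

    pairs: tuple[PlantedPair, ...]
    n_models: int = 1
    decoy_atom_count: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        labels = [p.pair.label for p in self.pairs]
        if len(set(labels)) != len(labels):
            raise ValueError("pair labels must be unique")
        keys = [
            (r.chain_id, r.resid, r.icode) for p in self.pairs for r in (p.pair.a, p.pair.b)
        ]
        if len(set(keys)) != len(keys):
            raise ValueError(
                "planted residues must be distinct (a residue cannot occupy two "
                "planted positions); give shared residues distinct chains"
            )


def _draw_distance(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated to > 0.5 A, quantized."""
    if sd == 0.0:
        d = mean
        if d <= 0.5:
            raise GenerationError(f"planted mean {mean} A is below the 0.5 A floor")
        return _q(d)
    for _ in range(100):
        d = rng.normal(mean, sd)
        if d > 0.5:
            return _q(d)
    raise GenerationError(f"could not draw a distance > 0.5 A from N({mean}, {sd})")


def _residue_atoms(
    ref: ResidueRef,
    model_id: int,
    base: np.ndarray,
    primary_offset: np.ndarray,
    secondary_axis: np.ndarray,
    ca_offset: np.ndarray,
) -> list[AtomRecord]:
    """Minimal residue: CA plus the terminal charged atoms of its type.

    The first listed terminal atom goes at ``base + primary_offset``; the
    remaining ones step away along ``secondary_axis`` so they are strictly
    farther from the opposing residue.  The CA sits at ``base + ca_offset``,
    independent of the planted distance, so backbone positions stay static
    along a trajectory whose side-chain distance varies.
    """
    names = TERMINAL_CHARGED_ATOMS[ref.resname]
    atoms = []
    ca_pos = base + ca_offset
    atoms.append(
        AtomRecord(
            model_id=model_id,
            chain_id=ref.chain_id,
            resid=ref.resid,
            icode=ref.icode,
            resname=ref.resname,
            atom_name="CA",
            element="C",
            altloc="",
            xyz=_qv(ca_pos),
        )
    )
    for j, name in enumerate(names):
        pos = base + primary_offset + j * 2.0 * secondary_axis
        atoms.append(
            AtomRecord(
                model_id=model_id,
                chain_id=ref.chain_id,
                resid=ref.resid,
                icode=ref.icode,
                resname=ref.resname,
                atom_name=name,
                element=name[0],
                altloc="",
                xyz=_qv(pos),
            )
        )
    return atoms


def _pair_block(
    p: ResiduePairSpec, d: float, model_id: int, offset: np.ndarray
) -> list[AtomRecord]:
    """Residues a and b with min terminal-atom distance exactly d.

    a's primary atom at offset, extras stepping along +z; b's primary at
    offset + (d, 0, 0), extras stepping along +x.  Every non-primary pairing
    is then strictly longer than d.
    """
    x = np.array([1.0, 0.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    atoms = _residue_atoms(p.a, model_id, offset, np.zeros(3), z, np.array([-3.0, -3.0, 0.0]))
    atoms += _residue_atoms(p.b, model_id, offset, d * x, x, np.array([28.0, -3.0, 0.0]))
    return atoms


def _decoy_atoms(
    rng: np.random.Generator,
    count: int,
    model_id: int,
    keep_away_from: np.ndarray,
    min_dist: float,
) -> list[AtomRecord]:
    atoms = []
    for k in range(count):
        for _ in range(200):
            pos = rng.uniform(-60.0, 60.0, size=3)
            if keep_away_from.size == 0 or np.linalg.norm(
                keep_away_from - pos, axis=1
            ).min() >= min_dist:
                break
        else:
            raise GenerationError("could not place decoy atoms")
        atoms.append(
            AtomRecord(
                model_id=model_id,
                chain_id="Z",
                resid=500 + k,
                icode="",
                resname="GLY",
                atom_name="CA",
                element="C",
                altloc="",
                xyz=_qv(pos),
            )
        )
    return atoms


def gen_bridge_ensemble(s: BridgeEnsembleSpec) -> tuple[StructureEnsemble, pd.DataFrame]:
    """Ensemble with planted pair distances, plus the ground-truth table.

    Truth columns: model (1-based), pair_label, distance_A (the realized,
    quantized minimum terminal-atom distance).
    """
    rng = np.random.default_rng(s.seed)
    # draw all distances first so decoy placement does not perturb the stream
    draws = {
        p.pair.label: [_draw_distance(rng, p.mean_A, p.sd_A) for _ in range(s.n_models)]
        for p in s.pairs
    }
    # decoys are static across models (topology and coordinates)
    pair_anchor_points = np.array(
        [[0.0, 60.0 * k, 0.0] for k in range(len(s.pairs))]
    ) if s.pairs else np.empty((0, 3))
    decoys = _decoy_atoms(rng, s.decoy_atom_count, 1, pair_anchor_points, 35.0)

    models: list[list[AtomRecord]] = []
    rows = []
    for m in range(1, s.n_models + 1):
        atoms: list[AtomRecord] = []
        for k, p in enumerate(s.pairs):
            d = draws[p.pair.label][m - 1]
            offset = np.array([0.0, 60.0 * k, 0.0])
            atoms += _pair_block(p.pair, d, m, offset)
            rows.append({"model": m, "pair_label": p.pair.label, "distance_A": d})
        atoms += [
            AtomRecord(
                model_id=m,
                chain_id=a.chain_id,
                resid=a.resid,
                icode=a.icode,
                resname=a.resname,
                atom_name=a.atom_name,
                element=a.element,
                altloc=a.altloc,
                xyz=a.xyz,
            )
            for a in decoys
        ]
        models.append(atoms)
    truth = pd.DataFrame(rows, columns=["model", "pair_label", "distance_A"])
    return StructureEnsemble(models=models, source_label=""), truth


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairProcess:
    """Distance process of one pair along a trajectory.

    Post-changepoint frames fluctuate around ``mean_A`` with sd
    ``fluct_sd_A``; before the changepoint an optional linear drift starting
    at ``mean_A + pre_onset_drift_A`` decays to the mean.
    """

    pair: ResiduePairSpec
    mean_A: float
    fluct_sd_A: float = 0.0
    pre_onset_drift_A: float = 0.0


@dataclass(frozen=True)
class TrajectorySpec:
    """Trajectory frames with a planted RMSD changepoint and pair processes."""

    pairs: tuple[PairProcess, ...]
    n_frames: int = 500
    frame_interval: float = 0.2  # ns
    changepoint: int = 150
    plateau_rmsd_A: float = 3.0
    rmsd_noise_A: float = 0.05
    cluster_size: int = 5
    seed: int = 0
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 <= self.changepoint < self.n_frames):
            raise ValueError("changepoint must lie inside the trajectory")


_ANCHORS = [
    (50.0, 0.0, 0.0),
    (-50.0, 0.0, 0.0),
    (0.0, 50.0, 0.0),
    (0.0, -50.0, 0.0),
    (0.0, 0.0, 50.0),
    (0.0, 0.0, -50.0),
]


def _scaffold_atoms(model_id: int, u: float, k: int) -> list[AtomRecord]:
    """Static anchors plus the two mirror clusters displaced by +/-u along x."""
    atoms = []
    resid = 1
    for pos in _ANCHORS:
        atoms.append(
            AtomRecord(model_id, "R", resid, "", "GLY", "CA", "C", "", _qv(pos))
        )
        resid += 1
    for j in range(k):
        atoms.append(
            AtomRecord(
                model_id, "R", resid, "", "GLY", "CA", "C", "",
                _qv((20.0 + 2.0 * j + u, 0.0, 0.0)),
            )
        )
        resid += 1
    for j in range(k):
        atoms.append(
            AtomRecord(
                model_id, "R", resid, "", "GLY", "CA", "C", "",
                _qv((-(20.0 + 2.0 * j) - u, 0.0, 0.0)),
            )
        )
        resid += 1
    return atoms


def gen_trajectory(s: TrajectorySpec) -> tuple[StructureEnsemble, pd.DataFrame]:
    """Trajectory frames plus the ground-truth series.

    Truth columns: frame (0-based), time_ns, rmsd_A, and one ``d_<label>``
    column per pair with the realized (quantized) planted distance.
    """
    rng = np.random.default_rng(s.seed)
    k = s.cluster_size
    n_scaffold = len(_ANCHORS) + 2 * k
    n_pair_ca = 2 * len(s.pairs)
    n_sel = n_scaffold + n_pair_ca  # every CA enters the default RMSD selection
    scale = np.sqrt(2.0 * k / n_sel)

    # displacement profile: linear rise to the changepoint, then noisy plateau
    u_plateau = s.plateau_rmsd_A / scale
    u = np.empty(s.n_frames)
    cp = max(s.changepoint, 1)
    for f in range(s.n_frames):
        if f < s.changepoint:
            base = u_plateau * f / cp
            jitter = 0.0
        else:
            base = u_plateau
            jitter = rng.normal(0.0, s.rmsd_noise_A / scale) if s.rmsd_noise_A else 0.0
        u[f] = _q(max(base + jitter, 0.0))

    dists = {
        pp.pair.label: np.array(
            [
                _q(
                    max(
                        pp.mean_A
                        + (
                            pp.pre_onset_drift_A * (1.0 - f / cp)
                            if f < s.changepoint
                            else 0.0
                        )
                        + (rng.normal(0.0, pp.fluct_sd_A) if pp.fluct_sd_A else 0.0),
                        0.501,
                    )
                )
                for f in range(s.n_frames)
            ]
        )
        for pp in s.pairs
    }

    models = []
    for f in range(s.n_frames):
        model_id = f + 1
        atoms = _scaffold_atoms(model_id, u[f], k)
        for kp, pp in enumerate(s.pairs):
            offset = np.array([0.0, 200.0 + 60.0 * kp, 0.0])
            atoms += _pair_block(pp.pair, dists[pp.pair.label][f], model_id, offset)
        models.append(atoms)

    truth = pd.DataFrame(
        {
            "frame": np.arange(s.n_frames),
            "time_ns": np.arange(s.n_frames) * s.frame_interval,
            "rmsd_A": scale * u,
        }
    )
    for label, d in dists.items():
        truth[f"d_{label}"] = d
    return StructureEnsemble(models=models, source_label=s.source_label), truth


# ---------------------------------------------------------------------------
# Ca2+ coordination sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaSiteSpec:
    """One ion with a planted oxygen shell plus decoy atoms beyond 5 A."""

    n_oxygens: int
    radius_A: float | tuple[float, ...] = 2.3
    decoys: int = 10
    seed: int = 0


def _shell_points(rng: np.random.Generator, radii: np.ndarray, min_sep: float) -> np.ndarray:
    """Points at the given radii in random directions, >= min_sep apart (bounded retries)."""
    points: list[np.ndarray] = []
    for r in radii:
        for _ in range(500):
            v = rng.normal(size=3)
            p = r * v / np.linalg.norm(v)
            if all(np.linalg.norm(p - q) >= min_sep for q in points):
                points.append(p)
                break
        else:
            raise GenerationError(
                f"could not place {radii.size} oxygens with {min_sep} A mutual separation"
            )
    return np.array(points)


def gen_ca_site(s: CaSiteSpec) -> tuple[StructureEnsemble, pd.DataFrame]:
    """Single-model ensemble: CA ion at the origin, oxygens at planted radii.

    Truth columns: oxygen index, planted radius, realized (quantized)
    distance from the ion.
    """
    rng = np.random.default_rng(s.seed)
    radii = (
        np.full(s.n_oxygens, float(s.radius_A))
        if np.isscalar(s.radius_A)
        else np.asarray(s.radius_A, dtype=float)
    )
    if radii.size != s.n_oxygens:
        raise ValueError("radius_A tuple must have n_oxygens entries")
    atoms = [
        AtomRecord(1, "I", 1, "", "CA", "CA", "CA", "", (0.0, 0.0, 0.0), is_hetero=True)
    ]
    rows = []
    if s.n_oxygens:
        points = _shell_points(rng, radii, 1.5)
        for j in range(s.n_oxygens):
            pos = _qv(points[j])
            atoms.append(
                AtomRecord(1, "W", 100 + j, "", "HOH", "O", "O", "", pos, is_hetero=True)
            )
            rows.append(
                {
                    "oxygen": j,
                    "planted_radius_A": radii[j],
                    "realized_distance_A": float(np.linalg.norm(pos)),
                }
            )
    for k in range(s.decoys):
        for _ in range(200):
            pos = rng.uniform(-15.0, 15.0, size=3)
            if np.linalg.norm(pos) >= 5.0:
                break
        else:  # pragma: no cover
            raise GenerationError("could not place decoys beyond 5 A")
        elem = "O" if k % 2 == 0 else "C"
        atoms.append(
            AtomRecord(
                1, "D", 300 + k, "", "GLY", "O" if elem == "O" else "CA", elem, "", _qv(pos)
            )
        )
    ensemble = StructureEnsemble(models=[atoms], source_label="")
    truth = pd.DataFrame(rows, columns=["oxygen", "planted_radius_A", "realized_distance_A"])
    return ensemble, truth


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentSpec:
    """Grouped alignment with exact per-column conservation by construction.

    Default columns are fully conserved at a residue cycling through the
    amino-acid alphabet.  ``fingerprint_columns`` are 100% one residue in the
    focal group and 100% a different residue everywhere else.
    ``variable_columns`` give every sequence of every group a distinct
    residue (low identity).  ``levels`` overrides single columns:
    column -> group -> (residue, identity_percent[, "gap"]) realized as exact
    counts, the remainder filled with distinct other residues or gaps.
    """

    groups: tuple[tuple[str, int], ...]
    L: int
    focal_group: str = ""
    fingerprint_columns: tuple[int, ...] = ()
    variable_columns: tuple[int, ...] = ()
    levels: Mapping[int, Mapping[str, tuple]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("alignment length must be >= 1")
        if self.fingerprint_columns and not self.focal_group:
            raise ValueError("fingerprint columns need a focal_group")


def _column_residues(
    spec: AlignmentSpec, col: int, group: str, size: int
) -> list[str]:
    """Residues of one (1-based) column for one group, exact counts."""
    if col in spec.levels and group in spec.levels[col]:
        entry = spec.levels[col][group]
        residue, level = entry[0], float(entry[1])
        fill_gap = len(entry) > 2 and entry[2] == "gap"
        n_modal = int(round(level * size / 100.0))
        out = [residue] * n_modal
        others = [r for r in AMINO_ALPHABET if r != residue]
        for j in range(size - n_modal):
            out.append("-" if fill_gap else others[j % len(others)])
        return out
    if col in spec.variable_columns:
        return [AMINO_ALPHABET[(j * 7 + col) % len(AMINO_ALPHABET)] for j in range(size)]
    if col in spec.fingerprint_columns:
        focal_res = AMINO_ALPHABET[col % len(AMINO_ALPHABET)]
        contrast_res = AMINO_ALPHABET[(col + 1) % len(AMINO_ALPHABET)]
        return [focal_res if group == spec.focal_group else contrast_res] * size
    return [AMINO_ALPHABET[(col * 3) % len(AMINO_ALPHABET)]] * size


def gen_alignment(s: AlignmentSpec) -> tuple[str, str, pd.DataFrame]:
    """(FASTA text, group-map TSV text, per-group per-column truth table).

    Truth columns: column (1-based), group, modal_residue, identity_percent —
    exact by construction, no sampling.
    """
    seqs: dict[str, list[str]] = {}
    ids: list[tuple[str, str]] = []
    for gname, size in s.groups:
        for j in range(size):
            sid = f"{gname}_{j + 1}"
            ids.append((sid, gname))
            seqs[sid] = []
    truth_rows = []
    for col in range(1, s.L + 1):
        for gname, size in s.groups:
            residues = _column_residues(s, col, gname, size)
            members = [sid for sid, g in ids if g == gname]
            for sid, r in zip(members, residues):
                seqs[sid].append(r)
            counts = Counter(r for r in residues if r != "-")
            if counts:
                top = max(counts.values())
                modal = min(r for r, c in counts.items() if c == top)
                identity = 100.0 * counts[modal] / size
            else:
                modal, identity = "", 0.0
            truth_rows.append(
                {
                    "column": col,
                    "group": gname,
                    "modal_residue": modal,
                    "identity_percent": identity,
                }
            )
    fasta = io.StringIO()
    for sid, _ in ids:
        fasta.write(f">{sid}\n{''.join(seqs[sid])}\n")
    group_map = "".join(f"{sid}\t{g}\n" for sid, g in ids)
    truth = pd.DataFrame(truth_rows, columns=["column", "group", "modal_residue", "identity_percent"])
    return fasta.getvalue(), group_map, truth


# ---------------------------------------------------------------------------
# Current traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    """Single-exponential whole-cell trace with additive Gaussian noise.

    Defaults mirror a fast-inactivating trace: 10 kHz sampling, 60 ms pulse
    at -160 mV, tau 10 ms, inward current of -100 pA at the start of the
    pulse; pre-pulse baseline 0 pA.
    """

    i0_pA: float = -100.0
    i_inf_pA: float = -5.0
    tau_ms: float = 10.0
    noise_sd_pA: float = 0.0
    sampling_rate: float = 10000.0
    pulse_start_ms: float = 5.0
    pulse_duration_ms: float = 60.0
    seed: int = 0


def gen_current_trace(s: TraceSpec) -> str:
    """CSV text (time_ms, current_pA) with the generator seed in the header."""
    dt = 1000.0 / s.sampling_rate
    n = int(round((s.pulse_start_ms + s.pulse_duration_ms) / dt))
    t = np.arange(n) * dt
    i = np.zeros(n)
    pulse = t >= s.pulse_start_ms - 1e-9
    trel = t[pulse] - s.pulse_start_ms
    i[pulse] = s.i_inf_pA + (s.i0_pA - s.i_inf_pA) * np.exp(-trel / s.tau_ms)
    if s.noise_sd_pA:
        rng = np.random.default_rng(s.seed)
        i[pulse] += rng.normal(0.0, s.noise_sd_pA, size=pulse.sum())
    out = io.StringIO()
    out.write(f"# gatemap synthetic trace seed={s.seed}\n")
    out.write(
        f"# i0_pA={s.i0_pA} i_inf_pA={s.i_inf_pA} tau_ms={s.tau_ms} "
        f"noise_sd_pA={s.noise_sd_pA} pulse_start_ms={s.pulse_start_ms} "
        f"pulse_duration_ms={s.pulse_duration_ms}\n"
    )
    out.write("time_ms,current_pA\n")
    for tv, iv in zip(t, i):
        out.write(f"{tv:.6f},{iv:.6f}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Paper-shaped scenario bundle
# ---------------------------------------------------------------------------

def canonical_pairs() -> list[ResiduePairSpec]:
    """The four interdomain pairs, TRPV6 numbering, one chain per pair.

    R606 takes part in two pairs; planting both at independent distances
    requires each pair to live in its own chain.
    """
    return [
        ResiduePairSpec(
            "HLH-TDhC",
            ResidueRef("A", 294, "GLU"),
            ResidueRef("A", 606, "ARG"),
        ),
        ResiduePairSpec(
            "HLH-TDhN",
            ResidueRef("B", 302, "ARG"),
            ResidueRef("B", 588, "GLU"),
        ),
        ResiduePairSpec(
            "ARD6-HLH",
            ResidueRef("C", 245, "LYS"),
            ResidueRef("C", 288, "GLU"),
        ),
        ResiduePairSpec(
            "S2S3-TDh",
            ResidueRef("D", 406, "ASP"),
            ResidueRef("D", 606, "ARG"),
        ),
    ]


#: Planted per-condition means (A) for the two channel archetypes: in the
#: TRPV6-like set the HLH stays in close contact with the TDh once Ca2+/CaM
#: is bound while ARD6-HLH stays apart; in the TRPV5-like set ARD6 holds the
#: HLH in both conditions and the HLH-TDh pairs stay long.
SCENARIO_MEANS: dict[str, dict[str, dict[str, float]]] = {
    "TRPV6-like": {
        "apo": {"HLH-TDhC": 12.0, "HLH-TDhN": 12.0, "ARD6-HLH": 15.0, "S2S3-TDh": 5.0},
        "Ca2+/CaM": {"HLH-TDhC": 4.0, "HLH-TDhN": 4.0, "ARD6-HLH": 15.0, "S2S3-TDh": 10.0},
    },
    "TRPV5-like": {
        "apo": {"HLH-TDhC": 12.0, "HLH-TDhN": 12.0, "ARD6-HLH": 4.0, "S2S3-TDh": 8.0},
        "Ca2+/CaM": {"HLH-TDhC": 13.0, "HLH-TDhN": 13.0, "ARD6-HLH": 4.0, "S2S3-TDh": 4.0},
    },
}


def scenario_ensembles(
    channel: str,
    *,
    seed: int = 0,
    n_structures: int = 2,
    n_models_each: int = 4,
    sd_A: float = 0.5,
) -> dict[str, list[StructureEnsemble]]:
    """Two-condition ensemble sets with the archetype's planted means."""
    if channel not in SCENARIO_MEANS:
        raise ValueError(f"unknown channel archetype {channel!r}")
    pairs = {p.label: p for p in canonical_pairs()}
    out: dict[str, list[StructureEnsemble]] = {}
    for c, (condition, means) in enumerate(SCENARIO_MEANS[channel].items()):
        ensembles = []
        for k in range(n_structures):
            spec = BridgeEnsembleSpec(
                pairs=tuple(
                    PlantedPair(pairs[label], mean, sd_A) for label, mean in means.items()
                ),
                n_models=n_models_each,
                seed=seed + 1000 * c + k,
            )
            e, _ = gen_bridge_ensemble(spec)
            e.source_label = condition
            ensembles.append(e)
        out[condition] = ensembles
    return out


def scenario_trajectories(
    channel: str, *, seed: int = 0, n_frames: int = 300, changepoint: int = 90
) -> dict[str, tuple[StructureEnsemble, pd.DataFrame]]:
    """Na+- vs Ca2+-condition trajectory pair for one channel archetype.

    TRPV6-like: the HLH-TDh distance relaxes to close contact only in CaCl2.
    TRPV5-like: the HLH-TDh stays long in both salts; Ca2+ instead tightens
    ARD6-HLH.
    """
    pairs = {p.label: p for p in canonical_pairs()}
    if channel == "TRPV6-like":
        means = {
            "NaCl": {"HLH-TDhC": 12.0, "ARD6-HLH": 15.0},
            "CaCl2": {"HLH-TDhC": 4.0, "ARD6-HLH": 15.0},
        }
    elif channel == "TRPV5-like":
        means = {
            "NaCl": {"HLH-TDhC": 12.0, "ARD6-HLH": 8.0},
            "CaCl2": {"HLH-TDhC": 12.0, "ARD6-HLH": 4.0},
        }
    else:
        raise ValueError(f"unknown channel archetype {channel!r}")
    out = {}
    for c, (cond, mm) in enumerate(means.items()):
        spec = TrajectorySpec(
            pairs=tuple(
                PairProcess(pairs[label], mean, fluct_sd_A=0.3, pre_onset_drift_A=2.0)
                for label, mean in mm.items()
            ),
            n_frames=n_frames,
            changepoint=changepoint,
            seed=seed + c,
            source_label=cond,
        )
        out[cond] = gen_trajectory(spec)
    return out


def scenario_traces(*, seed: int = 0, n_traces: int = 5) -> dict[str, list[str]]:
    """Trace sets for the two wild-type phenotypes.

    WT-TRPV6-like traces decay with tau ~ 10 ms to a small residual; the
    WT-TRPV5-like set barely decays within the 60 ms pulse (residual ~ 1,
    no resolvable tau).
    """
    out: dict[str, list[str]] = {"WT-TRPV6-like": [], "WT-TRPV5-like": []}
    for j in range(n_traces):
        out["WT-TRPV6-like"].append(
            gen_current_trace(
                TraceSpec(i0_pA=-100.0, i_inf_pA=-10.0, tau_ms=10.0, noise_sd_pA=2.0, seed=seed + j)
            )
        )
        out["WT-TRPV5-like"].append(
            gen_current_trace(
                TraceSpec(i0_pA=-100.0, i_inf_pA=-98.0, tau_ms=10.0, noise_sd_pA=2.0, seed=seed + 100 + j)
            )
        )
    return out
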