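"""Run-configuration driven orchestration of the analysis stages.

A run configuration (YAML or an equivalent dict) lists stages from the fixed
vocabulary {simulate, distances, sites, traj, conserve, ephys} with their
inputs and parameters.  Stages execute in declared order into per-stage
subdirectories; a consolidated ``report.md`` and a ``manifest.json`` (input
digests, parameters, seed, version) make the run self-documenting and
replayable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .bridges import (
    ResiduePairSpec,
    delta_table,
    state_comparison_table,
    wide_table,
)
from .conservation import column_identity, fingerprint_positions, read_alignment, scaffold_windows
from .errors import ConfigError
from .ion_sites import CoordinationConfig, find_coordination_sites
from .kinetics import analyze_trace, read_trace, summarize_metrics
from .model import ResidueRef, read_pdb, write_pdb
from .synth import (
    AlignmentSpec,
    BridgeEnsembleSpec,
    CaSiteSpec,
    PairProcess,
    PlantedPair,
    TraceSpec,
    TrajectorySpec,
    gen_alignment,
    gen_bridge_ensemble,
    gen_ca_site,
    gen_current_trace,
    gen_trajectory,
    scenario_ensembles,
    scenario_traces,
    scenario_trajectories,
)
from .trajectory import TrajectoryMeta, pair_distance_series, rmsd_series, stability_onset

logger = logging.getLogger(__name__)

STAGE_VOCABULARY = ("simulate", "distances", "sites", "traj", "conserve", "ephys")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def parse_pair(entry: Mapping[str, Any]) -> ResiduePairSpec:
    """Pair spec from config: {label, a: {chain, resid, resname[, icode]}, b: {...}}."""

    def ref(d: Mapping[str, Any]) -> ResidueRef:
        return ResidueRef(
            chain_id=str(d["chain"]),
            resid=int(d["resid"]),
            resname=str(d["resname"]).upper(),
            icode=str(d.get("icode", "")),
        )

    return ResiduePairSpec(
        label=str(entry["label"]),
        a=ref(entry["a"]),
        b=ref(entry["b"]),
        chain_mode=str(entry.get("chain_mode", "intra")),
    )


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Load and validate a run configuration; raises ConfigError before any stage runs."""
    if isinstance(source, Mapping):
        cfg = dict(source)
        base = Path(cfg.get("_base", "."))
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        cfg = yaml.safe_load(path.read_text())
        base = path.parent
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    cfg.setdefault("seed", 0)
    cfg.setdefault("output_dir", "gatemap_out")
    stages = cfg.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ConfigError("config needs a non-empty 'stages' list")
    for i, st in enumerate(stages):
        if not isinstance(st, dict) or "stage" not in st:
            raise ConfigError(f"stage {i}: each entry needs a 'stage' key")
        if st["stage"] not in STAGE_VOCABULARY:
            raise ConfigError(
                f"stage {i}: unknown stage {st['stage']!r}; valid: {STAGE_VOCABULARY}"
            )
        for f in _referenced_files(st):
            p = (base / f).resolve() if not Path(f).is_absolute() else Path(f)
            if not p.exists():
                raise ConfigError(f"stage {i} ({st['stage']}): input file {f} does not exist")
    cfg["_base"] = str(base)
    return cfg


def _referenced_files(stage: Mapping[str, Any]) -> list[str]:
    files: list[str] = []
    name = stage["stage"]
    if name == "distances":
        for paths in stage.get("conditions", {}).values():
            files.extend(paths)
    elif name in ("sites", "traj"):
        if "file" in stage:
            files.append(stage["file"])
    elif name == "conserve":
        files.extend(stage[k] for k in ("fasta", "groups") if k in stage)
    elif name == "ephys":
        files.extend(stage.get("traces", []))
    return files


def _resolve(base: str, f: str) -> Path:
    p = Path(f)
    return p if p.is_absolute() else Path(base) / f


# ---------------------------------------------------------------------------
# Stage runners (each writes its outputs and returns report lines)
# ---------------------------------------------------------------------------

def _run_distances(stage: dict, out: Path, base: str, seed: int) -> list[str]:
    pairs = [parse_pair(p) for p in stage["pairs"]]
    conditions = {
        cond: [read_pdb(_resolve(base, f).read_text(), source_label=cond) for f in paths]
        for cond, paths in stage["conditions"].items()
    }
    long = state_comparison_table(conditions, pairs)
    long.to_csv(out / "distances_long.csv", index=False)
    wide_table(long).to_csv(out / "distances_wide.tsv", sep="\t")
    lines = ["### Pair distances", "", long.to_string(index=False), ""]
    delta_pair = stage.get("delta")
    if delta_pair:
        d = delta_table(long, delta_pair[0], delta_pair[1])
        d.to_csv(out / "delta.csv", index=False)
        lines += ["### Delta (cond_a - cond_b)", "", d.to_string(index=False), ""]
    return lines


def _run_sites(stage: dict, out: Path, base: str, seed: int) -> list[str]:
    cfg = CoordinationConfig(
        distance_cutoff=float(stage.get("cutoff", 2.5)),
        min_oxygens=int(stage.get("min_ox", 4)),
        max_oxygens=int(stage.get("max_ox", 8)),
        include_water=bool(stage.get("include_water", True)),
    )
    ensemble = read_pdb(_resolve(base, stage["file"]).read_text(), keep_hetero=True)
    rows = []
    for model in ensemble.models:
        for s in find_coordination_sites(model, cfg):
            rows.append(
                {
                    "model_id": s.model_id,
                    "ion": f"{s.ion.chain_id}/{s.ion.resname}{s.ion.resid}",
                    "count": s.count,
                    "mean_distance_A": s.mean_distance,
                    "qualifies": s.qualifies,
                }
            )
    df = pd.DataFrame(rows, columns=["model_id", "ion", "count", "mean_distance_A", "qualifies"])
    df.to_csv(out / "sites.csv", index=False)
    n_q = int(df["qualifies"].sum()) if len(df) else 0
    return ["### Coordination sites", "", f"{len(df)} ion-model records, {n_q} qualifying", ""]


def _run_traj(stage: dict, out: Path, base: str, seed: int) -> list[str]:
    traj = read_pdb(_resolve(base, stage["file"]).read_text(), source_label=stage.get("condition", ""))
    meta = TrajectoryMeta(frame_interval=float(stage.get("frame_interval", 0.2)))
    series = rmsd_series(traj, meta)
    pd.DataFrame({"time_ns": series.times, "rmsd_A": series.values}).to_csv(
        out / "rmsd.csv", index=False
    )
    onset = stability_onset(
        series,
        window=int(stage.get("window", 50)),
        slope_tol=float(stage.get("slope_tol", 0.05)),
    )
    (out / "onset.json").write_text(
        json.dumps(
            {
                "onset_index": onset.onset_index,
                "onset_time_ns": onset.onset_time,
                "window": onset.window,
                "slope_tol": onset.slope_tol,
            },
            indent=2,
        )
    )
    lines = ["### Trajectory", "", f"stability onset: frame {onset.onset_index} ({onset.onset_time:.1f} ns)", ""]
    frames = []
    for p in stage.get("pairs", []):
        pair = parse_pair(p)
        times, values, stat = pair_distance_series(
            traj, pair, onset, frame_interval=meta.frame_interval
        )
        frames.append(
            pd.DataFrame({"time_ns": times, f"d_{pair.label}_A": values})
            .set_index("time_ns")
        )
        lines.append(
            f"- {pair.label}: post-onset mean {stat.mean_A:.2f} ± {stat.sd_A:.2f} A (n={stat.n})"
        )
    if frames:
        pd.concat(frames, axis=1).to_csv(out / "pair_series.csv")
        lines.append("")
    return lines


def _run_conserve(stage: dict, out: Path, base: str, seed: int) -> list[str]:
    ga = read_alignment(
        _resolve(base, stage["fasta"]).read_text(),
        _resolve(base, stage["groups"]).read_text(),
    )
    group_names = sorted(set(ga.groups.values()))
    profiles = {g: column_identity(ga, g) for g in group_names}
    rows = []
    for g, prof in profiles.items():
        for col, r in prof.columns.iterrows():
            rows.append(
                {
                    "group": g,
                    "column": col,
                    "modal": r["modal_residue"],
                    "identity": r["identity_percent"],
                    "n_nongap": r["n_nongap"],
                }
            )
    pd.DataFrame(rows).to_csv(out / "conservation.tsv", sep="\t", index=False)
    lines = ["### Conservation", ""]
    focal = stage.get("focal")
    contrast = stage.get("contrast")
    if focal and contrast:
        hits = fingerprint_positions(
            profiles[focal],
            profiles[contrast],
            t_high=float(stage.get("t_high", 80.0)),
            t_low=float(stage.get("t_low", 50.0)),
        )
        pd.DataFrame([vars(h) for h in hits]).to_csv(out / "fingerprints.tsv", sep="\t", index=False)
        lines.append(f"fingerprint columns ({focal} vs {contrast}): {[h.column for h in hits]}")
    if focal:
        windows = scaffold_windows(
            profiles[focal],
            threshold=float(stage.get("scaffold_threshold", 70.0)),
            min_len=int(stage.get("scaffold_min_len", 3)),
        )
        lines.append(f"scaffold windows in {focal}: {windows}")
    lines.append("")
    return lines


def _run_ephys(stage: dict, out: Path, base: str, seed: int) -> list[str]:
    rows = []
    metrics = []
    for f in stage["traces"]:
        tr = read_trace(
            _resolve(base, f).read_text(),
            pulse_start=stage.get("pulse_start"),
            pulse_duration=float(stage.get("pulse_duration", 60.0)),
        )
        m = analyze_trace(
            tr,
            edge_ms=float(stage.get("edge_ms", 5.0)),
            blank_ms=float(stage.get("blank_ms", 0.0)),
        )
        metrics.append(m)
        rows.append(
            {
                "trace": Path(f).name,
                "residual": m.residual,
                "tau_ms": m.tau,
                "converged": m.converged,
            }
        )
    df = pd.DataFrame(rows, columns=["trace", "residual", "tau_ms", "converged"])
    df.to_csv(out / "metrics.csv", index=False)
    summary = summarize_metrics(metrics)
    summary.to_csv(out / "summary.csv", index=False)
    return ["### Inactivation kinetics", "", df.to_string(index=False), "", summary.to_string(index=False), ""]


def _run_simulate(stage: dict, out: Path, base: str, seed: int) -> list[str]:
    what = stage.get("what", "scenario")
    stage_seed = int(stage.get("seed", seed))
    lines = [f"### Simulated inputs ({what})", ""]
    if what == "scenario":
        for channel in ("TRPV5-like", "TRPV6-like"):
            conditions = scenario_ensembles(channel, seed=stage_seed)
            for cond, ensembles in conditions.items():
                tag = cond.replace("/", "_").replace("+", "")
                for i, e in enumerate(ensembles):
                    (out / f"{channel}_{tag}_{i}.pdb").write_text(write_pdb(e))
            trajs = scenario_trajectories(channel, seed=stage_seed)
            for cond, (traj, truth) in trajs.items():
                (out / f"{channel}_traj_{cond}.pdb").write_text(write_pdb(traj))
                truth.to_csv(out / f"{channel}_traj_{cond}_truth.csv", index=False)
        for phenotype, traces in scenario_traces(seed=stage_seed).items():
            for i, csv in enumerate(traces):
                (out / f"{phenotype}_trace_{i}.csv").write_text(csv)
        lines.append("scenario bundle written (ensembles, trajectories, traces)")
    elif what == "bridge":
        spec = BridgeEnsembleSpec(
            pairs=tuple(
                PlantedPair(parse_pair(p), float(p["mean_A"]), float(p.get("sd_A", 0.0)))
                for p in stage["pairs"]
            ),
            n_models=int(stage.get("n_models", 1)),
            seed=stage_seed,
        )
        e, truth = gen_bridge_ensemble(spec)
        (out / "bridge.pdb").write_text(write_pdb(e))
        truth.to_csv(out / "bridge_truth.csv", index=False)
        lines.append(f"bridge ensemble: {e.n_models} models")
    elif what == "traj":
        spec = TrajectorySpec(
            pairs=tuple(
                PairProcess(
                    parse_pair(p), float(p["mean_A"]), float(p.get("fluct_sd_A", 0.0))
                )
                for p in stage.get("pairs", [])
            ),
            n_frames=int(stage.get("n_frames", 500)),
            changepoint=int(stage.get("changepoint", 150)),
            seed=stage_seed,
        )
        traj, truth = gen_trajectory(spec)
        (out / "traj.pdb").write_text(write_pdb(traj))
        truth.to_csv(out / "traj_truth.csv", index=False)
        lines.append(f"trajectory: {traj.n_models} frames")
    elif what == "casite":
        spec = CaSiteSpec(
            n_oxygens=int(stage.get("n_oxygens", 6)),
            radius_A=float(stage.get("radius_A", 2.3)),
            seed=stage_seed,
        )
        e, truth = gen_ca_site(spec)
        (out / "casite.pdb").write_text(write_pdb(e))
        truth.to_csv(out / "casite_truth.csv", index=False)
        lines.append(f"coordination site: {spec.n_oxygens} oxygens at {spec.radius_A} A")
    elif what == "aln":
        spec = AlignmentSpec(
            groups=tuple((g, int(n)) for g, n in stage["groups"].items()),
            L=int(stage.get("L", 40)),
            focal_group=stage.get("focal", ""),
            fingerprint_columns=tuple(stage.get("fingerprint_columns", [])),
            seed=stage_seed,
        )
        fasta, gmap, truth = gen_alignment(spec)
        (out / "aln.fasta").write_text(fasta)
        (out / "groups.tsv").write_text(gmap)
        truth.to_csv(out / "aln_truth.csv", index=False)
        lines.append(f"alignment: L={spec.L}")
    elif what == "trace":
        spec = TraceSpec(
            i0_pA=float(stage.get("i0_pA", -100.0)),
            i_inf_pA=float(stage.get("i_inf_pA", -5.0)),
            tau_ms=float(stage.get("tau_ms", 10.0)),
            noise_sd_pA=float(stage.get("noise_sd_pA", 0.0)),
            seed=stage_seed,
        )
        (out / "trace.csv").write_text(gen_current_trace(spec))
        lines.append(f"trace: tau={spec.tau_ms} ms")
    else:
        raise ConfigError(f"unknown simulate target {what!r}")
    lines.append("")
    return lines


_RUNNERS = {
    "simulate": _run_simulate,
    "distances": _run_distances,
    "sites": _run_sites,
    "traj": _run_traj,
    "conserve": _run_conserve,
    "ephys": _run_ephys,
}


def run_pipeline(config: str | Path | Mapping[str, Any], output_dir: str | Path | None = None) -> Path:
    """Execute all configured stages; returns the report directory.

    A stage failure aborts the run with the stage name; outputs of earlier
    stages are preserved.
    """
    cfg = load_config(config)
    base = cfg["_base"]
    seed = int(cfg["seed"])
    out_root = Path(output_dir) if output_dir is not None else _resolve(base, cfg["output_dir"])
    out_root.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_root / "run.log")
    logging.getLogger("gatemap").addHandler(handler)
    report = [f"# gatemap run report", "", f"version {__version__}, seed {seed}", ""]
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "stages": [],
    }
    try:
        for i, stage in enumerate(cfg["stages"], start=1):
            name = stage["stage"]
            stage_dir = out_root / f"{i:02d}_{name}"
            stage_dir.mkdir(parents=True, exist_ok=True)
            inputs = {
                f: _sha256(_resolve(base, f)) for f in _referenced_files(stage)
            }
            try:
                lines = _RUNNERS[name](stage, stage_dir, base, seed)
            except Exception as exc:
                raise RuntimeError(f"stage {i} ({name}) failed: {exc}") from exc
            report += [f"## Stage {i}: {name}", ""] + lines
            manifest["stages"].append(
                {
                    "index": i,
                    "stage": name,
                    "parameters": {k: v for k, v in stage.items() if k != "stage"},
                    "inputs_sha256": inputs,
                }
            )
    finally:
        (out_root / "report.md").write_text("\n".join(report) + "\n")
        (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        logging.getLogger("gatemap").removeHandler(handler)
        handler.close()
    return out_root
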