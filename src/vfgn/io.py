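"""Readers/writers, config schema, run manifests and the fixture bundle.

File dialects (all plain text; angles in degrees, coordinates in meters,
times in seconds, stated in every header):

* **Trajectory CSV** — ``#`` header comment block (schema version, units,
  arena radius, trial fields, pointed azimuth) followed by columns
  ``t,x,y,post_reveal``.  A legacy file missing the ``post_reveal`` column
  is accepted with the column defaulted to false (warning logged).
* **Phase-trace JSON sidecar** — one JSON object per trial next to its
  CSV, holding the pointed azimuth and phase timestamps.  A combined
  JSON-Lines log (one object per trial, samples inlined) is accepted by
  the reader and emitted alongside by the session writer.
* **Run manifest JSON** — schema version, config hashes, seeds and the
  per-trial file paths; re-running with the manifest reproduces outputs.
* **Session / agent configs** — YAML (or JSON), schema-versioned.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ArenaSpec, CueSet
from .metrics import Trajectory
from .protocol import TrialPhaseTrace, TrialSpec

logger = logging.getLogger("vfgn")

SCHEMA_VERSION = "1.0"

__all__ = [
    "SCHEMA_VERSION",
    "write_trajectory",
    "read_trajectory",
    "write_session_log",
    "read_session_log",
    "RunManifest",
    "write_manifest",
    "read_manifest",
    "verify_manifest",
    "load_session_config",
    "save_session_config",
    "generate_fixtures",
]


def _header_lines(trial: TrialSpec | None, arena: ArenaSpec | None, pointed) -> list[str]:
    lines = [
        f"# vfgn trajectory schema_version={SCHEMA_VERSION}",
        "# units: t=s x=m y=m angles=deg (azimuth CCW from +x, origin at arena center)",
    ]
    if arena is not None:
        lines.append(f"# arena_radius={arena.radius}")
    if trial is not None:
        lines.append(
            f"# trial_index={trial.index} phase={trial.phase_label} "
            f"goal_id={trial.goal_id} goal_x={trial.goal.center[0]:.6f} "
            f"goal_y={trial.goal.center[1]:.6f} goal_radius={trial.goal.radius}"
        )
    if pointed is not None:
        lines.append(f"# pointed_azimuth={pointed!r}")
    return lines


def write_trajectory(
    path,
    traj: Trajectory,
    trial: TrialSpec | None = None,
    arena: ArenaSpec | None = None,
    trace: TrialPhaseTrace | None = None,
) -> None:
    """Write a trajectory CSV plus its JSON sidecar (pointing + phase trace).

    Coordinates are serialized at full precision (repr round-trip).
    """
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(trial, arena, traj.pointed_azimuth):
            fh.write(line + "\n")
        fh.write("t,x,y,post_reveal\n")
        for t, x, y, prv in zip(traj.t, traj.x, traj.y, traj.post_reveal):
            fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r},{int(prv)}\n")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "pointed_azimuth": traj.pointed_azimuth,
        "start": list(traj.start),
        "phase_trace": asdict(trace) if trace is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV (and its sidecar, if present)."""
    path = Path(path)
    header = {}
    rows = []
    columns = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v
                continue
            if columns is None:
                columns = line.split(",")
                continue
            rows.append((lineno, line.split(",")))
    version = header.get("schema_version")
    if version is not None and version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise ValueError(
            f"schema version mismatch: file has {version}, reader supports {SCHEMA_VERSION}"
        )
    if columns is None or columns[:3] != ["t", "x", "y"]:
        raise ValueError(f"{path}: not a trajectory file (columns {columns})")
    has_pr = "post_reveal" in columns
    if not has_pr:
        logger.warning("%s: legacy file without post_reveal column; defaulting to false", path)
    t, x, y, pr = [], [], [], []
    last_t = -math.inf
    for lineno, parts in rows:
        ti = float(parts[0])
        if ti <= last_t:
            raise ValueError(f"{path}: non-monotone timestamp at row {lineno}")
        last_t = ti
        t.append(ti)
        x.append(float(parts[1]))
        y.append(float(parts[2]))
        pr.append(bool(int(parts[3])) if has_pr else False)
    pointed = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        pointed = json.loads(sidecar.read_text()).get("pointed_azimuth")
    elif "pointed_azimuth" in header:
        raw = header["pointed_azimuth"]
        pointed = None if raw == "None" else float(raw)
    return Trajectory(
        np.array(t), np.array(x), np.array(y), (x[0], y[0]), pointed, np.array(pr)
    )


def write_session_log(path, session, trajectories, traces) -> None:
    """Combined JSON-Lines log: one object per trial, samples inlined."""
    path = Path(path)
    with path.open("w") as fh:
        meta = {
            "schema_version": SCHEMA_VERSION,
            "kind": "session_log",
            "arena_radius": session.arena.radius,
            "rng_seed": session.rng_seed,
            "units": "t=s xy=m angles=deg",
        }
        fh.write(json.dumps(meta) + "\n")
        for trial, traj, trace in zip(session.trials, trajectories, traces):
            rec = {
                "trial_index": trial.index,
                "phase": trial.phase_label,
                "goal_id": trial.goal_id,
                "goal": {"center": list(trial.goal.center), "radius": trial.goal.radius,
                         "active": trial.goal.active, "visible": trial.goal.visible},
                "start": list(trial.start),
                "pointed_azimuth": traj.pointed_azimuth,
                "phase_trace": asdict(trace) if trace else None,
                "t": [float(v) for v in traj.t],
                "x": [float(v) for v in traj.x],
                "y": [float(v) for v in traj.y],
                "post_reveal": [int(v) for v in traj.post_reveal],
            }
            fh.write(json.dumps(rec) + "\n")


def read_session_log(path) -> list[Trajectory]:
    """Read a combined JSON-Lines session log back into trajectories."""
    path = Path(path)
    trajs = []
    with path.open() as fh:
        meta = json.loads(fh.readline())
        ver = str(meta.get("schema_version"))
        if ver.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
            raise ValueError(
                f"schema version mismatch: file has {ver}, reader supports {SCHEMA_VERSION}"
            )
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            trajs.append(
                Trajectory(
                    np.array(rec["t"]),
                    np.array(rec["x"]),
                    np.array(rec["y"]),
                    tuple(rec["start"]),
                    rec["pointed_azimuth"],
                    np.array(rec["post_reveal"], dtype=bool),
                )
            )
    return trajs


# ---------------------------------------------------------------------------
# manifests and configs
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    schema_version: str
    session_config_hash: str
    agent_config_hash: str
    seeds: dict
    trial_files: list[str]
    created_by: str = "vfgn"


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def write_manifest(path, manifest: RunManifest) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=1))


def read_manifest(path) -> RunManifest:
    return RunManifest(**json.loads(Path(path).read_text()))


def verify_manifest(path) -> None:
    """Check that every file the manifest references exists."""
    path = Path(path)
    m = read_manifest(path)
    missing = [f for f in m.trial_files if not (path.parent / f).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")


def save_session_config(path, config: dict) -> None:
    config = {"schema_version": SCHEMA_VERSION, **config}
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_session_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    ver = str(cfg.get("schema_version", SCHEMA_VERSION))
    if ver.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise ValueError(
            f"schema version mismatch: config has {ver}, reader supports {SCHEMA_VERSION}"
        )
    return cfg


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def generate_fixtures(out_dir, seed: int = 7) -> dict:
    """Deterministic miniature dataset: 1 RM + 1 DMP session for 4 agents.

    Two agents per shipped preset run both sessions; trajectories, a
    metrics CSV and a manifest are written under ``out_dir``.  Used by
    tests and docs; the same seed always yields byte-identical metrics.
    """
    from .agents import make_cohort
    from .metrics import score_session
    from .pipeline import (
        default_dmp_goals,
        default_rm_goal,
        simulate_subject_session,
    )
    from .protocol import build_dmp_session, build_rm_session

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arena = ArenaSpec()
    cohort = make_cohort(
        {"healthy_like": "healthy_like", "impaired_like": "impaired_like"}, 2, seed
    )
    rng = np.random.default_rng(seed)
    frames = []
    trial_files = []
    for subj in cohort:
        for kind in ("rm", "dmp"):
            s_seed = int(rng.integers(2**31))
            a_seed = int(rng.integers(2**31))
            if kind == "rm":
                session = build_rm_session(
                    arena, CueSet.default(arena, "rm"), default_rm_goal(), s_seed
                )
            else:
                session = build_dmp_session(
                    arena, CueSet.default(arena, "dmp"), default_dmp_goals(), s_seed
                )
            from .agents import MemoryNavigator
            from .protocol import run_session

            policy = MemoryNavigator(subj.params, arena, np.random.default_rng(a_seed))
            trajs, traces = run_session(session, policy)
            for trial, traj, trace in zip(session.trials, trajs, traces):
                fname = f"{subj.subject_id}_{kind}_t{trial.index:02d}.csv"
                write_trajectory(out / fname, traj, trial, arena, trace)
                trial_files.append(fname)
            df = score_session(session, trajs)
            df.insert(0, "session", kind)
            df.insert(0, "subject", subj.subject_id)
            df.insert(1, "group", subj.group)
            frames.append(df)
    metrics = pd.concat(frames, ignore_index=True)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.10g")
    manifest = RunManifest(
        SCHEMA_VERSION,
        _sha256(b"builtin-default-session"),
        _sha256(b"builtin-presets"),
        {"root": seed},
        trial_files + ["metrics.csv"],
    )
    write_manifest(out / "manifest.json", manifest)
    return {"metrics": metrics_path, "manifest": out / "manifest.json", "n_files": len(trial_files)}
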