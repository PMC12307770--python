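"""File formats, run configuration, and the end-to-end pipeline driver.

All tables are UTF-8 comma-separated CSV with "." decimals; floats are
written with 17 significant digits so write-then-read reproduces values
exactly.  Structured results are JSON with sorted keys.  Every pipeline
output directory carries a ``manifest.json`` (package version, seed, and a
hash of the canonical config), and re-running the same config reproduces
the outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arenas import (
    DEFAULT_MIN_DWELL,
    ArenaSpec,
    Track,
    Visit,
    VisitSequence,
    get_arena,
    session_metrics,
)
from .consistency import RepeatedMeasures, repeatability
from .effects import effects_table
from .endpoints import (
    anxiety_score,
    make_endpoint_table,
    mean_transition_latency,
    success_rate,
)
from .modality import select_modality
from .synth import SimConfig, simulate_visits
from .ymaze import actions_table, arm_sequence_from_visits

log = logging.getLogger("swimassay")

FLOAT_FMT = "%.17g"

TRACK_COLUMNS = ["subject_id", "session_id", "t", "x", "y"]
VISIT_COLUMNS = ["subject_id", "session_id", "zone_id", "t_enter", "t_exit"]
RM_COLUMNS = ["subject_id", "session", "endpoint", "value"]


# ---------------------------------------------------------------------------
# track CSV (Ethovision-export-like dialect)
# ---------------------------------------------------------------------------

def read_track_csv(path, frame_rate: float = 30.0) -> list[Track]:
    """Read per-frame tracking CSV into :class:`Track` objects.

    Header ``subject_id,session_id,t,x,y[,zone]``.  Rows with empty
    ``x``/``y`` fields (lost frames) are dropped and counted; time must be
    strictly increasing within each session.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str},
                     float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV {path}: missing columns {missing}")
    n0 = len(df)
    df = df.dropna(subset=["t", "x", "y"])
    dropped = n0 - len(df)
    if dropped:
        log.info("track CSV %s: dropped %d row(s) with empty samples",
                 path, dropped)
    tracks = []
    for (sid, sess), g in df.groupby(["subject_id", "session_id"],
                                     sort=True):
        t = g["t"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError(
                f"track CSV {path}: time not strictly increasing in "
                f"session {sess!r} (subject {sid!r})"
            )
        tracks.append(Track(sid, sess, t, g["x"].to_numpy(dtype=float),
                            g["y"].to_numpy(dtype=float),
                            frame_rate=frame_rate))
    return tracks


def write_track_csv(tracks: list[Track], path) -> None:
    frames = [
        pd.DataFrame({
            "subject_id": tr.subject_id, "session_id": tr.session_id,
            "t": tr.t, "x": tr.x, "y": tr.y,
        })
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# visit CSV
# ---------------------------------------------------------------------------

def write_visits_csv(sequences: list[VisitSequence], path) -> None:
    rows = []
    for seq in sequences:
        for v in seq.visits:
            rows.append({
                "subject_id": seq.subject_id, "session_id": seq.session_id,
                "zone_id": v.zone_id, "t_enter": v.t_enter,
                "t_exit": v.t_exit,
            })
    pd.DataFrame(rows, columns=VISIT_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_visits_csv(path) -> list[VisitSequence]:
    """Session length is taken as the last visit's exit time (visit
    sequences written by this package cover the whole session)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str,
                                  "zone_id": str},
                     float_precision="round_trip")
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"visit CSV {path}: missing columns {missing}")
    out = []
    for (sid, sess), g in df.groupby(["subject_id", "session_id"],
                                     sort=True):
        visits = [Visit(r.zone_id, float(r.t_enter), float(r.t_exit))
                  for r in g.itertuples()]
        out.append(VisitSequence(sid, sess, visits,
                                 session_length=float(g["t_exit"].max())))
    return out


# ---------------------------------------------------------------------------
# repeated measures / endpoint tables
# ---------------------------------------------------------------------------

def write_repeated_csv(data: RepeatedMeasures, path) -> None:
    long = (
        data.values.reset_index()
        .melt(id_vars="subject_id", var_name="session", value_name="value")
        .dropna(subset=["value"])
    )
    long["endpoint"] = data.endpoint
    long[RM_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_repeated_csv(path, endpoint: str | None = None) -> RepeatedMeasures:
    df = pd.read_csv(path, dtype={"subject_id": str, "session": str},
                     float_precision="round_trip")
    missing = [c for c in RM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"repeated-measures CSV {path}: missing columns "
                         f"{missing}")
    if endpoint is None:
        eps = df["endpoint"].unique()
        if len(eps) != 1:
            raise ValueError(f"CSV holds endpoints {sorted(eps)}; pass one")
        endpoint = eps[0]
    sub = df[df["endpoint"] == endpoint]
    wide = sub.pivot_table(index="subject_id", columns="session",
                           values="value", aggfunc="first")
    return RepeatedMeasures(values=wide, endpoint=str(endpoint))


def write_endpoints_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_endpoints_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "session_id": str,
                                    "group": str, "endpoint": str},
                       float_precision="round_trip")


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )


def read_arena_json(path) -> ArenaSpec:
    return ArenaSpec.from_dict(json.loads(Path(path).read_text()))


def write_arena_json(arena: ArenaSpec, path) -> None:
    write_json(arena.to_dict(), path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end synthetic pipeline configuration.

    ``groups`` maps group name to overrides of the simulation parameters
    (e.g. a higher ``avoidance``); ``stages`` limits which analysis stages
    run (default: everything applicable to the assay and design).
    """

    assay_id: str
    seed: int
    out_dir: str = "swimassay_out"
    n_subjects: int = 24
    n_sessions: int = 1
    session_length: float = 600.0
    mean_dwell: float = 5.0
    avoidance: float = 0.0
    subject_sd: float = 0.3
    explorer_mixture: list = dc_field(default_factory=lambda: [[1.0, 1.0]])
    groups: dict = dc_field(default_factory=lambda: {"ctrl": {}})
    stages: list | None = None
    min_dwell: float = DEFAULT_MIN_DWELL
    n_boot: int = 1000
    k_max: int = 3

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls(**raw)

    def canonical_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded,
        so the same analysis hashes identically wherever it is written)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


ALL_STAGES = ["endpoints", "ymaze", "consistency", "modality", "effects"]


def _derived_seed(seed: int, *path: int) -> int:
    """Stable sub-seed below 2**31 for a (group, session) cell."""
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0]
               % (2**31 - 1))


def _assay_endpoints(assay_id, arena, sequences, session_id, group):
    """Tidy endpoint rows for one group-session batch of visit sequences."""
    zone_ids = [z.zone_id for z in arena.zones]
    metrics = {s.subject_id: session_metrics(s, zone_ids=zone_ids)
               for s in sequences}
    rows = []

    def add(sid, endpoint, value, censored=False):
        rows.append({"subject_id": sid, "session_id": session_id,
                     "group": group, "endpoint": endpoint, "value": value,
                     "censored": censored})

    if assay_id in ("slalom", "sj"):
        chambers = [z for z in zone_ids if z != "chamber_1"]
        lat = pd.DataFrame(
            {c: {sid: (m.per_zone[c].latency_s if not m.per_zone[c].censored
                       else np.nan)
                 for sid, m in metrics.items()}
             for c in chambers}
        )
        L = sequences[0].session_length
        mtl = mean_transition_latency(lat, session_length=L)
        for sid, val in mtl.items():
            add(sid, "mean_transition_latency", float(val))
        for sid, m in metrics.items():
            add(sid, "total_entries",
                float(sum(zm.entries for zm in m.per_zone.values())))
    elif assay_id == "spm":
        shallow = arena.zones_with_role("shallow_arm")
        times, lats, sids = [], [], []
        for sid, m in metrics.items():
            times.append(sum(m.per_zone[z].time_s for z in shallow))
            lats.append(min(m.per_zone[z].latency_s for z in shallow))
            sids.append(sid)
        scores = anxiety_score(times, lats)
        for sid, sc, tm, lt in zip(sids, scores, times, lats):
            add(sid, "anxiety_score", float(sc))
            add(sid, "shallow_time_s", float(tm))
            add(sid, "shallow_latency_s", float(lt),
                censored=all(metrics[sid].per_zone[z].censored
                             for z in shallow))
            add(sid, "shallow_entries",
                float(sum(metrics[sid].per_zone[z].entries
                          for z in shallow)))
    elif assay_id == "ot":
        for sid, m in metrics.items():
            add(sid, "periphery_time_pct", m.per_zone["periphery"].time_pct)
            add(sid, "center_entries", float(m.per_zone["center"].entries))
    elif assay_id == "sociability":
        for sid, m in metrics.items():
            for z in ("stimulus", "no_stimulus", "intersection"):
                add(sid, f"{z}_time_pct", m.per_zone[z].time_pct)
                add(sid, f"{z}_entries", float(m.per_zone[z].entries))
    elif assay_id == "ymaze":
        for sid, m in metrics.items():
            add(sid, "arm_entries",
                float(sum(zm.entries for zid, zm in m.per_zone.items()
                          if zid != "center")))
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, analyse, and write the output bundle.

    Stages run in dependency order: simulate -> endpoints -> (ymaze |
    consistency | modality | effects), each stage skipped when the design
    cannot support it (one session -> no repeatability; one group -> no
    effects; fewer than 9 subjects -> no modality).  Returns the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arena = get_arena(config.assay_id)
    stages = config.stages if config.stages is not None else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")

    # --- simulate -------------------------------------------------------
    all_sequences: dict[tuple[str, str], list[VisitSequence]] = {}
    for gi, (gname, overrides) in enumerate(sorted(config.groups.items())):
        for sess in range(1, config.n_sessions + 1):
            params = dict(
                assay_id=config.assay_id, n_subjects=config.n_subjects,
                session_length=config.session_length,
                mean_dwell=config.mean_dwell, avoidance=config.avoidance,
                subject_sd=config.subject_sd,
                explorer_mixture=[tuple(p) for p in config.explorer_mixture],
            )
            params.update(overrides)
            sim = SimConfig(seed=_derived_seed(config.seed, gi, sess),
                            **params)
            seqs, _ = simulate_visits(sim, arena)
            for s in seqs:
                s.subject_id = f"{gname}_{s.subject_id}"
                s.session_id = f"sess{sess}"
            all_sequences[(gname, f"sess{sess}")] = seqs
            log.info("simulated %s %s sess%d: %d subjects", config.assay_id,
                     gname, sess, len(seqs))
    flat = [s for seqs in all_sequences.values() for s in seqs]
    write_visits_csv(flat, out / "visits.csv")

    manifest = {
        "package": "swimassay", "version": __version__,
        "seed": config.seed, "config_hash": config.canonical_hash(),
        "assay_id": config.assay_id, "stages": [],
        "n_sequences": len(flat),
    }

    # --- endpoints ------------------------------------------------------
    table = None
    if "endpoints" in stages:
        rows = []
        for (gname, sess), seqs in sorted(all_sequences.items()):
            rows.extend(_assay_endpoints(config.assay_id, arena, seqs, sess,
                                         gname))
        table = make_endpoint_table(rows)
        write_endpoints_csv(table, out / "endpoints.csv")
        manifest["stages"].append("endpoints")
        if config.assay_id in ("slalom", "sj"):
            final = "chamber_12" if config.assay_id == "slalom" \
                else "chamber_4"
            summary = {
                f"{g}/{s}": success_rate(seqs, final, arena)
                for (g, s), seqs in sorted(all_sequences.items())
            }
            write_json({"final_chamber": final,
                        "success_rate_pct": summary}, out / "success.json")

    # --- ymaze actions --------------------------------------------------
    if "ymaze" in stages and config.assay_id == "ymaze":
        arm_seqs = {}
        for (gname, sess), seqs in sorted(all_sequences.items()):
            for s in seqs:
                arm_seqs[f"{s.subject_id}_{sess}"] = \
                    arm_sequence_from_visits(s)
        at = actions_table(arm_seqs)
        at.to_csv(out / "actions.csv", index=False, float_format=FLOAT_FMT)
        manifest["stages"].append("ymaze")

    # --- consistency ----------------------------------------------------
    if "consistency" in stages and config.n_sessions >= 2 and table is not None:
        results = {}
        for ep in sorted(table["endpoint"].unique()):
            wide = table[table["endpoint"] == ep].pivot_table(
                index="subject_id", columns="session_id", values="value",
                aggfunc="first",
            )
            try:
                rm = RepeatedMeasures(values=wide, endpoint=ep)
                est = repeatability(rm, n_boot=config.n_boot,
                                    seed=_derived_seed(config.seed, 9001))
                results[ep] = est.to_dict()
            except ValueError as exc:
                log.warning("repeatability skipped for %s: %s", ep, exc)
        write_json(results, out / "repeatability.json")
        manifest["stages"].append("consistency")

    # --- modality -------------------------------------------------------
    if "modality" in stages and table is not None:
        focal = {"slalom": "mean_transition_latency",
                 "sj": "mean_transition_latency",
                 "spm": "anxiety_score", "ot": "periphery_time_pct"}.get(
                     config.assay_id)
        if focal is not None:
            decisions = {}
            for gname in sorted(config.groups):
                vals = table[(table["endpoint"] == focal)
                             & (table["group"] == gname)]["value"].dropna()
                if len(vals) < 9:
                    log.warning("modality skipped for %s: n = %d < 9",
                                gname, len(vals))
                    continue
                dec = select_modality(
                    vals.to_numpy(), k_max=config.k_max,
                    seed=_derived_seed(config.seed, 9002),
                )
                decisions[gname] = dec.to_dict()
            if decisions:
                write_json({"endpoint": focal, "groups": decisions},
                           out / "modality.json")
                manifest["stages"].append("modality")

    # --- effects --------------------------------------------------------
    if "effects" in stages and table is not None and len(config.groups) == 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eff = effects_table(table)
        eff.to_csv(out / "effects.csv", index=False, float_format=FLOAT_FMT)
        manifest["stages"].append("effects")

    write_json(manifest, out / "manifest.json")
    return manifest
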