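"""Behavioral endpoints computed from visit sequences and session metrics.

The endpoints here are population-scaled: both the slalom mean transition
latency and the plus-maze anxiety score min-max scale their raw variables
across the analysis batch ("the investigated population") before combining
them, so a subject's value is only meaningful relative to the batch it was
scaled in.  The batch is whatever set of subjects is passed in together —
typically one species x experiment group.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .arenas import SessionMetrics, VisitSequence


def minmax_scale(values: np.ndarray | Iterable[float]) -> np.ndarray:
    """Min-max scale a population vector to [0, 1].

    A constant column maps to 0 for every subject (not NaN), which keeps
    downstream averages defined when e.g. all subjects are censored at the
    same session length.
    """
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# slalom: mean transition latency and success
# ---------------------------------------------------------------------------

def mean_transition_latency(
    latencies: pd.DataFrame,
    session_length: float | None = None,
) -> pd.Series:
    """Per-subject mean transition latency (MTL) in [0, 1].

    Parameters
    ----------
    latencies
        Subjects x chambers table of first-entry latencies (s); one column
        per chamber (chamber 2 onwards — the start chamber has no entry
        latency).  NaN means the chamber was never entered; those cells are
        censored at ``session_length`` before scaling.
    session_length
        Censoring value for missing entries; required if any cell is NaN.

    Each chamber column is min-max scaled across the population (constant
    columns scale to 0), and a subject's MTL is the mean of its scaled
    chamber latencies.
    """
    if latencies.shape[0] < 2:
        raise ValueError("MTL scaling needs at least 2 subjects")
    lat = latencies.astype(float).copy()
    if lat.isna().any().any():
        if session_length is None:
            raise ValueError("NaN latencies present: session_length required "
                             "for censoring")
        lat = lat.fillna(float(session_length))
    scaled = lat.apply(lambda col: pd.Series(minmax_scale(col.to_numpy()),
                                             index=col.index))
    mtl = scaled.mean(axis=1)
    mtl.name = "mean_transition_latency"
    return mtl


def success_rate(
    visit_sequences: Iterable[VisitSequence],
    final_chamber_id: str,
    arena=None,
) -> float:
    """Percent of subjects with at least one visit to the final chamber.

    If ``arena`` (an :class:`~swimassay.arenas.ArenaSpec`) is given, the
    chamber id is validated against it; otherwise it must at least share
    the naming family of the zones actually visited.
    """
    seqs = list(visit_sequences)
    if not seqs:
        raise ValueError("success_rate needs at least one subject")
    if arena is not None:
        arena.zone(final_chamber_id)  # KeyError on unknown id
    else:
        known = set()
        for s in seqs:
            known |= set(s.zone_sequence())
        if final_chamber_id not in known and not any(
            final_chamber_id.rsplit("_", 1)[0] == z.rsplit("_", 1)[0]
            for z in known
        ):
            raise ValueError(f"unknown chamber id {final_chamber_id!r}")
    reached = sum(1 for s in seqs if final_chamber_id in s.zone_sequence())
    return 100.0 * reached / len(seqs)


# ---------------------------------------------------------------------------
# plus-maze anxiety score
# ---------------------------------------------------------------------------

def anxiety_score(
    shallow_time: Iterable[float],
    shallow_latency: Iterable[float],
    session_length: float | None = None,
) -> np.ndarray:
    """Avoidance score in [-1, 1] from aversive-zone time and latency.

    ``score = scaled_latency - scaled_time`` with min-max scaling of each
    variable across the population, i.e. (scaled time - scaled latency)
    multiplied by -1.  Higher scores mean stronger avoidance of the
    aversive (shallow) arms, so the score is positively correlated with
    anxiety-like behavior.  Latencies of subjects that never entered should
    already be censored at the session length; passing ``session_length``
    re-censors NaNs.
    """
    t = np.asarray(list(shallow_time), dtype=float)
    lat = np.asarray(list(shallow_latency), dtype=float)
    if t.size != lat.size:
        raise ValueError("time and latency vectors differ in length")
    if t.size < 2:
        raise ValueError("anxiety score scaling needs at least 2 subjects")
    if np.isnan(lat).any():
        if session_length is None:
            raise ValueError("NaN latencies present: session_length required")
        lat = np.where(np.isnan(lat), float(session_length), lat)
    return minmax_scale(lat) - minmax_scale(t)


# ---------------------------------------------------------------------------
# zone preference (sociability / SPM occupancy)
# ---------------------------------------------------------------------------

def zone_preference(
    metrics: SessionMetrics,
    roles: Mapping[str, str],
) -> pd.DataFrame:
    """Time% and entry counts aggregated by zone role.

    ``roles`` maps zone_id -> role (e.g. the arena's ``labels``); zones
    sharing a role (the two shallow arms, say) are summed.  Raises if a
    requested role resolves to no zone of the session.
    """
    by_role: dict[str, dict] = {}
    for zid, role in roles.items():
        if zid not in metrics.per_zone:
            raise KeyError(
                f"zone {zid!r} (role {role!r}) missing from session metrics"
            )
        zm = metrics.per_zone[zid]
        acc = by_role.setdefault(role, {"time_s": 0.0, "time_pct": 0.0,
                                        "entries": 0})
        acc["time_s"] += zm.time_s
        acc["time_pct"] += zm.time_pct
        acc["entries"] += zm.entries
    df = pd.DataFrame.from_dict(by_role, orient="index")
    df.index.name = "role"
    return df.sort_index()


# ---------------------------------------------------------------------------
# tidy endpoint tables
# ---------------------------------------------------------------------------

ENDPOINT_COLUMNS = ["subject_id", "session_id", "group", "endpoint", "value",
                    "censored"]


def make_endpoint_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Assemble a tidy endpoint table (one row per subject-session-endpoint).

    Rows need ``subject_id, session_id, group, endpoint, value`` and may
    carry a ``censored`` flag (defaults to False).
    """
    df = pd.DataFrame(list(rows))
    if "censored" not in df.columns:
        df["censored"] = False
    df["censored"] = df["censored"].fillna(False).astype(bool)
    missing = [c for c in ENDPOINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"endpoint rows missing columns: {missing}")
    dup = df.duplicated(subset=["subject_id", "session_id", "endpoint"])
    if dup.any():
        raise ValueError("duplicate subject-session-endpoint rows")
    return df[ENDPOINT_COLUMNS]


def endpoint_table_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy endpoint table to subject-session rows x endpoint columns."""
    return table.pivot_table(
        index=["subject_id", "session_id", "group"],
        columns="endpoint",
        values="value",
        aggfunc="first",
    ).reset_index()


def check_endpoint_ranges(table: pd.DataFrame) -> None:
    """Warn about scaled endpoints escaping their stated ranges."""
    ranges = {
        "mean_transition_latency": (0.0, 1.0),
        "anxiety_score": (-1.0, 1.0),
    }
    for name, (lo, hi) in ranges.items():
        vals = table.loc[table["endpoint"] == name, "value"]
        bad = vals[(vals < lo - 1e-12) | (vals > hi + 1e-12)]
        if len(bad):
            warnings.warn(
                f"{len(bad)} {name} value(s) outside [{lo}, {hi}]",
                stacklevel=2,
            )
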