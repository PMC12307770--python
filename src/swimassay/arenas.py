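"""Arena geometry, zone assignment, and visit-event extraction.

An arena is a flat (top-view) collection of named zones — rectangles,
circles, annuli, or polygons, all in mm with the origin at the lower-left —
plus an adjacency graph and a role label per zone.  Raw tracking data
(per-frame ``t, x, y`` samples) is converted into an ordered sequence of
zone visits, which is the event representation every downstream endpoint
consumes.

Conventions
-----------
* Zone membership is decided by the animal's center point.
* Shapes are closed sets; a point on a shared edge belongs to the zone
  declared first (declaration-order tie-break), which makes shared edges
  effectively half-open.
* Samples outside every zone are labelled ``"none"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box

NONE_ZONE = "none"

#: frames per second of the tracking convention (video recorded at 30 fps)
DEFAULT_FRAME_RATE = 30.0

#: de-bounce threshold (s): zone runs shorter than this are merged away,
#: suppressing single-frame tracking flicker at 30 fps
DEFAULT_MIN_DWELL = 0.2

#: immobility definition: speed below this (mm/s) ...
DEFAULT_SPEED_THR = 1.0
#: ... sustained for at least this long (s) counts as one immobile episode
DEFAULT_MIN_IMMOBILE = 1.0


# ---------------------------------------------------------------------------
# zones and arenas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Zone:
    """One named region of an arena.

    ``shape`` is one of ``rectangle`` (params ``x0, y0, x1, y1``),
    ``circle`` (``cx, cy, r``), ``annulus`` (``cx, cy, r_in, r_out``) or
    ``polygon`` (``vertices`` — sequence of (x, y) pairs).
    """

    zone_id: str
    shape: str
    params: tuple

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "circle", "annulus", "polygon"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "polygon":
            object.__setattr__(
                self, "params", tuple(tuple(map(float, p)) for p in self.params)
            )
        else:
            object.__setattr__(self, "params", tuple(map(float, self.params)))

    def contains(self, x: float, y: float) -> bool:
        """Closed-set containment of a single point."""
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.params
            return x0 <= x <= x1 and y0 <= y <= y1
        if self.shape == "circle":
            cx, cy, r = self.params
            return (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        if self.shape == "annulus":
            cx, cy, r_in, r_out = self.params
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            return r_in**2 <= d2 <= r_out**2
        poly = self._shapely()
        return poly.covers(Point(x, y))

    def contains_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.params
            return (x0 <= x) & (x <= x1) & (y0 <= y) & (y <= y1)
        if self.shape == "circle":
            cx, cy, r = self.params
            return (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        if self.shape == "annulus":
            cx, cy, r_in, r_out = self.params
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            return (r_in**2 <= d2) & (d2 <= r_out**2)
        poly = self._shapely()
        return np.fromiter(
            (poly.covers(Point(xi, yi)) for xi, yi in zip(x, y)),
            dtype=bool,
            count=len(x),
        )

    def _shapely(self, circle_segments: int = 256) -> Polygon:
        """Shapely geometry (circles approximated for overlap checks)."""
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.params
            return box(x0, y0, x1, y1)
        if self.shape == "circle":
            cx, cy, r = self.params
            return Point(cx, cy).buffer(r, quad_segs=circle_segments)
        if self.shape == "annulus":
            cx, cy, r_in, r_out = self.params
            outer = Point(cx, cy).buffer(r_out, quad_segs=circle_segments)
            inner = Point(cx, cy).buffer(r_in, quad_segs=circle_segments)
            return outer.difference(inner)
        return Polygon(self.params)

    @property
    def area(self) -> float:
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.params
            return (x1 - x0) * (y1 - y0)
        if self.shape == "circle":
            return math.pi * self.params[2] ** 2
        if self.shape == "annulus":
            _, _, r_in, r_out = self.params
            return math.pi * (r_out**2 - r_in**2)
        return self._shapely().area

    def sample_point(self, rng: np.random.Generator, margin: float = 0.0):
        """Uniform random interior point, at least ``margin`` from the edge."""
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.params
            return (
                rng.uniform(x0 + margin, x1 - margin),
                rng.uniform(y0 + margin, y1 - margin),
            )
        if self.shape == "circle":
            cx, cy, r = self.params
            rr = (r - margin) * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2 * math.pi)
            return cx + rr * math.cos(th), cy + rr * math.sin(th)
        if self.shape == "annulus":
            cx, cy, r_in, r_out = self.params
            lo, hi = r_in + margin, r_out - margin
            rr = math.sqrt(rng.uniform(lo**2, hi**2))
            th = rng.uniform(0.0, 2 * math.pi)
            return cx + rr * math.cos(th), cy + rr * math.sin(th)
        poly = self._shapely().buffer(-margin) if margin > 0 else self._shapely()
        minx, miny, maxx, maxy = poly.bounds
        for _ in range(10_000):
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if poly.covers(Point(x, y)):
                return x, y
        raise RuntimeError(f"rejection sampling failed in zone {self.zone_id}")

    def clamp_point(self, x: float, y: float, margin: float = 0.0):
        """Nearest interior point (used to keep simulated jitter in-zone)."""
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.params
            return (
                min(max(x, x0 + margin), x1 - margin),
                min(max(y, y0 + margin), y1 - margin),
            )
        if self.shape in ("circle", "annulus"):
            cx, cy = self.params[0], self.params[1]
            if self.shape == "circle":
                lo, hi = 0.0, self.params[2] - margin
            else:
                lo, hi = self.params[2] + margin, self.params[3] - margin
            d = math.hypot(x - cx, y - cy)
            if d == 0.0:
                return (cx + lo, cy) if lo > 0 else (cx, cy)
            rr = min(max(d, lo), hi)
            return cx + (x - cx) * rr / d, cy + (y - cy) * rr / d
        poly = self._shapely().buffer(-margin) if margin > 0 else self._shapely()
        p = Point(x, y)
        if poly.covers(p):
            return x, y
        q = poly.exterior.interpolate(poly.exterior.project(p))
        # nudge inward toward the centroid to stay strictly interior
        c = poly.centroid
        eps = 1e-6
        return q.x + (c.x - q.x) * eps, q.y + (c.y - q.y) * eps


@dataclass
class ArenaSpec:
    """Zone graph + geometry for one assay.

    ``adjacency`` holds unordered zone-id pairs; ``labels`` maps each zone to
    its behavioral role (e.g. ``"stimulus"``, ``"shallow_arm"``,
    ``"arm_A"``); ``aversive`` lists zones the animal avoids (used by the
    simulator and by the anxiety endpoints).
    """

    assay_id: str
    zones: list[Zone]
    adjacency: set[frozenset] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)
    aversive: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = {frozenset(p) for p in self.adjacency}
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self, overlap_tol: float = 1e-6) -> None:
        ids = [z.zone_id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate zone ids")
        known = set(ids)
        for pair in self.adjacency:
            if not pair <= known:
                raise ValueError(f"adjacency references unknown zone: {pair}")
        for zid in list(self.labels) + list(self.aversive):
            if zid not in known:
                raise ValueError(f"label references unknown zone {zid!r}")
        # pairwise-disjoint interiors (shapely, circles discretised)
        geoms = {z.zone_id: z._shapely() for z in self.zones}
        for i, a in enumerate(self.zones):
            for b in self.zones[i + 1 :]:
                inter = geoms[a.zone_id].intersection(geoms[b.zone_id]).area
                ref = min(a.area, b.area)
                if inter > overlap_tol * max(ref, 1.0):
                    raise ValueError(
                        f"zones {a.zone_id!r} and {b.zone_id!r} overlap "
                        f"(area {inter:.3g})"
                    )

    # -- lookups ---------------------------------------------------------
    def zone(self, zone_id: str) -> Zone:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(zone_id)

    def zones_with_role(self, role: str) -> list[str]:
        return [zid for zid, r in self.labels.items() if r == role]

    def neighbours(self, zone_id: str) -> list[str]:
        out = []
        for pair in self.adjacency:
            if zone_id in pair:
                (other,) = pair - {zone_id}
                out.append(other)
        return sorted(out)

    def bounding_box(self) -> tuple[float, float, float, float]:
        bounds = [z._shapely().bounds for z in self.zones]
        return (
            min(b[0] for b in bounds),
            min(b[1] for b in bounds),
            max(b[2] for b in bounds),
            max(b[3] for b in bounds),
        )

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "assay_id": self.assay_id,
            "zones": [
                {"zone_id": z.zone_id, "shape": z.shape, "params": list(z.params)}
                for z in self.zones
            ],
            "adjacency": sorted(sorted(p) for p in self.adjacency),
            "labels": dict(self.labels),
            "aversive": list(self.aversive),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaSpec":
        zones = [Zone(z["zone_id"], z["shape"], z["params"]) for z in d["zones"]]
        return cls(
            assay_id=d["assay_id"],
            zones=zones,
            adjacency={frozenset(p) for p in d.get("adjacency", [])},
            labels=dict(d.get("labels", {})),
            aversive=list(d.get("aversive", [])),
        )


# ---------------------------------------------------------------------------
# built-in assay presets (printed apparatus dimensions; mm, origin lower-left)
# ---------------------------------------------------------------------------

def _chain_arena(assay_id, n_chambers, width, length, prefix="chamber"):
    dx = length / n_chambers
    zones = [
        Zone(f"{prefix}_{k + 1}", "rectangle", (k * dx, 0.0, (k + 1) * dx, width))
        for k in range(n_chambers)
    ]
    adj = {
        frozenset((f"{prefix}_{k}", f"{prefix}_{k + 1}"))
        for k in range(1, n_chambers)
    }
    labels = {z.zone_id: z.zone_id for z in zones}
    return ArenaSpec(assay_id, zones, adj, labels)


def make_slalom_arena() -> ArenaSpec:
    """Slalom test: 12 equal chambers in a 20 x 85 mm linear maze."""
    return _chain_arena("slalom", 12, width=20.0, length=85.0)


def make_sj_arena() -> ArenaSpec:
    """Show jump test: 4 equal chambers in a 20 x 42 mm maze."""
    return _chain_arena("sj", 4, width=20.0, length=42.0)


def make_ot_arena(diameter_mm: float = 35.0) -> ArenaSpec:
    """Open tank: circular well; the central circle covering 80% of the
    area (radius ratio sqrt(0.8)) is the aversive open region, the
    remaining annulus the periphery."""
    r = diameter_mm / 2.0
    r_c = r * math.sqrt(0.8)
    c = (r, r)
    zones = [
        Zone("center", "circle", (*c, r_c)),
        Zone("periphery", "annulus", (*c, r_c, r)),
    ]
    return ArenaSpec(
        "ot",
        zones,
        {frozenset(("center", "periphery"))},
        {"center": "center", "periphery": "periphery"},
        aversive=["center"],
    )


def make_spm_arena() -> ArenaSpec:
    """Swimming plus-maze (top view): 8 x 8 mm center, four 8 x 10 mm arms.

    Depth (shallow 2.5 mm vs deep 5 mm) is encoded purely as zone labels:
    shallow arms are the aversive ones.
    """
    cx0, cy0 = 10.0, 10.0  # lower-left of the center square
    zones = [
        Zone("center", "rectangle", (cx0, cy0, cx0 + 8, cy0 + 8)),
        Zone("shallow_1", "rectangle", (cx0, cy0 + 8, cx0 + 8, cy0 + 18)),
        Zone("shallow_2", "rectangle", (cx0, cy0 - 10, cx0 + 8, cy0)),
        Zone("deep_1", "rectangle", (cx0 - 10, cy0, cx0, cy0 + 8)),
        Zone("deep_2", "rectangle", (cx0 + 8, cy0, cx0 + 18, cy0 + 8)),
    ]
    adj = {
        frozenset(("center", a))
        for a in ("shallow_1", "shallow_2", "deep_1", "deep_2")
    }
    labels = {
        "center": "center",
        "shallow_1": "shallow_arm",
        "shallow_2": "shallow_arm",
        "deep_1": "deep_arm",
        "deep_2": "deep_arm",
    }
    return ArenaSpec("spm", zones, adj, labels, aversive=["shallow_1", "shallow_2"])


def make_ymaze_arena() -> ArenaSpec:
    """Y-maze: three 7.5 x 30 mm arms at 120 degrees around a triangular
    center (arm dimensions 5 x 7.5 x 30 mm depth x width x length)."""
    half_w = 7.5 / 2.0
    r_in = half_w / math.tan(math.pi / 3)  # inradius of the center triangle
    origin = (40.0, 40.0)
    angles = {"arm_A": 90.0, "arm_B": 210.0, "arm_C": 330.0}

    def _arm(theta_deg):
        th = math.radians(theta_deg)
        u = (math.cos(th), math.sin(th))
        v = (-math.sin(th), math.cos(th))
        pts = []
        for du, dv in ((r_in, -half_w), (r_in + 30.0, -half_w),
                       (r_in + 30.0, half_w), (r_in, half_w)):
            pts.append((origin[0] + du * u[0] + dv * v[0],
                        origin[1] + du * u[1] + dv * v[1]))
        return tuple(pts)

    # center triangle vertices: where adjacent arm base edges meet
    tri = []
    for th_deg in (30.0, 150.0, 270.0):
        th = math.radians(th_deg)
        r_c = 2 * r_in  # circumradius of an equilateral triangle
        tri.append((origin[0] + r_c * math.cos(th), origin[1] + r_c * math.sin(th)))

    zones = [Zone("center", "polygon", tuple(tri))] + [
        Zone(name, "polygon", _arm(theta)) for name, theta in angles.items()
    ]
    adj = {frozenset(("center", a)) for a in angles}
    labels = {"center": "center", "arm_A": "arm_A", "arm_B": "arm_B",
              "arm_C": "arm_C"}
    return ArenaSpec("ymaze", zones, adj, labels)


def make_sociability_arena() -> ArenaSpec:
    """U-shaped sociability arena (40 x 32 mm footprint): stimulus and
    no-stimulus arms joined by the starting-point/intersection zone."""
    zones = [
        Zone("intersection", "rectangle", (0.0, 0.0, 40.0, 8.0)),
        Zone("stimulus", "rectangle", (0.0, 8.0, 15.0, 32.0)),
        Zone("no_stimulus", "rectangle", (25.0, 8.0, 40.0, 32.0)),
    ]
    adj = {
        frozenset(("intersection", "stimulus")),
        frozenset(("intersection", "no_stimulus")),
    }
    labels = {
        "intersection": "intersection",
        "stimulus": "stimulus",
        "no_stimulus": "no_stimulus",
    }
    return ArenaSpec("sociability", zones, adj, labels)


ARENA_PRESETS = {
    "slalom": make_slalom_arena,
    "sj": make_sj_arena,
    "ot": make_ot_arena,
    "spm": make_spm_arena,
    "ymaze": make_ymaze_arena,
    "sociability": make_sociability_arena,
}


def get_arena(assay_id: str) -> ArenaSpec:
    try:
        return ARENA_PRESETS[assay_id]()
    except KeyError:
        raise KeyError(
            f"unknown assay {assay_id!r}; known: {sorted(ARENA_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# tracks and visit sequences
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """Per-frame positions for one subject in one session (t in s, x/y in mm)."""

    subject_id: str
    session_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size < 2:
            raise ValueError("a track needs at least 2 samples")
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError(
                f"time not strictly increasing in session {self.session_id!r}"
            )
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x))
                and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite coordinates in track")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Session length: last-sample time plus one frame interval."""
        return float(self.t[-1] - self.t[0] + 1.0 / self.frame_rate)


@dataclass(frozen=True)
class Visit:
    zone_id: str
    t_enter: float
    t_exit: float

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_enter


@dataclass
class VisitSequence:
    """Ordered, non-overlapping zone visits covering one session."""

    subject_id: str
    session_id: str
    visits: list[Visit]
    session_length: float

    def __post_init__(self) -> None:
        prev_exit = None
        prev_zone = None
        for v in self.visits:
            if not v.t_enter < v.t_exit:
                raise ValueError(f"visit {v} has t_enter >= t_exit")
            if prev_exit is not None and v.t_enter < prev_exit - 1e-12:
                raise ValueError("visits overlap or are out of order")
            if v.zone_id == prev_zone:
                raise ValueError("consecutive visits to the same zone")
            prev_exit, prev_zone = v.t_exit, v.zone_id

    def zone_sequence(self) -> list[str]:
        return [v.zone_id for v in self.visits]

    def __len__(self) -> int:
        return len(self.visits)


# ---------------------------------------------------------------------------
# zone assignment
# ---------------------------------------------------------------------------

def assign_zones(track: Track, arena: ArenaSpec) -> np.ndarray:
    """Label every track sample with its zone id (or ``"none"``).

    Containment uses the animal's center point; a point inside several
    zone boundaries (shared edges) goes to the zone declared first.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    labels = np.full(len(track), NONE_ZONE, dtype=object)
    unassigned = np.ones(len(track), dtype=bool)
    for zone in arena.zones:  # declaration order = tie-break priority
        if not unassigned.any():
            break
        idx = np.flatnonzero(unassigned)
        hit = zone.contains_many(track.x[idx], track.y[idx])
        labels[idx[hit]] = zone.zone_id
        unassigned[idx[hit]] = False
    if unassigned.any():
        x0, y0, x1, y1 = arena.bounding_box()
        out_of_box = (
            (track.x < x0) | (track.x > x1) | (track.y < y0) | (track.y > y1)
        ) & unassigned
        if out_of_box.any():
            warnings.warn(
                f"{int(out_of_box.sum())} sample(s) outside the arena "
                f"bounding box in session {track.session_id!r}; labelled "
                f"'{NONE_ZONE}'",
                stacklevel=2,
            )
    return labels


# ---------------------------------------------------------------------------
# visit extraction (de-bounce)
# ---------------------------------------------------------------------------

def _runs_from_labels(t: np.ndarray, labels: Sequence[str], session_end: float):
    """Compress per-sample labels into (zone, t_start, t_end) runs.

    A run extends from its first sample to the first sample of the next run
    (the last run ends at ``session_end``).
    """
    runs = []
    start = 0
    for i in range(1, len(labels)):
        if labels[i] != labels[start]:
            runs.append([labels[start], float(t[start]), float(t[i])])
            start = i
    runs.append([labels[start], float(t[start]), session_end])
    return runs


def extract_visits(
    track: Track,
    labels: Sequence[str],
    min_dwell: float = DEFAULT_MIN_DWELL,
) -> VisitSequence:
    """Turn a zone-labelled track into a de-bounced :class:`VisitSequence`.

    ``"none"`` runs are absorbed into the preceding visit (the leading run,
    having no predecessor, joins the following one).  Runs shorter than
    ``min_dwell`` are merged into their flanking visits: if both flanks are
    the same zone the three coalesce, otherwise the short run joins the
    preceding visit.  Merging repeats until every remaining visit is at
    least ``min_dwell`` long or a single visit remains.
    """
    if min_dwell < 0:
        raise ValueError("min_dwell must be >= 0")
    labels = list(labels)
    if len(labels) != len(track):
        raise ValueError("labels length must match track length")
    session_end = float(track.t[0]) + track.duration
    runs = _runs_from_labels(track.t, labels, session_end)

    # absorb "none" runs
    cleaned: list[list] = []
    for run in runs:
        if run[0] == NONE_ZONE:
            if cleaned:
                cleaned[-1][2] = run[2]
            else:
                # leading none: its span goes to the first real visit
                cleaned.append(run)
        else:
            if cleaned and cleaned[-1][0] == NONE_ZONE:
                run[1] = cleaned[-1][1]
                cleaned[-1] = run
            elif cleaned and cleaned[-1][0] == run[0]:
                cleaned[-1][2] = run[2]
            else:
                cleaned.append(run)
    if cleaned and cleaned[0][0] == NONE_ZONE:
        warnings.warn(
            f"track {track.session_id!r} never enters a zone; "
            "empty visit sequence",
            stacklevel=2,
        )
        return VisitSequence(track.subject_id, track.session_id, [],
                             session_end - float(track.t[0]))
    runs = cleaned

    # de-bounce: merge sub-threshold runs
    def _merge_pass(runs):
        for i, run in enumerate(runs):
            if run[2] - run[1] >= min_dwell:
                continue
            prev_run = runs[i - 1] if i > 0 else None
            next_run = runs[i + 1] if i + 1 < len(runs) else None
            if prev_run is None and next_run is None:
                return runs, False
            if prev_run is not None and next_run is not None \
                    and prev_run[0] == next_run[0]:
                prev_run[2] = next_run[2]
                return runs[:i] + runs[i + 2 :], True
            if prev_run is not None:
                prev_run[2] = run[2]
                return runs[:i] + runs[i + 1 :], True
            next_run[1] = run[1]
            return runs[i + 1 :], True
        return runs, False

    changed = True
    while changed and len(runs) > 1:
        runs, changed = _merge_pass(runs)

    visits = [Visit(z, t0, t1) for z, t0, t1 in runs]
    return VisitSequence(
        track.subject_id, track.session_id, visits,
        session_end - float(track.t[0]),
    )


def visits_from_track(
    track: Track, arena: ArenaSpec, min_dwell: float = DEFAULT_MIN_DWELL
) -> VisitSequence:
    """Convenience: ``assign_zones`` then ``extract_visits``."""
    return extract_visits(track, assign_zones(track, arena), min_dwell)


# ---------------------------------------------------------------------------
# per-session metrics
# ---------------------------------------------------------------------------

@dataclass
class ZoneMetrics:
    time_s: float
    time_pct: float
    entries: int
    latency_s: float
    censored: bool


@dataclass
class SessionMetrics:
    subject_id: str
    session_id: str
    session_length: float
    per_zone: dict[str, ZoneMetrics]
    mean_velocity: float | None
    immobile_episodes: int | None


def session_metrics(
    visits: VisitSequence,
    track: Track | None = None,
    zone_ids: Iterable[str] | None = None,
    speed_thr: float = DEFAULT_SPEED_THR,
    min_immobile: float = DEFAULT_MIN_IMMOBILE,
) -> SessionMetrics:
    """Per-zone occupancy/entry/latency metrics plus whole-session kinematics.

    First-entry latencies of zones never visited are censored at the session
    length (flagged).  Mean velocity is path length over elapsed time for
    the whole session, immobile periods included.  An immobile episode is a
    maximal run of samples with speed below ``speed_thr`` lasting at least
    ``min_immobile`` seconds.
    """
    if track is not None and (
        track.subject_id != visits.subject_id
        or track.session_id != visits.session_id
    ):
        raise ValueError("track and visits refer to different sessions")

    L = visits.session_length
    if zone_ids is None:
        zone_ids = sorted({v.zone_id for v in visits.visits})
    per_zone: dict[str, ZoneMetrics] = {}
    for zid in zone_ids:
        zvis = [v for v in visits.visits if v.zone_id == zid]
        time_s = sum(v.duration for v in zvis)
        if zvis:
            lat, cens = zvis[0].t_enter - (
                visits.visits[0].t_enter if visits.visits else 0.0
            ), False
        else:
            lat, cens = L, True
        per_zone[zid] = ZoneMetrics(
            time_s=time_s,
            time_pct=100.0 * time_s / L if L > 0 else float("nan"),
            entries=len(zvis),
            latency_s=lat,
            censored=cens,
        )

    mean_vel = None
    n_immobile = None
    if track is not None:
        dx = np.diff(track.x)
        dy = np.diff(track.y)
        dt = np.diff(track.t)
        path = float(np.sum(np.hypot(dx, dy)))
        elapsed = float(track.t[-1] - track.t[0])
        mean_vel = path / elapsed if elapsed > 0 else float("nan")
        speed = np.hypot(dx, dy) / dt
        slow = speed < speed_thr
        n_immobile = 0
        i = 0
        while i < slow.size:
            if slow[i]:
                j = i
                while j < slow.size and slow[j]:
                    j += 1
                # episode spans samples i..j (inclusive of the closing sample)
                if float(track.t[j] - track.t[i]) >= min_immobile:
                    n_immobile += 1
                i = j
            else:
                i += 1

    return SessionMetrics(
        subject_id=visits.subject_id,
        session_id=visits.session_id,
        session_length=L,
        per_zone=per_zone,
        mean_velocity=mean_vel,
        immobile_episodes=n_immobile,
    )
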