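"""Synthetic behavior generator.

Produces data with the statistical structure the analysis stages assume,
without any claim of biomechanical realism:

* **zone-visit sequences** — a continuous-time Markov walk on the arena's
  zone adjacency graph (exponential dwell per zone, next zone proportional
  to edge weights), with an avoidance parameter ``a`` that multiplies both
  the dwell time in aversive zones and the entry weight into them by
  ``exp(-a)``, a log-normal subject-level random effect on rates (which
  induces repeatability across sessions), and an optional explorer-mixture
  over rate multipliers (which induces multimodal endpoint distributions);
* **tracks** — visit sequences optionally rendered to 30 Hz positions with
  within-zone jitter (a mean-reverting walk around a per-visit anchor) and
  hazard-driven immobile episodes;
* **Y-maze arm sequences** — a parameterized choice policy containing the
  uniform no-stay random walk (50% alternation) as a special case;
* **repeated measures** — the normal random-intercept model with known
  true repeatability;
* **population values** — i.i.d. draws from a specified 1-D Gaussian
  mixture.

Everything is driven by one mandatory seed; per-subject streams are split
by stable sub-seeding so each subject's output is independent of how many
other subjects are simulated after it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .arenas import (
    DEFAULT_FRAME_RATE,
    ArenaSpec,
    Track,
    Visit,
    VisitSequence,
    get_arena,
)
from .consistency import RepeatedMeasures
from .ymaze import ARM_ALPHABET


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of one simulated assay run.

    ``mean_dwell`` is the expected stay (s) in a zone before the subject's
    multiplier and the avoidance discount; ``avoidance`` multiplies both
    aversive-zone dwell and aversive-zone entry weight by ``exp(-a)``.
    ``subject_sd`` is the SD (log scale) of a per-subject log-normal
    multiplier on all transition rates.  ``explorer_mixture`` is a list of
    ``(weight, rate_multiplier)`` pairs assigning each subject to a latent
    explorer type.
    """

    assay_id: str
    n_subjects: int
    seed: int
    session_length: float = 600.0
    mean_dwell: float | dict = 5.0
    transition_weights: dict = dc_field(default_factory=dict)
    avoidance: float = 0.0
    subject_sd: float = 0.0
    explorer_mixture: list[tuple[float, float]] = dc_field(
        default_factory=lambda: [(1.0, 1.0)]
    )
    start_zone: str | None = None
    # track rendering
    frame_rate: float = DEFAULT_FRAME_RATE
    jitter_pull: float = 0.25      # mean-reversion per frame toward anchor
    jitter_sd: float = 1.0         # per-frame noise, mm
    immobility_hazard: float = 0.0  # episodes per second
    immobile_duration: float = 2.0  # mean episode length, s

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.avoidance < 0:
            raise ValueError("avoidance must be >= 0")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        w = [p for p, _ in self.explorer_mixture]
        if any(p < 0 for p in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("explorer mixture weights must be >= 0 and "
                             "sum to 1")
        if isinstance(self.mean_dwell, dict):
            if any(v <= 0 for v in self.mean_dwell.values()):
                raise ValueError("mean dwell times must be > 0")
        elif self.mean_dwell <= 0:
            raise ValueError("mean dwell times must be > 0")


DEFAULT_START = {
    "slalom": "chamber_1",
    "sj": "chamber_1",
    "spm": "center",
    "ymaze": "center",
    "sociability": "intersection",
    "ot": "periphery",
}


def _check_connected(arena: ArenaSpec) -> None:
    ids = [z.zone_id for z in arena.zones]
    seen = {ids[0]}
    frontier = [ids[0]]
    while frontier:
        nxt = []
        for z in frontier:
            for nb in arena.neighbours(z):
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        frontier = nxt
    if seen != set(ids):
        raise ValueError(
            f"zone graph of {arena.assay_id!r} is disconnected: "
            f"unreachable {sorted(set(ids) - seen)}"
        )


def _subject_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Stable per-subject RNG streams (order-independent outputs)."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# zone-visit simulation (continuous-time Markov walk)
# ---------------------------------------------------------------------------

def simulate_visits(
    config: SimConfig,
    arena: ArenaSpec | None = None,
    render_tracks: bool = False,
) -> tuple[list[VisitSequence], list[Track] | None]:
    """Simulate per-subject visit sequences (and optionally 30 Hz tracks).

    Per subject: exponential dwell in the current zone with mean
    ``mean_dwell[z] * exp(-a * aversive(z)) / m_subject`` where
    ``m_subject`` is the subject's log-normal rate multiplier times its
    explorer-type multiplier; the next zone is drawn over graph neighbours
    with weight ``w_edge * exp(-a * aversive(next))``.  The final visit is
    truncated at the session length.
    """
    if arena is None:
        arena = get_arena(config.assay_id)
    _check_connected(arena)
    aversive = set(arena.aversive)
    start = config.start_zone or DEFAULT_START.get(
        config.assay_id, arena.zones[0].zone_id
    )
    arena.zone(start)  # KeyError on unknown start

    def dwell_mean(zid: str) -> float:
        if isinstance(config.mean_dwell, dict):
            base = float(config.mean_dwell.get(zid, 5.0))
        else:
            base = float(config.mean_dwell)
        if zid in aversive:
            base *= math.exp(-config.avoidance)
        return base

    def edge_weight(frm: str, to: str) -> float:
        w = float(config.transition_weights.get(
            tuple(sorted((frm, to))), 1.0
        ))
        if to in aversive:
            w *= math.exp(-config.avoidance)
        return w

    comp_w = np.array([p for p, _ in config.explorer_mixture])
    comp_m = np.array([m for _, m in config.explorer_mixture])

    streams = _subject_streams(config.seed, config.n_subjects)
    sequences: list[VisitSequence] = []
    tracks: list[Track] | None = [] if render_tracks else None
    for i, rng in enumerate(streams):
        sid = f"s{i + 1:03d}"
        comp = int(rng.choice(comp_w.size, p=comp_w))
        mult = comp_m[comp] * float(
            rng.lognormal(0.0, config.subject_sd)
        ) if config.subject_sd > 0 else comp_m[comp]
        t = 0.0
        zone = start
        raw: list[tuple[str, float, float]] = []
        while t < config.session_length:
            dwell = rng.exponential(dwell_mean(zone) / mult)
            t_exit = min(t + dwell, config.session_length)
            raw.append((zone, t, t_exit))
            t = t_exit
            if t >= config.session_length:
                break
            nbs = arena.neighbours(zone)
            w = np.array([edge_weight(zone, nb) for nb in nbs])
            zone = nbs[int(rng.choice(len(nbs), p=w / w.sum()))]
        # collapse zero-length tail visits and same-zone repeats
        visits: list[Visit] = []
        for zid, t0, t1 in raw:
            if t1 - t0 <= 0:
                continue
            if visits and visits[-1].zone_id == zid:
                visits[-1] = Visit(zid, visits[-1].t_enter, t1)
            else:
                visits.append(Visit(zid, t0, t1))
        seq = VisitSequence(sid, "sess1", visits, config.session_length)
        sequences.append(seq)
        if render_tracks:
            tracks.append(render_track(seq, arena, config, rng))
    return sequences, tracks


def render_track(
    visits: VisitSequence,
    arena: ArenaSpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> Track:
    """Render a visit sequence to a 30 Hz track with within-zone jitter.

    Position follows a mean-reverting walk around a per-visit anchor point
    and is clamped to the zone interior (0.5 mm margin), so re-assigning
    zones to the rendered track reproduces the generating visit sequence.
    Immobile episodes (position frozen) arrive with rate
    ``immobility_hazard`` and exponential mean length
    ``immobile_duration``.
    """
    dt = 1.0 / config.frame_rate
    margin = 0.5
    ts, xs, ys = [], [], []
    pos = None
    frozen_until = -1.0
    n_frames = int(round(visits.session_length / dt))
    frame_times = np.arange(n_frames) * dt
    vi = 0
    anchor = None
    zone = None
    for t in frame_times:
        while vi < len(visits.visits) - 1 and t >= visits.visits[vi].t_exit:
            vi += 1
            anchor = None
        v = visits.visits[vi]
        if anchor is None or zone != v.zone_id:
            zone = v.zone_id
            z = arena.zone(zone)
            anchor = z.sample_point(rng, margin=margin)
            if pos is None:
                pos = anchor
        if t < frozen_until:
            pass  # immobile: hold position
        else:
            if config.immobility_hazard > 0 and \
                    rng.uniform() < config.immobility_hazard * dt:
                frozen_until = t + rng.exponential(config.immobile_duration)
            z = arena.zone(v.zone_id)
            nx = pos[0] + config.jitter_pull * (anchor[0] - pos[0]) \
                + rng.normal(0.0, config.jitter_sd)
            ny = pos[1] + config.jitter_pull * (anchor[1] - pos[1]) \
                + rng.normal(0.0, config.jitter_sd)
            pos = z.clamp_point(nx, ny, margin=margin)
        ts.append(t)
        xs.append(pos[0])
        ys.append(pos[1])
    return Track(visits.subject_id, visits.session_id,
                 np.array(ts), np.array(xs), np.array(ys),
                 frame_rate=config.frame_rate)


# ---------------------------------------------------------------------------
# Y-maze choice policy
# ---------------------------------------------------------------------------

def simulate_ymaze(
    n_subjects: int,
    n_visits: int,
    p_alt: float = 0.5,
    p_direct: float = 0.0,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Arm-visit sequences from a parameterized choice policy.

    First two visits: uniform over distinct arms.  Thereafter, with
    probability ``p_direct`` the current arm is repeated; otherwise, with
    probability ``p_alt`` the subject moves to the arm completing an
    alternation (the arm visited neither of the last two times), else it
    returns to the previous arm.  When the last two visits are to the same
    arm the two non-current arms are equivalent and one is drawn uniformly.

    ``p_alt = 0.5, p_direct = 0`` is the uniform no-stay random walk —
    the 50%-alternation random-choice reference.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if not (0.0 <= p_alt <= 1.0 and 0.0 <= p_direct <= 1.0):
        raise ValueError("p_alt and p_direct must lie in [0, 1]")
    if p_alt + p_direct > 1.0 + 1e-12:
        raise ValueError("p_alt + p_direct must be <= 1 "
                         "(p_alt is conditional on no direct revisit)")
    arms = list(ARM_ALPHABET)
    out: dict[str, list[str]] = {}
    for i, rng in enumerate(_subject_streams(seed, n_subjects)):
        seq: list[str] = []
        if n_visits >= 1:
            seq.append(arms[int(rng.integers(3))])
        if n_visits >= 2:
            others = [a for a in arms if a != seq[0]]
            seq.append(others[int(rng.integers(2))])
        while len(seq) < n_visits:
            prev, cur = seq[-2], seq[-1]
            if rng.uniform() < p_direct:
                seq.append(cur)
                continue
            if prev == cur:
                others = [a for a in arms if a != cur]
                seq.append(others[int(rng.integers(2))])
            elif rng.uniform() < p_alt:
                (third,) = set(arms) - {prev, cur}
                seq.append(third)
            else:
                seq.append(prev)
        out[f"s{i + 1:03d}"] = seq
    return out


# ---------------------------------------------------------------------------
# repeated measures with known repeatability
# ---------------------------------------------------------------------------

def simulate_repeated(
    mu: float,
    sd_between: float,
    sd_within: float,
    n_subjects: int,
    k_sessions: int,
    seed: int | None = None,
    endpoint: str = "simulated",
) -> RepeatedMeasures:
    """Normal random-intercept data ``y_ij = mu + b_i + e_ij``.

    ``b_i ~ N(0, sd_between^2)``, ``e_ij ~ N(0, sd_within^2)``; the true
    repeatability ``sd_between^2 / (sd_between^2 + sd_within^2)`` is
    attached as metadata.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if sd_between < 0 or sd_within < 0:
        raise ValueError("SDs must be >= 0")
    if n_subjects < 2 or k_sessions < 2:
        raise ValueError("need n_subjects >= 2 and k_sessions >= 2")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sd_between, size=n_subjects)
    e = rng.normal(0.0, sd_within, size=(n_subjects, k_sessions))
    y = mu + b[:, None] + e
    denom = sd_between**2 + sd_within**2
    true_r = sd_between**2 / denom if denom > 0 else 0.0
    df = pd.DataFrame(
        y,
        index=[f"s{i + 1:03d}" for i in range(n_subjects)],
        columns=[f"sess{j + 1}" for j in range(k_sessions)],
    )
    df.index.name = "subject_id"
    return RepeatedMeasures(values=df, endpoint=endpoint, true_r=true_r)


# ---------------------------------------------------------------------------
# population endpoint values from a Gaussian mixture
# ---------------------------------------------------------------------------

def simulate_population_values(
    weights,
    means,
    sds,
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """i.i.d. draws from a 1-D Gaussian mixture (feeds modality analysis)."""
    if seed is None:
        raise ValueError("seed is mandatory")
    w = np.asarray(weights, dtype=float)
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    if not (w.size == m.size == s.size):
        raise ValueError("weights, means, sds must have equal length")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be >= 0 and sum to 1")
    if np.any(s < 0):
        raise ValueError("sds must be >= 0")
    rng = np.random.default_rng(seed)
    comp = rng.choice(w.size, size=n, p=w)
    return rng.normal(m[comp], s[comp])
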