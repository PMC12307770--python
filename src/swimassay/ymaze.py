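"""Y-maze exploration actions: spontaneous alternation scoring.

Arm visits over the three-arm alphabet are scored in overlapping windows of
three consecutive visits.  Each window gets exactly one label:

* **direct revisit** — the window contains an immediate repeat
  (``x == y`` or ``y == z``);
* **alternation** — three distinct arms (ABC-type);
* **indirect revisit** — return to the first arm after one step away
  (ABA-type, ``x == z != y``).

The precedence direct > alternation > indirect makes the three labels
exhaustive and mutually exclusive over all 27 triples.  Alternation percent
uses the number of windows (``len - 2``) as denominator, the rodent-
literature convention in which 50% is random choice and 100% perfect
alternation.  Pair-level immediate repeats are also counted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .arenas import VisitSequence

ARM_ALPHABET = ("A", "B", "C")

ALTERNATION = "alternation"
DIRECT_REVISIT = "direct_revisit"
INDIRECT_REVISIT = "indirect_revisit"


@dataclass(frozen=True)
class ActionCounts:
    """Window tallies for one subject."""

    alternations: int
    direct_revisits: int
    indirect_revisits: int
    n_windows: int
    pairwise_direct: int = 0  # immediate same-arm repeats, counted on pairs

    def __post_init__(self) -> None:
        total = self.alternations + self.direct_revisits + self.indirect_revisits
        if total != self.n_windows:
            raise ValueError("action counts do not sum to the window count")


def classify_window(x: str, y: str, z: str) -> str:
    """Label one window of three consecutive arm visits."""
    if x == y or y == z:
        return DIRECT_REVISIT
    if len({x, y, z}) == 3:
        return ALTERNATION
    return INDIRECT_REVISIT  # x == z != y


def classify_actions(
    arms: Sequence[str], alphabet: Sequence[str] = ARM_ALPHABET
) -> ActionCounts:
    """Tally alternations / direct / indirect revisits over all windows.

    Every overlapping window of three consecutive visits contributes one
    label; sequences shorter than 3 produce zero windows.
    """
    arms = list(arms)
    allowed = set(alphabet)
    bad = [a for a in arms if a not in allowed]
    if bad:
        raise ValueError(f"arm symbols outside alphabet {sorted(allowed)}: "
                         f"{sorted(set(bad))}")
    tally = {ALTERNATION: 0, DIRECT_REVISIT: 0, INDIRECT_REVISIT: 0}
    for i in range(max(len(arms) - 2, 0)):
        tally[classify_window(arms[i], arms[i + 1], arms[i + 2])] += 1
    pairwise = sum(1 for i in range(len(arms) - 1) if arms[i] == arms[i + 1])
    return ActionCounts(
        alternations=tally[ALTERNATION],
        direct_revisits=tally[DIRECT_REVISIT],
        indirect_revisits=tally[INDIRECT_REVISIT],
        n_windows=max(len(arms) - 2, 0),
        pairwise_direct=pairwise,
    )


def alternation_percent(counts: ActionCounts) -> float:
    """100 * alternations / windows; NaN (with a warning) if no windows."""
    if counts.n_windows == 0:
        warnings.warn("no length-3 windows: alternation percent undefined",
                      stacklevel=2)
        return float("nan")
    return 100.0 * counts.alternations / counts.n_windows


def action_distribution(counts: ActionCounts) -> dict[str, float]:
    """Per-window rates of each action type (fractions summing to 1)."""
    if counts.n_windows == 0:
        warnings.warn("no length-3 windows: action distribution undefined",
                      stacklevel=2)
        return {ALTERNATION: float("nan"), DIRECT_REVISIT: float("nan"),
                INDIRECT_REVISIT: float("nan")}
    n = counts.n_windows
    return {
        ALTERNATION: counts.alternations / n,
        DIRECT_REVISIT: counts.direct_revisits / n,
        INDIRECT_REVISIT: counts.indirect_revisits / n,
    }


def arm_sequence_from_visits(
    visits: VisitSequence,
    arm_roles: dict[str, str] | None = None,
    center_zone: str = "center",
) -> list[str]:
    """Reduce a Y-maze visit sequence to its arm-to-arm transitions.

    Visits to the center are absorbed (passing through the center does not
    end an arm visit; only arrival at a *different* arm does), and the
    consecutive same-arm duplicates that absorption exposes are collapsed —
    the output records arm changes only.

    ``arm_roles`` maps zone ids to arm symbols; by default ``arm_A`` ->
    ``A`` etc.
    """
    if arm_roles is None:
        arm_roles = {f"arm_{s}": s for s in ARM_ALPHABET}
    arms: list[str] = []
    for zid in visits.zone_sequence():
        if zid == center_zone:
            continue
        if zid not in arm_roles:
            raise ValueError(f"zone {zid!r} is neither the center nor an arm")
        sym = arm_roles[zid]
        if not arms or arms[-1] != sym:
            arms.append(sym)
    return arms


def actions_table(sequences: dict[str, Sequence[str]]):
    """Per-subject action counts as a tidy table (subject_id keyed)."""
    import pandas as pd

    rows = []
    for sid, arms in sequences.items():
        c = classify_actions(arms)
        row = {
            "subject_id": sid,
            "n_visits": len(list(arms)),
            "n_windows": c.n_windows,
            "alternations": c.alternations,
            "direct_revisits": c.direct_revisits,
            "indirect_revisits": c.indirect_revisits,
            "pairwise_direct": c.pairwise_direct,
        }
        if c.n_windows > 0:
            row["alternation_pct"] = alternation_percent(c)
        else:
            row["alternation_pct"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
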