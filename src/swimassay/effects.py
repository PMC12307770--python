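"""Standardized effect sizes for the multi-assay sensitivity summary.

The effect size used throughout is the absolute difference of group means
divided by the *total* standard deviation — the SD of the two groups pooled
into one sample (n - 1 denominator) — rather than Cohen's pooled-within-
groups SD.  Both flavours are available; the pooled-observations form is
the default.  Composite effects (e.g. an isolation effect summarised over
several endpoints of two tests) are unweighted means of component d's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EffectSize:
    endpoint: str
    group_a: str
    group_b: str
    d: float
    n_a: int
    n_b: int


def standardized_effect(
    a: Sequence[float],
    b: Sequence[float],
    endpoint: str = "",
    group_a: str = "a",
    group_b: str = "b",
    sd_mode: str = "total",
) -> EffectSize:
    """|mean(a) - mean(b)| / SD, with SD of the pooled observations.

    ``sd_mode="total"`` (default) divides by the n-1 SD of the combined
    sample; ``sd_mode="pooled_within"`` uses Cohen's pooled within-group
    SD instead.  Zero SD yields a NaN effect with a warning.
    """
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd_mode == "total":
        sd = float(np.std(np.concatenate([av, bv]), ddof=1))
    elif sd_mode == "pooled_within":
        sa2, sb2 = np.var(av, ddof=1), np.var(bv, ddof=1)
        sd = float(np.sqrt(
            ((av.size - 1) * sa2 + (bv.size - 1) * sb2)
            / (av.size + bv.size - 2)
        ))
    else:
        raise ValueError("sd_mode must be 'total' or 'pooled_within'")
    if sd == 0.0:
        warnings.warn("zero pooled SD: effect size undefined", stacklevel=2)
        d = float("nan")
    else:
        d = abs(float(np.mean(av) - np.mean(bv))) / sd
    return EffectSize(endpoint=endpoint, group_a=group_a, group_b=group_b,
                      d=d, n_a=av.size, n_b=bv.size)


def composite_effect(effects: Iterable[EffectSize]) -> float:
    """Unweighted mean of component effect sizes."""
    ds = [e.d for e in effects]
    if not ds:
        raise ValueError("composite effect of an empty list")
    return float(np.mean(ds))


def effects_table(
    endpoints: pd.DataFrame,
    group_col: str = "group",
    group_a: str | None = None,
    group_b: str | None = None,
    sd_mode: str = "total",
) -> pd.DataFrame:
    """Pairwise group effects for every endpoint of a tidy endpoint table.

    ``endpoints`` is the tidy table (``subject_id, session_id, group,
    endpoint, value``); the comparison is ``group_a`` vs ``group_b``
    (defaulting to the two groups present, erroring if there are more).
    """
    groups = sorted(endpoints[group_col].unique())
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(
                f"table has groups {groups}; specify group_a and group_b"
            )
        group_a, group_b = groups
    rows = []
    for ep, sub in endpoints.groupby("endpoint"):
        a = sub.loc[sub[group_col] == group_a, "value"].dropna()
        b = sub.loc[sub[group_col] == group_b, "value"].dropna()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"endpoint {ep!r}: too few observations, skipped",
                          stacklevel=2)
            continue
        e = standardized_effect(a, b, endpoint=ep, group_a=group_a,
                                group_b=group_b, sd_mode=sd_mode)
        rows.append({
            "endpoint": e.endpoint, "group_a": e.group_a,
            "group_b": e.group_b, "d": e.d, "n_a": e.n_a, "n_b": e.n_b,
        })
    return pd.DataFrame(rows,
                        columns=["endpoint", "group_a", "group_b", "d",
                                 "n_a", "n_b"])
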