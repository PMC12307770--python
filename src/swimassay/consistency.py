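"""Behavioral consistency: repeatability and inter-test correlations.

Repeatability (R, an intraclass correlation) is the share of total variance
attributable to stable differences between subjects:

    R = var_between_subject / (var_between_subject + var_within_subject)

Variance components come from the closed-form one-way random-effects ANOVA
(method of moments): with subject mean squares MS_between and pooled
residual MS_within,

    var_within  = MS_within
    var_between = max(0, (MS_between - MS_within) / k0)

where k0 is the design coefficient (the common session count k for balanced
data, ``(N - sum(k_i^2)/N) / (n - 1)`` otherwise).  Confidence intervals
are parametric-bootstrap percentiles: data are resampled from the fitted
normal random-intercept model (same design), R is re-estimated per
replicate, and the 2.5/97.5 percentiles reported.  An estimate whose CI
excludes 0 is flagged significant.

The method-of-moments estimator is a closed-form, hand-checkable
approximation to the likelihood-based mixed-model estimator; on balanced
Gaussian designs the two coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_BOOT = 1000


@dataclass
class RepeatedMeasures:
    """Subject x session matrix of one endpoint (NaN = missing cell).

    Subjects with fewer than two observations are excluded from variance
    decomposition (they carry no within-subject information).
    """

    values: pd.DataFrame  # index: subject_id, columns: session labels
    endpoint: str = ""
    units: str = ""
    true_r: float | None = None  # attached by the simulator when known

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.shape[1] < 2:
            raise ValueError("repeated measures need at least 2 sessions")

    def complete_subjects(self) -> pd.DataFrame:
        keep = self.values.notna().sum(axis=1) >= 2
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(
                f"excluding {dropped} subject(s) with < 2 observations",
                stacklevel=3,
            )
        return self.values.loc[keep]


@dataclass
class RepeatabilityEstimate:
    r: float
    var_between: float
    var_within: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None
    significant: bool | None = None
    endpoint: str = ""

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "R": self.r,
            "var_between_subject": self.var_between,
            "var_within_subject": self.var_within,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "significant": self.significant,
        }


# ---------------------------------------------------------------------------
# variance components (one-way random-effects ANOVA, method of moments)
# ---------------------------------------------------------------------------

def _flatten(values: pd.DataFrame):
    """Long-form arrays (obs ordered by subject) + per-subject counts."""
    y, counts = [], []
    for _, row in values.iterrows():
        obs = row.dropna().to_numpy()
        y.append(obs)
        counts.append(len(obs))
    return np.concatenate(y), np.asarray(counts, dtype=int)


def _anova_components(y: np.ndarray, counts: np.ndarray):
    """Variance components from flat observations grouped by ``counts``."""
    n = counts.size
    N = counts.sum()
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    sums = np.add.reduceat(y, starts)
    means = sums / counts
    grand = y.sum() / N
    ss_within = np.sum((y - np.repeat(means, counts)) ** 2)
    ms_within = ss_within / (N - n)
    ms_between = np.sum(counts * (means - grand) ** 2) / (n - 1)
    k0 = (N - np.sum(counts**2) / N) / (n - 1)
    var_between = max(0.0, (ms_between - ms_within) / k0)
    return var_between, float(ms_within), float(grand)


def variance_components(data: RepeatedMeasures) -> tuple[float, float]:
    """(var_between_subject, var_within_subject) for one endpoint.

    Negative between-subject estimates are truncated at zero.
    """
    values = data.complete_subjects()
    if values.shape[0] < 2:
        raise ValueError("variance decomposition needs >= 2 subjects with "
                         ">= 2 observations each")
    y, counts = _flatten(values)
    var_between, var_within, _ = _anova_components(y, counts)
    return var_between, var_within


# ---------------------------------------------------------------------------
# repeatability with parametric bootstrap CI
# ---------------------------------------------------------------------------

def _bootstrap_r(
    grand: float,
    var_between: float,
    var_within: float,
    counts: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """R re-estimated on ``n_boot`` datasets drawn from the fitted
    random-intercept model (vectorised across replicates)."""
    n = counts.size
    N = int(counts.sum())
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    b = rng.normal(0.0, np.sqrt(var_between), size=(n_boot, n))
    e = rng.normal(0.0, np.sqrt(var_within), size=(n_boot, N))
    y = grand + np.repeat(b, counts, axis=1) + e

    sums = np.add.reduceat(y, starts, axis=1)
    means = sums / counts
    grand_b = y.sum(axis=1, keepdims=True) / N
    ss_within = np.sum((y - np.repeat(means, counts, axis=1)) ** 2, axis=1)
    ms_within = ss_within / (N - n)
    ms_between = np.sum(counts * (means - grand_b) ** 2, axis=1) / (n - 1)
    k0 = (N - np.sum(counts**2) / N) / (n - 1)
    var_b = np.maximum(0.0, (ms_between - ms_within) / k0)
    total = var_b + ms_within
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(total > 0, var_b / total, 0.0)
    return r


def repeatability(
    data: RepeatedMeasures,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> RepeatabilityEstimate:
    """Repeatability with a parametric-bootstrap percentile CI.

    ``n_boot = 1000`` replicates by default; identical seeds give
    bit-identical intervals.  Significance = the CI excluding zero.
    """
    if 0 < n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} is small; CI will be noisy",
                      stacklevel=2)
    values = data.complete_subjects()
    if values.shape[0] < 2:
        raise ValueError("repeatability needs >= 2 subjects with >= 2 "
                         "observations each")
    y, counts = _flatten(values)
    var_between, var_within, grand = _anova_components(y, counts)
    total = var_between + var_within
    if total == 0.0:
        warnings.warn("zero total variance: R defined as 0 with CI [0, 0]",
                      stacklevel=2)
        return RepeatabilityEstimate(
            r=0.0, var_between=0.0, var_within=0.0, ci_low=0.0, ci_high=0.0,
            n_boot=n_boot, seed=seed, significant=False,
            endpoint=data.endpoint,
        )
    r = var_between / total

    ci_low = ci_high = None
    significant = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = _bootstrap_r(grand, var_between, var_within, counts, n_boot,
                             rng)
        alpha = 1.0 - ci_level
        ci_low, ci_high = np.percentile(
            boots, [100 * alpha / 2, 100 * (1 - alpha / 2)]
        )
        ci_low, ci_high = float(ci_low), float(ci_high)
        significant = ci_low > 0.0

    return RepeatabilityEstimate(
        r=float(r), var_between=float(var_between),
        var_within=float(var_within), ci_low=ci_low, ci_high=ci_high,
        n_boot=n_boot, seed=seed, significant=significant,
        endpoint=data.endpoint,
    )


# ---------------------------------------------------------------------------
# SiM / SuM summaries and inter-test correlations
# ---------------------------------------------------------------------------

def summarise(data: RepeatedMeasures, mode: str = "SuM") -> pd.Series:
    """Per-subject scalar: SiM (first session) or SuM (mean of sessions).

    Subjects with no usable value are excluded with a warning.
    """
    mode = mode.lower()
    if mode == "sim":
        out = data.values.iloc[:, 0]
    elif mode == "sum":
        out = data.values.mean(axis=1, skipna=True)
    else:
        raise ValueError("mode must be 'SiM' or 'SuM'")
    dropped = int(out.isna().sum())
    if dropped:
        warnings.warn(f"excluding {dropped} subject(s) with no "
                      f"{mode.upper()} value", stacklevel=2)
    out = out.dropna()
    out.name = f"{data.endpoint}_{mode}" if data.endpoint else mode
    return out


def intertest_correlation(
    x: pd.Series,
    y: pd.Series,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """(r, two-sided p, n) over subjects present in both series.

    Returns NaN coefficients (with a warning) when either vector has zero
    variance on the complete pairs.
    """
    joined = pd.concat({"x": x, "y": y}, axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xv = joined["x"].to_numpy()
    yv = joined["y"].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan"), float("nan"), n
    if method == "pearson":
        res = stats.pearsonr(xv, yv)
    elif method == "spearman":
        res = stats.spearmanr(xv, yv)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue), n
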