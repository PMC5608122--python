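"""Repeatability statistics for paired repeat-scan measurements.

Covers the statistical machinery of a gated-vs-ungated repeatability study:

* nonparametric description (median, Tukey-hinge IQR) and Shapiro-Wilk
  normality screening;
* paired Wilcoxon signed-rank comparisons between sequences (repeat 1);
* Bland-Altman repeatability: bias = mean of pairwise differences, 95%
  limits-of-agreement (LOA) range = 2 * 1.96 * SD of pairwise differences,
  and the normalized LOA percentage (LOA range / median * 100);
* a permutation test on the variance ratio of two repeat-difference vectors
  (gated over ungated), with exact enumeration whenever the number of
  distinct re-partitions does not exceed the permutation budget.

The permutation null pools the 2n differences and re-splits them into two
groups of n without replacement ("pooled-resplit"); the sampled partitions
are de-duplicated so every draw is unique.  A within-pair label-swap scheme
is available as an alternative.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientDataError, InvalidParameterError, PairingError

__all__ = [
    "PairedSample",
    "RepeatabilityResult",
    "PermutationTestResult",
    "describe",
    "tukey_hinges",
    "normality_screen",
    "paired_wilcoxon",
    "bland_altman",
    "normalized_loa_pct",
    "permutation_variance_test",
    "build_comparison_table",
    "build_repeatability_table",
]


@dataclass(frozen=True)
class PairedSample:
    """Repeat-1/repeat-2 vectors of one metric for one sequence arm."""

    metric_name: str
    values_repeat1: tuple[float, ...]
    values_repeat2: tuple[float, ...]
    sequence_label: str = ""
    weighting: str = ""

    def __post_init__(self) -> None:
        r1 = np.asarray(self.values_repeat1, float)
        r2 = np.asarray(self.values_repeat2, float)
        if r1.size != r2.size:
            raise InvalidParameterError("repeat vectors must have equal length")
        if r1.size < 3:
            raise InsufficientDataError("need at least 3 pairs")
        if np.isnan(r1).any() or np.isnan(r2).any():
            raise InvalidParameterError("missing values must be filtered before pairing")

    @property
    def differences(self) -> np.ndarray:
        """Pairwise differences, fixed sign convention repeat1 - repeat2."""
        return np.asarray(self.values_repeat1, float) - np.asarray(self.values_repeat2, float)


@dataclass(frozen=True)
class RepeatabilityResult:
    """Bland-Altman summary of one paired sample."""

    metric_name: str
    bias: float
    loa_range: float
    loa_pct: float
    n: int
    sequence_label: str = ""
    weighting: str = ""


@dataclass(frozen=True)
class PermutationTestResult:
    """Outcome of the variance-ratio permutation test."""

    r_obs: float
    p_value: float
    n_permutations: int
    scheme: str
    seed: int | None
    exact: bool
    applicable: bool = True


def tukey_hinges(values) -> tuple[float, float]:
    """Lower and upper Tukey hinges (fourths) of a sample."""
    x = np.sort(np.asarray(values, float))
    n = x.size
    if n == 0:
        raise InsufficientDataError("empty sample")
    half = (n + 1) // 2  # halves share the median when n is odd
    return float(np.median(x[:half])), float(np.median(x[-half:]))


def describe(values) -> dict[str, float]:
    """Median and interquartile range (Tukey hinges) of a sample."""
    x = np.asarray(values, float)
    if x.size == 0:
        raise InsufficientDataError("empty sample")
    lo, hi = tukey_hinges(x)
    return {"median": float(np.median(x)), "iqr": hi - lo, "n": int(x.size)}


def normality_screen(values) -> dict[str, float | bool]:
    """Shapiro-Wilk W and p; not-applicable for constant input."""
    x = np.asarray(values, float)
    if not 3 <= x.size <= 5000:
        raise InsufficientDataError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return {"w": math.nan, "p": math.nan, "applicable": False}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.shapiro(x)
    return {"w": float(res.statistic), "p": float(res.pvalue), "applicable": True}


def paired_wilcoxon(x, y) -> dict[str, float]:
    """Two-sided Wilcoxon signed-rank test with Pratt zero handling.

    All-zero differences are a degenerate case reported as p = 1 rather than
    an error, so pipelines over many metrics keep running.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise InvalidParameterError("paired vectors must have equal length")
    d = x - y
    if np.count_nonzero(d) == 0:
        return {"statistic": math.nan, "p": 1.0}
    if np.count_nonzero(d) < 5:
        raise InsufficientDataError("need at least 5 nonzero differences")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(x, y, zero_method="pratt", alternative="two-sided")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def normalized_loa_pct(loa_range: float, median: float) -> float:
    """LOA range as a percentage of a reference median."""
    if median == 0:
        raise InvalidParameterError("reference median must be nonzero")
    return loa_range / median * 100.0


def bland_altman(
    sample: PairedSample,
    median_source: str = "pooled",
    reference_median: float | None = None,
) -> RepeatabilityResult:
    """Bland-Altman bias, 95% LOA range, and normalized LOA percentage.

    ``median_source`` picks the denominator of the normalized percentage:
    "pooled" (both repeats of this arm), "repeat1", or "external" (pass
    ``reference_median``, e.g. a published distribution median).
    """
    d = sample.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_range = 2.0 * 1.96 * sd
    if median_source == "pooled":
        med = float(np.median(np.concatenate([sample.values_repeat1, sample.values_repeat2])))
    elif median_source == "repeat1":
        med = float(np.median(sample.values_repeat1))
    elif median_source == "external":
        if reference_median is None:
            raise InvalidParameterError("median_source='external' needs reference_median")
        med = float(reference_median)
    else:
        raise InvalidParameterError("median_source must be pooled|repeat1|external")
    loa_pct = normalized_loa_pct(loa_range, med) if med != 0 else math.nan
    return RepeatabilityResult(
        metric_name=sample.metric_name,
        bias=bias,
        loa_range=loa_range,
        loa_pct=loa_pct,
        n=d.size,
        sequence_label=sample.sequence_label,
        weighting=sample.weighting,
    )


def _group_variances(pooled: np.ndarray, combos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample variances of the selected group and its complement, per row."""
    n = combos.shape[1]
    m = pooled.size - n
    g = pooled[combos]
    s_g = g.sum(axis=1)
    ss_g = (g * g).sum(axis=1)
    var_g = (ss_g - s_g * s_g / n) / (n - 1)
    s_u = pooled.sum() - s_g
    ss_u = (pooled * pooled).sum() - ss_g
    var_u = (ss_u - s_u * s_u / m) / (m - 1)
    return var_g, var_u


def _ratio(var_g: np.ndarray, var_u: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return var_g / var_u


def _count_ge(r_perm: np.ndarray, r_obs: float) -> int:
    """Permuted ratios at least as extreme as observed; NaN (0/0) counts as a tie."""
    tol = 1e-12 * max(1.0, abs(r_obs)) if math.isfinite(r_obs) else 0.0
    ge = r_perm >= (r_obs - tol) if math.isfinite(r_obs) else np.isinf(r_perm)
    return int(np.count_nonzero(ge | np.isnan(r_perm)))


def _sample_unique_combos(rng: np.random.Generator, n_total: int, n: int, budget: int) -> np.ndarray:
    seen: set[tuple[int, ...]] = set()
    rows: list[np.ndarray] = []
    while len(rows) < budget:
        k = max(budget - len(rows), 64)
        batch = np.argsort(rng.random((int(k * 1.05) + 8, n_total)), axis=1)[:, :n]
        batch.sort(axis=1)
        for row in batch:
            key = tuple(int(v) for v in row)
            if key not in seen:
                seen.add(key)
                rows.append(row)
                if len(rows) == budget:
                    break
    return np.asarray(rows, dtype=np.intp)


def permutation_variance_test(
    diff_gated,
    diff_ungated,
    n_perm: int = 50000,
    scheme: str = "pooled-resplit",
    seed: int | None = None,
) -> PermutationTestResult:
    """One-sided permutation test of var(diff_gated) / var(diff_ungated).

    Tests the alternative that the gated arm's repeat differences vary more
    than the ungated arm's.  Null distribution: under "pooled-resplit" the 2n
    differences are pooled and re-split without replacement into two groups
    of the original sizes; under "within-pair-swap" the two vectors are
    paired element-wise and each pair's labels are independently swapped.
    When the number of distinct re-partitions is at most ``n_perm`` the null
    is enumerated exhaustively and the exact p is reported; otherwise
    ``n_perm`` unique random partitions are drawn and the add-one estimator
    ``p = (1 + #{r >= r_obs}) / (1 + B)`` is used.

    If the ungated variance is exactly zero the observed ratio is infinite
    and only infinite permuted ratios count against it; if both variances are
    zero the test is reported as not applicable.
    """
    g = np.asarray(diff_gated, float)
    u = np.asarray(diff_ungated, float)
    if g.size < 3 or u.size < 3:
        raise InsufficientDataError("need at least 3 differences per arm")
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    if scheme not in ("pooled-resplit", "within-pair-swap"):
        raise InvalidParameterError("scheme must be pooled-resplit|within-pair-swap")
    var_g = float(np.var(g, ddof=1))
    var_u = float(np.var(u, ddof=1))
    if var_g == 0 and var_u == 0:
        return PermutationTestResult(
            r_obs=math.nan, p_value=math.nan, n_permutations=0,
            scheme=scheme, seed=seed, exact=False, applicable=False,
        )
    r_obs = math.inf if var_u == 0 else var_g / var_u

    rng = np.random.default_rng(seed)
    if scheme == "pooled-resplit":
        pooled = np.concatenate([g, u])
        n, n_total = g.size, g.size + u.size
        total = math.comb(n_total, n)
        if total <= n_perm:
            combos = np.fromiter(
                itertools.chain.from_iterable(itertools.combinations(range(n_total), n)),
                dtype=np.intp,
            ).reshape(total, n)
            r_perm = _ratio(*_group_variances(pooled, combos))
            return PermutationTestResult(
                r_obs=r_obs, p_value=_count_ge(r_perm, r_obs) / total,
                n_permutations=total, scheme=scheme, seed=seed, exact=True,
            )
        combos = _sample_unique_combos(rng, n_total, n, n_perm)
        r_perm = _ratio(*_group_variances(pooled, combos))
        p = (1 + _count_ge(r_perm, r_obs)) / (1 + n_perm)
        return PermutationTestResult(
            r_obs=r_obs, p_value=p, n_permutations=n_perm,
            scheme=scheme, seed=seed, exact=False,
        )

    # within-pair-swap: requires equal lengths; swap mask per pair
    if g.size != u.size:
        raise InvalidParameterError("within-pair-swap needs equal-length vectors")
    n = g.size
    total = 2**n
    if total <= n_perm:
        masks = (np.arange(total)[:, None] >> np.arange(n)[None, :]) & 1
        exact = True
        budget = total
    else:
        seen: set[int] = set()
        keys: list[int] = []
        while len(keys) < n_perm:
            cand = rng.integers(0, total, size=n_perm - len(keys) + 16)
            for c in cand:
                c = int(c)
                if c not in seen:
                    seen.add(c)
                    keys.append(c)
                    if len(keys) == n_perm:
                        break
        masks = (np.asarray(keys)[:, None] >> np.arange(n)[None, :]) & 1
        exact = False
        budget = n_perm
    gm = np.where(masks == 1, u[None, :], g[None, :])
    um = np.where(masks == 1, g[None, :], u[None, :])
    r_perm = _ratio(gm.var(axis=1, ddof=1), um.var(axis=1, ddof=1))
    count = _count_ge(r_perm, r_obs)
    p = count / budget if exact else (1 + count) / (1 + budget)
    return PermutationTestResult(
        r_obs=r_obs, p_value=p, n_permutations=budget,
        scheme=scheme, seed=seed, exact=exact,
    )


def build_comparison_table(metrics: pd.DataFrame, metric_columns: list[str]) -> pd.DataFrame:
    """Gated-vs-ungated distribution table from repeat-1 measurements.

    ``metrics`` is long-format with columns subject, sequence, weighting,
    repeat plus one column per metric.  Per (weighting, metric): gated and
    ungated median [IQR] over subjects and the paired Wilcoxon p.
    """
    required = {"subject", "sequence", "weighting", "repeat"}
    if not required.issubset(metrics.columns):
        raise PairingError(f"metrics table needs columns {sorted(required)}")
    rep1 = metrics[metrics["repeat"] == 1]
    rows = []
    for weighting, grp in rep1.groupby("weighting", sort=True):
        wide = grp.pivot(index="subject", columns="sequence", values=metric_columns)
        if wide.isna().any().any() or not {"gated", "ungated"}.issubset(grp["sequence"].unique()):
            raise PairingError(f"{weighting}: unmatched subjects between sequences")
        if len(wide) < 2:
            raise PairingError("need more than one subject to compare sequences")
        for metric in metric_columns:
            gated = wide[(metric, "gated")].to_numpy()
            ungated = wide[(metric, "ungated")].to_numpy()
            dg, du = describe(gated), describe(ungated)
            try:
                wil = paired_wilcoxon(gated, ungated)
            except InsufficientDataError:
                # too few nonzero differences for a signed-rank p; keep the
                # distribution summary and report the test as not applicable
                wil = {"statistic": math.nan, "p": math.nan}
            rows.append({
                "weighting": weighting,
                "metric": metric,
                "gated_median": dg["median"],
                "gated_iqr": dg["iqr"],
                "ungated_median": du["median"],
                "ungated_iqr": du["iqr"],
                "wilcoxon_p": wil["p"],
                "n": len(wide),
            })
    return pd.DataFrame(rows)


def _paired_sample(grp: pd.DataFrame, metric: str, sequence: str, weighting: str) -> PairedSample:
    wide = grp.pivot(index="subject", columns="repeat", values=metric)
    if wide.isna().any().any() or not {1, 2}.issubset(wide.columns):
        raise PairingError(f"{weighting}/{sequence}/{metric}: unmatched repeats")
    return PairedSample(
        metric_name=metric,
        values_repeat1=tuple(wide[1].to_numpy()),
        values_repeat2=tuple(wide[2].to_numpy()),
        sequence_label=sequence,
        weighting=weighting,
    )


def build_repeatability_table(
    metrics: pd.DataFrame,
    metric_columns: list[str],
    n_perm: int = 50000,
    scheme: str = "pooled-resplit",
    seed: int | None = None,
    median_source: str = "pooled",
) -> pd.DataFrame:
    """Repeatability table: per metric, per-arm Bland-Altman + permutation p.

    One permutation test per (weighting, metric) compares the gated against
    the ungated repeat-difference vector; seeds are derived per row from
    ``seed`` so rows are reproducible independently of evaluation order.
    """
    required = {"subject", "sequence", "weighting", "repeat"}
    if not required.issubset(metrics.columns):
        raise PairingError(f"metrics table needs columns {sorted(required)}")
    rows = []
    ss = np.random.SeedSequence(seed)
    for weighting, wgrp in metrics.groupby("weighting", sort=True):
        for metric in metric_columns:
            samples = {}
            for sequence in ("gated", "ungated"):
                sgrp = wgrp[wgrp["sequence"] == sequence]
                if sgrp.empty:
                    raise PairingError(f"{weighting}/{metric}: missing {sequence} arm")
                samples[sequence] = _paired_sample(sgrp, metric, sequence, weighting)
            ba = {seq: bland_altman(s, median_source=median_source) for seq, s in samples.items()}
            row_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            perm = permutation_variance_test(
                samples["gated"].differences,
                samples["ungated"].differences,
                n_perm=n_perm,
                scheme=scheme,
                seed=row_seed,
            )
            rows.append({
                "weighting": weighting,
                "metric": metric,
                "gated_bias": ba["gated"].bias,
                "gated_loa_range": ba["gated"].loa_range,
                "gated_loa_pct": ba["gated"].loa_pct,
                "ungated_bias": ba["ungated"].bias,
                "ungated_loa_range": ba["ungated"].loa_range,
                "ungated_loa_pct": ba["ungated"].loa_pct,
                "variance_ratio": perm.r_obs,
                "permutation_p": perm.p_value,
                "n_permutations": perm.n_permutations,
                "n": ba["gated"].n,
            })
    return pd.DataFrame(rows)
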