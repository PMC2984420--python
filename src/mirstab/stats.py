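"""Statistical battery and stability classifications.

Group comparisons follow a fixed recipe: for each species and each
characteristic (AMFE, bp %, (A-U) %, nucleotide composition) every
conserved set S_c^i is compared against the non-conserved set S_n with

* a two-sample, two-sided Welch t-test (means, no equal-variance
  assumption) -- reported as p1;
* a two-sample, two-sided variance F-test -- reported as p2;

and all p-values of a given characteristic are jointly adjusted with the
Benjamini-Hochberg step-up procedure (FDR control).  Normality is checked
with a Lilliefors test whose p-value comes from a seeded Monte Carlo null.

Stability classifications:

* *extreme stability*: per species, AMFEs above the 90th percentile are
  "ultra stable", below the 10th percentile "unstable" (strict
  inequalities; ties at the threshold are not extreme);
* *T1/T2 partition*: T1 and T2 are the 10th and 90th AMFE percentiles of
  the pooled most-conserved set S_c3.  Non-conserved records split into
  S_n_u (< T1), S_n_m (T1 <= AMFE <= T2) and S_n_s (> T2); conserved
  records inside the closed band form S_c_m.

Percentiles use linear interpolation between order statistics by default;
nearest-rank is available as an alternative convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from mirstab.conservation import CONSERVED_GROUPS, GROUPS
from mirstab.errors import ValidationError

METRICS = ("amfe", "bp_pct", "au_pair_pct", "AU_pct", "A_pct", "U_pct", "G_pct", "C_pct")

SUBGROUPS = ("S_n_u", "S_n_m", "S_n_s", "S_c_m")


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def _as_sample(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError(f"sample {name} needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"sample {name} contains non-finite values")
    return arr


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sample t-test, two-sided.

    Uses the Welch-Satterthwaite degrees of freedom.  When both samples
    have zero variance the convention is p = 1 for equal means and p = 0
    otherwise.
    """
    xa, ya = _as_sample(x, "x"), _as_sample(y, "y")
    nx, ny = xa.size, ya.size
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    dmean = xa.mean() - ya.mean()
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        return (0.0, 1.0) if dmean == 0.0 else (math.inf * np.sign(dmean), 0.0)
    t = dmean / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def variance_f_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample two-sided F-test for equality of variances.

    F = var(x)/var(y) (sample variances); p = 2 min(lower tail, upper
    tail), capped at 1.
    """
    xa, ya = _as_sample(x, "x"), _as_sample(y, "y")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vy == 0.0:
        raise ValidationError("denominator sample has zero variance")
    f = vx / vy
    dist = sps.f(xa.size - 1, ya.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def lilliefors_statistic(x: Sequence[float]) -> float:
    """Kolmogorov-Smirnov distance to N(mean, sd) with estimated parameters."""
    xa = np.sort(_as_sample(x, "x"))
    sd = xa.std(ddof=1)
    if sd == 0.0:
        raise ValidationError("sample has zero variance")
    z = (xa - xa.mean()) / sd
    cdf = sps.norm.cdf(z)
    n = xa.size
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def _null_lilliefors_sample(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Monte Carlo null distribution of the Lilliefors D statistic."""
    samples = rng.standard_normal((reps, n))
    samples.sort(axis=1)
    mean = samples.mean(axis=1, keepdims=True)
    sd = samples.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf((samples - mean) / sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf, axis=1)
    d_minus = np.max(cdf - (i - 1) / n, axis=1)
    return np.maximum(d_plus, d_minus)


@lru_cache(maxsize=32)
def _cached_null(n: int, reps: int, seed: int) -> tuple[float, ...]:
    rng = np.random.default_rng(seed)
    return tuple(_null_lilliefors_sample(n, reps, rng))


def lilliefors_test(
    x: Sequence[float], mc_reps: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Lilliefors normality test with a seeded Monte Carlo p-value.

    The p-value is the fraction of ``mc_reps`` standard-normal samples of
    the same size whose D statistic is at least the observed one; the null
    distribution is cached per (n, reps, seed), so repeated calls with the
    same arguments are cheap and identical.
    """
    xa = _as_sample(x, "x")
    if xa.size < 4:
        raise ValidationError("Lilliefors test needs n >= 4")
    d = lilliefors_statistic(xa)
    null = np.asarray(_cached_null(xa.size, mc_reps, seed))
    p = float(np.mean(null >= d))
    return d, p


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Standard step-up with monotonicity enforcement; the output preserves
    the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvals must be one-dimensional")
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


# ---------------------------------------------------------------------------
# Percentiles and stability classifications
# ---------------------------------------------------------------------------

def percentile(values: Sequence[float], q: float, mode: str = "linear") -> float:
    """q-th percentile (0-100), by linear interpolation or nearest rank."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValidationError("cannot take a percentile of an empty sample")
    if mode == "linear":
        return float(np.percentile(vals, q, method="linear"))
    if mode == "nearest":
        # classical nearest-rank: value at rank ceil(q/100 * n)
        vals = np.sort(vals)
        rank = max(1, math.ceil(q / 100.0 * vals.size))
        return float(vals[min(rank, vals.size) - 1])
    raise ValidationError(f"unknown percentile mode {mode!r}")


@dataclass
class ExtremeStabilityLabels:
    """Per-species top/bottom-10% AMFE classification."""

    ultra: set[str]
    unstable: set[str]
    lower: float
    upper: float
    low_n: bool = False


def classify_extreme_stability(
    amfe_by_id: Mapping[str, float], quantile_mode: str = "linear"
) -> ExtremeStabilityLabels:
    """Ultra stable = AMFE strictly above the 90th percentile; unstable =
    strictly below the 10th.  Fewer than 10 records sets the low-n flag."""
    if not amfe_by_id:
        raise ValidationError("empty AMFE set")
    vals = list(amfe_by_id.values())
    lower = percentile(vals, 10, quantile_mode)
    upper = percentile(vals, 90, quantile_mode)
    return ExtremeStabilityLabels(
        ultra={rid for rid, a in amfe_by_id.items() if a > upper},
        unstable={rid for rid, a in amfe_by_id.items() if a < lower},
        lower=lower,
        upper=upper,
        low_n=len(vals) < 10,
    )


@dataclass
class StabilityPartition:
    """T1/T2 thresholds with per-record subgroup assignments.

    ``subgroup`` maps record id to one of S_n_u / S_n_m / S_n_s (splits of
    the non-conserved set) or S_c_m (conserved, moderately stable);
    conserved records outside the closed [T1, T2] band get ``None``.
    """

    t1: float
    t2: float
    subgroup: dict[str, str | None] = field(default_factory=dict)

    def members(self, name: str) -> set[str]:
        return {rid for rid, sg in self.subgroup.items() if sg == name}


def partition_by_thresholds(
    sc3_amfes: Sequence[float],
    records: Mapping[str, tuple[str, float]],
    quantile_mode: str = "linear",
) -> StabilityPartition:
    """Split records around the 10th/90th AMFE percentiles of pooled S_c3.

    ``records`` maps id -> (conservation group, AMFE).  Band boundaries are
    inclusive into the middle band.
    """
    if len(sc3_amfes) == 0:
        raise ValidationError("S_c3 AMFE set is empty; T1/T2 are undefined")
    t1 = percentile(sc3_amfes, 10, quantile_mode)
    t2 = percentile(sc3_amfes, 90, quantile_mode)
    sub: dict[str, str | None] = {}
    for rid, (group, amfe) in records.items():
        if group == "S_n":
            if amfe < t1:
                sub[rid] = "S_n_u"
            elif amfe > t2:
                sub[rid] = "S_n_s"
            else:
                sub[rid] = "S_n_m"
        elif group in CONSERVED_GROUPS:
            sub[rid] = "S_c_m" if t1 <= amfe <= t2 else None
    return StabilityPartition(t1=t1, t2=t2, subgroup=sub)


# ---------------------------------------------------------------------------
# Group summaries, comparisons, pooled aggregates
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Summaries, pairwise tests and pooled aggregates for one population.

    ``summaries``: species, group, metric, n, mean, sd.
    ``comparisons``: species, group, metric, t_stat, p_mean, f_stat,
    p_var, q_mean, q_var, and significance flags at FDR 0.05 / 0.01.
    ``pooled``: metric, conserved / non-conserved sample-size-weighted
    means and their difference.
    """

    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    pooled: pd.DataFrame


def group_summary(values: Sequence[float]) -> tuple[int, float, float]:
    """(n, mean, sample sd) with the n-1 denominator."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("a group summary needs at least 2 values")
    return int(arr.size), float(arr.mean()), float(arr.std(ddof=1))


def pooled_weighted_mean(
    summaries: pd.DataFrame, metric: str, groups: Iterable[str]
) -> float:
    """Sample-size-weighted mean of per-set means, pooled across species.

    Operates purely on the summary level (n, mean per set), so it applies
    identically to summaries derived from raw data and to published
    summary-statistics tables.
    """
    groups = set(groups)
    sel = summaries[(summaries["metric"] == metric) & summaries["group"].isin(groups)]
    if sel.empty:
        raise ValidationError(f"no summary cells for metric {metric!r}, groups {sorted(groups)}")
    return float(np.average(sel["mean"], weights=sel["n"]))


def sd_ratio(
    summaries: pd.DataFrame, species: str, metric: str, group_num: str, group_den: str
) -> float:
    """Ratio of two sets' sample standard deviations within one species."""
    sel = summaries[(summaries["species"] == species) & (summaries["metric"] == metric)]
    by_group = sel.set_index("group")["sd"]
    return float(by_group[group_num] / by_group[group_den])


def mean_difference(
    summaries: pd.DataFrame, species: str, metric: str, group_a: str, group_b: str
) -> float:
    """mean(group_a) - mean(group_b) for one species and metric."""
    sel = summaries[(summaries["species"] == species) & (summaries["metric"] == metric)]
    by_group = sel.set_index("group")["mean"]
    return float(by_group[group_a] - by_group[group_b])


def summarize_and_compare(
    data: pd.DataFrame,
    metrics: Sequence[str] = METRICS,
    alpha_levels: Sequence[float] = (0.05, 0.01),
    min_set_size: int = 5,
) -> ComparisonReport:
    """Full per-species summary and S_c vs S_n comparison battery.

    ``data`` holds one row per record with columns ``id``, ``species``,
    ``group`` and one column per metric.  Rows whose group is not one of
    S_n / S_c1 / S_c2 / S_c3 (e.g. excluded or dropped records) are
    ignored.  Groups below ``min_set_size`` are summarised but skipped in
    comparisons.  BH adjustment is applied within each metric, separately
    for the mean-test (p1) and variance-test (p2) families, across all
    species and group pairs.
    """
    present = [m for m in metrics if m in data.columns]
    if not present:
        raise ValidationError("no metric columns found in data")
    pop = data[data["group"].isin(GROUPS)]

    sum_rows = []
    cmp_rows = []
    for species, by_species in pop.groupby("species", sort=True):
        groups_here = {g: df for g, df in by_species.groupby("group")}
        for metric in present:
            for g in GROUPS:
                if g not in groups_here or len(groups_here[g]) < 2:
                    continue
                n, mean, sd = group_summary(groups_here[g][metric].to_numpy())
                sum_rows.append(
                    {"species": species, "group": g, "metric": metric,
                     "n": n, "mean": mean, "sd": sd}
                )
            if "S_n" not in groups_here or len(groups_here["S_n"]) < min_set_size:
                continue
            sn = groups_here["S_n"][metric].to_numpy()
            for g in CONSERVED_GROUPS:
                if g not in groups_here or len(groups_here[g]) < min_set_size:
                    continue
                sc = groups_here[g][metric].to_numpy()
                t, p1 = welch_t_test(sc, sn)
                f, p2 = variance_f_test(sc, sn)
                cmp_rows.append(
                    {"species": species, "group": g, "metric": metric,
                     "t_stat": t, "p_mean": p1, "f_stat": f, "p_var": p2}
                )

    summaries = pd.DataFrame(
        sum_rows, columns=["species", "group", "metric", "n", "mean", "sd"]
    )
    comparisons = pd.DataFrame(
        cmp_rows,
        columns=["species", "group", "metric", "t_stat", "p_mean", "f_stat", "p_var"],
    )

    if not comparisons.empty:
        comparisons["q_mean"] = np.nan
        comparisons["q_var"] = np.nan
        for metric in present:
            mask = comparisons["metric"] == metric
            if mask.any():
                comparisons.loc[mask, "q_mean"] = bh_adjust(
                    comparisons.loc[mask, "p_mean"].tolist()
                )
                comparisons.loc[mask, "q_var"] = bh_adjust(
                    comparisons.loc[mask, "p_var"].tolist()
                )
        for alpha in alpha_levels:
            tag = f"{alpha:g}".replace("0.", "")
            comparisons[f"sig_mean_{tag}"] = comparisons["q_mean"] <= alpha
            comparisons[f"sig_var_{tag}"] = comparisons["q_var"] <= alpha

    pooled = pooled_aggregates(summaries, present)
    return ComparisonReport(summaries=summaries, comparisons=comparisons, pooled=pooled)


def pooled_aggregates(summaries: pd.DataFrame, metrics: Sequence[str]) -> pd.DataFrame:
    """Conserved vs non-conserved pooled weighted means per metric."""
    rows = []
    for metric in metrics:
        sel = summaries[summaries["metric"] == metric]
        has_cons = sel["group"].isin(CONSERVED_GROUPS).any()
        has_noncons = (sel["group"] == "S_n").any()
        if not (has_cons and has_noncons):
            continue
        cons = pooled_weighted_mean(summaries, metric, CONSERVED_GROUPS)
        noncons = pooled_weighted_mean(summaries, metric, ("S_n",))
        rows.append(
            {"metric": metric, "conserved_mean": cons,
             "nonconserved_mean": noncons, "difference": cons - noncons}
        )
    return pd.DataFrame(
        rows, columns=["metric", "conserved_mean", "nonconserved_mean", "difference"]
    )


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def write_report_tables(report: ComparisonReport, out_dir: str | Path) -> None:
    """Write the stability report (AMFE) and the composition report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def fmt(df: pd.DataFrame, path: Path) -> None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    stab_sum = report.summaries[report.summaries["metric"] == "amfe"]
    stab_cmp = report.comparisons[report.comparisons["metric"] == "amfe"] \
        if not report.comparisons.empty else report.comparisons
    fmt(stab_sum, out / "stability_summary.tsv")
    fmt(stab_cmp, out / "stability_comparisons.tsv")
    fmt(report.summaries, out / "group_summaries.tsv")
    fmt(report.comparisons, out / "group_comparisons.tsv")
    fmt(report.pooled, out / "pooled_means.tsv")


def write_partition_table(partition: StabilityPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsubgroup\tT1\tT2\n")
        for rid, sg in partition.subgroup.items():
            fh.write(f"{rid}\t{sg or ''}\t{partition.t1:.4f}\t{partition.t2:.4f}\n")
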