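"""Group summaries and nonparametric comparisons across experience levels.

The study design compares three surgeon cohorts (resident, specialist,
senior) on each efficiency metric, stratified by procedure and hand.  The
unit of observation is one recording's metric value — one value per
participant x hand x procedure, giving group sample sizes 10/10/4 per cell.

For every cell the battery reports per-group mean and sample SD, a per-group
Shapiro-Wilk normality check, and a tie-corrected Kruskal-Wallis omnibus
test referred to chi-squared with k-1 degrees of freedom.  No
multiple-testing correction is applied; the report states the number of
tests performed.  Dunn pairwise comparisons are available but off by
default.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imu_io import GROUPS, HANDS, PROCEDURES

__all__ = [
    "GroupSummary",
    "TestResult",
    "BatteryConfig",
    "DegenerateDataError",
    "summarize_groups",
    "shapiro_wilk",
    "kruskal_wallis",
    "dunn_posthoc",
    "run_battery",
    "summaries_frame",
    "tests_frame",
    "write_report",
    "format_cell_table",
]


class DegenerateDataError(ValueError):
    """The sample admits no meaningful test (e.g. all values identical)."""


@dataclass
class GroupSummary:
    """Mean and SD of one metric for one group within one stratum."""

    metric: str
    procedure: str
    hand: str          # DH, NDH or pooled
    group: str
    n: int
    mean: float
    sd: float | None   # None when n == 1 (flagged undefined)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TestResult:
    """Omnibus comparison of the three groups for one metric/stratum cell."""

    metric: str
    procedure: str
    hand: str
    shapiro: dict            # group -> {"W": float, "p": float} or {"error": str}
    kw_H: float | None
    kw_df: int | None
    kw_p: float | None
    degenerate: bool = False
    note: str = ""
    dunn: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BatteryConfig:
    """Which metric columns to test and how."""

    metrics: tuple[str, ...] = ("duration_s", "cum_resultant_acc", "path_length_m")
    hands: tuple[str, ...] = HANDS
    procedures: tuple[str, ...] = PROCEDURES
    groups: tuple[str, ...] = GROUPS
    #: 'chi2' refers H to chi-squared(k-1); 'permutation' uses a Monte-Carlo
    #: permutation null (n_permutations draws, seeded)
    p_method: str = "chi2"
    n_permutations: int = 9999
    permutation_seed: int = 0
    include_dunn: bool = False


def summarize_groups(table: pd.DataFrame, metric: str,
                     strata: Sequence[str] = ("procedure", "hand"),
                     groups: Sequence[str] = GROUPS) -> list[GroupSummary]:
    """Per-(group x stratum) arithmetic mean and sample SD (n-1 denominator).

    Empty strata are omitted; a single-observation cell carries ``sd=None``.
    """
    if metric not in table.columns:
        raise KeyError(f"metric column {metric!r} not in table")
    out: list[GroupSummary] = []
    for keys, sub in table.groupby(list(strata), sort=True, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        stratum = dict(zip(strata, keys))
        for group in groups:
            vals = sub.loc[sub["group"] == group, metric].to_numpy(dtype=float)
            if vals.size == 0:
                continue
            out.append(GroupSummary(
                metric=metric,
                procedure=str(stratum.get("procedure", "pooled")),
                hand=str(stratum.get("hand", "pooled")),
                group=group,
                n=int(vals.size),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else None,
            ))
    return out


def shapiro_wilk(values: Sequence[float]) -> dict:
    """Shapiro-Wilk normality test; needs 3 <= n <= 5000 and a non-constant sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs at least 3 observations, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n = 5000")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all values identical; W is undefined")
    w, p = sps.shapiro(x)
    return {"W": float(w), "p": float(p)}


def _kw_statistic(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    """Tie-corrected Kruskal-Wallis H via mid-ranks (used for permutation p)."""
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    grand = (n_tot + 1) / 2
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + g.size]
        h += g.size * (r.mean() - grand) ** 2
        start += g.size
    h *= 12.0 / (n_tot * (n_tot + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n_tot**3 - n_tot)
    if tie == 0:
        raise DegenerateDataError("all observations identical; tie correction is zero")
    return h / tie, len(groups) - 1


def kruskal_wallis(groups: Sequence[Sequence[float]], *, p_method: str = "chi2",
                   n_permutations: int = 9999, seed: int = 0) -> dict:
    """Tie-corrected Kruskal-Wallis omnibus test across k groups.

    Returns ``{"H", "df", "p"}``; p comes from the chi-squared(k-1) reference
    by default, or from a seeded Monte-Carlo permutation null when
    ``p_method='permutation'``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group needs at least 1 observation")
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need at least 3 observations in total")
    h, df = _kw_statistic(arrs)
    if p_method == "chi2":
        p = float(sps.chi2.sf(h, df))
        # cross-check against the reference implementation on clean input
        h_ref, _ = sps.kruskal(*arrs)
        assert abs(h - h_ref) < 1e-8 * max(1.0, abs(h_ref)) or np.isnan(h_ref)
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(arrs)
        sizes = [a.size for a in arrs]
        exceed = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            h_perm, _ = _kw_statistic(parts)
            if h_perm >= h - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return {"H": float(h), "df": int(df), "p": float(p)}


def dunn_posthoc(groups: dict[str, Sequence[float]]) -> dict:
    """Dunn pairwise rank comparisons (two-sided z, unadjusted p).

    Pairwise z uses pooled mid-ranks with the standard tie correction; meant
    as a follow-up after a significant omnibus test.
    """
    names = list(groups)
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pooled = np.concatenate([arrs[k] for k in names])
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank, start = {}, 0
    for k in names:
        mean_rank[k] = ranks[start:start + arrs[k].size].mean()
        start += arrs[k].size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12 * (n_tot - 1))
    out = {}
    for a, b in itertools.combinations(names, 2):
        na, nb = arrs[a].size, arrs[b].size
        se = np.sqrt((n_tot * (n_tot + 1) / 12 - tie_term) * (1 / na + 1 / nb))
        z = (mean_rank[a] - mean_rank[b]) / se
        out[f"{a}|{b}"] = {"z": float(z), "p": float(2 * sps.norm.sf(abs(z)))}
    return out


def run_battery(table: pd.DataFrame, config: BatteryConfig | None = None
                ) -> tuple[list[TestResult], list[GroupSummary]]:
    """Summaries + Shapiro-Wilk + Kruskal-Wallis for every metric/procedure/hand cell.

    Cells with a degenerate group (constant values, too few observations) are
    flagged in the result, never fatal.  Deterministic given the table.
    """
    config = config or BatteryConfig()
    tests: list[TestResult] = []
    summaries: list[GroupSummary] = []
    for metric in config.metrics:
        summaries.extend(summarize_groups(table, metric, groups=config.groups))
        for procedure, hand in itertools.product(config.procedures, config.hands):
            cell = table[(table["procedure"] == procedure) & (table["hand"] == hand)]
            if cell.empty:
                continue
            samples = {g: cell.loc[cell["group"] == g, metric].to_numpy(dtype=float)
                       for g in config.groups}
            samples = {g: v for g, v in samples.items() if v.size > 0}
            shapiro: dict = {}
            for g, v in samples.items():
                try:
                    shapiro[g] = shapiro_wilk(v)
                except (ValueError, DegenerateDataError) as exc:
                    shapiro[g] = {"error": str(exc)}
            result = TestResult(metric=metric, procedure=procedure, hand=hand,
                                shapiro=shapiro, kw_H=None, kw_df=None, kw_p=None)
            try:
                kw = kruskal_wallis(
                    list(samples.values()), p_method=config.p_method,
                    n_permutations=config.n_permutations, seed=config.permutation_seed,
                )
                result.kw_H, result.kw_df, result.kw_p = kw["H"], kw["df"], kw["p"]
            except (ValueError, DegenerateDataError) as exc:
                result.degenerate = True
                result.note = str(exc)
            if config.include_dunn and result.kw_p is not None:
                result.dunn = dunn_posthoc(samples)
            tests.append(result)
    return tests, summaries


def summaries_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


def tests_frame(tests: Sequence[TestResult]) -> pd.DataFrame:
    rows = []
    for t in tests:
        row = {"metric": t.metric, "procedure": t.procedure, "hand": t.hand,
               "kw_H": t.kw_H, "kw_df": t.kw_df, "kw_p": t.kw_p,
               "degenerate": t.degenerate, "note": t.note}
        for g, res in t.shapiro.items():
            row[f"shapiro_W_{g}"] = res.get("W")
            row[f"shapiro_p_{g}"] = res.get("p")
        rows.append(row)
    return pd.DataFrame(rows)


def format_cell_table(summaries: Sequence[GroupSummary], tests: Sequence[TestResult],
                      metric: str) -> str:
    """Plain-text table for one metric: procedure rows, per-group DH/NDH columns,
    trailing omnibus p-value — the layout used in the study report."""
    summ = {(s.procedure, s.hand, s.group): s for s in summaries if s.metric == metric}
    pvals = {(t.procedure, t.hand): t.kw_p for t in tests if t.metric == metric}
    group_order = ("senior", "specialist", "resident")
    lines = [f"metric: {metric}"]
    header = f"{'procedure':<22}" + "".join(
        f"{g + ' ' + h:>16}" for g in group_order for h in HANDS) + f"{'p (DH)':>10}{'p (NDH)':>10}"
    lines.append(header)
    for proc in PROCEDURES:
        cells = []
        for g in group_order:
            for h in HANDS:
                s = summ.get((proc, h, g))
                cells.append(f"{s.mean:>16.1f}" if s else f"{'-':>16}")
        p_dh, p_ndh = pvals.get((proc, "DH")), pvals.get((proc, "NDH"))
        ptxt = "".join(
            f"{('<0.001' if p is not None and p < 0.001 else (f'{p:.3f}' if p is not None else '-')):>10}"
            for p in (p_dh, p_ndh))
        lines.append(f"{proc:<22}" + "".join(cells) + ptxt)
    return "\n".join(lines)


def write_report(tests: Sequence[TestResult], summaries: Sequence[GroupSummary],
                 outdir: str | Path, *, formatted_tables: bool = True) -> dict[str, Path]:
    """Write summaries CSV, tests CSV and a JSON bundle (plus optional text tables)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summaries": outdir / "summaries.csv",
        "tests": outdir / "tests.csv",
        "bundle": outdir / "stats_bundle.json",
    }
    summaries_frame(summaries).to_csv(paths["summaries"], index=False)
    tests_frame(tests).to_csv(paths["tests"], index=False)
    bundle = {
        "n_tests": len(tests),
        "multiple_testing_correction": "none",
        "tests": [t.to_dict() for t in tests],
        "summaries": [s.to_dict() for s in summaries],
    }
    paths["bundle"].write_text(json.dumps(bundle, indent=1))
    if formatted_tables:
        metrics = sorted({t.metric for t in tests})
        text = "\n\n".join(format_cell_table(summaries, tests, m) for m in metrics)
        paths["tables"] = outdir / "tables.txt"
        paths["tables"].write_text(text + "\n")
    return paths
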