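"""Cohort-level statistics and summary tables.

Treatment groups (e.g. control vs single antibiotic vs antibiotic cocktail)
are compared on per-individual quantities — category fractions or growth
scores — with one-way ANOVA followed by Tukey's honestly-significant-
difference post-hoc test. Both are computed from the standard formulas (the
studentized-range distribution comes from scipy), so results can be checked
against independent implementations to numerical precision; the unbalanced
case uses the Tukey–Kramer standard error. Significance stars follow the
usual 0.05 / 0.01 / 0.001 thresholds.
"""

from __future__ import annotations

import itertools
import json
import platform
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy
from scipy import stats

from .errors import ConfigError


@dataclass
class GroupedSamples:
    """Named groups of real-valued observations (one value per individual)."""

    groups: dict[str, np.ndarray]

    def __post_init__(self):
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ConfigError("ANOVA needs at least two groups")
        for name, values in self.groups.items():
            if len(values) < 2:
                raise ConfigError(f"group {name!r} has fewer than 2 values")

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.groups.values())


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def one_way_anova(g: GroupedSamples) -> AnovaResult:
    """Standard between/within sum-of-squares decomposition.

    Degenerate inputs are total: all values identical gives F = 0, p = 1;
    zero within-group variance with distinct means gives F = inf, p = 0.
    """
    values = np.concatenate(list(g.groups.values()))
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in g.groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in g.groups.values())
    df_b, df_w = g.k - 1, g.n_total - g.k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, 0.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, float(ss_between), 0.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, float(ss_between), float(ss_within))


def tukey_hsd(g: GroupedSamples) -> pd.DataFrame:
    """Tukey HSD pairwise table with studentized-range adjusted p-values.

    Columns: group_a, group_b, mean_diff (a − b), q, p_adj, stars. Unbalanced
    designs use the Tukey–Kramer standard error sqrt(MSE/2 · (1/nᵃ + 1/nᵇ)).
    """
    anova = one_way_anova(g)
    mse = anova.ss_within / anova.df_within if anova.df_within > 0 else 0.0
    rows = []
    for a, b in itertools.combinations(g.groups, 2):
        va, vb = g.groups[a], g.groups[b]
        diff = float(va.mean() - vb.mean())
        if mse == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
            p = 1.0 if diff == 0.0 else 0.0
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, g.k, anova.df_within))
        p = min(max(p, 0.0), 1.0)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": diff,
                "q": float(q),
                "p_adj": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaTukeyResult:
    anova: AnovaResult
    pairwise: pd.DataFrame


def anova_tukey(g: GroupedSamples) -> AnovaTukeyResult:
    return AnovaTukeyResult(one_way_anova(g), tukey_hsd(g))


def boxplot_summary(values: Sequence[float]) -> dict[str, float]:
    """Median / mean / quartile summary matching a standard boxplot."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "n": int(len(v)),
        "median": float(med),
        "mean": float(v.mean()),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def report(
    out_dir,
    fractions: pd.DataFrame,
    grid_table: pd.DataFrame | None = None,
    metadata: Mapping | None = None,
) -> dict[str, Path]:
    """Write the cohort summary bundle.

    ``fractions`` holds one row per individual with a ``dataset`` column and
    one column per category group. Outputs: ``group_summary.tsv`` (boxplot
    summaries per dataset × group), ``tukey.tsv`` (pairwise dataset
    comparisons per group with stars), ``grid_heatmap.csv``, and
    ``run_metadata.json``. An empty input yields a valid, empty report with
    a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    group_cols = [c for c in fractions.columns if c not in ("individual_id", "dataset")]
    summaries, tukey_rows = [], []
    if fractions.empty or "dataset" not in fractions.columns:
        warnings.warn("empty classification set: writing an empty report", stacklevel=2)
    else:
        for group in group_cols:
            by_dataset = {
                ds: sub[group].to_numpy() for ds, sub in fractions.groupby("dataset")
            }
            for ds, vals in by_dataset.items():
                summaries.append({"metric": group, "dataset": ds, **boxplot_summary(vals)})
            usable = {ds: v for ds, v in by_dataset.items() if len(v) >= 2}
            if len(usable) >= 2:
                try:
                    table = tukey_hsd(GroupedSamples(usable))
                except ConfigError:
                    continue
                table.insert(0, "metric", group)
                tukey_rows.append(table)

    paths["group_summary"] = out / "group_summary.tsv"
    pd.DataFrame(
        summaries,
        columns=["metric", "dataset", "n", "median", "mean", "q1", "q3", "iqr", "min", "max"],
    ).to_csv(paths["group_summary"], sep="\t", index=False)

    paths["tukey"] = out / "tukey.tsv"
    tukey = (
        pd.concat(tukey_rows, ignore_index=True)
        if tukey_rows
        else pd.DataFrame(
            columns=["metric", "group_a", "group_b", "mean_diff", "q", "p_adj", "stars"]
        )
    )
    tukey.to_csv(paths["tukey"], sep="\t", index=False)

    if grid_table is not None:
        paths["grid_heatmap"] = out / "grid_heatmap.csv"
        grid_table.to_csv(paths["grid_heatmap"])

    paths["metadata"] = out / "run_metadata.json"
    meta = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        **(dict(metadata) if metadata else {}),
    }
    paths["metadata"].write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return paths
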