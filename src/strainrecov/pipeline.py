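"""End-to-end orchestration: simulate → wss → classify → grid → tree → report.

Stages exchange plain TSV files so each one can be rerun and inspected in
isolation; every stage writes through a temp-file-then-rename so a failure in
stage k leaves the outputs of earlier stages intact. A single integer seed
drives all randomness and is recorded in the run metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import marker_tree, stats_report
from .errors import ConfigError
from .growth_rate import GridSpec, estimate_grid, estimate_sample_heterogeneity, grid_matrix
from .recovery_patterns import (
    FOUR_POINT_LAYOUT,
    THREE_POINT_LAYOUT,
    RecoveryCategory,
    RelatednessMatrix,
    TimelineLayout,
    classify_timeline,
    cohort_category_fractions,
)
from .synthetic_cohort import NoiseModel, Reference, build_cohort, plan_dataset
from .variant_io import read_cutoffs, read_depth, read_manifest, read_vcf, validate_manifest
from .wss_core import RelatednessCall, WindowSpec, all_pairs

logger = logging.getLogger(__name__)

LAYOUTS = {"three_point": THREE_POINT_LAYOUT, "four_point": FOUR_POINT_LAYOUT}


@dataclass
class DatasetPlan:
    n_individuals: int = 3
    n_species: int = 4
    category_probs: dict[str, float] = field(
        default_factory=lambda: {"PERSISTENT": 0.7, "TRANSIENT_RETURN": 0.2, "NEW_PERMANENT": 0.1}
    )


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    layout: str = "four_point"
    datasets: dict[str, DatasetPlan] = field(
        default_factory=lambda: {
            "control": DatasetPlan(
                category_probs={"PERSISTENT": 0.85, "TRANSIENT_RETURN": 0.1, "NEW_PERMANENT": 0.05}
            ),
            "single": DatasetPlan(
                category_probs={
                    "PERSISTENT": 0.5,
                    "TRANSIENT_RETURN": 0.25,
                    "NEW_FROM_TREATMENT_END": 0.1,
                    "NEW_PERMANENT": 0.15,
                }
            ),
            "multiple": DatasetPlan(
                category_probs={
                    "PERSISTENT": 0.15,
                    "TRANSIENT_RETURN": 0.25,
                    "NEW_FROM_TREATMENT_END": 0.1,
                    "NEW_LATE": 0.1,
                    "NEW_PERMANENT": 0.4,
                }
            ),
        }
    )
    genome_length: int = 20_000
    n_snv: int = 120
    bin_size: int = 500
    cutoff: float = 0.8
    cutoffs_path: str | None = None  # overrides `cutoff` when given
    window: WindowSpec = field(default_factory=WindowSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    grid: GridSpec = field(default_factory=GridSpec)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        datasets = {
            name: DatasetPlan(**spec) for name, spec in raw.pop("datasets", {}).items()
        }
        window = WindowSpec(**raw.pop("window", {}))
        noise = NoiseModel(**raw.pop("noise", {}))
        grid = GridSpec(**raw.pop("grid", {}))
        out_dir = Path(raw.pop("out_dir"))
        cfg = cls(out_dir=out_dir, window=window, noise=noise, grid=grid, **raw)
        if datasets:
            cfg.datasets = datasets
        return cfg

    def validate(self) -> list[str]:
        """Collect every configuration problem rather than stopping at the first."""
        problems: list[str] = []
        if self.layout not in LAYOUTS:
            problems.append(f"unknown layout {self.layout!r}; choose from {sorted(LAYOUTS)}")
        if not self.datasets:
            problems.append("no datasets configured")
        for name, ds in self.datasets.items():
            if ds.n_individuals < 1 or ds.n_species < 1:
                problems.append(f"dataset {name!r}: n_individuals and n_species must be >= 1")
            for cat in ds.category_probs:
                try:
                    RecoveryCategory(cat)
                except ValueError:
                    problems.append(f"dataset {name!r}: unknown category {cat!r}")
        if self.cutoffs_path is not None and not Path(self.cutoffs_path).exists():
            problems.append(f"cut-off table not found: {self.cutoffs_path}")
        elif self.cutoffs_path is None and not 0.0 < self.cutoff < 1.0:
            problems.append(f"cutoff must lie in (0, 1); got {self.cutoff}")
        if self.genome_length < self.window.window_length:
            problems.append("genome_length smaller than one window")
        if self.n_snv > self.genome_length // 6:
            problems.append("n_snv too large for disjoint per-strain position pools")
        return problems


def _atomic_write_df(df: pd.DataFrame, path: Path, **to_csv_kwargs) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        df.to_csv(tmp, **{"sep": "\t", "index": False, **to_csv_kwargs})
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
    return path


# ---------------------------------------------------------------------------
# file-level stages


def load_timelines(cohort_dir, bin_size: int, layout: TimelineLayout):
    """Group a cohort directory's manifest into per-(individual, species) samples."""
    cohort_dir = Path(cohort_dir)
    manifest = read_manifest(cohort_dir / "manifest.tsv")
    report = validate_manifest(manifest, cohort_dir)
    if report["missing_files"]:
        raise ConfigError(f"manifest references missing files: {report['missing_files'][:5]}")
    label_order = {lbl: i for i, lbl in enumerate(layout.labels)}
    for (ind, sp), rows in manifest.groupby(["individual_id", "species_id"], sort=True):
        rows = rows.sort_values("timepoint_label", key=lambda s: s.map(label_order))
        samples = []
        for _, row in rows.iterrows():
            profile = read_vcf(cohort_dir / row["vcf_path"], species_id=sp)
            cov = read_depth(
                cohort_dir / row["depth_path"],
                bin_size,
                genome_length=profile.genome_length,
                sample_id=profile.sample_id,
            )
            samples.append((profile, cov))
        yield ind, sp, samples


def stage_wss(
    cohort_dir, window: WindowSpec, layout: TimelineLayout, out_path, bin_size: int = 500
) -> Path:
    """Score every sample pair of every timeline; one TSV row per pair."""
    cohort_dir = Path(cohort_dir)
    cutoffs = read_cutoffs(cohort_dir / "cutoffs.tsv")
    rows = []
    for ind, sp, samples in load_timelines(cohort_dir, bin_size, layout):
        pw = all_pairs(samples, window, cutoffs)
        for (i, j), res in pw.results.items():
            rows.append(
                {
                    "individual_id": ind,
                    "species_id": sp,
                    "label_a": layout.labels[i],
                    "label_b": layout.labels[j],
                    "score": res.score,
                    "coverage_a": res.coverage_a,
                    "coverage_b": res.coverage_b,
                    "n_windows_retained": res.n_windows_retained,
                    "call": res.call.value,
                }
            )
    logger.info("wss: scored %d pairs", len(rows))
    return _atomic_write_df(pd.DataFrame(rows), Path(out_path))


def calls_matrix_from_rows(rows: pd.DataFrame, layout: TimelineLayout) -> np.ndarray:
    t = len(layout)
    idx = {lbl: i for i, lbl in enumerate(layout.labels)}
    calls = np.full((t, t), None, dtype=object)
    for _, row in rows.iterrows():
        i, j = idx[row["label_a"]], idx[row["label_b"]]
        calls[i, j] = calls[j, i] = RelatednessCall(row["call"])
    return calls


def stage_classify(wss_path, layout: TimelineLayout, out_dir) -> dict[str, Path]:
    """Classify every timeline; write categories, per-individual fractions, color grid."""
    out_dir = Path(out_dir)
    wss = pd.read_csv(wss_path, sep="\t")
    records = []
    for (ind, sp), rows in wss.groupby(["individual_id", "species_id"], sort=True):
        calls = calls_matrix_from_rows(rows, layout)
        cls = classify_timeline(RelatednessMatrix(ind, sp, calls, layout))
        records.append(
            {
                "individual_id": ind,
                "species_id": sp,
                "category": cls.category.value,
                "color": cls.category.color,
                "reason": cls.reason,
            }
        )
    categories = pd.DataFrame(records)
    paths = {
        "categories": _atomic_write_df(categories, out_dir / "categories.tsv"),
        "fractions": _atomic_write_df(
            cohort_category_fractions(categories), out_dir / "fractions.tsv"
        ),
    }
    grid = (
        categories.pivot(index="species_id", columns="individual_id", values="color")
        if not categories.empty
        else pd.DataFrame()
    )
    grid.to_csv(out_dir / "color_grid.csv")
    paths["color_grid"] = out_dir / "color_grid.csv"
    logger.info("classify: %d timelines", len(records))
    return paths


def stage_grid(cohort_dir, grid_spec: GridSpec, layout: TimelineLayout, bin_size: int, out_path) -> Path:
    """Growth-score every (sample, species); one TSV row per sample."""
    rows, entries = [], []
    for ind, sp, samples in load_timelines(Path(cohort_dir), bin_size, layout):
        for label, (profile, cov) in zip(layout.labels, samples):
            het = estimate_sample_heterogeneity(profile)
            res = estimate_grid(cov, het, grid_spec)
            entries.append((ind, label, res))
            rows.append(
                {
                    "individual_id": ind,
                    "species_id": sp,
                    "timepoint_label": label,
                    "grid_score": res.score,
                    "mean_coverage": res.mean_coverage,
                    "heterogeneity": res.heterogeneity,
                    "retained": res.retained,
                    "slow_growing": res.slow_growing,
                }
            )
    out = _atomic_write_df(pd.DataFrame(rows), Path(out_path))
    heat = grid_matrix(entries)
    heat.to_csv(Path(out_path).with_name("grid_heatmap.csv"))
    logger.info("grid: %d estimates", len(rows))
    return out


def stage_tree(
    cohort_dir, layout: TimelineLayout, window: WindowSpec, out_dir, bin_size: int = 500
) -> Path:
    """NJ marker trees per timeline (>= 3 present samples) plus WSS concordance."""
    from Bio import SeqIO

    cohort_dir, out_dir = Path(cohort_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    references = {
        rec.id: Reference(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(cohort_dir / "references.fasta"), "fasta")
    }
    cutoffs = read_cutoffs(cohort_dir / "cutoffs.tsv")
    rows = []
    newicks: list[str] = []
    for ind, sp, samples in load_timelines(cohort_dir, bin_size, layout):
        present = [(p, c) for p, c in samples if c.mean_depth > 0]
        if len(present) < 3:
            continue
        alignment = marker_tree.build_alignment([p for p, _ in present], references[sp])
        ids, dmat = marker_tree.distance_matrix(alignment)
        if np.all(dmat == 0):
            # identical markers throughout: trivially concordant, no tree to draw
            rows.append({"individual_id": ind, "species_id": sp, "concordance": 1.0})
            continue
        tree = marker_tree.nj_tree(dmat, ids)
        pw = all_pairs(present, window, cutoffs)
        try:
            conc = marker_tree.tree_wss_concordance(
                tree, pw.calls(), [p.sample_id for p, _ in present]
            )
        except ConfigError:
            conc = float("nan")
        newicks.append(tree.to_newick())
        rows.append({"individual_id": ind, "species_id": sp, "concordance": conc})
    (out_dir / "trees.nwk").write_text("\n".join(newicks) + ("\n" if newicks else ""))
    _atomic_write_df(pd.DataFrame(rows), out_dir / "concordance.tsv")
    logger.info("tree: %d timelines with trees/concordance", len(rows))
    return out_dir / "concordance.tsv"


# ---------------------------------------------------------------------------
# run_all


@dataclass
class RunSummary:
    out_dir: Path
    paths: dict[str, Path]
    truth_vs_recovered: pd.DataFrame
    recovery_rate: float


def run_all(config: RunConfig) -> RunSummary:
    """Execute every stage for every configured dataset and write the report."""
    problems = config.validate()
    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("strainrecov").addHandler(handler)
    layout = LAYOUTS[config.layout]
    paths: dict[str, Path] = {}
    all_fractions, all_truth, all_categories = [], [], []
    try:
        rng = np.random.default_rng(config.seed)
        for name, ds in config.datasets.items():
            ds_dir = out / name
            plan = plan_dataset(
                ds.n_individuals,
                ds.n_species,
                {RecoveryCategory(c): p for c, p in ds.category_probs.items()},
                rng,
                individual_prefix=f"{name}_",
            )
            build_cohort(
                plan,
                layout,
                noise=config.noise,
                seed=int(rng.integers(2**31)),
                genome_length=config.genome_length,
                n_snv=config.n_snv,
                bin_size=config.bin_size,
                cutoff=config.cutoff,
                out_dir=ds_dir,
            )
            paths[f"{name}/manifest"] = ds_dir / "manifest.tsv"
            paths[f"{name}/wss"] = stage_wss(
                ds_dir, config.window, layout, ds_dir / "wss.tsv", config.bin_size
            )
            cls_paths = stage_classify(ds_dir / "wss.tsv", layout, ds_dir)
            paths[f"{name}/categories"] = cls_paths["categories"]
            paths[f"{name}/grid"] = stage_grid(
                ds_dir, config.grid, layout, config.bin_size, ds_dir / "grid.tsv"
            )
            paths[f"{name}/concordance"] = stage_tree(
                ds_dir, layout, config.window, ds_dir / "tree", config.bin_size
            )
            frac = pd.read_csv(cls_paths["fractions"], sep="\t")
            frac.insert(0, "dataset", name)
            all_fractions.append(frac)
            truth = pd.read_csv(ds_dir / "truth.tsv", sep="\t")
            truth.insert(0, "dataset", name)
            all_truth.append(truth)
            cats = pd.read_csv(cls_paths["categories"], sep="\t")
            cats.insert(0, "dataset", name)
            all_categories.append(cats)

        fractions = pd.concat(all_fractions, ignore_index=True)
        grid_heat = pd.read_csv(
            out / list(config.datasets)[0] / "grid_heatmap.csv", index_col=0
        )
        report_paths = stats_report.report(
            out / "report",
            fractions,
            grid_heat,
            metadata={
                "seed": config.seed,
                "layout": config.layout,
                "window": dataclasses.asdict(config.window),
                "noise": dataclasses.asdict(config.noise),
                "cutoff": config.cutoff,
            },
        )
        paths.update({f"report/{k}": v for k, v in report_paths.items()})

        truth = pd.concat(all_truth, ignore_index=True)
        recovered = pd.concat(all_categories, ignore_index=True)
        merged = truth.merge(
            recovered[["dataset", "individual_id", "species_id", "category"]],
            on=["dataset", "individual_id", "species_id"],
            suffixes=("_planted", "_recovered"),
        )
        merged["match"] = merged["category_planted"] == merged["category_recovered"]
        _atomic_write_df(merged, out / "truth_vs_recovered.tsv")
        paths["truth_vs_recovered"] = out / "truth_vs_recovered.tsv"
        rate = float(merged["match"].mean()) if len(merged) else float("nan")
        logger.info("run_all: %d timelines, recovery rate %.3f", len(merged), rate)
        return RunSummary(out, paths, merged, rate)
    finally:
        logging.getLogger("strainrecov").removeHandler(handler)
        handler.close()
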