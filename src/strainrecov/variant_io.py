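"""Readers, writers, and in-memory containers for the formats the pipeline exchanges.

The pipeline starts from per-sample variant calls (VCF v4.2) and binned depth
tracks (BedGraph) against a species reference; this module normalizes both
into light dataclass containers used everywhere downstream.

Coordinate convention: internal positions are 0-based half-open; VCF POS is
converted on ingestion and restored on writing. Indels are skipped with a
logged count — the similarity method is defined on single-nucleotide variants
only. Multi-allelic records are split per alternate allele and then collapsed
to the allele with the highest allele depth, so that each locus carries a
single call (profiles keep strictly increasing positions).
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class SnvCall:
    """A single-nucleotide variant call at one locus of one sample.

    ``alt_fraction`` is the fraction of reads supporting the alternate
    allele; intermediate values indicate within-sample strain mixture
    (heterogeneity).
    """

    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    depth: int
    alt_fraction: float

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) at {self.position}")
        if self.depth < 0:
            raise ValueError(f"negative depth at {self.position}")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError(f"alt_fraction {self.alt_fraction} outside [0, 1]")

    @property
    def minor_fraction(self) -> float:
        """Minor-allele fraction: min(alt, ref) read fraction at this locus."""
        return min(self.alt_fraction, 1.0 - self.alt_fraction)


@dataclass
class SampleVariantProfile:
    """All SNV calls of one sample against one species reference."""

    sample_id: str
    species_id: str
    calls: list[SnvCall]
    genome_length: int

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        pos = [c.position for c in self.calls]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("call positions must be strictly increasing")
        if pos and (pos[0] < 0 or pos[-1] >= self.genome_length):
            raise ValueError("call position outside genome")

    def __len__(self) -> int:
        return len(self.calls)

    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.calls], dtype=np.int64)

    def encoded(self) -> np.ndarray:
        """Encode each call as ``position * 4 + alt_base_index`` (int64).

        Two samples share an SNV iff their encodings collide, which makes
        set arithmetic on calls a plain integer-array operation.
        """
        if not self.calls:
            return np.empty(0, dtype=np.int64)
        return np.array(
            [c.position * 4 + _BASE_INDEX[c.alt_allele] for c in self.calls],
            dtype=np.int64,
        )

    def with_calls(self, calls: list[SnvCall]) -> "SampleVariantProfile":
        return SampleVariantProfile(self.sample_id, self.species_id, calls, self.genome_length)


@dataclass
class CoverageProfile:
    """Mean read depth per fixed-width bin along one genome."""

    sample_id: str
    species_id: str
    bin_size: int
    depths: np.ndarray
    genome_length: int

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.depths = np.asarray(self.depths, dtype=float)
        n_expected = math.ceil(self.genome_length / self.bin_size)
        if len(self.depths) != n_expected:
            raise ValueError(
                f"expected {n_expected} bins for genome_length={self.genome_length}, "
                f"bin_size={self.bin_size}; got {len(self.depths)}"
            )
        if np.any(self.depths < 0):
            raise ValueError("negative depth")

    @property
    def n_bins(self) -> int:
        return len(self.depths)

    def bin_lengths(self) -> np.ndarray:
        lengths = np.full(self.n_bins, self.bin_size, dtype=np.int64)
        rem = self.genome_length - (self.n_bins - 1) * self.bin_size
        lengths[-1] = rem
        return lengths

    @property
    def mean_depth(self) -> float:
        """Length-weighted mean depth over the whole genome."""
        return float(np.sum(self.depths * self.bin_lengths()) / self.genome_length)

    def per_base(self) -> np.ndarray:
        """Expand to a per-base depth vector of length ``genome_length``."""
        return np.repeat(self.depths, self.bin_lengths())

    def depth_at(self, positions: np.ndarray) -> np.ndarray:
        """Depth of the bin containing each position."""
        return self.depths[np.asarray(positions, dtype=np.int64) // self.bin_size]

    def low_depth_fraction_per_window(self, window_length: int, threshold: float) -> np.ndarray:
        """Per window, the fraction of bases whose depth is below ``threshold``."""
        low = (self.per_base() < threshold).astype(np.int64)
        starts = np.arange(0, self.genome_length, window_length)
        sums = np.add.reduceat(low, starts)
        counts = np.diff(np.append(starts, self.genome_length))
        return sums / counts


@dataclass
class CutoffTable:
    """Species-specific WSS relatedness cut-offs (configuration, not computed)."""

    cutoffs: dict[str, float]

    def __post_init__(self):
        for sp, c in self.cutoffs.items():
            if not 0.0 < c < 1.0:
                raise ConfigError(f"cut-off for {sp} must lie strictly in (0, 1); got {c}")

    def cutoff_for(self, species_id: str) -> float:
        try:
            return self.cutoffs[species_id]
        except KeyError:
            raise ConfigError(f"no WSS cut-off configured for species {species_id!r}") from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.cutoffs

    def __len__(self) -> int:
        return len(self.cutoffs)


# ---------------------------------------------------------------------------
# VCF


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=strainrecov
##contig=<ID={species},length={length}>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(profile: SampleVariantProfile, path: str | os.PathLike) -> Path:
    """Write one sample's profile as an uncompressed single-sample VCF v4.2."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            _VCF_HEADER.format(
                species=profile.species_id,
                length=profile.genome_length,
                sample=profile.sample_id,
            )
        )
        for c in profile.calls:
            alt_reads = int(round(c.alt_fraction * c.depth))
            ref_reads = c.depth - alt_reads
            gt = "1/1" if c.alt_fraction > 0.8 else "0/1"
            fh.write(
                f"{profile.species_id}\t{c.position + 1}\t.\t{c.ref_allele}\t"
                f"{c.alt_allele}\t.\tPASS\tDP={c.depth}\tGT:DP:AD\t"
                f"{gt}:{c.depth}:{ref_reads},{alt_reads}\n"
            )
    return path


def _prescan_vcf(path: Path) -> None:
    """Cheap line-level validation so parse errors can name a line number."""
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not line.strip():
                continue
            if not saw_header:
                raise FormatError("record before #CHROM header line", path, lineno)
            n_fields = line.count("\t") + 1
            if n_fields < 8:
                raise FormatError(
                    f"VCF record has {n_fields} fields; at least 8 required", path, lineno
                )


def read_vcf(
    path: str | os.PathLike,
    species_id: str | None = None,
    genome_length: int | None = None,
) -> SampleVariantProfile:
    """Read a single-sample VCF into a :class:`SampleVariantProfile`.

    1-based POS becomes 0-based; indel records are skipped (counted in the
    log); multi-allelic records are split and collapsed to the top-AD allele;
    records carrying no depth information get depth 0.
    """
    import cyvcf2

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_vcf(path)
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # htslib-level failure
        raise FormatError(f"unparseable VCF: {exc}", path) from exc

    sample_id = vcf.samples[0] if vcf.samples else path.stem
    chrom_seen: str | None = None
    n_indels = 0
    n_multi_dropped = 0
    by_pos: dict[int, SnvCall] = {}
    for var in vcf:
        if species_id is not None and var.CHROM != species_id:
            continue
        chrom_seen = chrom_seen or var.CHROM
        if len(var.REF) != 1:
            n_indels += 1
            continue
        depth = 0
        try:
            dp = var.format("DP")
            if dp is not None:
                depth = max(int(dp[0][0]), 0)
        except KeyError:
            pass
        if depth == 0:
            info_dp = var.INFO.get("DP")
            if info_dp is not None:
                depth = max(int(info_dp), 0)
        ad = None
        try:
            ad = var.format("AD")
        except KeyError:
            pass
        best: SnvCall | None = None
        best_ad = -1.0
        for k, alt in enumerate(var.ALT):
            if len(alt) != 1 or alt not in _BASE_INDEX:
                n_indels += 1
                continue
            if ad is not None and depth > 0 and k + 1 < len(ad[0]):
                alt_reads = float(max(ad[0][k + 1], 0))
                frac = min(alt_reads / depth, 1.0)
            else:
                alt_reads = float(depth)
                frac = 1.0 if depth > 0 else 0.0
            call = SnvCall(var.POS - 1, var.REF, alt, depth, frac)
            if alt_reads > best_ad:
                best, best_ad = call, alt_reads
            else:
                n_multi_dropped += 1
        if best is None:
            continue
        if best.position in by_pos:
            n_multi_dropped += 1
        else:
            by_pos[best.position] = best

    if genome_length is None:
        lengths = dict(zip(vcf.seqnames, vcf.seqlens or []))
        key = species_id or chrom_seen or (vcf.seqnames[0] if vcf.seqnames else None)
        if key is None or key not in lengths:
            raise FormatError("genome length missing from VCF header; pass genome_length", path)
        genome_length = lengths[key]
    if n_indels or n_multi_dropped:
        logger.info(
            "%s: skipped %d indel allele(s), collapsed %d extra allele(s)",
            path.name,
            n_indels,
            n_multi_dropped,
        )
    calls = [by_pos[p] for p in sorted(by_pos)]
    return SampleVariantProfile(
        sample_id, species_id or chrom_seen or path.stem, calls, genome_length
    )


# ---------------------------------------------------------------------------
# BedGraph depth tracks


def write_bedgraph(cov: CoverageProfile, path: str | os.PathLike) -> Path:
    """Write a binned coverage profile as BedGraph (runs of equal depth merged)."""
    path = Path(path)
    starts = np.arange(cov.n_bins) * cov.bin_size
    ends = np.minimum(starts + cov.bin_size, cov.genome_length)
    with open(path, "w") as fh:
        run_start, run_depth = 0, cov.depths[0]
        for i in range(1, cov.n_bins):
            if cov.depths[i] != run_depth:
                fh.write(f"{cov.species_id}\t{starts[run_start]}\t{ends[i - 1]}\t{run_depth:g}\n")
                run_start, run_depth = i, cov.depths[i]
        fh.write(f"{cov.species_id}\t{starts[run_start]}\t{ends[-1]}\t{run_depth:g}\n")
    return path


def read_depth(
    path: str | os.PathLike,
    bin_size: int,
    genome_length: int | None = None,
    sample_id: str | None = None,
) -> CoverageProfile:
    """Aggregate a sorted, non-overlapping BedGraph into fixed-width bins.

    Interval depths are length-weighted into bins; uncovered bases count as
    depth 0. Overlapping or unsorted intervals raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "depth"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": float},
        )
    except Exception as exc:
        raise FormatError(f"unparseable BedGraph: {exc}", path) from exc
    if df.empty:
        raise FormatError("empty BedGraph", path)
    if df["chrom"].nunique() != 1:
        raise FormatError("BedGraph must describe a single reference sequence", path)
    starts, ends = df["start"].to_numpy(), df["end"].to_numpy()
    if np.any(ends <= starts):
        bad = int(np.argmax(ends <= starts))
        raise FormatError("interval end <= start", path, bad + 1)
    if np.any(starts[1:] < ends[:-1]):
        bad = int(np.argmax(starts[1:] < ends[:-1])) + 1
        raise FormatError("overlapping or unsorted intervals", path, bad + 1)
    if genome_length is None:
        genome_length = int(ends[-1])
    n_bins = math.ceil(genome_length / bin_size)
    mass = np.zeros(n_bins)
    for s, e, d in zip(starts, ends, df["depth"].to_numpy()):
        e = min(int(e), genome_length)
        b = int(s) // bin_size
        while s < e:
            bin_end = min((b + 1) * bin_size, genome_length)
            span = min(e, bin_end) - s
            mass[b] += d * span
            s += span
            b += 1
    lengths = np.full(n_bins, bin_size, dtype=float)
    lengths[-1] = genome_length - (n_bins - 1) * bin_size
    return CoverageProfile(
        sample_id or path.stem, str(df["chrom"].iloc[0]), bin_size, mass / lengths, genome_length
    )


# ---------------------------------------------------------------------------
# TSV tables: cut-offs, manifest


def write_cutoffs(table: CutoffTable, path: str | os.PathLike) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"species_id": list(table.cutoffs), "cutoff": list(table.cutoffs.values())}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_cutoffs(path: str | os.PathLike) -> CutoffTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("species_id", "cutoff"):
        if col not in df.columns:
            raise FormatError(f"cut-off table missing column {col!r}", path)
    dup = df["species_id"][df["species_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate species rows: {sorted(set(dup))}", path)
    try:
        return CutoffTable(dict(zip(df["species_id"], df["cutoff"].astype(float))))
    except ConfigError as exc:
        raise FormatError(str(exc), path) from exc


MANIFEST_COLUMNS = [
    "individual_id",
    "species_id",
    "timepoint_label",
    "role",
    "vcf_path",
    "depth_path",
]


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}", path)
    return df


def validate_manifest(
    manifest: pd.DataFrame,
    base_dir: str | os.PathLike = ".",
    cutoffs: CutoffTable | None = None,
) -> dict[str, list[str]]:
    """Check that every referenced file exists and every species has a cut-off.

    Returns a report dict with ``missing_files`` and ``missing_cutoffs``
    lists; both empty means the manifest validates.
    """
    base = Path(base_dir)
    missing_files: list[str] = []
    for col in ("vcf_path", "depth_path"):
        for p in manifest[col]:
            if not (base / p).exists():
                missing_files.append(str(p))
    missing_cutoffs: list[str] = []
    if cutoffs is not None:
        missing_cutoffs = sorted(
            sp for sp in manifest["species_id"].unique() if sp not in cutoffs
        )
    return {"missing_files": missing_files, "missing_cutoffs": missing_cutoffs}


def merge_profiles(profiles: Sequence[SampleVariantProfile]) -> pd.DataFrame:
    """Multi-sample SNV view: one row per (position, alt), one column per sample.

    Cells hold the sample's alt-allele fraction, NaN where the sample carries
    no call for that allele.
    """
    rows: dict[tuple[int, str, str], dict[str, float]] = {}
    for prof in profiles:
        for c in prof.calls:
            rows.setdefault((c.position, c.ref_allele, c.alt_allele), {})[
                prof.sample_id
            ] = c.alt_fraction
    index = pd.MultiIndex.from_tuples(sorted(rows), names=["position", "ref", "alt"])
    df = pd.DataFrame(
        [rows[k] for k in sorted(rows)],
        index=index,
        columns=[p.sample_id for p in profiles],
    )
    return df
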