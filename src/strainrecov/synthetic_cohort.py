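"""Ground-truth cohort simulator: references, strains, timelines, and noise.

Simulation happens at the variant + depth level — the level at which the
analysis itself operates — not at the read level. A species is a random
reference genome; a strain is a set of SNVs against it; an individual's
timeline assigns a strain (or absence) to each timepoint according to a
planted recovery category. Each timeline is then realized as per-timepoint
variant profiles and binned coverage tracks under a noise model:

* per-bin depth follows a smooth replication profile that decays
  log-linearly from the replication origin (coordinate 0) to the terminus
  (half the genome, circular), with peak/trough ratio ``ori_ter_ratio``,
  overdispersed negative-binomially around the expectation;
* each true SNV is independently dropped with ``snv_dropout_rate`` and its
  observed allele fraction is binomially resampled at the local depth;
* spurious SNVs appear at ``false_snv_rate`` per base;
* a sample may carry a two-strain mixture: a contaminating strain at
  fraction ``mixture_fraction`` shifts allele fractions at the loci where
  the two strains differ (at most two strains per sample);
* ABSENT timepoints emit zero-depth tracks and no calls.

Setting ``depth_dispersion`` to 0 switches every stochastic realization
step (depth, allele counts) to its expectation, which makes zero-noise
cohorts byte-reproducible and lets closed-loop tests demand exact recovery
of the planted categories.

Strains of one (individual, species) pool are drawn on disjoint position
sets, so distinct strains share no SNV and their planted pairwise similarity
is exactly zero — the idealization of strains differing at private sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .recovery_patterns import (
    RecoveryCategory,
    TimelineLayout,
    TimepointRole,
)
from .variant_io import (
    BASES,
    CoverageProfile,
    CutoffTable,
    SampleVariantProfile,
    SnvCall,
    write_bedgraph,
    write_cutoffs,
    write_vcf,
)
from .wss_core import RelatednessCall

_BASE_ARRAY = np.array(list(BASES))


# ---------------------------------------------------------------------------
# references and strains


@dataclass(frozen=True)
class ReferenceSpec:
    species_id: str
    genome_length: int
    seed: int

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")


@dataclass(frozen=True)
class Reference:
    species_id: str
    sequence: str

    @property
    def genome_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class StrainGenotype:
    """A within-species genotype: the set of (position, alt allele) SNVs."""

    strain_id: str
    species_id: str
    snvs: frozenset[tuple[int, str]]

    def positions(self) -> np.ndarray:
        return np.array(sorted(p for p, _ in self.snvs), dtype=np.int64)


def generate_reference(spec: ReferenceSpec) -> Reference:
    """Draw a uniform-random genome sequence; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    seq = rng.choice(_BASE_ARRAY, size=spec.genome_length)
    return Reference(spec.species_id, "".join(seq))


def write_reference_fasta(references: Sequence[Reference], path) -> Path:
    """Write references as FASTA plus a sibling ``.lengths.tsv`` table."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    path = Path(path)
    records = [
        SeqRecord(Seq(r.sequence), id=r.species_id, description="") for r in references
    ]
    seqio_write(records, str(path), "fasta")
    lengths = pd.DataFrame(
        {"species_id": [r.species_id for r in references],
         "genome_length": [r.genome_length for r in references]}
    )
    lengths.to_csv(path.with_suffix(".lengths.tsv"), sep="\t", index=False)
    return path


def generate_strain(
    reference: Reference,
    n_snv: int,
    seed: int | np.random.Generator,
    strain_id: str = "s0",
    position_pool: np.ndarray | None = None,
) -> StrainGenotype:
    """Plant ``n_snv`` SNVs at distinct positions, each alt differing from ref.

    ``position_pool`` restricts the candidate positions, which lets a caller
    hand disjoint pools to different strains and so guarantee zero shared
    SNVs between them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.arange(reference.genome_length) if position_pool is None else np.asarray(position_pool)
    if n_snv > len(pool):
        raise ConfigError(f"n_snv={n_snv} exceeds available positions ({len(pool)})")
    positions = rng.choice(pool, size=n_snv, replace=False)
    snvs = set()
    for p in positions:
        ref_base = reference.sequence[int(p)]
        alts = [b for b in BASES if b != ref_base]
        snvs.add((int(p), alts[rng.integers(3)]))
    return StrainGenotype(strain_id, reference.species_id, frozenset(snvs))


# ---------------------------------------------------------------------------
# noise and scenarios


@dataclass(frozen=True)
class NoiseModel:
    """Sequencing-noise settings shared by every realized sample.

    ``mean_depth`` is the genome-wide mean coverage (reads per base);
    ``depth_dispersion`` d gives per-bin read counts variance m + d·m²
    (0 switches to deterministic expectations everywhere);
    ``ori_ter_ratio`` is the planted replication peak/trough coverage ratio.
    """

    mean_depth: float = 30.0
    depth_dispersion: float = 0.02
    snv_dropout_rate: float = 0.02
    false_snv_rate: float = 1e-5
    ori_ter_ratio: float = 1.0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ConfigError("depth_dispersion must be >= 0")
        for name in ("snv_dropout_rate", "false_snv_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.ori_ter_ratio < 1.0:
            raise ConfigError("ori_ter_ratio must be >= 1")

    @property
    def deterministic(self) -> bool:
        return self.depth_dispersion == 0.0


#: Zero-noise model: expectations everywhere, flat coverage.
ZERO_NOISE = NoiseModel(
    mean_depth=30.0,
    depth_dispersion=0.0,
    snv_dropout_rate=0.0,
    false_snv_rate=0.0,
    ori_ter_ratio=1.0,
)


@dataclass(frozen=True)
class TimepointOccupancy:
    """Which strain occupies a timepoint; None means the species is absent."""

    strain_id: str | None
    mixture_fraction: float = 0.0
    contaminant_id: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.mixture_fraction <= 0.5:
            raise ConfigError("mixture_fraction must lie in [0, 0.5]")
        if self.mixture_fraction > 0 and self.contaminant_id is None:
            raise ConfigError("mixture_fraction > 0 requires a contaminant_id")


@dataclass(frozen=True)
class ScenarioSpec:
    """A planted timeline: strain occupancy per timepoint plus its category."""

    individual_id: str
    species_id: str
    layout: TimelineLayout
    occupancy: tuple[TimepointOccupancy, ...]
    planted_category: RecoveryCategory

    def __post_init__(self):
        if len(self.occupancy) != len(self.layout):
            raise ConfigError("occupancy must cover every timepoint")

    def strain_ids(self) -> list[str]:
        ids: list[str] = []
        for occ in self.occupancy:
            for sid in (occ.strain_id, occ.contaminant_id):
                if sid is not None and sid not in ids:
                    ids.append(sid)
        return ids


def implied_relatedness(scenario: ScenarioSpec) -> np.ndarray:
    """The relatedness call matrix a noise-free realization must produce."""
    t = len(scenario.layout)
    calls = np.full((t, t), None, dtype=object)
    for i in range(t):
        for j in range(i + 1, t):
            a, b = scenario.occupancy[i].strain_id, scenario.occupancy[j].strain_id
            if a is None or b is None:
                call = RelatednessCall.INDETERMINATE
            elif a == b:
                call = RelatednessCall.RELATED
            else:
                call = RelatednessCall.UNRELATED
            calls[i, j] = calls[j, i] = call
    return calls


def scenario_for_category(
    category: RecoveryCategory,
    layout: TimelineLayout,
    individual_id: str,
    species_id: str,
) -> ScenarioSpec:
    """Construct a strain occupancy whose noise-free classification is ``category``.

    Occupancies use abstract strain ids ``s0`` (the pre-strain), ``s1``,
    ``s2``, ... which the realizer maps to concrete genotypes. NEW_LATE
    requires a layout with a LATE timepoint.
    """
    t = len(layout)
    pre, last = layout.pre_index, layout.last_index
    eot, late = layout.end_of_treatment_index, layout.late_index
    occ: list[str | None]
    if category is RecoveryCategory.PERSISTENT:
        occ = ["s0"] * t
    elif category is RecoveryCategory.TRANSIENT_RETURN:
        if not layout.intermediate_indices:
            raise ConfigError("TRANSIENT_RETURN needs at least one intermediate timepoint")
        occ = ["s1"] * t
        occ[pre] = occ[last] = "s0"
    elif category is RecoveryCategory.NEW_FROM_TREATMENT_END:
        if eot is None:
            raise ConfigError("NEW_FROM_TREATMENT_END needs an END_OF_TREATMENT timepoint")
        occ = ["s0" if i < eot else "s1" for i in range(t)]
    elif category is RecoveryCategory.NEW_LATE:
        if late is None:
            raise ConfigError(f"layout {layout.labels} has no LATE timepoint; NEW_LATE impossible")
        occ = ["s0" if i < late else "s1" for i in range(t)]
    elif category is RecoveryCategory.NEW_PERMANENT:
        # Every post-treatment strain distinct, so no "new strain persists"
        # rule can fire and the pattern is pure replacement.
        occ = [f"s{i}" for i in range(t)]
    elif category is RecoveryCategory.INDETERMINATE:
        occ = [None] * t
        occ[pre] = "s0"
    else:  # pragma: no cover - exhaustive enum
        raise ConfigError(f"unknown category {category}")
    scenario = ScenarioSpec(
        individual_id,
        species_id,
        layout,
        tuple(TimepointOccupancy(s) for s in occ),
        category,
    )
    return scenario


# ---------------------------------------------------------------------------
# realization


def expected_depth_profile(
    genome_length: int,
    bin_size: int,
    mean_depth: float,
    ori_ter_ratio: float,
    ori_position: int = 0,
) -> np.ndarray:
    """Smooth per-bin expected depth of a replicating circular genome.

    Log-depth falls linearly with circular distance from the origin
    (``ori_position``) to the terminus at half the genome; the profile is
    scaled so its length-weighted genome mean equals ``mean_depth``.
    """
    n_bins = math.ceil(genome_length / bin_size)
    starts = np.arange(n_bins) * bin_size
    ends = np.minimum(starts + bin_size, genome_length)
    centers = (starts + ends) / 2.0
    half = genome_length / 2.0
    dist = np.abs((centers - ori_position) % genome_length)
    dist = np.minimum(dist, genome_length - dist)
    shape = np.power(ori_ter_ratio, 1.0 - dist / half)
    lengths = ends - starts
    shape_mean = float(np.sum(shape * lengths) / genome_length)
    return shape * (mean_depth / shape_mean)


def realize_coverage(
    sample_id: str,
    species_id: str,
    genome_length: int,
    bin_size: int,
    noise: NoiseModel,
    rng: np.random.Generator,
    absent: bool = False,
) -> CoverageProfile:
    """Draw one sample's binned coverage track under the noise model."""
    n_bins = math.ceil(genome_length / bin_size)
    if absent:
        return CoverageProfile(sample_id, species_id, bin_size, np.zeros(n_bins), genome_length)
    expected = expected_depth_profile(
        genome_length, bin_size, noise.mean_depth, noise.ori_ter_ratio
    )
    if noise.deterministic:
        depths = np.round(expected)
    else:
        lengths = np.minimum(
            (np.arange(n_bins) + 1) * bin_size, genome_length
        ) - np.arange(n_bins) * bin_size
        m = expected * lengths  # expected bases covered per bin
        lam = rng.gamma(1.0 / noise.depth_dispersion, m * noise.depth_dispersion)
        counts = rng.poisson(lam)
        depths = counts / lengths
    return CoverageProfile(sample_id, species_id, bin_size, depths, genome_length)


def realize_sample(
    sample_id: str,
    reference: Reference,
    strain: StrainGenotype,
    coverage: CoverageProfile,
    noise: NoiseModel,
    rng: np.random.Generator,
    mixture_fraction: float = 0.0,
    contaminant: StrainGenotype | None = None,
) -> SampleVariantProfile:
    """Realize the observable SNV calls of one sample.

    Allele fractions: loci private to the occupying strain sit at 1 − m,
    loci private to the contaminant at m, shared loci at 1 (m the mixture
    fraction); observed fractions are binomial draws at the local bin depth
    unless the noise model is deterministic.
    """
    if mixture_fraction > 0 and contaminant is None:
        raise ConfigError("mixture requires a contaminant strain")
    truth: dict[int, tuple[str, float]] = {}
    contam_snvs = contaminant.snvs if (contaminant and mixture_fraction > 0) else frozenset()
    contam_by_pos = dict(contam_snvs)
    for pos, alt in strain.snvs:
        f = 1.0 if contam_by_pos.get(pos) == alt else 1.0 - mixture_fraction
        truth[pos] = (alt, f)
    for pos, alt in contam_snvs:
        if pos not in truth:  # at a conflicting locus the occupying strain wins
            truth[pos] = (alt, mixture_fraction)

    calls: list[SnvCall] = []
    for pos in sorted(truth):
        alt, f = truth[pos]
        if noise.snv_dropout_rate > 0 and rng.random() < noise.snv_dropout_rate:
            continue
        depth = int(round(float(coverage.depth_at(np.array([pos]))[0])))
        if depth <= 0:
            continue
        if noise.deterministic:
            alt_reads = int(round(depth * f))
        else:
            alt_reads = int(rng.binomial(depth, f))
        if alt_reads == 0:
            continue
        calls.append(
            SnvCall(pos, reference.sequence[pos], alt, depth, alt_reads / depth)
        )

    if noise.false_snv_rate > 0:
        n_false = rng.binomial(reference.genome_length, noise.false_snv_rate)
        taken = set(truth)
        for _ in range(n_false):
            pos = int(rng.integers(reference.genome_length))
            if pos in taken:
                continue
            taken.add(pos)
            depth = int(round(float(coverage.depth_at(np.array([pos]))[0])))
            if depth <= 0:
                continue
            ref_base = reference.sequence[pos]
            alt = [b for b in BASES if b != ref_base][rng.integers(3)]
            calls.append(SnvCall(pos, ref_base, alt, depth, 1.0))
        calls.sort(key=lambda c: c.position)
    return SampleVariantProfile(sample_id, reference.species_id, calls, reference.genome_length)


def realize_timeline(
    scenario: ScenarioSpec,
    strains: Mapping[str, StrainGenotype],
    reference: Reference,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    bin_size: int = 500,
) -> dict[str, tuple[SampleVariantProfile, CoverageProfile]]:
    """Realize every timepoint of one planted timeline.

    Returns ``{timepoint_label: (variant profile, coverage track)}``; absent
    timepoints yield zero-depth tracks with no calls.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for sid in {s for occ in scenario.occupancy for s in (occ.strain_id, occ.contaminant_id) if s}:
        if sid not in strains:
            raise ConfigError(f"occupancy references unknown strain {sid!r}")
    out: dict[str, tuple[SampleVariantProfile, CoverageProfile]] = {}
    for label, occ in zip(scenario.layout.labels, scenario.occupancy):
        sample_id = f"{scenario.individual_id}|{scenario.species_id}|{label}"
        absent = occ.strain_id is None
        cov = realize_coverage(
            sample_id, scenario.species_id, reference.genome_length, bin_size, noise, rng, absent
        )
        if absent:
            profile = SampleVariantProfile(
                sample_id, scenario.species_id, [], reference.genome_length
            )
        else:
            profile = realize_sample(
                sample_id,
                reference,
                strains[occ.strain_id],
                cov,
                noise,
                rng,
                occ.mixture_fraction,
                strains[occ.contaminant_id] if occ.contaminant_id else None,
            )
        out[label] = (profile, cov)
    return out


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class PlantedTimeline:
    individual_id: str
    species_id: str
    category: RecoveryCategory
    scenario: ScenarioSpec
    strains: dict[str, StrainGenotype]
    samples: dict[str, tuple[SampleVariantProfile, CoverageProfile]]


@dataclass
class Cohort:
    """A fully realized synthetic cohort with its planted ground truth."""

    layout: TimelineLayout
    references: dict[str, Reference]
    timelines: list[PlantedTimeline]
    cutoffs: CutoffTable
    seed: int

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [t.individual_id for t in self.timelines],
                "species_id": [t.species_id for t in self.timelines],
                "category": [t.category.value for t in self.timelines],
            }
        )

    def write(self, out_dir) -> Path:
        """Materialize the cohort on disk; returns the manifest path.

        Layout: ``references.fasta`` (+ lengths), ``cutoffs.tsv``,
        ``truth.tsv``, per-sample ``<ind>_<sp>_<label>.vcf`` / ``.bedgraph``,
        and ``manifest.tsv`` indexing them all.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_reference_fasta(list(self.references.values()), out / "references.fasta")
        write_cutoffs(self.cutoffs, out / "cutoffs.tsv")
        self.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        rows = []
        for tl in self.timelines:
            for label, role in zip(self.layout.labels, self.layout.roles):
                profile, cov = tl.samples[label]
                stem = f"{tl.individual_id}_{tl.species_id}_{label}"
                write_vcf(profile, out / f"{stem}.vcf")
                write_bedgraph(cov, out / f"{stem}.bedgraph")
                rows.append(
                    {
                        "individual_id": tl.individual_id,
                        "species_id": tl.species_id,
                        "timepoint_label": label,
                        "role": role.value,
                        "vcf_path": f"{stem}.vcf",
                        "depth_path": f"{stem}.bedgraph",
                    }
                )
        manifest = out / "manifest.tsv"
        pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
        return manifest


def build_cohort(
    plan: Sequence[tuple[str, str, RecoveryCategory]],
    layout: TimelineLayout,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    genome_length: int = 50_000,
    n_snv: int = 250,
    bin_size: int = 500,
    cutoff: float = 0.8,
    mixture_fraction: float = 0.0,
    out_dir=None,
) -> Cohort:
    """Realize a cohort from a plan of (individual, species, category) rows.

    Each planted timeline draws its own strain pool on disjoint position
    sets. With ``mixture_fraction > 0`` every occupied non-PRE timepoint
    carries that fraction of a dedicated contaminant strain. Deterministic
    per (plan, seed); pass ``out_dir`` to also write all files to disk.
    """
    if not plan:
        raise ConfigError("empty cohort plan")
    master = np.random.SeedSequence(seed)
    species_ids = sorted({sp for _, sp, _ in plan})
    ref_seeds = master.spawn(len(species_ids))
    references = {
        sp: generate_reference(
            ReferenceSpec(sp, genome_length, int(ss.generate_state(1)[0] % 2**31))
        )
        for sp, ss in zip(species_ids, ref_seeds)
    }
    cutoffs = CutoffTable({sp: cutoff for sp in species_ids})
    timelines: list[PlantedTimeline] = []
    tl_seeds = master.spawn(len(plan))  # continues the spawn-key sequence deterministically
    for (individual_id, species_id, category), ss in zip(plan, tl_seeds):
        rng = np.random.default_rng(ss)
        scenario = scenario_for_category(category, layout, individual_id, species_id)
        if mixture_fraction > 0:
            occ = [
                o
                if o.strain_id is None or i == layout.pre_index
                else TimepointOccupancy(o.strain_id, mixture_fraction, "contam")
                for i, o in enumerate(scenario.occupancy)
            ]
            scenario = replace(scenario, occupancy=tuple(occ))
        strain_ids = scenario.strain_ids()
        reference = references[species_id]
        pools = np.array_split(
            rng.permutation(genome_length), max(len(strain_ids), 1)
        )
        strains = {
            sid: generate_strain(reference, n_snv, rng, sid, pool)
            for sid, pool in zip(strain_ids, pools)
        }
        samples = realize_timeline(scenario, strains, reference, noise, rng, bin_size)
        timelines.append(
            PlantedTimeline(individual_id, species_id, category, scenario, strains, samples)
        )
    cohort = Cohort(layout, references, timelines, cutoffs, seed)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def plan_from_counts(
    category_counts: Mapping[RecoveryCategory, int], species_id: str = "sp01"
) -> list[tuple[str, str, RecoveryCategory]]:
    """One individual per planted timeline, a single shared species."""
    if not category_counts or all(n == 0 for n in category_counts.values()):
        raise ConfigError("empty category list")
    plan = []
    i = 0
    for category, n in category_counts.items():
        if n < 0:
            raise ConfigError("multiplicities must be >= 0")
        for _ in range(n):
            plan.append((f"ind{i:03d}", species_id, category))
            i += 1
    return plan


def plan_dataset(
    n_individuals: int,
    n_species: int,
    category_probs: Mapping[RecoveryCategory, float],
    rng: np.random.Generator,
    individual_prefix: str = "ind",
) -> list[tuple[str, str, RecoveryCategory]]:
    """Random multi-species plan: each (individual, species) draws a category."""
    cats = list(category_probs)
    p = np.array([category_probs[c] for c in cats], dtype=float)
    if p.sum() <= 0:
        raise ConfigError("category probabilities must sum to a positive value")
    p = p / p.sum()
    plan = []
    for i in range(n_individuals):
        for s in range(n_species):
            cat = cats[int(rng.choice(len(cats), p=p))]
            plan.append((f"{individual_prefix}{i:03d}", f"sp{s:02d}", cat))
    return plan
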