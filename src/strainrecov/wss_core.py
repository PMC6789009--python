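"""Window-based SNV similarity (WSS) between two samples of one species.

The genome is cut into fixed-length windows; within each window the two
samples' SNV sets (position + alternate allele) are compared with the Jaccard
index, and the genome-wide score is the unweighted mean over windows that
survive the filters and contain at least one SNV in either sample. Windows
that pass the depth filter but contain no SNV in either sample carry no
information about strain identity and are excluded from the mean rather than
counted as perfect matches (the count is kept as a diagnostic).

Three filters precede scoring, mirroring standard strain-tracking practice:

* locus heterogeneity — SNV loci whose minor-allele fraction exceeds 20% are
  removed per sample (likely strain mixtures, uninformative for identity);
* window depth — a window is ignored when, in either sample, more than 50% of
  its bases have read depth below 5;
* genome coverage — if either sample retains 30% of windows or fewer, the
  pair is not scored and the relatedness call is INDETERMINATE.

The score is compared against a species-specific cut-off: strictly above the
cut-off the pair is called RELATED (same strain), otherwise UNRELATED. All
boundary rules are strict inequalities; a score exactly equal to the cut-off
is UNRELATED.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .variant_io import CoverageProfile, CutoffTable, SampleVariantProfile


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry and filter thresholds for WSS scoring.

    Defaults encode the published filter rules: windows of 1 kb, a base is
    low-depth below 5 reads, a window is dropped above 50% low-depth bases,
    loci are dropped above 20% minor-allele fraction, and pairs are dropped
    at or below 30% retained genome.
    """

    window_length: int = 1000
    low_depth_threshold: float = 5.0
    low_depth_fraction: float = 0.5
    het_fraction: float = 0.2
    min_genome_coverage: float = 0.3

    def __post_init__(self):
        if self.window_length <= 0:
            raise ConfigError("window_length must be positive")
        for name in ("low_depth_fraction", "het_fraction", "min_genome_coverage"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1); got {v}")


class RelatednessCall(str, enum.Enum):
    RELATED = "RELATED"
    UNRELATED = "UNRELATED"
    INDETERMINATE = "INDETERMINATE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class WindowSimilarity:
    """Jaccard similarity of the two samples' SNV sets within one window."""

    window_index: int
    n_shared: int
    n_union: int
    retained: bool

    @property
    def similarity(self) -> float | None:
        """``n_shared / n_union``; None when the window holds no SNV at all."""
        if self.n_union == 0:
            return None
        return self.n_shared / self.n_union


@dataclass(frozen=True)
class WssResult:
    """Genome-wide similarity of one sample pair with its relatedness call."""

    sample_a: str
    sample_b: str
    species_id: str
    score: float  # NaN when INDETERMINATE
    n_windows_retained: int
    n_windows_defined: int
    n_zero_union: int
    coverage_a: float
    coverage_b: float
    call: RelatednessCall


def filter_heterogeneous(
    profile: SampleVariantProfile, spec: WindowSpec = WindowSpec()
) -> SampleVariantProfile:
    """Drop SNV loci whose minor-allele fraction strictly exceeds the threshold.

    A locus with alt fraction 0.5 (minor fraction 0.5) is excluded; a locus at
    exactly the threshold (default 0.2) is retained.
    """
    kept = [c for c in profile.calls if c.minor_fraction <= spec.het_fraction]
    if len(kept) == len(profile.calls):
        return profile
    return profile.with_calls(kept)


def window_depth_mask(
    cov_a: CoverageProfile, cov_b: CoverageProfile, spec: WindowSpec = WindowSpec()
) -> tuple[np.ndarray, float, float]:
    """Depth-filter windows; return (joint retained mask, coverage_a, coverage_b).

    A window passes for one sample when at most ``low_depth_fraction`` of its
    bases fall below ``low_depth_threshold`` (exactly 50% low-depth still
    passes — the rule excludes only *more than* 50%). The joint mask requires
    both samples to pass; each sample's genome coverage fraction is the share
    of windows passing under its own mask alone.
    """
    if cov_a.genome_length != cov_b.genome_length:
        raise ConfigError(
            f"genome length mismatch: {cov_a.genome_length} vs {cov_b.genome_length}"
        )
    frac_a = cov_a.low_depth_fraction_per_window(spec.window_length, spec.low_depth_threshold)
    frac_b = cov_b.low_depth_fraction_per_window(spec.window_length, spec.low_depth_threshold)
    pass_a = frac_a <= spec.low_depth_fraction
    pass_b = frac_b <= spec.low_depth_fraction
    return pass_a & pass_b, float(pass_a.mean()), float(pass_b.mean())


def window_similarity(
    a: SampleVariantProfile,
    b: SampleVariantProfile,
    retained: np.ndarray,
    spec: WindowSpec = WindowSpec(),
) -> list[WindowSimilarity]:
    """Per-window shared/union SNV counts between two (filtered) profiles.

    SNVs are assigned to windows by integer division of position by the
    window length; "shared" requires identical position *and* alternate
    allele.
    """
    n_windows = len(retained)
    enc_a, enc_b = a.encoded(), b.encoded()
    shared = np.intersect1d(enc_a, enc_b, assume_unique=True)

    def per_window(enc: np.ndarray) -> np.ndarray:
        win = (enc // 4) // spec.window_length
        return np.bincount(win, minlength=n_windows)

    cnt_a, cnt_b, cnt_s = per_window(enc_a), per_window(enc_b), per_window(shared)
    cnt_union = cnt_a + cnt_b - cnt_s
    return [
        WindowSimilarity(w, int(cnt_s[w]), int(cnt_union[w]), bool(retained[w]))
        for w in range(n_windows)
    ]


def wss_score(
    a: SampleVariantProfile,
    b: SampleVariantProfile,
    cov_a: CoverageProfile,
    cov_b: CoverageProfile,
    spec: WindowSpec = WindowSpec(),
    cutoffs: CutoffTable | None = None,
    cutoff: float | None = None,
) -> WssResult:
    """Score one sample pair and call relatedness against the species cut-off.

    The pair is INDETERMINATE when either sample's retained-genome fraction
    is at or below ``min_genome_coverage``, or when no retained window holds
    any SNV. Otherwise RELATED iff score > cut-off (strict), else UNRELATED.
    """
    if a.species_id != b.species_id:
        raise ConfigError(f"species mismatch: {a.species_id} vs {b.species_id}")
    if cutoff is None:
        if cutoffs is None:
            raise ConfigError("either a CutoffTable or an explicit cutoff is required")
        cutoff = cutoffs.cutoff_for(a.species_id)

    fa = filter_heterogeneous(a, spec)
    fb = filter_heterogeneous(b, spec)
    retained, coverage_a, coverage_b = window_depth_mask(cov_a, cov_b, spec)
    sims = window_similarity(fa, fb, retained, spec)
    values = [s.similarity for s in sims if s.retained and s.n_union > 0]
    n_zero_union = sum(1 for s in sims if s.retained and s.n_union == 0)

    if min(coverage_a, coverage_b) <= spec.min_genome_coverage or not values:
        return WssResult(
            a.sample_id,
            b.sample_id,
            a.species_id,
            float("nan"),
            int(retained.sum()),
            len(values),
            n_zero_union,
            coverage_a,
            coverage_b,
            RelatednessCall.INDETERMINATE,
        )
    score = float(np.mean(values))
    call = RelatednessCall.RELATED if score > cutoff else RelatednessCall.UNRELATED
    return WssResult(
        a.sample_id,
        b.sample_id,
        a.species_id,
        score,
        int(retained.sum()),
        len(values),
        n_zero_union,
        coverage_a,
        coverage_b,
        call,
    )


@dataclass
class PairwiseWss:
    """All pairwise WSS results over one (individual, species) timeline."""

    sample_ids: list[str]
    results: dict[tuple[int, int], WssResult]

    def calls(self) -> np.ndarray:
        """Symmetric (T, T) object array of RelatednessCall; diagonal is None."""
        n = len(self.sample_ids)
        m = np.full((n, n), None, dtype=object)
        for (i, j), r in self.results.items():
            m[i, j] = m[j, i] = r.call
        return m


def all_pairs(
    samples: Sequence[tuple[SampleVariantProfile, CoverageProfile]],
    spec: WindowSpec = WindowSpec(),
    cutoffs: CutoffTable | None = None,
    cutoff: float | None = None,
) -> PairwiseWss:
    """Score every unordered sample pair of one timeline.

    Results are computed once per unordered pair; symmetry of the score is
    exact because the pair statistic itself is symmetric.
    """
    if len(samples) < 2:
        raise ConfigError("need at least two samples for pairwise comparison")
    results: dict[tuple[int, int], WssResult] = {}
    for i, j in itertools.combinations(range(len(samples)), 2):
        (pa, ca), (pb, cb) = samples[i], samples[j]
        results[(i, j)] = wss_score(pa, pb, ca, cb, spec, cutoffs, cutoff)
    return PairwiseWss([p.sample_id for p, _ in samples], results)
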