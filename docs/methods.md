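# Methods

## Problem and scope

After a course of antibiotics, a gut species' niche may be re-occupied by
the strain that was there before treatment, by a transient invader that is
later displaced, or by a permanent replacement. `strainrecov` implements the
analysis layer of strain-resolved longitudinal tracking: it starts from
per-sample variant calls (VCF) and binned depth tracks (BedGraph) against a
species reference, and ends at per-individual recovery-pattern fractions,
growth-rate tables, marker-tree cross-checks, and group-level statistics.
Read-level processing (QC, alignment, variant calling) is out of scope;
the synthetic-cohort module stands in for that upstream pipeline and plants
known ground truth at exactly the level where the analysis begins.

## Window-based SNV similarity (WSS)

For one species and two samples, the genome is divided into windows of
`window_length` (default 1000 bp). Within a window, each sample contributes
the set of its SNVs — (position, alternate allele) pairs — and the window
similarity is the Jaccard index |A∩B| / |A∪B|. The genome-wide score is the
unweighted mean over windows that pass the filters and contain at least one
SNV in either sample. The per-window kernel is a declared stand-in: the
Jaccard mean is the simplest statistic consistent with a genome-wide
similarity on a [0, 1] cut-off scale, and it is isolated behind
`window_similarity` so an alternative kernel can be swapped in.

Filters, in order:

1. **Locus heterogeneity** (per sample, before pairing): drop SNV loci whose
   minor-allele fraction strictly exceeds `het_fraction` (default 0.2).
   Intermediate allele fractions indicate a within-sample strain mixture and
   carry no clean identity signal.
2. **Window depth** (per pair): drop windows where, in either sample, more
   than `low_depth_fraction` (default 50%) of bases have depth below
   `low_depth_threshold` (default 5 reads). Exactly 50% still passes.
3. **Genome coverage** (per pair): if either sample's fraction of retained
   windows (computed under its own mask) is at or below
   `min_genome_coverage` (default 0.3), the pair is INDETERMINATE.

Relatedness is called against a per-species cut-off in (0, 1): RELATED iff
score > cut-off, strictly; a score exactly at the cut-off is UNRELATED.
Windows that pass the depth filter but hold no SNV in either sample are
excluded from the mean rather than scored 1.0 — counting reference-identical
windows as perfect matches would inflate similarity wherever two unrelated
strains both match the reference; the count is kept as a diagnostic.
Cut-offs are configuration (in real use they come from reference cohorts of
known related/unrelated pairs); synthetic cohorts use 0.8, a mid-range value
typical of published per-species cut-offs.

## Recovery-pattern classification

Each (individual, species) timeline yields a symmetric matrix of
RELATED / UNRELATED / INDETERMINATE calls over its timepoints. Timepoints
carry roles: PRE (first), END_OF_TREATMENT, optionally LATE, and LAST.
Two built-in layouts mirror the common study designs: a three-point course
(Day 0 / 7 / 90, single antibiotic) and a four-point course
(Day 0 / 8 / 42 / 180, antibiotic cocktail).

Categories, evaluated in precedence order (first match wins):

1. **gray / INDETERMINATE** — a strict majority of pairs INDETERMINATE;
2. **green / PERSISTENT** — pre ↔ t RELATED for every later t;
3. **green\* / TRANSIENT_RETURN** — pre ↔ last RELATED, and pre ↔ t
   UNRELATED for at least one intermediate t;
4. **red / NEW_FROM_TREATMENT_END** — pre ↔ last UNRELATED and the
   end-of-treatment sample RELATED to every later timepoint;
5. **blue / NEW_LATE** — pre ↔ last UNRELATED, red not satisfied, and
   LATE ↔ last RELATED;
6. **purple / NEW_PERMANENT** — pre ↔ t UNRELATED for every later t;
7. residue — gray, with a logged reason, so the classifier is total.

The precedence order resolves overlaps the verbal definitions leave
implicit. Two consequences are deliberate: a timeline whose single new
strain occupies *every* post-treatment timepoint is red, not purple (the
new-strain-persists rule is more specific than "no relationship"), so the
generator's planted purple scenarios use distinct strains at each post
timepoint — pure replacement with no persisting newcomer. And layouts
without a LATE timepoint can structurally never produce blue. For red, the
end-of-treatment strain is required to be related to **all** later
timepoints, not only the last. Exhaustive enumeration of all 3^6 call
matrices of the four-point layout against an independently hand-coded
decision table proves totality and exclusivity.

Cohort summaries report, per individual, the fraction of species in each
category; the red and blue groups are merged into a single
"new strain at an intermediate timepoint" group, following the convention
of the summary figures this mirrors. Top-species selection ranks species by
the number of individuals whose pre ↔ last comparison produced a defined
score, with ties broken by mean coverage and then species id.

## Growth-rate score (peak-to-trough ratio)

Replicating bacteria over-represent the replication origin, so coverage
decays from an ori peak to a ter trough; the ratio is a growth proxy. The
estimate is `max(smoothed) / min(smoothed)` over a circular moving-median
smoothed profile (window ≈ n_bins/10, odd, clipped to [3, 51]), with the
trough floored at a pseudo-depth of 0.1 (floored cells flagged). Estimates
are discarded below 0.2× mean coverage or above 0.3 sample heterogeneity,
and scores under 1.5 flag slow growers. Heterogeneity is a declared proxy:
the fraction of SNV loci with minor-allele fraction above 0.1.

Numerical behavior, measured on the generator: at 50× depth with the
default overdispersion, planted ratios {1.0, 1.5, 2.0, 3.0} are recovered
with a median absolute relative error around 6% overall and per-ratio
medians in the correct rank order. The ratio-1.0 case is biased upward
(~15–20%) because the max/min of any noisy profile exceeds 1 — an inherent
property of extreme-value statistics, reported rather than hidden; wider
smoothing windows trade this bias for attenuation of true high ratios, and
the default window was chosen at that trade-off's sweet spot.

## Marker-tree cross-check

Per sample, marker sequences are reconstructed by substituting the sample's
SNVs into configured reference sub-regions (default ten non-overlapping
500 bp regions spread evenly; loci under a depth threshold keep the
reference base and are counted as masked). Distances are percent-identity
(PID): 1 − matches / compared columns, with gap-containing columns excluded
pairwise. Trees are built with canonical Saitou–Nei neighbor joining,
implemented here with a deterministic tie-break (smallest row-major index
pair in the Q matrix) and negative branch lengths clamped to zero with a
count; exact topology recovery on additive matrices is enforced by tests
against an independent Robinson–Foulds oracle.

Tree/call concordance: a pair is concordant when RELATED with patristic
distance at or below the cohort median, or UNRELATED at or above it. Ties
count as concordant on either side, which keeps the degenerate all-one-
strain cohort (all distances zero) fully concordant; for tie-free distances
the permutation null sits at 0.5.

## Statistics

Group comparisons use one-way ANOVA (standard between/within sum-of-squares
decomposition) followed by Tukey's HSD, with adjusted p-values from the
studentized-range distribution and the Tukey–Kramer standard error for
unbalanced groups. Both are written from the formulas so they can be
verified against independent implementations (agreement with scipy's
reference routines to well below 1e-6 is part of the acceptance checks, as
is a null family-wise error rate of ~0.05). Degenerate inputs are total:
identical data give F = 0, p = 1; zero within-group variance with distinct
means gives F = ∞, p = 0. The per-individual category fraction is the unit
of analysis, and significance stars map to 0.05 / 0.01 / 0.001.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants a recovery category per (individual, species), builds
the strain occupancy that category implies, and realizes variant + depth
data per timepoint:

- **References**: uniform-random genomes (default 50 kb for closed-loop
  tests, smaller for high-replicate simulations). Real genomes are larger
  and compositionally structured; nothing downstream depends on either.
- **Strains**: SNV sets (default 250 per strain, ~0.5% divergence over
  50 kb, around five SNVs per 1 kb window). Distinct strains of one
  timeline draw positions from disjoint pools, so their planted similarity
  is exactly 0 — the idealization that strains differ at private sites.
  Real unrelated strains share part of their variation; the cut-off, not
  the generator, is what absorbs that in real data.
- **Depth**: a log-linear circular decay from an ori at coordinate 0 to a
  ter at half the genome with planted peak/trough ratio, scaled to the mean
  depth (default 30×), with per-bin negative-binomial noise
  (`depth_dispersion` 0.02: variance m + 0.02·m² around bin mean m —
  moderate overdispersion typical of binned metagenomic depth).
- **Variants**: per-SNV dropout (default 0.02), false SNVs at 1e-5 per
  base, allele fractions binomially resampled at the local depth. Mixtures
  put a second strain at a contaminant fraction in [0, 0.5]; the default
  mixture grid for heterogeneity experiments is {0, 0.1, 0.3}.
- **Absence**: an ABSENT timepoint emits a zero-depth track and no calls,
  which is what drives INDETERMINATE pairs and the gray category.
- Setting `depth_dispersion = 0` switches all stochastic steps to their
  expectations; zero-noise cohorts are byte-reproducible and must classify
  to their planted category exactly — the closed loop that every category
  satisfies by construction and test.

Passing closed-loop tests therefore shows the machinery is internally
consistent under these planted conditions; it does not calibrate the method
against real sequencing artifacts (mapping bias, GC skew, reference
mis-assignment, shared variation between strains), which is what the
published per-species cut-offs encode in real use.

## Numerical and interface choices

- Internal coordinates are 0-based half-open; VCF POS converts on the way
  in and out. Indels are skipped with a logged count (the method is
  SNV-defined). Multi-allelic records are split per allele and collapsed to
  the highest-AD allele so each locus carries one call and profiles keep
  strictly increasing positions.
- All filter thresholds are strict inequalities exactly as quoted in their
  rules; boundary tests pin each one.
- Simulation sizes in the tests (50 kb closed-loop genomes, 20 kb for the
  100-replicate power study, 200+ planted timelines, 50 seeds per growth
  ratio) were chosen as the smallest sizes at which the measured quantities
  are stable under reseeding.
- Stage outputs are plain TSV/CSV written atomically (temp file + rename);
  a failing stage leaves earlier outputs intact.

## Known limitations

- The window similarity kernel is a documented stand-in, not a reproduction
  of any previously published kernel; per-species cut-offs are inputs.
- The growth estimator reads the peak/trough from smoothed extrema rather
  than replichore segmentation, and inherits the upward bias at ratio ≈ 1
  described above.
- Heterogeneity proxies (locus minor-allele fractions) conflate strain
  mixture with systematic allele-balance artifacts that real data can show.
- The classifier's residue-to-gray rule means ambiguous patterns are
  reported as indeterminate rather than forced into a substantive category.
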