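# Methods

This note documents the models, parameter choices and numerical decisions
behind `venomprint`, in the spirit of the methods documentation of packages
like statsmodels or msprime: what is computed, under which assumptions, and
what the defaults mean.

## 1. Signal model and alignment

An electropherogram is modelled as fluorescence (FU) sampled on a strictly
increasing migration-time axis (s). Run-to-run timing differences are
treated as a per-run **affine injection warp** corrected exactly by the two
internal standards (1.6 and 95 kDa) co-loaded with every sample: if a run's
standards sit at `(l, u)` and the reference's at `(L, U)`, the map
`t' = a·t + b` with `a = (U−L)/(u−l)` and `b = L − a·l` places both
standards exactly on the reference. A two-point affine map is the simplest
transform that uses all the information the two standards carry; any
residual nonlinearity ends up in the migration jitter that the bins absorb.
The reference scale is either configured explicitly
(`standards.reference_lower_s/upper_s`) or taken from the first sample
whose standards are found.

Standards are located as the **tallest local maximum** inside a search
window (default: the first and last 25% of the trace span). A window with
no maximum above the detection threshold raises a standards-not-found
error and the sample is flagged and excluded — the automated counterpart
of manually re-running a failed chip lane. This rule assumes the system
peaks dominate the sample peaks in their windows, which holds on the real
instrument (and in the simulator, where sample peaks saturate at 500 FU
versus 600 FU standards).

**Peak calling** uses `scipy.signal.find_peaks` with three thresholds:

| parameter | default | meaning |
|---|---|---|
| `detection.min_height_fu` | 20 FU | the protocol's scoring threshold |
| `detection.min_prominence_fu` | 5 FU | suppresses baseline ripple maxima |
| `detection.min_separation_s` | 0.2 s | one apex per protein; taller wins |

Only the 20 FU height rule is part of the protocol proper; prominence and
separation are implementation guards for noisy baselines, exposed in the
config. The apex time is the time of the maximal sample — sub-sample
refinement is pointless when bins are 0.3–1 s wide and sampling is
~0.02 s. The scoreable window is `[lower + min_separation, upper)`:
everything at or beyond the upper standard (above 95 kDa) is excluded, as
is the lower standard's own flank. Sizing interpolates log₁₀(kDa) linearly
in time between ladder points (the standard calibration form for
gel/chip migration); outside the ladder span the nearest segment is
extended and the result flagged `extrapolated_mass`.

## 2. Bins

Replicate apex times are pooled and clustered by **single linkage** with a
0.5 s gap. A cluster may contain at most one peak per run — two peaks of
one run cannot be the same protein — and violating clusters are split
recursively at their largest internal gap. This constraint is what keeps
single linkage usable on dense pooled data, where the tails of adjacent
marker clouds would otherwise chain.

Each cluster with support ≥ 2 becomes a bin centered on its mean time with

```
half_width = clip(3 · SD, 0.15 s, 0.5 s)
```

3·SD covers ~99.7% of Gaussian jitter. The 0.15 s floor guards clusters
with degenerate spread (e.g. two coincident replicates). The 0.5 s cap is
this package's own addition: the sample SD of a small cluster has a heavy
right tail, and a single inflated bin would otherwise swallow its
neighbours when bin sets are merged by interval union; a bin wider than
the linkage gap is also internally inconsistent with the clustering that
produced it. Bins are built per group (the per-species workflow) by
default; per-individual granularity (`binning.granularity: individual`)
reproduces the duplicate-by-duplicate workflow but gives much noisier SD
estimates from 2-point clusters.

Merging bin sets unions overlapping or touching intervals transitively;
the merged bin spans the union, is centered at the support-weighted mean
of member centers, and pools supports. Merging is idempotent and
order-independent, and its output intervals are pairwise disjoint. Labels
follow the field's convention "P" + center rounded to 0.1 s (`P40.5`),
with `a`, `b`, … suffixes on collisions.

Scoring marks a marker present iff any peak falls inside its closed
interval; a peak inside several (pre-merge) bins goes to the nearest
center. Peaks in no bin are returned as *unassigned*; after an operator
confirms one by re-running the sample, `extend_bins` adds a minimal-width
bin there and re-merges. Replicate rows are combined by majority
consensus with **ties called present** — the protocol re-runs doubtful
absences, not doubtful presences — and every tie decision is logged.

## 3. Duplicate QC

For each duplicated individual the designated pair is replicates 1 and 2.
A marker discordant within a pair is a mismatch; the error rate is

```
total mismatches / (n_pairs × n_markers)
```

counting all markers × pairs (not only scoreable cells), which is the
denominator convention of AFLP error-rate reporting. Markers with ≥ 3
mismatches (configurable `qc.mismatch_threshold`, recorded in the QC
report) are discarded; the rate is reported before and after, and
discarding markers with maximal counts can only lower it. Note the
threshold is an absolute count, so its stringency depends on the number
of duplicate pairs: with the study-sized QC subset (~28 pairs) it removes
genuinely unstable markers, while duplicating all 98 individuals at a
~1.5% per-cell error rate would push most markers' expected counts to ~3.
The packaged preset therefore duplicates a 28-individual subset and runs
the rest once, which is also the real protocol's design.

With independent per-replicate flip probability δ the expected mismatch
rate is `2δ(1−δ)`; the test suite verifies this calibration at δ = 0.05.

Before diversity analysis, markers with frequency exactly 1 (fixed) are
dropped as uninformative; frequency-0 markers are dropped by the same
argument (they only occur in externally supplied matrices) and logged
separately.

## 4. Diversity and ordination

* **Richness**: row sums (peaks per venom).
* **Shannon index**: on a single binary row the classical Shannon index
  degenerates to ln(richness), so the primary statistic is the per-marker
  two-state information index `I(p) = −p·ln p − (1−p)·ln(1−p)` (nats), as
  used for dominant markers in population-genetics software, summarised
  as the mean over markers; ln(richness) is exposed as a labelled
  secondary per-individual value.
* **Phenotypes**: distinct rows with multiplicities; singletons are
  profiles seen once.
* **Bray–Curtis**: computed with the general abundance formula via scipy,
  which on 0/1 data equals Sørensen dissimilarity `1 − 2a/(2a+b+c)`; a
  pair of all-zero profiles has no defined distance and raises, naming
  the pair. Results are returned as a scikit-bio `DistanceMatrix`.

**NMDS** minimises Kruskal stress-1,
`sqrt(Σ(D−d̂)² / ΣD²)`, where `D` are configuration distances and `d̂` the
isotonic regression of `D` on the rank order of the input dissimilarities
with **primary tie treatment** (ties impose no mutual constraint —
implemented by pre-sorting distances within tie blocks, then
pool-adjacent-violators via `scipy.optimize.isotonic_regression`). Each
iteration alternates the isotonic fit with a Guttman configuration
update; if a step would raise stress it is halved toward the previous
configuration (up to 20 times), so the stress sequence within a start is
non-increasing by construction; convergence is a stress change < 1e−7.
The minimiser runs from one principal-coordinates start (scikit-bio PCoA)
plus 19 random starts on a deterministic seed schedule (`seed + start`),
and keeps the lowest-stress solution. The final configuration is
centered, rotated to principal axes, and sign-fixed so each axis's
largest-|coordinate| entry is positive — removing NMDS's
rotation/reflection indeterminacy so fixed seed + fixed input gives
bit-identical output.

**Marker vectors** (envfit-style): each marker column is regressed on the
centered coordinates; r² = 1 − RSS/TSS, the unit coefficient vector is
the arrow of increasing marker frequency, and
`p = (1 + #{permuted r² ≥ observed}) / (1 + n_perm)` with one shared set
of row permutations for all markers (default n_perm = 999, so the
smallest attainable p is 0.001). Constant markers get r² = 0, no
direction, p = 1.

## 5. The synthetic-data generator

`simulate_dataset` draws, per individual, marker presence once from its
group's probabilities (biology is shared across replicates, so duplicate
discordance measures technical error only — the quantity QC estimates);
then per replicate run: an affine warp (slope ~ N(1, 0.01), offset ~
N(0, 0.5 s)) applied to all true times including the standards; per
present peak an apex at warped(true time + N(0, 0.14 s)), the 0.14 s
default being the replicate jitter magnitude measured on real duplicate
runs; lognormal heights (median 100 FU, σ_log 0.5) clipped to
[25, 500] FU — the floor makes "present in truth" mean "detectable", so
the 2% per-peak dropout is the sole source of false negatives, and the
ceiling emulates detector saturation, keeping sample peaks below the
600 FU standards; Poisson(0.3) spurious peaks per trace, uniform over the
scoreable range at 20–40 FU, so some fall into bins and some exercise the
unassigned-peak path; Gaussian peak shapes (SD 0.08 s) on a 0.02 s grid
with 1 FU baseline noise. Everything is deterministic given the seed.

The **demonstration preset** (`two_group_preset`) mirrors the structure of
a real intraspecific survey: 98 individuals in two venom-type groups
(78 + 20), 28 true markers ~1.04 s apart, of which 4 fixed (probability 1
everywhere), 3 strongly group-diagnostic (0.05 vs 0.92, |Δp| ≥ 0.8) and
the rest drawn from a bimodal frequency distribution (two-thirds low,
0.05–0.35; one-third intermediate, 0.35–0.65), since most venom proteins
in real panels are either ubiquitous or locally rare. A 28-individual
QC subset is duplicated. Structure only: no claim is made to reproduce
any real study's values.

What the simulator does **not** model: nonlinear electrokinetic
migration, detector response curves, correlated presence among markers
(real phenotype counts cluster because of population substructure;
independent Bernoulli draws make nearly every simulated profile unique),
peak-height biology (heights are i.i.d., so abundance patterns cannot be
studied), and co-migration of distinct proteins into one peak. Passing
tests therefore demonstrate the pipeline's correctness and calibration
under the stated noise model, not instrument-level realism.

`evaluate_against_truth` maps scored bins to true markers by interval
overlap (several bins mapping to one true marker are OR-combined;
unmappable bins count their presences as false positives) and reports
TP/FP/FN/TN with per-marker sensitivity and specificity.

## 6. Degenerate inputs and tie-breaks

* Peak-detection separation conflicts: taller apex wins; equal heights →
  earlier time.
* Cluster split with zero internal gap (coincident duplicate times):
  split at the first repeated-replicate position.
* Bin-label collisions: alphabetic suffixes in center order.
* Consensus ties: present (logged).
* Empty polymorphic matrix, all-zero profile pairs, zero QC comparisons,
  coincident standards, sub-10-row traces: explicit typed errors, never
  silent results.

## 7. Problem sizes and runtime

The shipped tests and the acceptance script run the full pipeline at the
preset's survey scale (98 individuals, 126 traces of ~1,900 samples each),
the jitter calibration on 200 replicate runs, permutation calibration
over 400 trials × 999 permutations, and NMDS with 20 starts on up to 98
objects. The whole suite completes in well under a minute on one CPU;
these sizes give 3-standard-error statistical tolerances that are tight
enough to catch real defects while keeping every check deterministic.
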