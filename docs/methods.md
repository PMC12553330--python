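# Methods

## Data model

Input is a long-format table `(ID, Time, Reads)`. Counts are placed on the
dense (barcode × timepoint) grid; a pair absent from the file is a zero
count (sequencing non-detection), not missing data. Frequencies are
per-timepoint column normalizations f_k(t) = c_k(t) / Σ_j c_j(t). Timepoints
are opaque ordered reals; no unit conversion between generations and days is
attempted.

Zeros are handled in one place: a pseudo-frequency *floor*, by default half
the smallest detectable frequency at the deepest timepoint,
1/(2·max_t total reads). The floor is applied only by log-space consumers
(log-scale plots, the log10 trajectory transform); it never enters the
diversity computation, where zero frequencies are simply excluded from the
power sum (the standard Hill-number convention — also what makes q = 0 the
count of detected barcodes).

## Filters

Before clustering, barcode k survives iff

* mean_t f_k(t) > `min_mean_frequency` (default 10⁻⁴; arithmetic mean over
  **all** timepoints, zeros included; strict inequality), and
* |{t : reads_k(t) > 0}| ≥ `min_persistence` (default 12; detection is a
  read-count event, not a frequency-above-floor event).

Survivors are **not** renormalized: downstream cluster abundances remain
fractions of the whole population, which is what the final-abundance ranking
reports. Filtering is idempotent and monotone in both thresholds.

## Effective diversity

D_q(t) = (Σ_{k: f_k>0} f_k^q)^{1/(1−q)} with the analytic limits
D_1 = exp(−Σ f ln f) and D_∞ = 1/max f (computed as limits, not numerically
near the singularities). The implementation is validated on the identities
D_q = S for uniform profiles, continuity at q = 1, replication invariance,
and monotone non-increase in q. A timepoint with no detected barcode has
undefined diversity and is reported as NaN with a warning.

## Trajectory distances

Default comparison scale is log10 frequency with the floor substituted for
zeros: trajectories span orders of magnitude and the log view is what makes
low-frequency but persistent lineages comparable. Linear scale is available.

* **Pearson**: d = 1 − r. Affine-invariant, so it compares trajectory
  *shape*; anti-correlated dynamics are maximally distant (d = 2). Constant
  trajectories are rejected with an error naming the barcode (correlation
  with a constant is undefined; the filters normally remove such barcodes).
* **DTW**: classic dynamic programming with local cost |x_i − y_j|,
  symmetric steps {(1,0),(0,1),(1,1)}, no path-length normalization, and an
  optional Sakoe–Chiba band. DTW operates on index positions; sampling times
  are assumed shared. The kernel is verified exactly against exhaustive
  enumeration of all monotone warping paths for short series.

A useful property of correlation distance worth knowing when interpreting
clusters: for lineages whose log-trajectories differ only through a constant
selection differential (x_i(t) = s_i·t − G(t) with a shared normalizer G),
pairwise correlations collapse to a one-parameter family,
r_ij = cos(θ_i − θ_j) with θ_i = arctan((s_i − β)·sd(t)/sd(R)) where β and R
are the slope and residual of regressing G on t. Only a limited number of
constant-fitness classes can therefore be mutually separated; lineages whose
dynamics *change* in time (mutation-driven sweeps at different times) leave
this family and separate much more strongly. This drives the benchmark
design below.

## Clustering and consensus

UPGMA (unweighted average linkage on the distance matrix) is computed with
`scipy.cluster.hierarchy.linkage(method="average")`; merge heights are
verified against a naive O(n³) re-implementation to 10⁻¹². Leaves are sorted
lexicographically by barcode ID before linkage so that tie handling is
deterministic and reproducible. UPGMC is centroid linkage computed on the
transformed trajectory matrix (Euclidean centroids in trajectory space)
rather than via Lance–Williams on the precomputed distances, because
correlation distance is not Euclidean and centroid updates on it would be
ill-defined; UPGMC heights may show the usual centroid inversions, UPGMA
heights are monotone.

A cut at height h yields the maximal subtrees whose internal merges are all
≤ h; cluster labels are assigned deterministically by each cluster's
lexicographically smallest member. `quantify_thresholds` sweeps an even grid
of 100 cut heights from 0 to the maximum merge height and records the
cluster count and the minimum pairwise distance between cluster mean
trajectories (under the matrix's own metric) — the evidence on which the
user chooses a threshold. Threshold choice is deliberately user-driven; two
convenience rules are provided (`knee`: maximum second difference of the
count curve; `plateau`: midpoint of the longest non-trivial constant-count
run), with the caveat that no count-only rule is reliable on deeply
hierarchical data.

Each cluster's consensus is a LOESS fit (tricube weights, local polynomial
of degree 1 or 2, span = fraction of pooled points per window; defaults span
0.75, degree 2) through the pooled member points on the same transform used
for clustering, evaluated on the common time grid and back-transformed to
frequencies (clipped to [floor, 1]) for reporting. Members are pooled
unweighted. With too few distinct timepoints for the local polynomial the
consensus falls back to the pointwise mean with a warning. The degree-1 path
reproduces statsmodels' lowess on scattered data; exactness on linear
(degree 1) and quadratic (degree 2) data is tested. Clusters are named C1,
C2, … by descending summed member frequency at the final timepoint (ties by
smallest member ID); clusters ending below `min_cluster_frequency`
(default 0.01) are flagged minor, never dropped.

## Wright–Fisher simulator

State is a set of sub-lineages (barcode, fitness w, cell count) at constant
population size N. Per generation: expected offspring shares ∝ n_i·w_i with
w = 1 + Σs (additive selection coefficients within a genome); next-generation
counts are one multinomial draw of size N; beneficial mutations arise
Poisson(μ·n_i) per sub-lineage, each founding a one-cell sub-lineage that
keeps the parental barcode; at sampling times, reads are one multinomial
draw of the configured depth over barcode frequencies (no PCR artifacts, by
design). Runs are bit-reproducible for a fixed seed.

Configuration supports standing variation (per-barcode founder fitness and
founder cell counts; founder fitness is recorded in the truth table as
generation-0 mutations) and *scheduled* mutations — deterministic injections
(barcode, generation, s, cell fraction) used by the benchmark scenarios to
stage reproducible sweeps. Deleterious de-novo supply is excluded by default
(the DFE models beneficial supply); founder fitness may be negative.

Truth output per barcode: mutation events, realized mean fitness at each
sampling time, final true frequency, and fate. Fate is `extinct` at zero
cells, `fixed` at final frequency ≥ `fixation_threshold`, else
`segregating`. The threshold defaults to 1.0 (strict fixation); the fixation
benchmark sets 0.5 — there a majority lineage carrying the top fitness class
is destined to fix, and calling it `fixed` lets the scenario expose both the
committed sweep and the not-yet-extinct losers at the final sampling time
(a strict threshold and surviving losers are mutually exclusive).

Engine correctness is checked three ways: the neutral single-step martingale
E[f(t+1)|f(t)] = f(t) over 1000 replicates (3 SE); the deterministic
selection limit at N = 10⁶ against the logistic map f' = f(1+s)/(1+sf)
within 1% until f > 0.99; and the fixation probability of a single mutant
(s = 0.01, N = 10⁴, 10⁴ replicates) against the diffusion approximation
(1−e^{−2s})/(1−e^{−2Ns}). The fixation-probability run uses a vectorized
two-type reduction with the same binomial sampling law (the marginal of the
engine's multinomial); a separate test confirms the full engine's one-step
law matches it. Neutral heterozygosity decays by (1 − 1/N) per generation
within a 3σ replicate band.

## Benchmark scenarios

`make_benchmark_scenario(name, scale)` returns canned configurations. At
scale 1 the fixation benchmark is a 10⁷-cell population with 10⁵ barcodes
evolved 1125 generations and sampled at 17 evenly spaced times.

**Desk-scale runs.** `scale` multiplies the population and barcode count;
the run length shrinks as 1125·scale^(2/3) and all selection coefficients
(and mutation-injection times) are rescaled so s·T is invariant. Rationale:
log-frequency drift variance of a lineage grows like T divided by its cell
count. Shrinking N by 100× while keeping 1125 generations would multiply
drift a hundredfold and erase the very trajectory structure the benchmark
exists to exhibit; shortening time and strengthening selection preserves the
deterministic log-trajectories while keeping drift near its full-scale
level. At scale 0.01 this gives N = 10⁵, 1000 barcodes, 52 generations, and
per-generation selection coefficients up to ≈0.28 — large per generation,
but corresponding to ordinary values (≤0.013) at the full-scale run length.

**Fixation scenario.** Six trajectory families plus a doomed background,
tuned (as this benchmark requires) so the default pipeline resolves exactly
six dominant clusters:

| class | barcodes (per 1000) | founding share | dynamics |
|---|---|---|---|
| C1 | 1 | 1.5% | beneficial mutation at 0.22·T (s·T ≈ 10.4) — sweeps to ~0.7, destined to fix |
| C2 | 2 | 0.5% | stronger mutation at 0.51·T — late riser, still below C1 at the end |
| C3 | 3 | 0.4% | weak mutation at 0.04·T — early riser, outcompeted mid-run |
| C4 | 8 | 3.3% | standing s·T ≈ 3.2 — rises, peaks, declines |
| C5 | 12 | 8.5% | standing s·T ≈ 1.7 — shallow rise, long decline |
| C6 | 25 | 40.7% | neutral bulk — monotone decline |
| background | ~949 | 45.0% | deleterious; drops below detection early and is removed by the persistence filter |

The class geometry was designed with a deterministic replicator model
(exact for constant fitness: f_i(t) ∝ p_i e^{s_i t}), searching mutation
times, strengths and shares to maximize the minimum between-class
correlation distance minus the largest within-class noise distance, subject
to every family holding ≥ 2% of the population at the last sample and the
fixer ending between 0.55 and 0.85. Staggered mutation-driven sweeps are
essential: by the cosine-family argument above, constant-fitness classes
alone cannot produce six mutually separable shapes.

The benchmark ships with a recommended cut height
(`BENCHMARK_CUT_HEIGHTS["fixation"] = 0.06`), the midpoint of the
dominant-cluster plateau of the threshold sweep at desk scale — fixed once
at design time, playing the role of the user's threshold choice in
automated runs. With it, the default Pearson+UPGMA pipeline yields exactly
six clusters with final summed frequency ≥ 1% in ~80–95% of seeds, the
most abundant cluster contains the fixing lineage in effectively all seeds,
and the cluster/true-class agreement is ARI ≈ 1.

**Fitness-class benchmark.** `make_fitness_class_config()` builds three
standing classes s = 0, 0.05, 0.10 at N = 10⁵, sequencing depth 10⁶, 17
sampling times over 56 generations, with cell shares (0.68, 0.30, 0.02) and
(20, 12, 4) barcodes per class. The fittest class is rare on purpose: with
equal shares the initial mean fitness sits exactly at 0.05 and the middle
class's trajectory is flat, hence shapeless under correlation distance. In
the rare-fittest design the middle class rises then falls as the top class
takes over, and some cut height recovers the classes with ARI ≥ 0.9 in
every tested seed.

**Other scenarios.** `neutral` (no mutation, no fitness variation) and
`clonal_interference` (de-novo beneficial supply, exponential DFE with mean
s·T ≈ 34 at desk scale, Nμ = 1 per generation at scale 0.01) are provided
for exploration and engine tests.

## Pipeline

`run_pipeline` executes read → frequencies → diversity → filter → distances
→ linkage → threshold sweep → cut → consensus → ranking → plots, writing
CSV/Newick/PNG outputs, a rejection report and a structured run log stamped
with the config hash and seed. Diversity is computed on the **unfiltered**
matrix: effective diversity is a property of the whole population, and
filtered frequencies intentionally no longer sum to one (the `diversity` CLI
subcommand normalizes whatever table it is given, so diversity of the
filtered subpopulation is still one command away). Outputs are
deterministic: identical config and input give byte-identical non-image
files. Tests assert only on the plot-data companions, never on rendered
pixels.

## What the simulations do and do not show

The generator reproduces the measurement model of barcoded evolution
experiments — heritable neutral tags, fitness carried by unobserved
mutations, multinomial sequencing noise — and therefore exercises the full
inference chain end to end with known truth. It does not model serial-passage
bottlenecks, PCR jackpotting or barcode-calling errors, ecological
interactions between species, or recombination; passing its benchmarks shows
the pipeline recovers fitness-structured lineage families under drift and
multinomial sampling noise, not that it is robust to those unmodeled
artifacts. Real data with strong PCR artifacts should be corrected upstream.

## Numerical choices and degenerate inputs

* Frequency columns must sum to 1 within 10⁻⁹ (hill numbers validate this).
* Pearson requires ≥ 3 timepoints and nonzero variance; errors name the
  offending barcode.
* DTW with a window narrower than the length difference has no admissible
  path and errors.
* The threshold grid is linear from 0 to the maximum merge height
  (default 100 points); a cut below the first merge yields all singletons,
  above the last merge one cluster.
* LOESS windows with zero bandwidth (all window points at the evaluation
  time) return the window mean; rank-deficient local fits fall back to the
  weighted mean.
* All tie-breaks (merge order, cluster labels, ranking) are lexicographic in
  barcode ID, making outputs bit-reproducible.

## Known limitations

* Correlation distance cannot separate lineages whose log-trajectories are
  affinely related (constant fitness differentials under a shared
  normalizer) — a property of the statistic, not the implementation; DTW on
  log frequencies is the alternative when absolute level changes matter.
* Automatic threshold rules (`knee`, `plateau`) are conveniences; on deeply
  hierarchical data they can land a level above or below the structure of
  interest, and the threshold sweep should be inspected.
* UPGMC is defined here in trajectory space; its heights are not comparable
  to UPGMA heights and may invert.
* The simulator's desk-scale rescaling preserves deterministic trajectories
  and approximate drift levels, not the full-scale distribution of rare
  events (e.g. establishment probabilities of single-cell mutants differ).
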