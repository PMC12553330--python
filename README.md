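# clonaltraj

Identify **dominant clonal lineages** in DNA-barcode lineage-tracking time
series by clustering frequency trajectories, and validate the whole chain
against a built-in Wright–Fisher simulator of barcoded evolution.

High-resolution lineage tracking tags cells with heritable chromosomal DNA
barcodes and reads their abundances over time by amplicon sequencing. In a
polyclonal population, barcodes whose frequency trajectories move together
mark lineages of comparable relative fitness — clones rising on a beneficial
mutation, competing under clonal interference, or dying out. `clonaltraj`
turns a long-format table of `(barcode ID, time, read count)` into:

* **lineage-dynamics views** of barcode frequencies (log or linear scale);
* the **effective diversity** (Hill number) time series
  D_q(t) = (Σ_k f_k(t)^q)^{1/(1−q)} — q=0 richness, q=1 the exponential of
  Shannon entropy, q=∞ the inverse of the top barcode's frequency;
* a **trajectory distance matrix** (Pearson correlation distance `1 − r`, or
  dynamic time warping with |Δ| cost), by default on log10 frequencies with a
  detection floor;
* **hierarchical clustering** (UPGMA or UPGMC) with a cut-height sweep that
  reports cluster counts and centroid separations so the user can pick a
  threshold;
* **clonal clusters**: per-cluster LOESS consensus trajectories, ranked C1,
  C2, … by summed member frequency at the final timepoint, with sub-1%
  clusters flagged as minor.

The simulator evolves N barcoded cells under multinomial Wright–Fisher
resampling with de-novo beneficial mutations (sub-lineages keep the parental
barcode — sequencing sees only the barcode, which is exactly why trajectory
clustering, not genotype reading, is the inference problem). Every lineage's
true fitness and fate are recorded, so cluster calls can be scored with the
adjusted Rand index.

## Worked example

Simulate the barcoded-evolution benchmark (a 10⁵-cell population, 1000
barcodes, one lineage destined to fix, a late riser and several losers),
filter, cluster and score against the simulation truth:

```python
from clonaltraj import (make_benchmark_scenario, simulate, to_frequencies,
                        apply_filters, FilterSpec, build_distance_matrix,
                        linkage, call_clonal_clusters, evaluate_recovery,
                        BENCHMARK_CUT_HEIGHTS)

cfg = make_benchmark_scenario("fixation", scale=0.01, seed=7)
res = simulate(cfg)

fm = to_frequencies(res.observed)
fmf, rejected = apply_filters(fm, FilterSpec(1e-4, 12, fm.n_timepoints))
print(f"{fmf.n_barcodes} of {fm.n_barcodes} barcodes pass the filters")

dm = build_distance_matrix(fmf, metric="pearson", transform="log10_floored")
tree = linkage(dm, "upgma")
clusters = call_clonal_clusters(fmf, dm, tree,
                                height=BENCHMARK_CUT_HEIGHTS["fixation"])
for name in clusters.rank:
    print(f"{name}: {len(clusters.members(name)):3d} barcodes, "
          f"final frequency {clusters.final_frequency[name]:.3f}")

report = evaluate_recovery(res, clusters)
print(f"adjusted Rand index vs true fitness classes: {report.ari:.3f}")
```

Output:

```
51 of 1000 barcodes pass the filters
C1:   1 barcodes, final frequency 0.700
C2:   2 barcodes, final frequency 0.120
C3:   8 barcodes, final frequency 0.059
C4:  12 barcodes, final frequency 0.045
C5:   3 barcodes, final frequency 0.039
C6:  25 barcodes, final frequency 0.038
adjusted Rand index vs true fitness classes: 1.000
```

Reading: the mean-frequency (>10⁻⁴) and persistence (≥12 of 17 timepoints)
filters strip the low-fitness background; the six surviving trajectory
families are recovered as six clusters, each holding ≥1% of the population
at the end. C1 is the single barcode that swept to 70% on a strong beneficial
mutation; C2 is the late riser that was still climbing when sampling ended;
C3–C6 are lineage families lost at staggered times. ARI = 1.0 means the
clustering matches the simulated fitness classes exactly.

The same pipeline is available from the shell:

```bash
clonaltraj simulate --scenario fixation --scale 0.01 --seed 7 --out sim.csv --truth truth.csv
clonaltraj filter --min-mean-freq 1e-4 --min-persistence 12 --in sim.csv --out filtered.csv --report rejected.csv
clonaltraj diversity --orders 0,1,2,inf --in sim.csv --out diversity.csv
clonaltraj cluster --in filtered.csv --cut-height 0.06 --out-prefix run
clonaltraj run --config pipeline.yaml --in sim.csv --out-dir results/
```

Every plot command writes a tidy CSV next to the image with exactly the
plotted values; `run` also writes a structured run log (stage, parameters,
input hash, config hash) and is byte-reproducible for a fixed config.

For array-based workflows the same steps exist as scikit-learn estimators
(`TrajectoryFilter`, `TrajectoryDistance`, `ClonalClusterer`) operating on a
`(n_barcodes, n_timepoints)` frequency matrix, composable with sklearn
pipelines and model selection.

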