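"""Forward Wright-Fisher simulation of a barcoded evolving population.

The simulator is the package's validation oracle: it produces barcode
read-count time series *with known per-lineage fitness*, so cluster calls can
be scored against the truth.

Model
-----
A constant population of ``N`` cells carries heritable chromosomal barcodes.
Each generation:

1. every sub-lineage i (cells sharing a barcode *and* a mutation set) has
   expected offspring share proportional to ``n_i * w_i``, with multiplicative
   fitness ``w_i = 1 + sum of its selection coefficients``;
2. next-generation counts are a single multinomial draw of size ``N``;
3. new beneficial mutations arise Poisson(``mu * n_i``) per sub-lineage, each
   founding a new sub-lineage of one cell that keeps the parent barcode —
   sequencing reads only the barcode, so a sweep by a mutant sub-lineage is
   visible only as its parent barcode's trajectory;
4. at each sampling time, reads are one multinomial draw of size
   ``reads_per_sample`` over the barcode frequencies (no PCR artifacts).

Standing founder fitness variation is supported (``founder_fitness``): it is
recorded in the truth table as generation-0 mutations, modelling pre-existing
beneficial mutations in the founding pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .core import BarcodeTimeSeries

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "LineageTruth",
    "simulate",
    "make_benchmark_scenario",
    "make_fitness_class_config",
    "evaluate_recovery",
    "fixation_probability",
    "BENCHMARK_CUT_HEIGHTS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Wright-Fisher run.

    ``dfe`` is the distribution of selection coefficients of de novo
    beneficial mutations: ``("exponential", mean)``, ``("fixed", s)`` or
    ``"none"``. ``founder_fitness`` / ``founder_counts`` optionally assign
    per-barcode initial selection coefficients and cell counts (defaults:
    all-neutral founders, near-uniform counts). ``scheduled_mutations``
    injects deterministic mutation events ``(barcode, generation, s,
    cell_fraction)``: at that generation the given fraction of the barcode's
    cells founds a sub-lineage carrying an extra coefficient ``s`` (used by
    benchmark scenarios to stage reproducible sweeps). ``barcode_classes``
    optionally names each barcode's true fitness class for recovery scoring.
    ``fixation_threshold`` is the
    final true frequency above which a barcode's fate is called ``fixed``
    (1.0 = strict fixation; benchmark scenarios with an incomplete sweep use
    0.5, i.e. a majority lineage destined to fix).
    """

    population_size: int
    n_barcodes: int
    n_generations: int
    mutation_rate: float = 0.0
    dfe: tuple | str = "none"
    sampling_times: tuple[int, ...] = ()
    reads_per_sample: int = 1_000_000
    seed: int = 0
    founder_fitness: tuple[float, ...] | None = None
    founder_counts: tuple[int, ...] | None = None
    scheduled_mutations: tuple[tuple[int, int, float, float], ...] = ()
    barcode_classes: tuple[str, ...] | None = None
    fixation_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")
        if not 0 < self.n_barcodes <= self.population_size:
            raise ValueError("need 0 < n_barcodes <= population_size")
        st = tuple(int(t) for t in self.sampling_times)
        if any(t < 0 or t > self.n_generations for t in st):
            raise ValueError("sampling_times must lie in [0, n_generations]")
        if list(st) != sorted(set(st)):
            raise ValueError("sampling_times must be strictly increasing")
        object.__setattr__(self, "sampling_times", st)
        if self.founder_fitness is not None and len(self.founder_fitness) != self.n_barcodes:
            raise ValueError("founder_fitness length must equal n_barcodes")
        if self.founder_counts is not None:
            fc = tuple(int(c) for c in self.founder_counts)
            if len(fc) != self.n_barcodes or sum(fc) != self.population_size:
                raise ValueError("founder_counts must sum to population_size")
            object.__setattr__(self, "founder_counts", fc)
        for b, g, _s, frac in self.scheduled_mutations:
            if not 0 <= b < self.n_barcodes:
                raise ValueError("scheduled mutation on unknown barcode")
            if not 0 < g <= self.n_generations:
                raise ValueError("scheduled mutation outside the run")
            if not 0 < frac <= 1:
                raise ValueError("scheduled mutation cell fraction must be in (0, 1]")
        if self.barcode_classes is not None and len(self.barcode_classes) != self.n_barcodes:
            raise ValueError("barcode_classes length must equal n_barcodes")


@dataclass(frozen=True)
class LineageTruth:
    """Ground truth per barcode lineage."""

    barcode_ids: list[str]
    founder_fitness: np.ndarray  # selection coefficient of each founder
    mutations: pd.DataFrame  # columns: ID, s, generation (generation 0 = founder)
    true_frequency: np.ndarray  # (n_barcodes, n_samples)
    mean_fitness: np.ndarray  # realized mean w per barcode per sample (NaN extinct)
    fate: np.ndarray  # "fixed" | "extinct" | "segregating"
    named_classes: tuple[str, ...] | None = None

    def class_labels(self) -> np.ndarray:
        """True class labels: named classes if configured, else founder
        fitness classes when founders vary, else fate."""
        if self.named_classes is not None:
            return np.asarray(self.named_classes, dtype=object)
        if np.unique(self.founder_fitness).size > 1:
            return np.array(
                [f"s={s:.6g}" for s in self.founder_fitness], dtype=object
            )
        return self.fate.astype(object)

    def to_frame(self) -> pd.DataFrame:
        n_mut = self.mutations.groupby("ID").size() if len(self.mutations) else {}
        return pd.DataFrame(
            {
                "ID": self.barcode_ids,
                "founder_s": self.founder_fitness,
                "n_mutations": [
                    int(n_mut.get(b, 0)) if len(self.mutations) else 0
                    for b in self.barcode_ids
                ],
                "final_frequency": self.true_frequency[:, -1],
                "fate": self.fate,
            }
        )


@dataclass(frozen=True)
class SimulationResult:
    observed: BarcodeTimeSeries
    truth: LineageTruth
    config: SimulationConfig = field(repr=False)


def _draw_s(rng: np.random.Generator, dfe) -> float:
    if isinstance(dfe, tuple):
        kind, param = dfe
        if kind == "exponential":
            return float(rng.exponential(param))
        if kind == "fixed":
            return float(param)
    raise ValueError(f"cannot draw from dfe {dfe!r}")


def _allocate(total: int, k: int) -> np.ndarray:
    """Split ``total`` cells over ``k`` lineages as evenly as possible."""
    base, rem = divmod(total, k)
    out = np.full(k, base, dtype=np.int64)
    out[:rem] += 1
    return out


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run one Wright-Fisher simulation; bit-reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    N = config.population_size
    B = config.n_barcodes
    barcode_ids = [f"BC{i:06d}" for i in range(B)]

    founder_s = (
        np.asarray(config.founder_fitness, dtype=float)
        if config.founder_fitness is not None
        else np.zeros(B)
    )
    counts = (
        np.asarray(config.founder_counts, dtype=np.int64)
        if config.founder_counts is not None
        else _allocate(N, B)
    )
    # sub-lineage state
    lin_barcode = np.arange(B, dtype=np.int64)
    lin_w = 1.0 + founder_s.copy()
    lin_count = counts.copy()

    mut_rows = [
        {"ID": barcode_ids[i], "s": founder_s[i], "generation": 0}
        for i in np.flatnonzero(founder_s != 0.0)
    ]

    sample_set = set(config.sampling_times)
    n_samples = len(config.sampling_times)
    true_freq = np.zeros((B, n_samples))
    mean_fit = np.full((B, n_samples), np.nan)
    reads = np.zeros((B, n_samples), dtype=np.int64)
    sample_col = {t: i for i, t in enumerate(config.sampling_times)}

    def record(gen: int) -> None:
        col = sample_col[gen]
        bc_counts = np.bincount(lin_barcode, weights=lin_count, minlength=B)
        freqs = bc_counts / N
        true_freq[:, col] = freqs
        fit_sum = np.bincount(lin_barcode, weights=lin_count * lin_w, minlength=B)
        alive = bc_counts > 0
        mean_fit[alive, col] = fit_sum[alive] / bc_counts[alive]
        reads[:, col] = rng.multinomial(config.reads_per_sample, freqs)

    if 0 in sample_set:
        record(0)

    scheduled: dict[int, list[tuple[int, float, float]]] = {}
    for b, g, s, frac in config.scheduled_mutations:
        scheduled.setdefault(int(g), []).append((int(b), float(s), float(frac)))

    use_mutation = config.mutation_rate > 0 and config.dfe != "none"
    for gen in range(1, config.n_generations + 1):
        weights = lin_count * lin_w
        p = weights / weights.sum()
        lin_count = rng.multinomial(N, p)
        if gen in scheduled:
            for b, s, frac in scheduled[gen]:
                owner = np.flatnonzero(lin_barcode == b)
                if owner.size == 0:
                    continue  # lineage already extinct
                src = owner[np.argmax(lin_count[owner])]
                n_move = min(
                    max(int(round(frac * lin_count[owner].sum())), 1),
                    int(lin_count[src]),
                )
                if n_move == 0:
                    continue
                lin_count[src] -= n_move
                lin_barcode = np.append(lin_barcode, b)
                lin_w = np.append(lin_w, lin_w[src] + s)
                lin_count = np.append(lin_count, n_move)
                mut_rows.append(
                    {"ID": barcode_ids[b], "s": s, "generation": gen}
                )
        if use_mutation:
            n_mut = rng.poisson(config.mutation_rate * lin_count)
            n_mut = np.minimum(n_mut, lin_count)
            hit = np.flatnonzero(n_mut)
            if hit.size:
                new_b, new_w, new_n = [], [], []
                for i in hit:
                    for _ in range(int(n_mut[i])):
                        s = _draw_s(rng, config.dfe)
                        new_b.append(lin_barcode[i])
                        new_w.append(lin_w[i] + s)
                        new_n.append(1)
                        mut_rows.append(
                            {
                                "ID": barcode_ids[lin_barcode[i]],
                                "s": s,
                                "generation": gen,
                            }
                        )
                    lin_count[i] -= int(n_mut[i])
                lin_barcode = np.concatenate([lin_barcode, np.asarray(new_b)])
                lin_w = np.concatenate([lin_w, np.asarray(new_w)])
                lin_count = np.concatenate([lin_count, np.asarray(new_n)])
        keep = lin_count > 0
        lin_barcode, lin_w, lin_count = lin_barcode[keep], lin_w[keep], lin_count[keep]
        if gen in sample_set:
            record(gen)

    final_counts = np.bincount(lin_barcode, weights=lin_count, minlength=B)
    final_freq = final_counts / N
    fate = np.where(
        final_counts == 0,
        "extinct",
        np.where(final_freq >= config.fixation_threshold, "fixed", "segregating"),
    ).astype(object)

    mutations = pd.DataFrame(mut_rows, columns=["ID", "s", "generation"])
    observed = BarcodeTimeSeries(
        barcode_ids, np.asarray(config.sampling_times, dtype=float), reads
    )
    truth = LineageTruth(
        barcode_ids, founder_s, mutations, true_freq, mean_fit, fate,
        named_classes=config.barcode_classes,
    )
    return SimulationResult(observed, truth, config)


# --- benchmark scenarios ---------------------------------------------------

#: Fixation benchmark classes:
#: (name, n_barcodes, founding-cell share, founder s (base units),
#:  scheduled mutation (generation fraction of run, s base, cell fraction)).
#: C1 gains a strong beneficial mutation early and sweeps to dominance; C2
#: gains a weaker one later, rises, and is outcompeted near the end; C3-C5
#: carry standing fitness advantages lost at staggered times; C6 is the
#: neutral class; the low-fitness background falls below detection early, so
#: the persistence filter removes it before clustering. Selection
#: coefficients are in base units (per generation at the full-scale run
#: length) and are rescaled with the run length so s*T is scale-invariant.
#: Six shape-distinct dominant trajectory families result.
_FIXATION_CLASSES = (
    ("C1", 1, 0.0153, 0.0, (0.221, 0.0092, 0.3)),   # the fixer
    ("C2", 2, 0.0052, 0.0, (0.514, 0.0129, 0.4)),   # late riser, outcompeted
    ("C3", 3, 0.0043, 0.0, (0.0375, 0.0056, 0.3)),  # early riser, lost mid-run
    ("C4", 8, 0.0326, 0.0028, None),
    ("C5", 12, 0.0854, 0.0015, None),
    ("C6", 25, 0.4072, 0.0, None),                  # neutral bulk
    ("background", None, 0.45, -0.01, None),        # doomed background
)

#: Recommended dendrogram cut height per benchmark scenario, chosen once from
#: the threshold sweep (the flat stretch of the cluster-count curve between
#: within-class and between-class merge heights at desk scale).
BENCHMARK_CUT_HEIGHTS = {"fixation": 0.06}

_BASE_N = 10_000_000
_BASE_BARCODES = 100_000
_BASE_GENERATIONS = 1125
_N_SAMPLES = 17


def _default_sampling(n_generations: int) -> tuple[int, ...]:
    # dedupe: at very small scales 17 rounded times may collide
    times = np.unique(np.round(np.linspace(0, n_generations, _N_SAMPLES)))
    return tuple(int(t) for t in times)


def _scaled_duration(scale: float) -> int:
    """Run length for desk-scale runs.

    Shrinking the population inflates genetic drift (log-frequency drift
    variance grows like generations / lineage size), so a faithful scaled-down
    run also shortens time (as scale^(2/3)) and rescales selection
    coefficients by the inverse factor: the deterministic log-trajectories
    (s * t) are preserved while drift stays comparable to the full-scale run.
    """
    return int(round(_BASE_GENERATIONS * scale ** (2.0 / 3.0)))


def make_benchmark_scenario(
    name: str, scale: float = 1.0, seed: int = 0
) -> SimulationConfig:
    """Canned simulation configurations for pipeline validation.

    ``scale`` in (0, 1] multiplies the population size and barcode count for
    desk-scale runs (at scale 1: N = 1e7 cells, 1e5 barcodes, 1125
    generations, 17 evenly spaced sampling times).

    * ``neutral`` — no mutation, no fitness variation.
    * ``fixation`` — standing fitness classes tuned so one lineage sweeps to
      dominance while a late riser and several weaker classes are lost at
      staggered times (six trajectory families).
    * ``clonal_interference`` — de novo beneficial mutations (exponential
      DFE) at a supply rate high enough that competing beneficial lineages
      coexist through the run.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    N = int(round(_BASE_N * scale))
    B = int(round(_BASE_BARCODES * scale))
    T = _scaled_duration(scale)
    s_factor = _BASE_GENERATIONS / T  # keeps s * T invariant across scales
    common = dict(
        population_size=N,
        n_barcodes=B,
        n_generations=T,
        sampling_times=_default_sampling(T),
        reads_per_sample=1_000_000,
        seed=seed,
    )
    if name == "neutral":
        return SimulationConfig(mutation_rate=0.0, dfe="none", **common)
    if name == "clonal_interference":
        return SimulationConfig(
            mutation_rate=1e-5, dfe=("exponential", 0.03 * s_factor), **common
        )
    if name == "fixation":
        fitness = np.zeros(B)
        cells = np.zeros(B, dtype=np.int64)
        classes: list[str] = []
        mutations: list[tuple[int, int, float, float]] = []
        start = 0
        for cname, k, share, s0, mut in _FIXATION_CLASSES:
            if k is None:
                k = B - start  # background takes the remaining barcodes
            else:
                # class barcode counts are stated for B = 1000 and scale with B
                k = max(int(round(k * B / 1000)), 1)
            fitness[start : start + k] = s0 * s_factor
            cells[start : start + k] = _allocate(int(round(share * N)), k)
            if mut is not None:
                g_frac, s_mut, cell_frac = mut
                g = max(int(round(g_frac * T)), 1)
                for b in range(start, start + k):
                    mutations.append((b, g, s_mut * s_factor, cell_frac))
            classes.extend([cname] * k)
            start += k
        cells[-1] += N - cells.sum()  # exact population size
        return SimulationConfig(
            mutation_rate=0.0,
            dfe="none",
            founder_fitness=tuple(fitness),
            founder_counts=tuple(cells),
            scheduled_mutations=tuple(mutations),
            barcode_classes=tuple(classes),
            fixation_threshold=0.5,
            **common,
        )
    raise ValueError(f"unknown scenario {name!r}")


def make_fitness_class_config(
    s_values=(0.0, 0.05, 0.10),
    shares=(0.68, 0.30, 0.02),
    barcodes_per_class=(20, 12, 4),
    population_size: int = 100_000,
    n_generations: int = 56,
    reads_per_sample: int = 1_000_000,
    seed: int = 0,
) -> SimulationConfig:
    """Standing fitness classes with known labels, for recovery benchmarks.

    Each class i holds ``barcodes_per_class[i]`` barcodes sharing the founder
    selection coefficient ``s_values[i]`` and the founding-cell fraction
    ``shares[i]``. The default has a rare strongly beneficial class (2% of
    cells at s = 0.10), so the intermediate class rises while the mean
    fitness is below its s and declines once the fittest class takes over —
    three shape-distinct trajectory families. 17 evenly spaced sampling
    times.
    """
    if not len(s_values) == len(shares) == len(barcodes_per_class):
        raise ValueError("class specs must have equal lengths")
    if abs(sum(shares) - 1.0) > 1e-9:
        raise ValueError("shares must sum to 1")
    N = population_size
    fitness = np.concatenate(
        [np.full(k, s) for k, s in zip(barcodes_per_class, s_values)]
    )
    classes = np.concatenate(
        [np.full(k, f"s={s:g}") for k, s in zip(barcodes_per_class, s_values)]
    )
    cells = np.concatenate(
        [_allocate(int(round(sh * N)), k) for sh, k in zip(shares, barcodes_per_class)]
    )
    cells[-1] += N - cells.sum()
    samp = tuple(int(round(x)) for x in np.linspace(0, n_generations, _N_SAMPLES))
    return SimulationConfig(
        population_size=N,
        n_barcodes=int(fitness.size),
        n_generations=n_generations,
        sampling_times=samp,
        reads_per_sample=reads_per_sample,
        seed=seed,
        founder_fitness=tuple(fitness),
        founder_counts=tuple(int(c) for c in cells),
        barcode_classes=tuple(classes),
    )


# --- recovery scoring ------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    """Agreement between called clusters and simulated ground truth."""

    ari: float
    cluster_fitness: pd.DataFrame  # cluster, Time, n, mean_fitness, sd


def evaluate_recovery(result: SimulationResult, clusters) -> RecoveryReport:
    """Score a clustering against the simulation truth.

    ``clusters`` is a :class:`~clonaltraj.clustering.ClonalClusterSet`
    computed on ``result.observed`` (possibly on a filtered subset of
    barcodes). Reports the Adjusted Rand Index between cluster labels and
    true fitness-class labels, and the per-cluster distribution of realized
    lineage fitness at each sampling time.
    """
    truth = result.truth
    idx = {b: i for i, b in enumerate(truth.barcode_ids)}
    clustered = sorted(clusters.assignment)
    missing = [b for b in clustered if b not in idx]
    if missing:
        raise ValueError(
            f"clustered barcodes absent from the simulation: {missing[:3]}..."
        )
    labels_true = truth.class_labels()
    y_true = [labels_true[idx[b]] for b in clustered]
    y_pred = [clusters.assignment[b] for b in clustered]
    ari = float(adjusted_rand_score(y_true, y_pred))

    times = result.observed.timepoints
    rows = []
    for cname in clusters.rank:
        mem = [idx[b] for b in clusters.members(cname)]
        for t_i, t in enumerate(times):
            w = truth.mean_fitness[mem, t_i]
            w = w[~np.isnan(w)]
            rows.append(
                {
                    "cluster": cname,
                    "Time": t,
                    "n": int(w.size),
                    "mean_fitness": float(w.mean()) if w.size else np.nan,
                    "sd": float(w.std(ddof=1)) if w.size > 1 else np.nan,
                }
            )
    return RecoveryReport(ari, pd.DataFrame(rows))


# --- analytic-check helper -------------------------------------------------

def fixation_probability(
    population_size: int,
    s: float,
    n0: int = 1,
    n_replicates: int = 10_000,
    seed: int = 0,
    max_generations: int = 1_000_000,
) -> float:
    """Monte-Carlo fixation probability of a beneficial mutant.

    Vectorized two-type reduction of the same Wright-Fisher sampling law used
    by :func:`simulate` (the mutant count's marginal is binomial with
    fitness-weighted success probability). Used to check the engine against
    the diffusion approximation.
    """
    rng = np.random.default_rng(seed)
    N = population_size
    n = np.full(n_replicates, n0, dtype=np.int64)
    active = np.ones(n_replicates, dtype=bool)
    fixed = 0
    for _ in range(max_generations):
        if not active.any():
            break
        na = n[active]
        p = na * (1.0 + s) / (N + na * s)
        na = rng.binomial(N, p)
        done_fix = na == N
        done_ext = na == 0
        fixed += int(done_fix.sum())
        n[active] = na
        idx = np.flatnonzero(active)
        active[idx[done_fix | done_ext]] = False
    return fixed / n_replicates
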