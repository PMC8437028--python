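"""Synthetic pooled count tables with known genotype-dependent mortality.

The generator emulates a pooled larval-cohort experiment: a composite embryo
pool is split into replicate cultures, sampled repeatedly across development
(days post-fertilization), and each sample is sequenced as a pool, yielding
biallelic read counts per locus.  Mortality is massive (type III
survivorship, ~4% cumulative survival by day 22) and may be
genotype-dependent according to one of four fitness scenarios:

``neutral``
    all three genotypes share the same viability in every interval;
``directional``
    the major homozygote is consistently fittest (w_AA >= w_AB >= w_BB),
    emulating selection against a deleterious minor allele (genetic load);
``balanced``
    the direction of selection between the homozygotes reverses at least
    once across development (temporally balanced selection);
``overdominant``
    the heterozygote is strictly fittest in every interval.

True genotype trajectories follow the deterministic Hardy-Weinberg fitness
update (see :mod:`poolsel.hw`); observed counts add binomial sampling noise
per replicate at uniformly drawn read depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from poolsel import hw

SCENARIOS = ("neutral", "directional", "balanced", "overdominant")

#: Default sampling schedule, in days post-fertilization.  Day 0 is the
#: unreplicated fertilized-egg pool; later days have replicated cultures.
DEFAULT_SAMPLING_DAYS = (0, 2, 6, 10, 14, 16, 22)

#: Target cumulative survival per sampling day (type III survivorship:
#: heavy losses early and again around metamorphosis, ~4% left at day 22).
DEFAULT_SURVIVAL_SHAPE = {0: 1.0, 2: 0.55, 6: 0.40, 10: 0.30, 14: 0.22, 16: 0.15, 22: 0.04}

DEFAULT_DEPTH_RANGE = (50, 1000)

COUNT_COLUMNS = ["locus_id", "scaffold", "position", "tag_id", "replicate", "day", "n_major", "n_minor"]
SURVIVAL_COLUMNS = ["replicate", "day", "cum_survival"]

EGG_REPLICATE = "egg"


@dataclass
class SimulationScenario:
    """Complete parameterization of one synthetic experiment."""

    n_loci: int
    n_replicates: int
    sampling_days: tuple[int, ...]
    initial_maf: np.ndarray  # (n_loci,)
    fitness_schedule: np.ndarray  # (n_loci, n_intervals, 3)
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE
    survival_shape: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SURVIVAL_SHAPE))
    rng_seed: int = 0
    label: str = "custom"

    def __post_init__(self) -> None:
        days = tuple(self.sampling_days)
        if days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"sampling_days must be strictly increasing and start at 0, got {days}")
        self.sampling_days = days
        self.initial_maf = np.asarray(self.initial_maf, dtype=float)
        if self.initial_maf.shape != (self.n_loci,):
            raise ValueError("initial_maf must have one entry per locus")
        if np.any((self.initial_maf <= 0.0) | (self.initial_maf > 0.5)):
            raise ValueError("initial minor-allele frequencies must lie in (0, 0.5]")
        self.fitness_schedule = np.asarray(self.fitness_schedule, dtype=float)
        expected = (self.n_loci, len(days) - 1, 3)
        if self.fitness_schedule.shape != expected:
            raise ValueError(
                f"fitness_schedule has shape {self.fitness_schedule.shape}, expected {expected}"
            )
        if np.any((self.fitness_schedule < 0.0) | (self.fitness_schedule > 1.0)):
            raise ValueError("fitness values must lie in [0, 1]")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid depth range {self.depth_range}")


@dataclass
class GroundTruth:
    """True per-locus trajectories underlying a synthetic dataset."""

    days: tuple[int, ...]
    locus_ids: list[str]
    states: np.ndarray  # (n_loci, n_days, 3) genotype states on the simplex
    maf: np.ndarray  # (n_loci, n_days)
    survival: np.ndarray  # (n_loci, n_days) cumulative survival

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def cohort_survival(self) -> np.ndarray:
        """Cumulative survival of the whole cohort (mean across loci)."""
        return self.survival.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, locus in enumerate(self.locus_ids):
            for j, day in enumerate(self.days):
                rows.append(
                    {
                        "locus_id": locus,
                        "day": day,
                        "f_AA": self.states[i, j, 0],
                        "f_AB": self.states[i, j, 1],
                        "f_BB": self.states[i, j, 2],
                        "maf": self.maf[i, j],
                        "cum_survival": self.survival[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _base_interval_viability(sampling_days, survival_shape) -> np.ndarray:
    """Per-interval cohort viability implied by the target survival curve."""
    surv = [survival_shape[d] for d in sampling_days]
    if any(b > a for a, b in zip(surv, surv[1:])):
        raise ValueError("survival shape must be non-increasing over days")
    return np.array([b / a for a, b in zip(surv, surv[1:])])


def simulate_fitness_schedule(
    n_loci: int,
    n_intervals: int,
    scenario_label: str,
    seed,
    base_viability: np.ndarray | None = None,
    effect_range: tuple[float, float] = (0.1, 0.3),
) -> np.ndarray:
    """Draw a per-locus, per-interval fitness schedule for one scenario.

    ``base_viability`` sets the neutral per-interval survival fraction; by
    default it follows the type III curve when ``n_intervals`` matches the
    default sampling schedule, and a flat geometric decline otherwise.
    ``effect_range`` bounds the per-locus selection strength ``s`` drawn
    uniformly; genotype viabilities are ``base*(1 +/- s)``-style
    perturbations that respect the ordering each scenario demands.
    """
    if n_loci < 1 or n_intervals < 1:
        raise ValueError("n_loci and n_intervals must be >= 1")
    if scenario_label not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_label!r}; expected one of {SCENARIOS}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if base_viability is None:
        if n_intervals == len(DEFAULT_SAMPLING_DAYS) - 1:
            base_viability = _base_interval_viability(DEFAULT_SAMPLING_DAYS, DEFAULT_SURVIVAL_SHAPE)
        else:
            base_viability = np.full(n_intervals, 0.04 ** (1.0 / n_intervals))
    base = np.asarray(base_viability, dtype=float)
    if base.shape != (n_intervals,):
        raise ValueError("base_viability must have one entry per interval")

    schedule = np.empty((n_loci, n_intervals, 3))
    if scenario_label == "neutral":
        schedule[:] = base[None, :, None]
        return schedule

    s = rng.uniform(*effect_range, size=n_loci)
    if scenario_label == "directional":
        sign = np.ones((n_loci, n_intervals))
    elif scenario_label == "balanced":
        if n_intervals < 2:
            raise ValueError("balanced scenario needs >= 2 intervals to reverse direction")
        # direction of selection flips once, at a random interior interval
        flip_at = rng.integers(1, n_intervals, size=n_loci)
        sign = np.where(np.arange(n_intervals)[None, :] < flip_at[:, None], 1.0, -1.0)
    elif scenario_label == "overdominant":
        # heterozygote strictly fittest; homozygote penalties drawn separately
        pen = rng.uniform(0.3, 1.0, size=(n_loci, 2))
        schedule[:, :, 1] = np.minimum(1.0, base[None, :] * (1.0 + s[:, None]))
        schedule[:, :, 0] = base[None, :] * (1.0 - s[:, None] * pen[:, 0:1])
        schedule[:, :, 2] = base[None, :] * (1.0 - s[:, None] * pen[:, 1:2])
        return schedule
    # directional/balanced: w_AA = base*(1+s), w_AB = base, w_BB = base*(1-s),
    # with the homozygote roles swapped wherever sign is negative.
    schedule[:, :, 1] = base[None, :]
    schedule[:, :, 0] = np.minimum(1.0, base[None, :] * (1.0 + sign * s[:, None]))
    schedule[:, :, 2] = np.clip(base[None, :] * (1.0 - sign * s[:, None]), 0.0, 1.0)
    return schedule


def propagate_truth(initial_state, schedule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic genotype/survival trajectory of one locus under a schedule.

    Applies the Hardy-Weinberg fitness update once per interval and
    accumulates survival as the running product of mean fitness.

    Returns ``(states, maf, survival)`` with one row per sampling day
    (the initial day included).
    """
    state = hw.as_state(initial_state)
    schedule = np.asarray(schedule, dtype=float)
    n_intervals = schedule.shape[0]
    states = np.empty((n_intervals + 1, 3))
    survival = np.empty(n_intervals + 1)
    states[0] = state
    survival[0] = 1.0
    for t in range(n_intervals):
        state, w_bar = hw.advance_interval(state, schedule[t])
        states[t + 1] = state
        survival[t + 1] = survival[t] * w_bar
    maf = states[:, 1] / 2.0 + states[:, 2]
    return states, maf, survival


def make_scenario(
    scenario_label: str,
    n_loci: int = 751,
    n_replicates: int = 5,
    sampling_days=DEFAULT_SAMPLING_DAYS,
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE,
    maf_range: tuple[float, float] = (0.05, 0.5),
    effect_range: tuple[float, float] = (0.1, 0.3),
    seed: int = 0,
) -> SimulationScenario:
    """Build a fully parameterized scenario with drawn MAFs and fitness schedule."""
    rng = np.random.default_rng(seed)
    days = tuple(sampling_days)
    initial_maf = rng.uniform(*maf_range, size=n_loci)
    base = _base_interval_viability(days, DEFAULT_SURVIVAL_SHAPE) if days == DEFAULT_SAMPLING_DAYS else None
    schedule = simulate_fitness_schedule(
        n_loci, len(days) - 1, scenario_label, rng, base_viability=base, effect_range=effect_range
    )
    return SimulationScenario(
        n_loci=n_loci,
        n_replicates=n_replicates,
        sampling_days=days,
        initial_maf=initial_maf,
        fitness_schedule=schedule,
        depth_range=depth_range,
        rng_seed=seed,
        label=scenario_label,
    )


def simulate_truth(scenario: SimulationScenario) -> GroundTruth:
    """Propagate every locus of a scenario from Hardy-Weinberg initial states."""
    n_days = len(scenario.sampling_days)
    states = np.empty((scenario.n_loci, n_days, 3))
    maf = np.empty((scenario.n_loci, n_days))
    survival = np.empty((scenario.n_loci, n_days))
    for i in range(scenario.n_loci):
        init = hw.hwe_expected(scenario.initial_maf[i])
        states[i], maf[i], survival[i] = propagate_truth(init, scenario.fitness_schedule[i])
    locus_ids = [f"L{i:04d}" for i in range(scenario.n_loci)]
    return GroundTruth(scenario.sampling_days, locus_ids, states, maf, survival)


def sample_count_table(
    truth: GroundTruth,
    n_replicates: int,
    depth_range: tuple[int, int],
    seed,
    overdispersion: float | None = None,
) -> pd.DataFrame:
    """Draw a pooled read-count table from true minor-allele frequencies.

    Each locus x replicate x day sample gets a read depth drawn uniformly
    from ``depth_range`` and a minor-allele count drawn binomially at the
    true MAF.  Day 0 is the single unreplicated egg-pool sample; later days
    have ``n_replicates`` cultures.  Replicates share the true MAF: they
    descend from one common embryo pool, so all replicate-level variation
    is sampling noise.

    ``overdispersion``, if given, is a beta-binomial concentration for
    robustness experiments: each sample's success probability is drawn from
    Beta(q*c, (1-q)*c) around the true MAF q (smaller c = noisier counts);
    the default is plain binomial sampling.
    """
    lo, hi = depth_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid depth range {depth_range}")
    if overdispersion is not None and overdispersion <= 0:
        raise ValueError("overdispersion concentration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for i, locus in enumerate(truth.locus_ids):
        scaffold = f"scaffold_{i // 8:03d}"
        position = 1 + (i % 8) * 500
        tag_id = f"tag_{i:04d}"
        for j, day in enumerate(truth.days):
            reps = [EGG_REPLICATE] if day == 0 else [f"R{r+1}" for r in range(n_replicates)]
            q = truth.maf[i, j]
            for rep in reps:
                depth = int(rng.integers(lo, hi + 1))
                p = q
                if overdispersion is not None and 0.0 < q < 1.0:
                    p = rng.beta(q * overdispersion, (1.0 - q) * overdispersion)
                n_minor = int(rng.binomial(depth, p))
                rows.append((locus, scaffold, position, tag_id, rep, day, depth - n_minor, n_minor))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def sample_survival_series(
    truth: GroundTruth,
    n_replicates: int,
    seed,
    noise_sigma: float = 0.05,
) -> pd.DataFrame:
    """Replicate-level cumulative survival observations.

    The cohort-level curve is the mean of per-locus true survival (all loci
    live in the same animals, so they share one mortality history up to
    locus-specific selection); each replicate observes it with small
    multiplicative lognormal noise, clipped to [0, 1], day 0 fixed at 1.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cohort = truth.cohort_survival()
    rows = []
    for r in range(n_replicates):
        rep = f"R{r+1}"
        for j, day in enumerate(truth.days):
            if day == 0:
                obs = 1.0
            else:
                obs = min(1.0, cohort[j] * rng.lognormal(0.0, noise_sigma))
            rows.append((rep, day, obs))
    return pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)


def simulate_experiment(scenario: SimulationScenario):
    """Generate (counts, survival, truth) for one scenario, deterministically.

    All randomness derives from ``scenario.rng_seed``; regenerating with the
    same scenario reproduces identical tables.
    """
    truth = simulate_truth(scenario)
    rng = np.random.default_rng(scenario.rng_seed + 1)
    counts = sample_count_table(truth, scenario.n_replicates, scenario.depth_range, rng)
    survival = sample_survival_series(truth, scenario.n_replicates, rng)
    return counts, survival, truth


def write_experiment(out_dir, counts: pd.DataFrame, survival: pd.DataFrame, truth: GroundTruth) -> None:
    """Write the three TSVs (counts, survival, ground truth) to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    survival.to_csv(out / "survival.tsv", sep="\t", index=False)
    truth.to_frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"locus_id", "replicate", "day", "n_major", "n_minor"} - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} missing columns: {sorted(missing)}")
    return df


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SURVIVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survival table {path} missing columns: {sorted(missing)}")
    return df
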