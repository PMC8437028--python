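"""Rejection-sampling reconstruction of genotype-frequency and fitness trajectories.

From pooled data alone, genotype frequencies cannot be computed — but the
space of trajectories consistent with what *was* measured (cohort survival
and minor-allele frequency at each sampling day) is bounded.  The forecaster
explores that space: starting from an estimated fertilized-egg genotype
state, it repeatedly

1. draws relative viabilities ``(w_AA, w_AB, w_BB) ~ Uniform(0,1)^3`` for
   the current inter-sample interval,
2. advances the genotype state with the Hardy-Weinberg fitness update
   (``f_g' = f_g w_g / w_bar``) and multiplies cumulative survival by the
   mean fitness ``w_bar``,
3. accepts the interval only if the simulated MAF and cumulative survival
   both land within a tolerance (default 10%) of the empirical means,
   re-drawing viabilities otherwise.

A trajectory that clears every sampling day is one plausible history of the
locus; an ensemble of accepted trajectories (default 50) summarizes the
plausible range of genotype frequencies and genotype-specific fitness at
each stage of development.

The MAF tolerance is absolute (frequencies live on [0,1]; a relative window
would collapse near 0) while the survival tolerance is relative (cumulative
survival reaches ~0.04 by the final day, where a 0.10 absolute window would
accept anything).  Both interpretations are switchable.

If an interval exhausts its re-draw budget the trajectory restarts from the
initial state; exhausted restart budgets yield a partial ensemble with an
explicit infeasibility report, never a silent hang.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from poolsel import hw

DEFAULT_FORECAST_DAYS = (2, 6, 10, 14, 22)


@dataclass
class EmpiricalConstraints:
    """Replicate-mean MAF and cumulative survival at each constrained day."""

    days: tuple[int, ...]
    maf: np.ndarray
    survival: np.ndarray
    tolerance: float = 0.10
    maf_mode: str = "absolute"
    survival_mode: str = "relative"

    def __post_init__(self) -> None:
        self.days = tuple(int(d) for d in self.days)
        self.maf = np.asarray(self.maf, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if len(self.days) < 2:
            raise ValueError("constraints must cover at least two time points")
        if self.maf.shape != (len(self.days),) or self.survival.shape != (len(self.days),):
            raise ValueError("maf and survival must have one value per constrained day")
        if np.any((self.maf < 0) | (self.maf > 1)):
            raise ValueError("empirical MAF must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 0):
            raise ValueError("empirical cumulative survival must be non-increasing")
        if np.any(self.survival <= 0):
            raise ValueError("empirical survival must be positive (zero makes the constraint unusable)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.maf_mode not in ("absolute", "relative") or self.survival_mode not in ("absolute", "relative"):
            raise ValueError("constraint modes must be 'absolute' or 'relative'")


@dataclass
class TrajectoryEnsemble:
    """Accepted forecaster simulations for one locus."""

    locus_id: str
    days: tuple[int, ...]  # includes day 0 (initial state)
    states: np.ndarray  # (n_accepted, n_days, 3)
    survival: np.ndarray  # (n_accepted, n_days)
    fitness: np.ndarray  # (n_accepted, n_days - 1, 3)
    n_target: int
    attempts: int = 0
    restarts: int = 0
    infeasible: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_accepted(self) -> int:
        return self.states.shape[0]

    def maf(self) -> np.ndarray:
        """(n_accepted, n_days) MAF implied by the genotype states."""
        return self.states[:, :, 1] / 2.0 + self.states[:, :, 2]


def check_constraints(sim_maf: float, sim_survival: float, constraints: EmpiricalConstraints, day_index: int):
    """Accept/reject one simulated time point against the empirical means.

    Returns ``(True, "")`` on acceptance, else ``(False, reason)``.
    """
    tol = constraints.tolerance
    emp_maf = constraints.maf[day_index]
    emp_surv = constraints.survival[day_index]
    dev_maf = abs(sim_maf - emp_maf)
    if constraints.maf_mode == "relative":
        if emp_maf <= 0:
            raise ValueError("relative MAF constraint undefined at empirical MAF 0")
        dev_maf /= emp_maf
    if dev_maf > tol:
        return False, "maf"
    dev_surv = abs(sim_survival - emp_surv)
    if constraints.survival_mode == "relative":
        dev_surv /= emp_surv
    if dev_surv > tol:
        return False, "survival"
    return True, ""


def _accept_mask(states, survival, constraints, day_index):
    """Vectorized constraint check over a batch of candidate advances."""
    maf = states[:, 1] / 2.0 + states[:, 2]
    tol = constraints.tolerance
    dev_maf = np.abs(maf - constraints.maf[day_index])
    if constraints.maf_mode == "relative":
        dev_maf = dev_maf / constraints.maf[day_index]
    dev_surv = np.abs(survival - constraints.survival[day_index])
    if constraints.survival_mode == "relative":
        dev_surv = dev_surv / constraints.survival[day_index]
    return (dev_maf <= tol) & (dev_surv <= tol)


def forecast_locus(
    initial_state,
    constraints: EmpiricalConstraints,
    n_accept: int = 50,
    max_attempts_per_interval: int = 10_000,
    max_restarts: int = 1_000,
    seed=0,
    locus_id: str = "",
    batch_size: int = 64,
) -> TrajectoryEnsemble:
    """Collect an ensemble of accepted trajectories for one locus.

    Viabilities are proposed in batches for speed; acceptance takes the
    first passing proposal in draw order, so results are identical to
    one-at-a-time proposing with the same random stream consumed in blocks.
    """
    initial = hw.as_state(initial_state)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_intervals = len(constraints.days)
    acc_states = np.empty((n_accept, n_intervals + 1, 3))
    acc_surv = np.empty((n_accept, n_intervals + 1))
    acc_fit = np.empty((n_accept, n_intervals, 3))
    total_attempts = 0
    total_restarts = 0
    collected = 0
    infeasible = False

    while collected < n_accept:
        state = initial.copy()
        surv = 1.0
        traj_states = [initial.copy()]
        traj_surv = [1.0]
        traj_fit = []
        restarted = False
        for t in range(n_intervals):
            attempts = 0
            found = False
            while attempts < max_attempts_per_interval:
                n_draw = min(batch_size, max_attempts_per_interval - attempts)
                w = rng.uniform(0.0, 1.0, size=(n_draw, 3))
                w_bar = w @ state
                valid = w_bar > 0.0
                cand_states = np.where(valid[:, None], state[None, :] * w / np.where(valid, w_bar, 1.0)[:, None], 0.0)
                cand_surv = surv * w_bar
                ok = valid & _accept_mask(cand_states, cand_surv, constraints, t)
                idx = np.flatnonzero(ok)
                if idx.size:
                    j = int(idx[0])
                    attempts += j + 1  # draws consumed up to the accepted proposal
                    state = cand_states[j]
                    surv = float(cand_surv[j])
                    traj_states.append(state.copy())
                    traj_surv.append(surv)
                    traj_fit.append(w[j].copy())
                    found = True
                    break
                attempts += n_draw
            total_attempts += attempts
            if not found:
                total_restarts += 1
                restarted = True
                break
        if restarted:
            if total_restarts >= max_restarts:
                infeasible = True
                break
            continue
        acc_states[collected] = np.array(traj_states)
        acc_surv[collected] = np.array(traj_surv)
        acc_fit[collected] = np.array(traj_fit)
        collected += 1

    days = (0,) + constraints.days
    return TrajectoryEnsemble(
        locus_id=locus_id,
        days=days,
        states=acc_states[:collected],
        survival=acc_surv[:collected],
        fitness=acc_fit[:collected],
        n_target=n_accept,
        attempts=total_attempts,
        restarts=total_restarts,
        infeasible=infeasible,
        diagnostics={
            "accepted": collected,
            "target": n_accept,
            "attempts": total_attempts,
            "restarts": total_restarts,
        },
    )


def verify_ensemble(ensemble: TrajectoryEnsemble, constraints: EmpiricalConstraints) -> bool:
    """Independent post-hoc check that every accepted trajectory satisfies the constraints."""
    if ensemble.n_accepted == 0:
        return True
    maf = ensemble.maf()
    for i in range(ensemble.n_accepted):
        for t, _day in enumerate(constraints.days):
            ok, _ = check_constraints(maf[i, t + 1], ensemble.survival[i, t + 1], constraints, t)
            if not ok:
                return False
    return True


def summarize_ensemble(ensemble: TrajectoryEnsemble) -> pd.DataFrame:
    """Per-day ensemble mean and 95% interval for genotype frequencies, MAF, survival and fitness.

    Fitness rows describe the interval ending at the given day (none at day 0).
    """
    if ensemble.n_accepted < 2:
        raise ValueError("ensemble needs at least two accepted trajectories to summarize")
    rows = []
    maf = ensemble.maf()
    for j, day in enumerate(ensemble.days):
        row = {"locus_id": ensemble.locus_id, "day": day, "n_accepted": ensemble.n_accepted}
        for gi, g in enumerate(hw.GENOTYPES):
            vals = ensemble.states[:, j, gi]
            row[f"f_{g}"] = vals.mean()
            row[f"f_{g}_lo"], row[f"f_{g}_hi"] = np.percentile(vals, [2.5, 97.5])
        row["maf"] = maf[:, j].mean()
        row["survival"] = ensemble.survival[:, j].mean()
        if j > 0:
            for gi, g in enumerate(hw.GENOTYPES):
                vals = ensemble.fitness[:, j - 1, gi]
                row[f"w_{g}"] = vals.mean()
                row[f"w_{g}_lo"], row[f"w_{g}_hi"] = np.percentile(vals, [2.5, 97.5])
        rows.append(row)
    return pd.DataFrame(rows)


def n_simulation_records(n_loci: int, n_accept: int, n_timepoints: int) -> int:
    """Bookkeeping: total per-time-point simulation records in a full run."""
    return int(n_loci) * int(n_accept) * int(n_timepoints)


def constraints_from_tables(
    per_day_mean_maf: pd.Series,
    survival_by_day: pd.Series,
    days=DEFAULT_FORECAST_DAYS,
    tolerance: float = 0.10,
) -> EmpiricalConstraints:
    """Build constraints for one locus from replicate-mean MAF and survival tables."""
    days = tuple(int(d) for d in days)
    return EmpiricalConstraints(
        days=days,
        maf=np.array([float(per_day_mean_maf[d]) for d in days]),
        survival=np.array([float(survival_by_day[d]) for d in days]),
        tolerance=tolerance,
    )
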