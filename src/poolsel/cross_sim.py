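"""Factorial-cross genotype estimation for the fertilized egg pool.

Pooled sequencing yields allele frequencies, not genotypes.  But when the
larval pool is the product of a controlled factorial cross (every sire
paired with every dam, families combined in equal proportions), the egg-pool
allele frequency reflects the complete parental gamete pool, and the
genotype composition of the fertilized eggs can be estimated by simulation:
distribute the observed number of minor-allele copies at random among the
parents' chromosomes, form every sire x dam family, take Mendelian
expectations per family, and average over families.  Repeating the random
placement quantifies the uncertainty contributed by the unknown parental
genotype configuration.

The default design is 5 sires x 19 dams (95 families) and 50 simulated
broodstock populations per locus, with the parental minor-copy count fixed
at ``round(q * 2 * n_parents)`` so the parental allele frequency is exact
and only the genotype composition varies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from poolsel.hw import hwe_expected  # noqa: F401  (re-exported: HWE benchmark for the simulation)

_TRANSMIT = {"AA": 0.0, "AB": 0.5, "BB": 1.0}


@dataclass
class EggGenotypeEstimate:
    mean_state: np.ndarray  # (3,) mean over simulations
    sd_state: np.ndarray  # (3,)
    ci_low: np.ndarray  # (3,) 2.5th percentile
    ci_high: np.ndarray  # (3,) 97.5th percentile
    states: np.ndarray  # (n_sims, 3) per-simulation egg genotype states
    n_families: int
    n_minor_copies: int
    monomorphic: bool = False


def mendelian_offspring(genotype_sire: str, genotype_dam: str) -> np.ndarray:
    """Expected offspring genotype state (f_AA, f_AB, f_BB) for one family."""
    try:
        bs, bd = _TRANSMIT[genotype_sire], _TRANSMIT[genotype_dam]
    except KeyError as exc:
        raise ValueError(f"parental genotypes must be AA/AB/BB, got {genotype_sire!r}, {genotype_dam!r}") from exc
    f_bb = bs * bd
    f_aa = (1.0 - bs) * (1.0 - bd)
    return np.array([f_aa, 1.0 - f_aa - f_bb, f_bb])


def simulate_egg_genotypes(
    egg_maf: float,
    n_sims: int = 50,
    n_sires: int = 5,
    n_dams: int = 19,
    seed=0,
) -> EggGenotypeEstimate:
    """Estimate the egg-pool genotype state from its minor-allele frequency.

    Each simulation places ``round(q * 2 * (n_sires + n_dams))`` minor-allele
    copies uniformly at random among the parental allele slots, builds the
    full factorial cross with equal family weights, and averages Mendelian
    offspring expectations over the ``n_sires * n_dams`` families.

    A ``q`` too small to yield a single parental minor copy is flagged
    monomorphic-in-parents and returns the fixed state (1, 0, 0).
    """
    if not 0.0 <= egg_maf <= 1.0:
        raise ValueError(f"egg MAF must lie in [0, 1], got {egg_maf}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_parents = n_sires + n_dams
    n_slots = 2 * n_parents
    n_families = n_sires * n_dams
    copies = int(round(egg_maf * n_slots))
    if copies == 0:
        warnings.warn(f"egg MAF {egg_maf} yields zero parental minor copies; monomorphic in parents")
        fixed = np.array([1.0, 0.0, 0.0])
        z = np.zeros(3)
        return EggGenotypeEstimate(fixed, z, fixed.copy(), fixed.copy(),
                                   np.tile(fixed, (n_sims, 1)), n_families, 0, monomorphic=True)

    states = np.empty((n_sims, 3))
    for s in range(n_sims):
        slots = np.zeros(n_slots, dtype=int)
        slots[rng.choice(n_slots, size=copies, replace=False)] = 1
        minor_per_parent = slots.reshape(n_parents, 2).sum(axis=1)
        b = minor_per_parent / 2.0  # transmission probability of the minor allele
        # equal family weights: the factorial average factorizes over sires and dams
        mb_s = b[:n_sires].mean()
        mb_d = b[n_sires:].mean()
        f_bb = mb_s * mb_d
        f_aa = (1.0 - mb_s) * (1.0 - mb_d)
        states[s] = (f_aa, 1.0 - f_aa - f_bb, f_bb)
    return EggGenotypeEstimate(
        mean_state=states.mean(axis=0),
        sd_state=states.std(axis=0, ddof=1) if n_sims > 1 else np.zeros(3),
        ci_low=np.percentile(states, 2.5, axis=0),
        ci_high=np.percentile(states, 97.5, axis=0),
        states=states,
        n_families=n_families,
        n_minor_copies=copies,
    )


def egg_genotype_table(
    egg_maf: pd.Series,
    n_sims: int = 50,
    n_sires: int = 5,
    n_dams: int = 19,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus egg genotype estimates for a series of egg-pool MAFs."""
    rng = np.random.default_rng(seed)
    rows = []
    for locus, q in egg_maf.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = simulate_egg_genotypes(float(q), n_sims, n_sires, n_dams, rng)
        rows.append(
            {
                "locus_id": locus,
                "egg_maf": float(q),
                "f_AA": est.mean_state[0],
                "f_AB": est.mean_state[1],
                "f_BB": est.mean_state[2],
                "sd_AA": est.sd_state[0],
                "sd_AB": est.sd_state[1],
                "sd_BB": est.sd_state[2],
                "n_minor_copies": est.n_minor_copies,
                "monomorphic": est.monomorphic,
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")
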