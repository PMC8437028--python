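"""Hardy-Weinberg fitness-equation primitives shared across the package.

Genotype states are triples ``(f_AA, f_AB, f_BB)`` on the probability
simplex, stored as length-3 numpy arrays in the fixed order AA, AB, BB
(A = globally major allele, B = globally minor allele).  One episode of
viability selection with relative viabilities ``w = (w_AA, w_AB, w_BB)``
updates a state by

    f_g'  =  f_g * w_g / w_bar,      w_bar = sum_g f_g * w_g,

where ``w_bar`` is the mean fitness of the cohort, i.e. the fraction of
individuals expected to survive the episode.  When the state is at
Hardy-Weinberg proportions (p^2, 2pq, q^2) this ``w_bar`` coincides with
the textbook form p^2 w_AA + 2pq w_AB + q^2 w_BB.
"""

from __future__ import annotations

import numpy as np

GENOTYPES = ("AA", "AB", "BB")

SIMPLEX_ATOL = 1e-9


class ExtinctionError(ValueError):
    """All genotypes present in the state have zero fitness (w_bar = 0)."""


def as_state(values) -> np.ndarray:
    """Validate and return a genotype state as a float array (AA, AB, BB)."""
    state = np.asarray(values, dtype=float)
    if state.shape != (3,):
        raise ValueError(f"genotype state must have 3 components, got shape {state.shape}")
    if np.any(state < -SIMPLEX_ATOL):
        raise ValueError(f"genotype state has negative component: {state}")
    if abs(state.sum() - 1.0) > 1e-6:
        raise ValueError(f"genotype state does not sum to 1: {state} (sum={state.sum()})")
    return np.clip(state, 0.0, None)


def maf_of_state(state: np.ndarray) -> float:
    """Minor-allele frequency implied by a genotype state: q = f_AB/2 + f_BB."""
    return float(state[1] / 2.0 + state[2])


def hwe_expected(q: float) -> np.ndarray:
    """Hardy-Weinberg genotype proportions (p^2, 2pq, q^2) for minor-allele frequency q."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {q}")
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])


def mean_fitness(state: np.ndarray, w: np.ndarray) -> float:
    """Mean fitness w_bar = sum_g f_g w_g of a genotype state under viabilities w."""
    return float(np.dot(state, w))


def advance_interval(state: np.ndarray, w) -> tuple[np.ndarray, float]:
    """Apply one episode of viability selection to a genotype state.

    Parameters
    ----------
    state
        Genotype state (f_AA, f_AB, f_BB) on the simplex.
    w
        Relative viabilities (w_AA, w_AB, w_BB), each in [0, 1].

    Returns
    -------
    (new_state, w_bar)
        The post-selection state and the mean fitness of the interval
        (the fraction of the cohort surviving it).

    Raises
    ------
    ExtinctionError
        If every genotype present in the state has zero fitness.
    """
    state = np.asarray(state, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape != (3,):
        raise ValueError(f"fitness vector must have 3 components, got shape {w.shape}")
    if np.any((w < 0.0) | (w > 1.0)):
        raise ValueError(f"fitness values must lie in [0, 1], got {w}")
    w_bar = mean_fitness(state, w)
    if w_bar <= 0.0:
        raise ExtinctionError(
            f"mean fitness is zero for state {state} with fitness {w}: cohort extinct"
        )
    return state * w / w_bar, w_bar
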