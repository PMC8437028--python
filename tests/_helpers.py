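"""Shared helpers for the test suite."""

from itertools import permutations

import numpy as np


def blob_matrix(n_blobs=5, per_blob=80, n_features=5, spread=0.01, seed=0):
    """Well-separated synthetic dAF blobs with true labels."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-0.9, 0.9, size=(n_blobs, n_features))
    X = np.vstack([c + rng.normal(0.0, spread, size=(per_blob, n_features)) for c in centers])
    labels = np.repeat(np.arange(n_blobs), per_blob)
    return X, labels


def best_agreement(labels_a, labels_b):
    """Fraction agreeing under the best one-to-one label matching (brute force)."""
    ks = sorted(set(labels_b))
    best = 0.0
    for perm in permutations(sorted(set(labels_a))):
        mapping = dict(zip(ks, perm))
        best = max(best, float(np.mean([mapping[b] == a for a, b in zip(labels_a, labels_b)])))
    return best
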