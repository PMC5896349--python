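"""Quantile normalization across arrays.

Forces every array's intensity distribution onto a common reference so
that probe intensities are comparable between arrays.  The reference is
the per-rank mean: element *k* is the mean, over arrays, of each
array's *k*-th order statistic.  Each array is then remapped so the
value at the position of its *k*-th smallest element becomes
``reference[k]``.

The procedure is deliberately two-phase so it decomposes onto a
map/shuffle/reduce engine: computing each array's order statistics is a
per-array map, averaging ranks across arrays is a single reduce, and
remapping is again a per-array map.

Ties: all positions holding a tied value receive the mean of the
reference values across the tied rank span, which keeps the result
deterministic and invariant under permutations of equal elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class QuantileReference:
    """The cross-array mean-quantile vector (nondecreasing)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("reference must be a 1-D vector")
        if not np.all(np.isfinite(v)):
            raise ValueError("reference must be finite")
        if np.any(np.diff(v) < 0):
            raise ValueError("reference must be nondecreasing")

    def __len__(self) -> int:
        return len(self.values)


def sorted_intensities(vector) -> np.ndarray:
    """Order statistics of one array (the map half of phase 1)."""
    return np.sort(np.asarray(vector, dtype=float))


def compute_reference(vectors) -> QuantileReference:
    """Mean of per-array order statistics, rank by rank.

    Accumulation runs in array order so the floating-point result is
    independent of any parallel partitioning upstream.  The mean is
    computed as ``first + mean(sorted - first)`` so that arrays with
    identical distributions yield their common sorted vector exactly —
    this is what makes re-normalization an exact identity.
    """
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("need at least one array")
    n = len(vectors[0])
    for i, v in enumerate(vectors):
        if len(v) != n:
            raise ValueError(f"array {i} has length {len(v)}, expected {n}")
    base = np.sort(vectors[0])
    acc = np.zeros(n)
    for v in vectors[1:]:
        acc += np.sort(v) - base
    return QuantileReference(values=base + acc / len(vectors))


def apply_reference(vector, ref: QuantileReference) -> np.ndarray:
    """Remap one array onto the reference distribution.

    Tie-free input: the output's sorted multiset equals the reference
    exactly.  Tied input values all receive the mean of the reference
    over the tied rank span.
    """
    x = np.asarray(vector, dtype=float)
    if len(x) != len(ref):
        raise ValueError(f"vector length {len(x)} != reference length {len(ref)}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    out_sorted = ref.values.astype(float).copy()
    # Boundaries of runs of equal values in the sorted input.
    starts = np.flatnonzero(np.concatenate(([True], xs[1:] != xs[:-1])))
    if len(starts) < len(xs):  # at least one tie
        counts = np.diff(np.concatenate((starts, [len(xs)])))
        run_means = np.add.reduceat(ref.values, starts) / counts
        out_sorted = np.repeat(run_means, counts)
    out = np.empty_like(out_sorted)
    out[order] = out_sorted
    return out


def quantile_normalize(vectors) -> list[np.ndarray]:
    """Full two-phase normalization of a batch of equal-length arrays."""
    ref = compute_reference(vectors)
    return [apply_reference(v, ref) for v in vectors]
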