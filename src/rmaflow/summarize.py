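"""Probeset summarization by Tukey median polish.

After background correction and normalization, the log2 intensity of
probe *j* on array *i* within a probeset is modelled additively:

    Y[j, i] = theta[i] + phi[j] + eps[j, i]

with ``theta`` the per-array expression of the probeset's gene,
``phi`` a probe-specific affinity effect and ``eps`` measurement error.
Median polish fits this two-way model by alternately sweeping row
(probe) medians and column (array) medians out of the residuals,
accumulating them into the effects; medians make the fit robust to
outlier probes.  The reported expression is ``overall + array_effect``.

The sweep follows the classical algorithm: rows first, then columns,
with the median of the accumulated effects folded into the overall
term each half-sweep (this pins the effect medians at zero, making the
decomposition identifiable).  Iteration stops when the total absolute
residual changes by less than ``tol`` relative, or after ``max_iter``
sweeps.  The median of an even number of values is the mean of the two
central ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ProbesetMatrix:
    """Probes x arrays log2 intensities for one probeset."""

    probeset_id: str
    probe_ids: list[int]
    array_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.array_ids)):
            raise ValueError(f"probeset {self.probeset_id!r}: shape mismatch")
        if self.values.size == 0:
            raise ValueError(f"probeset {self.probeset_id!r}: empty matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"probeset {self.probeset_id!r}: non-finite values")


@dataclass
class MedianPolishFit:
    """Decomposition input = overall + probe_effects + array_effects + residuals."""

    overall: float
    probe_effects: np.ndarray  # rows
    array_effects: np.ndarray  # columns
    residuals: np.ndarray
    iterations: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return (
            self.overall
            + self.probe_effects[:, None]
            + self.array_effects[None, :]
            + self.residuals
        )


def log2_transform(matrix) -> np.ndarray:
    """Element-wise base-2 log; inputs must be strictly positive."""
    m = np.asarray(matrix, dtype=float)
    if np.any(~np.isfinite(m)) or np.any(m <= 0):
        raise ValueError("log2 transform requires finite positive inputs")
    return np.log2(m)


def median_polish(matrix, tol: float = 0.01, max_iter: int = 10) -> MedianPolishFit:
    """Alternating row/column median sweep of a two-way table.

    The reconstruction identity holds exactly (to floating point)
    whether or not the sweep converged within ``max_iter``.
    """
    z = np.array(matrix, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median polish needs a non-empty 2-D matrix")
    if not np.all(np.isfinite(z)):
        raise ValueError("median polish input must be finite")
    if tol <= 0 or max_iter <= 0:
        raise ValueError("tol and max_iter must be positive")

    nr, nc = z.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    oldsum = 0.0
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row_eff += rdelta
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col_eff += cdelta
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        newsum = float(np.abs(z).sum())
        if newsum == 0.0 or abs(newsum - oldsum) < tol * newsum:
            converged = True
            break
        oldsum = newsum

    return MedianPolishFit(
        overall=float(overall),
        probe_effects=row_eff,
        array_effects=col_eff,
        residuals=z,
        iterations=iterations,
        converged=converged,
    )


def summarize_probeset(
    pm: ProbesetMatrix, tol: float = 0.01, max_iter: int = 10
) -> np.ndarray:
    """One expression value per array: overall + array effect."""
    fit = median_polish(pm.values, tol=tol, max_iter=max_iter)
    return fit.overall + fit.array_effects
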