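"""Local, deterministic map/shuffle/reduce executor.

The preprocessing pipeline is expressed as keyed map and reduce stages,
mirroring how it would be distributed across data nodes: per-array work
(background correction, distribution remapping) is *map*, grouping
probe values by probeset is *shuffle*, and per-probeset summarization
is *reduce*.  Execution is local, on a process pool, with a hard
contract: the output is identical — not just statistically equivalent —
for any worker count and any chunking of the inputs.

Determinism is achieved by (a) canonicalizing map output order by
``(key, input index, emit index)`` rather than arrival order, (b)
sorting shuffle groups by key, and (c) fixing every floating-point
reduction order (e.g. per-rank means accumulate in array index order).

The full expression pipeline (:func:`run_rma_pipeline`) runs as:

* Map 1 — per array: extract PM probes, fit the norm-exp background
  model, background-correct.
* Reduce 1 — per-rank mean of the sorted corrected vectors: the
  quantile reference (the only cross-array data flow).
* Map 2 — per array: remap onto the reference, log2, split the probe
  vector by probeset.
* Reduce 2 — per probeset: median-polish summarization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .background import NormExpParams, bg_adjust, estimate_normexp_params
from .io_model import ArraySet, ExpressionMatrix, extract_pm
from .normalize import QuantileReference, apply_reference, compute_reference
from .summarize import ProbesetMatrix, log2_transform, summarize_probeset


class StageError(RuntimeError):
    """A map or reduce task failed; the message names the record key."""


@dataclass(frozen=True)
class KeyedRecord:
    key: Any
    payload: Any


@dataclass
class PipelineConfig:
    """Execution and algorithm settings for the expression pipeline."""

    workers: int = 1
    chunk_size: int | None = None  # records per map task; default ceil(n/workers)
    tol: float = 0.01
    max_iter: int = 10
    log2: bool = True
    estimator: str = "mle"
    # Frozen background parameters applied to every array instead of a
    # per-array fit (e.g. known simulation truth, or parameters carried
    # over from a reference batch).
    fixed_params: NormExpParams | None = None
    seed: int | None = None  # logged for provenance; the pipeline is deterministic

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.chunk_size is not None and self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


def _chunks(seq: Sequence, size: int) -> list[list]:
    return [list(seq[i : i + size]) for i in range(0, len(seq), size)]


def _map_chunk(items: list[tuple[int, Any]], fn: Callable) -> list[tuple[int, int, Any, Any]]:
    out = []
    for idx, record in items:
        try:
            emitted = fn(record)
        except Exception as exc:
            raise StageError(f"map failed on record {idx} ({record!r:.120}): {exc!r}") from exc
        for emit_idx, item in enumerate(emitted):
            if isinstance(item, KeyedRecord):
                key, payload = item.key, item.payload
            else:
                key, payload = item
            out.append((idx, emit_idx, key, payload))
    return out


def run_map(
    records: Iterable,
    fn: Callable[[Any], Iterable],
    workers: int = 1,
    chunk_size: int | None = None,
) -> list[KeyedRecord]:
    """Apply a pure mapper to every record on a process pool.

    ``fn`` returns an iterable of ``(key, payload)`` pairs (or
    :class:`KeyedRecord`).  Output order is canonical — sorted by
    ``(key, input index, emit index)`` — so the result is a function of
    the inputs alone, independent of ``workers`` and chunking.
    """
    indexed = list(enumerate(records))
    if not indexed:
        return []
    if chunk_size is None:
        chunk_size = max(1, math.ceil(len(indexed) / workers))
    parts = _chunks(indexed, chunk_size)
    if workers == 1 or len(parts) == 1:
        results = [_map_chunk(p, fn) for p in parts]
    else:
        results = Parallel(n_jobs=workers)(delayed(_map_chunk)(p, fn) for p in parts)
    flat = [t for chunk in results for t in chunk]
    flat.sort(key=lambda t: (t[2], t[0], t[1]))
    return [KeyedRecord(key=k, payload=p) for _, _, k, p in flat]


def shuffle(records: Iterable[KeyedRecord]) -> list[tuple[Any, list]]:
    """Group payloads by key; groups come out in sorted key order.

    Within a group, payloads keep the canonical map-output order, so
    the grouping is independent of arrival order.
    """
    groups: dict[Any, list] = {}
    for rec in records:
        groups.setdefault(rec.key, []).append(rec.payload)
    return [(k, groups[k]) for k in sorted(groups)]


def _reduce_one(key: Any, payloads: list, fn: Callable) -> Any:
    try:
        return fn(key, payloads)
    except Exception as exc:
        raise StageError(f"reduce failed on key {key!r}: {exc!r}") from exc


def run_reduce(
    grouped: Iterable[tuple[Any, list]],
    fn: Callable[[Any, list], Any],
    workers: int = 1,
) -> list[KeyedRecord]:
    """Apply a reducer to each key group; one output record per key.

    Key order of the input (sorted, from :func:`shuffle`) is preserved.
    """
    grouped = list(grouped)
    if workers == 1 or len(grouped) <= 1:
        results = [_reduce_one(k, v, fn) for k, v in grouped]
    else:
        results = Parallel(n_jobs=workers)(
            delayed(_reduce_one)(k, v, fn) for k, v in grouped
        )
    return [KeyedRecord(key=k, payload=r) for (k, _), r in zip(grouped, results)]


# ---------------------------------------------------------------------------
# The expression pipeline on top of the primitives
# ---------------------------------------------------------------------------

def run_rma_pipeline(aset: ArraySet, config: PipelineConfig | None = None) -> ExpressionMatrix:
    """Background-correct, normalize and summarize an array batch.

    Output rows follow layout probeset order; columns follow batch
    array order.  For a fixed input the result is identical across all
    worker counts and chunkings.
    """
    if config is None:
        config = PipelineConfig()
    if not aset.arrays:
        raise ValueError("ArraySet contains no arrays")

    pmm = extract_pm(aset)
    n_arrays = pmm.values.shape[1]
    estimator = config.estimator

    # Map 1: per-array background correction.
    fixed_params = config.fixed_params

    def _bg_map(record):
        i, column = record
        params = fixed_params or estimate_normexp_params(column, method=estimator)
        return [("bg", (i, bg_adjust(column, params)))]

    records = [(i, pmm.values[:, i]) for i in range(n_arrays)]
    bg_out = run_map(records, _bg_map, workers=config.workers, chunk_size=config.chunk_size)

    # Reduce 1: the quantile reference (sole cross-array step).
    def _ref_reduce(key, payloads):
        ordered = [vec for _, vec in sorted(payloads, key=lambda t: t[0])]
        return compute_reference(ordered)

    (ref_rec,) = run_reduce(shuffle(bg_out), _ref_reduce)
    ref: QuantileReference = ref_rec.payload
    corrected = {i: vec for i, vec in (r.payload for r in bg_out)}

    # Map 2: remap each array onto the reference, log-transform, and
    # split the probe vector by probeset.
    keys = pmm.keys
    probeset_ids = aset.layout.probeset_ids
    row_index: dict[str, list[int]] = {ps: [] for ps in probeset_ids}
    for row, (ps, _) in enumerate(keys):
        row_index[ps].append(row)
    apply_log2 = config.log2

    def _norm_map(record):
        i, vec = record
        normed = apply_reference(vec, ref)
        if apply_log2:
            normed = log2_transform(normed)
        return [(ps, (i, normed[rows])) for ps, rows in row_index.items()]

    norm_records = [(i, corrected[i]) for i in range(n_arrays)]
    norm_out = run_map(
        norm_records, _norm_map, workers=config.workers, chunk_size=config.chunk_size
    )

    # Reduce 2: per-probeset median polish.
    array_ids = pmm.array_ids
    tol, max_iter = config.tol, config.max_iter

    def _summ_reduce(key, payloads):
        cols = sorted(payloads, key=lambda t: t[0])
        mat = np.column_stack([v for _, v in cols])
        psm = ProbesetMatrix(
            probeset_id=key,
            probe_ids=list(range(mat.shape[0])),
            array_ids=array_ids,
            values=mat,
        )
        return summarize_probeset(psm, tol=tol, max_iter=max_iter)

    summ_out = run_reduce(shuffle(norm_out), _summ_reduce, workers=config.workers)
    by_probeset = {rec.key: rec.payload for rec in summ_out}
    values = np.vstack([by_probeset[ps] for ps in probeset_ids])
    return ExpressionMatrix(probeset_ids=probeset_ids, array_ids=array_ids, values=values)
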