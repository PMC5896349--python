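import numpy as np
import pytest

from rmaflow.background import bg_adjust, estimate_normexp_params
from rmaflow.engine import (
    KeyedRecord,
    PipelineConfig,
    StageError,
    run_map,
    run_reduce,
    run_rma_pipeline,
    shuffle,
)
from rmaflow.io_model import extract_pm
from rmaflow.normalize import quantile_normalize
from rmaflow.summarize import ProbesetMatrix, log2_transform, summarize_probeset
from rmaflow.synth import SimConfig, simulate


def straight_line_rma(aset, estimator="mle"):
    """No-engine reference composition of the three pipeline stages."""
    pmm = extract_pm(aset)
    corrected = []
    for i in range(pmm.values.shape[1]):
        col = pmm.values[:, i]
        corrected.append(bg_adjust(col, estimate_normexp_params(col, method=estimator)))
    normed = [log2_transform(v) for v in quantile_normalize(corrected)]
    probeset_ids = aset.layout.probeset_ids
    rows_of = {ps: [] for ps in probeset_ids}
    for r, (ps, _) in enumerate(pmm.keys):
        rows_of[ps].append(r)
    out = []
    for ps in probeset_ids:
        mat = np.column_stack([v[rows_of[ps]] for v in normed])
        psm = ProbesetMatrix(probeset_id=ps, probe_ids=list(range(mat.shape[0])),
                             array_ids=pmm.array_ids, values=mat)
        out.append(summarize_probeset(psm))
    return np.vstack(out)


class TestMapReducePrimitives:
    @pytest.mark.parametrize("workers", [1, 2, 4])
    def test_identity_mapper_any_workers(self, workers):
        records = ["c", "a", "b", "a"]
        out = run_map(records, lambda r: [(r, r)], workers=workers)
        assert [(r.key, r.payload) for r in out] == [
            ("a", "a"), ("a", "a"), ("b", "b"), ("c", "c")
        ]

    def test_word_count_toy(self):
        mapped = run_map(["a", "b", "a"], lambda w: [(w, 1)])
        grouped = shuffle(mapped)
        assert grouped == [("a", [1, 1]), ("b", [1])]
        reduced = run_reduce(grouped, lambda k, vs: sum(vs))
        assert [(r.key, r.payload) for r in reduced] == [("a", 2), ("b", 1)]

    def test_empty_input(self):
        assert run_map([], lambda r: [(r, r)], workers=4) == []

    def test_shuffle_sorted_independent_of_arrival(self):
        recs = [KeyedRecord("z", 1), KeyedRecord("a", 2), KeyedRecord("m", 3)]
        assert [k for k, _ in shuffle(recs)] == ["a", "m", "z"]
        assert [k for k, _ in shuffle(recs[::-1])] == ["a", "m", "z"]

    def test_singleton_identity_reduce(self):
        grouped = [("a", [5]), ("b", [7])]
        out = run_reduce(grouped, lambda k, vs: vs[0])
        assert [(r.key, r.payload) for r in out] == [("a", 5), ("b", 7)]

    def test_map_error_names_record(self):
        def bad(r):
            if r == 3:
                raise ValueError("boom")
            return [(r, r)]

        with pytest.raises(StageError, match="record 1"):
            run_map([2, 3], bad)

    def test_reduce_error_names_key(self):
        def bad(k, vs):
            raise ValueError("boom")

        with pytest.raises(StageError, match="'k1'"):
            run_reduce([("k1", [1])], bad)

    def test_chunking_does_not_change_output(self, rng):
        records = list(rng.integers(0, 10, size=23))
        fn = lambda r: [(int(r) % 3, int(r))]
        base = run_map(records, fn, workers=1)
        for chunk in (1, 2, 7, 50):
            assert run_map(records, fn, workers=2, chunk_size=chunk) == base


@pytest.fixture(scope="module")
def small_sim():
    return simulate(SimConfig(n_arrays=6, n_probesets=100, seed=31))


@pytest.fixture(scope="module")
def sequential_em(small_sim):
    return run_rma_pipeline(small_sim.arrays, PipelineConfig(workers=1))


class TestRmaPipeline:
    def test_output_shape_and_labels(self, small_sim, sequential_em):
        em = sequential_em
        assert em.values.shape == (100, 6)
        assert em.probeset_ids == small_sim.layout.probeset_ids
        assert em.array_ids == small_sim.arrays.array_ids

    @pytest.mark.parametrize("workers,chunk", [(2, None), (4, None), (3, 1)])
    def test_parallel_equals_sequential(self, small_sim, sequential_em, workers, chunk):
        em = run_rma_pipeline(
            small_sim.arrays, PipelineConfig(workers=workers, chunk_size=chunk)
        )
        assert np.max(np.abs(em.values - sequential_em.values)) <= 1e-12

    def test_matches_straight_line_composition(self, small_sim, sequential_em):
        ref = straight_line_rma(small_sim.arrays)
        assert np.allclose(sequential_em.values, ref, atol=1e-12)

    def test_mappers_see_single_arrays_only(self, small_sim):
        # Cross-array information may flow only through the quantile
        # reference reduce; per-record map inputs are single arrays.
        seen = []
        records = [(i, v) for i, v in enumerate(np.eye(3))]

        def spy(record):
            seen.append(record[0])
            return [("k", record[0])]

        run_map(records, spy, workers=1)
        assert sorted(seen) == [0, 1, 2]

    def test_empty_arrayset_rejected(self, small_sim):
        from rmaflow.io_model import ArraySet

        empty = ArraySet(layout=small_sim.layout, arrays=[])
        with pytest.raises(ValueError, match="no arrays"):
            run_rma_pipeline(empty)
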