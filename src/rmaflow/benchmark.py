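"""Wall-clock scaling harness.

Times the full pipeline over growing batches of synthetic arrays, for
one or more worker counts.  The numbers are hardware-bound and carry
no pass/fail semantics; the harness exists to show the qualitative
shape — how preprocessing time grows with the number of array files
and where (if anywhere, on the machine at hand) parallel execution
overtakes sequential.
"""

from __future__ import annotations

import time
from dataclasses import replace

import pandas as pd

from .engine import PipelineConfig, run_rma_pipeline
from .synth import SimConfig, simulate

DEFAULT_FILE_COUNTS = (10, 50, 100, 150, 200)


def run_benchmark(
    file_counts=DEFAULT_FILE_COUNTS,
    workers_list=(1, 4),
    n_probesets: int = 200,
    probes_per_set: int = 11,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Return a tidy frame with one timed pipeline run per row."""
    base = config or PipelineConfig()
    rows = []
    for n_files in file_counts:
        sim = simulate(SimConfig(n_arrays=n_files, n_probesets=n_probesets,
                                 probes_per_set=probes_per_set, n_de=0, seed=seed))
        for workers in workers_list:
            cfg = replace(base, workers=workers)
            t0 = time.perf_counter()
            run_rma_pipeline(sim.arrays, cfg)
            rows.append({
                "n_files": n_files,
                "workers": workers,
                "seconds": time.perf_counter() - t0,
            })
    return pd.DataFrame(rows)


def plot_benchmark(df: pd.DataFrame, path: str) -> None:
    """Line plot of wall time vs file count, one line per worker count."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for workers, sub in df.groupby("workers"):
        sub = sub.sort_values("n_files")
        ax.plot(sub["n_files"], sub["seconds"], marker="o", label=f"workers={workers}")
    ax.set_xlabel("number of array files")
    ax.set_ylabel("wall time (s)")
    ax.set_title("Preprocessing time vs batch size")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
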