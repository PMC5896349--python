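# rmaflow

RMA preprocessing of probe-level oligonucleotide microarray data,
executed through a small, deterministic local map/shuffle/reduce
engine — with a synthetic-chip generator so the whole pipeline can be
exercised and validated without any real array files.

## The problem

An expression microarray reports one fluorescence intensity per probe
cell; each gene is interrogated by a *probeset* of ~11 perfect-match
(PM) probes. Turning hundreds of per-array probe files into a single
genes × samples expression table requires three statistical steps,
jointly known as RMA (robust multi-array average):

1. **Background correction.** Each observed PM intensity is modelled
   as a Gaussian background plus an exponential signal,

   PM = bg + s, bg ~ N(μ, δ²), s ~ Exp(λ),

   and replaced by the posterior mean E[s | PM], which has the closed
   form

   E[s | PM] = a + b·(φ(a/b) − φ((PM−a)/b)) / (Φ(a/b) + Φ((PM−a)/b) − 1),

   with a = PM − μ − δ²λ, b = δ, and φ/Φ the standard normal density
   and CDF. (μ, δ, λ) are fitted per array by maximum likelihood of
   the convolution density.

2. **Quantile normalization.** Every array's intensity distribution is
   forced onto the common reference of per-rank means, making arrays
   comparable.

3. **Median-polish summarization.** Within each probeset, the log2
   intensities follow the additive model
   Y<sub>ji</sub> = θ<sub>i</sub> + φ<sub>j</sub> + ε<sub>ji</sub>
   (array expression + probe affinity + error). Tukey median polish
   fits it robustly; the reported expression is the overall term plus
   the array effect.

Each step decomposes naturally onto keyed map/shuffle/reduce stages —
per-array work is *map*, the quantile reference is the single
cross-array *reduce*, grouping probes by probeset is *shuffle*, and
per-probeset summarization is a second *reduce*. The engine here runs
those stages on a local process pool with a hard guarantee that
parallel output is identical to sequential output, element for
element.

## Worked example

Generate a small synthetic study (6 arrays, 200 probesets of 11 PM
probes, 20 probesets differentially expressed by 2 log2 units in the
second group of arrays) and preprocess it:

```sh
$ rmaflow simulate --out-dir demo --n-arrays 6 --n-probesets 200 --n-de 20 --seed 42
wrote 6 CEL files, layout and ground truth to demo (200 probesets x 11 probes, seed 42)

$ rmaflow run --input-dir demo --layout demo/layout.tsv --output demo/expression.tsv --workers 2
... INFO read 6 arrays (2200 probes each) in 0.01s
... INFO pipeline: 200 probesets x 6 arrays in 2.35s
... INFO wrote demo/expression.tsv

$ head -4 demo/expression.tsv
probeset_id  array000   array001   array002   array003   array004   array005
PS00000      10.734883  10.833525  10.534098  10.452338  10.565703  10.589014
PS00001      8.705909   8.626175   8.948984   8.561078   8.615050   8.736750
PS00002      11.455762  11.374181  11.318737  12.942112  12.716170  12.807222
```

Each row is one probeset's log2 expression across the six arrays.
`PS00002` is one of the differentially expressed probesets: its values
jump by ~1.5 log2 units between the first three arrays (group 1) and
the last three (group 2). Comparing the output to the generator's
ground truth (`demo/ground_truth.tsv`) gives per-array Spearman
correlations of 0.996–0.997 with the true expression matrix, and a
mean recovered log2 fold change of 1.74 for the probesets simulated at
2.0 (quantile normalization slightly attenuates global group shifts —
see `docs/methods.md`).

The same pipeline is available as a library:

```python
from rmaflow import SimConfig, simulate, run_rma_pipeline, PipelineConfig

sim = simulate(SimConfig(n_arrays=20, n_probesets=500, seed=7))
em = run_rma_pipeline(sim.arrays, PipelineConfig(workers=4))
# em.values: 500 x 20 log2 expression matrix
```

`rmaflow benchmark` times the pipeline over growing batches of array
files for several worker counts and writes a CSV and plot; the numbers
are hardware-bound and carry no pass/fail semantics.

## File formats

* **ASCII CEL v3** — sectioned text (`[CEL]`, `[HEADER]` with
  `Cols=`/`Rows=`, `[INTENSITY]` with `X Y MEAN STDV NPIXELS` lines);
  the MEAN column is the intensity.
* **Chip layout TSV** — replaces the binary chip description file: a
  `#layout name=... rows=... cols=...` preamble, then
  `probeset_id  x  y  is_pm` rows mapping grid cells to probesets.
* **Expression matrix** — tab-delimited, `probeset_id` first column,
  one column per array, 6 decimal places.

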