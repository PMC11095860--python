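# icipair

Analysis toolkit for **matched pre/post-therapy tumor biopsy pairs**, built
for serial-biopsy studies of acquired resistance (AR) to immune checkpoint
inhibition in solid tumors. Given per-sample variant tables, segmented
copy-number profiles with tumor purity, single-cell spatial tables from
multiplexed immunofluorescence (mIF), and paired IHC measurements, it
answers the questions such a study asks:

- **Are the two biopsies really the same tumor?** A shared-lineage
  similarity score over a cohort event-frequency catalog:

  `score = -ln prod_i [ alpha * f_i^2  if event i in both samples, else 1 - f_i^2 ]`

  where `f_i` is the cohort frequency of event *i* and the product runs
  over the union of the pair's events. Rare shared events dominate; a
  cross-patient permutation null calibrates the shared-lineage call.

- **What is the purity-corrected copy number?** From the overlap-weighted
  gene-level segment log2 ratio *l* and purity *p*:

  `ACN = (2^(l+1) - 2(1-p)) / p`

  so *l* = 0 gives ACN = 2 at every purity. Categories (homozygous /
  heterozygous deletion, neutral, gain, high amplification) and a
  simplified arm-level aneuploidy score (amplitude + coverage rule)
  follow.

- **What changed at resistance?** Acquired mutations (present post, absent
  pre), acquired CNAs (category change away from the pre state), biallelic
  inactivation (acquired mutation + acquired copy loss of one gene),
  cohort summaries with exact denominators, and stratified contrasts with
  Fisher exact tests.

- **How did the microenvironment change?** PD-1/PD-L1 *engagement* — the
  fraction of PD-L1+ cells with a PD-1+ neighbor within 20 µm (boundary
  inclusive, k-d tree backed, brute-force-exact) — tumor-to-CD8+PD-1+
  nearest-neighbor distances, and per-phenotype densities in cells/mm².

- **Is the paired shift real at n = 6?** IHC H-scores
  (`1*pct1 + 2*pct2 + 3*pct3`, range 0–300), absolute/percent change, and
  a Wilcoxon signed-rank test that is *exact* (full sign-flip null with
  average ranks for ties) up to n = 25, plus probability-ordering
  two-sided Fisher exact tests.

A seeded synthetic-cohort generator (`icipair.simulate`) plants acquired
events at configured frequencies, realizes copy-number truths through
segment profiles that invert the ACN formula exactly at zero noise, builds
spatial point patterns whose engagement fraction is exact by construction,
and shifts paired H-scores — so every pipeline stage can be validated
against known ground truth.

## Worked example

```python
from icipair import Segment, absolute_copy_number, weighted_gene_log2

segments = [Segment("chr1", 1, 1000, 1.0), Segment("chr1", 1001, 4000, 0.0)]
l = weighted_gene_log2(segments, ("chr1", 1, 4000))   # 0.25
acn = absolute_copy_number(l, purity=0.3)             # 3.261 -> "gain"
```

Running `python examples/04_spatial_metrics.py` prints

```
PD-L1+ cells              : 52
engaged (PD-1 within 20um): 16
engagement fraction       : 0.3077 (planted 0.3077)
median tumor-to-CD8+PD-1+ distance: 127.4 um (1563 tumor cells)
TIL density               : 84 cells/mm^2
```

— the measured engagement equals the generator's planted fraction exactly
(16 of 52 PD-L1+ cells have a PD-1+ cell within 20 µm), the median
distance from each cytokeratin+ tumor cell to its nearest CD8a+PD-1+
T cell is 127 µm, and the lymphocyte density is 84 cells/mm² on this
1 mm² frame. The other `examples/` scripts cover lineage scoring,
copy-number calling, acquired-event calling, exact paired statistics, and
the end-to-end pipeline.

The same flows are scriptable from the shell:

```bash
icipair run --n-patients 50 --seed 7 --out run_dir      # simulate + analyze
icipair cna --seg run_dir/segments.seg --purity run_dir/purity.tsv
icipair stats fisher 7 5 2 17
```

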