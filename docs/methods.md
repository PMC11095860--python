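# Methods

This note documents the models, conventions and numerical choices behind
`icipair`, and what the synthetic-cohort validation does and does not
establish about real data.

## Shared-lineage similarity score

For a catalog of genomic events (SNVs, small indels, gene-level CNAs,
structural variants) with cohort frequencies `f_i = (samples carrying
i) / N`, a pair of samples (a, b) is scored over the union of their
events:

```
score = -ln prod_i { alpha * f_i^2        if i in a and in b
                     1 - f_i^2            otherwise }
```

`f_i^2` is the probability of observing event *i* independently in two
unrelated samples, so `-ln(alpha f_i^2)` is the surprisal of a shared
event and rare shared events contribute most. Conventions:

- **alpha = 1** by default (pure independence surprisal); exposed because
  the weighting of shared vs unshared evidence is a modeling choice with
  no canonical value.
- **Event universe = union of the pair's events.** An all-catalog mode is
  available (`universe="catalog"`), under which events absent from both
  samples also contribute `-ln(1 - f_i^2)`; it shifts every pair by a
  constant-like term and does not change ranking among pairs scored
  against the same catalog.
- **Natural log**; the base only scales scores.
- **Cohort counting is one sample per patient** (the pre-treatment sample
  by default) so a patient with two biopsies does not inflate their own
  events' frequencies.
- **Unseen events** (when scoring external pairs) are imputed at
  `1/(N+1)` and logged.
- **Known anomaly, kept as defined:** an *unshared* event's factor
  `1 - f_i^2` shrinks as `f_i` grows, so a discordant but very common
  event *increases* the score. The formula is implemented as stated
  rather than "corrected"; with the per-pair universe and realistic
  frequency spectra the effect is small relative to shared-event terms.
- `f_i = 1` with the event unshared yields `-ln(0)`: the contribution is
  reported as `+inf` and the result flagged, never silently dropped.

Because no analytic null exists, `calibrate_null` scores randomly drawn
cross-patient sample pairs (which cannot share lineage); a pair is called
shared-lineage when its score exceeds the null's 95th percentile
(configurable). On simulated cohorts where each patient carries five
private clonal events of frequency 1/N, planted pairs separate from the
null essentially completely — that is a statement about this generative
setting, not about any particular tumor type's event spectrum.

## Absolute copy number

A biopsy with tumor purity `p` whose tumor compartment carries `ACN`
copies of a locus, mixed with diploid normal cells, has expected ratio
`(p*ACN + 2(1-p))/2`, i.e. segment log2 ratio
`l = log2(p*ACN + 2(1-p)) - 1`. The caller inverts this:

```
ACN = (2^(l+1) - 2(1-p)) / p ,   p in (0, 1]
```

This is the only grouping of the inversion for which `l = 0` implies
`ACN = 2` at every purity, and it is strictly increasing in `l`. The raw
value can be negative when the observed ratio is deeper than a pure
homozygous deletion allows; the raw value is preserved in output as a
purity-misestimation diagnostic and clamped at 0 for categorization.

Gene-level `l` is the overlap-length-weighted mean of segment log2 ratios
across the gene, on 1-based inclusive coordinates throughout (SEG files
are read and written without coordinate conversion). A gene with no
overlapping segment is *uncallable* (missing, logged), never defaulted.

**CNA categories** use module-default ACN cut points 0.5 / 1.5 / 2.5 /
6.0 (homozygous deletion < 0.5 ≤ heterozygous deletion < 1.5 ≤ neutral ≤
2.5 < gain ≤ 6.0 < high amplification), boundaries assigned to the class
nearer neutral. These mirror common targeted-panel practice; the category
names are standard but no universal cut points exist, so they are
config-exposed and recorded in output.

**Aneuploidy** is a deliberately simplified arm-level caller: an arm with
at least 70% of its length covered by segments is called gained (lost)
when ≥ 70% of the covered length has log2 ratio ≥ +0.2 (≤ −0.2); the
score counts gained + lost arms. It follows the amplitude-plus-coverage
logic of arm-level callers for targeted panels without their
quality-weighting machinery, and says so in its docstring.

## Acquired-event calling

Matching is presence/absence on canonical event identity (targeted-panel
setting; no allele fractions): a mutation is acquired iff its event key
is in the post sample and not the pre sample — any pre-treatment presence
blocks the call. A CNA is acquired iff the post category differs from the
pre category and is non-neutral (neutral→loss, neutral→amplification and
heterozygous→homozygous deletion all qualify). Genes uncallable at either
timepoint are skipped, not guessed. Reversions (present pre, absent post)
go to a separate "lost" table. Benign-predicted and clonal-hematopoiesis
(CHIP) flagged variants are filtered before calling; flags are consumed
as input, with absent flags treated as false and logged.

**Biallelic inactivation** = acquired mutation + acquired copy loss of
the same gene in the same post sample.

Summaries report percentages with explicit denominators (pairs with
genomic profiling), rounded to one decimal; per-gene counts deduplicate a
patient within each finding type. Stratified contrasts (time-to-AR cutoff
at 6 months, therapy category, best response, PD-L1 TPS bin) produce 2×2
Fisher exact tests per outcome — stratum vs rest when more than two
strata exist; pairs missing the stratification variable are excluded with
a log line.

## Spatial metrics

Cells are centroids in microns with boolean marker flags (a pixel→micron
scale factor is applied at I/O when given). Neighbor queries use a k-d
tree; the distance of each reported pair is computed with `hypot`, whose
libm rounding is identical scalar or vectorized, so results are
bit-identical to a brute-force all-pairs scan (verified on random frames
up to 2,000 cells).

- **Engagement**: fraction of PD-L1+ cells with ≥ 1 PD-1+ cell within
  20 µm, boundary *inclusive* (d ≤ 20). The pre-normalization pair count
  is also emitted. Zero PD-L1+ cells make the fraction undefined
  (missing), never 0.
- **Nearest distance** (default cytokeratin+ tumor cells →
  CD8a+PD-1+ T cells): per-cell nearest neighbor distance, median
  summary; double-positive cells never pair with themselves.
- **Density**: matching cells / tissue area (cells/mm²); linear in
  counts, inverse in area.

Distances are center-to-center; no cell-shape modeling and no edge
correction — instead the fraction of query cells within 20 µm of the
frame's bounding box is recorded as a diagnostic.

## Exact paired statistics

- **H-score** `= 1*pct1 + 2*pct2 + 3*pct3` from intensity-proportion
  profiles that must sum to 100; range 0–300. Percent change from a zero
  baseline is reported missing, not infinite. H-scores may equally be
  consumed directly as numbers.
- **Wilcoxon signed-rank**, two-sided. Zero differences are dropped by
  default (classic behavior; the Pratt variant, which ranks zeros before
  discarding them, is behind a flag). For ≤ 25 informative pairs the p is
  exact: the null distribution of `W+` is built by convolution over the
  rank multiset (ranks are sign-invariant even with ties, which receive
  average ranks; doubling maps half-integer ranks to an integer lattice),
  and the two-sided p doubles the smaller tail, capped at 1. Above 25
  pairs: normal approximation with continuity and tie corrections. This
  is hand-implemented because no installed routine combines an exact
  branch with average-rank ties.
- **Fisher exact**, two-sided by probability ordering (tables with
  probability ≤ observed), delegated to scipy; a central (doubled-tail)
  variant is flagged. Zero-margin tables return p = 1 with a warning. A
  continuity-corrected chi-square is provided only as the large-sample
  fallback. No multiplicity correction is applied by default.

## Synthetic cohort generator

The generator's defaults are the study conditions the package is
validated under; they emulate a serial-biopsy AR cohort:

- **n = 82 patients**; therapy mix 56.1% PD-(L)1 monotherapy / 6.1%
  PD-1+CTLA-4 / 37.8% chemo-immunotherapy; best response 2.4% CR / 41.5%
  PR / 56.1% SD; time-to-AR ≥ 3 months (3 + Gamma(2, 3) months).
- **Acquired events** are planted per patient per event, independently,
  at published cohort rates (e.g. STK11 LOF mutation 8.9%, B2M 6.3%; B2M
  heterozygous loss 22.8%, CDKN2A homozygous deletion 8.9%, MDM2
  amplification 5.1%). An explicit `biallelic_freqs` knob plants
  concurrent mutation + heterozygous loss (STK11 5.1%, SMARCA4 2.5%,
  KEAP1/B2M/JAK1 1.3%), since concurrence is observed but no generative
  co-occurrence model is published. Under independence the *union* rates
  (patients with ≥ 1 acquired mutation / CNA) exceed the corresponding
  observed cohort rates, which reflect strong per-patient co-occurrence;
  cohort-proportion identities are therefore checked on manifests with
  prescribed counts, where they are arithmetic.
- **Baseline events** (e.g. KRAS G12C at 34.1%) appear in both samples;
  each patient also carries Poisson(4) private clonal variants, the
  signal the lineage score keys on.
- **Copy number**: purity ~ U(0.3, 0.9), equal pre/post (purity was
  reported similar across timepoints; the range is a realistic
  targeted-panel assumption). True ACNs (loss 1.0, homozygous deletion
  0.25, amplification 8.0) are realized as segment profiles via the exact
  inverse formula plus Gaussian log2 noise (default sd 0.05), with
  copy-neutral background segments; at zero noise the production caller
  recovers planted ACN to < 1e-9. Calls are re-derived through the
  segment path so category noise behaves as on real segmented data.
- **Spatial frames** (6 patients by default, matching a small mIF
  subset): homogeneous Poisson placement per cell class on a 1 mm² frame
  (a clustered Thomas-process option exists but is off — no point-process
  model is published). Default densities put tumor cells at
  1,540/mm² (40/mm² PD-L1+) and total lymphocytes at 88/mm²
  pre-treatment, scaled by 36/88 post — the published TIL medians. The
  engagement construction designates `round(target * n_PDL1)` PD-L1+
  cells as interactors, places one PD-1+ companion 3–12 µm from each, and
  keeps every other PD-1+ cell > 21 µm from all non-interactor PD-L1+
  cells, so the realized fraction equals `round(target*n)/n` *exactly*
  (exactly the target at 0 and 1). Target engagement defaults: 0.30 pre,
  0.10 post — the published comparison reports a significant decrease
  without printing values, so these are package choices. Coordinates are
  rounded to 0.01 µm for cross-platform file stability; the 1 µm margin
  over the 20 µm radius absorbs the rounding.
- **H-scores** (8 patients by default): pre ~ N(285, 20) clipped to
  [0, 300]; post = pre − 70 + N(0, 25), clipped — a shift matching the
  published paired medians (300 → 230).

All randomness flows from one integer seed through spawned generator
streams; identical configs give byte-identical outputs (files included).

**What passing recovery tests shows — and does not.** Recovery of planted
frequencies, engagement fractions and copy numbers demonstrates that the
calling chain is unbiased under the generator's assumptions:
independent events, categorical CNAs realized without subclonality,
presence/absence variant detection with no sequencing noise, Poisson
spatial nulls, equal pre/post purity. Real cohorts violate all of these
to some degree (co-occurring events, subclonal fractions, detection
limits near purity bounds, clustered tissue architecture), so green tests
certify the *computations*, not robustness to those violations.

The joint recovery assertion ("every planted frequency within its exact
binomial CI") uses Šidák-adjusted per-event Clopper–Pearson intervals
(per-event confidence `0.95^(1/m)` for m planted events) so the *family*
coverage is 95%; per-event 95% intervals would fail ~84% of seeds across
m ≈ 36 events by construction. The single-event demonstration keeps its
plain 95% interval.

## Problem sizes

Default validation sizes — 500-patient recovery cohorts, 200 random
frames (≤ 2,000 cells) for neighbor-search equivalence, 1,000 random
instances for the similarity oracle, 200 planted clonal pairs against a
500-permutation null — run in seconds to a couple of minutes on one core
and were chosen as the smallest sizes at which the binomial/permutation
arguments above have meaningful resolution.

## Known limitations

- No VAF/CCF modeling: "acquired" is presence/absence; emergence of a
  pre-existing subclone below detection is indistinguishable from true
  acquisition.
- The arm-level caller is a simplification; it is not a substitute for a
  full arm-level event caller on real panels.
- Survival analysis, TMB computation, CHIP prediction and image/cell
  segmentation are out of scope; their outputs are consumed as inputs.
- The pipeline's file-based mode re-derives copy-number calls with the
  bundled synthetic gene panel unless a real interval table is supplied
  through the library.
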