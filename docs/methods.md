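# Methods

## Generative model of the simulator

The simulator emulates a six-genotype rescue screen measured in technical
replicates. Gene *g* in sample *s* (role *r(s)*, library size *N_s*) has
count

    X_gs ~ NB(mu_gs, phi),    mu_gs = b_g · (N_s / 10^6) · 2^(delta_g(r(s)))

with the mean–dispersion parameterisation Var = mu + phi·mu². phi = 0
degenerates to Poisson. Per-gene baselines b_g are lognormal around
`baseline_mean` (default 200 counts at 10⁶ library size, natural-log
sigma 1.0), giving the ~2 decades of dynamic range typical of bulk
expression data. Default library size is 10⁶ per sample; lengths are
drawn uniformly in [500, 5000] bp so FPKM normalisation is exercised
non-trivially.

The planted shift delta_g depends on the gene's class:

- **NULL** — 0 in every role.
- **RESTORED** — ±`effect_log2fc` in the pathogenic role only; wild-type,
  protective and rescue roles sit at baseline. This encodes "altered
  pathogenically, reversed by protection/rescue": both ordered contrasts
  WT→pathogenic and pathogenic→rescue have expected log2FC of opposite
  sign and equal magnitude.
- **NOT_RESTORED** — the shift persists in the rescue roles (and,
  optionally via `shift_protective`, in the protective-only roles; the
  default leaves protective genotypes at baseline, i.e. protection alone
  resembles wild-type).

Signs are assigned per gene at random. All randomness flows from one
`numpy.random.Generator` seeded by `SimulationConfig.seed`; identical
configs are bit-identical.

The **standard screen simulation** used by the test suite and the
acceptance script is 2000 NULL + 100 RESTORED genes at effect 1.5 log2
units, dispersion 0.05, 3 technical replicates per role, seed 7. These
sizes keep the whole suite fast while leaving ~100 true positives, enough
to estimate sensitivity to a few percent.

What the simulator does **not** model: read-level structure (FASTQ,
positional coverage), isoform mixtures, GC/length bias, batch effects,
correlated genes, and biological (between-animal) variability — the
replicates are technical, i.e. exchangeable draws from one NB law.
Passing tests therefore demonstrate the pipeline's statistical behaviour
under its stated model, not robustness to the full messiness of real
libraries.

## FPKM

FPKM = count · 10⁹ / (effective_length_bp · total_mapped). Depth defaults
to the column sum of the count matrix (no alignment layer exists in this
pipeline) and can be overridden per sample. Effective length is the
annotated feature length; no fragment-length correction is applied. Two
identities are enforced by tests: mass conservation
(Σ_g FPKM·len·N/10⁹ = column total) and invariance of FPKM under uniform
scaling of a column's counts.

## Differential test

Contrasts are ordered: the reported log2FC is the mean of
log2(FPKM + pseudocount) in `group_to` minus that in `group_from`
(pseudocount 1.0 FPKM). Significance per contrast is controlled with
Benjamini–Hochberg q-values; the screen threshold is q < 0.05 applied
per contrast.

The default statistic is a **moderated t**. Per gene, the pooled
within-group variance s² (df = n₁+n₂−2) is shrunk toward a prior fitted
across genes by moment-matching log s² against a scaled-inverse-χ² law
(the limma-style squeeze): posterior variance
(d₀s₀² + df·s²)/(d₀ + df), reference distribution t with d₀+df degrees
of freedom; d₀ = ∞ (common variance) when the spread of log variances
does not exceed χ² sampling noise. The rationale is the screen's
replication level: with three technical replicates the per-gene variance
estimate has 4 df and the plain Welch t has essentially no power at
BH-corrected thresholds over thousands of genes, whereas the dominant
technical noise is well described by a shared mean–variance law —
exactly the situation variance moderation was designed for, and the same
pooling-across-features idea used by mainstream RNA-seq DE tools. The
classical Welch t (Welch–Satterthwaite df, per-group variance floored at
1e-8) remains available via `TestParams(moderate_variance=False)` and is
used in tests as the hand-checkable closed form.

Degenerate inputs: groups with all-identical values give log2FC 0 and
p = 1; a variance floor of 1e-8 (log2 scale squared) prevents division
by zero when one group is constant; a group with fewer than two
replicates is an error, since no variance can be estimated.

## Directional rescue filter

With criteria (q*, c) — defaults (0.05, 0.3):

- NOT_SIGNIFICANT unless the pathogenic contrast has q < q* and
  |log2FC| > c (strict; ties at exactly c are excluded).
- RESTORED_UP / RESTORED_DOWN when **every** reversal contrast has
  sign opposite to the pathogenic log2FC, |log2FC| > c, and — default,
  toggleable via `require_reversal_significance` — its own q < q*.
  Requiring significance in the reversals is the conservative reading of
  "reversed"; the relaxed variant (sign and magnitude only) is
  first-class because reversal contrasts may be underpowered.
- NOT_RESTORED otherwise.

The per-contrast gene sets feeding the three-way Venn intersection apply
the magnitude cutoff *before* intersecting (the default); the deferred
ordering — intersect q-significant sets first, cut on magnitude later —
is available via `cutoff_before_intersect=False`. Under the default the
RESTORED set is contained in the triple intersection, a structural
invariant the tests assert. Which reversal contrasts must agree is
configurable (protective only, rescue only, or both); the default
requires every supplied reversal contrast.

## Enrichment

The EASE score is the one-tailed Fisher exact (hypergeometric upper-tail)
probability of the 2×2 list/term table with the list-hit count replaced
by max(count−1, 0). The jackknife makes 0- and 1-gene overlaps
uninformative (p = 1) and is conservative relative to plain Fisher
(offered behind `jackknife=False` for cross-checks). Per term the chart
reports: count, percent of the submitted list (denominator = submitted
genes mapped to the catalog, overridable), EASE p, list total (list genes
with any annotation in the category), fold enrichment
(count/list_total)/(pop_hits/pop_total), and BH FDR across the terms
tested within the category (terms reaching `min_count`, default 2).
The background universe defaults to the union of all member sets and can
be supplied explicitly; population margins are always computed after
intersecting member sets with the universe.

## Comparative Ct

Relative quantity = E^(−ΔΔCt) with efficiency E fixed at 2.0 by default
(an efficiency parameter is accepted). Per genotype, ΔCt values are
averaged before the ΔΔCt point estimate — so the calibrator genotype's
mean RQ is exactly 1 — while per-replicate RQs supply the spread. The
spread is the population (n-denominator) standard deviation, which makes
the summary invariant under exact duplication of the replicate set.
Closed-form identities (self-calibration = 1, one-cycle shift = 2, global
Ct-shift invariance, sample/calibrator inversion) are property-tested.

## Ordination

PCA of the samples × log2(FPKM+1) matrix after gene-wise centering; no
unit-variance scaling by default (high-expression genes keep their
weight, the usual choice for transcriptome PCA; scaling is a flag). Axis
signs are fixed by making the largest-magnitude gene loading positive, so
maps are reproducible run to run. The screen-level claim checked on the
standard simulation: both rescue genotypes' mean coordinates lie closer
to wild-type than the pathogenic genotype's do — the geometry expected
when restored genes dominate the between-genotype variance.

## Pipeline

`run_all` sequences simulate/load → FPKM → contrasts → screen →
enrichment → qPCR → PCA, writes every intermediate as TSV and a
`manifest.json` recording stage order, parameters, the seed and SHA-256
digests of all inputs and outputs (paths stored relative to the output
directory), so a rerun with the same config and seed reproduces every
byte. A stochastic stage without an explicit seed is an error, never a
silent default. Optional stages (no GMT catalog, no Ct table) are skipped
and the skip is recorded.

## Known limitations

- Technical-replicate inference: the test treats replicates as the unit
  of variance; conclusions transfer to biological populations only with
  biological replication.
- The moderated test assumes a shared mean–variance law across genes;
  strong heteroscedastic subpopulations would dilute the prior.
- Enrichment FDR is computed within each annotation category over the
  terms actually tested; it is not a genome-wide FDR, and fold
  enrichment depends entirely on the chosen background universe.
- FPKM depth defaults to in-matrix column sums, which differs from
  aligner-reported mapped totals when features are filtered upstream.
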