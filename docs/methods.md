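# Methods note

This note records the statistical model, the default parameterization of
the synthetic generator, and the numerical choices made in `metorgan`. It
makes no empirical claims beyond what the test suite and
`scripts/acceptance.py` compute.

## Statistical methods

### 2x2 site-vs-primary tests

For a gene with `k_site / n_site` altered samples at a metastatic site and
`k_kidney / n_kidney` at the primary, the 2x2 table is tested two-sided
with Fisher's exact test when any expected cell count is below 5 and with
Pearson chi-square otherwise. Choices:

- **No continuity correction** on the chi-square. Yates' correction makes
  the test conservative at moderate n; the uncorrected statistic is
  approximately calibrated in the regime where the chi-square branch is
  selected (all expected counts >= 5), which the type-I simulations
  confirm.
- **Untestable tables** (a zero row or column margin) return `p = NaN` and
  are excluded from BH adjustment rather than silently assigned p = 1.
- Direction ("enriched"/"depleted") compares the two rates; exact ties
  report "enriched".
- The Fisher branch is verified against exhaustive hypergeometric
  enumeration on every 2x2 table with total n <= 40 (agreement < 1e-10).

### Mann-Whitney U

Two-sided throughout. The exact null distribution is used when the smaller
group has <= 8 observations and the pooled data has no ties; otherwise the
tie-corrected normal approximation **without continuity correction** is
used. The continuity correction was deliberately dropped: with it, the raw
flag rate on null data sits visibly below the nominal 5%, and downstream
screens compare flag counts across sites, where a calibrated raw rate
matters more than exactness in the extreme tail. Degenerate rows whose
pooled values are all identical return p = 1. The exact branch is verified
against the all-permutations null for all group-size pairs in 2..7.

### Multiple testing

Benjamini-Hochberg via `statsmodels` (`fdr_bh`), applied once across each
whole screen (not per site or per gene). NaN p-values pass through as NaN
and do not consume rank positions.

### Subtype classification

Expression x is transformed to log2(x+1) and z-scored per gene over the
pooled cohort with sample standard deviation (ddof = 1). Constant genes
map to all-zero z rows (with a warning) instead of NaN. Signature scores
are unweighted means of member-gene z-scores. Composite scores are
`C = W @ S`; the assigned subgroup is the argmax over the 7 subgroups, and
exact ties break by the declared subgroup order (first wins). The
coefficient matrix `W` is a runtime input; the shipped default is a
row-normalized incidence matrix over the synthetic signatures (each
subgroup weights its own characteristic signatures 1/k), which is what the
generator's latent structure warrants. Real analyses should supply a `W`
derived from their reference cohort.

### Differential expression

`log2fc = log2((mean_B + 1) / (mean_A + 1))` computed on linear-scale
means (the +1 pseudocount bounds the ratio for silent genes). Flags: "up"
when log2fc >= 1 and BH q < 0.05, "down" for the mirror, else "ns".
Over-representation uses the hypergeometric survival function
`sf(k-1, N, K, n)` over a user-supplied universe, with the DEG list
required to be a subset of the universe.

### TME and checkpoint comparison

Population abundance is the mean log2(x+1) over the population's marker
genes (MCP-counter style). Per-(population, site) and per-(checkpoint
gene, site) comparisons vs kidney use the Mann-Whitney machinery above;
star buckets are assigned from raw p at 0.05 / 0.01 / 0.001 / 0.0001.
Sites with fewer than 2 samples are reported as untested rather than
dropped.

### Biomarkers

- TMB = count of missense, nonsense, in-frame indel, and frameshift calls
  not known to be germline, divided by `panel_mb` (default 1.4 Mb, a
  typical large-panel coding footprint); TMB-high at >= 10/Mb, boundary
  inclusive.
- PD-L1 (SP142 convention): positive iff intensity >= 2+ and >= 5% tumor
  cells stained, both boundaries inclusive.
- MSI consensus over up to three platforms: unanimity wins; on discordance
  the IHC call decides; discordance without IHC is "indeterminate".
  Missing platform calls (None/NaN) are simply absent.

## Synthetic generator

The generator exists to validate the pipeline, not to model RCC biology
faithfully. Scope and defaults:

- **Cohort composition.** 657 samples by default: kidney 340, lung 66,
  bone 50, soft tissue 40, liver 28, lymph node 26, endocrine 23, pleura
  20, CNS 14, skin 10, GI tract 9, other 31. The four smallest counts are
  plausible placeholders chosen to be consistent with the per-site
  denominators exercised in the tests; they are configurable.
- **Alterations.** Per-(gene, site) Bernoulli alteration probabilities;
  defaults use overall rates (e.g. VHL 0.619, PBRM1 0.382, SETD2 0.206)
  with a small set of site-specific overrides that plant enrichment
  effects (e.g. PBRM1 at lung 0.477, TP53 at bone 0.229, PTEN at liver
  0.214). Per-gene evaluable fractions subsample the denominator.
  Passenger VUS/benign/germline rows top each sample's qualifying-variant
  count up to Poisson(tmb_rate x panel_mb), so the pathogenicity and
  germline filters are exercised without affecting driver frequencies.
- **Expression.** log2 expression = baseline (5.0) + signature effect
  (2.0 for the latent subtype's signature genes) + metastatic DE effects
  (e.g. ASPN +2, REN -3) + per-(population-or-gene, site) TME shifts +
  N(0, 0.5); then exp2 to linear scale. Latent subtypes are drawn from
  per-site priors.
- **Platform calls.** MSI truth at rate 0.01; discordance flips one
  non-IHC platform; PD-L1 intensity categorical (0.35, 0.2, 0.25, 0.2)
  with Beta(1.2, 3)-distributed percent staining. The NGS unstable-loci
  count is drawn consistent with the call around a 46-locus threshold.
- **Determinism.** All draws come from `np.random.default_rng(seed)`; the
  platform-call generator uses `SeedSequence([seed, 1])` so it is
  independent of cohort generation but still seed-derived. TSV outputs are
  sorted on natural keys and formatted with 6 significant digits, so equal
  seeds give byte-identical files.

## Limitations

- The generator's effects are additive on the log2 scale with homoskedastic
  Gaussian noise; real expression has heavier tails, correlated genes, and
  library-size artifacts. Calibration results transfer only to the extent
  the rank-based tests are distribution-free.
- The default subtype coefficient matrix is synthetic-identity style;
  classifier accuracy statements hold for the generator's latent model,
  not for any real reference classifier.
- Fisher's exact test is conservative by construction; the type-I
  calibration checks therefore target the chi-square/asymptotic branches,
  while the exact branches are verified against enumeration oracles
  instead.
- Per-site sample sizes below ~10 leave 2x2 screens severely underpowered;
  the package reports such tests honestly (wide-p, Fisher branch) rather
  than suppressing them.
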