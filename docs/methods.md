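# Methods

## Model and procedure

The pipeline compares the *distribution* of pairwise coexpression between
two phenotype groups rather than testing pairs one at a time. Inputs are a
normalized expression matrix (genes × samples, e.g. VSN-transformed
microarray intensities), a two-group sample labelling, a TF → target-gene
reference, and a named gene-set collection.

1. **Preprocessing.** Probes are collapsed to genes by the arithmetic mean
   of probe intensities per sample, on the normalized scale as provided;
   no re-normalization is attempted. Rows with any missing value are
   dropped (complete-case) — Pearson correlations over differing sample
   subsets would make the two groups' level distributions incomparable on
   a common grid. Each group must contain at least 3 samples: |r| from two
   samples is identically 1 and carries no information.
2. **Candidate selection.** Candidates are the intersection of the target
   sets of all requested TFs, restricted to measured genes, sorted
   lexicographically. Symbols are matched exactly after upper-casing and
   whitespace stripping; the fixed ordering makes pair enumeration
   (always i < j) deterministic.
3. **Coexpression.** For each unordered candidate pair and each group, the
   level is |Pearson r| of the two profiles across that group's samples.
   Genes with zero variance in either group are removed first (their
   correlation is undefined; silently scoring them 0 would distort the
   level distributions) and the pair universe is rebuilt from survivors.
   Values are computed in double precision; |r| exceeding 1 by rounding is
   clamped to 1.
4. **Cutoff.** Both groups' levels are summarized by survival functions
   F(c) = Prob(level ≥ c), evaluated on the sorted union of all observed
   levels — survival curves of finite samples are step functions, so the
   deviation extremum occurs at an observed point and no interpolation is
   needed. D = max |F_d − F_n| is the two-sample KS statistic; the cutoff
   C is the smallest grid value attaining D (a deterministic tie-break;
   ties are rare on continuous data but possible). The asymptotic p-value
   is the Kolmogorov tail series 2·Σ_{k≥1} (−1)^{k−1} exp(−2k²λ²) with
   λ = D·√(nm/(n+m)), clamped to [0, 1], without small-sample bias
   corrections — exact p-values may differ from corrected implementations
   in late digits.
5. **Classification.** A pair is *strong* in a group when its level is
   ≥ C there (ties to strong, matching the cutoff's definition as an
   attained level). The four specific classes follow set identities:
   normal-specific strong ≡ disease-specific weak, and vice versa. The
   strong/weak × group proportions are compared with a Pearson chi-square
   (df = 1) without Yates correction; on tables of ~2×10⁴ pairs the
   correction is negligible and the uncorrected statistic is the one that
   matches published reference values for this design.
6. **Gene-set mapping.** Per set: an upper-tail hypergeometric p for the
   candidate/set intersection (annotation context); all pairs of annotated
   candidate genes mapped onto the four classes, giving (a, b, c, d) with
   a = d, b = c; a one-sided Fisher's exact test, upper tail in a (more
   normal-specific strong pairs than disease-specific strong ones),
   computed exactly from the hypergeometric law, with an all-zero table
   scoring p = 1 by convention. Sets with fewer than two annotated genes
   yield no pairs and are kept at p = 1 rather than dropped, so the
   multiple-testing family is explicit. FDR control is Benjamini–Hochberg
   step-up; empirical-null estimators (Storey-type) are deliberately not
   used — they are under-determined at the family sizes (~10 sets) this
   analysis produces. Significance is declared at FDR < 0.05.
7. **Export.** One undirected graph per gene set × pair class (nodes =
   genes, edges = mapped pairs carrying both groups' levels), written as
   SIF (`coexpressed_with` relation) and GraphML; a node attribute flags
   genes shared between several sets' networks. Layout and drawing are out
   of scope.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `tfs` | — | TFs whose target sets must all contain a candidate |
| `cutoff_override` | data-derived C | forces classification at a fixed level (reproduction studies); D/C are still reported from data |
| `fdr_threshold` | 0.05 | BH-FDR significance level across gene sets |
| `universe_size` | measured gene count | hypergeometric annotation universe; override when the collection's universe differs |
| minimum group size | 3 samples | hard floor for a defined, non-trivial Pearson r |

## Synthetic data generator

The generator emulates the study design the method targets: two groups of
8 and 9 samples (a realistic small cohort), 60 genes by default, and a
12-gene block drawn from a single-factor equicorrelation model per group —
gene g in sample s is `baseline + noise_sd·(√ρ·z_s + √(1−ρ)·ε_gs)`, which
gives every block pair population correlation ρ within the group. Defaults
ρ_normal = 0.85, ρ_disease = 0 plant a coexpression module that exists in
the normal state and dissolves in disease; non-block genes are independent
noise. The baseline intensity (8.0) mimics a typical VSN-scale level and
is irrelevant to every correlation-based statistic. The TF reference
forces the block into every TF's target set (so candidate selection
provably recovers it) and the gene-set collection contains one
block-enriched signal set among random sets.

What the generator does *not* emulate: probe-level noise, platform or
batch effects, heavy-tailed intensity distributions, correlated background
modules, and annotation bias. Passing recovery tests therefore shows the
statistical machinery identifies a planted distributional shift under
idealized noise — not that real-data preprocessing artifacts are handled.

## Numerical choices and degenerate inputs

- Survival functions use ≥ (ties included), so F(min) = 1 exactly.
- Cutoff tie-break: smallest grid value attaining D.
- |r| clamped to [0, 1] after `np.corrcoef`; zero-variance profiles raise
  a named degenerate-gene condition rather than returning NaN.
- Chi-square requires all margins positive; a zero marginal is an error,
  not a 0/0.
- Fisher and hypergeometric tails are exact (scipy hypergeometric
  survival function); no normal approximations anywhere.
- All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed reproduces matrices, references and GMT files byte-identically,
  and `report.json` is byte-stable across runs (sorted keys, no
  timestamps).

## Problem sizes

Default analyses run at 60 genes / 17 samples (≤ 1770 pairs) and the
recovery study at 50 replicates; the pair-count law is additionally
exercised at 217 genes (23,436 pairs). These sizes make every stage exact
and the full suite fast while keeping the sampling regime (8–10 samples
per group) identical to the motivating design, where small-sample |r|
distributions are the whole story.

## Known limitations

- The asymptotic KS p-value is anti-conservative for very small pair
  counts; at the default 105–23,436 pairs this is immaterial, but
  permutation p-values are not implemented.
- Pairs sharing a gene are not independent, and the chi-square and KS
  tests treat pair levels as exchangeable observations; this is inherent
  to the method, and p-values should be read as descriptive strength of
  separation rather than literal error rates.
- Only two groups are supported; multi-condition extensions are out of
  scope.
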