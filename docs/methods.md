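# Methods

## Study design and model

The pipeline analyses a paired 2×2 intervention design: two arms of
subjects (intervention vs control activity, default 10 per arm), each
providing one sample immediately before and one immediately after a
session. The scientific question is the condition × time interaction —
whether the post-vs-pre change differs between arms — not any group main
effect.

Counts are modelled per miRNA as negative binomial with a log link:

    K_gs ~ NB(mean = sf_s · μ_gs, Var = μ + α_g μ²)
    log μ_gs = subject_p(s) + β_time·1[post] + β_int,g·1[perf]·1[post]

**Design coding.** The textbook formula `Pair + condition + time +
condition:time` is rank deficient when subjects are nested in condition:
the condition main effect is a linear combination of the subject
indicators. We therefore fit one indicator per subject (absorbing the
intercept and the condition main effect, which is confounded with
subjects and not estimable in this design anyway) plus `time` and
`condition:time`. The interaction contrast — the quantity of interest —
is identical to the nested-recoding alternative; the full model has
2·n_pairs + 2 columns (22 at the default size) and the reduced model
drops exactly the interaction column. `build_design` rejects any rank
deficiency and names the collinear columns.

**Size factors** are median-of-ratios: for every gene with all-positive
counts, form count / geometric-mean ratios per sample and take the
per-sample median; factors are then rescaled to geometric mean one
(an exact convention, convenient for offset comparisons). If no gene has
all-positive counts this normalisation is undefined and the stage raises
a dedicated error rather than guessing.

**Dispersion** is estimated gene-wise, with no sharing of information
across genes, by maximising the Cox–Reid adjusted profile likelihood
`ℓ(α) − ½ log det(XᵀWX)` over `log α ∈ [log 1e−8, log 10]`, alternating
three times with batched IRLS refits of the mean model (the adjustment
term compensates the downward bias of plain ML when p/n is large; with
22 mean parameters in 40 samples plain ML underestimates α enough to
visibly inflate the interaction test, which is why the adjusted profile
is used rather than raw ML). The inner maximisation is a vectorised
golden-section search, so the whole estimation runs as dense linear
algebra across all genes at once. Genes whose IRLS fit fails to
converge fall back to a method-of-moments estimate and are flagged in
the output (`status = ok_mom_dispersion`).

**IRLS** uses the standard NB working weights `w = μ/(1 + αμ)`,
converges on a relative log-likelihood change below 1e−8 (max 100
iterations), clips the linear predictor to ±30 to prevent overflow, and
adds a 1e−10 ridge to the normal equations for numerical safety. The
reported log-likelihood is the exact NB log-likelihood at the fitted
mean. All-zero miRNAs are excluded from fitting but keep their row in
the output with a missing p-value, so the result table always has one
row per input miRNA.

**Testing.** The interaction is tested by a likelihood-ratio statistic
`Λ = 2(ℓ_full − ℓ_reduced)`, floored at zero. By default `run_de`
references Λ to F(1, n − p_full) rather than χ²(1): with a plug-in
dispersion and 22 mean parameters in 40 samples the χ² reference rejects
at ≈6.6% at nominal 5% (and ≈5× nominal at the 0.001 level), while the
F reference — the same device used by quasi-likelihood F-tests in this
field — is calibrated (4.5–5.1% at nominal 5% in 2,000-gene null
simulations, tails near nominal). The asymptotic χ²(1) reference remains
available (`test_reference="chisq"`, and it is the default of the
low-level `lrt_interaction`). Benjamini–Hochberg adjustment is applied
to the tested genes only; missing p-values pass through.

No independent filtering, outlier handling (Cook's distance) or
empirical-Bayes dispersion shrinkage is performed; those are deliberate
simplifications relative to full DESeq2 and are out of scope here.

## Candidate selection

Three conjunctive filters on the DE table, all bounds inclusive:

* `q < 0.05` (BH FDR);
* fold: `max(r, 1/r) ≥ 1.3` where `r` is the intervention arm's
  post/pre fold divided by the control arm's — two-sided, since
  candidates may move in either direction;
* change: `|post − pre| / pre ≥ 0.15` on the intervention arm's
  normalized means.

Folds are computed from normalized arm-level means, not GLM
coefficients, because the 15% criterion is a statement about mean
expression levels; the percentage-change base is the pre-session mean
(the natural reading of "post–pre change"; a mean-of-pre-and-post or
absolute-scale base would be defensible alternatives, which is why the
choice is stated here). miRNAs whose pre-session mean is zero have an
undefined relative change and are excluded with a warning.

## Target filtering

Predicted records (TargetScan-style) are kept iff:

* conserved / broadly conserved family: conserved site AND PCT ≥ 0.2
  AND context++ ≤ −0.15 (both bounds inclusive);
* poorly conserved / other: context++ strictly < −0.15;
* non-canonical sites: always dropped.

The inclusive/strict asymmetry at −0.15 between the two family branches
is intentional and pinned by tests. Records missing a needed score are
dropped conservatively (with a logged count) rather than passed.
Validated records are admitted only with reporter-assay or western-blot
evidence; merging is keyed on (miRNA, gene), with records present in
both sources kept once as `source="both"`. Gene identity is by symbol,
upper-cased, since inputs mix species naming conventions.

## Overlap permutation test

Two gene sets in different species' universes are compared through a
many-to-one ortholog map: the observed statistic is
`|image(set_A) ∩ set_B|` with the image collapsed before intersecting
(unmapped genes contribute nothing). Each of `n_perm` permutations draws
a set of size |A| uniformly without replacement from universe A and one
of size |B| from universe B and recomputes the mapped overlap —
resampled draws may include unmapped genes, exactly as a uniform draw
implies. Ties with the observed value count into the upper tail
(conservative). Two p-value conventions are reported:
`plus_one = (#{null ≥ obs} + 1)/(n_perm + 1)` (default; never exactly
zero) and `raw = #{null ≥ obs}/n_perm`, which can reach 0 for signals
beyond the null's range. In the identity-universe limit the null is
exactly hypergeometric; `hypergeom_tail` (log-space mass summation)
serves as the standing analytic oracle, and agreement is tested at
|U| = 200, |A| = 30, |B| = 40 within Monte-Carlo error.

Because the statistic is integer-valued, the raw p is uniform only on
its achievable grid and conservative in between (bias ≈ half the null's
maximum point mass, a direct consequence of tie-inclusive counting). The
null-calibration check therefore uses sets large enough that the grid is
fine relative to the KS band (sets of 1,200 in universes of 5,000, null
sd ≈ 12, point masses ≈ 0.03); with coarser grids the same estimator is
visibly superuniform without being wrong.

## Cohort statistics

Group comparability uses `t_{1−(1−level)/2, n−1} · sd/√n` confidence
half-widths, two-sided t-tests (Welch by default — the safer choice when
arm variances differ several-fold, as they do for age; a pooled variant
is available by flag), and a two-sided Fisher exact test that sums all
fixed-margin tables whose point mass does not exceed the observed
table's (the common "mass ≤ observed" rule). Degenerate inputs have
stated conventions: both groups constant and equal → t-test p = 1; any
zero margin → Fisher p = 1.

## Synthetic data

The generator produces exactly the structure the analysis assumes — and
nothing more:

* per-gene log2 baselines uniform on (3, 10), spanning low-count to
  abundant miRNAs;
* subject (pair) effects Normal(0, 0.5) on the log2 scale — the simplest
  exchangeable subject model;
* dispersion trend α(μ) = 3/μ + 0.05, mimicking typical bulk count
  data (the asymptote 0.05 ≈ 22% biological CV);
* per-sample depth multipliers uniform on (0.5, 2);
* a planted interaction in `frac_de` (default 5%) of miRNAs, random
  sign, |log2 fold| uniform on (1, 1.5);
* no condition main effect (confounded with subjects) and no common
  time effect by default (`time_lfc = 0`);
* target tables with score distributions straddling the filter
  thresholds (context++ ~ Normal(−0.15, 0.15) clipped to [−1, 0.2],
  PCT ~ Beta(1.2, 3)), categorical annotations drawn independently of
  scores;
* universe pairs at the annotation sizes of the motivating comparison
  (17,926 and 20,219 genes), a many-to-one ortholog map covering 90% of
  universe A by default, and sets constructed so their mapped
  intersection equals the planted overlap exactly.

What the generator does **not** emulate: correlated miRNA expression,
composition effects, zero inflation beyond NB sampling, batch structure,
mean-dependent fold changes, or any biological relation between a
miRNA's expression change and its target annotations. Passing
calibration and recovery tests on this generator therefore demonstrates
correctness of the statistical machinery under the stated model, not
robustness to real-data pathologies.

Problem sizes used in the shipped analyses and checks (800–2,000
simulated miRNAs, 2–5 replicates, 10,000–20,000 permutations) were
chosen to make Monte-Carlo error small relative to the quantities being
checked while keeping each script a desk-scale run.

## Known limitations

* The dispersion estimate is plug-in: its sampling error is not
  propagated into the test beyond the F-reference's residual df.
* The F(1, n−p) reference is itself an approximation; at very low
  counts the discreteness of the data makes the test mildly
  conservative.
* The 15%-change base and the Welch default resolve ambiguities a real
  protocol would have to state; both are flagged above.
* The ortholog map abstraction covers both symbol-equality and curated
  ortholog matching, but cannot decide which a given study used.
* The TF layer of the regulatory network is user-supplied curation; the
  package only assembles and exports it.
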