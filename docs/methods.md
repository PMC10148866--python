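# Methods

## The screening model

`slidekit` screens ordered gene pairs (A, B): A is a *focus* gene whose
loss-of-function (LoF) alterations occur endogenously in tumors and cell
lines; B is the candidate SL partner, possibly druggable.  Evidence is
gathered by eight tests on four modalities and integrated in two stages —
discovery in cell-line dependency screens, confirmation in patient data —
with drug and pathway tests as annotation.

### LoF classification

A variant counts as LoF when its consequence term is high impact (splice
site, nonsense/stop-gained, frameshift indel, start-codon insertion/
deletion/SNP, stop-codon indel, stop/start lost) or when it is missense and
at least 3 of 5 damaging verdicts from external effect predictors agree.
The verdicts are inputs; no predictor is run.  Matching is case-insensitive
over a fixed vocabulary; unknown terms are an error rather than silently
benign.  When fewer than five verdicts are present the consensus is taken
over the available ones if at least three exist, otherwise the variant is
conservatively non-LoF (warned).  Any start-codon-disrupting term counts as
LoF, including start-codon SNPs.

Alteration matrices are binary samples × genes indicators: 1 iff the sample
carries ≥ 1 LoF variant in the gene.  Expression is log2(count + 1) followed
by quantile normalization across samples (reference = mean of sorted
vectors, ties averaged); the pseudocount of +1 is the conventional choice
for raw counts, and the map is idempotent.

### Cell-line tests

**SPID** is a one-sided Wilcoxon rank-sum test of "LoF-A lines have lower
dependency scores for B".  The exact null distribution is used when both
groups have ≤ 25 tie-free observations, otherwise the tie-corrected normal
approximation with continuity correction.  The *positive dependency
percentage* — the fraction of LoF-A lines whose score for B is positive —
is reported as a veto diagnostic (denominator = LoF lines by default; an
all-lines variant is exposed as an option because the phrase is ambiguous
in common usage).

**SPEA** ranks cell lines ascending by dependency score (most sensitive
first) and walks the list: +|score|^w / Σ_hits|score|^w at LoF-A lines,
−1/(N − N_hits) at wild-type lines; the enrichment score ES is the signed
running-sum value of maximal magnitude (∈ [−1, 1]).  The default weight
exponent is w = 1 (GSEA-style); w = 0 gives the classic KS statistic.  If
all hit weights are zero the walk falls back to unweighted with a warning.
Significance comes from reassigning the LoF labels uniformly at random 200
times (permuting labels is equivalent to re-sorting the line list, which
does not change the statistic); p = (b + 1)/(m + 1) where b counts
sign-matched permuted scores at least as extreme — never zero, with floor
1/201 ≈ 0.005 at the default 200 permutations.

### Patient tests

**SoF**: one-sided rank-sum for "B expressed higher in LoF-A tumors"
(compensatory upregulation — selection removed the double-inactivated
cells).  **ExprSL**: Spearman ρ with p from t = ρ√((n−2)/(1−ρ²)) on n−2 df,
two-sided; |ρ| = 1 is reported p = 0 with a degeneracy flag, constant
vectors are inapplicable.

**SurvLRT** assumes the Lehmann model S_g(t) = S(t)^{Δ_g}: the survival of
patients whose tumor has genotype g = (g_A, g_B) is a power of a reference
survival function S, with tumor fitness Δ_g.  S is the Kaplan–Meier curve
of a reference cohort (lifelines), floored at 1e−12 before logs and carried
flat beyond its support.  Under the model −ln S(T) ~ Exponential(Δ_g), so
the group MLE is closed form: Δ̂ = d / Σᵢ(−ln S(tᵢ)) over all patients in
the group (censored included), d = events.  The null δ₀₀ + δ₁₁ = δ₀₁ + δ₁₀
is fit by reparameterizing δ₁₁ and maximizing the 3-parameter log-likelihood
Σ_g (d_g δ_g − e^{δ_g} X_g) with Nelder–Mead (tolerances 1e−8, started at
the unconstrained estimates); 2(ℓ_alt − ℓ_null) is referred to χ²(1).  The
test is two-sided with sign-based flags: SL flag = 1 iff the effect size
δ = δ̂₀₀ + δ̂₁₁ − δ̂₀₁ − δ̂₁₀ < 0, CL flag = 1 iff δ̂₀₀ > δ̂₁₁ (without the
CL condition, inhibiting B therapeutically would make double-inactivated
patients fare *worse* than untreated wild type).  δ₁₁^expected =
δ̂₀₁ + δ̂₁₀ − δ̂₀₀ is reported for interpretation.

**iSurvLRT** replaces g_B with low expression: g_B(t) = 1 iff e_B < t for
thresholds t on the quantile grid q(0.05), …, q(0.5) of B's empirical
expression distribution (duplicates deduplicated, strict inequality).  The
iteration with the smallest p-value is returned with its threshold.  No
multiplicity correction is applied across the grid — the returned minimum
is anti-conservative by construction and should be read as a screening
statistic, not a calibrated p-value.

**Gates.**  Every LoF-based test requires ≥ 20 LoF carriers for gene A
(cell lines or patients as appropriate) to ensure power; the survival tests
additionally require ≥ 5 deceased patients in *each* of the four genotype
groups, including (0, 0).  Applying the deceased gate to the wild-type
group is a deliberate literal reading; `gate_wild_type_group=False` exempts
it.  Gate failures yield inapplicable results (with reason codes), never
exceptions, so a pipeline run always completes.

### Drug and pathway tests

**SPDD**: for each drug annotated to target B, a one-sided rank-sum test of
"response lower (more sensitive) in LoF-A lines" on ln(IC50) or collapsed
log-fold-change; the minimum-p drug is reported *without* inner multiplicity
correction (the per-drug table is retained so users can correct downstream),
and each screen is analyzed separately — response scales are not pooled.
**SPSP**: upper-tail hypergeometric probability of the observed shared-
pathway count given each gene's membership counts and the pathway universe
(default: the number of pathways in the loaded collection, overridable).

### Evidence integration

Per pair, the four cell-line p-values (SPID + SPEA × two screens) are
combined with Fisher's method (−2Σln p ~ χ²(2k)); zero p-values are clamped
to 1e−300 with a warning.  By default a pair must be testable on all
screens to receive a combined value (mirroring a joint-screen design);
`require_all_cellline_tests=False` combines whatever is available.  BH
correction is applied jointly across all tested pairs, both pair series
together; each patient test and SPSP are BH-corrected separately across
their own tested pairs; SPDD evidence deliberately uses the raw p-value.
Note the Fisher combination treats SPID and SPEA on the same screen as
independent, which they are not; the combined p is therefore optimistic and
is used for *ranking*, with the patient-confirmation stage controlling the
false-positive burden.

Evidence criteria: cell line = adjusted combined p < 0.05; SoF adjusted
p < 0.05; ExprSL adjusted p < 0.05 **and** |ρ| > 0.4; SurvLRT/iSurvLRT
adjusted p < 0.05 **and** SL flag = CL flag = 1; SPDD raw p < 0.05; SPSP
adjusted p < 0.05.  A pair is *clinically relevant* when it is a top
cell-line candidate and at least one patient test confirms it; these pairs
are ranked by adjusted combined p, ties broken by raw combined p then pair
name.  Tests not run (missing modality, failed gate) are "not assessed",
never false.  Every threshold above is a `PipelineConfig` field.

No single score summarizing all tests is computed — p-value ranges differ
by orders of magnitude across tests and a sum would be dominated by one of
them; the per-test columns are kept separate in the results table.

## The synthetic-data generator

The generator targets the statistical assumptions of the tests, not
biological realism: no correlation structure between genes, no batch
effects, no mutation signatures.  Passing tests on it demonstrates the
statistics and the plumbing, not performance on real pan-cancer data.

Default study conditions: 60 genes (8 focus × 26 partners = 208 candidate
pairs in two series), 300 cell lines, 800 patients plus a 400-patient
reference cohort, 2 dependency screens, 2 drug screens × 40 drugs, 50
pathways, background LoF prevalence 0.10, and 5 planted SL pairs whose
focus genes carry LoF at prevalence 0.25 (assigned to the first k samples
of a seeded shuffle so the ≥ 20-carrier gates hold by construction).
Planted effects: dependency scores of B in LoF-A lines shift from
N(0, 1) to N(−2, 1); expression of B in LoF-A tumors rises by +2 (log2
units); drug responses for drugs targeting B drop by −2 in LoF-A lines;
pairs are co-assigned to 5 shared pathways.  Survival uses an exponential
baseline S(t) = e^{−λt} with λ = 0.02 month⁻¹ and log-fitness map
δ₀₀ = 0, δ₀₁ = δ₁₀ = −0.2, δ₁₁ = −1.5 (no-epistasis expectation −0.4, so
the planted epistasis is δ = −1.1 with the CL condition satisfied); with
several planted pairs the per-pair log fitnesses add (independent pairs
multiply fitness).  Censoring is independent exponential with its rate
solved numerically so the expected censored fraction is 0.30.  The
exponential baseline keeps every quantity closed form and checkable; the
architecture admits swapping in a Weibull baseline.

One pair cannot carry both the SoF and the expression-threshold survival
signal: upregulating B in LoF-A tumors empties the (LoF-A, low-B) genotype
that iSurvLRT needs.  The default planted profile therefore uses SoF plus
LoF-based survival, and a separate `EXPRESSION_SURVIVAL_PROFILE`
(dichotomization at q(0.25), SoF off) serves threshold-recovery studies.

## Numerical choices and problem sizes

- Exact Wilcoxon null when both groups ≤ 25 and tie-free; tie-corrected
  normal approximation with continuity otherwise.
- Permutation p-values use (b + 1)/(m + 1); closed-form p-values of 0 are
  clamped to 1e−300 before logs.
- SPEA sorting is stable; ties in scores keep input order.
- Nelder–Mead for the constrained survival fit (gradient-free, tolerance
  1e−8, ≤ 4000 iterations, started at the unconstrained optimum); the LRT
  statistic is clamped at 0 against numerical jitter of nested optima.
- Quantile-threshold ties in iSurvLRT: strict `e_B < t`, duplicate
  thresholds collapse to a single iteration; a constant expression vector
  leaves no admissible iteration.
- Results TSVs are written with 6 significant digits in a fixed column and
  row order, so identical inputs and seed reproduce byte-identical output.

Simulation studies in the test suite use sizes chosen for estimator
precision at desk scale: 500 replicates for type-I-error and uniformity
checks (rejection rate 0.05 ± 0.03; Kolmogorov–Smirnov p > 0.01), n = 2000
patients for fitness recovery (within 5% uncensored, 10% at 30% censoring)
and for threshold recovery (exact grid-point recovery in a majority of 100
replicates), and the default 208-pair bundle for end-to-end planted-pair
recovery.

## Known limitations

- Pan-cancer style analysis only: no covariate adjustment, no Cox
  regression, no cancer-type stratification.
- The Fisher-combined cell-line p ignores SPID–SPEA dependence (see above).
- The iSurvLRT minimum over thresholds is anti-conservative.
- The SPSP universe convention (total pathways evaluated, upper tail)
  matters: published shared-pathway p-values computed under other effective
  universes or tail conventions will not reproduce exactly.
- The Lehmann-model group estimator is the closed-form MLE; no small-sample
  variance correction is applied beyond the ≥ 5-deceased gate.
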