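# Methods

## Model

The unit model is a categorical Naive Bayes classifier over SNP genotypes.
Genotypes are ternary attributes coded 0 = homozygous minor, 1 =
heterozygous, 2 = homozygous major (note: the reverse of PLINK's additive
minor-allele dosage; the `.tped` reader performs the flip so every internal
formula sees this orientation). Class-conditional probability tables and
the class prior are estimated by counting with a Dirichlet pseudo-count
*l*:

    theta_ijk = (count{X_i = j, Y = k} + l) / (count{Y = k} + 3 l)
    pi_k      = (count{Y = k} + l) / (n + 2 l)

*l* = 1 (Laplace smoothing) everywhere by default, exposed as a parameter.
No genetic model (additive/dominant/recessive) is assumed: the three
genotype classes are free categories, which is the main reason for
preferring this family over log-additive penalized regression on data with
heterogeneous effect shapes.

Conditional independence of the attributes given the class is the model's
load-bearing assumption. It is enforced approximately, not assumed
blindly: each classifier in the ensemble selects a small attribute set in
which no two SNPs are both physically close (< 1 Mb, same chromosome) and
correlated (r² > θ).

## Training procedure

Bagging with B bootstrap replicates (default 200, B = 50 in the test
harness for speed). Per replicate:

1. Every SNP is scored on the in-bag multiset by the closed-form
   single-SNP score: the MCC that a single-attribute, Laplace-smoothed NB
   classifier would attain when trained and tested on that same sample.
   Three indicator inequalities (one per genotype) determine the induced
   classifier's predictions; the score follows algebraically from the
   contingency table. When all three indicators agree the induced
   classifier is a majority classifier and the score is 0, matching the
   MCC convention for degenerate confusion denominators. The closed form
   is verified in the test suite against a brute-force
   train-and-test-yourself oracle, exhaustively for all tables with
   n ≤ 12 and on random larger tables.
2. Attributes are taken from the top of the ranking in doubling batches
   (1, 2, 4, 8, ...). After each inclusion, all still-eligible SNPs within
   the linkage window and above the r² threshold (computed on the in-bag
   multiset, pairwise-complete over missing genotypes) are removed. A
   grown candidate is kept only if its OOB MCC strictly exceeds the
   incumbent's; the empty classifier counts as OOB MCC 0, so the first
   batch must beat the majority classifier. The first non-improvement
   stops growth and the incumbent is kept. Strictness prefers smaller
   models on plateaus.
3. Ties everywhere resolve deterministically: ranking ties by genomic
   order (chromosome, position, snp_id), posterior ties to the control
   class (the a-priori "healthy" default).

Prediction averages the B posterior pairs; test columns are aligned to
training SNPs by snp_id, never by position.

RNG discipline: one master seed; per-replicate streams are spawned with
`numpy.random.SeedSequence(seed).spawn(B)`, so training is bit-identical
regardless of how many workers run the replicates (`n_jobs`).

## Biomarker selection

SNPs included by at least 5% of the classifiers are candidates. For each
classifier that includes a candidate, the candidate's genotype column is
permuted once, uniformly at random, among that classifier's OOB subjects
(missing values travel with the permutation), and the marginal utility is

    MU = (MCC_orig - MCC_perm) / |MCC_orig|        (absolute decrease
                                                    when MCC_orig = 0)

A one-tailed Wilcoxon signed-rank test (alternative: location > 0, zeros
dropped, exact distribution for tie-free samples up to n = 25, normal
approximation with tie correction beyond) yields a p-value per candidate;
candidates with p < 0.05 are flagged selected. All candidates are reported
in genomic order with their statistics, selected or not. A configuration
knob allows averaging k > 1 permutations per (SNP, classifier); the
default is the single permutation the procedure defines.

## Synthetic data generator

`bonb.synthetic.simulate` emulates the two features of real GWAS panels
the algorithm must handle — linkage structure and planted causal signal —
while staying transparent and exactly seed-reproducible:

* **LD blocks.** Each block has one tag SNP; every proxy copies the tag
  allele-wise with probability q = sqrt(target r²), else draws a fresh
  allele at the block's MAF. Tag–proxy genotype r² therefore hits the
  target; proxy–proxy r² is the target squared (star topology). Blocks
  are separated by more than the 1 Mb window, so the distance condition
  of the pruning rule is exercised in both directions.
* **Causal signal.** Designated blocks carry a penetrance triple
  Pr(case | tag genotype 0/1/2). Multiple causal blocks combine on the
  log-odds scale (multiplicative odds — the standard multi-locus model),
  which keeps each tag's stated triple as approximately its marginal
  penetrance. Subjects are generated in fixed-size batches and kept until
  the case and control quotas fill, fixing class unbalance exactly.
* **Missingness.** Uniform masking at a configurable rate (1% in the
  canonical panel).

The canonical test panel (`standard_fixture`): 1,000 subjects (400/600,
unbalanced to keep the MCC-vs-accuracy distinction visible), 50 blocks ×
10 SNPs, tag–proxy r² 0.6, MAF ~ U(0.2, 0.4), three causal blocks with
triples (0.85, 0.55, 0.25), (0.75, 0.50, 0.30), (0.70, 0.50, 0.35).

What the generator does *not* emulate: haplotype-level LD (proxies are
conditionally independent given their tag), recombination maps, population
structure, genotyping-error models. Two consequences matter when reading
test results. First, passing recovery tests here show the pipeline finds
planted signal and respects the linkage rule — they do not certify
performance on real haplotype structure. Second, because proxies are
conditionally independent given the tag, a plain NB classifier trained on
*all* univariately significant SNPs is unusually strong on this generator
(its redundant proxies average out genotype noise rather than
double-counting correlated evidence), so comparisons against that baseline
on this generator are biased in the baseline's favour relative to real
data.

## Evaluation harness

Repeated random sub-sampling: 90% train / 10% test, default 10
repetitions, summarised as mean ± sd of MCC and accuracy, with
precision–recall and TPR-vs-TNR curves from a threshold sweep over the
distinct posterior values. Splits are stratified by class — a deliberate
choice (plain random splits can produce single-class training sets at
small n); the majority-classifier baseline is computed on the same splits
and its MCC is exactly 0 by the degenerate-denominator convention. The
univariate comparator trains one NB classifier on every SNP whose 2-df
Pearson χ² (general genetic model, applicable only when all six cells
hold ≥ 5 observations) clears p < 5×10⁻⁷ on the training split, falling
back to majority classification when none does. A parameter sweep utility
runs the grid (B, θ) over shared splits and reports a Kruskal–Wallis
p-value across cells.

## Numerical conventions

* Posteriors accumulate in log space with a final two-class softmax;
  smoothing guarantees no log(0).
* MCC returns 0 whenever any denominator factor is 0.
* r² returns 0 for constant columns or fewer than two pairwise-complete
  subjects (treated as uncorrelated, hence never pruned).
* χ² on tables with empty genotype columns is computed on the reduced
  table and marked not applicable.
* Indicator inequalities are evaluated in exact integer cross-multiplied
  form; the score's radicand is guarded so degenerate margins yield 0.

## Known limitations

* **Winner's curse in biomarker selection on small panels.** The MU
  samples of one SNP across classifiers all share that SNP's whole-dataset
  chance association: the direction fitted in-bag carries to the OOB
  subjects whenever the association is a property of the realized dataset
  rather than of one replicate. The signed-rank test treats these
  dependent samples as independent evidence and is therefore
  anticonservative for "dataset-lucky" null SNPs; the OOB-driven
  acceptance gate adds selection conditioning on top (an included SNP had
  positive OOB contribution at inclusion time). At the canonical panel's
  scale (1,000 × 500, B = 50) this produces occasional spurious
  biomarkers from non-causal blocks and non-empty biomarker lists on
  fully null data, which the acceptance tests document. Forcing a null
  SNP into every classifier — bypassing the acceptance gate — restores
  near-nominal type-I behaviour, confirming the mechanism. At
  genome scale with dominant real signal the 5% inclusion rule filters
  most such SNPs before testing, but the effect is intrinsic to
  permutation importance computed on the data that guided selection.
* The OOB set of a bootstrap replicate holds on average e⁻¹ ≈ 36.8% of
  the subjects; OOB-based estimates at n = 1,000 carry the corresponding
  noise, which is what makes the stopping rule and the MU statistic
  noticeably stochastic at test scale.
* Covariates, quantitative phenotypes, >2 classes and haplotype phase are
  out of scope; `.bed`/VCF/BGEN parsing is not provided.
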