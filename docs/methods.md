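# Methods

`brainvar` implements a three-stage integrative analysis for linking a
candidate SNP to a neurodevelopmental phenotype: (1) a developmental
expression-trajectory test on brain transcriptome atlas data, (2) a
cis-eQTL scan of the SNP against nearby genes across adult brain regions,
and (3) a case-control genotype association with genetic-model selection
and power calculation. A synthetic-data module generates inputs with the
statistical structure each stage assumes, so the pipeline is fully
testable without access to the restricted source datasets.

## Stage 1 — developmental expression trajectories

**Data model.** Expression is RPKM from RNA-seq, annotated per sample
with donor, brain region, and developmental age. Ages are normalised to
days post conception with fixed constants: 1 post-conception week = 7 d,
birth (full gestation) = 280 d, 1 month = 30.44 d, 1 year = 365.25 d.
Postnatal atlas ages are not shipped as post-conception days, so these
conversions are part of the model; a sample is prenatal iff its
normalised age is below 280 d. All analysis happens on the log2 scale.

**Zero handling.** `log2(RPKM + offset)` with default `offset = 0`: a
zero RPKM value then has no finite logarithm and is *dropped* from all
means and tests rather than imputed (the retained-sample count in every
summary reflects this). A positive offset retains all values; the choice
is a config knob (`log2_offset`), not hidden behaviour.

**Region filter.** Regions with fewer than `min_region_points` (default
5) retained values for the focal gene are excluded before analysis, and
the dropped regions are reported. With the default atlas geometry this
reproduces a 26-region → 16-region reduction when 10 regions are sparse.

**Permutation test.** The source analyses report a permutation test for
"non-random" developmental patterning without defining the statistic. We
chose the prenatal/postnatal contrast — the most salient feature of the
trajectories in question (low prenatal expression rising toward birth and
sustained afterwards):

    T = mean(log2 postnatal) − mean(log2 prenatal)

The null distribution relabels samples as prenatal/postnatal uniformly at
random, preserving group sizes, and the two-sided p-value uses the
add-one estimator p = (#{|T_perm| ≥ |T_obs|} + 1)/(B + 1), which is a
valid, never-zero p-value at any B. Sample-level exchangeability is the
default permutation unit; with one sample per donor × region × timepoint
(the atlas design) donor-level permutation would be equivalent up to
blocking, and we deliberately kept the simpler unit. B defaults to 999.
The test is invariant to adding a constant on the log2 scale and flips
sign under wholesale label exchange; under the null its rejection rate at
α = 0.05 is calibrated (checked over 200 synthetic replicates).

## Stage 2 — cis-eQTL scan

**Coding.** Genotype calls (VCF or TSV) are additively coded as minor-
allele dosage 0/1/2; the minor allele is the less frequent among
non-missing calls in the defining sample, with exact ties broken to the
lexicographically smaller allele. Only biallelic records are accepted;
multi-allelic VCF records are skipped with a warning; phase is ignored.

**Test.** For each (region, gene) pair, ordinary least squares of
expression on dosage with a two-sided t-test on the slope (n − 2 df),
missing individuals excluded pairwise. Linear regression on dosage is the
convention of the brain-eQTL panels this stage emulates; the exact model
behind the published panel values is not documented, so the simple,
reproducible choice is used. No covariates are included (the emulated
analysis reports none).

**Family control.** The per-test threshold is α/(n_regions × n_genes)
over the *full* grid — e.g. 0.05/(10 × 7) = 7.142857 × 10⁻⁴, displayed as
0.0007 — including pairs that turn out to be untestable (monomorphic
subsets or too few complete observations). Untestable pairs are listed in
the result rather than silently dropped. Each record carries the
direction of effect (which allele raises expression) and the per-genotype
class counts.

**Degenerate inputs.** A pair needs ≥ 3 complete individuals and ≥ 2
distinct dosage values; zero residual variance yields the smallest
positive float as p with a warning rather than p = 0.

## Stage 3 — case-control association

**Input.** A 2×3 table of genotype counts (cases and controls × MM, Mm,
mm), with M/m the major/minor allele defined from controls.

**HWE QC.** Goodness-of-fit χ² (1 df, no continuity correction) of the
control genotypes against Hardy-Weinberg proportions at the allele
frequency estimated from the same counts. Failure (p ≤ 0.05) warns but
does not abort — the analyst sees the flag in the result.

**Model selection (four steps).**

1. OR1 = odd(Mm)/odd(MM) and OR2 = odd(mm)/odd(Mm), with odd(g) =
   cases(g)/controls(g). Any zero cell triggers a Haldane–Anscombe 0.5
   correction on all six cells, flagged in the output.
2. Plot (ln OR1, ln OR2) and select the genetic model whose
   characteristic curve is nearest in Euclidean distance: dominant
   (y = 0), recessive (x = 0), multiplicative (y = x), over-dominant
   (y = −x), additive (y = ln(2eˣ − 1) − x for x > −ln 2, plus its
   reflection through the origin for the protective direction; distance
   minimised numerically). The published selection method cites a plane
   partition without reproducing its geometry; minimal curve distance
   reproduces every exact-locus anchor case and is fully specified, so it
   is our selection rule, documented as an approximation of the cited
   partition. Exact ties break in the fixed order multiplicative >
   dominant > recessive > over-dominant > additive. Points within 0.05
   (configurable) of the origin carry a `near_null` flag but still get a
   model — significance is judged by the Step-3 p-value, not by the
   selection.
3. Unconditional logistic regression of case status on the selected
   model's coding — dominant 1{Mm ∪ mm}, recessive 1{mm}, over-dominant
   1{Mm}, additive dosage 0/1/2, multiplicative on the allele-level 2×2
   (each subject contributes two alleles, treated as independent — the
   standard allelic-test assumption and a documented limitation). Fitted
   by a grouped binomial GLM; the Wald covariance is recomputed from the
   Fisher information at the converged MLE, so binary codings match the
   closed-form 2×2 cross-product OR, CI and p to better than 1e-8.
   Separation (an empty coding level) falls back to the 0.5-corrected
   closed form, flagged. CIs are Wald on the log-OR scale throughout.
4. Model-constrained ORs: multiplicative → (OR, OR); dominant → (OR, 1);
   recessive → (1, OR); over-dominant → (OR, 1/OR); additive →
   (OR, (2OR − 1)/OR).

**The disease model behind simulation and power.** Genotype *odds*
multipliers ψ_MM = 1, with (ψ_Mm, ψ_mm) = (OR, OR²) multiplicative,
(OR, OR) dominant, (1, OR) recessive, (OR, 1) over-dominant, and
(OR, 2OR − 1) additive. The additive rule is risk-scale additivity mapped
to the odds scale under a rare disease; the literature names the additive
model without defining its OR2 constraint, and this convention makes the
Step-4 constraint and the simulator's planted parameter coincide. It
requires OR > 1/2. The baseline odds o₀ is solved by root-finding so that
Σ_g f_g·o_g/(1 + o_g) equals the prevalence, with f_g the Hardy-Weinberg
genotype frequencies; Bayes' rule then gives P(g | case) and
P(g | control). Working on the odds scale means the planted OR is exactly
the estimand of Step 3, so parameter recovery is exact in expectation.
Controls are population non-cases, so control genotype frequencies
deviate slightly from Hardy-Weinberg at appreciable prevalence (they
converge to HWE as prevalence → 0) — relevant because HWE QC runs on
controls.

**Power.** Case and control minor-allele frequencies are derived from the
multiplicative disease model above; power is that of the two-sided
two-proportion χ² (normal approximation, pooled null / unpooled
alternative standard errors). The group-size convention matters. The
classical case-control power calculators this stage mirrors (the
PS/Power family) treat the allele frequency as a per-subject binary
exposure, i.e. use the numbers of *subjects* as the group sizes; that is
the default (`unit="subjects"`) and it reproduces the reference scenario
— MAF 0.4709, prevalence 2 %, OR 1.5, 602/604, α = 0.05 → 93.95 %,
against a published 93.6 % from an unnamed calculator. Counting each
subject's two chromosomes as independent observations (`unit="alleles"`)
gives 99.87 % for the same scenario, which no published figure matches;
the variant is retained as an explicit option. The analytic approximation
is cross-checked against a 50,000-replicate simulation of exposure tables
(agreement well within 1.5 points). At OR = 1 the power equals α exactly.

## Synthetic data: what it does and does not emulate

* **Trajectory generator** — one sample per donor × region × timepoint;
  log2 expression Gaussian around μ_prenatal (default 1.0) before birth
  and μ_postnatal (default 3.0) after, σ = 0.75, stored as RPKM = 2^value.
  Defaults use 16 region codes and 31 timepoints (8 pcw to 40 yrs)
  matching the printed atlas design, with 2 donors giving sample counts
  comparable to the n = 42 atlas. It emulates a clean prenatal→postnatal
  step; it does not emulate smooth age trends within each period,
  donor-level correlation, region-specific means, or the heavy-tailed
  RPKM noise of real RNA-seq. Passing tests therefore demonstrate correct
  inference under the stated Gaussian two-level model, not robustness to
  real atlas noise.
* **eQTL generator** — Hardy-Weinberg genotypes at MAF 0.32 (the allele
  frequency implied by the printed 16/53/64 genotype classes), n = 134,
  10 regions × 7 genes, one planted additive effect (default β = 1,
  σ = 0.3 on the log2 scale) in hippocampus × focal gene. No LD,
  haplotypes, covariates, expression correlation across regions, or
  population structure.
* **Case-control generator** — multinomial genotype rows drawn from the
  status-conditional distributions of the odds-scale disease model;
  defaults 602/604, MAF 0.4709, prevalence 2 %, multiplicative OR 1.5
  (the published power scenario).

All generators take a single integer seed; the pipeline config derives
per-stage sub-seeds deterministically from one master seed, so a fixed
seed yields byte-identical reports.

## Numerical choices and edge cases

* Root-finding for o₀ by Brent's method on the log-odds scale, bracket
  ±60; an unbracketable prevalence raises a domain error.
* Additive-curve distance by bounded scalar minimisation on each branch
  (xatol 1e-12); the anchor-case distances are exact to ~1e-7, far below
  any decision-relevant scale.
* Permutation comparisons use |T_perm| ≥ |T_obs| − 1e-12 so exact ties
  count as extreme (conservative).
* All probability vectors are accurate to 1e-10; report floats are
  serialised with 17 significant digits so write-then-read round-trips
  are exact.

## Known limitations

* The selection plane's additive and multiplicative curves nearly
  coincide for small effects; at modest sample sizes the two models are
  frequently confused with each other (never with the other three). The
  end-to-end confusion matrix remains diagonal-dominant at OR = 1.5 with
  n = 5000 per group, but single runs at n ≈ 600 may select either
  member of the pair.
* The multiplicative fit's allele-level table assumes within-subject
  allele independence (exact under HWE in both groups).
* The permutation statistic is a design choice; other statistics (trend
  across ordered timepoints, donor-blocked permutation) would answer
  slightly different questions and are not implemented.
* Problem sizes in the test suite (e.g. 100–500 replicates, n = 5000 per
  group for recovery checks, B = 199 for null calibration) were chosen as
  the smallest designs whose pass/fail criteria have comfortable
  statistical margins.
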