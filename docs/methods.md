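# Methods

This note records the models, parameter choices and numerical conventions
behind `fshd_nipd`, and what the simulation-based tests do and do not
establish.

## Genetic model

FSHD1 is autosomal dominant: an allele is pathogenic iff the D4Z4 array is
contracted to 1–10 repeat units *and* lies on a 4qA distal haplotype; 11+
units or 4qB are classified normal. The boundary is implemented strictly
(10 + 4qA pathogenic, 11 + 4qA normal). Incomplete penetrance is real but
not modeled; reports carry a fixed textual caveat instead. D4Z4 structural
calls (repeat count, 4qA/4qB per haplotype) are *inputs* — typically from
optical mapping — never computed from sequence.

The family configuration addressed is a paternally transmitted pathogenic
allele, phased against the paternal grandparents (the fetus is a firstborn,
so no affected sibling is available for phasing). The maternal-carrier case
is out of scope: it requires distinguishing maternal from fetal copies of
the *maternal* alleles, a dosage problem this two-state model does not
express.

## Informative SNPs and trio phasing

A site is informative when (i) the father is heterozygous, (ii) exactly one
paternal grandparent is heterozygous and the other homozygous, and (iii) the
mother is homozygous. Conditions (i)–(ii) make the father's phase
deducible — the homozygous grandparent pins one allele, and Mendelian
consistency is then automatic, so phase is never ambiguous at an accepted
site. Condition (iii) is required by the plasma model: only when the mother
is homozygous does the allele she lacks (called B) measure the paternal
contribution directly. Exhaustive enumeration over all 3^4 genotype
assignments yields exactly 8 informative configurations; this enumeration is
frozen into the tests against an independent allele-multiset filter.
hap0 denotes the father's haplotype inherited from the affected grandparent
(default: grandmother), hap1 the other. Sites failing the rules, or with
missing genotypes, are rejected and logged, never fatal; zero informative
sites is a hard error.

## Fetal fraction and error rate

With parents homozygous for different alleles the fetus is an obligate
heterozygote and the paternal-specific allele appears at frequency f/2,
giving the pooled estimator f = 2Σp/Σ(p+q). Two known properties: (a) it
carries a small upward bias ≈ 2ε(1−f) from sequencing error (~1e-3 at
ε = 6e-4), which the published formula does not correct and we deliberately
do not either; (b) its single-run binomial SE at 200 sites × 300X is
≈ 2·sqrt((f/2)(1−f/2)/60000) ≈ 2e-3. The recovery tests therefore check the
mean of 100 replicates against the truth within three *single-estimate*
SEs, a band that admits the estimator's intrinsic bias without hiding
implementation errors (which would shift results by far more).

The error rate ε is the pooled off-genotype read fraction at background
sites where both parents are homozygous for the same allele (the fetus is
then an obligate homozygote, so every discordant read is an error). The
two-count input format means reads matching neither ref nor alt are not
observable and are implicitly ignored. ε is pooled over sites and samples,
i.e. a per-read average, not a per-site distribution.

## The inheritance HMM

* **States:** hap0 / hap1 — which paternal haplotype the fetus carries at
  each informative SNP. Uniform 0.5/0.5 prior.
* **Emissions:** B-read count k ~ Binomial(n, μ) with
  μ = (f/2)(1−ε) + (1−f/2)ε when the state's haplotype carries B, μ = ε
  otherwise. f and ε are plugged in from the estimation step (two-step
  workflow); they are not re-estimated inside the HMM. A beta-binomial
  overdispersion option was considered and left out: the simulator's counts
  are exactly binomial, and on real data overdispersion would be absorbed
  conservatively by the transition prior before flipping calls.
* **Transitions:** Haldane map, switch probability
  r(d) = (1 − exp(−2cd))/2 between SNPs d bp apart, with uniform
  c = 1e-8 Morgans/bp (≈ 1 cM/Mb). No crossover interference.
* **Algorithms:** scaled forward–backward for exact posteriors and the data
  log-likelihood (stable at 10^4 sites); Viterbi for the joint path, with
  ties broken toward staying in the current state and a final-site tie
  resolving to hap0. Both are verified against exhaustive enumeration over
  all 2^n paths for n ≤ 12.
* **Numerics:** emissions with probability 0 (e.g. ε = 0 with a stray read)
  are floored at log(tiny double) ≈ −708 rather than −inf; posteriors are
  clipped at the smallest positive double before forming the log10 odds
  track, whose sign convention is positive = hap0 (pathogenic) inherited.
* **Segments and breakpoints:** maximal constant-state Viterbi runs; a
  switch is localized to the interval (last SNP of the old segment, first
  SNP of the new segment] and reported at the first SNP of the new
  segment — the finest localization the SNP spacing supports.
* **Locus call:** the state at the informative SNP nearest the locus
  boundary, with its posterior and distance. If a detected breakpoint
  interval spans a locus boundary, the call is flagged low-confidence: the
  crossover may fall between that SNP and the repeat array, in which case
  the nearest SNP no longer vouches for the locus. A crossover in the
  terminal gap with *no* informative SNPs beyond the locus is undetectable
  in principle; the distance-to-locus field quantifies that exposure.

## Synthetic-family generator

The generator reproduces the study design it is tested against:

| parameter | default | meaning |
|---|---|---|
| locus | chr4:190,060,000–190,100,000 | D4Z4 proxy interval (coordinates are opaque labels; no genome build implied) |
| window_bp | 5,000,000 | target-panel flank on each side of the locus |
| n_target_snps | 567 | target-panel size |
| n_background_snps | 1,262 | background autosomal SNPs |
| maf_min | 0.30 | strict MAF floor; site MAF ~ U(maf_min, 0.5) |
| fetal_fraction | 0.1558 | cfDNA fetal fraction (reported median) |
| error_rate | 6e-4 | per-read substitution error |
| mean_depth_cfdna / gdna | 300 / 40 | Poisson depth means |
| recomb_rate_c | 1e-8 M/bp | Haldane rate (≈ 1 cM/Mb) |

Founder (grandparental, maternal) haplotypes are independent Hardy–Weinberg
draws per site — linkage disequilibrium between panel SNPs is *not*
simulated, which is immaterial here because phasing and inference condition
on the observed genotypes. Transmission is one recombined gamete per
meiosis (grandparents → father, mother → fetus, father → fetus), with the
fetal paternal meiosis optionally forced through fixed breakpoints; the new
segment starts at the breakpoint coordinate. Plasma counts are binomial in
the error-perturbed mixture rate μ′ = μ(1−ε) + (1−μ)ε at Poisson depth;
zero-depth sites are retained to exercise the degenerate-input paths.
Depth means are the stated *minimums* of the study design, so the strict
">300X / >40X" QC verdicts hover at threshold on simulated data; QC is
reported, not enforced, by the pipeline.

Everything is driven by a single seed through per-stage independent
`numpy` generators, so identical configurations give bit-identical outputs.

What passing tests show: the estimators and the HMM recover the quantities
the generator encodes, at the stated depths, panel sizes and error rates,
including recombination localization to the correct inter-SNP interval.
What they do not show: robustness to GC/capture bias, overdispersed or
correlated read counts, fragment-size effects, genotyping error in the
family gDNA, population LD structure, or chromosome-10 D4Z4 homolog
cross-mapping — none of which the generator emulates.

## Design choices on open points

* **Informativeness requires maternal homozygosity** even though it is a
  consequence rather than an independent rule in the published three
  conditions: every admissible configuration has a homozygous mother, and
  the emission model needs it.
* **"Scattered on autosomes"** for the background panel is operationalized
  as round-robin allocation across chromosomes with even spacing within
  each — the source procedure is unstated.
* **Depth QC uses the mean** (threshold strict >40X/>300X); configurable
  choice, since the summary statistic is unstated.
* **ε is pooled** (total mismatched reads / total reads) rather than
  per-site averaged; the estimand an aggregate per-read error rate.
* **Per-sample inference:** with multiple plasma samples each gets its own
  f and its own HMM run; the final call is taken from the sample with the
  highest fetal fraction (strongest allelic separation) and all per-sample
  calls are reported. Evidence pooling across samples is out of scope.
* **Simulation scale in tests:** statistical tests use 100-seed batteries
  for estimator recovery and breakpoint localization, and a 50-family
  end-to-end accuracy check; these sizes give binomial confidence bands an
  order of magnitude tighter than the effects being checked.

## Known limitations

Single-proband design (no population validation); f < ~5% degrades the
binomial separation and is reported but not specially handled; the maternal
copy of a pathogenic allele is neither simulated nor diagnosable;
coordinates are treated as build-agnostic labels; clinical-grade report
language is out of scope.
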