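# Methods

## Model and assumptions

`prsx` treats the PRS as what it is — a linear model over allele counts —
and attributes it exactly rather than approximately. All quantities are
computed on the *standardized* scale: raw per-allele weights `β_i` are
divided by the cohort standard deviation of the raw PRS, and dosages are
mean-centered (`G′_i = G_i − 2p_i`), so the standardized PRS has mean 0 and
sd 1 in the cohort and every variant's centered term is its additive
contribution.

Three assumptions matter:

1. **Linearity.** The attribution `A_gene = CS_gene − mean(CS_gene)` is the
   exact Shapley value only because the PRS is additive in its inputs. Under
   the marginal-mean background (a region absent from a coalition is
   replaced by its population-mean contribution), the Shapley sum collapses
   analytically; the package still ships a full `2^k` enumeration oracle
   (`scores.shapley_oracle`, refused above k = 12) and tests the identity to
   1e-10. Correlation-aware (conditional) SHAP is deliberately out of scope:
   with correlated regions it would no longer equal the closed form, and the
   linear derivation assumes the marginal background.
2. **Single ancestry.** Frequencies, the standardization constants and the
   percentile cohort must come from one ancestry. In individual mode the
   reference cohort supplies `p_i`, `mean_raw`, `sd_raw`, the per-region
   means/variances and the percentile distribution; the scored individual
   contributes nothing to them.
3. **A partition of SNPs.** Additivity (`Σ CS_gene = PRS_std`) holds only
   because regionizing makes attribution units disjoint. Per-region
   variances are reported as-is; their sum differs from 1 by twice the sum
   of cross-region covariances, which the summary prints rather than
   assumes away.

## Harmonization

Scoring variants join the genotype panel by rsID when both sides carry
rsIDs, else by `chrom:pos`. If the panel counts the scoring file's *other*
allele, the dosage is reflected (`2 − G`); palindromic (A/T, C/G) variants
are dropped as strand-ambiguous rather than frequency-resolved — simpler
and conservative. Missing hard calls are imputed to `2p_i`, which makes the
variant's centered contribution exactly zero for that sample (a neutral
attribution, not a guess at the genotype).

Two numerical choices deserve a note:

* **Centering constant.** For a diploid 0/1/2 dosage the mean is `2p`, and
  only `G − 2p` yields mean-zero contributions and hence the mean-zero SHAP
  property. A `center_constant="p"` mode (subtracting `p`) exists for
  comparison with conventions that treat the dosage as per-haplotype; it
  sacrifices the exact mean-zero identities and is not the default.
* **Frequency clipping.** Reported frequencies are clipped to
  `[1/(2n+2), 1 − 1/(2n+2)]` so that per-SNP heritability `2p(1−p)β²` is
  never degenerate at monomorphic sites. The *centering* uses the unclipped
  per-variant dosage mean; clipping the centering constant would inject a
  constant offset at monomorphic sites and break the additivity and
  mean-zero identities that the rest of the method relies on.
* **Variance convention.** All standard deviations and variances use the
  n−1 (sample) denominator. Under that convention the two-sample cohort
  `{0,2}` with β = 1 standardizes to ±1/√2, and `sd(prs_std) = 1` holds
  exactly by construction.

## Mapping protocol

The three stages are strictly sequential: cS2G applies only to SNPs with no
positional link, the GWAS fallback only to SNPs with neither. This keeps
each SNP's links attributable to a single, earliest evidence tier. Defaults:
200 kb positional window (boundary inclusive, distance measured to gene-body
edges, not TSS), cS2G minimum score 0, fallback search radius 1 Mb. The
fallback assigns by smallest association p-value, breaking ties by distance
and then gene name so the output is a deterministic total order; the per-SNP
heritability `2p(1−p)β̂²_std` is recorded in the link table and names the
evidence for ranking synthetic loci. SNPs with no association in range get a
1-Mb bucket label (`chr7:23Mb`), guaranteeing mapping totality.

Regionizing merges genes on ≥ 1 shared SNP (connected components of the
shared-SNP gene graph). A stronger overlap criterion would leave shared
SNPs double-counted across units and destroy additivity; one shared SNP is
the weakest criterion that restores a partition, and the component's member
genes remain listed in every output row so no gene identity is lost.
Region ids concatenate up to three member-gene symbols ordered by genomic
start, then `+k more`.

## Percentiles

Percentile of a score within the cohort uses the mid-rank convention:
`rank = #below + (#tied + 1)/2`, `percentile = 100·rank/(n+1)`. The highest
of 99 distinct values lands at 99.0; an all-tied cohort puts everyone at
50.0. Cohorts below 10 samples are refused.

## Synthetic cohorts

The generator draws genotypes per SNP as binomial(2, p) — Hardy-Weinberg
and linkage equilibrium — with frequencies uniform on [0.05, 0.5], because
independence is what makes per-gene variance shares analytically equal to
`Σ 2p(1−p)β²` and hence checkable. Betas are N(0, scale) rescaled per gene
so the theoretical shares match the planted fractions (default 0.5/0.3/0.1
across three 50-kb genes, ten SNPs each, with the remaining 0.1 spread over
nine intergenic SNPs). Intergenic SNPs cycle through three planted fates —
reachable only via a cS2G link, only via a GWAS association, or via neither
(synthetic locus) — on a chromosome no gene occupies, more than 1 Mb apart,
so each mapping stage is exercised in isolation. Allele pairs are drawn
from non-palindromic combinations only, so the harmonizer drops nothing and
planted truth stays exact. `truth.json` records the intended stage and the
theoretical variance share per gene.

What this does **not** emulate: linkage disequilibrium (an optional AR(1)
Gaussian-copula mode induces local correlation to exercise, not validate,
the covariance reporting), imputation dosages, strand errors, build
mismatches, and genuinely overlapping gene windows. Passing tests therefore
demonstrate the algebraic contracts and the mapping/report logic, not
robustness to real-data harmonization pathologies.

## Problem sizes and determinism

Test and acceptance runs use cohorts of 120–5000 samples and 39–2000 SNPs:
large enough for the stochastic checks (frequency estimation within 3 SE,
planted-share recovery within 10% at n = 5000 with the error shrinking from
n = 500) while keeping the full suite in seconds. All randomness flows
through explicit seeds; rendered PNGs carry fixed metadata and no
timestamps, so a re-run with the same seed is byte-identical — which the
suite asserts, and which makes `score` + `report` exactly reproduce `run`.

## Known limitations

* Hard-call genotypes only (no BGEN/VCF dosages); no liftover or build
  validation — the caller must assert one genome build across inputs.
* Palindromic SNPs are discarded even when frequencies could disambiguate
  strand; scores lose that (usually small) weight mass.
* Per-region variances are reported without confidence intervals.
* The exact Shapley enumeration is a validation tool, not a scalable
  explainer; the analytic path is the implementation.
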