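# Methods

This note documents the models behind each stage, the tunable parameters
and their defaults, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Per-SNP differentiation and AIM classification

Differentiation between the two reference panels is measured per site with
Hudson's estimator in ratio form,

    N = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    D = p1(1−p2) + p2(1−p1),        F_ST = N / D,

with p the sample alternate-allele frequencies over called genotypes and n
the called allele-copy counts (2 × called diploids). The estimator was
chosen for per-site stability at small panels and because it needs no
within-population weighting assumptions; swapping in Weir–Cockerham would
only require replacing `hudson_fst_site`. Conventions that matter:

- a site is *undefined* (NaN) when either panel has < 2 called allele
  copies or the site is monomorphic across both panels (D = 0);
- negative values are **kept** when summarising — clamping at 0 would bias
  the classification threshold upward;
- the summary SD is the population (n-denominator) SD: the site set is a
  fixed collection being described, not a sample from a superpopulation;
- AIMs are sites with F_ST **strictly greater** than mean + 2 SD; ties at
  the threshold are excluded. An all-equal profile (SD = 0) warns and
  classifies nothing.

Important estimator property: the *mean of per-site* Hudson values is an
average of ratios and sits below the divergence parameter F of the
underlying frequency model (the ratio-of-averages, not computed here, is
the unbiased analogue of F). At background F = 0.04–0.05 the difference is
small (the 20-seed acceptance test recovers F = 0.05 within ±0.015); at
F = 0.4 it is large (~0.24 vs 0.4), which drove the generator's AIM-tail
design below.

## Local ancestry: switch-penalty Viterbi

Each admixed diploid is decoded over the ordered AIMs into donor-dosage
states k ∈ {0, 1, 2} maximising

    Σ_j log P(g_j | k_j, p_a_j, p_b_j) − s · |k_{j+1} − k_j| .

The emission is the exact genotype likelihood when k of the two allele
copies come from the donor panel: the convolution of Binomial(k, p_b) and
Binomial(2−k, p_a) evaluated at g. Missing genotypes emit log 1. Panel
frequencies are clamped to [0.01, 0.99] (with a warning) because emissions
degenerate at fixed frequencies; sample frequencies of exactly 0/1 are
common at strongly divergent AIMs in panels of this size.

- **Switch penalty** `s` (default 10, natural-log units per haplotype
  switch): the simplest cost linear in the number of haplotype switches,
  `s·|Δk|`. It sets a hard detection floor: a donor segment is decoded only
  when its cumulative emission log-likelihood advantage exceeds `2s` (both
  boundaries), i.e. roughly 10–25 informative AIMs at typical AIM
  informativeness (per-AIM log-likelihood ratio ~0.7–2.8 depending on
  genotype and frequencies). Short segments spanning fewer AIMs are
  invisible *by design* — that is what the penalty is for.
- **Tie-breaking** is toward the smaller dosage at every argmax, so output
  is deterministic and conservative against claiming donor ancestry.
- Decoding is exact (dynamic programming over 3 states); a property test
  asserts the decoded objective dominates the truth path's objective on
  every synthetic instance, and small instances are checked against
  exhaustive enumeration of all 3^m paths.

Global donor proportion per sample is mean(dosage)/2 over AIMs. The
sliding-window scan averages dosage/2 over all admixed samples and the
member AIMs of each window (cohort signal, not per-sample): windows are
**AIM-index windows** (default 100 AIMs, step 50), the final partial window
is kept and flagged, and outlier windows (> mean + 2 SD of window means)
merge into bp regions when they share AIMs or touch. With 50% window
overlap, adjacent window means are ~0.5-correlated; any rate computed over
windows should use a design-effect correction of ~2 (the acceptance test
does).

Haplotype PCA centres columns, standardises polymorphic ones, and takes row
scores from an SVD; each component's sign is fixed so its largest-magnitude
loading is positive.

## Selection scan: EHH, iHH, XP-EHH, composite score

EHH at extent x is the probability that two haplotypes drawn without
replacement are identical over the inclusive interval [core..x]:
Σ_g C(n_g,2) / C(n,2) over identity groups g. EHH at the core equals the
core-site homozygosity (not 1), matching the cross-population statistic's
per-population ingredient; the alternative EHH(core) ≡ 1 convention would
only rescale both panels. Groups are refined incrementally site by site, so
EHH is non-increasing by construction; a compiled (numba) kernel does the
per-extension refinement in O(n), with a pure-numpy walk as fallback and as
the independent path used by the curve API. Both are tested against an
O(n²m) pairwise-identity oracle for exact rational agreement.

iHH integrates the EHH curve over genetic distance (cM) by trapezoid, both
directions summed. Each direction stops at the first EHH value below the
cutoff (default 0.05), *including* the crossing trapezoid; a direction that
reaches the chromosome edge with EHH still at or above the cutoff is
flagged edge-truncated. Cores are skipped (not imputed) when either panel's
iHH is 0 or when both directions edge-truncate in both panels, so undefined
ratios never contaminate the z-normalisation.

XP-EHH = ln(iHH_target / iHH_ref); identical panels give exactly 0 and
swapping panels negates the score. For the composite, per-site F_ST between
the target (admixed) and reference (recipient) genotype groups and XP-EHH
are each z-normalised (population SD over jointly scored sites) and
multiplied. Outliers are the top ⌈N·(1−p/100)⌉ composite values
(nearest-rank, default p = 97.5), with ties at the cut value included
together — the only reading under which "exactly 5 of 200 distinct values"
and "ties at the cut included" are simultaneously true. Consecutive scored
outlier sites merge into bp regions.

With no map supplied the scan assumes a uniform 1 cM/Mb map (logged). The
uniform-map constructor itself places site i at `pos_i / pos_last ×
total_cM` — genetic position proportional to physical position — making the
units of the proportional construction explicit via `total_cM`.

## Recombination clock

For a shared haplotype of genetic length L cM present as `n_copies`
independently recombining IBD copies, the time to the first breakage is
exponential with rate `n_copies · L/100` per generation:

    P(broken by t years) = 1 − exp(−n_copies · (L/100) · t / g).

Defaults: g = 3 years (canid generation time), n_copies = 2 (one copy in
each of the two populations sharing the haplotype). All recombination
events are assumed detectable; L is taken as input rather than re-estimated,
so a printed, rounded L reproduces published ages only to within the
rounding (~0.5% for a 2-significant-figure length). `prob_broken` and
`years_for_prob` are exact inverses (property-tested to machine precision).
The standing-variation verdict compares P(broken) at a chosen bound of the
divergence-time range (default: upper) against a 95% threshold; the lower
bound is exposed because the rejection is only marginal there for
plausible parameter values.

## Synthetic-data generator

The generator reproduces the *features the statistics consume*, not a
coalescent process:

- **Background divergence**: per site, ancestral frequency
  p0 ~ U(0.05, 0.95); each population's frequency is an independent Beta
  draw with mean p0 and variance p0(1−p0)F (Balding–Nichols), F =
  `fst_background` (default 0.04). Frequencies are clamped to [0.01, 0.99]
  so reference panels are not monomorphic in expectation.
- **AIM tail** (`aim_fraction`, default 5%): designated sites get
  frequencies p0 ± δ/2 (random orientation) with δ chosen so the
  true-frequency Hudson F_ST equals `f_aim` (default 0.4) exactly;
  p0 is drawn from the range where the split stays inside the clamp
  bounds ([0.216, 0.784] at f_aim = 0.4). Independent Beta draws at
  F = 0.4 would leave most designated sites essentially undiverged
  (average-of-ratios effect above), which is not what an
  ancestry-informative-marker tail is: AIMs are the *consistently*
  divergent sites.
- **Haplotypes**: each panel copies a founder pool (default 1000
  haplotypes, themselves Bernoulli draws from the panel's frequencies) as a
  mosaic with per-bp switch probability `copy_switch_rate` (default 2e-6;
  geometric segment lengths, mean 500 kb), so haplotype homozygosity decays
  with distance. The pool is large because sampled allele copies are draws
  with replacement from it, which inflates realised F_ST by ~1/pool; at
  1000 the inflation is negligible while EHH decay is governed by the
  switch rate and marker density, not pool size.
- **Admixture**: each admixed haplotype receives a Poisson number of donor
  segments (exponential lengths, mean `background_segment_bp` = 1 Mb,
  totalling `background_admixture` = 2% of the chromosome in expectation),
  plus the focal tract: an exact-count fraction `tract_freq` (default 0.8)
  of haplotypes has the `tract_bp` interval (default 600 kb) replaced by
  donor sequence — one shared donor founder when `sweep` is set, which
  creates the long-range homozygosity of a sweep. The 1 Mb background
  segment scale is chosen so segments carry enough AIMs to clear the
  decoder's `2s` detection floor; much shorter segments would be
  undetectable by construction and decoded proportions would
  systematically undershoot truth.
- **Site map**: `tract_site_fraction` (default 12%) of sites fall inside
  the tract, emulating the denser typing real studies use around a focal
  candidate gene; missingness is per-genotype i.i.d. (`missing_rate`,
  0–14% range, default 0).
- **Truth**: exact per-site donor dosage and the haplotype-level origin
  mask are recorded and asserted consistent at construction.

Default cohort sizes (15 + 22 + 21 diploids, ~18k sites on a 50 Mb
chromosome, ~900 AIMs → ~20 windows) mirror the motivating study design.
The selection-scan tests use a denser, shorter configuration (2,500 sites
on 6 Mb with 30% in the tract) so EHH curves are well resolved while scans
over all cores stay fast; the simulation-study sizes throughout the test
suite (10k sites, 20 seeds) were chosen to keep sampling error well below
the asserted tolerances.

What passing tests do **not** show about real data: no recombination-map
heterogeneity, no demography or drift-phylogeny beyond the one-parameter
divergence, no mutation model, no phasing or genotyping error, LD from
founder mosaics rather than coalescent genealogies, and an AIM tail that is
cleaner than empirical F_ST outliers. Detection rates measured here are
therefore best-case calibrations of the machinery, not field performance.

## Known limitations

- The AIM classifier's sensitivity to the designated tail is bounded by
  per-site estimator noise: at 30/44 allele copies the sampled Hudson value
  at a true-0.4 site has SD ≈ 0.12 while the 2-SD threshold sits ≈ 1 SD
  below the tail mean, capping sensitivity near ~0.85 regardless of site
  count. Larger reference panels, not more sites, are the remedy.
- Posterior (forward–backward) ancestry decoding, haploid-resolution
  decoding, and map-aware transition probabilities are out of scope; the
  Viterbi point estimate carries no uncertainty.
- The composite outlier rule is an empirical percentile: it always flags
  ~2.5% of scored sites, including under the null — localisation, not
  significance, is the signal.
- Single chromosome per run; BCF/tabix and multi-chromosome parallel I/O
  are not supported.
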