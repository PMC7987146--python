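# Methods

`roanmap` implements the analysis chain used to map a dominant tandem
duplication from SNP-array cohorts: mixed-model association, haplotype-
sharing fine-mapping, three channels of CNV evidence, and four selection
signatures, validated end-to-end against a synthetic cohort generator with
full ground truth. This note records the models, the defaults and why they
are set where they are, and what the synthetic validation does and does not
demonstrate.

## Coordinates and containers

All coordinates are 1-based inclusive (so CFA38:11,131,835–11,143,237 spans
11,403 bp); BED export converts to 0-based half-open at the boundary only.
Genotypes are dosages of `allele2` in {0,1,2} with −1 for missing; missing
calls never enter allele counts and minor-allele frequency uses the
non-missing denominator, matching PLINK. Multi-allelic and indel VCF
records are skipped, not decomposed, because the array markers being
modelled are biallelic SNVs. PLINK `.ped` input carries no ref/alt
designation, so dosages there count the lexicographically larger observed
allele; monomorphic sites therefore cannot round-trip polarity through the
text PLINK format (they are counted as dosage 0). The X chromosome is
treated as autosomal; no dosage compensation is attempted.

## Linear mixed model association

Per marker:

    y = Wα + xβ + u + ε,   u ~ MVN(0, λτ⁻¹K),   ε ~ MVN(0, τ⁻¹I)

with case/control phenotypes coded 0/1 and fitted with the *linear* mixed
model (the ordinal tick score, 0/1/2, is likewise analysed as a numeric
trait). `K` is the centred relatedness matrix
K = (1/p) Σ_k (x_k − 2f_k·1)(x_k − 2f_k·1)ᵀ with per-marker mean imputation
of missing dosages; the centred (not standardized) form is assumed where a
choice existed. `K` is eigendecomposed once (eigenvalues clipped at 1e-10);
per marker, λ is estimated by REML over ln λ ∈ [ln 1e-5, ln 1e5] with a
21-point coarse grid followed by bounded Brent refinement (tolerance 1e-6
on ln λ). REML rather than ML, and an F(1, n−c−1) reference for the Wald
statistic rather than χ², are the defaults of the standard mixed-model
GWAS implementations this stage mirrors; both choices are assumptions and
are isolated in `lmm_gwas`. At the λ→0 boundary the scan reduces exactly to
ordinary least squares, which is asserted in the tests. Significance lines
are drawn at 5×10⁻⁸ (genome-wide) and 1×10⁻⁵ (suggestive). Stratified scans
recompute the kinship within each stratum and skip strata with fewer than
20 individuals or a single phenotype class.

## Haplotype fine-mapping

`build_catalog` groups phased haplotypes by exact identity over a marker
window; labels are deterministic (count-descending, ties by first
occurrence) so fixtures are stable. `narrow_region` implements the
two-step narrowing argument:

1. the maximal marker run over which all *common* carrier haplotypes are
   identical — carrier haplotypes with count ≤ `rare_count_max` (default 2)
   are ignored, a count threshold being the implementable proxy for "a few
   rare exceptions". If every carrier haplotype is ignorable the identity
   constraint is vacuous and the full window is returned (this keeps the
   output monotone in the tolerance: lowering `rare_count_max` can only
   shrink the interval);
2. each flank sub-run over which some control individual is homozygous for
   a haplotype identical to the carrier consensus is trimmed, the last
   matched marker surviving as the boundary. The consensus is the most
   frequent common carrier haplotype — a deterministic generalization of
   comparing against specific named haplotypes. Homozygous controls are
   phase-unambiguous, so this check is valid on unphased data as well.

`classify_carrier` calls a haplotype a carrier iff it is identical to a
confirmed carrier haplotype at every marker inside the core interval; the
call is a pure function of the core substring (asserted as a property
test). Identity over the full window is tagged `core-match`, identity in
the core only `recombinant-match` — the classifier encodes only the
core-sharing rule and reports the tag rather than asserting molecular
certainty about recombinants. Phasing is consumed, never computed.

## CNV evidence

ΔLRR subtracts from the in-duplication probe the mean LRR of the
`flank_k` (default 10) nearest flanking probes, split five per side — the
even split is a choice, configurable, since only the total is canonical.
Group separation uses Welch's unequal-variance t-test ("t-test" alone
underdetermines the variant; Welch is the safer default). With a single
in-duplication probe, per-individual copy number is *not* estimated from
LRR alone — only the ΔLRR score and group separation are reported.

Read depth is averaged in non-overlapping 5-kb windows tiled from position
1 and normalized by the global mean of the supplied table; the inside/flank
copy ratio has expectation CN/2 under the Poisson model and is invariant
under global depth rescaling. Read pairs are classified after normalizing
pos1 ≤ pos2: forward–reverse pairs within insert_mean ± 4·insert_sd are
proper-inward, reverse-then-forward pairs (facing away) are outward — the
tandem-duplication junction signature — equal strands are same-strand and
over-long proper pairs are distance-anomalies.

The breakpoint caller requires a run of ≥ 2 consecutive windows with depth
ratio ≥ 1.25 *and* ≥ 3 outward pairs whose ends cluster near the run
boundaries; because a breakpoint can sit anywhere inside a boundary window,
the clustering tolerance is the insert size plus one window width.
Breakpoints are the median outward-pair end coordinates; CN rounds twice
the mean ratio of the windows fully inside the called interval (half-up,
with a tie flag at exact midpoints, e.g. ratio 1.75). Depth runs without
pair support are surfaced as depth-only candidates, never calls. This is
deliberately an evidence-logic caller, not a general SV caller: no
split-read or assembly evidence, no BAF, no CN > 4.

## Selection signatures

* **π** — per site, π_s = 2c₀c₁/(n(n−1)) over non-missing allele counts
  (sites with > 50 % missingness excluded); a window's value is Σπ_s over
  its variant sites divided by the window length. 500-kb windows sliding in
  10-kb steps, anchored at position 1. Invariant under allele relabeling.
* **F_ST** — Weir & Cockerham (1984) variance components with r = 2
  samples, windowed as Σa/Σ(a+b+c); windows with non-positive denominator
  are missing, and small negative estimates for undifferentiated
  populations are reported as computed.
* **ROH** — the sliding-window hit-rate algorithm of PLINK `--homozyg`
  with the parameter block window 41 SNPs / 0 het / 0 missing / hit-rate
  threshold 0.05 / minimum 41 SNPs and 500 kb, with density and gap checks
  disabled. ROH frequency at a marker is the fraction of individuals with
  an overlapping segment. The implementation is checked against an
  exhaustive reference on hundreds of random instances.
* **XP-EHH** — site-EHH from each core marker: EHHS(core) = 1 and, for a
  span extended to marker x, identity classes of haplotypes over the
  inclusive span [core..x] give EHHS = Σ C(k_g,2)/C(n,2) (unnormalized,
  Sabeti-style; the Tang normalization is not implemented). EHHS is
  integrated by trapezoid over genetic distance (cM if present, else a
  fixed cM/Mb), truncated where EHHS < 0.05; XP-EHH is
  ln(iES_obj/iES_ref) standardized by the scan-wide mean and sd, without
  frequency binning (standard for XP-EHH, unlike iHS). Markers with zero
  reference integral are missing.

Extreme chi-squared tails are computed in log space: scipy's `logsf` where
finite, otherwise the asymptotic series for the normalized upper incomplete
gamma function — never via 1 − CDF. The continuity (Yates) correction is
applied to 2×2 tables only, the convention of mainstream statistics
software; on a 2×k table with disjoint support the Pearson statistic equals
the total count, a useful audit identity asserted in the tests. The
genotype-frequency scan reports raw p-values (a Bonferroni column is
emitted for convenience, not used for ranking).

## The synthetic cohort generator

The generator emulates the observable structure the analyses rely on, not
canine demography:

* **Breed structure** — each breed draws haplotypes as mosaics of a
  breed-specific founder pool (default 8 founders) derived from one shared
  ancestral haplotype by per-marker flips (`mutation_density`, default
  0.15). Mosaic crossovers are Poisson with an *effective* generation
  count (`mosaic_generations`, default 100) times the map length, so
  background haplotype identity decays on the ~1 Mb scale as it would
  after many generations of recombination. This founder-pool construction
  induces the kinship confounding the mixed model must absorb; it is not a
  coalescent and makes no claim about realistic LD decay or demography.
* **The duplication** — a single carrier founder lineage carries the
  duplication together with a private allele at the marker nearest the
  duplication midpoint (the analogue of a perfectly tagging array probe).
  Carrier haplotypes copy the carrier founder over the duplication plus
  exponentially distributed flanking extents (mean `sweep_decay_bp`,
  default 1 Mb, minimum 30 kb) on top of an ordinary breed mosaic — so
  sweep signatures decay away from the locus, localizing the F_ST peak and
  the EHH contrast the way a real sweep does. In swept breeds the carrier
  frequency is forced exactly; elsewhere it is binomial. New mutations
  (rate 0.001/marker) are suppressed inside the duplication ± 25 kb core
  zone, which is what makes perfect carrier classification attainable at
  full penetrance — real data would include genotyping error here, so the
  100 %-concordance checks demonstrate internal consistency, not expected
  field performance.
* **Phenotype** — dominant: P(roan | CN ≥ 3) = penetrance × (1 − masking),
  P(roan | CN = 2) = 0. Defaults penetrance 0.99 and masking 0.05; the
  masking probability is a deliberately crude stand-in for white-spotting
  epistasis (a roan genotype is invisible without white coat areas), not a
  model of the S-locus. Tick scores are drawn independently of genotype
  (mirroring a null scan for that trait) and only for non-roan
  individuals, so roan cases are never used as tick controls.
* **Evidence channels** — LRR ~ Normal(mean_by_CN, 0.15) with means
  {2: 0.0, 3: 0.2, 4: 0.35}, placing het/hom carrier ΔLRR in the observed
  positive range while keeping the distributions overlapping enough that
  detection is nontrivial; depth ~ Poisson(30 × CN/2) per site inside the
  duplication (emitted for the duplication ± 150 kb by default, per-site);
  junction-spanning outward pairs per carrier copy ~ Poisson(depth/2) with
  ends uniform within half an insert of the breakpoints, over a background
  of proper pairs with Normal(400, 50) inserts.
* **Determinism** — every stream is derived from the single config seed via
  fixed spawn keys (stage, individual index), so any subset of individuals
  reproduces bit-identically regardless of call order.

A separate Balding–Nichols generator (`simulate_structured_null`, drift
F = 0.1, per-breed prevalence differences) provides a structured *null*
cohort whose markers are independent given breed — this is what makes a
binomial bound on the type-I error fraction valid, which the LD-structured
cohort generator could not provide.

## Problem sizes used in the validation suite

The test suite exercises: type-I error on 500 individuals × 5,000 null
markers; power on 300 individuals × 1,000 markers (the injected dominant
locus must be the top hit at P < 5×10⁻⁸, allowing the hit to land on a
tightly linked marker of the swept segment); caller sensitivity/specificity
on 100 simulated carriers and 100 diploid individuals at 30×; the joint
four-signature sweep pattern (depressed π, F_ST peak within 250 kb, ROH
frequency and XP-EHH elevated at the locus) on a 100-dog, 2,000-marker
cohort with the object breed swept at 0.95; and copy-ratio recovery over
20 Poisson replicates (asserted within ±0.05 of CN/2). These sizes were
chosen as the smallest at which the underlying statistical claims are
clearly separated from sampling noise.

## Known limitations

* Linear (not logistic) mixed model for binary traits; no LOCO kinship, no
  genomic-control correction, no covariate selection.
* One simulated chromosome; no X-chromosome dosage model; no genotyping
  error beyond Gaussian LRR noise; sweep by frequency forcing rather than
  forward selection dynamics (it reproduces the observable signatures, not
  the trajectory).
* The breakpoint caller assumes a single tandem duplication in the profiled
  region and CN ≤ 4.
* Statistical phasing and imputation are out of scope — phased input is
  consumed as given; phase-switch error propagates directly into carrier
  classification.
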