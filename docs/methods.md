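# Methods

This note documents the models, defaults and numerical choices behind
`bsakit`, and what the synthetic-data generator does and does not emulate.

## The mapping design

The package targets a classical mapping-by-sequencing design for a
monogenic recessive trait: a mutagenised line (EMS on an inbred
background) is crossed to its progenitor, the F1 selfed, and the F2
phenotyped. Two bulks — a wild-type pool (WP) and a mutant pool (MP),
200 plants each by default — are sequenced, variants are called, and
per-site pooled allele counts are the input to the scan. Read alignment
and variant calling are outside the package's scope; it consumes a
two-sample VCF with AD/DP FORMAT fields, or an equivalent TSV.

## SNP-index scan

Per site and pool, `SNP-index = alt/total`; `ΔSNP-index = MP − WP`. Sites
with zero depth in either pool are filtered (reason "zero depth") and a
per-pool minimum depth (default 10×) removes unstable ratios; indices are
plain floating divisions with no intermediate rounding.

**Threshold statistic.** The interval caller applies the threshold
(default 0.9) to the MP SNP-index by default. For a recessive causal
locus the MP index has expectation 1.0 while ΔSNP-index has expectation
only 1 − 1/3 = 2/3 (the WP is depleted of, but not free of, the mutant
allele), so a 0.9 cut on Δ would be unreachable in expectation; the
Δ mode is supported (`statistic="delta"`) and the choice is recorded in
the results summary.

**Interval calling.** Candidate intervals are maximal runs of
consecutive retained sites with statistic ≥ threshold. A gap tolerance
(default 0) lets a run bridge that many consecutive sub-threshold sites.
Interval endpoints are the first and last passing sites' positions
(1-based inclusive); widths are reported in bp and in Mb rounded half-up
to two decimals; output is sorted widest-first with leftmost-first
tie-breaking for determinism. Windowed smoothing (span/step sliding
windows, unweighted means, minimum-site support flag) is available but
off by default — per-site dots are what this design usually plots.

## Recombinant-count fine mapping

All individuals in the screen carry the mutant phenotype and are
therefore homozygous mutant at the locus. A marker call of 0 or 1 is a
recombinant; missing calls are excluded from numerator and denominator
(never treated as recombinant). The refined interval runs from the
nearest recombinant-bearing marker left of the longest zero-recombinant
run (leftmost on ties) to the nearest such marker on the right, endpoints
at the flanking markers' own positions, inclusive; widths round half-up
to integer kb. A zero-recombinant run touching the outermost marker
leaves that side open-ended. An optional mode requiring the same
individual to be recombinant at ≥ 2 adjacent markers could absorb
genotyping error; the default trusts the calls, since the assay is
modelled error-free.

## Cross engine

Progeny distributions are enumerated over parental gametes with exact
`fractions.Fraction` arithmetic (loci unlinked, Mendelian transmission),
so probabilities sum to one identically and ratios reduce to smallest
integer terms. Two rival models formalise a complementation (allelic)
test between two recessive mutations a1 and a2: *same gene* (compound
heterozygote mutant) versus *two genes* (mutations complement). Under the
two-gene model a parent's unmentioned locus defaults to homozygous
functional. Lethal genotype classes (e.g. an albino-lethal insertion
homozygote a2a2) are removed before phenotyping and the distribution
renormalised exactly: removing prior mass q rescales survivors by
1/(1−q).

Goodness of fit is the Pearson statistic Σ(O−E)²/E on k−1 degrees of
freedom, with the upper tail computed from the regularized incomplete
gamma function Q(df/2, x/2); the Yates continuity correction is available
but off by default. The allelism verdict uses α = 0.05 per cross with no
multiple-testing correction — these are few, pre-planned tests — and
requires the winning model to fit every cross while the rival is rejected
in at least one informative cross; anything else is inconclusive. An
observed phenotype the model gives probability zero rejects that model
outright.

## Phenotyping formulas

Pigments (mg per g fresh weight) from absorbances at 663/645/470 nm with
extract volume V (ml), dilution N and fresh weight W (g):

- Chl a = (12.72·OD663 − 2.69·OD645)·V·N/W
- Chl b = (22.88·OD645 − 4.68·OD663)·V·N/W
- Chls = Chl a + Chl b
- Car = [OD470·(V/W) − 3.27·Chl a − 104·Chl b]/198

The carotenoid equation is implemented exactly as above. Note it omits
the dilution factor and uses a 104 coefficient where the common
Lichtenthaler form uses 1000·OD470 scaling with 1.82/85.02 coefficients —
possibly a transcription artefact in the source protocol, but the printed
form is the contract here; a `variant="lichtenthaler"` switch exists for
comparison and is never the default. Negative contents are returned with
a warning, not clamped: silent clamping would hide bad readings.

Fluorescence parameters: Fv/Fm = (Fm−Fo)/Fm; Phi2 = (Fm′−Fs)/Fm′;
qL = (Fm′−Fs)/(Fm′−Fo′)·(Fo′/Fs); PhiNPQ = 1 − Phi2 − Fs/Fm; gH⁺ = 1/τ;
active-PSI fraction = P_M/P_0; relative chlorophyll =
k·log₁₀[(Abs940·ref.Abs650)/(Abs650·ref.Abs940)]. The instrument constant
k defaults to 1 and P_M/P_0 are accepted as given — their measurement
protocol is instrument-specific and not interpreted here. By
construction Phi2 + PhiNPQ + Fs/Fm = 1; the test suite asserts this to
1e-12. The quotient parameters lie in [0, 1] when additionally Fo′ ≤ Fs
and Fm′ ≤ Fm, which the property tests impose.

2^−ΔΔCt: ΔCt = Ct_target − Ct_reference per replicate pair, ΔΔCt is the
difference of condition means, fold change 2^−ΔΔCt, with a spread
interval at ΔΔCt ± one combined standard error of the two ΔCt means.

## Synthetic-data generator

**What it emulates.** A biallelic EMS variant set (default 70% G→A/C→T
transitions, uniform over the genome, all alt alleles on the mutant line)
on a 10-chromosome map with maize-scale physical (~2.1 Gb) and genetic
(~1500 cM) lengths and uniform within-chromosome recombination; F2
meiosis under the Haldane model — crossover counts Poisson with mean the
genetic length in Morgans, positions uniform in genetic distance,
converted to bp by piecewise-linear interpolation, no interference;
recessive phenotype with penetrance 1.0 by default (configurable), with
an optional lethal-homozygote mode that removes causal homozygotes before
pooling; phenotype-pure pools sampled without replacement; and read
counts with Poisson total depth and binomial alt draws at
f(1−ε) + (1−f)ε for pool allele frequency f and symmetric per-read error
ε. Marker genotyping is exact by default with an optional uniform
miscall rate.

**Default study conditions.** Pools of 200 + 200 from an F2 of 1100
(enough that 200 mutants are essentially always available), mean depth
50× per pool, error rate 0.005, 1200 variant sites. Pool sizes mirror the
design the package targets; depth, error rate and site count are declared
defaults in a realistic range for pooled RNA/DNA-seq — the upstream
sequencing parameters of any particular study are rarely published, so
they are parameters, not inferences.

**What it does not emulate.** Read-level artefacts (no FASTQ, mapping
bias, duplicates), RNA-seq expression-dependent coverage heterogeneity
(depth is homogeneous Poisson; a negative-binomial overdispersion knob
would be the first extension), linked selection or segregation
distortion, genotyping-error structure in melt-curve assays, and crossover
interference. Passing tests therefore demonstrate correctness of the
statistics under the stated sampling model, not robustness to every
artefact of real pooled sequencing.

**Phenotyping-record generation** inverts the pigment equations (solving
the 2×2 linear chlorophyll system and the carotenoid equation for the
ODs, rejecting truths with no non-negative absorbance solution) and
perturbs fluorescence traces multiplicatively, so zero-noise records
round-trip to their generating truth exactly (asserted to ≤ 1e-9 relative
error).

## Numerical and testing choices

- Coordinates are 1-based inclusive bp throughout (VCF convention); BED
  exports convert to 0-based half-open.
- Mb/kb widths round half-up via `decimal` to avoid banker's rounding.
- Cross probabilities are exact rationals; everything stochastic is
  driven by `numpy.random.Generator` and reproducible under a seed —
  identical seed and configuration give byte-identical outputs.
- The 1:2:1 segregation property is checked over 20 seeds at α = 0.01
  allowing up to 2 rejections, the number whose exceedance probability
  under the null is ~1e-3 — a per-seed "always non-significant" assertion
  would itself be a ~18% false alarm.
- Monte-Carlo assertions use 3-standard-error bands at the stated sample
  sizes (e.g. 50,000 gametes for the Haldane recombination fraction at
  10 cM, ≈ 0.0906).
- The end-to-end recovery check runs 200 simulated experiments at the
  default study conditions (seconds per run with the vectorised meiosis
  path); the χ² calibration uses 10,000 samples of n = 400, where the
  exact type-I error of the nominal-0.05 test is 0.0565 due to binomial
  discreteness.

## Known limitations

- The interval caller has no permutation-based significance envelope
  (QTL-seq style confidence bands); the threshold is a fixed rule.
- The two-locus cross engine assumes unlinked genes; linkage between the
  two mutations in the non-allelic model is not modelled.
- The fine mapper assumes a single causal locus on one chromosome and
  reports one interval; multi-locus traits are out of scope.
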