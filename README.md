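# bsakit

Bulked-segregant mapping of recessive mutant loci, from pooled allele
counts to a fine-mapped interval — plus the cross-ratio genetics and
leaf-phenotyping calculators that accompany a forward-genetics mapping
study, and a forward simulator so the whole pipeline runs on fully
synthetic data.

## Who this is for

Forward-genetics labs that map an EMS-induced recessive mutation by
crossing the mutant to its progenitor line, selfing the F1, and sequencing
phenotype-extreme bulks of the F2 (BSA / MutMap / QTL-seq style designs).
`bsakit` covers the computational chain downstream of variant calling:

1. **SNP-index scan** (`bsakit.bsa`): for each site and pool,
   `SNP-index = alt reads / total reads`, and
   `ΔSNP-index = SNP-index(MP) − SNP-index(WP)` where MP/WP are the
   mutant and wild-type pools. Candidate regions are maximal runs of
   consecutive sites whose statistic clears a threshold (default: MP
   SNP-index ≥ 0.9). For a recessive locus the MP index has expectation 1
   at the causal site and 0.5 at unlinked sites; the WP index is 1/3 at
   the causal site.
2. **Recombinant-count fine mapping** (`bsakit.finemap`): among
   mutant-phenotype F2 plants, any non-homozygous-mutant call at a marker
   witnesses a crossover; the locus is bounded by the nearest
   recombinant-bearing markers flanking the zero-recombinant core.
3. **Cross-ratio genetics** (`bsakit.crosses`): exact-rational progeny
   predictions for one- and two-locus crosses, Pearson χ² goodness of
   fit, and the complementation allelic test that discriminates
   "same gene" (compound heterozygote is mutant → 1:1 and 3:1 test-cross
   ratios) from "two genes" (complementation → all green).
4. **Phenotyping formulas** (`bsakit.phenotype`): chlorophyll a/b and
   carotenoid contents from 663/645/470 nm absorbances, the MultispeQ
   fluorescence parameter set (Fv/Fm, Phi2, qL, PhiNPQ, gH⁺ = 1/τ,
   active-PSI ratio, relative chlorophyll), and 2^−ΔΔCt relative
   expression.
5. **Synthetic data** (`bsakit.simulate`): Haldane-model meiosis
   (Poisson crossovers, no interference), phenotype pools, Poisson-depth /
   binomial read sampling, and generators that invert the phenotyping
   formulas — so every stage above is testable without any sequencing
   data.

Analyses follow a model/results pattern: build `BsaScan(counts, config)`
or `RecombinantScreen(genotypes, markers)` or
`SegregationTest(observed, cross, model)`, call `.fit()`, and read
estimates, tables and `summary()` off the results object.

## Worked example

```python
import numpy as np
import bsakit as bk

gmap = bk.GeneticMap.maize_like()                  # 10 chromosomes
rng = np.random.default_rng(8)
variants = bk.EMSVariantSet.random(gmap, 1200, rng=rng)
mut = variants.sites[variants.sites["origin"] == "mutant-line"]
row = mut.iloc[int(rng.integers(len(mut)))]
causal = bk.CausalLocusSpec(str(row["chrom"]), int(row["pos"]))

pop = bk.simulate_f2_population(gmap, variants, causal, 1100, rng)
wp, mp = bk.build_pools(pop, bk.PoolSpec("WP", 200, 50, 0.005),
                        bk.PoolSpec("MP", 200, 50, 0.005), rng)
counts = bk.simulate_pool_read_counts(wp, mp, rng)
print(bk.BsaScan(counts).fit().summary())
```

prints (the simulated causal locus is chr2:94,456,361):

```
SNP-index bulked-segregant scan
===============================
statistic: mp  threshold: 0.9  min depth/pool: 10
sites used: 1200  filtered: 0
candidate intervals: 5
  chr2:84448058-100228664 (15.78 Mb, peak 1.000, 9 sites)
  chr2:78334862-83523061 (5.19 Mb, peak 0.979, 4 sites)
  ...
```

The widest interval contains the true locus: only sites tightly linked to
the causal mutation reach an MP SNP-index near 1, so the above-threshold
run brackets it. Testing the observed F2 segregation against the 3:1
expectation of a single recessive gene:

```python
res = bk.SegregationTest({"green": 827, "pale-green": 273},
                         "A1a1 x A1a1", bk.AlleleModel.same_gene()).fit()
print(res.summary())
```

```
Segregation test
================
expected distribution: green: 3/4 (0.75), pale-green: 1/4 (0.25)
expected ratio (green:pale): 3:1
observed: {'green': 827, 'pale-green': 273}
chi2 = 0.0194, df = 1, p = 0.8892
```

χ² ≈ 0.02 with p ≈ 0.89: the observed counts are fully consistent with a
monogenic recessive trait.

The same pipeline is scriptable from the shell:

```bash
bsakit simulate -n 1100 --seed 8 --out sim
bsakit bsa --vcf sim.vcf --out scan
bsakit finemap --genotypes sim.genotypes.tsv --markers sim.markers.tsv --out fm
bsakit cross --cross "A2a2 x a1a1" --observed "green=102,pale=98"
```

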