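# lipidqtl

Simulation and analysis toolkit for **X-QTL bulk-segregant mapping** and
**backcross introgression analysis** of neutral-lipid (NL) storage in a
*Saccharomyces cerevisiae* cross between the laboratory strain **BY4741** and
the wine strain **AWRI1631**.

The two parents differ roughly two-fold in storage-lipid content
(triacylglycerol + steryl esters). lipidqtl implements the complete desk-side
counterpart of the mapping experiment:

* **`lipidqtl.synthetic_cross`** — a generator for every upstream object:
  a two-parent SNV map (~68,000 sites over a 16-chromosome, ~12.07 Mb genome),
  haploid segregant genomes from a no-interference meiosis model
  (crossovers ~ Poisson(cM/100), uniform on the genetic scale), haploid
  selection-marker filtering, a configurable polygenic Nile Red fluorescence
  (FI) trait, a FACS gate on the top trait fraction, pooled sequencing at the
  allele-count level (Poisson depth, binomial allele sampling), and
  per-segregant SNV calls.
* **`lipidqtl.phenotyping`** — microplate NL proxies
  `(FI_post − FI_pre)/OD600`, per-plate normalization to a reference strain,
  the 100-bin log2 frequency distribution, transgressive-segregation
  fractions, top-k selection, lipid summaries and two-tailed t-tests.
* **`lipidqtl.xqtl_mapping`** — per-SNV AWRI:BY allele ratios with a
  pseudocount, medians in 10,000 bp windows, the selected-minus-average
  allele-frequency difference track, a selection-free simulation null for the
  calling threshold, QTL peak calling, and allele enrichment among genotyped
  top segregants.
* **`lipidqtl.backcross_analysis`** — a 7-generation backcross driver with
  per-generation top-FI selection, parental-origin haplotype blocks from the
  ≥5-consecutive-SNV rule, donor-genome fractions against the drift
  expectation 100·(1/2)^g, and duplicated-segment detection from windowed
  sequencing depth.
* **`lipidqtl.io`** / **`lipidqtl.cli`** — VCF/TSV/BED/bedGraph readers and
  writers, a declarative run configuration, a deterministic end-to-end
  pipeline, and the `lipidqtl` command-line tool.

The model at the core of the mapping stage: for SNV *i* with pooled allele
depths *(n_BY, n_AWRI)*, the ratio is *(n_AWRI + c)/(n_BY + c)* with
pseudocount *c* = 0.5 and the AWRI frequency is *n_AWRI/(n_BY + n_AWRI)*;
window statistics are medians over the SNVs in non-overlapping 10 kb windows,
and a QTL candidate is a run of ≥2 contiguous windows whose frequency
difference Δ = f̃_selected − f̃_average exceeds a simulation-null threshold
with constant sign (Δ > 0 ⇒ AWRI-enriched, Δ < 0 ⇒ BY-enriched). Genetic
distances use Haldane's map function r = (1 − e^(−2d))/2 with a uniform
0.345 cM/kbp genome (26.2 kbp ≈ 9 cM).

## Worked example

```python
import lipidqtl as lq

# a scaled-down cross: 600 SNVs on two chromosomes, one AWRI- and one
# BY-beneficial locus
lengths = {"c1": 400000, "c2": 300000}
vmap = lq.build_parental_map(600, lengths, seed=5)
gmap = lq.GeneticMap.uniform(lengths)          # 0.345 cM/kbp
model = lq.TraitModel(100.0, [("c1", 200000, 0.0, 25.0),
                              ("c2", 100000, 12.0, 0.0)], noise_sd=8.0)

segs = lq.simulate_f1_segregants(vmap, gmap, 2000, seed=6)
fi = lq.trait_values(segs, model, seed=7)
top = lq.facs_sort(fi, 0.02)                   # top-2% FACS gate -> 40 cells

avg = lq.pool_sequencing(segs, vmap, 738, 0.002, seed=8, pool_label="average")
sel = lq.pool_sequencing([segs[i] for i in top], vmap, 1407, 0.002,
                         seed=9, pool_label="selected")
delta = lq.pool_delta(
    lq.window_median(lq.allele_ratio(sel), 10000, lengths),
    lq.window_median(lq.allele_ratio(avg), 10000, lengths),
)
for p in lq.call_peaks(delta, threshold=0.15):
    print(p.chrom, p.start, p.end, p.enriched_parent, round(p.apex_delta, 2))
```

prints

```
c1 10000 340000 AWRI 0.51
c2 0 250000 BY -0.49
```

two candidate QTLs: the selected pool is enriched for AWRI alleles around the
planted AWRI-beneficial locus on `c1` (positive Δ of the AWRI allele
frequency) and for BY alleles around the BY-beneficial locus on `c2`
(negative Δ) — the same directional contrast seen between AWRI-beneficial and
BY-beneficial loci in a real selected pool.

The same machinery is available from the shell:

```bash
lipidqtl run-all --outdir run1 --seed 1
lipidqtl map-qtl --selected pool_sel.tsv --average pool_avg.tsv \
                 --window 10000 --pseudocount 0.5 --threshold auto \
                 --variants variant_map.tsv --out-prefix out/qtl
lipidqtl backcross --recurrent BY --generations 7 --n 190 --seed 7 --outdir bc
```

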