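# Methods

This note documents the models behind `lipidqtl`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## Genome and variant model

The default genome is the 16 nuclear chromosomes of the S288C reference at
their sacCer3 lengths (12,071,326 bp total; no mitochondrial genome). The two
parents are assumed to differ at ~68,000 single-nucleotide sites, giving a
mean inter-SNV spacing of ~177.5 bp. `build_parental_map` allocates SNV counts
to chromosomes multinomially in proportion to length and draws positions
uniformly without replacement per chromosome; the BY allele is a uniform
nucleotide and the AWRI allele a uniformly chosen different nucleotide. SNV
positions are 1-based (VCF convention); all segments, windows and blocks are
0-based half-open (BED convention). Parental origins are coded BY = 0,
AWRI = 1 throughout.

## Meiosis

`simulate_meiosis` draws, per chromosome, a crossover count from
Poisson(L_cM/100) and places crossovers uniformly on the genetic scale, i.e. a
no-interference (Haldane) model with no obligate chiasma. Physical positions
come from inverting the cumulative genetic map (piecewise-linear; exactly
linear under the default uniform rate). Crossover positions are rounded to
integer bp; if two crossovers round to the same bp they cancel pairwise,
preserving parity. The starting chromatid is a fair coin per chromosome.

The default genetic map is uniform at **0.345 cM/kbp** (~2.9 kbp per cM),
chosen so that a 26.2 kbp physical distance corresponds to ~9 cM — the
marker-to-candidate-gene distance used for the linkage argument around the
canavanine selection marker. Per-chromosome piecewise rates are supported via
`GeneticMap.piecewise`; interference is not modelled (a switchable model could
be added without changing the mosaic representation).

Under this model the recombination fraction between two loci d cM apart
follows Haldane's map function r = (1 − e^(−2d/100))/2, which the
marker-hitchhiking tests verify directly (r ≈ 0.082 at 9 cM).

## Selection markers

Haploid selection (e.g. canavanine/thialysine counter-selection) is modelled
as a hard filter: a segregant survives iff its origin at every marker locus
equals the required parent. The default marker set is two stylized loci, a
can1-like site on chrV (position 32,000, 26.2 kbp from the RML2-like trait
locus) and a lyp1-like site on chrXIV; the real marker system involves
additional loci and is therefore configurable rather than fixed. Marker
selection distorts allele frequencies in *both* the average and the selected
pool identically, so the distortion cancels in the difference track — the
package reproduces why a marker-linked locus can show parental bias in each
pool without the subtraction flagging it, and why linkage (not the
subtraction) confounds a marker-proximal candidate.

## Trait model

The Nile Red FI proxy is `baseline + Σ locus effects (by origin) + Σ
epistasis terms (both origin conditions met) + N(0, noise_sd)`. FACS
measurement noise is folded into `noise_sd` rather than modelled as a separate
instrument channel; there is no basis for calibrating a separate gate-noise
term, so the single Gaussian lumps biological and instrument variation.

The default model (`default_trait_model`) has baseline 100 FI units, two
AWRI-beneficial loci (PIG1-like on chrXII:250,000 and PHO23-like on
chrXIV:560,000, each ≈ +38.5 when AWRI) and one BY-beneficial locus (RML2-like
on chrV:58,200, +12 when BY), with noise_sd = 10. The AWRI-beneficial effects
are solved in closed form so the noise-free parental ratio is exactly
2^0.66 ≈ 1.58 — the parental log2 FI ratio anchoring the histogram classes.
The locus coordinates are stylized placements on the correct chromosomes, not
gene coordinates; the RML2-like locus is deliberately 26.2 kbp from the
can1-like marker to reproduce the linkage confound.

## FACS gate

`facs_sort` selects the indices of the ceil(gate_fraction·n) largest trait
values (default gate 2%), ties broken in favour of the lower index via a
stable sort. A small downward tolerance (1e-9 absolute plus 4 ulp relative)
guards the ceiling against float round-up so that, e.g., 2% of 1.5×10^8 cells
is exactly 3×10^6.

## Pooled sequencing

Reads are simulated per SNV at the allele-count level: depth ~
Poisson(mean_depth), AWRI-supporting reads ~ Binomial(depth, f(1−e) + (1−f)e)
where f is the true pool AWRI frequency and e a symmetric base-call error
(default 0.002, a post-filter short-read error scale). Default target depths
follow the study conditions: 738× for the average pool and 1407× for the
selected pool. There is no read-level model — no FASTQ, alignment,
base-quality or mapping-bias model — by design; the analysis starts at allele
counts.

## X-QTL mapping

Per-SNV ratios are oriented AWRI:BY (the orientation of the windowed figure
tracks); the reciprocal phrasing that appears in some report text is noted in
output headers. A pseudocount of 0.5 (Haldane–Anscombe) keeps ratios finite
and positive at zero counts; with pseudocount 0, undefined sites are dropped
with a logged count. Window medians use non-overlapping 10 kb windows tiling
each chromosome from 0; the last window of a chromosome may be shorter and is
emitted; empty windows are omitted, producing gaps (a long gap marks a region
with no segregating sites). The difference track is computed on the
allele-frequency scale by default because ratio-scale differences are
asymmetric around 1; a ratio-scale mode is kept for figure parity.

No explicit significance rule is inherited for promoting loci to candidates,
so the default threshold is a simulation null: `null_threshold` simulates
selection-free population/pool pairs under identical depths and gate sizes
(the "selected" pool is a random, not trait-selected, subset) and returns the
0.99 quantile of |Δ| over all windows and ≥20 simulations. Peaks are maximal
runs of ≥2 contiguous windows with |Δ| ≥ threshold and constant sign; the
apex is the window with the largest |Δ|, and the enriched parent follows the
sign of Δ.

## Backcrossing and haplotype blocks

`run_backcross` crosses the currently selected segregant to the recurrent
parent each round, simulates batches of progeny until `n_per_gen` (default
190) marker survivors exist, phenotypes them, and carries the argmax-FI
segregant forward. Generation indices follow the convention in which the F1
founder is generation 1 with expected 50% donor genome and each backcross
meiosis halves it, so generation g has drift expectation 100·(1/2)^g percent
and F7 corresponds to 0.78125%, printed as 0.8% at one decimal. (Counted
strictly as pedigree rounds, F1→F7 is six meioses; the adopted convention is
the one consistent with the printed 0.8% figure.) Donor fractions on lineage
records are measured on the true simulated mosaic by default — exact and
cheap; pass `infer=True` to genotype the selected segregant and measure the
fraction from inferred blocks instead.

`infer_blocks` applies the consecutive-SNV rule: a maximal run of ≥5
same-parent calls becomes an assigned block spanning the half-open interval
between its furthest two SNVs, [first_pos − 1, last_pos). Runs shorter than
the minimum stay unassigned and are never merged into neighbours (merging
would manufacture precision); the intervals between assigned blocks are
explicit unassigned blocks, so the output always tiles the genome. Block
boundaries sit at the terminal SNV coordinates by default; a midpoint mode
(boundaries halfway to the nearest flanking call) is available behind the
`boundary="midpoint"` flag. Donor fractions default to the whole-genome
denominator so the (1/2)^g comparison is well-defined; an assigned-only
denominator is provided, and depth-flagged duplicated regions can be excluded
from both numerator and denominator.

## Duplicated segments

`detect_duplication` normalizes a windowed depth track by the genome-wide
median window depth and calls maximal runs of contiguous windows with fold ≥
1.5 and total length ≥ 50 kb. The depth simulator draws window read counts as
Poisson with expectation mean_depth·window/read_len scaled by copy number
(default 30× / 150 bp reads / 5 kb windows), so a heterozygous-free haploid
duplication at 2× is recovered essentially exactly. Only depth-gain flagging
is modelled; breakpoint-resolution translocation calling is out of scope.

## Phenotyping

The NL proxy is (FI_post − FI_pre)/OD600 with OD600 ≤ 0 rejected; negative
proxies (post < pre) are retained with a logged count but excluded from log2
binning. Plate normalization divides by the per-plate mean of the reference
strain (Y7092, isogenic with BY4741; four replicates per plate in the
simulated layout). Histograms use 100 equal-width bins on the log2 scale over
the [min, max] of the dataset being binned by default — a degenerate range is
an error, not a single bin; a common range across panels can be passed
explicitly and is the recommended mode when comparing generations, since the
per-panel default makes class indices panel-specific. Class indices are
1-based; bins are half-open [left, right) except the last, which is closed.
The class↔log2 map is exactly linear with slope (max − min)/100.

The t-test defaults to the equal-variance Student form (the common
spreadsheet default for this kind of plate data), with Welch behind a flag;
two zero-variance samples with equal means return p = 1 by convention.

## What the generator does and does not emulate

The generator reproduces the *structure* of the experiment: segregating-site
density, Poisson recombination under a genetic map, marker hitchhiking,
selection-driven allele-frequency shifts, pool-size and depth noise,
genotyping miscalls/missingness, plate-scale drift, and depth-gain
duplications. It does not emulate read-level artifacts (mapping bias, indels,
repeats), crossover interference, aneuploidy beyond a single duplicated
segment, mating-type mechanics, growth-rate confounds between FI and fitness,
or any real linkage disequilibrium structure of the two strains. Passing
tests therefore demonstrate that the analysis correctly recovers signals the
model can represent at realistic noise levels — not that it is robust to
alignment- or culture-level artifacts absent from the model.

## Problem sizes used by the test and acceptance runs

Monte-Carlo checks run at sizes chosen to keep the full suite fast while
leaving the statistical assertions well-powered: the Poisson crossover
goodness-of-fit uses 10 seeds × 4,000 meioses; the drift backcross uses 200
replicates × 7 generations with 8 progeny per generation (under a zero-effect
trait the selected progeny is an exchangeable random draw, so the
donor-fraction distribution does not depend on the per-generation panel
size); the QTL-recovery experiment keeps the full study conditions — 68,000
SNVs, 10,000 segregants, top-2% gate, 738×/1407× depths, 20 seeded
replicates — because the pool-size noise structure is what is being tested.
Oracle-equivalence suites run 1,000 random instances per kernel.

## Known limitations

* The null threshold assumes exchangeability between the selected subset and
  the population; strong marker selection is shared by both pools and cancels,
  but trait-correlated survival bias would not.
* Window medians are unweighted by depth; at very low depth a window median
  can be driven by a handful of noisy sites (the pseudocount bounds, but does
  not remove, this).
* The block caller reports unassigned intervals rather than probabilistic
  boundaries; with sparse SNVs the unassigned mass can be large, which is why
  the genome denominator is the default for donor fractions.
* `run_backcross` models the recurrent parent as a uniform genome; residual
  heterozygosity or de novo mutation in the recurrent stock is not modelled.
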