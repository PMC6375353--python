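# Methods

## The inference problem

A young XX–XY region leaves four coupled signatures in a sexed
resequencing cohort: elevated male–female differentiation with an
analytic ceiling of F_ST = 0.5 at fully sex-linked sites; an excess of
sites where all males are heterozygous and all females homozygous
(XY-patterned sites); heterozygote excess (negative F_IS) in males,
anti-correlated with the F_ST profile; and, once cross-mapping Y reads are
excluded, a ~50% male coverage deficit over X-specific sequence plus
female-silent Y-specific sequence. `sexscan` computes each signature as an
explicit windowed track and combines them with a transparent,
parameterized rule rather than a classifier: the output is evidence, not a
verdict.

## Statistics and their numerical conventions

All coordinates are 0-based half-open internally; a VCF site at 1-based
position P belongs to window `(P−1)//width`. Windows tile each contig; the
last window may be partial.

**Hudson F_ST.** Per-site numerator
`(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`, denominator
`p1(1−p2) + p2(1−p1)`, with n the *called* allele copies (missing
genotypes never enter frequencies). Windows use ratio-of-sums; negative
per-site numerators are retained so the ratio stays unbiased; a window
with zero summed denominator is NA. Sites where either group has fewer
than 2 called copies contribute nothing. Weir & Cockerham (1984) variance
components are available behind `fst_estimator="wc"` for sensitivity
analysis. Genome summaries are reported both as means of window values and
as pooled ratio-of-sums (`pooled_fst`), since the two differ and published
genome-wide numbers rarely say which was used.

**π and d_xy.** Per-site unbiased heterozygosity `(n/(n−1))·2p(1−p)` and
between-group `p1(1−p2)+p2(1−p1)`, summed and divided by window width by
default (`denominator_mode="width"`, the whole-genome-sequencing
convention where every position is treated as callable); a
callable-site-count mode exists for sparse data. `d_a = d_xy −
(π1+π2)/2` exactly, per window.

**Tajima's D.** Standard 1989 constants (a₁…e₂) on the window's
segregating sites; within a group, sites with any missing call are dropped
so the sequence count n is fixed; NA below 3 segregating sites.

**XY-patterned sites.** Strict mode (default) requires complete calls in
both sexes, every male heterozygous, every female homozygous (for either
allele class — the two female homozygote classes need not agree, matching
the genotype-pattern definition rather than an allele-identity one);
lenient mode evaluates called genotypes only with a per-sex minimum.
Strict is the default because the selection the method mimics used
complete 5v5 calls.

**F_IS.** Per individual, `F = (O_hom − E_hom)/(N − E_hom)` over sites
polymorphic within the analysis subset, with per-site expected
homozygosity `1 − 2p(1−p)·2n/(2n−1)` (the small-sample correction used by
the conventional `--het` computation, so outputs are comparable to such
tables). The normalized window track subtracts each individual's
genome-wide-excluding-focal baseline before averaging within sex.
Degenerate individuals (N = E_hom) are NA. The F_IS–F_ST window
correlation is Pearson with a two-sided p; the originally cited method's
exact formulation is not documented in accessible text, so Spearman is a
one-line sensitivity change.

**PCA / A_jk.** Sites centered by 2p̂ and scaled by `sqrt(2p̂(1−p̂))`;
missing genotypes mean-imputed (zero after centering); monomorphic sites
dropped; plain SVD. `A_jk = mean[(g_j−2p)(g_k−2p)/(2p(1−p))]` over
polymorphic sites with both calls; the diagonal is left NaN because the
off-diagonal definition does not extend to j = k. Note the estimator's
−1/(n−1) centering bias for unrelated samples: at n = 10 the null
off-diagonal mean is ≈ −0.11, not 0.

**Coverage.** Per sex s: global median M_s over all positions × all
individuals of s (computed exactly from depth histograms); per-position
per-sex median / M_s; window mean; log2 with NA at zero (no pseudo-count —
"no coverage" stays categorically distinct). Male-only regions: maximal
runs ≥ 1 kb where ≥ ⌈0.8·n_males⌉ males have nonzero depth, pooled male
depth > 5 and pooled female depth < 3 (the literal reading that keeps the
three clauses non-redundant). Y-contig vetting drops contigs with any
single-male depth > 50 (individual-specific repeats) or pooled female
depth ≥ 5 at any position; per-individual female mode is a flag, since the
source description does not disambiguate.

**K-mers.** Words are counted from reads as written — no
reverse-complement canonicalization — because the trigger-prefix scheme
operates on raw reads; this halves per-strand sensitivity, which the
placement step compensates by searching both strands explicitly.
`min_count` applies to the pooled per-sex catalog after merging
individuals. Y-mer and X-mer thresholds are exact integer/ratio boundaries
(male ≥ 10 ∧ female ≤ 4; male ≥ 1 ∧ ratio ∈ [1.75, 2.25], Y tested first
so the classes are exclusive); with unequal sex sample sizes the female
count is scaled by n_m/n_f before the ratio. The trigger ("AG") and k (37)
are configuration values; no equivalence across triggers is asserted.

**Topology weighting.** For quartets the four-point condition on Hamming
distances is equivalent to inferring the tree under additive distances, so
per-window tree building reduces to `argmin{d(AB)+d(CD), d(AC)+d(BD),
d(AD)+d(BC)}` with ties split equally; weights are tallies normalized over
all quartets (exhaustive ≤ 10,000, else seeded uniform sampling). This is
a deliberate quartet-scale reimplementation of topology weighting, not a
port of the original subtree-iteration tool, and no numerical agreement
with it is claimed. Unphased genotypes are expanded to seeded
pseudo-haplotypes (heterozygous alt assigned to a random haplotype per
site); true phased haplotypes are used as-is when available.

**Candidate regions.** A window is flagged by sex F_ST ≥ 0.15, XY-count
≥ 5/window, or perfect-dialect male/female coverage ratio ≤ 0.75; flagged
windows merge across gaps ≤ 50 kb. Because every 10 kb window is
effectively one genealogy (below), both the F_ST null and the XY count
have heavy tails — ~4–5% of autosomal windows exceed the F_ST flag, and
roughly one window per thousand collects a burst of spurious XY sites when
a chance clade groups one haplotype of every male. Such noise stays
confined to a few windows, so an interval is reported only when it spans
≥ 4 flagged windows (≥ 6 if a single track supports it); both knobs are
exposed and setting them to 1 recovers the raw OR rule. Measured on the
generator: 0/40 no-SD replicates produce any interval, and the true
interval's Jaccard with truth is ≥ 0.7 in 19/20 replicates.

## The synthetic cohort generator

Each contig is tiled into non-recombining blocks (default 10 kb, equal to
the analysis window); blocks are independent, standing in for free
recombination between them. Within a block, haplotypes follow a Kingman
coalescent with infinite-sites mutation at per-block rate θ
(E[π] = θ, E[S] = θ·Σ1/i); the engine is a direct implementation kept
deliberately small and fast (thousands of independent blocks per cohort),
and is cross-checked in the test suite against msprime and against the
closed forms.

Males carry one X and one Y. Per SD-region block, one ancestral Y
haplotype is drawn from the X pool; Poisson(τ·length) shared Y-specific
derived mutations make every male heterozygous and every female
ancestral-homozygous; Y copies additionally coalesce among themselves with
rate `y_internal_theta`. Y-specific insertions live in a male-assembly
coordinate space (the SD contig with insertions spliced in), emitted as
its own FASTA and depth track. Two-population mode draws population A's
haplotypes from a common ancestral pool, the bottlenecked population B
from ≤ 4 founder haplotypes (forcing positive Tajima's D), and adds
population-private fixed differences at rate `split_theta_scale·θ/2` per
block. Depth is Poisson per position; under the "perfect" dialect male
depth halves wherever an X/Y mismatch lies within one read length
(`full_sd_mask` treats the whole region as differentiated); under "all",
cross-mapping hides hemizygosity. Reads are error-free fixed-quality pairs
sampled uniformly from each individual's two haplotypes on a random strand
of the duplex; names carry origin tags mirrored into the truth file. All
randomness descends from one seed via numpy `SeedSequence` spawn keys
(streams 1–5 for genotypes, depth, reads, references, insertions), so
identical configurations are byte-identical.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| cohort | 5 males + 5 females per population | the sexed per-population sample size the scan design targets |
| genome | 10 contigs × 2 Mb | desk-scale stand-in for a ~1 Gb genome; enough windows per contig to rank |
| θ per 10 kb block | 50 (π ≈ 0.005/bp) | lake-population diversity of the motivating system |
| sd_region | LG7: 0.3–1.8 Mb | one contig carrying a large recombination-suppressed block |
| τ (Y-specific mutations/bp) | 1.75×10⁻³ | μ = 3.5×10⁻⁹/bp/gen × ~5×10⁵ generations: a Y younger than 1 Myr; the simulator exposes τ directly and leaves the μ×generations conversion to the user |
| `y_internal_theta` | 1.0 per block | low diversity among Y copies (young, non-recombining lineage) |
| Y insertions | 12 × 1.5 kb | kb-scale male-only presence/absence sequence, matching what male-only-coverage calling can detect (≥ 1 kb) |
| `split_theta_scale` | 0.8 | net divergence between populations comparable to within-population diversity |
| `bottleneck_founders` | 4 | recent strong contraction: haplotype excess, positive Tajima's D |
| depth λ | 20 | mid-teens-to-twenty × short-read coverage |
| reads | 150 bp pairs, 350 bp fragments, 20× | standard paired-end Illumina geometry |

### What the generator does and does not emulate

It reproduces the *signatures* the scan keys on: HWE genotypes on
autosomes, the XY genotype pattern, male heterozygote excess, dialect-
dependent coverage loss, female-silent insertions, 2:1 X dosage in k-mer
space, bottleneck SFS distortion. It does **not** model recombination
within blocks, gene flow, sequencing error, base-quality variation,
indels within reads, mapping artifacts, or reference bias. Two
consequences matter for interpreting green tests. First, one genealogy
per window makes window-level noise *heavier* than in recombining real
data: per-window F_IS signs, window F_ST nulls and PCA axes are noisier
here than a real cohort of the same size, so directional tests aggregate
over windows and seeds, and the scan's span thresholds exist. Second,
error-free reads make k-mer counting *cleaner* than reality at the
word-count level, yet classified Y-mers are still contaminated: at
realistic depth, a k-mer overlapping an allele rare in females (expected
pooled female count ≈ 7) falls under the female < 5 threshold a few
percent of the time, so a sex-private-looking word is often just a
sampling fluctuation on a rare variant. Passing tests therefore show the
extraction machinery and thresholds behave exactly as specified, not that
the classified Y catalog is pure — on real data the downstream coverage
and homology filters (here `filter_y_contigs`) do that cleaning.

## Test problem sizes

The suite runs on one CPU in under a minute by scaling simulation size,
never the pass bands: 20-replicate parameter recovery uses ten 200 kb
contigs with a 120 kb SD region; F_IS direction and correlation tests use
a 600 kb focal contig (40 SD windows); the read-level k-mer tests use a
120 kb genome at 20×; simulator calibration uses 2,000 replicates at
n = 10, θ = 5 and 500 at n = 20, θ = 10. The acceptance script's coverage
target simulates a 40 Mb genome so that the 2 Mb hemizygous region is a
small fraction of the male depth distribution (the sex median is an
integer; a large hemizygous fraction would shift it discretely).

## Known limitations

- Window statistics on the simulator inherit block-level linkage; treat
  per-window values as one draw per genealogy, not independent replicates.
- The Welch test on windows ignores autocorrelation between adjacent
  windows; its p-values are anti-conservative on real data.
- With n = 10 samples a genotype PCA has nine axes and chance
  sex-correlations of |r| ≈ 0.3–0.7; sex separation is reliable only on
  the SD contig itself at this sample size.
- `A_jk` retains its −1/(n−1) small-sample centering bias.
- Topology weighting groups whole individuals, so at most ~1/4 of
  male-male quartets draw two Y haplotypes; a shared ancestral Y raises
  the males-together weight but cannot push it near 1, which is why
  support summaries use thresholds on weights rather than expecting
  fixation.
- Every contig is treated uniformly; concatenated unplaced-scaffold
  pseudo-chromosomes, if present, get windows like any other contig and
  their statistics should be interpreted accordingly.
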