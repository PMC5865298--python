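# Methods

## The scan

poolscan detects selective sweeps from pooled resequencing (Pool-Seq) of a
small number of population pools. The observable per site is the vector of
allele read counts per pool; individual genotypes are never seen. The scan
assumes variants are biallelic, that reads within a pool are independent
draws from the pool's allele frequency, and that upstream processing
(mapping/quality filtering, indel removal) already happened — its input is
a PoPoolation-style sync count table.

A SNP is called in a pool when the highest-count non-reference allele has
at least `min_nonref_reads` reads (default 2). Sites where a second
non-reference allele also reaches the threshold are discarded by default
(`multiallelic_policy="drop"`), because every downstream statistic is
biallelic; a `top_two` policy that keeps the two highest-count alleles is
available. Within-population statistics use each pool's own SNP set. The
between-population F_st uses the sites called in *every* pool, with one
major/minor labeling shared across pools chosen by summed read counts
(reference wins ties) — per-pool major alleles can differ, and F_st needs a
single frequency axis.

Windows of `window_size` (default 200 kb) slide by `window_step` (50 kb);
a window starts at every multiple of the step below the chromosome length
and is truncated at the chromosome end, so chromosome tails are scanned
rather than silently dropped. Windows with fewer than `min_snps_per_window`
(10) SNPs of the relevant SNP set carry no statistic and are excluded from
the Z-score distributions: sparse windows make the ratio estimators
unstable, and the window size is meant to be chosen (see
`calibrate_window_size`) so that almost none are excluded.

Each statistic's genome-wide distribution over eligible windows is
standardized to Z-scores (sample SD, n−1; configurable only in the sense
that the distinction from n is negligible at genome scale). Windows with
Z(Hp) < −6 or Z(D) < −6 (their union by default — either signature
suffices; `within_combine_mode="intersection"` requires both) or
Z(F_st) > +6 are significant; the comparisons are strict.

## Statistics

**Pooled heterozygosity.** Hp = 2·(Σ n_MAJ)(Σ n_MIN)/(Σ n_MAJ + Σ n_MIN)²
over the window's SNPs. Bounded by [0, 0.5], maximal when summed major and
minor counts balance, and invariant to a global major/minor label swap.

**Pooled Tajima's D.** Per SNP with c = n_MAJ + n_MIN reads,
π_i = 2 n_MAJ n_MIN / (c (c−1)) estimates the site's expected
heterozygosity from the read sample; θπ is the window sum and S the window
SNP count. An effective sample size n_eff is the floored window median of
c, by default capped at the haploid pool size 2N
(`tajima_neff_mode="pool_capped"`): reads beyond 2N cannot sample new
chromosomes. Tajima's constants a1, a2, b1, b2, c1, c2, e1, e2 follow the
classical normalization at n_eff, and
D = (θπ − θW)/sqrt(e1·S + e2·S(S−1)).

The ≥2-read calling rule censors the low-frequency allele classes, which
removes more segregating sites than diversity and biases classical D
upward (≈ +1.2 on this package's own neutral simulation at 16×). The
default `bias="min_count"` estimator therefore removes the censored
classes from both neutral expectations: with minimum count b and the
expected count of derived-allele class i proportional to 1/i,

    θW = S / (a1 − Σ_{i<b} 1/i),
    θπ = Σ π_i / (1 − Σ_{i<b} 2(n_eff − i)/(n_eff (n_eff − 1))).

With b = 1 both reduce to the classical estimators (`bias="none"` keeps
those regardless). The correction is first-order — it treats the read
sample as a clean sample of n_eff chromosomes and ignores depth variation
and double sampling through the finite pool — and the variance
normalization keeps the classical constants. Residual miscalibration is a
smooth monotone distortion, which the Z-transform absorbs; the neutral mean
window D under the default simulation is ≈ +0.16. This estimator is this
package's own ascertainment-aware design; it is not a byte-level
reimplementation of any other tool's corrected estimator.

**Pooled F_st.** Per common SNP, with p_k the shared-major read frequency
in pool k: H_S = (2p₁(1−p₁) + 2p₂(1−p₂))/2, p̄ = (p₁+p₂)/2,
H_T = 2p̄(1−p̄). The window value is Σ(H_T − H_S)/Σ H_T (ratio of sums,
default) or the mean per-SNP ratio over SNPs with H_T > 0
(`fst_scheme="mean_of_ratios"`); the ratio-of-sums form is much more stable
at 16× depth. Negative values are clamped to 0 (Wright's index
interpretation; the outlier test is one-sided upward). Frequencies are raw
read frequencies without pool-size correction, so the absolute level is
inflated by binomial sampling — at 25 diploids and 16× the neutral mean
window F_st is ≈ 0.053 against a simulated divergence of 0.05 — and again
the Z-transform consumes the level.

## SCR construction

Maximal stretches of significant windows form region cores (the core span
is the union of the member windows). Two cores on one chromosome are
collapsed when the gap between their spans is at most `max_gap_windows`
(default 2) window steps; the collapsed gap is inside the resulting span
but its windows are not members. Gap length is measured on the spans in
step units, not in window indices: with 200 kb windows sliding by 50 kb,
consecutive windows overlap, and span-gap counting is the convention that
reproduces the published worked example (three chromosome-6 stretches at
36.45–37.0, 37.05–38.1 and 38.2–38.4 Mb, separated by one and two steps,
merging into a single 1.95 Mb region). Cores are extended ±`flank_bp`
(100 kb), clipped to the chromosome, before gene annotation; a gene is
assigned on ≥ 1 bp overlap with the extended span (half-open intervals, so
mere abutment does not count), and duplicate gene ids are deduplicated.

With three pools (a focal population and two sisters), regions are
classified by core-span overlap (≥ 1 bp): **A** — focal within-population
regions overlapping no sister within-population region; **B** — merged
spans where the two sisters' within-population regions overlap; **C** — all
regions of the sister-pair F_st scan. Overlap on spans rather than window
identity keeps the classification robust to grid offsets.

## The synthetic-data generator

The generator emulates the scan's target design: 3 pools (2 supported) of
25 diploids at mean depth 16×, one 10 Mb chromosome with expected 0.004
polymorphic sites/bp (~40 k sites — a desk-scale stand-in for the ~10⁷ SNPs
of a full mammalian genome scan). Ancestral minor-allele frequencies follow
a 1/x density on [1/(2N), 0.5]; per-pool frequencies are Balding–Nichols
draws, Beta(a(1−F)/F, (1−a)(1−F)/F), around the ancestral value with
divergence F = 0.05, giving direct control of the expected F_st. Reads are
two-stage binomial: a Binomial(2N, f)/2N realized pool frequency, then
Binomial(depth, realized) alternate reads at Poisson(16) depth truncated at
≥ 1. The reference base is the ancestral major allele.

Sweeps are phenomenological frequency distortions, not haplotype
simulations — the scan consumes frequency summaries only. Inside a sweep,
f′ = f + I·w(d)·(round(f) − f), with w decaying linearly from 1 at the
center to 0 at the half-width; intensity I = 1 fixes the center.

The default sweep half-width (200 kb) and the canonical scenario (one
sweep private to the focal pool, one private to the first sister pool, at
2.5 and 6.5 Mb) come from a design power analysis. On a ~200-window grid
the largest attainable |Z| is bounded near sqrt(#windows), and every sweep
present in a scan inflates that scan's Z denominator; the scenario
therefore places exactly one sweep in each scan that must detect it (the
focal pool's Hp/D scan; the sister-pair F_st scan), and 200 kb is the
smallest half-width whose planted signal clears the 6-SD cut-off with a
~3 SD margin. A sweep shared identically by both sisters is deliberately
absent from the default scenario: at this desk scale two equal sweeps in
one scan push the attainable maximum below Z = 6, so a group-B
demonstration needs either a larger genome or a relaxed threshold (both
available through configuration).

What the simulation does not model — linkage, recombination, haplotype
structure, sequencing error, mapping artifacts, variable depth beyond
Poisson — bounds what passing tests show: the pipeline recovers planted
frequency signals of realistic scale under the design's sampling noise; it
says nothing about LD-dependent statistics or artifact robustness on real
reads.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open everywhere in memory; sync and GFF3
convert at the parser/writer boundary (`SiteCounts.pos` stays 1-based, as
printed in sync files; window assignment uses pos − 1). Undefined window
statistics (no SNPs, zero variance term, all-fixed F_st denominators) are
NaN, excluded from Z distributions, and never significant; a constant
statistic vector raises a degenerate-distribution error rather than
emitting Z = 0. Tajima's D is 0 when both its numerator and variance term
vanish (the symmetric singleton window). Count ties in SNP calling break
toward the reference allele, then allele order A < C < G < T. All pipeline
outputs are pure functions of (inputs, config, seed); the run log records
SNP counts, common-SNP counts, eligible-window counts, the mean/SD behind
each Z-transform and significant-window counts.

## Known limitations

The ascertainment correction for D is first-order (see above). F_st has no
pool-size correction. The SNP caller applies no depth floor beyond the
implicit ≥ 2 non-reference reads, and no maximum-depth filter (repeat
regions in real data would need one upstream). Group classification
assumes the three-pool focal/sisters design; other designs get per-scan
SCR lists without group labels. The calibration routine reports the
sparse-window fraction only; it does not choose a size for you.
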