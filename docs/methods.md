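# Methods

This note records the models, algorithms, numerical conventions and design
choices behind popgenkit, in the spirit of a software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Genotypes are biallelic, unphased hard calls stored variant-major at
2 bits per call in the standard `.bed` dialect: `00` = homozygous a1,
`01` = missing, `10` = heterozygous, `11` = homozygous a2, four calls per
byte, first sample in the lowest-order bits. By convention a1 is the
minor allele, and the decoded *dosage* of a call is its a1 count
(0, 1, 2; −1 for missing). Pad bits beyond the last sample are held at a
fixed code (zero, as PLINK writes them) and every kernel masks them out,
so appending phantom pad positions can never change a result. Missing
phenotypes use the sentinel −9; sex 0 means unknown; base-pair positions
are 1-based as in `.bim`, internal indices 0-based. Arbitrary chromosome
names are accepted.

VCF import is deliberately lossy: phase separators are ignored; sites
with more than one alternate allele are either skipped
(`biallelic_only`) or reduced to the most common alternate with all other
alternate calls set missing (ties keep the first-listed alternate); when
a GP field is present, a biallelic call is accepted only if its *maximum*
genotype probability reaches `hard_call_threshold` (default 0.9). The
threshold compares the maximum probability, not a specific genotype's
probability — with near-uniform triplets this is the more conservative
reading, and the alternative (per-called-genotype probability) would
only differ for calls the maximum rule already rejects. After import, a1
is the lower-frequency allele (tie → the alternate); reference/alternate
bookkeeping is out of scope.

## Bit kernels

All inner loops operate on 64-bit words holding 32 two-bit codes.
Population counts (`popcount`, and `popcount2`, which sums 2-bit fields)
are pure-integer SWAR reductions with no hardware-intrinsic dependency;
since they are exact integer computations, the vectorized numpy
formulation is bit-identical to a scalar loop by construction (and is
tested against one).

*IBS.* Calls are re-encoded ϕ→01, 0→00, 1→10, 2→11 with a companion mask
(00 at missing, 11 otherwise). This code map is exactly the one that
makes the Hamming weight of the masked XOR equal |a_i − b_i| — set-bit
contributions {0:0, 1:1, 2:2} — which the tests verify exhaustively over
all 16 genotype pairs rather than assume. Rows are padded with missing
codes to whole 960-call blocks (30 words), so block-at-a-time
accumulation and whole-row evaluation agree exactly.

*Dot products / correlation.* For the correlation r between two variants,
recoded dosages v = 1 − dosage ∈ {−1, 0, +1} (missing → 0) give
per-sample products v·w whose complements t = 1 − v·w ∈ {0, 1, 2} fit in
2 bits: with hom-minor→00, het-or-missing→01, hom-major→10,

    Z := (X OR Y) AND 0101…₂
    t-fields := ((X XOR Y) AND (1010…₂ − Z)) OR Z

and Σ v_i w_i = #fields − popcount2(t-fields). The 2-bit subtraction
`1010…₂ − Z` is per-field safe: every minuend field is 10₂ and every Z
field is 00₂ or 01₂, so no borrow crosses a field boundary. Moments over
the intersection come from masked popcounts of per-variant indicator bit
vectors; for all-pairs scans over missing-free data the per-variant
moments are precomputed once (O(mn) instead of O(m²n)), and the fast
path feeds the identical integers to the identical arithmetic, making it
bitwise equal to the general path.

## Exact tests

All three tests (HWE, Fisher 2×2, Fisher 2×3) use the same principles:
adjacent tables in a fixed-margin family have simple likelihood ratios
(factorials cancel), all likelihoods are kept *relative* to the modal
table (the shared constant cancels in the p-value ratio), and tails are
truncated when the IEEE-754 double partial sums stop changing, which
costs O(√n) terms with no loss of precision because the likelihoods
decay super-geometrically. "At least as extreme" means null likelihood
≤ that of the observed table, ties included; a relative tolerance of
1e−9 keeps exactly tied tables (e.g. from symmetric margins) together
despite floating-point noise — genuinely distinct tables are never that
close except within a vanishing neighbourhood of the mode, where
misclassification is impossible in practice. The mid-p value subtracts
half of the observed table's probability (only the observed table's
mass, not that of tied tables; the common mid-p definition). Both walks
track only a few scalars, so memory is constant in n.

One subtlety: a tail is exhausted only when *both* the denominator and
the numerator partial sums saturate. For an observed table deep in one
tail, the opposite tail's equally extreme region lies far beyond the
point where the denominator stops changing, so the walk must continue
until it has entered the ≤-observed region and the numerator stops
changing too.

The 2×3 test works on the two-parameter lattice of tables (top-row cells
a, b free). Work is restricted to the elliptical region of tables with
likelihood above 2⁻⁵³ relative to the mode (denominator) and the annulus
within a factor 2⁵³ below the observed likelihood (numerator); truncated
terms are bounded by 2⁻⁵³ times the number of tables, i.e. far below the
10th significant digit. Rows lying entirely at-or-below the observed
likelihood are added in one step via the identity that a row of 2×3
likelihoods sums to one 2×2 likelihood. Log-likelihoods come from a
log-factorial table built by cumulative summation (a recurrence, not a
gamma-function approximation); the mode is found by hill-climbing from
the independence expectation, which is exact for this log-concave
family.

The support-range helper (the 2×2 worked example) reports the upper-left
cells whose *absolute* hypergeometric probability — the likelihood
normalized over the family, which sums to 1 — reaches 2⁻⁵³; this is the
normalization under which sub-threshold tables vanish from a naively
summed denominator. Boundaries located in log space are confirmed with
exact big-integer binomials.

Library functions return both the ordinary and mid-p values in one
result object (rather than taking a mode flag); the CLI's `--midp`
selects which is reported.

## Relationship matrices

The GRM accumulates (x_j − 2q)(x_k − 2q)/(2q(1−q)) per marker (x = minor
dosage, q = minor-allele frequency over non-missing calls, optionally
supplied externally); a missing call contributes zero and decrements the
pair's denominator. Per marker a sample pair is in one of seven cases
(six genotype combinations + any-missing), coded in 3 bits; 20 markers
pack into one word and four 2¹⁵-entry partial-sum tables (doubles, 1 MB
total — 8-byte entries chosen for accuracy) replace twenty lookups with
four. The table build adds the five per-marker increments left to right,
and the equivalence test performs its five single lookups in the same
association so the comparison is bitwise. Monomorphic variants
(q ∈ {0, 1}) must be excluded upstream and are rejected loudly.

Diagonal entries use the same squared-deviate increment with x = y; the
GCTA self-relationship variant 1 + (x² − (1+2q)x + 2q²)/(2q(1−q)) is
available behind the `gcta_diagonal` flag. Note a structural property
verified by the tests: with in-sample frequencies the deviates sum to
zero across samples, forcing the mean off-diagonal to
−mean(diagonal)/(n−1) exactly; unbiasedness (mean off-diagonal ≈ 0,
mean diagonal ≈ 1) therefore holds at the *generative* frequencies, and
that is how calibration is asserted.

Row-chunked execution (`row_chunk=(k, K)`) computes rows
⌈n(k−1)/K⌉..⌈nk/K⌉−1 with per-row arithmetic independent of the chunking,
so the K bands concatenate bitwise-identically to the full run.
Complete-linkage clustering delegates to scipy's nearest-neighbor-chain
implementation (O(n² log n)); merge heights are the farthest-point
criterion and tie-breaking follows scipy's deterministic ordering, which
the naive-oracle test compares on heights (the merge *order* under exact
ties is conventional).

## Linkage disequilibrium

*Pruning.* `indep_pairwise(window, step, r²)` slides a window of
`window` variants by `step` within each chromosome; while any surviving
pair in the window exceeds the threshold, the member with the smaller
MAF is removed (tie → the later-positioned variant; this removal rule
is a documented convention, not canon). Correlations are computed
lazily, cached, and never against removed variants.

*D′ machinery.* The 3×3 genotype-pair table determines unambiguous
haplotype counts plus the phase-ambiguous double-heterozygote cell.
With allele frequencies fixed at their MLEs, interior stationary points
of the profile likelihood in the minor–minor haplotype frequency p11
satisfy the EM fixed-point cubic, solved in closed form
(Cardano/trigonometric); roots outside
[max(0, pA+pB−1), min(pA, pB)] are discarded, boundary candidates are
always included, and log-likelihoods are compared only when several
candidates survive. D′ = D/Dmax with the usual sign-dependent Dmax.

The 90% confidence interval for |D′| evaluates relative likelihoods at
the 101 grid points D′ = 0, 0.01, …, 1 (second locus flipped first so
D ≥ 0); ci_low is the largest grid value with cdf ≤ 0.05 and ci_high the
smallest with cdf ≥ 0.95. Classification: *strong LD* if ci_low ≥ 0.70
and ci_high ≥ 0.98; *recombination* if ci_high < 0.90; else
*inconclusive*. Only the 0.90 bound is intrinsic to the recombination
definition; 0.70/0.98 follow the Gabriel/Haploview convention and all
three are parameters.

The fast classifier is lossless by construction: it first establishes
unimodality (a unique interior stationary point, from the same cubic)
and then applies the bound S_right ≤ 11·L(0.90) ≤ L(peak)/19, i.e. it
declares recombination only when L(0.90) < L(peak)/209, which *implies*
the grid cdf condition; the constant 209 = 19·11 is derived from the
5%/95% definition rather than hard-coded from any particular dataset.
Anything not settled this way — including multimodal likelihoods —
falls back to the full grid, so agreement with the grid classifier is
exact, and is tested exhaustively on small tables and on random large
ones.

*Blocks.* After a MAF ≥ 0.05 pre-filter (the conventional preparation
for block estimation; adjustable), candidate blocks are contiguous
variant runs within 200 kb (default span cap, adjustable) whose endpoint
pair is strong-LD and whose informative pairs (strong or recombination;
inconclusive pairs are excluded from the ratio) are more than 19:1
strong. All within-candidate informative pairs are counted. Candidates
are selected greedily by descending base-pair span (ties leftmost),
discarding overlaps. Pair classifications are computed lazily with the
fast classifier and cached; an exact early-abort bound (once
strong-so-far + remaining-pairs ≤ 19·recombination-so-far the candidate
cannot pass) skips work without ever changing the output, which the
toggle test verifies against a full-grid brute-force reference.

## Association and permutation

Contingency tables come from masked popcounts of per-variant
genotype-class bit vectors; a permutation is just a new case bit mask,
so the per-permutation cost is a few popcounts per variant. Statistics:
allelic 1-df chi-square, Cochran–Armitage trend (weights 0, 1, 2), or
the Fisher 2×2 exact p on allele counts (made affordable inside the
permutation loop by the early-termination test). Missing genotypes are
excluded per variant, so per-variant case counts vary — the reason each
variant keeps its own non-missing mask.

max(T): case labels are permuted among phenotyped samples with the case
count fixed, using one seeded 64-bit generator (numpy PCG64; the
permutation is a Fisher–Yates shuffle). Empirical p-values use
(k+1)/(R+1), never zero and unbiased under the null. For the Fisher
mode the per-permutation extremum is the minimum p-value (ranking by p;
ranking by a transformed statistic would be an alternative convention).
Corrected ≥ pointwise holds by construction. Results are reproducible
from (dataset, phenotype, R, seed) and independent of any threading.

## Synthetic data generator

The generator emulates exactly the structure the methods assume:
per-variant MAFs uniform on [maf_min, 0.5]; genotypes at
Hardy–Weinberg proportions p², 2pq, q², or with inbreeding F via het
frequency 2pq(1−F); LD blocks built by giving each sample two latent
haplotype draws Bernoulli(p) and copying them per site with probability
1−ε (else a fresh Bernoulli(p)), which keeps every site marginally at
HWE with pairwise genotype correlation (1−ε)², so ε = 1 − r²^(1/4)
meets a within-block r² target; case/control phenotypes from a logistic
model with per-allele log-odds-ratio effects on frequency-centred
dosages, with the intercept at logit(case_fraction); missingness applied
uniformly at random last. One seeded generator drives all draws in a
fixed documented order (MAFs, block haplotypes, remaining genotypes,
phenotype, missingness), so a spec + seed reproduces the fileset
byte-for-byte.

It does **not** emulate coalescent genealogies, recombination maps,
realistic allele-frequency spectra, population structure, relatedness,
or genotyping-error processes. Passing calibration tests on these
fixtures therefore demonstrates correctness of the algorithms under
their stated assumptions, not robustness to real-data pathologies such
as stratification or batch effects.

## Problem sizes and numerical conventions

Test and acceptance runs use deliberately modest sizes chosen to
exercise every code path with comfortable statistical resolution:
datasets up to ~200 samples × ~1000 variants for oracle-equivalence
checks, 10⁵–10⁶-scale margins for exact-test precision sweeps,
Monte-Carlo calibration with 60–80 replicates of 120–150 permutations,
and exhaustive table enumerations to totals of 6–8 plus large random
samples. Exact references use Python big integers / `fractions` (and a
40-digit `decimal` recurrence where factorials are impractical).
Agreement between an early-termination p-value and its reference is
measured in leading significant digits, floor(−log10(relative error)),
capped at 17 when bit-equal after rounding to double.

Degenerate inputs are contracts, not crashes: zero-margin tables give
p = 1; pairs with no overlapping calls, zero-variance variants and
monomorphic loci yield flagged (NaN) statistics or explicit errors as
documented per function; empty datasets and all-missing variants are
either representable (0-variant `.bed` files round-trip) or rejected
with a clear message.

## Known limitations

* Only hard-call, biallelic, unphased data; dosages, phase and
  multiallelics are representable neither in memory nor on disk.
* Exact tests stop at 2×3 tables; larger tables and asymptotic
  regression-based association are out of scope.
* The Gabriel block scan memoizes pair classifications within the span
  cap, so its memory is O(window²) rather than the O(window) of a fully
  streaming counter; outputs are identical, and the cap keeps windows
  small.
* p-values below ~1e−300 underflow to 0 inside the relative-likelihood
  walks (the observed table's relative likelihood leaves the double
  range).
* The CLI covers the analyses listed in the README; it is a thin layer
  and does not aim for byte-identical report formatting with other
  tools.
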