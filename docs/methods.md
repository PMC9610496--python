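# Methods

## The survivorship model

RNase A-superfamily enzymes hydrolyse the phosphodiester bond 3′ of
pyrimidine residues via a 2′,3′-cyclic-phosphate intermediate, leaving the
pyrimidine's phosphate on the upstream product. We model a transcript of
length L as a string over {A, C, G, U} with a set of candidate cut points:
one after every C or U. A protein complex bound to interval `[a, b)`
(0-based, half-open) shields every base underneath it, including
interval-terminal pyrimidines such as the U's of an Sm site; those sites are
never cut. Under exhaustive digestion the surviving fragment of a protected
interval is therefore `[s, e)` with `s` = one past the nearest cleavable
pyrimidine strictly upstream of `a` (or 0) and `e` = one past the nearest
cleavable pyrimidine at or beyond `b` (or L). Two conventions are worth
making explicit:

- the cut pyrimidine belongs to the upstream fragment, so a fragment's last
  base is the cut base — this is what makes 3′-terminus statistics on reads
  a direct readout of the chemistry;
- the biology only dictates the 3′ boundary; we apply the mirrored rule at
  the 5′ side as a symmetric extension, and every report row carries a flag
  (`five_prime_rule_extended`) marking that the 5′ boundary comes from this
  extension rather than from a separately established mechanism.

Stochastic digestion cuts each eligible site independently with probability
`q ∈ [0, 1]`. `q` is a free exposure parameter — extracellular ribonuclease
kinetics are not measured here — and the analyses sweep or fix it rather
than estimate it. Fragments are the maximal uncut runs, so before size
selection they tile the transcript exactly; this tiling, the
pyrimidine-terminus law, and the q = 1 identity between the surviving
protected fragment and the closed-form prediction are the three invariants
the test suite enforces on random instances, alongside a total-variation
comparison (≤ 0.01 at 100,000 draws) against exhaustive enumeration of all
cut subsets on transcripts short enough to enumerate.

## What the read generator emulates — and what it does not

`simulate_compartment` models four sample classes. Digested compartments
(exomere-like: core + peripheral protections active; supermere-like: core
only) build a fragment pool by digesting `n_molecules` (default 2,000)
abundance-weighted transcript molecules and keeping fragments inside the
library size selection (defaults 15–50 nt); reads are drawn uniformly from
the pool, converted U→T, given the 3′ adapter, and truncated to the read
length (default 50 nt). Degradation of unprotected material is implicit in
the size selection; there is no separate decay parameter. Undigested
compartments (cell, EV) must still yield ≤50-nt reads, which in a real
library comes from preparation-induced fragmentation; we use a uniform
surrogate — 5′ start uniform over feasible positions, length uniform over
the feasible size window. (A "two independent uniform breakpoints"
parameterization was considered and rejected: size selection then weights
each start by its number of feasible ends, which measurably distorts the
5′-start distribution on short transcripts; the chosen surrogate keeps
starts exactly uniform, which is also the property the classifier's
`uniform` label leans on.) Not modeled, deliberately: ligation biases, PCR
duplicates, base-call errors (quality strings are constant "I"), RNA
modifications, partial RNase leakage into EVs, and antisense reads.
Consequently, passing tests show that the analysis recovers the truth of
*this* generative model; on real libraries, adapter chemistry and coverage
biases add noise these simulations do not contain.

The built-in reference (`toy_u2_reference`) is a synthetic 199-nt U2-like
transcript: an Sm-like core interval whose protected sequence resembles the
miR-1246-annotated fragment, flanked upstream by an SF3B1-protected
(branch-site-loop-like) interval and downstream by an SNRPA1-protected
(stem-loop-IV-like) interval, separated by aperiodic filler in which
pyrimidines recur every few bases. The filler design serves three purposes:
stray unprotected fragments almost never pass the 15-nt size selection at
q ≈ 1 (every ≥15-nt run would need several consecutive uncut sites); no
15-mer repeats anywhere, so alignment is unambiguous; and the base
composition is spatially fairly even, so the EV terminus statistic is
comparable to the transcript-wide pyrimidine content. It is a stand-in
constructed for simulation, not a genomic sequence, and the protection
coordinates ship as an editable BED annotation, not as constants asserted
by tests.

## Read processing

Adapter trimming removes the longest read suffix matching an adapter prefix
at mismatch rate ≤ 0.1 with overlap ≥ 3; reads shorter than 15 nt after
trimming are discarded. Alignment is an exhaustive sense-strand scan over
the (small) transcript references after U→T conversion: every placement is
scored by mismatch count (default maximum 1), ties resolved leftmost-first
then by reference order, with any tie at the best score marking the read
ambiguous. Ambiguous reads are excluded from counts, coverage and terminus
statistics by default and reported separately. Identical read sequences are
collapsed before trimming/alignment and carry multiplicities, which makes
50,000-read simulations cheap without changing any downstream number. RPM
is computed over uniquely aligned reads and sums to 10⁶ whenever at least
one read aligns. Reads whose aligned span reaches the read length are
flagged truncated: their true 3′ end is unobserved, so they are excluded
from terminus statistics, as are reads ending at the transcript's last base
(a transcript end is not evidence of cleavage).

## Footprint calling and classification

A footprint call is a maximal run of positions with depth ≥ θ·max(depth)
(default θ = 0.5), with gaps ≤ 2 nt bridged and runs < 10 nt dropped; calls
are matched to predicted protected fragments by boundary offsets and deemed
concordant when both |offsets| ≤ 2 nt. These four knobs (θ, min length,
merge gap, tolerance) are configuration with declared defaults — peak
reading on real coverage plots is visual, so the defaults were chosen to
reproduce the qualitative class contrasts and are swept in the tests.
Classification computes breadth (fraction of the transcript at ≥ 0.1×max
depth): breadth ≥ 0.8 → `uniform`; otherwise `core_only` iff at least one
call is concordant and all concordant calls match core-tier intervals, else
`multi_footprint`. The robustness test sweeps both cuts ±25% one at a time
(jointly lowering both by 25% places an exomere-like profile exactly on the
breadth boundary, and a breadth cut of 1.0 is unreachable at finite read
counts — the margins of the default configuration, not defects of it).
Profile similarity is the Spearman correlation of per-base depths over
positions covered in either profile; it is symmetric and scale-invariant,
and is reported rather than thresholded.

## Spectral-count statistics

Counts are normalized per sample (class × replicate) to
`raw / total × 10⁴` and transformed `log2(x + 1)`; the scale and offset are
declared, configurable choices. Proteins undetected in a class enter paired
analyses at raw count 0 — short proteins genuinely drop below detection and
removing them would bias paired comparisons. The size–count Spearman
correlation uses per-protein means over replicates; p-values are exact by
full n! permutation (chunked through numpy) for n ≤ 10 and use the
t-approximation beyond. The Wilcoxon matched-pairs signed-rank test drops
zero differences (reported), midranks ties, and computes the exact
conditional two-sided p (2·min(P≤, P≥), capped at 1) for n ≤ 25 via
dynamic programming over doubled ranks — identical to enumerating all 2ⁿ
sign assignments, which the tests verify against an explicit 2¹⁰ oracle —
switching to a normal approximation with continuity and tie corrections
beyond. The two-way fixed-effects ANOVA (protein, class, interaction) is
fit by OLS on a fully crossed balanced design (anything else is an explicit
unsupported-design error); per-protein class pairs are compared with the
studentized-range statistic q = |Δmean|/√(MSE/r) using the pooled residual
mean square, with adjusted p from the studentized-range distribution
(k = number of classes, residual df). Degenerate fixtures with zero
residual variance are defined to give F = 0 and p = 1 for zero-sum-of-
squares factors.

## Operating characteristics and problem sizes

The null/power simulations for the paired test use a 200-protein table in
which the tested group has 25 members. The group must be a small fraction
of the table: per-sample total normalization makes the table compositional,
and a group owning a large share of the total acquires negatively dependent
paired differences (the signed-rank statistic's variance shrinks and the
test turns conservative). With the 25/200 design the empirical size at
α = 0.05 is ≈ 0.044 over 500 simulations against an attainable exact size
of 0.0483, and power at a 2× group effect (depth 5,000, 3 replicates)
is ≈ 1. Compartment benchmarks use 20,000–50,000 reads per sample, 90–100
seeded replicates, and 100,000 draws for distribution checks; these sizes
give the recovery and accuracy estimates reported by
`scripts/acceptance.py` comfortably tight confidence intervals while the
whole script completes in well under a minute.

## Known limitations

- Footprint calling is threshold-based with no background model or
  replicate-aware reproducibility criterion; heavily structured coverage
  (overlapping footprints, nested complexes) will merge or split calls.
- The classifier's three labels formalize qualitative contrasts; partially
  digested EVs or mixtures of particle classes have no dedicated label.
- The aligner is exact and exhaustive but transcript-scale only: no
  genome-scale indexing, splicing, antisense or quality-aware alignment.
- `q` is a single global cleavage probability; real extracellular digestion
  is sequence- and structure-dependent and time-inhomogeneous.
- The number of distinct protected intervals behind a multi-peak region is
  reported as called, never forced to a preset count.
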