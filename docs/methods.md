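# Methods

This note records the exact procedure `mmejsig` implements, the
parameter values it fixes, what the simulator does and does not emulate,
and the numerical and design choices that are not forced by the model.

## Input processing

**Variant reading.** Indels are read from VCF with pysam. Multi-allelic
records are split per ALT; SNVs, MNVs, symbolic alleles
(`<DEL>`-style, breakends) and complex substitutions that do not reduce
to a pure insertion or deletion after allele trimming are skipped with a
logged count. Records with QUAL below `qual_min` (default **40**) are
removed. Records with *missing* QUAL are also removed: a missing score
cannot demonstrate that the call meets the threshold, so the
conservative choice is exclusion.

**Normalization.** Every indel is reduced to anchor-base-minimal form
(shared suffix then prefix trimmed) and left-aligned: while the
reference base before the anchor equals the last base of the inserted or
deleted sequence, the event shifts left. Two call sets then agree on an
event if and only if their normalized `(contig, pos, ref, alt)` keys are
equal. A record whose REF disagrees with the reference genome raises an
error (dropped with a warning during batch normalization).

**Exclusion and artifact removal.** Known variants are removed by exact
normalized key (an optional position-only mode exists for panels with
inconsistent representations; exact matching is the default because
left-alignment already canonicalizes representation). Calls whose key
appears in two or more *unrelated* subjects — in any sample of each —
are treated as systematic artifacts and removed from every set.

**Partition.** For each subject, the derived (LCL) set is split into
**pre-existing** calls (key also present in the ancestral B-cell set)
and **new** calls (LCL-only). Ancestral-only calls are discarded. By
construction |pre| + |new| = |LCL|.

## Deletion microhomology

For a normalized deletion of sequence *d* at position *p* (anchor at
*p*), the 3' flank starts at reference coordinate *p* + |*d*| + 1. The
microhomology length is the longest common prefix of *d* and that flank,
compared base-by-base; `N` matches nothing, including another `N`. The
scan is capped at **20 bp** and, near a contig end, by the available
flank. Only the 3' (downstream) flank is scored: for a left-aligned
deletion, annealing of a direct repeat always leaves the retained copy
starting at the breakpoint's 3' side, so the 5' comparison is redundant
on normalized calls (an optional upstream scan exists for diagnostics).

Deletions are stratified into **small (2–29 bp)** and **long
(30–500 bp)**; 1 bp deletions carry no usable repeat signal and
>500 bp calls are dominated by other mechanisms and caller artifacts.
For each threshold **T = 2..20** a row counts, among deletions of length
≥ T (shorter events cannot physically carry T matching bases), how many
have microhomology ≥ T, separately for the pre-existing and new sets.
These counts are monotone non-increasing in T; the long-class totals are
constant for T ≤ 20 < 30. Rows are compared with the proportion test
below.

## Insertion signatures

**Templated small insertions (1–3 bp).** Using ±**15 nt** of reference
context around the insertion point, the junction word is built from
*k* ≥ **2** bases of one flank, the inserted bases, and *m* ≥ **2**
bases of the other flank. The insertion is "templated" if the word
occurs elsewhere in the 30 nt context with at least **1 nt** between the
template copy's footprint and the insertion-adjacent copy (so the two
are distinct). Words containing `N` never match. The search is
performed on the plus strand only — a same-strand slippage template; the
reverse-strand case is a different mechanism and is out of scope. When
several (k, m) pairs match, the call reports the largest k + m,
preferring upstream templates and then the smallest gap.

**Snapback large insertions.** Insertions of at least
2×7 + 4 = **18 nt** are scanned for a substring of ≥ **7 nt** whose
reverse complement also occurs in the insertion with footprints
separated by ≥ **4 nt** (room for a fold-back loop). Shorter insertions
are *ineligible*, not negative, and are reported as unclassified
(lengths 4–17 bp). The scan prefers the longest repeat, then the
leftmost first copy.

## Statistics

Signature rates in the pre-existing versus new sets are compared with
the two-proportion chi-squared test **with Yates continuity
correction** — the default of R's `prop.test` and the conservative
choice for count data:

X² = N·(max(0, |ad − bc| − N/2))² / (r₁·r₂·c₁·c₂),  p = P(χ²₁ ≥ X²).

The p-value is computed via `scipy.stats.chi2.sf`, which retains full
precision in the far tail (p ≈ 5.6e-50 for the largest tables; a
1 − CDF formulation would underflow to 0 at p < 1e-16). If any marginal
is zero the test is undefined and reported as `NA`. Displayed values
follow: `NA` for undefined, `NS` for p ≥ 0.05 (`ns_alpha`), scientific
notation with three significant digits for p < 0.001, three decimals
otherwise; the raw p accompanies every table row.

## Simulator

The simulator exists to give the pipeline inputs with exact ground
truth. Its defaults emulate the study conditions at desk scale: two
subjects, paired call sets sharing a pre-existing subset, small-deletion
microhomology fractions 0.77 (pre) vs 0.84 (new), long deletions in
similar proportion, equal templated-small-insertion fractions, a
snapback fraction enriched in the new set, ancestral-only noise calls,
and a handful of cross-subject shared artifacts.

Construction guarantees, not sampling, make truth labels exact:

- events occupy a fixed slot grid (110 bp slots for small events,
  580 bp for long ones, 50 bp contig-end margins), so footprints never
  collide and flank extraction is never truncated;
- the base preceding each event is forced to differ from the event's
  last base, so every planted record is its own left-aligned normal
  form and pipeline normalization is the identity;
- a microhomology deletion's 3' flank is overwritten so the common
  prefix is *exactly* the designated length (drawn from a geometric-
  decay distribution over 2..20 by default), with a forced mismatch at
  the next base; "plain" deletions force a first-base mismatch
  (an optional `plain_mh_policy="random"` leaves flanks untouched to
  measure incidental background matching, which decays with T and is
  < 1% at T = 8);
- templated insertions write a real template copy into the upstream
  context at a gap that keeps the whole word inside the ±15 nt window;
  plain insertions and non-snapback large insertions are
  rejection-resampled until the corresponding classifier calls them
  negative.

All randomness flows from a single seeded `numpy` generator, so output
bundles (FASTA + VCFs + JSON truth manifests) are byte-identical across
runs with the same configuration.

**Scope limits.** The reference is i.i.d. with a GC knob (default 0.41)
— no repeat families, no chromatin or replication-timing structure, no
polymorphism spectrum. There is no read-level or caller-error model;
QUAL is a constant. Event positions are uniform over slots, not
hotspot-clustered. The simulator validates signal recovery and set
algebra; it does not predict real-genome background rates.

## Numerical and testing choices

- Exact-rational (`fractions.Fraction`) recomputation of the
  chi-squared statistic backs the test suite, with the identity
  `chi2.sf(x, 1) = erfc(sqrt(x/2))` as an independent tail check, and
  `scipy.stats.chi2_contingency(correction=True)` as a third opinion.
- Every sequence classifier is tested against an exhaustive brute-force
  enumeration (all prefix lengths; all (k, m, position) triples; all
  (i, j, L) triples) on hundreds of random instances.
- Test problem sizes (n = 2,000 per set for the power check; 100
  replicates of n = 500 per set for the null-calibration check) are
  this package's own choices, sized so binomial 3σ bounds and the
  p < 1e-10 power margin are comfortably decided in seconds.
- Fractions in reports are rounded to 2 decimals for display; raw
  counts and raw p-values are always emitted alongside, so no
  downstream computation depends on rounded values.
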