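# Methods

This note documents the models, parameter choices and numerical conventions
behind `mirfish`, and what the synthetic-data tests do and do not establish
about real libraries.

## Read cleaning

The pipeline assumes 58-cycle single-end reads from a strand-specific
small-RNA library, so every genuine insert (≤ ~30 nt) is followed by the 3′
adapter within the read. Cleaning applies five rules in a fixed order, and
tallies each rejected read under the first rule it fails:

| rule | default | rationale |
|---|---|---|
| mean Phred quality | ≥ 20 | removes whole-read base-calling failures |
| ambiguous bases | ≤ 0 N | N cannot be matched or collapsed reliably |
| 3′ adapter present | required | an insert with no detectable adapter is longer than any small RNA |
| post-trim length | ≥ 15 nt | shorter fragments cannot be annotated confidently |
| homopolymer fraction | ≤ 0.8 | removes poly-A/poly-T artefacts |

Adapter matching: the earliest read position carrying an exact 12-nt
adapter seed, verified over the full read/adapter overlap at ≤ 1 mismatch
per 10 nt (floor). When no seed occurs anywhere, an exhaustive tolerant
scan runs instead. Requiring a short exact seed is standard trimmer
practice; a position that satisfies the mismatch tolerance without any
exact 12-mer arises with probability ~1e-9 per read, and the seed makes
trimming O(1) per read rather than O(read × adapter).

Reads are compared T-normalized (U→T) throughout, so sequenced cDNA matches
RNA-alphabet reference entries; sequences are stored as given.

## Screening and RPM

Unique tags are the collapse of cleaned reads by exact T-normalized
sequence. Abundance is reads per million *filtered* reads:
rpm = count/total_usable × 10⁶, so Σ rpm = 10⁶ per library by construction.
Candidates must have 20 ≤ length ≤ 23 and rpm ≥ 6, both bounds inclusive;
the screen is idempotent. Strand specificity is modelled as a pipeline
guarantee (sense-orientation reads only), not a per-tag test.

The length profile is summarised by the modal band: the 3-nt window of
maximal read mass. Ties prefer the window centred on the modal length,
then the leftmost window, so summaries are deterministic.

## Homology annotation

The aligner is a seeded ungapped local alignment. Every shared 7-mer
between tag and reference defines a diagonal; each run of ≥ 7 consecutive
matches is extended in both directions to the maximal-scoring segment
under match +1 / mismatch −3, with score ties resolved toward the longer
segment (more matched positions — the variant a practitioner expects when
a terminal mismatch is score-neutral). Gap-free alignment is sufficient
here: queries are 20–23 nt and acceptance caps mismatches at 3, so a
gapped alignment could never pass. For +1/−3 the published ungapped
Karlin–Altschul parameters are λ = 1.374, K = 0.711, giving

    E = K · m · n · exp(−λ·S)

with m the query length and n the total reference letters (database-wide
expectation). Acceptance requires ≥ 15 matches, ≤ 3 mismatches and
E < 0.06 (strict); no multiple-testing correction is applied beyond the
fixed E cut. "Highest homology" is interpreted as the highest alignment
score, ties broken by fewer mismatches, then more matches, then the
lexicographically smallest reference id — all deterministic.

Per reference *name* (species prefixes stripped; arm-suffixed names are
distinct), the candidate ordering is (count desc, score desc, sequence);
the first is the canonical candidate and every tag in the group is kept as
a supporting variant. Abundance is compared in raw counts; within one
library this ordering is identical under RPM. Names normalizing to the
same family-plus-arm label (strip arm, then a trailing gene-copy number,
then paralog letters: miR-138-1-3p → miR-138-3p; let-7a → let-7) share a
paralog group. Family derivation is purely lexical; curated family
definitions are out of scope.

## Enrichment, Venn and conservation

Presence of a type in a library means: annotated there with rpm > 0
(detection is therefore thresholded by the upstream rpm ≥ 6 screen). A
type present in all six libraries is common-to-all; present in exactly one
tissue (either sex, ovary and testis forming the gonad class) and absent
from the other two tissues is tissue-enriched; anything else is "other" —
the categories partition the matrix rows. Tissue-enriched types are
partitioned by sex of the carrying libraries. Venn regions per sex are
computed by direct set algebra, so inclusion–exclusion holds exactly.

Conservation: a species belongs to a type's set when any reference record
of that species under the same name is hit by the type's canonical tag
under the annotation criteria. A non-empty set within
{dre, fru, tni, ola} is teleost-specific; a set containing all of
{hsa, mmu, dre, fru, tni, ola, cel, dme} is flagged pan-model.

Percentages are rendered at one decimal with a trailing ".0" dropped
("24.7", "4"), the convention of the tables this accounting mirrors.

## qPCR statistics

ΔCt normalizes the target to the arithmetic mean of the U6 and 5S
reference Cts — equivalent to geometric-mean normalization in expression
space, the standard multi-reference practice. Technical triplicates are
averaged to one Ct per biological sample before statistics. Fold change is
2^−ΔΔCt. Group comparison uses the Wilcoxon–Mann–Whitney U (pairwise wins,
0.5 for ties) with a two-sided p-value

    p = P( |U − n₁n₂/2| ≥ |u_obs − n₁n₂/2| )

computed exactly for n₁+n₂ ≤ 25 by a subset-sum dynamic program over
doubled midranks (tie credit falls out automatically; counts stay exact in
int64), and by the tie-corrected normal approximation with continuity
correction beyond that. Degenerate input (all observations identical)
returns p = 1. The exact test's true size at n = 10/10 and α = 0.05 is
0.0433. No correction is applied across targets; each comparison is
reported per gene.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
reduced scale (2×10⁵ raw reads per library; the sequencing study it
mirrors used ~2×10⁷, and scale is a config knob):

* **Reference** — 60 types (55 planted, 5 decoys) across up to 8 species.
  Unrelated sequence cores are rejection-sampled to share no 7-mer, so the
  truth table is unambiguous; declared paralogs reuse a parent core with 2
  substitutions; each ortholog record is the core with ≤ 2 substitutions,
  redrawn until it remains a detectable homolog under the acceptance
  criteria (real conserved orthologs conserve the seed region; an
  "ortholog" the criteria cannot detect would be a contradiction in the
  planted truth). Real references are messier in both respects.
* **Libraries** — planted abundances are log-uniform on 6–30,000 RPM (the
  observed dynamic range of deep small-RNA studies), floored at the
  screening boundary so every planted type passes rpm ≥ 6 in the noiseless
  limit. isomiR end shifts (±1–2 nt, rate 0.2) and per-base substitutions
  (rate 0.01) model variant noise. Gonad libraries receive a 26–28-nt
  random background of half the usable reads (piRNA length band only — no
  piRNA biology), which reproduces the gonadal 26–28-nt length mode and
  the inflated gonadal unique-tag counts; brain/liver modes fall at
  21–23 nt from the planted length mix. All libraries carry a degradation
  background of random 15–30-nt fragments drawn from a reused pool (so
  some recur above the screen and stay unannotated, as in real data);
  pool members are rejection-sampled to share no 7-mer with the reference,
  making them known failing decoys. Contamination: 5% adapter dimers, 1%
  low-quality reads, 0.5% homopolymer reads. Quality strings are uniform
  high (Q40) apart from the planted low-quality reads — no realistic
  error-rate profile is modelled.
* **qPCR** — per (target, tissue, sex): control ΔCt ~ N(base, σ²), treated
  ΔCt ~ N(base + ΔΔCt, σ²) with σ = 0.3, n = 10 per group, technical
  triplicates with 0.05-cycle jitter. The default effect map includes a
  −1 ΔΔCt (two-fold) testis induction and null effects as negative
  controls.

Everything derives from one integer seed (numpy `SeedSequence` spawning),
and outputs are byte-identical across runs.

What passing synthetic tests shows: the pipeline's bookkeeping,
thresholds, selection rules and statistics are implemented correctly and
recover a planted truth exactly (noiseless) or within the designed noise
margin. What it does not show: performance on real libraries, where
references are not seed-disjoint, isomiR structure is richer, error
profiles are position-dependent, and true novel miRNAs exist that homology
cannot find.

## Problem sizes and tolerances

The test suite runs the full pipeline at the default 2×10⁵ reads/library
scale twice (noiseless, noisy) and at 1–2×10⁴ for unit-level fixtures.
Aligner-oracle equivalence is checked on 1,000 random pairs of lengths
15–35; exact-test calibration on 10,000 null simulations at n = 10/10.
RPM conservation is asserted at 10⁻⁹ relative tolerance; set accounting,
Venn identities and count recoveries are exact.

## Known limitations

* No gapped alignment, precursor/hairpin prediction or novel-miRNA
  discovery — impossible without a genome by design.
* E-values use the package's own defined statistics; they are a documented
  stand-in for the original external aligner's internals and are not
  bit-comparable with it.
* Family assignment is lexical, not curated.
* The qPCR module assumes equal amplification efficiency (no standard
  curves) and analyses pooled-sample designs as given.
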