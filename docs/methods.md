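# Methods

te-prospector re-implements, at desk scale, a combined structure- and
homology-based strategy for de novo transposable-element (TE) discovery,
family clustering, insertion dating and genome annotation.  This note
documents the models, the parameters that matter, the synthetic study
conditions, and the numerical choices behind each stage.

## Coordinate and sequence conventions

All coordinates are 0-based half-open internally; GFF3 and the `.out`-style
TSV are converted to 1-based inclusive at serialization only.  Genomes are
uppercase `ACGTN` strings; ambiguity codes collapse to `N` on ingest and `N`
never seeds or extends a match in any detector.  Minus-strand loci are
stored on forward coordinates with a strand flag.  Soft masking lives on a
parallel mask track and is lowercased only in written FASTA, so the
in-memory alphabet contract is never broken.

All pairwise alignment (family clustering, homology filtering, library
masking) goes through one affine-gap core (`Bio.Align.PairwiseAligner`) with
the pinned scheme match +2 / mismatch −3 / gap open −5 / gap extend −2, so
every score cutoff in the toolkit has a single meaning.  Identity is
matches over aligned columns with end-gap columns excluded in global mode.
Biopython's first traceback is deterministic; where several co-optimal
alignments exist (essentially only for unrelated short pairs) the identity
of `align(a, b)` and `align(b, a)` may differ even though the score never
does — for homologous pairs the value is symmetric in practice, and the
clustering predicate is always evaluated with a fixed argument order.

## Structural LTR retrotransposon discovery

A full-length LTR-RT is modeled as 5′LTR + internal region + 3′LTR with an
exact target-site duplication (TSD) flanking the whole element.  Discovery
is seed-and-extend:

* exact 20-mer matches at the same spacing (diagonal) within
  [1 kb, 25.5 kb] are chained; chains split at seed gaps > 500 bp so one
  diagonal cannot bridge two repeat arms;
* arms are extended ungapped with an X-drop of 20 (match +1, mismatch −2).
  A small X-drop dies inside diverged arms and truncates their ends, which
  would condition the retained arm pair on local conservation and bias the
  divergence — and hence the age — estimate downward.  The final arm
  intervals are therefore re-derived from the TSD-pinned element bounds and
  the seed diagonal rather than from the X-drop end points;
* the TSD search looks for an exact 4–6 bp direct repeat within 10 bp of
  both provisional element ends (inward or outward), longest length first,
  then the placement closest to the detected bounds, and pins the element
  boundaries onto the duplication.  This is what gives ≤ 10 bp boundary
  accuracy on planted elements;
* the arm pair must reach 85 % global identity, the published default of
  the tool family the paper's pipeline builds on, with arm length in
  [100, 3500] bp.

Overlapping candidates are resolved by higher LTR identity, then longer
element — after first removing any candidate that fully contains another
candidate.  The containment rule suppresses chimeras: two nearby copies of
one family present four homologous repeat arms, and a pair bridging the two
copies always swallows at least one genuine candidate.  Bridging pairs that
contain no full candidate lose the identity comparison to the less-diverged
of the two copies they straddle.  Dense same-family neighborhoods can still
occasionally cost a planted element (observed ~1–2 of 20 in adversarial
packings); the recall criterion (≥ 90 %) holds with margin.

Internal ORFs are stop-to-stop (no start-codon requirement, the convention
of the classic ORF extractor), ≥ 100 aa, all six frames; codons containing
`N` translate to `X` and break ORFs.  Translated ORFs are scored against
position-weight matrices (below); hits at or above each profile's threshold
are recorded as domain annotations.  Candidates are then screened against a
labeled repeat library by local alignment on both strands: best score below
`min_hit_score` (default 100 under the pinned scheme) discards the
candidate as a structural false positive — this is also what removes
direct-repeat pairs formed by two identical copies of a MITE or Helitron
family, which are structurally indistinguishable from an LTR pair.
Survivors take the superfamily of the best hit (ties: longer alignment,
then lexicographic library id).

## Non-LTR detection

The genome is first hard-masked over the retained LTR loci.  Stop-to-stop
ORFs of ≥ 500 bp (sized to contain an APE endonuclease gene) are extracted
on both strands and their translations scored against per-clade reverse
transcriptase (RT) profiles; the RT hit is mandatory, the APE hit
corroborating (the R2 and CRE clades encode RT alone).  Profiles are
log-odds PWMs over the 20 amino acids against a uniform 1/20 background —
a deliberate, transparent simplification of profile HMMs; full
match/insert/delete Viterbi scoring is out of scope.  The bundled toy
profiles are built from fixed 12-residue marker motifs (consensus
probability 0.7, threshold 0.55 × maximum attainable score, reachable with
up to ~3 substitutions); real PWMs derived from curated alignments can be
supplied in the same TSV format.  Clade = highest-scoring passing profile;
exact ties resolve to the lexicographically first clade and are flagged
ambiguous.  Elements are single-ORF; ORF1+ORF2 joining is not attempted.

## Class II detection

**MITEs.**  Every 9-mer whose reverse complement occurs downstream within
800 bp seeds a terminal-inverted-repeat (TIR) pair; arms grow inward while
the mismatch fraction stays ≤ 0.2, keeping the extension that maximizes
the confidence score; candidates need element length in [50, 800] bp
(50–650 flagged canonical), an exact TSD of 2, 3, 8 or 10 bp immediately
flanking, and confidence = TIR identity × min(1, TIR length / 15) ≥ 0.5.
The confidence formula is pinned in config and tests; the threshold (0.5)
and the TSD lengths are published values, the formula itself is this
package's definition.  Known limitation: with a 9 bp seed, 2 bp exact TSDs
and the 0.5 threshold, i.i.d. background yields chance emissions at a
measured ~0.1–0.2 per kb.  Those emissions are separable — background
confidences stay below ~0.9 while well-formed planted MITEs score 1.0 —
and the tests pin that separation rather than an unattainable zero-emission
claim.  Families are connected components under the 80-80-80 relation; the
representative is the best library scorer, or the longest member without a
library.

**Helitrons.**  Termini are scored additively: 5′ = 4·[TC at start] +
2·[A at −1]; 3′ = 3·[CTRR at end] + 1·[T at +1] + 4·[hairpin upstream];
a terminus is reported at score ≥ 6 (so a 5′ hit needs both features, a 3′
hit needs at least CTRR + hairpin).  Two defaults are this package's own
calibration, recorded here because the bare feature vocabulary is
information-poor (~6 bits at the 5′ end — an `A|TC` occurs every ~64 bp of
random sequence): the hairpin stem minimum is 10 bp (stem ≥ 6 would put a
chance 3′ signature every ~800 bp and corrupt end pairing), and 5′/3′
pairing is anchored on a 12 bp 5′-terminal consensus motif (≥ 10/12
matches, user-overridable), standing in for the trained family heads the
original scanner learns from curated Helitrons.  Each anchored 5′ hit takes
the highest-scoring, then nearest, downstream 3′ hit at distance 0.5–15 kb;
overlaps resolve best joint score, then shorter.  Elements are clustered by
greedy centroid assignment (longest first) at 80 % identity.

## Families, divergence, gene conversion, ages

**80-80-80 rule.**  Two copies are related when a local alignment reaches
≥ 80 % identity over ≥ 80 % of the shorter sequence with ≥ 80 aligned bp
("of the element length" is resolved as the shorter member, and families
are single-linkage connected components, as "clustered" implies).  The
partition is verified against a brute-force transitive-closure oracle on
random instances.

**HKY85 distance.**  For an aligned pair (gap/N columns dropped), base
frequencies are the pooled empirical frequencies and (d, κ) maximize the
two-sequence likelihood Σ n_xy log(π_x P_xy(d, κ)), with P = exp(Qd) for
the rate-normalized HKY85 matrix.  Optimization is L-BFGS-B over
d ∈ [1e-8, 5], κ ∈ [0.05, 100] from two κ starts; identical pairs return
d = 0 exactly; estimates pinned at the upper d bound are flagged saturated
and excluded from age histograms.  Numerical ML was chosen over a
method-of-moments formula because HKY85 lacks a simple closed form; in the
equal-frequency κ→1 limit the estimate reproduces the Jukes–Cantor closed
form −(3/4)·ln(1 − (4/3)p) to < 0.005, which the tests pin.

**Gene conversion.**  Within a family (≥ 3 members, so an outgroup context
exists), each element's aligned LTR pair is scanned over informative
columns — pair-mismatch columns, or pair-match columns where a context
member differs.  Matches score +1 and mismatches −(1/f − 1) with f the
overall mismatch fraction, making the expected segment score zero under
uniform divergence; all maximal-scoring segments (Ruzzo–Tompa) are
candidate tracts; significance is a seeded permutation test on column order
(default 10 000 permutations, α = 0.05), and tracts with fewer than three
supporting informative sites are rejected ("fewer than three total
differences" is interpreted as informative support — an interpretation,
not a published fact).  The null false-positive rate is calibrated to
≤ 1.5 α on simulated uniform pairs.

**Corrected divergence.**  Assuming non-tract regions diverge at the
element's true rate, the distance re-estimated on columns outside the
accepted tract union applies to the whole element (linear scaling).  With
no tracts the corrected value equals the raw one; tracts covering > 90 % of
columns trigger a flagged fallback.  Following the source convention that
corrected distributions "remain very similar", default age reporting (the
histogram, the dating benchmark) uses the unaltered divergence, with the
corrected value always emitted alongside; a false tract (α-level event)
re-estimates d from few columns and can produce a wild corrected value,
which is another reason the default report is the raw estimate.

**Ages.**  T = d / (2r) with r = μ_gen / g, μ_gen = 2.5×10⁻⁸ per
generation, g = 5 years, so r = 5×10⁻⁹/year and d = 0.01 ⇔ 1.0 My.  The
constants are immutable defaults, overridable per call.

**Length statistics.**  Kruskal–Wallis (tie-corrected, scipy) across
groups plus pairwise Welch t tests, two-sided, no multiplicity adjustment
— mirroring the source's species-by-species comparison layout.

## Library assembly and annotation

Detected exemplars (retained LTR elements, non-LTR ORFs, MITE family
representatives, Helitron cluster representatives) are merged with the
external labeled library; exact byte-identical duplicates are removed,
first occurrence kept, reverse complements deliberately not considered
duplicates.  Annotation is seeded local alignment: shared 11-mers (seeds
with Shannon entropy < 1 bit/base are excluded, mirroring low-complexity
exclusion) nominate windows where the implied entry start positions of at
least 3 seeds agree within 200 bp — even a minimal hit at the score floor
carries ~10 seeds, while random 11-mer hits are isolated; each window is
refined by local affine alignment and kept at Smith–Waterman score ≥ 225.
Three further window rules keep the annotation pass near-linear in
practice without changing its output on planted genomes: entries are
processed longest first and seeds falling inside an already-accepted hit
are dropped (a locus is not re-aligned against every near-identical
library relative); within an entry the most-seeded window is aligned
first, so the direct placement of a repeat suppresses its diagonal echoes
(an LTR entry otherwise re-aligns each family copy once per repeat-arm
offset); and a window whose seeds span < 40 bp is discarded, since a hit
at the score floor must extend ≥ ~113 bp and a short shared motif (such
as a conserved domain marker) cannot support one.  Retained hits score
≥ 225
under the pinned scheme (the cutoff's published meaning is preserved as
"minimum local score", not a bit-exact reproduction of another engine's
matrices).  Overlaps resolve best score, then longer, then library id;
the genome is returned hard-masked over retained hits.  The published
rescue stage that runs de novo family induction on the unmasked remainder
is reduced to a re-annotation hook with a user-supplied auxiliary library;
repeat-family induction from scratch is out of scope.

## The synthetic study conditions

The generator is the package's test instrument, not a realism claim.
Background is i.i.d. (GC 0.41, the mammalian-like default), so false
positives in tests are attributable to the detectors.  Plants:

* **LTR-RT** (default): 400 bp LTRs, 2 kb internal with a conserved
  ≥ 100-codon ORF carrying the RT marker, 5 bp TSD, κ = 4,
  π = (0.295, 0.205, 0.205, 0.295); both LTRs evolve d/2 from one ancestral
  LTR so their expected pairwise divergence is d, matching the dating
  model's insertion-time assumption.  Family copies share an ancestor; the
  non-coding internal sequence drifts with each copy (d/2) while the ORF is
  conserved, emulating purifying selection and preventing family copies
  from being artifactually identical outside their LTRs.
* **MITE**: 15 bp perfect TIRs, 180 bp total, TSD ∈ {2, 3, 8, 10} (default
  3); **Helitron**: 2.5 kb, bundled 12 bp 5′ head, stem-12/loop-5 hairpin
  10 bp upstream of CTRR, A/T host flanks; **LINE**: single ~850 aa-capable
  ORF carrying a clade RT marker plus the APE marker, 1.6 kb element.
* The standard fixture is 100 kb with 10 LTR-RTs (d = 0.01…0.10, two
  families), 10 MITEs (two families), 5 Helitrons, 5 LINE surrogates.
* The dating benchmark plants 20 LTR-RTs with d cycling 0.01…0.10 and
  1.2 kb LTRs: the sampling noise of d̂ scales as √(d/L), so the stated
  regression quality (slope in [0.85, 1.15], R² ≥ 0.9) is a property of
  full-length LTRs; 400 bp repeats are information-limited to R² ≈ 0.85
  regardless of estimator.

What the generator does **not** emulate — and hence what passing tests do
not establish about real genomes: nested and fragmented insertions, indels
(substitutions only), solo LTRs, 5′-truncated LINEs, segmental duplication,
compositional heterogeneity, and real superfamily sequence diversity
(classification runs against the generator's own labeled exemplars, a
stand-in for curated libraries).  Problem sizes throughout (50–180 kb
genomes, tens of elements, hundreds of null pairs, ≤ 10⁴ permutations)
were chosen to keep each analysis step in the seconds-to-minutes range at
desk scale.

## Determinism

Every stochastic step takes a seed: the generator, the permutation null,
the pipeline (one config seed feeds all stages).  Pipeline outputs carry no
timestamps; two runs with identical config and seed are byte-identical,
which the tests assert on the summary and age tables.
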