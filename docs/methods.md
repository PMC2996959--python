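# Methods

This note documents the models, parameter choices and numerical conventions
behind srnakit, and what the synthetic-data generator does and does not
emulate.

## Read preprocessing and annotation

Raw reads are collapsed to unique sequences with redundant counts; collapsed
output is sorted by count (descending) then sequence, so files are
reproducible. The size window is inclusive on both bounds and defaults to
18–30 nt, the span over which plant small-RNA libraries are analyzed.

Annotation partitions reads into ncRNA classes by **exact, ungapped,
full-read substring containment** in per-class reference sets, querying both
the reference strand and its reverse complement (reference strand of
Rfam-style collections is not guaranteed). This is the strictest
reproducible reading of database-comparison filtering; it deliberately
avoids alignment parameters. Classes are tried in a configurable priority
order (default rRNA > tRNA > snRNA > snoRNA > exon > intron > repeat), so a
read matching several references gets exactly one label and the partition
property (class sums equal library totals) holds by construction. PolyA
artifacts are removed first; a read is an artifact when ≥ 90 % of it is A or
its 3' end is a run of ≥ 10 A. Both thresholds are configurable — no
standard values exist, and these are conservative enough that genuine
21-mers are essentially never caught.

## Conserved miRNA identification

A read is a conserved miRNA only when **identical, full length**, to a known
mature sequence. An opt-in allowance (`allow_3p_trim`, default 0) admits
reads shorter by up to N nt at the 3' end, because sequenced libraries
commonly contain 3'-trimmed isoforms; it is off by default to keep the
strict reading. Families are the numeric miR token of the name
(ath-miR156a → miR156); related families such as miR165/miR166 are never
merged. Family abundance profiles report distinct matched sequences,
summed redundant counts and each family's fraction of all conserved reads.

## Folding model

The folder is an energy-scored Nussinov dynamic program:

    E(i,j) = min( E(i+1,j),  min_k  e(i,k) + E(i+1,k−1) + E(k+1,j) )

with per-pair energies e (defaults G:C −3.0, A:U −2.0, G:U −1.0 kcal/mol)
and a minimum hairpin loop of 3 unpaired nt (steric standard). The fill is
vectorized per antidiagonal; the traceback is canonical and deterministic —
at (i, j) pairing i is preferred over leaving it unpaired, trying the
nearest partner first — so identical inputs give bit-identical structures on
any platform. Optimal-energy ties are resolved by that order with a 1e-6
energy tolerance (energies are small sums of table entries, so this is
safe). Sequences up to 1,000 nt are accepted.

This model maximizes a stacked-pair score rather than evaluating a
nearest-neighbor thermodynamic ensemble. Its |MFE| magnitudes are therefore
larger than thermodynamic ones, and every downstream threshold that touches
energy (notably the MFEI cutoff) is calibrated to the built-in model. An
adapter for an external `RNAfold` binary is provided; plugging it in makes
MFE magnitudes comparable to published values, but the MFEI threshold must
then be raised to the conventional ~0.85.

Hairpin indices: AMFE = |MFE|/L × 100; MFEI = AMFE / GC% with GC expressed
as a percentage; MFEI is undefined (None) for sequences with no G or C.

## Novel-candidate screening

Un-annotated, non-conserved reads of 18–25 nt are mapped by exact substring
search (both orientations) onto the transcript set, and a deterministic
ladder of windows — flank lengths {20, 40, …, 250} independently on each
side, clipped and deduplicated — is folded around each locus.

A maximum-pairing folder pairs aggressively, so a raw window around a
genuine precursor almost always carries incidental stems in its random
flanks. The screen therefore **excises the precursor structurally** before
applying criteria: starting from the terminal loop served by the mature's
stem, the stem is extended outward through single-branch parents; the
enclosed region is the candidate precursor. The single-hairpin requirement,
precursor length (LP), A+U% and MFEI all apply to that excised stem-loop
unit — which is also what published precursor lengths describe, as opposed
to the arbitrary window size.

Acceptance requires all of: single stem-loop; mature wholly on one arm (not
overlapping the terminal loop); ≤ 6 unpaired mature positions; ≤ 6 unpaired
positions in the star region (its two 3'-overhang positions excepted);
LP ∈ [50, 300]; A+U% ∈ [20, 80]; MFEI ≥ 0.5 under the built-in model. The
A+U window is deliberately wide because genuine candidates span roughly
47–71 %. Every rejection carries a machine-readable reason. Among a locus's
windows the accepted window with the highest MFEI wins.

The star region is computed from the dominant pairing register: in an
antiparallel duplex i + partner(i) is a constant C, so the modal C over all
paired mature positions defines the opposing span, shifted by +2 for the
canonical 2-nt 3' overhangs. Using the modal register rather than the raw
outermost partners makes the star span immune to terminal fraying and small
bulges. A candidate is star-supported when a library read equals the star
region, with ±1 nt of slack per terminus (smallest shift preferred) —
sequenced stars are rarely bit-exact Dicer products.

Two accepted candidates whose precursor stems overlap on the same transcript
are duplex partners (a mature and its star excise the same hairpin); the
more abundant strand is kept, which is how the mature/star ambiguity is
conventionally resolved. When one read maps to several loci, star evidence
ranks first, then MFEI, then the given orientation. Star support is never
*required* for acceptance (a `require_star` flag exists): half of real
candidate sets lack sequenced stars.

## Target prediction

With a budget of at most 3 mismatches over ~21 nt, exhaustive ungapped
scanning is exact and deterministic, so no heuristic aligner (and no gap
model) is used; no validated plant duplex in the reference fixture shows a
gap. Wobbles are drawn as pairings and excluded from the mismatch count by
default; `wobble_as_half` scores them 0.5 toward the budget. Transcripts
are scanned in their given orientation; `scan_reverse` adds the reverse
complement for unoriented ESTs.

## Cleavage mapping

Clones map by exact unique occurrence of their 20-nt 5' anchor — RACE
products are cDNA copies of the cleaved mRNA, so exact prefix matching is
adequate at desk scale and deterministic. Clone ends are counted within a
100-nt window centered on the site midpoint (floor((start+end)/2) for
even-length sites), inclusive on both boundaries. The modal terminus is
called with ties broken toward the coordinate opposing the miRNA's 10th
nucleotide, then toward the smaller coordinate. A call is *validated* when
the mode carries ≥ 3 clones and ≥ 30 % of in-window clones; these thresholds
are this toolkit's convention — sequencing 15 clones per reaction describes
effort, not a call rule — and are configurable.

## Synthetic study generator

The generator emulates the structure of a deep-sequenced plant library:

- **Planted conserved miRNAs** drawn from a synthetic known-mature registry
  (miRBase-style names over common plant families).
- **Planted novel precursors**: flank(15) + mature(21) + loop(6) + star
  arm + flank(15) = 78 nt, embedded at random positions in EST-like
  transcripts (default 40 × 220 nt). The star arm is the reverse complement
  of the mature; the flanks are mutually complementary so they extend the
  stem; the loop is drawn over {A, C} so it cannot pair internally. Star
  reads (the arm shifted +2 for the overhang geometry) are emitted with
  probability 0.5, mirroring the roughly half-supported candidate sets seen
  in practice, with counts 1–3 — always below the mature's count (≥ 5) so
  duplex-partner resolution is well-posed.
- **ncRNA fragments** cut from random per-class reference sequences, **polyA
  artifacts**, and 5,000 random **decoys**.
- **Redundant counts** follow a rank-frequency Zipf law with exponent 1.2
  (drawn by inverting P(X ≥ x) = x^(−1/1.2), capped at 2,000): most unique
  reads are seen once or twice, a few thousands of times.
- **Read lengths** follow a bimodal 18–30 nt distribution with modes at 21
  and 24 nt — the canonical plant shape (21-nt miRNAs, 24-nt siRNAs).
- **RACE clone sets** place ceil(0.8 × 15) clone ends at the coordinate
  opposing the miRNA's 10th nucleotide and the rest uniformly in the 100-nt
  window (defaults 15 clones, noise fraction 0.2).

Identical config + seed gives byte-identical files, and every emitted read
is recorded in the ground-truth ledger exactly once.

What the generator does **not** emulate: sequencing errors and quality
scores, adapter read-through, isomiR end-heterogeneity, biased 5'-uridine
starts (mature first nucleotides are uniform), imperfect planted stems
(available via `stem_mismatches` but defaulting to 0), genomic multi-copy
loci, and expression correlation between tissues. Recovery tests passing on
this data therefore demonstrate the correctness of the pipeline's logic
under clean conditions, not its robustness to real library noise.

## Problem sizes and runtime

The default study bundle (10 novel precursors, 20 conserved plants, 5,000
decoys, ~620 ncRNA/polyA reads on 40 × 220-nt transcripts) was chosen so a
full discovery run completes in well under a minute on one CPU; folding cost
grows cubically with window length, so transcript length is the main dial.
The acceptance script's quantities are desk-scale by construction (four
21-nt duplexes; one 15-clone RACE simulation on a 300-nt target).

## Known limitations

- The Nussinov-style model overpairs relative to thermodynamics; structures
  are suitable for hairpin screening, not for fine structural claims.
- Annotation is exact-match only; diverged ncRNA fragments in real data
  would not be caught without a covariance-model scanner.
- Target prediction is ungapped by design; bulged duplexes are out of scope.
- Clone mapping tolerates no mismatches in the anchor; RT/PCR errors in real
  RACE clones would need the mismatch-tolerant extension.
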