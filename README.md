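# srnakit

A desk-scale toolkit for plant microRNA discovery from deep-sequenced small
RNA libraries. It covers the full analysis arc used for non-model plants
without a reference genome: collapse and size-select reads (18–30 nt),
partition them against ncRNA reference classes (rRNA, tRNA, snRNA, snoRNA,
exon, intron, repeat) and remove polyA artifacts, identify conserved miRNAs
by perfect match to a known mature set and profile their families, discover
novel miRNA candidates by folding stem-loop precursors excised from
transcript (EST) sequences, predict targets by ungapped antiparallel
complementarity with G:U-wobble awareness, and map miRNA-guided cleavage
sites from 5'-RACE clones. A synthetic-data generator with a complete
ground-truth ledger stands in for a raw sequencing library, so every stage
can be scored exactly.

## The models at the core

**Hairpin quality.** A candidate precursor of length *L* with minimum
folding free energy MFE is scored with the standard plant indices

    AMFE = |MFE| / L × 100          MFEI = AMFE / GC%

together with its A+U percentage and the requirement that the mature sits
wholly on one arm of a single stem-loop, mostly paired against its star
region. The built-in folder is an energy-scored Nussinov dynamic program
(pair energies G:C −3.0, A:U −2.0, G:U −1.0 kcal/mol; minimum hairpin loop
3 nt; deterministic traceback), chosen so the toolkit is self-contained and
bit-stable; an `RNAfold` adapter plugs in a thermodynamic model through the
same interface. MFEI thresholds are calibrated per energy model — see
`docs/methods.md`.

**miRNA* (star) support.** The star region is derived from the folded
structure as the positions opposing the mature, shifted to leave the
canonical 2-nt 3' overhang on each duplex strand; a library read matching
that region (±1 nt per terminus) marks the candidate as star-supported.

**Target scoring.** miRNA nucleotide *i* is opposed to site nucleotide
*L*+1−*i*; each opposed pair is Watson–Crick (A:U, G:C), G:U wobble, or a
mismatch. Sites with at most 3 mismatches (wobbles free by default) are
reported — exhaustive ungapped scanning, no heuristic aligner.

**Cleavage mapping.** Clone 5' ends are mapped by unique 20-nt anchor
occurrence, profiled inside a 100-nt window centered on the complementary
site, and the modal terminus is called; canonical miRNA-guided cleavage
opposes the miRNA's 10th nucleotide.

## Worked example

Score a validated duplex — the ctr-miRn4 mature against its site on citrus
unigene 17900:

```python
from srnakit.targets import TargetHit, count_mismatches

mirna = "UAGACCGCAAGAGACUAGCAA"   # ctr-miRn4
site  = "UUGCUAGUCUCUUGCGAUCUA"   # validated site, unigene 17900
mm, wob = count_mismatches(mirna, site)
print(f"mismatches={mm} wobbles={wob}")
print(TargetHit("ctr-miRn4", "17900", 1, 21, site, mm, wob).alignment(mirna))
```

prints

```
mismatches=1 wobbles=0
5' UUGCUAGUCUCUUGCGAUCUA 3'  17900:1-21
   |||||||||||||||| ||||
3' AACGAUCAGAGAACGCCAGAU 5'  ctr-miRn4
```

one mismatch in an otherwise perfect antiparallel duplex — the reported
count for this validated target. Or run the whole pipeline on a synthetic
study:

```
srnakit simulate --seed 42 --out bundle --n-decoys 500
srnakit run-all --config run.yaml        # paths to the bundle files
cat out/summary.json
```

```json
{
 "candidates": {
  "n_candidates": 10,
  "n_five_prime_u": 1,
  "n_star_supported": 8,
  "star_supported_percent": 80.0
 },
 "conserved_matches": 20,
 "kept_reads": 1183,
 "unannotated_reads": 708,
 "unique_reads": 1183
}
```

All 10 planted novel precursors and all 20 planted conserved miRNAs are
recovered; `out/novel_candidates.tsv` carries the per-candidate table
(mature, precursor, A+U%, |MFE|, AMFE, MFEI, arm, LM, LP, reads, star) and
`out/novel_structures.txt` the dot-bracket structures.

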