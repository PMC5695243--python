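# Methods

## The problem

Photosynthetic orchids show unusually dynamic degradation of the plastid
*ndh* gene family (the 11 genes *ndhA*–*ndhK* encoding the
NADH-dehydrogenase-like complex of cyclic electron flow).  Comparative
surveys score each gene into four states — (1) in-frame, (2) pseudogene
through substitutions or short indels, (3) highly truncated, (4) completely
deleted — and ask how the degradation arose: large deletions concentrate
between direct repeats (intramolecular recombination) or in extremely
AT-rich tracts (illegitimate recombination), the *ycf1–ndhF–rpl32* region
near the IR/SSC junction occurs in four configurations connected by gene
conversion and deletion, and seemingly "lost" plastid genes reappear in the
mitochondrial genome after intracellular gene transfer (IGT), recognizable
by read-depth ratios (plastid DNA is far more abundant per cell) and by
gene trees in which mitochondrial copies cluster apart from their plastid
counterparts.

`ndhscan` implements that entire analysis chain as a tested pipeline, and
ships a synthetic-genome generator so every stage can be validated against
construction-time truth without any sequence downloads.

## Pairwise alignment

All gene-scale comparisons use an exact affine-gap Gotoh/Smith–Waterman DP
(match +1, mismatch −2, gap open 5, gap extend 1 by default; a gap of
length L costs `open + L·extend`).  Determinism is part of the contract:
ties prefer match/mismatch over deletion over insertion, and after
traceback every indel run is shifted to its 5′-most equivalent placement so
breakpoint coordinates are canonical regardless of DP internals.  `N` never
matches anything.

Two supporting choices keep the exact DP practical and the calls stable:

* **Window seeding.**  Before aligning a gene model against a genome, chunks
  of the gene are placed by fast edit-distance infix search (edlib) and the
  exact DP runs only on the densest placement cluster, padded.  This is a
  search heuristic only — scores and transcripts inside the window are the
  exact DP's.  Low-complexity chunks can place promiscuously, which is why
  the densest proximity cluster, not the raw hull, defines the window.
* **Event parameters.**  For structural-event extraction the gap-open is
  raised to 30 (`EVENT_PARAMS`).  With the default open of 5, a 200–300 bp
  deletion through a random spacer fragments into several gap runs
  separated by chance match islands (an island of three matches already
  pays for an extra gap opening); the heavier opening keeps one deletion
  one event without affecting small-indel placement.

Terminal exon pieces that Smith–Waterman trims around a long insertion
(keeping a 39-bp 5′ piece costs less than an 87-bp gap saves) are rescued
after the fact: the clipped reference piece is re-aligned to the adjacent
query sequence, directly or across the insertion, and merged back when it
matches at ≥ 75% (direct) / ≥ 85% (relocated) identity.  Without this, a
gene with a long in-frame insertion near its start would be misread as
having lost its start codon.

## Degradation classification

Coverage is the fraction of reference CDS positions aligned as match or
mismatch.  Class 4 below `t_del = 0.10`, class 3 below `t_trunc = 0.50` —
the literature never quantifies "highly truncated" versus "deleted", so
these are declared conventions, config-exposed and echoed in every report.
Above `t_trunc`, class 2 requires positive evidence: a CDS-projected indel
run whose net length is not a multiple of 3 (intron indels never count), an
in-frame stop before the final 5% of codons (ragged 3′ ends are tolerated),
or a lost start codon (ATG/GTG/TTG under the plastid/bacterial code, table
11; no RNA-editing rescue).  Compensating ±1 indels that restore frame
without creating a stop leave the gene class 1 with a logged note.  1-bp
indels inside reference homopolymers ≥ 8 bp are flagged as possible
sequencing artifacts but still counted.

## Deletion mechanisms

For a deletion with bounds (s, e), direct-repeat evidence is the longest
k ≥ 7 with `ref[s−k..s−1] == ref[e−k+1..e]` — one copy retained, the other
removed with the intervening tract.  Because a repeat-mediated deletion is
placement-ambiguous by exactly the repeat length and events are left-
shifted, the mirrored configuration `ref[s..s+k−1] == ref[e+1..e+k]` is
tested too, plus ±3 bp of breakpoint fuzz.  AT evidence requires both
20-bp breakpoint-centred windows to reach ≥ 85% A+T.  Both kinds of
evidence can hold at once (pure-AT windows frequently contain short AT
microhomologies), so `analyze_interval` reports every mechanism whose
criterion is met rather than an arbitrary winner.  Insertions are tested
for their smallest string period (tandem-unit detection, brute-force over
candidate periods).

Inversions are segments whose reverse-complement local alignment beats the
forward per-position match support by ≥ 10% of segment length, with
well-matched forward sequence on both flanks; a wholesale
reverse-complemented query is an orientation flip handled at annotation
level, not an inversion.

## *ycf1–rpl32* typing

Typing is anchored on the *ndhF* reference frame.  After locating *ycf1*
and *rpl32* anchors: M-coverage of *ndhF* below 0.10 ⇒ type D (plus the
intergenic deletion toward *rpl32*, recovered against the type-A
exemplar); *ndhF* aligned to within 10 bp of its 3′ end ⇒ type A;
otherwise the 3′ tract is missing from the gene frame and the query is
examined immediately downstream of the aligned prefix — a ycf1-like tract
≥ 100 bp with ≥ 10-percentage-point identity advantage ⇒ type B, none ⇒
type C.  This anchored cascade replaces a naive "near-full-length then
scan the 3′ 600 bp" test because M-only coverage cannot distinguish a
chimeric full-length region from a truncation.  The type-B junction is
refined to the column level by maximizing (ndhF matches in the prefix) +
(ycf1 matches in the suffix), which recovers the replaced-tract length
exactly on chimera constructions; the type-B/type-C endpoint coincidence is
reported as evidence (±10 bp), not used as the classification criterion,
since nothing in the reference set encodes type-B history.  The survey
literature's roman-numeral region labels map I→A, II→B, III→C, IV→D.

## Bait-and-extend assembly

Read ends are trimmed by the modified-Mott algorithm (per-base weight
`p_limit − 10^(−Q/10)`, error-probability limit 0.01, maximal-sum segment);
pairs are dropped when either trimmed mate is under 40 bp.  Recruitment
keeps pairs in which either whole mate infix-aligns to the bait at ≥ 95%
identity on either strand; reads hanging off the bait ends are recovered
later because extension re-aligns the full trimmed set each cycle.

Strict de-novo assembly is greedy exact suffix–prefix merging (overlap
≥ 25 bp, longest first, lexicographic tie order, both orientations in the
pool, contained sequences absorbed); when two partners at the same longest
overlap disagree on the extension content, merging stops — that branch
point is exactly what zero-mismatch semantics require at a SNP between
haplotypes.  Iterative extension then runs 25 inner sweeps per outer
cycle: reads that match a contig end exactly and overhang extend it base
by base while *all* overhanging reads agree, and a read may extend an end
only if its mate (either orientation) sits exactly inside the contig
within insert range (mean + 3 SD estimated from placed pairs, fallback
1 kb).  The paired constraint is what keeps diverged paralogous reads out:
a plastid read near an IGT junction may chance-match a mitochondrial
contig end, but its mate will not match exactly.  After the inner sweeps
contigs are re-merged strictly, and outer cycles repeat until total length
is unchanged (hard cap 50 cycles, logged).  Contigs are reported in
canonical orientation (lexicographic minimum of sequence and reverse
complement), so downstream checks must be orientation-agnostic.

## Organelle assignment

Contig depth is mean exact-placement depth (consistent with the
zero-mismatch assembler); plastome depth admits whole-read infix mappings
at ≥ 98% identity.  The ratio plastome/contig assigns: plastid within
[0.5, 2]; mitochondrial within [4, 20] (deliberately wider than the
published 5.5–14.5 observation, which is itself not exactly reconstructible
from the printed per-contig depths), or above 2 with mitochondrial flank
support; otherwise ambiguous — the honest verdict for nuclear-copy-like
depths.  Plastome-like intervals inside contigs (IGT evidence) come from a
500-bp sliding infix-identity scan at ≥ 80% identity, merged across
overlapping windows; at the generator's 8% pt/mt divergence, transferred
segments scan at ~0.92 identity while random backbone stays near 0.55.

## Copy clustering

Gene copies are projected onto reference CDS columns (insertions dropped,
deletions as gaps; introns never enter), p-distances use pairwise deletion
of gap/N columns (≥ 50 comparable columns required per pair), and trees
are built by Saitou–Nei neighbor joining with lexicographic tie-breaking
and negative branch estimates clamped to zero.  Clade support is the
fraction of column-resampled NJ replicates containing the group's
bipartition.  dendropy supplies the tree container and newick
serialization; its own NJ serves only as an independent cross-check in the
test suite.  *ndhF* is excluded from tree-building by convention (its two
region types make organellar placement ambiguous), though nothing prevents
opting in.

## The synthetic generator

`make_reference` builds a ~20-kb toy plastome — genes and spacers only,
not a full 150-kb plastome — with the amplicon-style order
*ndhJ–K–C*, *ndhD*, *ndhB* (two exons, inside a mirrored inverted repeat),
*ndhE–G–I–A–H* (*ndhA* two exons), then *ycf1–ndhF–rpl32* at the SSC end.
CDSs are random non-stop codons between ATG and TAA at 37% GC; edits to IR
content are automatically mirrored.  Two junction guard bases make the
ycf1→ndhF conversion tract sharply defined (a shared base at the junction
would make the tract length genuinely ambiguous).

Degradation operators record construction-time truth: classes come from a
survivor mask over original CDS positions plus direct translation of the
mutated CDS — never from the alignment pipeline under test.  The
repeat-deletion operator plants two exact copies (guard bases on both
sides of both copies so the detected length is exactly the planted one
under either deletion placement) and keeps the tract in the spacer's 5′
half, both because the real repeats sit just downstream of the upstream
gene and because a deletion directly abutting the neighbouring gene's
insertion would let the aligner fold two gaps into mismatch soup.  The
AT-deletion operator writes pure-A/T 20-bp windows at both breakpoints.
Planting edits are confined to spacers and applied to the returned
*reference* as well — the repeat must exist in the reference frame for the
detector to see it — while length-changing edits touch only the mutated
genome.

`build_chondriome` embeds plastome segments in a random 40-kb backbone
(44% GC) with i.i.d. substitutions at 8% — matching the ~91–92% pt/mt
similarity of real organellar gene pairs, and operationally necessary: an
identical IGT copy would absorb plastid reads and drag the depth ratio
toward 1.  An "inverted" segment carries an internal inversion (central
half reverse-complemented between forward flanks), the configuration in
which organellar inversions actually present.  `simulate_reads` draws
fragments uniformly, weighted by copy number × length (so expected depth
ratios equal copy ratios), with constant Q40 and optional i.i.d. errors
marked at Q13.

What the generator does not emulate: real error profiles and quality decay,
mitochondrial recombination dynamics and subgenomic circles, nuclear
organellar copies (NUPT/NUMT), homopolymer-length slippage, and full
plastome architecture.  Green tests therefore demonstrate correctness of
the algorithms under clean, well-separated conditions, not performance on
raw survey data.

## Problem sizes and determinism

Default scales were chosen so the complete suite runs in minutes on one
core: 20-kb plastome, 40-kb chondriome backbone, 50,000 read pairs at
2×100 bp for the assembly experiment (≈ 400× plastid, ≈ 40× mitochondrial
depth at the 10:1 copy ratio), 50-seed replication for classification and
mechanism checks, 100 seeds for region typing, 100 clustering replicates
with 100 bootstrap resamples each.  Every stochastic component takes an
explicit seed (numpy `default_rng`); identical seeds give byte-identical
genomes, reads, assemblies and bootstrap supports.

## Known limitations

* The aligner is exact DP without banding, so single alignments beyond a
  few kb per side are expensive; genome-scale placement always goes
  through the edlib-seeded window path.
* Frameshift offsets are reported at the left-shifted (5′-most) indel
  position; conventions that quote the 3′-most position will differ by the
  length of any flanking repeat.
* Zero-mismatch assembly is intolerant by design: any real sequencing
  error fragments contigs at the error site.  The Mott trimmer plus the
  paired constraint mitigate but do not remove this; error-free simulation
  is the intended regime for the reconstruction guarantees.
* Depth-ratio assignment assumes uniform coverage; amplification bias or
  GC skew would widen the bands in practice.
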