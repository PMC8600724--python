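# Methods

This note documents the models, decision rules and numerical choices behind
`t2tcurate`, what the synthetic fixtures do and do not emulate, and the
known limitations.

## Coordinate conventions

All internal coordinates are 0-based half-open. 1-based inclusive
coordinates appear only at the GFF3 and per-base-coverage file boundaries,
where those formats define them. A single convention internally prevents
off-by-one drift between modules that exchange intervals (anchors, spans,
breakpoints, windows).

## Telomere scanning

Fungal telomeres are tandem arrays of a 6-mer motif: CCCTAA at the 5'
(sequence start) terminus and its reverse complement TTAGGG at the 3'
(sequence end) terminus. Instead of generic tandem-repeat discovery, the
scanner counts **exact motif copies** in the maximal chain of tandem runs,
where runs separated by gaps of at most `max_interruption` bases (default
6, one motif length) chain together. This matches how a generic
tandem-repeat finder tolerates small interruptions in near-perfect telomere
arrays while keeping the count interpretable as a copy number.

Parameters: `terminal_window` = 1000 bp (arrays of 12–17 copies occupy
72–102 bp, so 1 kb comfortably covers real arrays plus slack; scaffolds
shorter than the window are scanned whole with a warning);
`min_copies` = 3 for a presence call (one or two chance copies occur in
random sequence, three tandem copies essentially never); motif phase is
free. When two chains tie on copy count the one nearer the terminus wins.
A scaffold is T2T iff both termini have a presence call.

## Assembly statistics

N50 is the length of the smallest scaffold in the minimal set of largest
scaffolds whose cumulative length reaches half the assembly total; L50 is
the size of that set (descending sort, cumulative scan; ties resolved by
the scan itself). GC% is computed over non-N bases — the ambiguity
characters carry no compositional information, and a gap-free assembly is
unaffected either way.

## Unique k-mer anchoring and chaining

Whole-assembly comparison uses **anchors**: canonical k-mers (lexicographic
minimum of the k-mer and its reverse complement; k odd so no k-mer is its
own reverse complement) that occur exactly once in each assembly. k = 21 by
default: at desk-genome sizes a random 21-mer collision is vanishingly
rare, which the test suite verifies on generated genomes rather than
assumes. k-mer codes are computed by vectorised base-4 polynomial
evaluation (exact in float64 for k ≤ 26), making a multi-megabase
comparison sub-second.

Anchors chain when adjacent in query order, in the same scaffold pair and
orientation, with both coordinate deltas positive (negative in target for
reverse orientation), at most `max_gap` = 10 kb, and agreeing within
10 kb. The gap limit tolerates indel noise and anchor deserts (repeat
arrays have no unique k-mers) without bridging distinct repeats.

* **Correspondence / split evidence.** Chains with ≥ `min_anchors` = 50
  anchors are partners. A query scaffold with two or more partners on
  disjoint query spans of ≥ 50 kb each, pointing at *different* target
  scaffolds, is a chimera candidate; the breakpoint estimate is the
  midpoint between adjacent partner spans. Junction recovery is therefore
  bounded by k plus the anchor desert around the junction (for chimeras of
  complete chromosomes, the back-to-back telomere arrays).
* **Terminal overlaps.** The overlap estimate between two contigs is the
  query extent of the largest chain reaching within `terminal_search` =
  200 kb of a terminus of both contigs, with dovetail-consistent geometry
  (opposite termini for forward orientation, same for reverse). A merge
  candidate needs ≥ `min_overlap` = 50 kb. For an exact overlap the chain
  span equals the overlap length (the flanking k-mers cross the junction
  and are not shared), so the estimate is exact up to k.

## Curation pipeline

Stage order: **drop → mito → merge → split → trim → rename**, the order of
the manual workflow it automates; merging precedes splitting, and trimming
runs last.

* Drop: contigs shorter than `min_contig_length` = 10 kb (the minimum
  input read length); boundary keeps a contig of exactly 10 kb.
* Mitochondrial quarantine: a contig whose anchor-chain coverage by any
  supplied mitochondrial reference reaches `mito_cover_fraction` = 0.5 of
  its length is moved to a separate output record, not deleted — organelle
  sequence is reported, never silently discarded.
* Merge: candidate pairs are re-evaluated to a fixpoint, longest overlap
  first. Overlap bases are taken from the longer contig; no base-level
  consensus is computed (the workflow this models re-polished after
  merging, which is out of scope here). The cut coordinate is the end of
  the anchor chain in the shorter contig, which is exact for exact
  overlaps.
* Split: breakpoints come from cross-assembly correspondence. A proposed
  breakpoint within 5 kb of a back-to-back telomere junction (an end-motif
  run followed within 100 bp by a start-motif run, both at presence
  threshold) is snapped to the end of the end-motif run — the true
  chromosome boundary in a chimera of complete chromosomes, which anchor
  midpoints alone cannot resolve exactly because telomere arrays carry no
  unique k-mers. Splitting without correspondence or dual-centromere
  evidence is refused unless forced.
* Trim: maximal terminal runs with coverage below `trim_min_depth` = 1 are
  removed; internal zero-coverage runs are untouched; a wholly unsupported
  scaffold is an error, not an empty output. Coverage arrays are carried
  through merges and splits so trimming applies to derived scaffolds.
* Rename: final scaffolds become `scaffold_1 … scaffold_n` in decreasing
  length order.

Every stage logs a `CurationAction` with measured evidence and enough
parameters to re-apply it; `replay_actions` reproduces the final assembly
byte-identically from the baseline, which the tests assert on every
benchmark run. Read partitioning for local reassembly (keep reads ≥ 10 kb
whose aligned fraction elsewhere, by interval union over PAF records, is
< 0.80) is provided as a standalone operation; running an assembler on the
recruited reads is out of scope.

Baseline selection ranks candidate summaries by T2T contig count
(descending), then contig count (ascending), then N50 (descending) — 
continuity and telomere support dominate, N50 breaks ties.

## Landscape tracks

Windows are fixed-size with a partial, length-normalised last window. GC%
windows use non-N bases (an all-N window is NaN). Coverage windows use
log2(mean depth + 1): the source workflow plots "log2 of average coverage"
without stating zero handling, and the +1 keeps zero-coverage windows
finite; every table produced from these tracks states the transform. A
gene is assigned to the window containing its start coordinate — count
semantics, not fractional overlap.

**Centromeres** are AT-rich, gene-scarce troughs. Both tracks are smoothed
(moving average, 25 windows) and z-scored; the trough is the interior
minimum of z(GC) + z(gene density), with the terminal 5% of windows
excluded because telomere regions are also AT-rich. The reported
*position* is refined on the GC component alone — a weighted centroid of
the half-depth GC trough around the minimum — because GC has per-base
resolution while gene density is a sparse feature count (at one gene per
3 kb it jitters the combined argmin by several windows); the gene signal
still gates trough identification and the confidence flag. On planted
30 kb troughs this recovers the centre to well within one 1 kb window.
Arms are measured from the position; long/short ≤ 1.7 is metacentric,
otherwise submetacentric (standard cytogenetic convention; the source
classification was qualitative). A trough whose combined z-score stays
above −5.0 is flagged low-confidence: the minimum of a smoothed, z-scored
noise-only series over hundreds of windows sits around −2 to −4.4, while a
genuine 0.25-GC trough scores below −5.4 (measured over seeded genomes, so
the cutoff separates the two regimes with margin). Centromere calls on real data are
advisory: no quantitative criterion exists in the source workflow, which
identified centromeres visually.

**rRNA cistrons** are counted as the maximal uninterrupted repetition of
the ordered subunit pattern (18S, 5.8S, 26S) over position-sorted rRNA
features — reversed for minus-strand blocks — with an inter-member gap cap
of 50 kb to prevent chaining across a chromosome. ITS spacers are not
features of the pattern.

**Coverage peaks** are maximal base runs with depth ≥ 10× the track
median (threshold floored at 1 so an all-zero track has no peaks), merged
across gaps ≤ 1 kb.

## Gene tables

Asparaginase classes are domain architectures: class I = PF01112,
class II = PF00710 + PF17763 (both), class III = PF06089; a protein with
no class domain whose product annotation contains "asparaginase" is a
homology-only candidate. Precedence II > III > I is fixed for determinism;
no known protein carries domains of two classes.

DEG rules: `deg4` means |log2FC| ≥ 2 (the "4-fold or greater" rule,
boundary inclusive); `significant` means adjusted p ≤ 0.05 (inclusive; a
missing adjusted p is never significant). *Significantly up-regulated* is
significance plus a positive fold change — **not** the 4-fold rule; the
published count of three up-regulated asparaginase genes includes one at
log2FC 1.70, which fixes this definition. Both filters are exposed
separately. The count prefilter keeps a gene iff the maximum across groups
of the within-group median count is ≥ 10. The external model that produces
the results tables is consumed, never re-implemented; linear folds are
always reported as 2^log2FC (the example table's narrative "~128-fold" for
the top gene differs from 2^7.61 ≈ 195; the discrepancy is documented, not
reconciled).

## Synthetic fixtures

The generator plants exactly the structures the detectors look for:
chromosomes of specified length with exact terminal motif arrays of known
copy number, a 30 kb AT-boosted (−0.25 GC) gene-free centromere at a
specified position, an optional tandem rRNA cluster with labelled
features, genes scattered at one per 3 kb, and a 28 kb AT-rich
mitochondrial contig. Body sequence is i.i.d. per-base at GC 0.48. Two
construction details matter:

* 7–12 guard bases of motif-free GT alternation flank each planted
  telomere array on the interior side, so a chance motif copy in random
  body sequence can never chain onto the array and corrupt the planted
  count.
* Candidate derivation is substitution-noise only by default; chaining
  tolerances are documented for substitutions, and indels would loosen the
  exactness of overlap cuts.

Coverage is negative-binomial per base (r = 20 equivalent via
dispersion = 0.05) around a smooth local mean (per-kb gamma multipliers),
with forced-zero ends and interval boosts for peaks. Expression counts are
negative-binomial (dispersion 0.02, lognormal gene means around 200, two
replicates per group as in the study design) with planted log2 fold
changes; the results table uses a documented stand-in statistic —
pseudocount-shrunken log2 ratio of group means, Welch t on log2(count+1),
Benjamini–Hochberg step-up adjustment — chosen so that null tables are
calibrated (median |estimated log2FC| < 0.2 at mean 200) and 8-fold plants
are recovered with ≥ 80% power at two replicates.

The standard benchmark (`make_benchmark`) draws three chromosomes of
0.5–0.8 Mb and builds a baseline with one 60 kb terminal-overlap split,
one two-chromosome chimera, a 5 kb junk contig, the mitochondrial contig
and 100 bp zero-coverage flanks at every true chromosome end, plus an
identity alternate for split evidence. These sizes keep a 20-seed
end-to-end suite under two minutes on one CPU while exercising every
pipeline stage; they are scaled-down stand-ins for a ~40 Mb,
7-chromosome genome.

What the fixtures do **not** emulate: read-level sequencing error models,
indel-dominated long-read noise, real repeat families (transposons,
segmental duplications) beyond the rRNA array, GC-coverage bias, and the
external quantification/statistics stack behind real expression tables.
Passing the plant-recover suite shows the decision rules and their
implementations are correct under these idealised conditions; it does not
certify performance on repeat-dense or highly heterozygous real genomes,
where unique-k-mer anchor deserts grow and overlap estimates lose the
exactness they have here.

## Degenerate inputs and tie-breaks

Empty assemblies, empty sequences, whole-scaffold zero coverage,
breakpoints at 0 or scaffold length, non-candidate merges and malformed
files are errors, not silent coercions. Ties: equal-copy telomere chains →
nearer the terminus; equal-length scaffolds at rename → lexicographic id;
equal overlap candidates → longest first, then ids. All pipeline stages
are deterministic given identical inputs and configuration.
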