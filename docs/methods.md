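# Methods

This note documents the models and conventions behind each stage, the
defaults that matter, what the synthetic data does and does not emulate,
and the numerical/design choices made where more than one reading was
defensible.

## Coordinates and orientation

All in-memory coordinates are 0-based half-open on the genomic forward
strand; GFF3 is converted on read/write (1-based inclusive), bedgraph is
written 0-based half-open. "Sense" always means the transcript's strand:
minus-strand sequence operations reverse-complement first, offsets count
5′→3′ from the TSS. The poly(A) site is the strand-aware last transcribed
nucleotide unless the annotation's `pA_site` attribute says otherwise.

## Preprocessing

Stage order: 3′ adaptor clip → 3′ quality trim → whole-read quality filter
→ homopolymer-artifact filter → barcode demultiplex (UMI + barcode
stripped and stored) → PCR-duplicate collapse. Defaults: adaptor
`TGGAATTCTCGGGTGCCAAGG` (miRCat-33-style), minimum clip overlap 5 nt,
post-clip minimum length 27 nt (3 UMI + 6 barcode + 18 mappable insert),
trim below Q20, drop unless ≥ 70 % of bases ≥ Q20, artifact when ≥ 95 % of
the insert is one nucleotide. Barcode matching is exact by default
(`barcode_mismatches` configurable). These thresholds are conventional
fastx-style settings; the analysis is insensitive to them on clean data.

Duplicates collapse on the key **(UMI, full insert sequence)** — the
strictest reading of "identical reads": two reads are copies of one cDNA
only if both the random trimer and the entire insert agree. Demultiplexing
runs before collapsing so the collapse key never spans samples.
Every stage's input count equals kept + dropped + unassigned; the stats
report carries a `conserved` flag asserting this identity.

## Alignment model

The built-in aligner is deliberately minimal and exactly specified, because
its two side channels *are* the scientific signal:

* **5′-anchored seed-and-extend**: the first 18 nt (seed, also the minimum
  match) locate candidate loci on both strands; extension is maximal from
  the 5′ end.
* **At most one 1-nt genomic deletion**, accepted only if it strictly
  extends the match; among equal placements the 5′-most (leftmost) deleted
  position is recorded. This mirrors the leftmost CIGAR convention and
  makes homopolymer ambiguity deterministic. One deletion per read reflects
  the single-nucleotide reverse-transcriptase drop-out at the crosslinked
  base.
* **The unmatched 3′ remainder is the tail candidate.** Maximal extension
  means templated bases can never end up in a tail; the flip side is that
  genuine oligo(A) tails upstream of genomic A-runs are partially absorbed
  (an undercount bias shared with BLAST-style tail detection). The
  simulator consequently guarantees planted tails are non-templated (below).
* Equally scored loci are enumerated in genome order and one is chosen
  uniformly at random under a fixed seed.

SAM import applies identical semantics to external alignments: CIGAR `D`
ops become deletion positions, the read-sense 3′ soft clip becomes a tail
candidate subject to the same maximal-extension absorption against the
genome, `N` marks junction alignments, and secondary alignments are grouped
for random assignment. Export then import round-trips exactly on the toy
genome.

## Oligo(A) calling

A non-templated 3′ portion is an oligo(A) tail iff it contains **≥ 2 A
residues** and its non-A fraction is **≤ 1/5** (so `AAAAG` qualifies at the
boundary, `AAG` does not). The rule is evaluated on the read-sense strand
and depends only on (length, A-count) — a property the tests exploit by
brute-force enumeration of all tails up to length 8. Only reads whose 3′
adaptor was found are candidates (otherwise the molecule's 3′ end was not
sequenced and absence of a tail is uninformative); this denominator choice
is a config flag. Tailed-read frequencies use a 2-nt minimum tail length.

## Quantification and clustering

Counts assign each read to the sense-strand transcript with the largest
overlap (ties uniform under a seed); "dubious" ORFs are excluded by
default. HPM scales by 10⁶ over a declared transcript universe, so HPM
sums to 10⁶ per sample by construction. Binding ratios and fold changes
add a 1-HPM pseudocount (configurable) to both terms; replicate fold
changes are averaged on the log2 scale. Pearson matrices use log2(HPM+1)
on the top-2000 mRNAs ranked by mean HPM across **all** samples (sample-
order independent).

The eight directional clusters map the (Pol II, Nab3, Mtr4) fold-change
sign triple with Pol II as the most significant bit:
(+,+,+)→1, (+,+,−)→2, (+,−,+)→3, (+,−,−)→4, (−,+,+)→5, (−,+,−)→6,
(−,−,+)→7, (−,−,−)→8. This is the unique ordering consistent with the
verbal characterizations of clusters 1 ("more transcription, more
binding"), 5–7 ("less Pol II, more Nab3 and/or Mtr4") and 8 (all down);
the table is exposed as `CLUSTER_TABLE` and configurable. The
increased/decreased threshold ε defaults to 0 (pure sign); values inside
the dead band classify as "down" by default. The representation filter
requires ≥ 10 reads (configurable; only the resulting gene count, not the
threshold, is conventionally reported) in every factor's time-0 sample.

## Crosslink sites and motifs

A crosslink site is the deleted genomic nucleotide itself. Sites are
tallied per (chrom, strand, position), annotated to the containing sense
transcript, ranked by deletion count (ties by coordinate), and 13-nt
(±6) sense-strand windows are extracted around the top 50. A window
"conforms" when the consensus (`TCTTG`) occurs as an exact substring —
the simplest operational reading of consensus conformance. k-mer
enrichment compares observed window k-mer counts to dinucleotide-
preserving shuffles (Altschul–Erickson Euler-walk shuffle, implemented
here because no installed library exposes one). Which transcript set
scopes the top-site selection is an explicit parameter: the pipeline uses
the cluster-5/6 gene list, but the operation takes any scope.

## Metagene profiles and junctions

Two weighting modes: `hpm_sum` adds HPM-scaled coverage across genes
(highly bound genes dominate — used for TSS-aligned profiles), and
`per_gene_unit` normalizes each gene's window to total 1 and averages rows
equally (used for site-anchored profiles). "Normalized to 1" is read as
row-sum = 1 (a density), not max = 1; a flag switches. Fixed-window TSS
profiles default to [−100, +2800] with a 500–2800 nt transcript-length
filter (shorter/longer transcripts are excluded, not truncated). The
50-bin length-normalized mode splits each transcript into near-equal bins
with the remainder given to the 5′-most bins; bin sums conserve raw
coverage exactly, and transcripts shorter than the bin count are excluded
and counted.

Junction quantification matches read inserts as exact substrings of
annotated junction templates — exon–exon (spliced) and intron–3′-exon
(unspliced; the 5′ junction is not used) — requiring ≥ 3 nt (default)
on each side of the boundary; reads matching junctions of multiple
transcripts are dropped as ambiguous and counted. The per-class aggregate
ratio pools counts before dividing.

## The synthetic experiment

The simulator plants, at recorded positions, exactly the signals the
analysis detects, so every stage can be scored against machine-readable
truth. Defaults (each a condition chosen once; where the motivating
biology states a magnitude the default emulates it, otherwise the value is
a realistic desk-scale choice):

* **Genome/annotation**: one chromosome; 60 transcripts, biotype mix
  70 % mRNA / 12 % CUT / 10 % SUT / 8 % snoRNA; mRNA lengths 500–2500 nt,
  noncoding classes shorter on average; snoRNA transcribed units extend a
  40-nt margin beyond the mature ends; 25 % of (sufficiently long) mRNAs
  carry one intron; 5 % of mRNAs flagged dubious; intergenic gaps
  150–300 nt. Baseline expression is heavy-tailed — per-transcript
  lognormal(0, σ = 0.5) times a biotype factor (mRNA 1.0, snoRNA 0.7,
  SUT 0.5, CUT 0.4) — which is what makes replicate correlations and
  top-transcribed-mRNA selection meaningful.
* **Motifs**: every transcript gets one 5′-proximal `TCTTG` instance
  (offset 25–80 nt from the TSS) and, if long enough, one or two further
  downstream. The crosslinked nucleotide is planted directly 3′ of the
  motif with unlike neighbours (`…TCTTG|C|T…`) so a planted deletion is
  never ambiguous within a homopolymer run.
* **Factor positioning**: Pol II uniform along the transcript; Nab3
  concentrated at motif crosslink sites with a 5′-proximal/downstream
  mixture whose downstream weight rises with time after shift
  (0.10 at 0 min and mock, 0.60 at 4, 0.75 at 8); Mtr4 at Nab3 sites
  offset downstream by Poisson(mean 25) nt; Nab2 poly(A)-proximal; Cbc1
  cap-proximal. Reads are genomic-contiguous (nascent RNA), 40–55 nt.
* **Deletions**: planted on Nab3 reads at the motif-adjacent nucleotide
  with probability 0.2 (no rate is conventionally reported; 0.2 gives
  dense site tables at desk scale).
* **Tails**: appended with per-factor probabilities (Mtr4 0.25, Nab3 0.05,
  Pol II 0.03 — emulating the 20–30 % vs 1–6 % tailed-read contrast);
  lengths are shifted-geometric (minimum 1) with mean 4 nt in gene bodies
  and 12 nt within 25 nt of the poly(A) site ("significantly longer");
  pure A by default. Note that with a min-1 geometric of mean 4 the
  *called* tails (≥ 2 nt by the rule) average 5 nt — the `min_len=2`
  setting plants only rule-qualifying tails and makes the called mean
  equal the model mean. The generator guarantees tails are non-templated:
  the read 3′ end is moved (≤ 12 nt) until the next two genomic sense
  bases differ from the first tail base, so neither direct extension nor a
  one-nt genomic skip can absorb tail bases; if no such junction exists
  locally the tail is skipped rather than planted ambiguously.
* **Library structure**: `[3-nt UMI][6-nt barcode][insert][3′ adaptor]`,
  Phred+33 Q40 throughout; PCR copy numbers 1 + Poisson(mean 1); distinct
  molecules are guaranteed distinct (UMI, insert) keys, so duplicate
  collapse recovers molecule counts exactly. The UMI-before-barcode order
  matches common CRAC linker designs and is configurable in effect through
  the prep configuration.
* **Planted differential design**: per factor, a fraction f = 0.2 of
  (non-dubious) mRNAs is shifted up (weight ×u) and the rest down (×d)
  with u = 16d and d = 1/(1 + 15f), so total library weight is conserved
  and expected post-normalization log2 fold changes are exactly ±2.
  Clusters 1–7 get equal small memberships satisfying the three up-
  fraction constraints simultaneously; cluster 8 (all-down) takes the
  remainder — also the biologically dominant response to glucose
  withdrawal. Conserving the weight budget matters: an unbalanced design
  would shift all fold changes through the HPM normalization and push
  weak effects across the sign boundary.
* **Junction libraries**: reads span exactly one junction with ≥ 10 nt
  overhangs; the pipeline simulates Mtr4 libraries moving from spliced
  fraction 0.5 (time 0) to 0.8 (after shift) and Nab3 constant at 0.3,
  mirroring post-transcriptional Mtr4 targeting vs cotranscriptional Nab3
  binding.

**What the simulator does not emulate** — and hence what passing tests do
not certify about real data: sequencing errors and quality variation,
rRNA/tRNA contamination, biological replicate variability (replicates
differ only by sampling noise), overlapping/antisense transcription units,
alternative TSS/poly(A) usage, and genome repetitiveness (multi-mapping is
exercised via constructed duplications, not realistic repeat families).
Real libraries should be aligned externally and imported as SAM.

## Scale and determinism

The standard full-experiment run (18 CRAC libraries × 2500 molecules plus six
2000-read junction libraries over a 60-transcript genome) is the package's
standard demonstration size: large enough that every planted effect is
recovered with wide margins (planted ±2 log2 effects are ≥ 4 σ from the
sign boundary at these depths), small enough to run end-to-end in well
under a minute on one core. All randomness flows from one seed through
labelled child generators (`rng_for`), dictionaries are written with
sorted keys, floats with fixed rounding, and the manifest records a
sha256 per artifact — two runs from one seed are byte-identical.

## Known limitations

* The aligner is exact-match (plus one deletion); substitution errors
  cause truncated matches and spurious short "tails" on real data — the
  adaptor-required flag and the ≥ 2-A rule absorb most of this, but real
  libraries are better aligned with a production mapper and imported.
* Tail undercounting at genomic A-runs is inherent to maximal extension;
  per-read absorption is visible in the SAM round trip but not separately
  flagged in summaries.
* Junction matching is exact-substring; one mismatch near a junction loses
  the read (counted as unmatched).
* `consensus_score` enrichment uses a per-window shuffle background, which
  preserves composition but not positional structure across windows.
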