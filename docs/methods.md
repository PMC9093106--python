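# Methods

## The problem

HERV-K is the youngest human endogenous retrovirus family. A provirus is
flanked by two long terminal repeats (LTRs, each U3–R–U5); new integrations
are detected by ligation-mediated PCR (LM-PCR): genomic DNA is sheared by
sonication, linker-ligated, and amplified with one primer in the 3′ LTR and
one in the linker, so each amplicon spans the junction between the LTR's
terminal hexamer (CCTACA or CCTTCA) and host DNA. Read 1 starts inside the
LTR at the sequencing-primer position and runs through the terminal hexamer
into host sequence; read 2 enters from the linker-proximal shear end; an
8-bp index read carries the sample barcode.

`retrosite` implements the full inference chain — demultiplex/quality gate,
LTR trimming, mapping, duplicate removal, site calling, clonality
estimation, and cross-sample classification — together with a simulator
that plants proviruses with known ground truth, so every stage is testable
without external data.

## Simulator (`simlib`)

**Planting.** An integration at 0-based host offset *p* with TSD length *t*
produces `host[:p+t] + provirus + host[p:]`: the *t* host bases at the cut
appear once on each side of the provirus, exactly as retroviral integrase
leaves them (5–6 bp for HERV-K). Minus-strand insertions insert the reverse
complement. The reported junction coordinate is the 1-based reference
position of the first host base 3′ of the LTR terminus in provirus
orientation: `p+1` on plus, `p+t` on minus.

**Surrogate provirus.** A ~400-bp construct with labelled segments: 5′ LTR
(U3 tag or CMV tag, then R and U5), an internal stuffer, a reporter
cassette (exon–intron–exon, the intron optionally spliced out), and a 3′
LTR ending in the terminal hexamer. Reverse transcription regenerates U3 at
the 5′ end, so a U3 5′ junction marks a retrotransposed copy while CMV
marks a plasmid-derived integrant; an integrated copy that went through an
RNA intermediate has also lost the reporter intron. Segment sequences are
fixed arbitrary DNA so truth is stable across runs.

**Clone/molecule model.** Clone abundance follows the distinct-amplicon
convention: each genome copy of a clone shears at one random position
(uniform in [150, 600] bp from the junction by default; the real shear
profile of the assay is not published, so this is a convention), so one
copy contributes one fragment length. `molecules_per_copy` models library
oversampling of that single fragment, and `pcr_dup_rate` adds further
identical emissions. Under this model distinct lengths can collide but
never split, which is what makes the distinct-length count a lower bound on
the clone count.

**Error model.** Substitutions only, at a configurable per-base rate
(validation uses 0 and 0.2%); no indels, so the ungapped mapper is
sufficient. Qualities are constant Phred 35 except the index read, whose
per-position profile is configurable so the >20 gate can be exercised.
Determinism: one master seed; per-sample streams are spawned from it in
sorted sample order.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: indel sequencing errors and real quality decay,
chimeric PCR artifacts, non-uniform shear profiles, genome-scale repeat
structure (toy references are uniform random with homopolymer runs capped
at 30 bp), and full-length proviral sequence. Results on real libraries
would additionally depend on an external gapped aligner.

## Junction reduction (`junction`)

The index gate keeps a read only if **every** position of the 8-bp index
read has Phred strictly greater than 20 (">20" read as a strict
inequality; a position at exactly 20 discards the read). Malformed index
reads are rejected per-read with a warning.

Trimming finds the **first** exact occurrence of a terminal hexamer ending
within 60 bp of the read start and keeps everything after it, requiring at
least 20 bp of host. First occurrence is deliberate: R1 begins at a fixed
primer position inside the LTR, so everything 5′ of the terminal hexamer is
known LTR sequence containing no hexamer — whereas the host flank contains
one by chance at ~2% of loci, and trimming at a *later* occurrence would
then mis-place every read of such a site. Optionally the bases immediately
5′ of a candidate hexamer are validated against the known U5 suffix
(`LtrMotifSet.ltr_context`); this rejects hexamers fabricated by sequencing
error after the true one was destroyed, the one remaining way a spurious
trim point can arise. The check is off by default and enabled in the canned
study configuration.

## Mapping and deduplication (`mapper`)

A deterministic, auditable mapper replaces an external aligner: an exact
k-mer index (k = 15, both strands) is seeded with the read's first k-mer,
extended ungapped, and mismatches counted (≤2 allowed). A read is `unique`
only if exactly one placement attains the minimal mismatch count; ties are
`multi` and are discarded, as are unmapped reads. Candidate order — and so
tie-breaking — is (chromosome, offset, strand), making unique/multi calls
reproducible. The seed must match exactly, so a substitution in the first k
bases loses the read rather than misplacing it; at the depths simulated
this costs coverage, not sites. Equivalence with an exhaustive both-strand
Hamming scan is asserted in the tests for reads whose substitutions lie
outside the seed.

Duplicate removal collapses reads sharing (chromosome, junction, strand,
fragment length) into one molecule — reads from the same sonication
fragment are PCR/optical duplicates. Fragment length is recovered from the
mate: R2 enters from the shear end, so a concordant pair brackets the
fragment. Coordinate+length (rather than coordinate alone) is the dedup
key because the length-distinct fragment is the abundance unit.

## Site calling and hallmarks (`sites`)

Molecules on one chromosome/strand within 5 bp of a neighbour (single
linkage) form a site at the read-weighted modal junction (ties to the
smallest coordinate). Two support filters exist: `min_molecules` (spec
default 1) and `min_reads` — at deep coverage a junction carried by a
handful of reads against hundreds for true sites is a trimming or PCR
artifact; the study configuration uses `min_reads=5` at ~120 reads per
molecule.

*Junction integrity*: sites whose modal junction carries <80% of reads are
flagged `indel_suspect` and excluded from classification. This is an
explicit proxy — the original exclusion of indel-bearing junctions was
likely Sanger-based and its criterion is not published.

*TSD*: the largest L ≤ 10 with suffix(upstream flank, L) = prefix
(downstream flank, L). The upstream flank must come from 5′-junction
information (simulation truth, or a supplied Sanger read in practice);
for 3′-only data the TSD stays unset rather than guessed. When the host
repeats itself at the cut (e.g. a homopolymer) the apparent duplication is
genuinely longer than the planted one and the planted length is not
recoverable from sequence; `apparent_tsd` computes the expected observable
value, equal to the planted length at every unambiguous locus.

*Promoter and intron*: exact substring tests for the U3/CMV tags at the 5′
junction and for the reporter intron/exons, mirroring how diagnostic PCR
and Sanger sequencing interrogate these features.

## Clonality (`clonality`)

Copy number = number of distinct amplicon lengths at a site, compared as
shear *endpoints* (junction ± length): identical to distinct lengths when
all molecules agree on the junction, but robust to few-bp junction jitter
inside a cluster, where a jittered read shares its endpoint with its parent
fragment and must not count as an extra clone. No collision correction is
applied (plain counting, as in the source assay); a `correction` hook
exists and defaults to identity. Relative abundance divides each site's
copy number by the per-sample total over **all** sites — reference and
nonreference both enter the denominator — and sums to 1 per sample.

## Cohort comparison (`cohort`)

Per-sample sites merge into loci (single linkage within 10 bp on the same
chromosome/strand; merged coordinate = minimum member coordinate). Against
a designated reference group: present there → *reference*; absent there
but present in every focal sample → *nonreference universal*; confined to
one focal group and present in all its samples → *nonreference specific*.
These definitions are not exhaustive, so any remaining pattern (e.g. a
locus in some but not all samples of one group) is reported explicitly as
*nonreference partial* rather than forced into a class. Sites failing
integrity or flank-uniqueness checks are excluded **before** the census,
matching the raw-sites → exclusions → classification order of the
original analysis.

Flank uniqueness extracts the 50 junction-proximal host bases and
exact-searches both strands of the genome; exactly one hit passes (the
in-package analogue of requiring 100%-identity single-hit BLAST matches).
Known-insertion matching accepts a coordinate within 100 bp or, for
entries without coordinates, an equal cytoband label ("almost identical"
is unquantified in the literature; both windows are configurable).

## Validation scale and numerical choices

The study-scale validation simulates 3 samples, 15 loci (5 reference, 4
shared nonreference, 3+3 sample-specific) over 29 insertion events on a
85-kb two-chromosome reference, ~10,000 read triples per condition, at
substitution rates 0 and 0.2% — sizes chosen so the whole suite runs in
well under a minute on one CPU while every failure mode observed during
development (chance host hexamers, error-destroyed motifs, homopolymer
TSD ambiguity, length-jitter overcounting) is exercised. Ties are broken
lexicographically throughout; abundance sums are checked to 1e-9; all
randomness flows from explicit seeds.

## Known limitations

- Ungapped, seed-exact mapping: reads with indels or with errors in the
  first k bases are lost, not recovered.
- No sample demultiplexing by barcode assignment: libraries arrive
  pre-split; only the index quality gate is modelled.
- Reference status is operational (presence in a control group or supplied
  BED), not a curated insertion database.
- Cytobands are labels carried on encoded tables, never computed from
  coordinates.
- No statistical collision correction for clone counting; at high clone
  counts over a narrow shear range the distinct-length estimate saturates.
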