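# retrosite

Integration-site calling for LTR retroelements (HERV-K-style) from
ligation-mediated PCR (LM-PCR) junction libraries, plus a library simulator
with complete ground truth.

LM-PCR captures the junction between a provirus's 3′ LTR and host DNA:
sheared genomic DNA is linker-ligated and amplified with one primer in the
LTR and one in the linker. Read 1 runs through the LTR's terminal hexamer
(`CCTACA`/`CCTTCA`) into the host genome; read 2 enters from the
sonication shear end; an 8-bp index read gates read quality. From such
libraries the package:

- filters reads by per-position index quality (Phred > 20, strict);
- trims reads at the LTR terminus and maps the host segment with a
  deterministic unique-best k-mer mapper;
- removes duplicates into molecules keyed by (chrom, junction, strand,
  fragment length) and calls integration sites at modal junctions;
- estimates clone copy numbers by **distinct-amplicon counting** — each
  genome copy of a clone shears at a different position, so the number of
  different fragment lengths at a site estimates its clone count — and
  relative abundances per sample;
- verifies retrotransposition hallmarks: the 5–6-bp target-site
  duplication (TSD) integrase leaves on both flanks, a U3 (vs plasmid CMV)
  5′ junction, and removal of a reporter intron;
- classifies loci across samples as reference / nonreference-universal /
  nonreference-specific against a control group, and matches calls to
  known polymorphic insertions (K113, K20, K22).

Encodings of two published nonreference-site tables (HeLa/HeLa-inBLC and
fibroblast/iPSC cohorts) ship as package data for the classification
worked example. See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from retrosite import simlib, pipeline

genome = simlib.make_reference(1, {"chr1": 60_000, "chr2": 60_000})
specs = [
    simlib.InsertionSpec("ctrl",  "chr1", 3_000,  "+", tsd_len=6, copy_count=3),
    simlib.InsertionSpec("lineB", "chr1", 3_000,  "+", tsd_len=6, copy_count=3),
    simlib.InsertionSpec("lineB", "chr1", 8_000,  "-", tsd_len=5, copy_count=2),
    simlib.InsertionSpec("lineB", "chr1", 13_000, "+", tsd_len=6,
                         promoter5="CMV", intron_present=True, copy_count=4),
]
sim = simlib.simulate_library(genome, specs,
                              simlib.LibraryParams(seed=7, molecules_per_copy=2))
res = pipeline.process_cohort(sim.reads, genome,
                              {"ref": ["ctrl"], "B": ["lineB"]}, "ref")
for key, call in res.classification.items():
    print(key, call.category)
print(res.abundance)
```

prints

```
chr1:3001:+ reference
chr1:8005:- nonreference_universal
chr1:13001:+ nonreference_universal
  sample_id          site  copy_number  rel_abundance
0      ctrl   chr1:3001:+            3       1.000000
1     lineB  chr1:13001:+            4       0.444444
2     lineB   chr1:3001:+            3       0.333333
3     lineB   chr1:8005:-            2       0.222222
```

Every planted junction is recovered at its exact coordinate (`position+1`
on plus, `position+tsd_len` on minus — the first host base 3′ of the LTR
terminus), the locus shared with the control sample is classified
reference, and copy numbers equal the planted clone counts with abundances
normalised per sample. With a single focal group, loci absent from the
control are "universal"; specific calls arise with two or more focal
groups.

A `retrosite` CLI wraps the same steps (`simulate`, `prep`, `call`,
`compare`, `report`); see `retrosite --help`.

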