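# Methods

This note documents the models behind `replaceseq`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Coordinates and cut-site model

All coordinates are 0-based, half-open; cut positions are inter-base.
SpyCas9 is modelled as cutting bluntly 3 nt 5′ of the NGG PAM, i.e. between
protospacer positions 17 and 18 (1-based protospacer numbering). Each break
therefore produces a *PAM side* (NGG plus protospacer nt 18–20) and a
*protospacer side* (nt 1–17). Staggered (1–2 nt 5′-overhang) cutting is
treated as a repair-time phenomenon: it never enters outcome enumeration,
only the junction-mutation model and the InDel callers.

## Outcome enumeration

A Replace design (locus, two guide sites with `cut_left < cut_right`,
linearized donor) splits the locus into fragments `l | m | r`. The eight
expected alleles are perfect ligations: `original` (`l+m+r`), `deletion`
(`l+r`), `replacement` (`l+D+r`, donor forward or reverse-complemented),
and the four donor `insertion` alleles at either cut with `m` retained.
"Forward" is the orientation the designer declares desired; the software
never infers intent. Every junction records its two side labels (pam /
protospacer) and the guide that made the local break; donor ends carry the
side labels the designer declares (a minicircle donor is itself linearized
by Cas9, so its ends are also pam or protospacer sides).

## Directional-design validation

A junction is *re-cleavable* if an intact protospacer+NGG for any design
guide lies, on either strand, within ±30 nt of the ligation point. The
window is a package choice: wide enough to cover a full 23-nt site plus
staggered-cut remnants, narrow enough not to count the undisturbed flanking
sites. The validator requires the designed replacement junctions to be
non-re-cleavable (error unless forced — a re-cuttable correct product
defeats the capture logic), and warns when the deletion or the inverted
replacement junctions fail to reform a cleavable site (those products would
then not be re-opened), when fewer than two distinct guides are used, when
sacrificial buffers are under 30 nt, and on degenerate toy geometries
(excision < 40 nt, donor < 50 nt) — warnings, not errors, so that small
test designs remain usable.

## The example design

`example_design()` builds the validation fixture used throughout the tests:
a 466-nt locus with two *identical* guide sites (same 20-nt protospacer,
'+' strand, AGG PAM) flanking a 120-nt segment — the geometry of a reporter
locus whose deletion junction reforms the complete target site — and a
160-nt donor emulating a minicircle linearized by the same guide, with
40-nt sacrificial buffers between the half-site remnants and a 57-nt cargo
core. The donor is supplied reverse-complemented relative to its raw
linearization because that is the orientation whose junctions do **not**
reconstitute the target: the designed-orientation junctions are
protospacer/protospacer and pam/pam chimeras, while the inverted integrant
and the deletion both reform the complete site. This reproduces the
directional behaviour computationally rather than asserting it.

## Junction-mutation model (generator)

Each ligated junction independently draws one of:

| event | probability (default) | effect |
|---|---|---|
| perfect ligation | `p_perfect` = 0.75 | none |
| +1 templated insertion | `p_stagger1` = 0.08 | duplicate protospacer nt 17 |
| +2 templated insertion | `p_stagger2` = 0.04 | duplicate protospacer nt 16–17 |
| deletion | remainder = 0.13 | Geometric(`del_geom_p` = 0.25) nt, support ≥ 1, from one uniformly chosen side |

Staggered-cut insertions are realized **only at pam/pam junctions** (the
fill-in model: only PAM-side ends carry the overhang); when the draw lands
on an insertion at any other junction the ligation is emitted blunt and
clean, i.e. the stagger mass folds into the perfect class rather than into
deletions. A 1-based-position-17 duplication convention is used for the +1
insertion (the direction of "next to the cut" is ambiguous in principle;
the PAM-side fill-in model fixes it PAM-distal).

Deletions additionally acquire, with probability `p_large_resection` = 0.03,
an Exponential(`large_resection_scale` = 80 nt) large-resection extension on
the same side — large resection is strongly asymmetric in this model (one
side of one junction per event). The scale is a deliberate rescaling of
"large" (> 500 bp on multi-kilobase amplicons with primers 800–2000 bp from
the cuts) to this package's desk-scale fixture, whose primers sit ~140 nt
from the cuts: resections beyond the primer distance would abolish
amplification altogether. With these defaults the small-deletion majority
is < 30 nt and whole-donor wipeout (which converts a replacement molecule
into a structural deletion) is rare (~0.4% of reads).

Sequencing error is off by default — the pipelines under test consume
consensus-grade reads — and available as a uniform substitution rate for
robustness testing. Quality strings are constant placeholders. One
`numpy.random.Generator` seeded from a single integer drives every draw;
the per-junction consumption order is documented in the source.

## Library geometries (generator)

**Long-read amplicons**: the full amplicon between two primers 30 nt from
the locus ends (~406-nt unedited amplicon). Class sampling weight is
`weight × exp(−alpha × amplicon_length)`; `alpha = 0` (default) disables
PCR length bias, positive values over-represent short amplicons, emulating
the two-primer protocol's known bias. Reads are emitted on either strand
(p = 0.5). No UMIs — the long-read protocol has none, so downstream counts
are read-level and bias-prone; this is a documented limitation, and the
single-primer pipeline is the quantitative one.

**Single-primer (tagmentation/LAM-style) libraries**: reads start at a
25-nt genomic anchor primer 47 nt upstream of the left cut and extend to a
per-molecule fragment endpoint, uniform in [250, 400] nt, truncated at a
340-nt read length. The fragment floor is chosen so every fragment spans
all class-discriminating junctions of the example design (the farthest sits
232 nt from the anchor): the pipeline requires junction coverage to
distinguish, e.g., replacement from donor insertion, and fragments below
that floor are structurally uninformative. Each molecule carries a random
10-mer UMI; PCR duplicates are identical reads.

**Donor-anchored libraries**: reads start at a 22-nt donor-internal primer
38 nt from the donor's ligated end and continue into on-target flank,
a planted off-target genomic locus, or another donor copy (head-to-tail or
head-to-head, uniform) with configurable probabilities (defaults 0.55 /
0.11 / 0.34). The synthetic genome is 3 × 1.2 Mb of uniform random sequence
with the target locus embedded in chromosome 1 and 293 predicted off-target
sites written as BED; the 28 planted integration loci are rejection-sampled
at least 6 kb from every predicted site (so a 5-kb proximity analysis has a
true count of zero) and away from the target locus.

What the generator does **not** emulate: instrument error profiles,
chimeric PCR artifacts other than donor concatemers, translocations and
chromosomal fusions, UMI sequencing errors, donor-end junction InDels on
donor-anchored reads, and real-genome repeat structure (the uniform random
genome makes 15-mer seeding nearly collision-free; real genomes would
produce multi-mapping flanks, which the pipeline reports as `unmapped
(multi)` but the tests do not exercise). Passing tests therefore
demonstrate correctness of the classification logic under clean structural
variation, not robustness to instrument noise or repetitive DNA.

## Classification

All classifiers share one affine-gap aligner (match +2, mismatch −4, gap
open −7, extend −1; a length-L gap costs open + (L−1)·extend), implemented
on `Bio.Align.PairwiseAligner` with an edit-distance prefilter (edlib) that
shortlists candidate references before affine scoring — the prefilter slack
(12 edit units) is far above any score-relevant margin. Ties between
co-optimal alignments resolve to the first alignment in the aligner's
deterministic enumeration order.

* **Long-read binning**: each read (both orientations) is scored against
  all eight expected amplicons; the best class wins, and a best-vs-runner-up
  margin below 10 score units yields `unclassified` rather than an
  arbitrary call. Junction InDels are alignment operations overlapping a
  ±20-nt window around each expected junction (one InDel → its type; more
  than one → `complex`); the window separates junction InDels from distal
  noise while capturing the < 30-nt resections that dominate. Junction
  deletions > 500 bp set the large-deletion flag. Reads shorter than 0.3 ×
  the shortest reference are `unclassified (short)`.
* **Single-primer assignment**: reads must begin with the anchor primer
  (≤ 2 mismatches, no InDels; otherwise discarded `off_primer`), are
  aligned semi-globally (reference 3′ overhang free), and junctions not
  spanned by ≥ 10 aligned nt on both sides are `not_covered` — counted for
  class, excluded from InDel statistics. Exact score ties (a read ending
  before the junction that discriminates two structures) resolve by
  parsimony: fewest junctions within the aligned span, then fewest
  junctions overall, then canonical class order. UMI conflicts resolve by
  strict majority; ties discard the molecule. No UMI error-clustering is
  performed (synthetic UMIs are exact); a Hamming-merge could be added for
  real data.
* **Integration mapping**: concatemer detection (flank prefix matches the
  donor start in either orientation, ≥ 90% identity over ≥ 20 nt) runs
  *before* genome mapping so donor-derived flanks cannot multi-map against
  the vector record. Genome mapping is exact 15-mer seed + edlib
  verification (≤ 10% errors); a best-score tie between distinct sites is
  `unmapped (multi)`. `on_target` means within 1000 nt of either embedded
  cut — generous, to absorb pre-junction resection. Flanks < 20 nt are
  unmappable (`short`); empty flanks are counted as vector/short ends.
  Clusters merge mapped positions within 100 nt; proximity to predicted
  sites is inclusive at the 5000-bp boundary. Category fractions are
  reported under both denominators (all measured donor reads, and
  genome-mapped reads only), since either convention is defensible for the
  concatemer question.

## Allele arithmetic

Ploidy conversion assumes editing events are independent across alleles
within a cell: `p = 1 − (1 − f_obs)^(1/n_from)` per allele, then
`f' = 1 − (1 − p)^(n_to)`, computed in the log domain (`log1p`) with a
saturation guard at `f_obs = 1`. The conversion round-trips to ~1e−8
(float error amplifies through the power near saturation). The dual-donor
homozygosity estimator assumes exactly two alleles and equal, independent
donor choice per knocked-in allele, giving `h = 2·f_double`; both
assumptions are stated here because the estimator is only as good as they
are (aneuploid lines or donor-uptake bias violate them). Percent reporting
rounds half away from zero to integer percent; raw fractions are always
retained. Ploidy is always a user input, never inferred.

## Problem sizes

The test and acceptance runs use the 466-nt example design, 5000-read
mixture-recovery runs per pipeline, a 3.6-Mb synthetic genome with 293
predicted sites and 28 planted loci (4000 donor-anchored reads), and 1e5
Monte-Carlo cells for the homozygosity estimator — sizes chosen so each
stochastic check sits at ≥ 3-standard-error resolution for the fractions it
measures while a full suite run stays in the minutes range on one CPU.
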