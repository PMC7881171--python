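"""Truth-tagged synthetic reads from a configurable mixture of Replace outcomes.

This generator is first-class code: it defines the study conditions under
which the three quantification pipelines are exercised. It emulates

* the enumerable outcome classes of two-cut Replace editing (original,
  deletion, replacement/insertion in both orientations),
* the junction-mutation spectrum at ligated interfaces: a majority of
  InDel-free ligations, templated +1/+2 insertions only where two PAM sides
  meet (staggered-cut fill-in), small geometric deletions with a rare
  exponential large-resection tail applied asymmetrically to one side,
* two library types: two-primer long amplicons (PCR length bias optional)
  and single gene-specific-primer libraries with UMIs and a random
  tagmentation/shear endpoint,
* a synthetic mini-genome with an embedded target locus, predicted
  off-target sites (BED) and planted off-target/concatemer donor
  integration events.

Sequencing error is off by default (the pipelines under test consume
consensus-grade reads); an optional uniform substitution rate is available
for robustness testing. Quality strings are constant placeholders.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .design import (
    OUTCOME_CLASSES,
    GuideSite,
    Junction,
    OutcomeAllele,
    ReplaceDesign,
    enumerate_outcomes,
)
from .dna import as_rng, random_dna, revcomp

QUAL_CHAR = "I"


@dataclass
class OutcomeMixture:
    """Mixture weights over outcome classes plus the junction-mutation model.

    ``p_perfect`` is the probability a ligated junction is InDel-free;
    ``p_stagger1``/``p_stagger2`` the probabilities of a 1-/2-nt templated
    duplication (realized only at junctions joining two PAM sides; at other
    junctions the draw yields a clean blunt ligation); the remaining mass is
    a deletion of Geometric(``del_geom_p``) nt (support >= 1) from one
    uniformly chosen side, extended with probability ``p_large_resection``
    by an Exponential(``large_resection_scale``) tail.
    """

    weights: dict = field(default_factory=lambda: {"replacement_fwd": 1.0})
    p_perfect: float = 0.75
    p_stagger1: float = 0.08
    p_stagger2: float = 0.04
    del_geom_p: float = 0.25
    p_large_resection: float = 0.03
    large_resection_scale: float = 80.0
    seq_error_rate: float = 0.0

    def __post_init__(self):
        for k in self.weights:
            if k not in OUTCOME_CLASSES:
                raise ValueError(f"unknown outcome class {k!r}")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("mixture weights must sum to a positive value")
        self.weights = {k: v / total for k, v in self.weights.items() if v > 0}
        probs = [self.p_perfect, self.p_stagger1, self.p_stagger2,
                 self.p_large_resection, self.seq_error_rate]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.p_perfect + self.p_stagger1 + self.p_stagger2 > 1 + 1e-9:
            raise ValueError("p_perfect + p_stagger1 + p_stagger2 must be <= 1")
        if not 0 < self.del_geom_p <= 1:
            raise ValueError("del_geom_p must lie in (0, 1]")

    def class_probs(self) -> tuple[list[str], np.ndarray]:
        classes = [k for k in OUTCOME_CLASSES if k in self.weights]
        p = np.array([self.weights[k] for k in classes], dtype=float)
        return classes, p / p.sum()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "OutcomeMixture":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ReadRecord:
    """A sequencing read, optionally UMI-tagged and truth-tagged."""

    id: str
    sequence: str
    qualities: str = ""
    umi: str | None = None
    truth: dict | None = None

    def __post_init__(self):
        if not self.qualities:
            self.qualities = QUAL_CHAR * len(self.sequence)


@dataclass
class JunctionEdit:
    """Truth record of what happened to one junction during ligation."""

    junction_index: int
    type: str  # none | insertion | deletion
    size: int = 0
    side: str | None = None  # left | right (deletions)
    inserted: str | None = None


def staggered_insertion(guide: GuideSite, overhang_len: int) -> str:
    """Templated duplication left by a staggered Cas9 cut after fill-in.

    SpyCas9 sometimes leaves a 1-2 nt 5' overhang on the PAM side of the
    break; repair fills it in, duplicating the protospacer base(s)
    immediately PAM-distal to the canonical cut. Convention used here:
    protospacer position 17 (1-based) for a 1-nt overhang, positions 16-17
    for a 2-nt overhang. The duplication becomes a junction insertion when
    two PAM sides are ligated.
    """
    if overhang_len == 1:
        return guide.protospacer[16:17]
    if overhang_len == 2:
        return guide.protospacer[15:17]
    raise ValueError("overhang_len must be 1 or 2")


def _junction_guide(junction: Junction, side: str) -> GuideSite:
    primary = junction.left if side == "left" else junction.right
    other = junction.right if side == "left" else junction.left
    return primary.guide or other.guide


def _draw_junction_edit(
    junction: Junction, mixture: OutcomeMixture, rng: np.random.Generator
) -> JunctionEdit:
    """One junction-fate draw. RNG consumption order: one uniform for the
    category; staggered insertions draw one integer (guide side); deletions
    draw one integer (side), one geometric, one uniform and - if the large
    tail fires - one exponential."""
    u = rng.random()
    if u < mixture.p_perfect:
        return JunctionEdit(junction_index=-1, type="none")
    if u < mixture.p_perfect + mixture.p_stagger1 + mixture.p_stagger2:
        k = 1 if u < mixture.p_perfect + mixture.p_stagger1 else 2
        side = "left" if rng.integers(2) == 0 else "right"
        if not junction.is_pam_pam:
            # no overhang available: blunt ligation
            return JunctionEdit(junction_index=-1, type="none")
        guide = _junction_guide(junction, side)
        return JunctionEdit(
            junction_index=-1, type="insertion", size=k,
            inserted=staggered_insertion(guide, k), side=side,
        )
    side = "left" if rng.integers(2) == 0 else "right"
    size = int(rng.geometric(mixture.del_geom_p))
    if rng.random() < mixture.p_large_resection:
        size += max(1, int(round(rng.exponential(mixture.large_resection_scale))))
    return JunctionEdit(junction_index=-1, type="deletion", size=size, side=side)


def mutate_junction(
    allele: OutcomeAllele,
    junction_index: int,
    mixture: OutcomeMixture,
    rng_seed,
) -> tuple[str, JunctionEdit]:
    """Apply the junction-mutation model to one junction of *allele*.

    Returns the mutated full-allele sequence and the truth record.
    Deletions are clamped at the sequence bounds (recorded size is the
    realized size).
    """
    if not 0 <= junction_index < len(allele.junctions):
        raise IndexError(
            f"junction_index {junction_index} invalid; allele {allele.klass} "
            f"has junction indices 0..{len(allele.junctions) - 1}"
        )
    rng = as_rng(rng_seed)
    seq, edits = _apply_edits(
        allele.sequence, [allele.junctions[junction_index]], mixture, rng,
        indices=[junction_index],
    )
    return seq, edits[0]


def _apply_edits(
    sequence: str,
    junctions: list[Junction],
    mixture: OutcomeMixture,
    rng: np.random.Generator,
    indices: list[int] | None = None,
) -> tuple[str, list[JunctionEdit]]:
    """Mutate every listed junction; right-to-left so positions stay valid."""
    if indices is None:
        indices = list(range(len(junctions)))
    edits: list[JunctionEdit] = []
    drawn = [_draw_junction_edit(j, mixture, rng) for j in junctions]
    seq = sequence
    for idx, junction, edit in sorted(
        zip(indices, junctions, drawn), key=lambda t: -t[1].position
    ):
        edit.junction_index = idx
        pos = junction.position
        if edit.type == "insertion":
            seq = seq[:pos] + edit.inserted + seq[pos:]
        elif edit.type == "deletion":
            if edit.side == "left":
                lo = max(0, pos - edit.size)
                edit.size = pos - lo
                seq = seq[:lo] + seq[pos:]
            else:
                hi = min(len(seq), pos + edit.size)
                edit.size = hi - pos
                seq = seq[:pos] + seq[hi:]
        edits.append(edit)
    edits.sort(key=lambda e: e.junction_index)
    return seq, edits


def _add_seq_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _edits_to_str(edits: list[JunctionEdit]) -> str:
    parts = []
    for e in edits:
        if e.type == "none":
            parts.append(f"j{e.junction_index}:none")
        elif e.type == "insertion":
            parts.append(f"j{e.junction_index}:ins{e.size}:{e.inserted}")
        else:
            parts.append(f"j{e.junction_index}:del{e.size}:{e.side}")
    return ";".join(parts) if parts else "."


def simulate_longread(
    design: ReplaceDesign,
    mixture: OutcomeMixture,
    n_reads: int,
    primer_left_offset: int = 30,
    primer_right_offset: int | None = None,
    length_bias_alpha: float = 0.0,
    seed=0,
    p_revcomp: float = 0.5,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Two-primer long-amplicon reads spanning both cuts.

    Each read is the full amplicon between the primer positions of one
    mutated outcome allele. Sampling weight of class k is
    ``weight_k * exp(-length_bias_alpha * amplicon_length_k)``, so
    ``length_bias_alpha=0`` disables PCR length bias and positive values
    over-represent shorter amplicons. Reads are emitted on the reverse
    strand with probability ``p_revcomp``. Deterministic under *seed*.
    """
    rng = as_rng(seed)
    locus_len = len(design.locus_seq)
    if primer_right_offset is None:
        primer_right_offset = locus_len - 30
    if not (primer_left_offset < design.cut_left
            and primer_right_offset > design.cut_right
            and 0 <= primer_left_offset and primer_right_offset <= locus_len):
        raise ValueError("primer offsets must flank both cuts within the locus")
    right_tail = locus_len - primer_right_offset

    outcomes = {al.klass: al for al in enumerate_outcomes(design)}
    classes, base_p = mixture.class_probs()
    amp_len = np.array(
        [len(outcomes[k].sequence) - primer_left_offset - right_tail for k in classes],
        dtype=float,
    )
    w = base_p * np.exp(-length_bias_alpha * amp_len)
    w /= w.sum()

    reads: list[ReadRecord] = []
    rows = []
    draws = rng.choice(len(classes), size=n_reads, p=w)
    for i, ki in enumerate(draws):
        klass = classes[ki]
        allele = outcomes[klass]
        seq, edits = _apply_edits(allele.sequence, list(allele.junctions), mixture, rng)
        amp = seq[primer_left_offset : len(seq) - right_tail]
        amp = _add_seq_errors(amp, mixture.seq_error_rate, rng)
        strand = "-" if rng.random() < p_revcomp else "+"
        out_seq = revcomp(amp) if strand == "-" else amp
        rid = f"lr{i:06d}"
        truth = {
            "read_id": rid,
            "klass": klass,
            "orientation": allele.orientation,
            "strand": strand,
            "edits": _edits_to_str(edits),
            "length": len(out_seq),
        }
        reads.append(ReadRecord(id=rid, sequence=out_seq, truth=truth))
        rows.append(truth)
    return reads, pd.DataFrame(rows)


def default_anchor(design: ReplaceDesign, anchor_len: int = 25, gap: int = 47) -> str:
    """Genomic anchor primer ending *gap* nt upstream of the left cut."""
    start = design.cut_left - gap - anchor_len
    if start < 0:
        raise ValueError("locus too short for the requested anchor placement")
    return design.locus_seq[start : start + anchor_len]


def simulate_linamp(
    design: ReplaceDesign,
    mixture: OutcomeMixture,
    n_reads: int,
    anchor: str = "genomic_primer",
    umi_len: int = 10,
    read_len: int = 340,
    frag_min: int = 250,
    frag_max: int = 400,
    mean_reads_per_molecule: float = 1.0,
    seed=0,
    anchor_primer: str | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Single gene-specific-primer (tagmentation/LAM-style) library.

    Reads start at the genomic anchor primer upstream of the left cut and
    extend a random shear/tagmentation-determined distance (uniform in
    [frag_min, frag_max]) across the junction, truncated at *read_len*.
    Each original molecule carries a random ``umi_len``-mer UMI and a single
    fragment endpoint; PCR duplicates of a molecule are identical reads.
    """
    if anchor != "genomic_primer":
        raise ValueError(
            "simulate_linamp generates genomic-anchored libraries; use "
            "simulate_donor_anchored for donor-primer runs"
        )
    rng = as_rng(seed)
    if anchor_primer is None:
        anchor_primer = default_anchor(design)
    anchor_start = design.locus_seq.find(anchor_primer)
    if anchor_start < 0 or design.locus_seq.find(anchor_primer, anchor_start + 1) >= 0:
        raise ValueError("anchor primer absent or ambiguous in the locus")
    if anchor_start + len(anchor_primer) > design.cut_left:
        raise ValueError("anchor primer must lie fully upstream of the left cut")

    outcomes = {al.klass: al for al in enumerate_outcomes(design)}
    classes, w = mixture.class_probs()

    reads: list[ReadRecord] = []
    rows = []
    mol = 0
    while len(reads) < n_reads:
        klass = classes[rng.choice(len(classes), p=w)]
        allele = outcomes[klass]
        seq, edits = _apply_edits(allele.sequence, list(allele.junctions), mixture, rng)
        umi = random_dna(rng, umi_len)
        frag = int(rng.integers(frag_min, frag_max + 1))
        mol_seq = seq[anchor_start : anchor_start + min(frag, read_len)]
        mol_seq = _add_seq_errors(mol_seq, mixture.seq_error_rate, rng)
        if mean_reads_per_molecule <= 1.0:
            k = 1
        else:
            k = 1 + int(rng.poisson(mean_reads_per_molecule - 1.0))
        k = min(k, n_reads - len(reads))
        for _ in range(k):
            rid = f"la{len(reads):06d}"
            truth = {
                "read_id": rid,
                "molecule_id": f"mol{mol:06d}",
                "umi": umi,
                "klass": klass,
                "orientation": allele.orientation,
                "edits": _edits_to_str(edits),
                "length": len(mol_seq),
            }
            reads.append(ReadRecord(id=rid, sequence=mol_seq, umi=umi, truth=truth))
            rows.append(truth)
        mol += 1
    return reads, pd.DataFrame(rows)


@dataclass
class SyntheticGenome:
    """Random mini-genome with an embedded target locus and planted events."""

    chromosomes: dict  # name -> sequence
    predicted_offtargets: list  # [(chrom, pos), ...]
    locus_chrom: str | None = None
    locus_pos: int | None = None  # position of locus_seq[0] in locus_chrom
    planted_events: list = field(default_factory=list)  # (chrom, pos, type)

    def chrom_names(self) -> list[str]:
        return list(self.chromosomes)

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.chromosomes[chrom][max(0, start) : end]
        return revcomp(seq) if strand == "-" else seq


def simulate_genome(
    n_chrom: int = 3,
    chrom_len: int = 1_200_000,
    n_offtarget_sites: int = 293,
    seed=0,
    design: ReplaceDesign | None = None,
) -> SyntheticGenome:
    """Random-sequence chromosomes with predicted off-target sites.

    If *design* is given, its locus is embedded into chromosome 1 (replacing
    a same-length slice at one third of its length) and recorded as the
    on-target event. Reproducible under *seed*.
    """
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10 kb")
    rng = as_rng(seed)
    chroms = {f"chr{i + 1}": random_dna(rng, chrom_len) for i in range(n_chrom)}
    genome = SyntheticGenome(chromosomes=chroms, predicted_offtargets=[])
    if design is not None:
        name = "chr1"
        pos = chrom_len // 3
        locus = design.locus_seq
        chroms[name] = chroms[name][:pos] + locus + chroms[name][pos + len(locus) :]
        genome.locus_chrom = name
        genome.locus_pos = pos
        genome.planted_events.append((name, pos + design.cut_left, "on_target"))
    names = sorted(chroms)
    sites = []
    for _ in range(n_offtarget_sites):
        c = names[int(rng.integers(len(names)))]
        p = int(rng.integers(0, chrom_len - 23))
        sites.append((c, p))
    genome.predicted_offtargets = sorted(sites)
    return genome


def plant_offtarget_loci(
    genome: SyntheticGenome,
    n_loci: int = 28,
    min_predicted_distance: int = 6000,
    min_locus_distance: int = 20_000,
    seed=0,
) -> list[tuple[str, int, str]]:
    """Choose donor integration loci away from predicted sites and the target.

    Rejection-samples ``(chrom, pos, strand)`` triples at least
    ``min_predicted_distance`` from every predicted off-target site (so a
    proximity analysis at 5 kb finds nothing) and away from the embedded
    locus. Loci are recorded in ``genome.planted_events``.
    """
    rng = as_rng(seed)
    names = genome.chrom_names()
    by_chrom: dict[str, np.ndarray] = {}
    for c, p in genome.predicted_offtargets:
        by_chrom.setdefault(c, []).append(p)
    by_chrom = {c: np.array(sorted(v)) for c, v in by_chrom.items()}
    loci: list[tuple[str, int, str]] = []
    attempts = 0
    while len(loci) < n_loci:
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("could not place off-target loci; genome too crowded")
        c = names[int(rng.integers(len(names)))]
        clen = len(genome.chromosomes[c])
        p = int(rng.integers(500, clen - 500))
        sites = by_chrom.get(c)
        if sites is not None and sites.size:
            if np.min(np.abs(sites - p)) <= min_predicted_distance:
                continue
        if (
            genome.locus_chrom == c
            and genome.locus_pos is not None
            and abs(p - genome.locus_pos) < min_locus_distance
        ):
            continue
        if any(lc == c and abs(lp - p) < 1000 for lc, lp, _ in loci):
            continue
        strand = "+" if rng.integers(2) == 0 else "-"
        loci.append((c, p, strand))
        genome.planted_events.append((c, p, "off_target_integration"))
    return loci


def donor_primer_and_terminal(
    design: ReplaceDesign, primer_len: int = 22, terminal_len: int = 38
) -> tuple[str, str]:
    """Donor-anchored primer near the donor's right (ligated) end and the
    terminal donor segment between primer and end."""
    D = design.donor_seq
    if len(D) < primer_len + terminal_len + 5:
        raise ValueError("donor too short for the requested primer geometry")
    primer = D[-(primer_len + terminal_len) : -terminal_len]
    terminal = D[-terminal_len:]
    return primer, terminal


def simulate_donor_anchored(
    design: ReplaceDesign,
    genome: SyntheticGenome,
    n_reads: int,
    p_offtarget: float = 0.11,
    p_concat: float = 0.34,
    n_offtarget_loci: int = 28,
    umi_len: int = 10,
    read_len: int = 220,
    frag_min: int = 110,
    frag_max: int = 260,
    mean_reads_per_molecule: float = 1.0,
    min_predicted_distance: int = 6000,
    seed=0,
) -> tuple[list[ReadRecord], pd.DataFrame, list[tuple[str, int, str]]]:
    """Donor-primer library for integration-site mapping.

    Reads start at a donor-internal primer pointing across the donor's right
    ligated end. With probability ``p_concat`` the read continues into
    another donor copy (head-to-tail or head-to-head, uniform); with
    ``p_offtarget`` into one of ``n_offtarget_loci`` planted genomic
    integration loci; otherwise into the genomic flank at the embedded
    target locus (on-target). Returns reads, truth table and planted loci.
    """
    if genome.locus_pos is None:
        raise ValueError("genome must embed the design locus (simulate_genome(design=...))")
    if p_offtarget + p_concat > 1:
        raise ValueError("p_offtarget + p_concat must be <= 1")
    rng = as_rng(seed)
    primer, terminal = donor_primer_and_terminal(design)
    loci = plant_offtarget_loci(
        genome, n_offtarget_loci, min_predicted_distance, seed=rng
    )
    on_flank_start = genome.locus_pos + design.cut_right
    D = design.donor_seq
    need = read_len + 10

    reads: list[ReadRecord] = []
    rows = []
    mol = 0
    while len(reads) < n_reads:
        u = rng.random()
        if u < p_concat:
            category = "concatemer"
            head_to_tail = rng.integers(2) == 0
            flank = (D * 3)[:need] if head_to_tail else (revcomp(D) * 3)[:need]
            detail = "head_to_tail" if head_to_tail else "head_to_head"
            chrom, pos, strand = ".", -1, "."
        elif u < p_concat + p_offtarget:
            category = "off_target"
            chrom, pos, strand = loci[int(rng.integers(len(loci)))]
            flank = genome.fetch(chrom, pos, pos + need) if strand == "+" else \
                genome.fetch(chrom, pos - need, pos, "-")
            detail = "."
        else:
            category = "on_target"
            chrom, pos, strand = genome.locus_chrom, on_flank_start, "+"
            flank = genome.fetch(chrom, pos, pos + need)
            detail = "."
        umi = random_dna(rng, umi_len)
        frag = int(rng.integers(frag_min, frag_max + 1))
        mol_seq = (primer + terminal + flank)[: min(frag, read_len)]
        if mean_reads_per_molecule <= 1.0:
            k = 1
        else:
            k = 1 + int(rng.poisson(mean_reads_per_molecule - 1.0))
        k = min(k, n_reads - len(reads))
        for _ in range(k):
            rid = f"da{len(reads):06d}"
            truth = {
                "read_id": rid,
                "molecule_id": f"mol{mol:06d}",
                "umi": umi,
                "category": category,
                "detail": detail,
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "length": len(mol_seq),
            }
            reads.append(ReadRecord(id=rid, sequence=mol_seq, umi=umi, truth=truth))
            rows.append(truth)
        mol += 1
    return reads, pd.DataFrame(rows), loci
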