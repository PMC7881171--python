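"""Pipeline 1: outcome quantification from single gene-specific-primer libraries.

UDiTaS/LAM-style libraries amplify across the break from one anchored primer
regardless of the repair outcome, so they measure all structural variants
approximately equally (no two-primer length bias). This module builds the
in-silico expected reference for every reachable outcome, assigns each read
to its best reference by semi-global affine alignment (reference 3' overhang
free, since reads end at a random tagmentation/shear point), calls junction
InDels on reads that actually span a junction, and tallies unique UMIs so
that molecules - not PCR duplicates - are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .design import ReplaceDesign, enumerate_outcomes
from .dna import hamming
from .longread import (
    JUNCTION_WINDOW,
    MIN_SCORE_MARGIN,
    _attach_inserted_seq,
    _junction_calls,
)
from .pairwise import DEFAULT_SCORING, Scoring, align_pair, align_score
from .simulate import ReadRecord

logger = logging.getLogger(__name__)

MIN_JUNCTION_OVERLAP = 10
MAX_PRIMER_MISMATCHES = 2
_EDLIB_SLACK = 12


@dataclass
class ExpectedReference:
    """In-silico reconstructed amplicon for one outcome, from the anchor primer."""

    klass: str
    sequence: str
    junctions: list  # positions relative to reference start

    @property
    def orientation(self) -> str:
        if self.klass.endswith("_fwd"):
            return "fwd"
        if self.klass.endswith("_rev"):
            return "rev"
        return "n/a"


@dataclass
class ReadAssignment:
    read_id: str
    status: str  # assigned | unclassified | off_primer
    klass: str = ""
    umi: str | None = None
    score: float = float("nan")
    margin: float = float("nan")
    junction_calls: list = field(default_factory=list)
    reason: str = ""


def build_expected_references(
    design: ReplaceDesign,
    anchor_primer: str,
    max_ref_len: int | None = None,
) -> list[ExpectedReference]:
    """One reference per outcome reachable from the genomic anchor primer.

    The anchor must map uniquely, fully upstream of the left cut. References
    are the outcome sequences clipped to *max_ref_len* from the anchor
    (default: farthest junction offset + 300 nt, bounding alignment cost
    while exceeding read length).
    """
    locus = design.locus_seq
    start = locus.find(anchor_primer)
    if start < 0:
        raise ValueError("anchor primer not found in locus")
    if locus.find(anchor_primer, start + 1) >= 0:
        raise ValueError("anchor primer ambiguous in locus")
    if start + len(anchor_primer) > design.cut_left:
        raise ValueError("anchor primer must lie fully upstream of the left cut")
    refs = []
    alleles = enumerate_outcomes(design)
    if max_ref_len is None:
        far = max(
            (j.position - start for al in alleles for j in al.junctions),
            default=0,
        )
        max_ref_len = far + 300
    for al in alleles:
        seq = al.sequence[start : start + max_ref_len]
        junctions = [
            j.position - start for j in al.junctions if j.position - start < len(seq)
        ]
        refs.append(ExpectedReference(al.klass, seq, junctions))
    return refs


_CLASS_ORDER = {k: i for i, k in enumerate(
    ("original", "deletion", "replacement_fwd", "replacement_rev",
     "insertion_up_fwd", "insertion_up_rev", "insertion_down_fwd",
     "insertion_down_rev"))}


def _class_rank(klass: str) -> int:
    return _CLASS_ORDER.get(klass, len(_CLASS_ORDER))


def _primer_matches(seq: str, primer: str, max_mm: int = MAX_PRIMER_MISMATCHES) -> bool:
    if len(seq) < len(primer):
        return False
    return hamming(seq[: len(primer)], primer) <= max_mm


def assign_and_call(
    reads,
    references: list[ExpectedReference],
    anchor_primer: str,
    min_junction_overlap: int = MIN_JUNCTION_OVERLAP,
    min_score_margin: float = MIN_SCORE_MARGIN,
    junction_window: int = JUNCTION_WINDOW,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[ReadAssignment]:
    """Assign each read to its best expected reference and call junction InDels.

    Reads not beginning with the anchor primer (<= 2 mismatches, no InDels)
    are discarded as ``off_primer``. Junctions not spanned by at least
    *min_junction_overlap* aligned bases on both sides are ``not_covered``:
    the read still counts for its class but is excluded from InDel
    statistics at that junction.
    """
    if not references:
        raise ValueError("references must be non-empty")
    out = []
    for read in reads:
        seq = read.sequence if isinstance(read, ReadRecord) else str(read)
        rid = read.id if isinstance(read, ReadRecord) else "read"
        umi = read.umi if isinstance(read, ReadRecord) else None
        if not _primer_matches(seq, anchor_primer):
            out.append(ReadAssignment(rid, "off_primer", umi=umi, reason="off-primer"))
            continue
        # shortlist by prefix edit distance (read vs reference prefix)
        cand = []
        for ref in references:
            d = edlib.align(seq, ref.sequence, mode="SHW", task="distance")["editDistance"]
            cand.append((d, ref))
        best_d = min(d for d, _ in cand)
        short = [(d, r) for d, r in cand if d <= best_d + _EDLIB_SLACK]
        scored = []
        for d, ref in short:
            sc = align_score(seq, ref.sequence, scoring, free_ref_right=True)
            scored.append((sc, ref))
        scored.sort(key=lambda t: (-t[0], t[1].klass))
        best_sc = scored[0][0]
        tied = [ref for sc, ref in scored if sc == best_sc]
        aln = None
        if len(tied) > 1:
            # exact ties arise when the read ends before the junction that
            # would discriminate two structures (e.g. replacement vs donor
            # insertion, or original vs downstream insertion). Resolve by
            # parsimony: fewest junctions within the aligned span, then
            # fewest junctions overall, then canonical class order.
            ranked = []
            for ref in tied:
                a = align_pair(seq, ref.sequence, scoring, free_ref_right=True,
                               query_id=rid, reference_id=ref.klass)
                n_cov = sum(1 for j in ref.junctions if j < a.reference_end)
                ranked.append(((n_cov, len(ref.junctions), _class_rank(ref.klass)),
                               ref, a))
            ranked.sort(key=lambda t: t[0])
            best_ref, aln = ranked[0][1], ranked[0][2]
            next_scores = [sc for sc, ref in scored if ref.klass != best_ref.klass
                           and sc < best_sc]
            margin = best_sc - next_scores[0] if next_scores else float("inf")
        else:
            best_ref = scored[0][1]
            margin = best_sc - scored[1][0] if len(scored) > 1 else float("inf")
        if margin < min_score_margin:
            out.append(
                ReadAssignment(rid, "unclassified", umi=umi, score=best_sc,
                               margin=margin, reason="ambiguous")
            )
            continue
        if aln is None:
            aln = align_pair(
                seq, best_ref.sequence, scoring, free_ref_right=True,
                query_id=rid, reference_id=best_ref.klass,
            )
        span = (aln.reference_start, aln.reference_end)
        calls = _junction_calls(
            aln, best_ref.junctions, junction_window,
            covered_span=span, min_overlap=min_junction_overlap,
        )
        _attach_inserted_seq(calls, aln, seq, best_ref.junctions, junction_window)
        out.append(
            ReadAssignment(
                rid, "assigned", klass=best_ref.klass, umi=umi,
                score=best_sc, margin=margin, junction_calls=calls,
            )
        )
    return out


@dataclass
class OutcomeTable:
    """Molecule-level (unique-UMI) tally of outcome classes with InDel breakdown."""

    counts: dict  # klass -> n molecules
    n_molecules: int
    counted_by: str  # "umi" or "read"
    n_reads_assigned: int
    n_discarded_umis: int = 0
    junction_breakdown: dict = field(default_factory=dict)
    # klass -> [per junction: {"none": n, "insertion": n, "deletion": n,
    #           "complex": n, "not_covered": n, "sizes": {size: n}}]

    @property
    def fractions(self) -> dict:
        if self.n_molecules == 0:
            return {}
        return {k: v / self.n_molecules for k, v in self.counts.items()}


def tally_umis(assignments: list[ReadAssignment]) -> OutcomeTable:
    """Collapse assigned reads to unique molecules by UMI.

    A UMI observed with conflicting classes is resolved by strict majority;
    ties are discarded. Junction InDel breakdown is taken from one
    representative read (lowest read id) of the majority class per molecule.
    When no UMIs are present the tally falls back to read counting with a
    logged warning (LAM libraries carry no UMIs).
    """
    assigned = [a for a in assignments if a.status == "assigned"]
    have_umis = assigned and all(a.umi for a in assigned)
    if not have_umis:
        if assigned and any(a.umi for a in assigned):
            raise ValueError("mixed UMI presence across reads")
        logger.warning("no UMIs present; falling back to read-level counting")
        groups = {a.read_id: [a] for a in assigned}
        counted_by = "read"
    else:
        groups = {}
        for a in assigned:
            groups.setdefault(a.umi, []).append(a)
        counted_by = "umi"

    counts: dict[str, int] = {}
    breakdown: dict[str, list] = {}
    discarded = 0
    for _, group in sorted(groups.items()):
        votes: dict[str, int] = {}
        for a in group:
            votes[a.klass] = votes.get(a.klass, 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            discarded += 1
            continue
        klass = ranked[0][0]
        counts[klass] = counts.get(klass, 0) + 1
        rep = min(
            (a for a in group if a.klass == klass), key=lambda a: a.read_id
        )
        slots = breakdown.setdefault(
            klass,
            [
                {"none": 0, "insertion": 0, "deletion": 0, "complex": 0,
                 "not_covered": 0, "sizes": {}}
                for _ in rep.junction_calls
            ],
        )
        for slot, call in zip(slots, rep.junction_calls):
            slot[call.type] += 1
            if call.type in ("insertion", "deletion") and call.size:
                slot["sizes"][call.size] = slot["sizes"].get(call.size, 0) + 1
    return OutcomeTable(
        counts=counts,
        n_molecules=sum(counts.values()),
        counted_by=counted_by,
        n_reads_assigned=len(assigned),
        n_discarded_umis=discarded,
        junction_breakdown=breakdown,
    )


def outcome_report(table: OutcomeTable) -> dict:
    """Per-class fractions, fwd:rev ratios and InDel-free fractions per junction."""
    fractions = table.fractions
    ratios = {}
    for stem in ("replacement", "insertion_up", "insertion_down"):
        fwd = table.counts.get(f"{stem}_fwd", 0)
        rev = table.counts.get(f"{stem}_rev", 0)
        if fwd + rev:
            ratios[stem] = {
                "fwd": fwd,
                "rev": rev,
                "fwd_fraction": fwd / (fwd + rev),
                "fwd_to_rev": (fwd / rev) if rev else float("inf"),
            }
    indel_free = {}
    for klass, slots in table.junction_breakdown.items():
        per_j = []
        for slot in slots:
            covered = sum(slot[k] for k in ("none", "insertion", "deletion", "complex"))
            per_j.append(
                {
                    "indel_free_fraction": slot["none"] / covered if covered else None,
                    "n_none": slot["none"],
                    "n_covered": covered,
                    "n_not_covered": slot["not_covered"],
                }
            )
        indel_free[klass] = per_j
    return {
        "counted_by": table.counted_by,
        "n_molecules": table.n_molecules,
        "n_reads_assigned": table.n_reads_assigned,
        "n_discarded_umis": table.n_discarded_umis,
        "class_counts": dict(sorted(table.counts.items())),
        "class_fractions": dict(sorted(fractions.items())),
        "orientation_ratios": ratios,
        "junction_indel_free": indel_free,
        "junction_breakdown": {
            k: [
                {kk: (dict(sorted(vv.items())) if kk == "sizes" else vv)
                 for kk, vv in slot.items()}
                for slot in slots
            ]
            for k, slots in sorted(table.junction_breakdown.items())
        },
    }
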