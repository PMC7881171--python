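"""Long-read amplicon structural-variant classification ("Pipeline Longread").

Full-length two-primer amplicon reads are binned into the enumerable Replace
outcome classes by aligning each read against the expected amplicon of every
outcome (both read orientations) and taking the best affine-gap score; an
ambiguous best/runner-up margin yields ``unclassified`` rather than an
arbitrary call. Junction InDels are extracted from alignment operations
within a +/-20 nt window of each expected junction. Per-base deletion
profiles and InDel-free ligation fractions are computed over the assigned
reads.

Reads are not UMI-deduplicated here: the long-read protocol has no UMIs, so
counts are read-level and subject to PCR length bias (a documented
limitation of the two-primer protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .design import DONOR_CLASSES, ReplaceDesign, enumerate_outcomes
from .dna import revcomp
from .pairwise import DEFAULT_SCORING, Alignment, Scoring, align_pair, align_score
from .simulate import ReadRecord

JUNCTION_WINDOW = 20
LARGE_DEL_THRESHOLD = 500
MIN_SCORE_MARGIN = 10.0
MIN_READ_FRAC = 0.3
_EDLIB_SLACK = 12  # candidate filter: edit distance within best+slack


@dataclass
class ReferenceAmplicon:
    """Expected amplicon of one outcome class, with junction coordinates."""

    klass: str
    sequence: str
    junctions: list  # junction positions in amplicon coordinates
    junction_sides: list = field(default_factory=list)  # (left_kind, right_kind)

    @property
    def orientation(self) -> str:
        if self.klass.endswith("_fwd"):
            return "fwd"
        if self.klass.endswith("_rev"):
            return "rev"
        return "n/a"


@dataclass
class JunctionCall:
    type: str  # none | insertion | deletion | complex | not_covered
    size: int = 0
    inserted: str | None = None


@dataclass
class StructuralCall:
    """Per-read classification result."""

    read_id: str
    klass: str  # outcome class or "unclassified"
    orientation: str = "n/a"
    junction_indels: list = field(default_factory=list)
    large_deletion: bool = False
    read_strand: str = "+"
    score: float = float("nan")
    margin: float = float("nan")
    reason: str = ""
    alignment: Alignment | None = None


def amplicon_references(
    design: ReplaceDesign,
    primer_left_offset: int = 30,
    primer_right_offset: int | None = None,
) -> list[ReferenceAmplicon]:
    """Expected amplicons between the two primers for all 8 outcomes."""
    locus_len = len(design.locus_seq)
    if primer_right_offset is None:
        primer_right_offset = locus_len - 30
    right_tail = locus_len - primer_right_offset
    refs = []
    for al in enumerate_outcomes(design):
        seq = al.sequence[primer_left_offset : len(al.sequence) - right_tail]
        junctions = [j.position - primer_left_offset for j in al.junctions]
        sides = [(j.left.kind, j.right.kind) for j in al.junctions]
        refs.append(ReferenceAmplicon(al.klass, seq, junctions, sides))
    return refs


def _junction_calls(
    aln: Alignment,
    junctions: list[int],
    junction_window: int = JUNCTION_WINDOW,
    covered_span: tuple[int, int] | None = None,
    min_overlap: int = 0,
) -> list[JunctionCall]:
    """Attribute alignment InDels to expected junctions.

    An InDel is attributed to a junction if it overlaps the +/-window
    interval at all. Multiple InDels (or both kinds) at one junction are
    ``complex``. If *covered_span* is given, junctions not flanked by at
    least *min_overlap* aligned reference bases on both sides are
    ``not_covered``.
    """
    indels = list(aln.indels())
    calls = []
    for j in junctions:
        if covered_span is not None:
            lo, hi = covered_span
            if j - min_overlap < lo or j + min_overlap > hi:
                calls.append(JunctionCall("not_covered"))
                continue
        here = []
        for op, rpos, n, qpos in indels:
            if op == "deletion":
                if rpos <= j + junction_window and rpos + n >= j - junction_window:
                    here.append((op, rpos, n, qpos))
            else:
                if j - junction_window <= rpos <= j + junction_window:
                    here.append((op, rpos, n, qpos))
        if not here:
            calls.append(JunctionCall("none"))
        elif len(here) == 1:
            op, rpos, n, qpos = here[0]
            calls.append(JunctionCall(op, size=n))
        else:
            calls.append(JunctionCall("complex", size=sum(h[2] for h in here)))
    return calls


def _attach_inserted_seq(calls: list[JunctionCall], aln: Alignment, query: str,
                         junctions: list[int], junction_window: int) -> None:
    indels = list(aln.indels())
    for call, j in zip(calls, junctions):
        if call.type != "insertion":
            continue
        for op, rpos, n, qpos in indels:
            if op == "insertion" and j - junction_window <= rpos <= j + junction_window:
                call.inserted = query[qpos : qpos + n]
                break


def classify_read(
    read,
    references: list[ReferenceAmplicon],
    min_score_margin: float = MIN_SCORE_MARGIN,
    junction_window: int = JUNCTION_WINDOW,
    large_del_threshold: int = LARGE_DEL_THRESHOLD,
    min_read_frac: float = MIN_READ_FRAC,
    scoring: Scoring = DEFAULT_SCORING,
) -> StructuralCall:
    """Assign a read to its best-scoring expected amplicon.

    Both read orientations are tried (classification is invariant to
    reverse-complementing the input). Candidate references are shortlisted
    by edit distance, then ranked by affine-gap score; if the best and
    runner-up class scores differ by less than *min_score_margin* the read
    is ``unclassified``. Junction InDels are read off the winning alignment.
    """
    if not references:
        raise ValueError("references must be non-empty")
    seq = read.sequence if isinstance(read, ReadRecord) else str(read)
    read_id = read.id if isinstance(read, ReadRecord) else "read"
    shortest = min(len(r.sequence) for r in references)
    if len(seq) < min_read_frac * shortest:
        return StructuralCall(read_id, "unclassified", reason="short_read")

    rc = revcomp(seq)
    # stage 1: edit-distance shortlist over (class, strand)
    cand = []
    for ref in references:
        for strand, s in (("+", seq), ("-", rc)):
            d = edlib.align(s, ref.sequence, mode="NW", task="distance")["editDistance"]
            cand.append((d, ref, strand, s))
    best_d = min(c[0] for c in cand)
    # keep best strand per class within the slack
    per_class: dict[str, tuple] = {}
    for d, ref, strand, s in cand:
        if d > best_d + _EDLIB_SLACK:
            continue
        cur = per_class.get(ref.klass)
        if cur is None or d < cur[0]:
            per_class[ref.klass] = (d, ref, strand, s)
    # stage 2: affine scores for shortlisted classes
    scored = []
    for d, ref, strand, s in per_class.values():
        sc = align_score(s, ref.sequence, scoring)
        scored.append((sc, ref, strand, s))
    scored.sort(key=lambda t: (-t[0], t[1].klass))
    best_sc, best_ref, best_strand, best_seq = scored[0]
    if len(scored) > 1:
        margin = best_sc - scored[1][0]
    else:
        # all other classes were culled by a large edit-distance gap
        margin = float("inf")
    if margin < min_score_margin:
        return StructuralCall(
            read_id, "unclassified", reason="ambiguous",
            score=best_sc, margin=margin,
        )
    aln = align_pair(
        best_seq, best_ref.sequence, scoring,
        query_id=read_id, reference_id=best_ref.klass,
    )
    calls = _junction_calls(aln, best_ref.junctions, junction_window)
    _attach_inserted_seq(calls, aln, best_seq, best_ref.junctions, junction_window)
    large = any(c.type == "deletion" and c.size > large_del_threshold for c in calls)
    return StructuralCall(
        read_id=read_id,
        klass=best_ref.klass,
        orientation=best_ref.orientation,
        junction_indels=calls,
        large_deletion=large,
        read_strand=best_strand,
        score=best_sc,
        margin=margin,
        alignment=aln,
    )


def classify_reads(reads, references, **kwargs) -> list[StructuralCall]:
    return [classify_read(r, references, **kwargs) for r in reads]


def calls_to_frame(calls: list[StructuralCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "read_id": c.read_id,
                "klass": c.klass,
                "orientation": c.orientation,
                "read_strand": c.read_strand,
                "score": c.score,
                "margin": c.margin,
                "large_deletion": c.large_deletion,
                "junction_indels": ";".join(
                    f"{jc.type}{jc.size if jc.size else ''}" for jc in c.junction_indels
                ) or ".",
                "reason": c.reason,
            }
        )
    return pd.DataFrame(rows)


def orientation_summary(calls: list[StructuralCall]) -> pd.DataFrame:
    """Class and orientation fractions over classified reads.

    ``fraction`` is over all classified reads; for donor-bearing classes
    ``orientation_fraction`` is the within-structure fwd/rev split (fwd and
    rev rows of one structure sum to 1). A note flags absent donor classes.
    """
    if not calls:
        raise ValueError("orientation_summary requires at least one call")
    classified = [c for c in calls if c.klass != "unclassified"]
    if not classified:
        raise ValueError("no classified reads")
    counts: dict[str, int] = {}
    for c in classified:
        counts[c.klass] = counts.get(c.klass, 0) + 1
    total = len(classified)
    rows = []
    for klass in sorted(counts):
        row = {
            "klass": klass,
            "n_reads": counts[klass],
            "fraction": counts[klass] / total,
            "orientation": "n/a",
            "orientation_fraction": np.nan,
        }
        if klass in DONOR_CLASSES:
            stem = klass.rsplit("_", 1)[0]
            pair = counts.get(f"{stem}_fwd", 0) + counts.get(f"{stem}_rev", 0)
            row["orientation"] = klass.rsplit("_", 1)[1]
            row["orientation_fraction"] = counts[klass] / pair
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_classified"] = total
    df.attrs["n_unclassified"] = len(calls) - total
    df.attrs["donor_classes_present"] = any(k in DONOR_CLASSES for k in counts)
    return df


def deletion_profile(
    calls: list[StructuralCall], reference: ReferenceAmplicon
) -> np.ndarray:
    """Per-base fraction of reads containing a deletion at each position.

    Computed over reads assigned to ``reference.klass``. Positions covered
    by zero reads are NaN (missing), not 0.
    """
    use = [c for c in calls if c.klass == reference.klass and c.alignment is not None]
    if not use:
        raise ValueError(f"no reads assigned to class {reference.klass!r}")
    n = len(reference.sequence)
    cov = np.zeros(n, dtype=float)
    dele = np.zeros(n, dtype=float)
    for c in use:
        aln = c.alignment
        rpos = aln.reference_start
        for op, ln in aln.operations:
            if op in ("match", "mismatch"):
                cov[rpos : rpos + ln] += 1
                rpos += ln
            elif op == "deletion":
                cov[rpos : rpos + ln] += 1
                dele[rpos : rpos + ln] += 1
                rpos += ln
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(cov > 0, dele / np.maximum(cov, 1), np.nan)
    return prof


def junction_indelfree_fraction(
    calls: list[StructuralCall], klass: str, junction_index: int
) -> tuple[float, int, int]:
    """Fraction of reads of *klass* whose junction is InDel-free.

    Returns (fraction, numerator, denominator); reads whose junction call is
    ``not_covered`` are excluded from the denominator.
    """
    use = [c for c in calls if c.klass == klass]
    if not use:
        raise ValueError(f"no calls of class {klass!r}")
    n_j = len(use[0].junction_indels)
    if not 0 <= junction_index < n_j:
        raise IndexError(
            f"junction_index {junction_index} invalid for class {klass!r}; "
            f"valid indices are 0..{n_j - 1}"
        )
    covered = [c for c in use if c.junction_indels[junction_index].type != "not_covered"]
    num = sum(1 for c in covered if c.junction_indels[junction_index].type == "none")
    den = len(covered)
    return (num / den if den else float("nan")), num, den
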