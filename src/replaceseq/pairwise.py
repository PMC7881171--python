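"""Affine-gap pairwise alignment with a uniform operation-list contract.

All read classification in this package goes through :func:`align_pair`,
a global (optionally end-gap-free) affine-gap aligner. The heavy lifting is
done by :class:`Bio.Align.PairwiseAligner`; this module converts its output
into an explicit ordered operation list (match/mismatch/insertion/deletion
with lengths) relative to the reference, which the junction-InDel callers
consume. Insertions are query bases absent from the reference; deletions are
reference bases absent from the query.

Tie-breaking between co-optimal alignments is deterministic: the first
alignment in PairwiseAligner's enumeration order is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align


@dataclass(frozen=True)
class Scoring:
    """Affine scoring: a gap of length L costs open + (L-1)*extend."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -7.0
    gap_extend: float = -1.0


DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    """One pairwise alignment of a query (read) to a reference."""

    query_id: str
    reference_id: str
    operations: list = field(default_factory=list)  # [(op, length), ...]
    score: float = 0.0
    reference_start: int = 0
    reference_end: int = 0
    query_start: int = 0
    query_end: int = 0

    def reference_span(self) -> int:
        return sum(n for op, n in self.operations if op in ("match", "mismatch", "deletion"))

    def indels(self):
        """Yield (op, ref_pos, length, query_pos) for every indel operation.

        ``ref_pos`` is the reference coordinate where the indel applies: for
        deletions the start of the deleted reference span, for insertions the
        inter-base reference coordinate of the insertion point.
        """
        rpos, qpos = self.reference_start, self.query_start
        for op, n in self.operations:
            if op in ("match", "mismatch"):
                rpos += n
                qpos += n
            elif op == "deletion":
                yield ("deletion", rpos, n, qpos)
                rpos += n
            elif op == "insertion":
                yield ("insertion", rpos, n, qpos)
                qpos += n

    def cigar(self) -> str:
        sym = {"match": "=", "mismatch": "X", "insertion": "I", "deletion": "D"}
        return "".join(f"{n}{sym[op]}" for op, n in self.operations)


@lru_cache(maxsize=32)
def _make_aligner(scoring: Scoring, free_ref_right: bool, free_ref_left: bool,
                  free_query_ends: bool) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    # Biopython terms: a "deletion" is a gap in the query (reference
    # overhang), an "insertion" a gap in the target/reference.
    if free_ref_right:
        a.open_right_deletion_score = 0.0
        a.extend_right_deletion_score = 0.0
    if free_ref_left:
        a.open_left_deletion_score = 0.0
        a.extend_left_deletion_score = 0.0
    if free_query_ends:
        a.open_left_insertion_score = 0.0
        a.extend_left_insertion_score = 0.0
        a.open_right_insertion_score = 0.0
        a.extend_right_insertion_score = 0.0
    return a


def align_score(
    query: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
    free_ref_right: bool = False,
    free_ref_left: bool = False,
    free_query_ends: bool = False,
) -> float:
    """Optimal alignment score only (cheaper than a full traceback)."""
    a = _make_aligner(scoring, free_ref_right, free_ref_left, free_query_ends)
    return a.score(reference, query)


def align_pair(
    query: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
    free_ref_right: bool = False,
    free_ref_left: bool = False,
    free_query_ends: bool = False,
    query_id: str = "query",
    reference_id: str = "reference",
) -> Alignment:
    """Optimal affine-gap alignment of *query* against *reference*.

    Global by default; ``free_ref_right``/``free_ref_left`` make reference
    overhangs free (semi-global, for reads truncated before the reference
    end), ``free_query_ends`` makes query overhangs free.
    """
    if not query or not reference:
        raise ValueError("align_pair requires non-empty sequences")
    a = _make_aligner(scoring, free_ref_right, free_ref_left, free_query_ends)
    aln = a.align(reference, query)[0]
    coords = aln.coordinates  # row 0: reference, row 1: query
    ops: list[tuple[str, int]] = []
    rpos = qpos = 0
    ref_start = ref_end = query_start = query_end = None
    for k in range(coords.shape[1] - 1):
        r0, r1 = int(coords[0, k]), int(coords[0, k + 1])
        q0, q1 = int(coords[1, k]), int(coords[1, k + 1])
        if r1 > r0 and q1 > q0:
            # aligned block: split into match/mismatch runs
            for i in range(r1 - r0):
                op = "match" if reference[r0 + i] == query[q0 + i] else "mismatch"
                if ops and ops[-1][0] == op:
                    ops[-1] = (op, ops[-1][1] + 1)
                else:
                    ops.append((op, 1))
            if ref_start is None:
                ref_start, query_start = r0, q0
            ref_end, query_end = r1, q1
        elif r1 > r0:
            ops.append(("deletion", r1 - r0))
        elif q1 > q0:
            ops.append(("insertion", q1 - q0))
    # trim free end gaps from the operation list so spans reflect the
    # aligned core; interior gaps always stay.
    if ref_start is None:  # no aligned block at all (degenerate)
        ref_start = ref_end = query_start = query_end = 0
        ops = []
    else:
        while ops and ops[0][0] in ("deletion", "insertion"):
            op, n = ops.pop(0)
        while ops and ops[-1][0] in ("deletion", "insertion"):
            ops.pop()
    return Alignment(
        query_id=query_id,
        reference_id=reference_id,
        operations=ops,
        score=float(aln.score),
        reference_start=int(ref_start),
        reference_end=int(ref_end),
        query_start=int(query_start),
        query_end=int(query_end),
    )
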