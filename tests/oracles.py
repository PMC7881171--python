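"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and implemented independently of the
package internals: quadratic Gotoh dynamic programming for affine-gap
alignment scores, exhaustive window scanning for guide placement, and
explicit string surgery for cut-and-ligate outcome enumeration.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


NEG = float("-inf")


def gotoh_score(
    query: str,
    reference: str,
    match: float = 2.0,
    mismatch: float = -4.0,
    gap_open: float = -7.0,
    gap_extend: float = -1.0,
    free_ref_right: bool = False,
) -> float:
    """Brute-force affine-gap global alignment score.

    A gap of length L costs gap_open + (L-1)*gap_extend. With
    ``free_ref_right`` the trailing reference overhang (gap in the query at
    the right end) is free.
    """
    n, m = len(reference), len(query)
    # M: end in aligned pair; X: gap in query (reference consumed); Y: gap in ref
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if reference[i - 1] == query[j - 1] else mismatch
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    if free_ref_right:
        # best over all reference suffixes left unaligned
        return max(max(M[i][m], X[i][m], Y[i][m]) for i in range(n + 1))
    return max(M[n][m], X[n][m], Y[n][m])


def scan_guide_sites(locus: str, protospacer: str):
    """Exhaustive window scan for protospacer+NGG on both strands.

    Returns sorted [(start, strand, cut), ...] with start the leftmost
    coordinate of the protospacer footprint.
    """
    hits = []
    P = len(protospacer)
    for i in range(len(locus)):
        w = locus[i : i + P + 3]
        if len(w) < P + 3:
            break
        if w[:P] == protospacer and w[P] in "ACGT" and w[P + 1 : P + 3] == "GG":
            hits.append((i, "+", i + 17))
    rcp = rc(protospacer)
    for i in range(3, len(locus)):
        w = locus[i - 3 : i + P]
        if len(w) < P + 3:
            break
        if w[3:] == rcp and rc(w[:3])[0] in "ACGT" and rc(w[:3])[1:] == "GG":
            hits.append((i, "-", i + 3))
    return sorted(hits)


def cut_and_ligate(locus: str, cut_left: int, cut_right: int, donor: str) -> dict:
    """All 8 expected outcome sequences by explicit string surgery."""
    l, m, r = locus[:cut_left], locus[cut_left:cut_right], locus[cut_right:]
    D = donor
    return {
        "original": l + m + r,
        "deletion": l + r,
        "replacement_fwd": l + D + r,
        "replacement_rev": l + rc(D) + r,
        "insertion_up_fwd": l + D + m + r,
        "insertion_up_rev": l + rc(D) + m + r,
        "insertion_down_fwd": l + m + D + r,
        "insertion_down_rev": l + m + rc(D) + r,
    }


def make_toy_design(rng: np.random.Generator, strands: tuple[str, str] | None = None):
    """A small random Replace design with two planted guide sites.

    Guides are random distinct protospacers on random (or given) strands;
    the donor is random sequence (no engineered directionality). Returns a
    ReplaceDesign.
    """
    from replaceseq.design import GuideSite, ReplaceDesign

    if strands is None:
        strands = tuple(rng.choice(["+", "-"], size=2))
    while True:
        p1, p2 = random_dna(rng, 20), random_dna(rng, 20)
        if p1 == p2:
            continue
        seg0 = random_dna(rng, int(rng.integers(40, 80)))
        seg1 = random_dna(rng, int(rng.integers(45, 90)))
        seg2 = random_dna(rng, int(rng.integers(40, 80)))
        donor = random_dna(rng, int(rng.integers(55, 120)))

        blocks = []
        guides = []
        pos = len(seg0)
        for proto, strand in zip((p1, p2), strands):
            if strand == "+":
                block = proto + "AGG"
                site = GuideSite(proto, "AGG", "+", pos, pos + 17)
            else:
                block = "CCT" + rc(proto)
                site = GuideSite(proto, "AGG", "-", pos + 3, pos + 6)
            blocks.append(block)
            guides.append(site)
            pos += len(block)
            if len(blocks) == 1:
                pos += len(seg1)
        locus = seg0 + blocks[0] + seg1 + blocks[1] + seg2
        try:
            return ReplaceDesign(
                locus_seq=locus,
                guide_left=guides[0],
                guide_right=guides[1],
                donor_seq=donor,
            )
        except Exception:
            continue  # accidental invariant violation; redraw
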