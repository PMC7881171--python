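"""Data model for a two-cut NHEJ Replace experiment.

A Replace design excises a genomic segment with two SpyCas9 cuts and ligates
a linearized donor in between. Because ligation is orientation-agnostic, the
repair outcome space is small and fully enumerable: the unedited allele, the
two-cut deletion, donor replacement in either orientation, and donor
insertion at either single cut in either orientation (the excised segment
retained). This module holds the cut-site arithmetic, the exhaustive
cut-and-ligate enumeration of those alleles, and the validation of the
directional design principle: junctions of *undesired* products should
reconstitute a cleavable protospacer+PAM (so Cas9 re-opens them), while the
designed replacement junctions must not.

Coordinates are 0-based half-open; cut positions are inter-base. The
canonical SpyCas9 blunt cut is placed 3 nt 5' of the PAM (between protospacer
positions 17 and 18 in 1-based protospacer coordinates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .dna import revcomp, is_dna, is_ngg, random_dna, as_rng

# Junction side labels: each Cas9 break splits the site into the fragment
# carrying the PAM plus 3 protospacer nt ("pam" side) and the fragment
# carrying protospacer nt 1-17 ("protospacer" side). Staggered-cut fill-in
# insertions arise only when two pam sides are ligated.
PAM_SIDE = "pam"
PROTO_SIDE = "protospacer"

OUTCOME_CLASSES = (
    "original",
    "deletion",
    "replacement_fwd",
    "replacement_rev",
    "insertion_up_fwd",
    "insertion_up_rev",
    "insertion_down_fwd",
    "insertion_down_rev",
)

DONOR_CLASSES = tuple(k for k in OUTCOME_CLASSES if k.endswith(("_fwd", "_rev")))


class DesignError(ValueError):
    """Raised when a Replace design violates its invariants."""


@dataclass(frozen=True)
class GuideSite:
    """One SpyCas9 target site on the reference locus.

    ``start`` is the leftmost reference coordinate of the 20-nt protospacer
    footprint regardless of strand; ``cut`` is the inter-base coordinate of
    the canonical blunt cut (start+17 on '+', start+3 on '-').
    """

    protospacer: str
    pam: str
    strand: str
    start: int
    cut: int

    def __post_init__(self):
        if len(self.protospacer) != 20 or not is_dna(self.protospacer):
            raise DesignError("protospacer must be a 20-nt ACGT string")
        if not is_ngg(self.pam):
            raise DesignError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in "+-":
            raise DesignError("strand must be '+' or '-'")
        expected = self.start + (17 if self.strand == "+" else 3)
        if self.cut != expected:
            raise DesignError(
                f"cut {self.cut} inconsistent with strand/start (expected {expected})"
            )

    def check_against(self, locus_seq: str) -> None:
        """Verify protospacer+PAM occur at (start, strand) in *locus_seq*."""
        if self.strand == "+":
            found = locus_seq[self.start : self.start + 20]
            pam = locus_seq[self.start + 20 : self.start + 23]
            if found != self.protospacer or not is_ngg(pam):
                raise DesignError("guide site does not match locus on + strand")
        else:
            found = locus_seq[self.start : self.start + 20]
            pam = locus_seq[self.start - 3 : self.start]
            if found != revcomp(self.protospacer) or not is_ngg(revcomp(pam)):
                raise DesignError("guide site does not match locus on - strand")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GuideSite":
        return cls(**d)


@dataclass(frozen=True)
class JunctionSide:
    """One ligated end: which side of a Cas9 break it is, and which guide cut it."""

    kind: str  # PAM_SIDE or PROTO_SIDE
    guide: GuideSite | None = None

    def __post_init__(self):
        if self.kind not in (PAM_SIDE, PROTO_SIDE):
            raise DesignError(f"unknown junction side kind {self.kind!r}")


@dataclass(frozen=True)
class Junction:
    """A ligation point inside an outcome sequence (inter-base coordinate)."""

    position: int
    left: JunctionSide
    right: JunctionSide

    @property
    def is_pam_pam(self) -> bool:
        return self.left.kind == PAM_SIDE and self.right.kind == PAM_SIDE


@dataclass(frozen=True)
class OutcomeAllele:
    """One post-editing allele structure with its full expected sequence."""

    klass: str
    sequence: str
    junctions: tuple[Junction, ...]

    @property
    def orientation(self) -> str:
        if self.klass.endswith("_fwd"):
            return "fwd"
        if self.klass.endswith("_rev"):
            return "rev"
        return "n/a"


def _left_end_side(guide: GuideSite) -> str:
    """Side label of the fragment left of the cut."""
    return PROTO_SIDE if guide.strand == "+" else PAM_SIDE


def _right_end_side(guide: GuideSite) -> str:
    return PAM_SIDE if guide.strand == "+" else PROTO_SIDE


@dataclass
class ReplaceDesign:
    """The geometry of a Replace experiment.

    ``donor_seq`` is the linearized donor 5'->3' in the orientation the
    designer declares desired ("fwd"); the software does not infer intent.
    ``donor_left_junction_side``/``donor_right_junction_side`` label which
    side of a Cas9 break each donor end reconstitutes (minicircle donors are
    themselves linearized by Cas9, so their ends are pam or protospacer
    sides too). Buffers are the sacrificial nt inside the donor ends.
    """

    locus_seq: str
    guide_left: GuideSite
    guide_right: GuideSite
    donor_seq: str
    donor_left_junction_side: str = PROTO_SIDE
    donor_right_junction_side: str = PAM_SIDE
    buffer_left: int = 0
    buffer_right: int = 0

    def __post_init__(self):
        if not self.donor_seq:
            raise DesignError("donor_seq must be non-empty")
        if self.buffer_left < 0 or self.buffer_right < 0:
            raise DesignError("buffers must be >= 0")
        if self.guide_left.cut == self.guide_right.cut:
            raise DesignError("the two cuts coincide")
        if self.guide_left.cut > self.guide_right.cut:
            raise DesignError("guide_left.cut must be < guide_right.cut")
        for side in (self.donor_left_junction_side, self.donor_right_junction_side):
            if side not in (PAM_SIDE, PROTO_SIDE):
                raise DesignError(f"unknown donor junction side {side!r}")
        self.guide_left.check_against(self.locus_seq)
        self.guide_right.check_against(self.locus_seq)

    @property
    def cut_left(self) -> int:
        return self.guide_left.cut

    @property
    def cut_right(self) -> int:
        return self.guide_right.cut

    @property
    def excised_len(self) -> int:
        return self.cut_right - self.cut_left

    def protospacers(self) -> list[str]:
        """Distinct protospacers used by this design."""
        out = [self.guide_left.protospacer]
        if self.guide_right.protospacer != out[0]:
            out.append(self.guide_right.protospacer)
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["guide_left"] = self.guide_left.to_dict()
        d["guide_right"] = self.guide_right.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ReplaceDesign":
        d = dict(d)
        d["guide_left"] = GuideSite.from_dict(d["guide_left"])
        d["guide_right"] = GuideSite.from_dict(d["guide_right"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ReplaceDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def locate_guide(locus_seq: str, protospacer: str) -> list[GuideSite]:
    """Find every placement of *protospacer* followed by an NGG PAM.

    Both strands are scanned; hits are returned sorted by ``start``. An empty
    list is a normal return. Overlapping placements are all reported.
    """
    if len(protospacer) != 20 or not is_dna(protospacer):
        raise DesignError("protospacer must be a 20-nt ACGT string")
    hits: list[GuideSite] = []
    # + strand: protospacer at i, PAM at [i+20, i+23)
    start = 0
    while True:
        i = locus_seq.find(protospacer, start)
        if i < 0:
            break
        pam = locus_seq[i + 20 : i + 23]
        if is_ngg(pam):
            hits.append(GuideSite(protospacer, pam, "+", i, i + 17))
        start = i + 1
    # - strand: revcomp(protospacer) at i, CCN (revcomp of NGG) at [i-3, i)
    rc = revcomp(protospacer)
    start = 0
    while True:
        i = locus_seq.find(rc, start)
        if i < 0:
            break
        pam_rc = locus_seq[i - 3 : i]
        if i >= 3 and is_ngg(revcomp(pam_rc)):
            hits.append(GuideSite(protospacer, revcomp(pam_rc), "-", i, i + 3))
        start = i + 1
    hits.sort(key=lambda g: (g.start, g.strand))
    return hits


def enumerate_outcomes(design: ReplaceDesign) -> list[OutcomeAllele]:
    """All 8 expected post-editing allele structures, by perfect cut-and-ligate.

    Fragments: ``l`` = locus left of the left cut, ``m`` = excised segment,
    ``r`` = locus right of the right cut, ``D`` = donor (designed
    orientation). Staggered cutting is a repair-time phenomenon handled by
    the read simulator, never here: every junction is a clean ligation.
    """
    a, b = design.cut_left, design.cut_right
    locus, D = design.locus_seq, design.donor_seq
    l, m, r = locus[:a], locus[a:b], locus[b:]
    gl, gr = design.guide_left, design.guide_right

    l_end = JunctionSide(_left_end_side(gl), gl)
    m_left = JunctionSide(_right_end_side(gl), gl)
    m_right = JunctionSide(_left_end_side(gr), gr)
    r_start = JunctionSide(_right_end_side(gr), gr)

    def donor_sides(orientation: str, at_guide: GuideSite):
        """(left end, right end) of the donor as ligated, carrying the local guide."""
        dl, dr = design.donor_left_junction_side, design.donor_right_junction_side
        if orientation == "rev":
            dl, dr = dr, dl
        return JunctionSide(dl, at_guide), JunctionSide(dr, at_guide)

    def donor(orientation: str) -> str:
        return D if orientation == "fwd" else revcomp(D)

    out = [OutcomeAllele("original", locus, ())]
    out.append(
        OutcomeAllele("deletion", l + r, (Junction(a, l_end, r_start),))
    )
    for o in ("fwd", "rev"):
        dL, dR = donor_sides(o, gl)
        dR = JunctionSide(dR.kind, gr)  # right junction forms at the right cut
        out.append(
            OutcomeAllele(
                f"replacement_{o}",
                l + donor(o) + r,
                (
                    Junction(a, l_end, dL),
                    Junction(a + len(D), dR, r_start),
                ),
            )
        )
    for o in ("fwd", "rev"):
        dL, dR = donor_sides(o, gl)
        out.append(
            OutcomeAllele(
                f"insertion_up_{o}",
                l + donor(o) + m + r,
                (
                    Junction(a, l_end, dL),
                    Junction(a + len(D), dR, m_left),
                ),
            )
        )
    for o in ("fwd", "rev"):
        dL, dR = donor_sides(o, gr)
        out.append(
            OutcomeAllele(
                f"insertion_down_{o}",
                l + m + donor(o) + r,
                (
                    Junction(b, m_right, dL),
                    Junction(b + len(D), dR, r_start),
                ),
            )
        )
    # restore the spec's class order
    order = {k: i for i, k in enumerate(OUTCOME_CLASSES)}
    out.sort(key=lambda al: order[al.klass])
    return out


def outcome_by_class(design: ReplaceDesign) -> dict[str, OutcomeAllele]:
    return {al.klass: al for al in enumerate_outcomes(design)}


def junction_recleavable(
    sequence: str,
    junction_pos: int,
    protospacers: list[str],
    window: int = 30,
) -> bool:
    """True iff an intact protospacer+NGG lies within +/-*window* nt of the junction.

    Both strands are checked. A reconstituted target means Cas9 can re-open
    this junction, which the directional design exploits to deplete
    undesired products.
    """
    if not 0 <= junction_pos <= len(sequence):
        raise ValueError(f"junction_pos {junction_pos} outside sequence")
    lo = max(0, junction_pos - window)
    hi = min(len(sequence), junction_pos + window)
    w = sequence[lo:hi]
    for proto in protospacers:
        for s in (w, revcomp(w)):
            start = 0
            while True:
                i = s.find(proto, start)
                if i < 0:
                    break
                if is_ngg(s[i + 20 : i + 23]):
                    return True
                start = i + 1
    return False


@dataclass
class DesignReport:
    """Validation result for a Replace design."""

    recleavable: dict  # klass -> list[bool] per junction
    n_guides_required: int
    buffer_ok: bool
    warnings: list = field(default_factory=list)
    ok: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["Replace design report", "====================="]
        lines.append(f"distinct guides: {self.n_guides_required}")
        lines.append(f"buffers ok (>= min): {self.buffer_ok}")
        for klass, flags in sorted(self.recleavable.items()):
            lines.append(f"  {klass}: junction re-cleavable = {flags}")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        lines.append("PASS" if self.ok else "FAIL")
        return "\n".join(lines)


def validate_design(
    design: ReplaceDesign, min_buffer: int = 30, force: bool = False
) -> DesignReport:
    """Check the directional design principles.

    The designed (fwd) replacement junctions must NOT be re-cleavable, or
    the orientation-capture logic is defeated (raises unless *force*). The
    deletion junction and the inverted (rev) replacement junctions should be
    re-cleavable so those products are re-opened; violations warn.
    """
    protos = design.protospacers()
    outcomes = enumerate_outcomes(design)
    recleavable: dict[str, list[bool]] = {}
    warnings: list[str] = []
    for al in outcomes:
        if al.klass == "original":
            continue
        recleavable[al.klass] = [
            junction_recleavable(al.sequence, j.position, protos)
            for j in al.junctions
        ]

    ok = True
    if any(recleavable["replacement_fwd"]):
        msg = (
            "designed-orientation replacement junction is re-cleavable; "
            "the correct product would be destroyed"
        )
        if not force:
            raise DesignError(msg)
        warnings.append(msg)
        ok = False
    if not any(recleavable["deletion"]):
        warnings.append(
            "deletion junction does not reform a cleavable target; deletion "
            "products will not be re-opened"
        )
    if not any(recleavable["replacement_rev"]):
        warnings.append(
            "no orientation selection: inverted donor junctions are not "
            "re-cleavable either"
        )

    n_guides = len(set(protos))
    if n_guides < 2:
        warnings.append(
            "fewer than 2 distinct guides; directional Replace requires at "
            "least two gRNAs (locus excision + donor linearization/deletion re-cut)"
        )

    buffer_ok = design.buffer_left >= min_buffer and design.buffer_right >= min_buffer
    if design.buffer_left < min_buffer:
        warnings.append(
            f"left donor buffer {design.buffer_left} nt < recommended {min_buffer} nt"
        )
    if design.buffer_right < min_buffer:
        warnings.append(
            f"right donor buffer {design.buffer_right} nt < recommended {min_buffer} nt"
        )

    # degenerate-geometry warnings (toy inputs are allowed, not errors)
    if design.excised_len < 40:
        warnings.append("excised segment shorter than 40 nt (toy-scale design)")
    if len(design.donor_seq) < 50:
        warnings.append("donor shorter than 50 nt (toy-scale design)")

    return DesignReport(
        recleavable=recleavable,
        n_guides_required=max(n_guides, 2),
        buffer_ok=buffer_ok,
        warnings=warnings,
        ok=ok,
    )


def example_design(
    seed: int = 0,
    up_len: int = 150,
    mid_len: int = 120,
    down_len: int = 150,
    core_len: int = 57,
    buffer_len: int = 40,
) -> ReplaceDesign:
    """A directional Replace design in the style of the reporter experiments.

    Two identical guide sites (same 20-nt protospacer, '+' strand, AGG PAM)
    flank the segment to excise, mirroring a reporter locus whose deletion
    junction reforms the complete target site. The donor emulates a
    minicircle linearized by the same guide: its raw ends are the PAM side
    (NGG plus 3 protospacer nt) and the protospacer side (protospacer nt
    1-17), separated from the cargo core by sacrificial buffers.
    ``donor_seq`` is supplied reverse-complemented relative to that raw
    linearization, because that is the orientation whose junctions do NOT
    reconstitute the target site - the designed orientation. The inverted
    integrant and the deletion both reform cleavable sites.
    """
    rng = as_rng(seed)
    for _ in range(100):
        proto = random_dna(rng, 20)
        up = random_dna(rng, up_len)
        mid = random_dna(rng, mid_len)
        down = random_dna(rng, down_len)
        core = random_dna(rng, core_len)
        buf_l = random_dna(rng, buffer_len)
        buf_r = random_dna(rng, buffer_len)
        locus = up + proto + "AGG" + mid + proto + "AGG" + down
        # raw linearized donor: PAM side ... cargo ... protospacer side
        donor_raw = proto[17:] + "AGG" + buf_l + core + buf_r + proto[:17]
        donor = revcomp(donor_raw)
        sites = locate_guide(locus, proto)
        if len(sites) != 2 or any(s.strand != "+" for s in sites):
            continue  # accidental extra site; redraw
        design = ReplaceDesign(
            locus_seq=locus,
            guide_left=sites[0],
            guide_right=sites[1],
            donor_seq=donor,
            donor_left_junction_side=PROTO_SIDE,
            donor_right_junction_side=PAM_SIDE,
            buffer_left=buffer_len,
            buffer_right=buffer_len,
        )
        try:
            validate_design(design)
        except DesignError:
            continue
        return design
    raise RuntimeError("could not construct an example design (seed exhausted)")
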