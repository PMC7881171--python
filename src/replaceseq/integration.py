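"""Pipeline 2: map where the donor integrated.

Donor-anchored reads (primer inside the donor pointing across its ligated
end) are checked for correct priming, trimmed up to the expected break so
only the flanking sequence remains, and the flank is classified: donor
re-entry (concatemer, tested first so donor-derived flanks do not
multi-map), genomic alignment (on-target if near either cut of the embedded
target locus, otherwise off-target), residual donor/vector match, or
unmapped. Mapped calls are clustered into integration sites and annotated
with the distance to the nearest predicted Cas9 off-target site.

Genome alignment at this scale uses exact 15-mer seeds (string search) with
edit-distance verification of the full flank; the normative contract is
best-scoring unique hit wins and score ties are unmapped ("multi").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .dna import hamming, revcomp
from .simulate import ReadRecord, SyntheticGenome

ON_TARGET_WINDOW = 1000
PROXIMITY_BP = 5000
MIN_FLANK = 20
SEED_K = 15
MAX_PRIMER_MISMATCHES = 2
TRIM_ERROR_FRAC = 0.10
FLANK_ERROR_FRAC = 0.10


@dataclass
class IntegrationCall:
    """Per-read integration category and, when mapped, the genomic site."""

    read_id: str
    category: str  # on_target | off_target | concatemer | vector | unmapped | off_primer
    chrom: str | None = None
    position: int | None = None
    strand: str | None = None
    flank_len: int = 0
    reason: str = ""


def check_priming(read, donor_primer: str, max_mm: int = MAX_PRIMER_MISMATCHES) -> bool:
    """True iff the read starts with the donor primer (<= *max_mm* mismatches, no InDels)."""
    if not donor_primer:
        raise ValueError("donor_primer must be non-empty")
    seq = read.sequence if isinstance(read, ReadRecord) else str(read)
    if len(seq) < len(donor_primer):
        return False
    return hamming(seq[: len(donor_primer)], donor_primer) <= max_mm


def trim_to_break(read, donor_terminal_seq: str,
                  max_err_frac: float = TRIM_ERROR_FRAC) -> str | None:
    """Strip everything up to the donor's ligated end; return the flank.

    Locates the donor terminal segment (donor sequence between primer and
    the donor end) within the read, tolerating up to ``max_err_frac``
    errors, and returns everything 3' of it (possibly empty). Returns None
    if the terminal segment cannot be found (the read is then categorized
    ``off_primer``).
    """
    seq = read.sequence if isinstance(read, ReadRecord) else str(read)
    k = int(math.floor(max_err_frac * len(donor_terminal_seq)))
    res = edlib.align(donor_terminal_seq, seq, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    end = res["locations"][0][1]  # inclusive end in read coordinates
    return seq[end + 1 :]


class GenomeIndex:
    """Seed-and-verify mapper over a :class:`SyntheticGenome`."""

    def __init__(self, genome: SyntheticGenome, seed_k: int = SEED_K):
        self.genome = genome
        self.k = seed_k

    def _seed_hits(self, flank: str):
        """Candidate (chrom, pos, strand) placements of flank[0] from exact seeds."""
        k = self.k
        # seed offsets beyond 0 are fallbacks for flanks whose first bases
        # carry junction-proximal errors; tried only when earlier offsets
        # yield no candidate anywhere
        for off in (0, 5, 10):
            if off + k > len(flank):
                break
            hits = set()
            seed = flank[off : off + k]
            seed_rc = revcomp(seed)
            for chrom, seq in self.genome.chromosomes.items():
                start = 0
                while True:
                    i = seq.find(seed, start)
                    if i < 0:
                        break
                    hits.add((chrom, i - off, "+"))
                    start = i + 1
                start = 0
                while True:
                    i = seq.find(seed_rc, start)
                    if i < 0:
                        break
                    # flank[off] maps to i+k-1 on '-': flank[0] maps to i+k-1+off
                    hits.add((chrom, i + k - 1 + off, "-"))
                    start = i + 1
            if hits:
                return hits
        return set()

    def map_flank(self, flank: str, max_err_frac: float = FLANK_ERROR_FRAC):
        """Best unique placement of *flank*, or None / "multi".

        Returns (chrom, pos, strand, edit_distance) for a unique best hit,
        the string "multi" for a score tie between distinct sites, or None.
        ``pos`` is the genomic coordinate of the first flank base (the
        junction-proximal base).
        """
        n = len(flank)
        kmax = int(math.floor(max_err_frac * n))
        best = None
        best_d = kmax + 1
        tie = False
        for chrom, pos, strand in sorted(self._seed_hits(flank)):
            seq = self.genome.chromosomes[chrom]
            pad = kmax + 2
            if strand == "+":
                lo = max(0, pos - pad)
                window = seq[lo : pos + n + pad]
            else:
                hi = min(len(seq), pos + 1 + pad)
                window = revcomp(seq[max(0, pos + 1 - n - pad) : hi])
            res = edlib.align(flank, window, mode="HW", task="distance", k=kmax)
            d = res["editDistance"]
            if d < 0:
                continue
            if d < best_d:
                best, best_d, tie = (chrom, pos, strand), d, False
            elif d == best_d and best is not None:
                bc, bp, bs = best
                if chrom != bc or abs(pos - bp) > 5 or strand != bs:
                    tie = True
        if best is None:
            return None
        if tie:
            return "multi"
        return (*best, best_d)


def classify_flank(
    flank: str,
    donor_seq: str,
    genome_index: GenomeIndex,
    read_id: str = "read",
    on_target_window: int = ON_TARGET_WINDOW,
    cut_positions: tuple[int, int] | None = None,
    min_flank: int = MIN_FLANK,
) -> IntegrationCall:
    """Classify a trimmed flank.

    Concatemer detection (flank re-enters the donor start, either
    orientation) precedes genome mapping so donor-derived flanks do not
    multi-map against the vector record. *cut_positions* are the genomic
    coordinates of the two Cas9 cuts of the embedded locus; defaults to the
    genome's recorded embedding.
    """
    genome = genome_index.genome
    if cut_positions is None:
        if genome.locus_pos is None:
            raise ValueError("genome records no embedded locus; pass cut_positions")
        # planted on-target event holds the left cut; the right cut is not
        # recorded, so use a window around the whole locus span instead
        cut_positions = tuple(
            p for c, p, t in genome.planted_events if t == "on_target"
        ) or (genome.locus_pos,)
    if len(flank) == 0:
        return IntegrationCall(read_id, "vector", reason="empty_flank")
    if len(flank) < min_flank:
        return IntegrationCall(read_id, "unmapped", reason="short",
                               flank_len=len(flank))
    # concatemer: flank matches the donor start in either orientation
    probe = flank[:min_flank]
    for cand in (donor_seq, revcomp(donor_seq)):
        res = edlib.align(probe, cand, mode="SHW", task="distance",
                          k=max(2, min_flank // 10))
        if res["editDistance"] >= 0:
            return IntegrationCall(read_id, "concatemer", flank_len=len(flank))
    hit = genome_index.map_flank(flank)
    if hit == "multi":
        return IntegrationCall(read_id, "unmapped", reason="multi",
                               flank_len=len(flank))
    if hit is not None:
        chrom, pos, strand, _d = hit
        on = (
            genome.locus_chrom == chrom
            and any(abs(pos - cp) <= on_target_window for cp in cut_positions)
        )
        return IntegrationCall(
            read_id, "on_target" if on else "off_target",
            chrom=chrom, position=pos, strand=strand, flank_len=len(flank),
        )
    # residual donor/vector match anywhere in the construct
    kv = int(math.floor(FLANK_ERROR_FRAC * len(flank)))
    for cand in (donor_seq, revcomp(donor_seq)):
        res = edlib.align(flank, cand, mode="HW", task="distance", k=kv)
        if res["editDistance"] >= 0:
            return IntegrationCall(read_id, "vector", flank_len=len(flank))
    return IntegrationCall(read_id, "unmapped", reason="no_hit",
                           flank_len=len(flank))


def run_pipeline2(
    reads,
    donor_primer: str,
    donor_terminal_seq: str,
    donor_seq: str,
    genome: SyntheticGenome,
    cut_positions: tuple[int, int] | None = None,
    on_target_window: int = ON_TARGET_WINDOW,
) -> list[IntegrationCall]:
    """Full per-read pass: priming check, trim to break, flank classification.

    The returned categories partition the input reads exactly.
    """
    index = GenomeIndex(genome)
    calls = []
    for read in reads:
        rid = read.id if isinstance(read, ReadRecord) else "read"
        if not check_priming(read, donor_primer):
            calls.append(IntegrationCall(rid, "off_primer", reason="bad_primer"))
            continue
        flank = trim_to_break(read, donor_terminal_seq)
        if flank is None:
            calls.append(IntegrationCall(rid, "off_primer", reason="no_donor_end"))
            continue
        calls.append(
            classify_flank(
                flank, donor_seq, index, read_id=rid,
                on_target_window=on_target_window, cut_positions=cut_positions,
            )
        )
    return calls


def category_summary(calls: list[IntegrationCall]) -> dict:
    """Category counts and fractions under both denominators.

    ``fraction_all`` is over every read that primed and trimmed correctly
    (concatemers included - the "all measured donor sequences" denominator);
    ``fraction_mapped`` is over genome-mapped reads only (concatemers
    excluded).
    """
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.category] = counts.get(c.category, 0) + 1
    measured = sum(
        v for k, v in counts.items() if k not in ("off_primer",)
    )
    mapped = counts.get("on_target", 0) + counts.get("off_target", 0)
    return {
        "n_reads": len(calls),
        "counts": dict(sorted(counts.items())),
        "fraction_all": {
            k: v / measured for k, v in sorted(counts.items()) if k != "off_primer"
        } if measured else {},
        "fraction_mapped": {
            k: counts.get(k, 0) / mapped for k in ("on_target", "off_target")
        } if mapped else {},
    }


def cluster_sites(calls: list[IntegrationCall], window: int = 100) -> pd.DataFrame:
    """Merge mapped calls within *window* nt into integration-site clusters.

    Returns one row per cluster: chrom, start, end, position (rounded mean),
    n_reads, log10_reads, and whether the cluster is the on-target site.
    """
    mapped = [c for c in calls if c.category in ("on_target", "off_target")]
    if not mapped:
        raise ValueError("no mapped calls to cluster")
    mapped.sort(key=lambda c: (c.chrom, c.position))
    rows = []
    cur: list[IntegrationCall] = []

    def flush():
        if not cur:
            return
        positions = [c.position for c in cur]
        rows.append(
            {
                "chrom": cur[0].chrom,
                "start": min(positions),
                "end": max(positions) + 1,
                "position": int(round(float(np.mean(positions)))),
                "n_reads": len(cur),
                "log10_reads": float(np.log10(len(cur))),
                "on_target": any(c.category == "on_target" for c in cur),
            }
        )

    for c in mapped:
        if cur and (c.chrom != cur[-1].chrom or c.position - cur[-1].position > window):
            flush()
            cur = []
        cur.append(c)
    flush()
    return pd.DataFrame(rows)


def offtarget_proximity(
    table: pd.DataFrame,
    predicted_sites,
    chrom_names,
    proximity_bp: int = PROXIMITY_BP,
) -> tuple[pd.DataFrame, dict]:
    """Annotate clusters with the distance to the nearest predicted off-target site.

    *predicted_sites* is a list of (chrom, pos) (BED-derived). Chromosome
    names in the BED must exist in the genome namespace, else an error
    listing the offenders is raised. Clusters on chromosomes with no
    predicted site get an infinite distance. A cluster within
    ``proximity_bp`` (inclusive) is flagged.
    """
    chrom_names = set(chrom_names)
    bad = sorted({c for c, _ in predicted_sites} - chrom_names)
    if bad:
        raise ValueError(
            f"predicted-site chromosomes not in genome namespace: {', '.join(bad)}"
        )
    by_chrom: dict[str, np.ndarray] = {}
    for c, p in predicted_sites:
        by_chrom.setdefault(c, []).append(p)
    by_chrom = {c: np.array(sorted(v)) for c, v in by_chrom.items()}
    dists = []
    for _, row in table.iterrows():
        sites = by_chrom.get(row["chrom"])
        if sites is None or sites.size == 0:
            dists.append(math.inf)
        else:
            dists.append(float(np.min(np.abs(sites - row["position"]))))
    out = table.copy()
    out["nearest_predicted_distance"] = dists
    out["within_proximity"] = [d <= proximity_bp for d in dists]
    offt = out[~out["on_target"]]
    summary = {
        "n_clusters": int(len(out)),
        "n_offtarget_clusters": int(len(offt)),
        "n_within_proximity": int(offt["within_proximity"].sum()),
        "proximity_bp": proximity_bp,
    }
    return out, summary
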