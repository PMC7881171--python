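"""Closed-form allele- and cell-fraction arithmetic for Replace experiments.

FACS measures the fraction of cells with at least one edited allele; under
independence of editing events across alleles this converts between ploidies
through the per-allele probability. A dual-donor co-transfection (two
distinguishable fluorophores) lets the homozygous knock-in fraction be read
off the double-positive population. Combining a FACS positive fraction with
the fraction of genotyped positive clones that carry the correct exchange
gives the overall correct-replacement estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def round_half_away(x: float) -> int:
    """Round half away from zero (matches conventional percent reporting)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def as_percent(fraction: float) -> int:
    return round_half_away(100.0 * fraction)


@dataclass(frozen=True)
class FractionInput:
    """A fraction in [0,1], optionally an exact count ratio (e.g. 24/25)."""

    value: float
    label: str = ""
    n: int | None = None  # denominator when the fraction is a count ratio

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"fraction {self.value} outside [0, 1]")

    @classmethod
    def from_counts(cls, k: int, n: int, label: str = "") -> "FractionInput":
        return cls(k / n, label=label, n=n)


def ploidy_convert(f_obs: float, n_from: int, n_to: int) -> float:
    """Convert a cell-positive fraction between ploidies under independence.

    The per-allele editing probability is p = 1 - (1 - f_obs)**(1/n_from);
    the expected positive fraction at the target ploidy is
    1 - (1 - p)**n_to. Monotone in ``f_obs`` and in ``n_to``.
    """
    if not 0.0 <= f_obs <= 1.0:
        raise ValueError("f_obs must lie in [0, 1]")
    if n_from < 1 or n_to < 1:
        raise ValueError("ploidies must be >= 1")
    if f_obs >= 1.0:
        return 1.0  # log-domain guard: saturated input stays saturated
    # (1-f)^(n_to/n_from) computed in log domain for numerical stability
    return 1.0 - math.exp((n_to / n_from) * math.log1p(-f_obs))


@dataclass(frozen=True)
class DualDonorFACS:
    """Fractions of cells positive for donor A only, donor B only, or both."""

    f_A_only: float
    f_B_only: float
    f_double: float

    def __post_init__(self):
        vals = (self.f_A_only, self.f_B_only, self.f_double)
        if any(v < 0 for v in vals):
            raise ValueError("fractions must be >= 0")
        if sum(vals) > 1.0 + 1e-12:
            raise ValueError("fractions sum to more than 1")


def homozygous_fraction(d: DualDonorFACS) -> tuple[float, float]:
    """(homozygous-KI fraction, fraction with >= 1 KI allele).

    Model assumptions (two alleles, equal and independent donor choice per
    knocked-in allele): a cell with both alleles knocked in receives two
    different donors half the time, so h = 2 * f_double. The any-KI fraction
    is the union of the three positive gates.
    """
    h = 2.0 * d.f_double
    any_ki = d.f_A_only + d.f_B_only + d.f_double
    if h > any_ki + 1e-12:
        raise ValueError(
            "inconsistent input: implied homozygous fraction exceeds the "
            "fraction of cells with any knock-in"
        )
    return h, any_ki


def combined_replacement(f_pos: float, f_correct_given_pos: float) -> float:
    """Overall correct-replacement fraction: FACS-positive x correct-given-positive."""
    for v in (f_pos, f_correct_given_pos):
        if not 0.0 <= v <= 1.0:
            raise ValueError("inputs must lie in [0, 1]")
    return f_pos * f_correct_given_pos
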