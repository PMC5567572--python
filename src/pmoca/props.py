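"""Primer property report: GC content, degeneracy, melting-temperature bounds.

GC content of a degenerate primer uses the unambiguous-only convention:
only positions that are literally G or C count toward the numerator,
while every position (wobbles included) counts in the denominator.  An
18-mer with ten literal G/C and three wobbles is 56% GC under this
convention even though some of its expansions have more.

Melting temperatures are reported as ranges over the expansion pool,
under two explicitly labeled formulas:

* Wallace rule: Tm = 2(A+T) + 4(G+C) °C — the quick short-oligo rule.
* GC formula:   Tm = 81.5 + 0.41·%GC − 675/N °C.

Both are rough screening numbers, not duplex thermodynamics; no salt or
nearest-neighbor correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .evaluate import PrimerSpec
from .iupac import IUPAC_SETS, DegenerateSequence

__all__ = [
    "gc_percent",
    "tm_wallace",
    "tm_wallace_bounds",
    "tm_gc_bounds",
    "PrimerProperties",
    "properties_report",
]


def gc_percent(seq: DegenerateSequence | str) -> int:
    """Percent of positions that are literally G or C, rounded to integer.

    Ambiguous symbols (S, R, N, ...) contribute zero to the numerator but
    stay in the denominator.
    """
    s = seq if isinstance(seq, DegenerateSequence) else DegenerateSequence(seq)
    gc = sum(1 for c in s.sequence if c in "GC")
    return round(100 * gc / len(s))


def tm_wallace(concrete: str) -> float:
    """Wallace rule for a concrete oligo: 2(A+T) + 4(G+C) °C."""
    if any(c not in "ACGT" for c in concrete.upper()):
        raise ValueError("tm_wallace needs a concrete A/C/G/T sequence")
    s = concrete.upper()
    gc = sum(1 for c in s if c in "GC")
    return 2.0 * (len(s) - gc) + 4.0 * gc


def _gc_count_bounds(seq: DegenerateSequence) -> tuple[int, int]:
    """(min, max) G+C count over all expansions, per-position extremes.

    Exact because G+C content is additive over positions: each wobble
    independently contributes 0 or 1 depending on whether an A/T or a G/C
    base is chosen from its set.
    """
    lo = hi = 0
    for c in seq.sequence:
        bases = IUPAC_SETS[c]
        has_at = bool(bases & {"A", "T"})
        has_gc = bool(bases & {"G", "C"})
        lo += 0 if has_at else 1
        hi += 1 if has_gc else 0
    return lo, hi


def tm_wallace_bounds(seq: DegenerateSequence) -> tuple[float, float]:
    """(min, max) Wallace Tm over the expansion pool."""
    lo, hi = _gc_count_bounds(seq)
    n = len(seq)
    return 2.0 * (n - lo) + 4.0 * lo, 2.0 * (n - hi) + 4.0 * hi


def tm_gc_bounds(seq: DegenerateSequence) -> tuple[float, float]:
    """(min, max) of 81.5 + 0.41·%GC − 675/N over the expansion pool."""
    lo, hi = _gc_count_bounds(seq)
    n = len(seq)

    def f(gc: int) -> float:
        return 81.5 + 0.41 * (100.0 * gc / n) - 675.0 / n

    return round(f(lo), 1), round(f(hi), 1)


@dataclass(frozen=True)
class PrimerProperties:
    name: str
    sequence: str
    length: int
    gc_percent: int
    degeneracy: int
    tm_wallace_min: float
    tm_wallace_max: float
    tm_gc_min: float
    tm_gc_max: float


def primer_properties(primer: PrimerSpec) -> PrimerProperties:
    seq = primer.sequence
    w_lo, w_hi = tm_wallace_bounds(seq)
    g_lo, g_hi = tm_gc_bounds(seq)
    return PrimerProperties(
        name=primer.name,
        sequence=seq.sequence,
        length=len(seq),
        gc_percent=gc_percent(seq),
        degeneracy=seq.degeneracy,
        tm_wallace_min=w_lo,
        tm_wallace_max=w_hi,
        tm_gc_min=g_lo,
        tm_gc_max=g_hi,
    )


def properties_report(primers: Sequence[PrimerSpec]) -> pd.DataFrame:
    """One row per primer, in input order; empty input gives header-only."""
    cols = [
        "name",
        "sequence",
        "length",
        "gc",
        "degeneracy",
        "tm_wallace_min",
        "tm_wallace_max",
        "tm_gc_min",
        "tm_gc_max",
    ]
    rows = []
    for p in primers:
        pp = primer_properties(p)
        rows.append(
            [
                pp.name,
                pp.sequence,
                pp.length,
                pp.gc_percent,
                pp.degeneracy,
                pp.tm_wallace_min,
                pp.tm_wallace_max,
                pp.tm_gc_min,
                pp.tm_gc_max,
            ]
        )
    return pd.DataFrame(rows, columns=cols)
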