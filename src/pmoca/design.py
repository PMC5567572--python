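"""Degenerate primer design over alignment windows.

The designer slides a fixed-width window along a nucleotide alignment of
an operon family and, at each window, asks: is there a degenerate
consensus — the per-position union of bases over some subset of rows —
that covers at least half the group exactly (0 mismatches), stays within
a degeneracy budget, and has 50-70% GC?  Surviving consensi are then
screened against an off-target gene family (the homologous ammonia
monooxygenase *amo* sequences): a candidate is kept only when its best
hit anywhere in the off-target set, on either strand, still carries more
than five mismatches (margin >= 6 by default).

Subset selection is exact for small groups (exhaustive search over row
subsets, <= 15 rows) and greedy beyond that: starting from all rows,
iteratively drop the row whose exclusion most reduces the consensus
degeneracy until the budget is met.  The exhaustive search doubles as
the small-instance oracle for the heuristic.

Ranking of accepted candidates is fully specified so output is
reproducible: coverage (desc), degeneracy (asc), GC distance from the
window midpoint (asc), leftmost window start.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .evaluate import best_hit_both_strands
from .iupac import IUPAC_SETS, DegenerateSequence, consensus_code
from .props import gc_percent
from .seqio import AlignmentSet, OperonRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DesignParams",
    "PrimerCandidate",
    "PrimerPair",
    "window_consensus",
    "scan_windows",
    "offtarget_margin",
    "design_pair",
]

#: Rows longer than this fall back to the greedy drop-worst heuristic.
EXHAUSTIVE_ROW_LIMIT = 15


@dataclass(frozen=True)
class DesignParams:
    """Primer-design constraints.

    Defaults encode the published design rules: 18-mers, 50-70% GC,
    group coverage of at least 50%, and specificity of more than five
    mismatches against the off-target family (margin >= 6).
    """

    primer_length: int = 18
    gc_min: float = 50.0
    gc_max: float = 70.0
    min_group_coverage: float = 0.5
    min_offtarget_mismatches: int = 6
    max_degeneracy: int = 64
    target_gene: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.min_group_coverage <= 1):
            raise ValueError("min_group_coverage must be in (0, 1]")
        if self.gc_min > self.gc_max:
            raise ValueError("gc_min must be <= gc_max")
        if self.primer_length < 10:
            raise ValueError("primer_length must be >= 10")


@dataclass(frozen=True)
class PrimerCandidate:
    """A window consensus with its design metrics.

    ``window_start``/``window_end`` are 1-based inclusive alignment
    columns; ``reference_position`` is the 1-based start of the site
    within ``gene`` of the reference record (None when the reference has
    a gap at the window start).  ``min_offtarget_mm`` is None when no
    off-target screening was performed — never a silent pass.
    """

    consensus: DegenerateSequence
    window_start: int
    window_end: int
    gene: str | None
    reference_position: int | None
    coverage0: float
    covered: int
    n_rows: int
    degeneracy: int
    gc: int
    min_offtarget_mm: int | None = None


# Windows are packed as one integer per string, 4 bits (one per base) per
# position, so a subset's consensus union is a single bitwise OR and
# "row covered by consensus" is row & ~consensus == 0.  Degeneracy is the
# product of per-position (nibble) popcounts and is monotone under
# subset growth, which lets the exhaustive search prune whole branches.

_BASE_NIBBLE = {"A": 1, "C": 2, "G": 4, "T": 8}
_NIBBLE_POPCOUNT = [bin(v).count("1") for v in range(16)]
_NIBBLE_CODE = {
    sum(_BASE_NIBBLE[b] for b in bases): code for code, bases in IUPAC_SETS.items()
}


def _pack(window: str) -> int:
    packed = 0
    for i, c in enumerate(window):
        packed |= _BASE_NIBBLE[c] << (4 * i)
    return packed


def _packed_degeneracy(packed: int, length: int) -> int:
    deg = 1
    for i in range(length):
        deg *= _NIBBLE_POPCOUNT[(packed >> (4 * i)) & 0xF]
    return deg


def _unpack(packed: int, length: int) -> str:
    return "".join(_NIBBLE_CODE[(packed >> (4 * i)) & 0xF] for i in range(length))


def _union_consensus(rows: Sequence[str]) -> tuple[str, int]:
    """Per-position base union over concrete rows -> (IUPAC string, degeneracy)."""
    L = len(rows[0])
    codes = []
    deg = 1
    for i in range(L):
        bases = frozenset(r[i] for r in rows)
        codes.append(consensus_code(bases))
        deg *= len(bases)
    return "".join(codes), deg


def _covers(consensus: str, row: str) -> bool:
    return all(row[i] in IUPAC_SETS[c] for i, c in enumerate(consensus))


def _coverage_of(cons: int, packed: Sequence[int], counts: Sequence[int]) -> int:
    return sum(c for p, c in zip(packed, counts) if p & ~cons == 0)


def _consensus_exhaustive(
    unique: list[str], counts: list[int], max_degeneracy: int
) -> tuple[str, int, int] | None:
    """Best (consensus, degeneracy, covered-row-count) by full subset search.

    Explores every subset whose union stays within the degeneracy budget
    (branches whose union already exceeds it cannot recover and are cut).
    The full union is the unique minimal consensus covering every row,
    so when it fits the budget the search ends immediately.
    """
    L = len(unique[0])
    packed = [_pack(u) for u in unique]
    full = 0
    for p in packed:
        full |= p
    full_deg = _packed_degeneracy(full, L)
    if full_deg <= max_degeneracy:
        return _unpack(full, L), full_deg, sum(counts)
    k = len(unique)
    # best = (-covered, degeneracy, consensus int); ties keep the first
    # subset visited, and the include-first DFS visits subsets containing
    # earlier rows first, so ties prefer earlier input rows.
    best: tuple[int, int, int] | None = None

    def consider(cons: int) -> None:
        nonlocal best
        deg = _packed_degeneracy(cons, L)
        covered = _coverage_of(cons, packed, counts)
        key = (-covered, deg)
        if best is None or key < (best[0], best[1]):
            best = (-covered, deg, cons)

    def dfs(i: int, cons: int) -> None:
        if i == k:
            if cons:
                consider(cons)
            return
        merged = cons | packed[i]
        if _packed_degeneracy(merged, L) <= max_degeneracy:
            dfs(i + 1, merged)  # include unique[i] first
        dfs(i + 1, cons)

    dfs(0, 0)
    if best is None:
        return None
    return _unpack(best[2], L), best[1], -best[0]


def _consensus_greedy(
    unique: list[str], counts: list[int], max_degeneracy: int
) -> tuple[str, int, int] | None:
    """Drop-worst heuristic: remove the string whose exclusion most reduces
    degeneracy (ties: fewest rows, then lexicographic) until the budget fits."""
    L = len(unique[0])
    packed = {i: _pack(u) for i in range(len(unique)) for u in [unique[i]]}

    def union_deg(pool: Sequence[int]) -> tuple[int, int]:
        u = 0
        for i in pool:
            u |= packed[i]
        return u, _packed_degeneracy(u, L)

    pool = list(range(len(unique)))
    while True:
        cons, deg = union_deg(pool)
        if deg <= max_degeneracy:
            covered = _coverage_of(cons, [packed[i] for i in range(len(unique))], counts)
            return _unpack(cons, L), deg, covered
        if len(pool) == 1:
            return None  # single concrete row has degeneracy 1; unreachable
        best_drop = None
        for j in pool:
            _, d = union_deg([i for i in pool if i != j])
            key = (d, counts[j], j)
            if best_drop is None or key < best_drop[0]:
                best_drop = (key, j)
        pool.remove(best_drop[1])


def window_consensus(
    rows: Sequence[str],
    min_coverage: float = 0.5,
    max_degeneracy: int = 64,
) -> tuple[DegenerateSequence, list[int]] | None:
    """Degenerate consensus of an alignment window, or None if infeasible.

    ``rows`` are the per-row window strings (equal length; may contain
    gaps).  Rows with a gap or unknown base in the window cannot be
    covered and are excluded from consensus building, but they stay in
    the coverage denominator.  Returns the consensus and the indices of
    covered rows (all at 0 mismatches), maximizing coverage then
    minimizing degeneracy among subsets examined.
    """
    if not rows:
        raise ValueError("window_consensus needs at least one row")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("window rows must have equal length")
    eligible = [i for i, r in enumerate(rows) if all(c in "ACGT" for c in r)]
    if not eligible:
        return None
    grouped: dict[str, list[int]] = {}
    for i in eligible:
        grouped.setdefault(rows[i], []).append(i)
    unique = list(grouped)  # first-appearance order: ties prefer earlier rows
    counts = [len(grouped[u]) for u in unique]
    if len(eligible) <= EXHAUSTIVE_ROW_LIMIT:
        found = _consensus_exhaustive(unique, counts, max_degeneracy)
    else:
        found = _consensus_greedy(unique, counts, max_degeneracy)
    if found is None:
        return None
    cons, _, covered = found
    if covered / len(rows) < min_coverage:
        return None
    covered_idx = [i for u in unique if _covers(cons, u) for i in grouped[u]]
    return DegenerateSequence(cons), sorted(covered_idx)


def _gene_columns(
    alignment: AlignmentSet, reference: OperonRecord, gene: str
) -> tuple[int, int]:
    """0-based column span of the reference record's annotated gene."""
    iv = reference.genes[gene]
    cm = alignment.col_map(reference.id)
    lo0, hi0 = iv.start - 1, iv.end - 1  # 0-based ungapped positions
    cols = [c for c in range(alignment.n_columns) if lo0 <= cm[c] <= hi0 and cm[c] >= 0]
    if not cols:
        raise ValueError(f"gene {gene} of reference {reference.id} maps to no alignment columns")
    return cols[0], cols[-1]


def scan_windows(
    alignment: AlignmentSet,
    params: DesignParams,
    group_rows: Sequence[str] | None = None,
    reference: OperonRecord | None = None,
    offtargets: Sequence[str] | None = None,
) -> list[PrimerCandidate]:
    """Enumerate accepted primer candidates over all alignment windows.

    ``group_rows`` restricts the coverage group (default: all rows).
    ``reference`` (an annotated record present in the alignment) enables
    the ``target_gene`` window restriction and gene-relative positions.
    ``offtargets`` are plus-strand off-target sequences; when provided,
    candidates failing the mismatch margin are dropped.  An empty result
    is a valid outcome.
    """
    row_ids = list(group_rows) if group_rows is not None else list(alignment.rows)
    if not row_ids:
        raise ValueError("scan_windows needs a nonempty group")
    L = params.primer_length
    col_lo, col_hi = 0, alignment.n_columns - L
    gene = params.target_gene
    if gene is not None:
        if reference is None or gene not in reference.genes:
            raise ValueError(f"target_gene={gene!r} requires an annotated reference record")
        g_lo, g_hi = _gene_columns(alignment, reference, gene)
        col_lo, col_hi = g_lo, g_hi - L + 1
    gc_mid = (params.gc_min + params.gc_max) / 2
    out: list[PrimerCandidate] = []
    for start in range(col_lo, col_hi + 1):
        win_rows = [alignment.window(rid, start, L) for rid in row_ids]
        if any(all(r[i] == "-" for r in win_rows) for i in range(L)):
            continue  # all-gap column: not a designable window
        found = window_consensus(win_rows, params.min_group_coverage, params.max_degeneracy)
        if found is None:
            continue
        consensus, covered_idx = found
        gc = gc_percent(consensus)
        if not (params.gc_min <= gc <= params.gc_max):
            continue
        ref_pos = None
        if reference is not None and gene is not None:
            p0 = alignment.ungapped_position(reference.id, start)
            if p0 >= 0:
                ref_pos = p0 - (reference.genes[gene].start - 1) + 1
        margin: int | None = None
        if offtargets is not None and len(offtargets) > 0:
            margin = offtarget_margin(consensus, offtargets)
            if margin < params.min_offtarget_mismatches:
                continue
        out.append(
            PrimerCandidate(
                consensus=consensus,
                window_start=start + 1,
                window_end=start + L,
                gene=gene,
                reference_position=ref_pos,
                coverage0=len(covered_idx) / len(row_ids),
                covered=len(covered_idx),
                n_rows=len(row_ids),
                degeneracy=consensus.degeneracy,
                gc=gc,
                min_offtarget_mm=margin,
            )
        )
    out.sort(
        key=lambda c: (-c.coverage0, c.degeneracy, abs(c.gc - gc_mid), c.window_start)
    )
    return out


def offtarget_margin(
    candidate: DegenerateSequence | PrimerCandidate, offtargets: Sequence[str]
) -> int:
    """Smallest best-hit mismatch count over all off-target sequences.

    Scans every window on both strands of every off-target sequence.  An
    empty off-target set is an error: "not screened" must never look
    like a pass.
    """
    seq = candidate.consensus if isinstance(candidate, PrimerCandidate) else candidate
    if not offtargets:
        raise ValueError("off-target set is empty: margin not screened")
    return min(best_hit_both_strands(seq, s) for s in offtargets)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse candidate pair with its predicted reference product.

    ``reverse`` is in primer orientation (reverse complement of the
    coding-strand consensus), ready to order.
    """

    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_length: int


def design_pair(
    alignment: AlignmentSet,
    reference: OperonRecord,
    params_forward: DesignParams,
    params_reverse: DesignParams,
    product_min: int = 100,
    product_max: int = 2000,
    group_rows: Sequence[str] | None = None,
    offtargets: Sequence[str] | None = None,
    max_pairs: int = 10,
) -> list[PrimerPair]:
    """Pair forward and reverse candidates by predicted product length.

    Forward and reverse target genes must differ (e.g. pmoC and pmoA).
    Product length is measured on the reference record from the forward
    site start to the reverse site end; pairs outside the bounds are
    dropped.  On an empty result the closest distance found is logged.
    """
    if params_forward.target_gene == params_reverse.target_gene:
        raise ValueError("forward and reverse target genes must differ")
    if product_min > product_max:
        raise ValueError("product_min must be <= product_max")
    fwd = scan_windows(alignment, params_forward, group_rows, reference, offtargets)
    rev = scan_windows(alignment, params_reverse, group_rows, reference, offtargets)
    cm = alignment.col_map(reference.id)
    pairs: list[PrimerPair] = []
    closest: int | None = None
    for f, r in itertools.product(fwd, rev):
        f_start0 = cm[f.window_start - 1]
        r_end0 = cm[r.window_end - 1]
        if f_start0 < 0 or r_end0 < 0:
            continue
        length = int(r_end0) - int(f_start0) + 1
        if length < 1:
            continue
        if product_min <= length <= product_max:
            rev_primer = replace(r, consensus=r.consensus.reverse_complement())
            pairs.append(PrimerPair(f, rev_primer, length))
        elif closest is None or abs(length - (product_min + product_max) / 2) < closest:
            closest = length
        if len(pairs) >= max_pairs:
            break
    if not pairs:
        logger.info(
            "no primer pair within [%d, %d] bp; closest product length found: %s",
            product_min,
            product_max,
            closest,
        )
    return pairs
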