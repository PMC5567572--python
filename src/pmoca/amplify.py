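"""In-silico PCR: predicted amplicons from a degenerate primer pair.

A product is called wherever a forward-primer site and a downstream
reverse-primer site (the reverse complement of the reverse primer on the
plus strand) both bind within the allowed mismatch count and the
spanned length falls inside the product-size window.  For operon records
annotated with pmoC and pmoA the hit also reports the intergenic span,
whose lineage-to-lineage length variation is what makes these amplicons
group-diagnostic.

No polymerase or thermal model is applied: binding is mismatch counting
only, and every admissible site pair is reported, nested and overlapping
products included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import PrimerSpec, best_hit
from .seqio import OperonRecord, translate

__all__ = [
    "AmpliconHit",
    "find_amplicons",
    "amplicon_length_profile",
    "residue_anchor_check",
]


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted PCR product on one record (1-based inclusive coords)."""

    record_id: str
    forward_start: int
    forward_end: int
    reverse_start: int
    reverse_end: int
    sequence: str
    length: int
    intergenic: int | None
    fwd_mm: int
    rev_mm: int


def _sites(motif_profile: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """[(0-based start, mismatches)] of all windows within the allowance."""
    idx = np.flatnonzero(motif_profile <= max_mm)
    return [(int(i), int(motif_profile[i])) for i in idx]


def find_amplicons(
    forward: PrimerSpec,
    reverse: PrimerSpec,
    record: OperonRecord,
    max_mm: int = 3,
    product_min: int = 100,
    product_max: int = 2000,
) -> list[AmpliconHit]:
    """All predicted products of a primer pair on one record.

    Both primers may bind with up to ``max_mm`` mismatches each; an
    empty list is a valid outcome.  Hits are ordered by forward then
    reverse position.
    """
    if product_min > product_max:
        raise ValueError("product_min must be <= product_max")
    seq = record.sequence
    f_len = len(forward.binding_motif)
    r_len = len(reverse.binding_motif)
    f_sites = _sites(forward.binding_motif.mismatch_profile(seq), max_mm)
    r_sites = _sites(reverse.binding_motif.mismatch_profile(seq), max_mm)
    inter = (
        record.intergenic_length()
        if "pmoC" in record.genes and "pmoA" in record.genes
        else None
    )
    hits = []
    for f0, f_mm in f_sites:
        for r0, r_mm in r_sites:
            r_end0 = r0 + r_len - 1
            if r_end0 <= f0:
                continue
            length = r_end0 - f0 + 1
            if not (product_min <= length <= product_max):
                continue
            hits.append(
                AmpliconHit(
                    record_id=record.id,
                    forward_start=f0 + 1,
                    forward_end=f0 + f_len,
                    reverse_start=r0 + 1,
                    reverse_end=r_end0 + 1,
                    sequence=seq[f0 : r_end0 + 1],
                    length=length,
                    intergenic=inter,
                    fwd_mm=f_mm,
                    rev_mm=r_mm,
                )
            )
    return hits


def amplicon_length_profile(
    hits: Sequence[AmpliconHit], records: Sequence[OperonRecord]
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-lineage amplicon length statistics and length-separability.

    Returns (table, separable) where the table has one row per group
    (n, mean, sd, min, max over hit lengths) and ``separable`` lists the
    group pairs whose observed length ranges do not overlap — the
    condition under which product size alone distinguishes lineages.
    """
    if not hits:
        raise ValueError("amplicon_length_profile needs at least one hit")
    group_of = {r.id: r.group for r in records}
    df = pd.DataFrame(
        {"group": [group_of.get(h.record_id, "unassigned") for h in hits],
         "length": [h.length for h in hits]}
    )
    stats = (
        df.groupby("group")["length"]
        .agg(n="count", mean="mean", sd="std", min="min", max="max")
        .reset_index()
        .sort_values("group", ignore_index=True)
    )
    separable = []
    rows = stats.to_dict("records")
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            if a["max"] < b["min"] or b["max"] < a["min"]:
                separable.append((a["group"], b["group"]))
    return stats, separable


def residue_anchor_check(
    primer: PrimerSpec,
    record: OperonRecord,
    expected_residue: str,
    frame: int,
) -> tuple[bool, str]:
    """Translate a primer's binding site and compare its first residue.

    The best-hit site must fall entirely inside one annotated gene; its
    plus-strand (coding) sequence is translated at the given frame
    offset and the first complete codon's residue is compared with the
    expectation.  Residue-ambiguous codons render 'X' and fail the check.
    """
    hit = best_hit(primer, record)
    start, end = hit.start, hit.start + len(primer.binding_motif) - 1
    inside = any(iv.start <= start and end <= iv.end for iv in record.genes.values())
    if not inside:
        raise ValueError(
            f"binding site {start}-{end} of {primer.name} on {record.id} "
            "is not inside an annotated gene"
        )
    site = record.sequence[start - 1 : end]
    aa = translate(site, frame=frame)
    observed = aa[0] if aa else "X"
    return observed == expected_residue.upper(), observed
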