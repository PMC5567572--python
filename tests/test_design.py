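"""Window-consensus search, candidate scanning, off-target screening, pairing."""

import itertools

import numpy as np
import pytest

from pmoca import DegenerateSequence, DesignParams, design_pair, scan_windows, window_consensus
from pmoca.design import (
    _consensus_exhaustive,
    _consensus_greedy,
    _union_consensus,
    offtarget_margin,
)
from pmoca.iupac import IUPAC_SETS


def brute_force_best(rows, max_degeneracy):
    """Independent oracle: full enumeration over all row subsets."""
    best = None
    for r in range(1, len(rows) + 1):
        for subset in itertools.combinations(range(len(rows)), r):
            cons, deg = _union_consensus([rows[i] for i in subset])
            if deg > max_degeneracy:
                continue
            covered = sum(
                1
                for row in rows
                if all(row[i] in IUPAC_SETS[c] for i, c in enumerate(cons))
            )
            key = (-covered, deg, cons)
            if best is None or key < best:
                best = key
    return best  # (-covered, degeneracy, consensus) or None


def test_window_consensus_identical_rows():
    cons, covered = window_consensus(["ACGT", "ACGT", "ACGT"])
    assert cons.sequence == "ACGT" and covered == [0, 1, 2]


def test_window_consensus_budgeted_subset():
    """With a degeneracy budget of 2 only {AAGT, AGGT} fits; ARGT covers 2/3."""
    cons, covered = window_consensus(["AAGT", "AGGT", "ACGT"], max_degeneracy=2)
    assert cons.sequence == "ARGT" and covered == [0, 1]


def test_window_consensus_infeasible_window_rejected():
    """Four maximally divergent rows: any half-coverage subset at L=4 needs
    degeneracy 16 > 4, so the window is rejected."""
    assert window_consensus(["AAAA", "CCCC", "GGGG", "TTTT"], 0.5, 4) is None
    cons, covered = window_consensus(["A", "C", "G", "T"], 0.5, 4)
    assert cons.sequence == "N" and len(covered) == 4


def test_gapped_rows_stay_in_denominator():
    result = window_consensus(["ACGT", "AC-T", "ACGT", "AC-T"], min_coverage=0.5)
    assert result is not None
    cons, covered = result
    assert covered == [0, 2]
    assert window_consensus(["ACGT", "AC-T", "AC-T", "AC-T"], min_coverage=0.6) is None


def test_exhaustive_search_matches_brute_force_oracle():
    rng = np.random.default_rng(99)
    for _ in range(40):
        n, L = int(rng.integers(2, 9)), int(rng.integers(3, 7))
        rows = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
        cap = int(rng.choice([2, 4, 8, 16]))
        unique = sorted(set(rows))
        counts = [rows.count(u) for u in unique]
        got = _consensus_exhaustive(unique, counts, cap)
        expected = brute_force_best(rows, cap)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert (-got[2], got[1]) == (expected[0], expected[1])


def test_greedy_heuristic_is_valid_and_near_oracle():
    """The drop-worst heuristic always returns a budget-respecting consensus;
    on small instances its coverage is checked against the exact optimum."""
    rng = np.random.default_rng(7)
    for _ in range(25):
        n, L = int(rng.integers(3, 10)), 6
        # clustered rows so feasible subsets exist
        center = "".join(rng.choice(list("ACGT"), L))
        rows = []
        for _ in range(n):
            row = list(center)
            for p in rng.choice(L, size=int(rng.integers(0, 3)), replace=False):
                row[p] = "ACGT"[int(rng.integers(0, 4))]
            rows.append("".join(row))
        unique = sorted(set(rows))
        counts = [rows.count(u) for u in unique]
        got = _consensus_greedy(unique, counts, 16)
        assert got is not None
        cons, deg, covered = got
        assert deg <= 16 and DegenerateSequence(cons).degeneracy == deg
        exact = _consensus_exhaustive(unique, counts, 16)
        assert covered <= exact[2]


def test_scan_recovers_planted_window(family, primer_set):
    """The planted conserved pmoC window is the top-ranked candidate with
    full coverage at its known gene position."""
    cands = scan_windows(
        family.alignment,
        DesignParams(target_gene="pmoC"),
        reference=family.records[0],
    )
    top = cands[0]
    assert top.consensus.sequence == "AGCARGACGGYACNTGGC"
    assert top.reference_position == 374
    assert top.coverage0 == 1.0


def test_scan_single_row_alignment_everything_covers():
    from pmoca.seqio import AlignmentSet

    rng = np.random.default_rng(3)
    aln = AlignmentSet({"only": "".join(rng.choice(list("ACGT"), 60))})
    cands = scan_windows(aln, DesignParams())
    assert cands  # at least one GC-passing window in 60 random bases
    assert all(c.coverage0 == 1.0 and c.degeneracy == 1 for c in cands)


def test_gc_filter_excludes_low_gc_planted_window(family_factory):
    """A planted motif with 7/18 G+C (39%) is absent from the results."""
    low_gc = "ATTCAATTAGCAGCATGC"  # 7 G/C of 18
    fam = family_factory(seed=5, planted_windows=[("pmoC", 374, low_gc)])
    cands = scan_windows(
        fam.alignment, DesignParams(target_gene="pmoC"), reference=fam.records[0]
    )
    assert all(c.consensus.sequence != low_gc for c in cands)
    assert all(50 <= c.gc <= 70 for c in cands)


def test_candidates_respect_all_bounds(family):
    params = DesignParams(target_gene="pmoC", max_degeneracy=32)
    offs = [s for _, s in family.offtargets]
    for c in scan_windows(family.alignment, params, reference=family.records[0], offtargets=offs):
        assert c.coverage0 >= params.min_group_coverage
        assert c.degeneracy <= params.max_degeneracy
        assert params.gc_min <= c.gc <= params.gc_max
        assert c.min_offtarget_mm >= params.min_offtarget_mismatches


def test_scan_is_deterministic(family):
    a = scan_windows(family.alignment, DesignParams(target_gene="pmoC"), reference=family.records[0])
    b = scan_windows(family.alignment, DesignParams(target_gene="pmoC"), reference=family.records[0])
    assert a == b


def test_offtarget_margin_zero_for_embedded_candidate():
    cand = DegenerateSequence("ACGTACGTACGTACGTAC")
    assert offtarget_margin(cand, ["TTTT" + "ACGTACGTACGTACGTAC" + "TTTT"]) == 0


def test_offtarget_margin_strand_symmetric(family, primer_set):
    """Scanning reverse-complemented off-targets gives the same margin."""
    comp = str.maketrans("ACGT", "TGCA")
    motif = primer_set["pmoC374"].sequence
    offs = [s for _, s in family.offtargets]
    rc_offs = [s.translate(comp)[::-1] for s in offs]
    assert offtarget_margin(motif, offs) == offtarget_margin(motif, rc_offs)


def test_offtarget_margin_empty_set_never_passes_silently():
    with pytest.raises(ValueError, match="not screened"):
        offtarget_margin(DegenerateSequence("ACGTACGT"), [])


def test_planted_offtarget_margin_respected(family_factory):
    fam = family_factory(seed=13, offtarget_min_mismatches=8)
    offs = [s for _, s in fam.offtargets]
    for gene, start, motif in [("pmoC", 374, "AGCARGACGGYACNTGGC")]:
        assert offtarget_margin(DegenerateSequence(motif), offs) >= 8


def test_design_pair_product_arithmetic(family):
    """The top pair's sites sit inside the planted pmoC/pmoA windows and its
    predicted product matches the planted arithmetic:
    (pmoC.end - fwd.start + 1) + spacer + (rev site end within pmoA)."""
    ref = family.records[0]
    pairs = design_pair(
        family.alignment,
        ref,
        DesignParams(target_gene="pmoC"),
        DesignParams(target_gene="pmoA"),
    )
    assert pairs
    p = pairs[0]
    # sites may shift by a base or two inside the conserved planted regions
    # (a narrower realized union can outrank the exact planted columns)
    assert abs(p.forward.reference_position - 374) <= 2
    rev_end_in_gene = p.reverse.reference_position + 18 - 1
    assert abs(rev_end_in_gene - 344) <= 2
    # reverse candidate is emitted in primer orientation: its reverse
    # complement is the plus-strand site consensus
    assert p.reverse.consensus.reverse_complement().sequence != p.reverse.consensus.sequence
    pmoc = ref.genes["pmoC"]
    expected = (
        (pmoc.length - p.forward.reference_position + 1)
        + ref.intergenic_length()
        + rev_end_in_gene
    )
    assert p.product_length == expected


def test_design_pair_out_of_range_product_is_empty(family):
    pairs = design_pair(
        family.alignment,
        family.records[0],
        DesignParams(target_gene="pmoC"),
        DesignParams(target_gene="pmoA"),
        product_min=10,
        product_max=50,  # smaller than the intergenic spacer alone
    )
    assert pairs == []


def test_design_pair_same_gene_rejected(family):
    with pytest.raises(ValueError, match="differ"):
        design_pair(
            family.alignment,
            family.records[0],
            DesignParams(target_gene="pmoC"),
            DesignParams(target_gene="pmoC"),
        )
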