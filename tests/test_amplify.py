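"""In-silico PCR: amplicon prediction, length profiles, residue anchors."""

import numpy as np
import pytest

from pmoca import (
    DegenerateSequence,
    GeneInterval,
    OperonRecord,
    PrimerSpec,
    amplicon_length_profile,
    find_amplicons,
    residue_anchor_check,
)


def _pair():
    fwd = PrimerSpec("pmoC374", DegenerateSequence("AGCARGACGGYACNTGGC"), "forward", "pmoC")
    rev = PrimerSpec("pmoA344", DegenerateSequence("ANGTCCAHCCCCAGAAGT"), "reverse", "pmoA")
    return fwd, rev


def test_planted_sites_give_expected_length():
    """Forward site at 100, reverse site spanning 799-816: one 717 bp product."""
    rng = np.random.default_rng(1)
    seq = list(rng.choice(list("ACGT"), 900))
    fwd, rev = _pair()
    seq[99 : 99 + 18] = "AGCAAGACGGTACTTGGC"  # one pmoC374 expansion
    seq[798 : 798 + 18] = "ACTTCTGGGGATGGACGT"  # one pmoA344 binding-site expansion
    rec = OperonRecord("r", "".join(seq))
    hits = [h for h in find_amplicons(fwd, rev, rec) if h.fwd_mm == 0 and h.rev_mm == 0]
    assert len(hits) == 1
    h = hits[0]
    assert (h.forward_start, h.reverse_end, h.length) == (100, 816, 717)
    assert h.sequence == "".join(seq)[99:816]


def test_forward_site_alone_yields_nothing():
    rng = np.random.default_rng(2)
    seq = list(rng.choice(list("ACGT"), 400))
    fwd, rev = _pair()
    seq[49 : 49 + 18] = "AGCAAGACGGTACTTGGC"
    hits = find_amplicons(fwd, rev, OperonRecord("r", "".join(seq)), max_mm=0)
    assert hits == []


def test_family_amplicon_lengths_equal_planted_arithmetic(family, primer_set):
    """Per record: length = (pmoC.end - fwd.start + 1) + spacer + (rev.end -
    pmoA.start + 1), with all planted coordinates known exactly."""
    fwd, rev = primer_set["pmoC374"], primer_set["pmoA344"]
    for rec in family.records:
        hits = [
            h
            for h in find_amplicons(fwd, rev, rec)
            if h.forward_start == rec.genes["pmoC"].start + 374 - 1
        ]
        assert len(hits) >= 1
        h = hits[0]
        expected = (
            (rec.genes["pmoC"].end - h.forward_start + 1)
            + rec.intergenic_length()
            + (327 + 18 - 1)
        )
        assert h.length == expected
        assert h.intergenic == rec.intergenic_length()


def test_amplicons_rematch_their_primers(family, primer_set):
    """Self-consistency: each product starts/ends with windows matching the
    primers at the reported mismatch counts."""
    fwd, rev = primer_set["pmoC374"], primer_set["pmoA344"]
    for rec in family.records[:6]:
        for h in find_amplicons(fwd, rev, rec):
            assert fwd.binding_motif.mismatch_count(h.sequence[:18]) == h.fwd_mm
            assert rev.binding_motif.mismatch_count(h.sequence[-18:]) == h.rev_mm


def test_hit_set_invariant_under_record_reverse_complement(family, primer_set):
    """On the reverse-complemented record the same products are found with the
    primers' roles swapped onto the opposite strand."""
    fwd, rev = primer_set["pmoC374"], primer_set["pmoA344"]
    for rec in family.records[:4]:
        plus = find_amplicons(fwd, rev, rec)
        rc = rec.reverse_complement()
        # swap: on the rc record, the reverse primer's motif is now the
        # forward-facing site and vice versa
        swapped_fwd = PrimerSpec("f", rev.sequence, "forward")
        swapped_rev = PrimerSpec("r", fwd.sequence, "reverse")
        minus = find_amplicons(swapped_fwd, swapped_rev, rc)
        assert sorted(h.length for h in plus) == sorted(h.length for h in minus)


def test_zero_mismatch_hits_equal_expansion_intersection(family, primer_set):
    """With max_mm=0 the hit set equals the brute-force intersection of exact
    expansion matches of both primers."""
    fwd, rev = primer_set["pmoC374"], primer_set["pmoA344"]
    f_exp = set(fwd.binding_motif.expand(64))
    r_exp = set(rev.binding_motif.expand(64))
    for rec in family.records[:6]:
        seq = rec.sequence
        f_sites = [i for i in range(len(seq) - 17) if seq[i : i + 18] in f_exp]
        r_sites = [i for i in range(len(seq) - 17) if seq[i : i + 18] in r_exp]
        brute = sorted(
            (f + 1, r + 18)
            for f in f_sites
            for r in r_sites
            if r + 17 > f and 100 <= r + 18 - f <= 2000
        )
        got = sorted(
            (h.forward_start, h.reverse_end)
            for h in find_amplicons(fwd, rev, rec, max_mm=0)
        )
        assert got == brute


def test_length_profile_flags_separable_groups(family_factory, primer_set):
    """Groups planted with spacer means 90 and 150 (sd 5) produce disjoint
    product-length ranges and are flagged length-separable."""
    fwd, rev = primer_set["pmoC374"], primer_set["pmoA344"]
    fam_a = family_factory(seed=31, groups=(("Short", 8),), spacer_ca=(90.0, 5.0))
    fam_b = family_factory(seed=32, groups=(("Long", 8),), spacer_ca=(150.0, 5.0))
    records = fam_a.records + fam_b.records
    hits = [h for r in records for h in find_amplicons(fwd, rev, r)]
    stats, separable = amplicon_length_profile(hits, records)
    assert ("Long", "Short") in separable or ("Short", "Long") in separable
    mean_short = stats.loc[stats["group"] == "Short", "mean"].item()
    assert abs(mean_short - (90 + 380 + 344)) < 15


def test_single_hit_profile_degenerate_stats(family, primer_set):
    fwd, rev = primer_set["pmoC374"], primer_set["pmoA344"]
    rec = family.records[0]
    hits = find_amplicons(fwd, rev, rec)[:1]
    stats, _ = amplicon_length_profile(hits, [rec])
    row = stats.iloc[0]
    assert row["mean"] == row["min"] == row["max"]


def test_residue_anchor_glutamine_and_phenylalanine(family, primer_set):
    """The forward binding site encodes Gln (CAR) and the reverse site's
    coding strand encodes Phe (TTC), both read at frame offset 2."""
    rec = family.records[0]
    ok_q, res_q = residue_anchor_check(primer_set["pmoC374"], rec, "Q", frame=2)
    assert ok_q and res_q == "Q"
    ok_f, res_f = residue_anchor_check(primer_set["pmoA344"], rec, "F", frame=2)
    assert ok_f and res_f == "F"


def test_residue_anchor_ambiguous_codon_reports_x():
    """An unknown base (N) inside the first translated codon renders 'X' and
    fails the check."""
    rng = np.random.default_rng(8)
    seq = list(rng.choice(list("ACGT"), 200))
    seq[50 : 50 + 18] = "AGCAAGACGGTACTTGGC"
    seq[53] = "N"  # frame-2 first codon of the site becomes CNR-like
    rec = OperonRecord("r", "".join(seq), {"pmoC": GeneInterval(1, 200)})
    primer = PrimerSpec("pmoC374", DegenerateSequence("AGCARGACGGYACNTGGC"), "forward", "pmoC")
    ok, observed = residue_anchor_check(primer, rec, "Q", frame=2)
    assert not ok and observed == "X"


def test_residue_anchor_outside_gene_errors(primer_set):
    """A best hit landing outside every annotated gene is a hard error: the
    anchor is a coding-frame statement and needs a gene to live in."""
    rng = np.random.default_rng(9)
    seq = list(rng.choice(list("ACGT"), 200))
    seq[100 : 100 + 18] = "AGCAAGACGGTACTTGGC"
    # only pmoB is annotated, so the pmoC374 search falls back to the whole
    # record and its hit lies outside the annotated gene
    rec = OperonRecord("r", "".join(seq), {"pmoB": GeneInterval(1, 50)})
    with pytest.raises(ValueError, match="not inside"):
        residue_anchor_check(primer_set["pmoC374"], rec, "Q", frame=2)
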