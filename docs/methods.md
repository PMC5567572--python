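# Methods

## Model of primer–template binding

A degenerate primer is a string over the 15 IUPAC nucleotide codes, read
5'→3'; it denotes the pool of concrete oligonucleotides obtained by
choosing one base from each position's set, and its *degeneracy* is the
pool size (product of per-position set sizes). Binding is modelled
purely combinatorially: a primer matches a concrete window wherever each
window base lies in the corresponding base set. The mismatch count of a
window is the number of positions violating this, which for concrete
windows equals the minimum Hamming distance over the expansion pool.
Three deliberate simplifications:

- **positional only** — no indels inside the primer window; a gap (`-`,
  `.`) or unknown base (`N`) in the template always counts as a
  mismatch, since a primer cannot pair with a deletion or an unknown;
- **unweighted** — a 3'-terminal mismatch counts the same as an internal
  one. Experimentally 3' mismatches are more disruptive, but coverage
  tables in this field count mismatches unweighted, and no defensible
  weighting scheme is available, so none is guessed;
- **no thermodynamics** — no nearest-neighbor ΔG, dangling ends or salt
  correction. Melting temperatures are screening numbers only (below).

Reverse primers are stored 5'→3' as ordered; everywhere they are
*searched*, the plus-strand binding motif (their reverse complement) is
used. This is conventional in-silico PCR semantics and makes a
forward/reverse pair a pair of plus-strand motifs with an orientation
constraint.

## Primer design

Given an alignment of an operon family, every window of the configured
length is examined. The candidate consensus for a set of rows is the
per-position union of their bases — the unique minimal degenerate
sequence matching all of them exactly — so design reduces to subset
selection: choose rows whose union stays within the degeneracy budget
while covering as much of the group as possible. Coverage counts rows
with 0 mismatches to the consensus (rows gapped inside the window can
never be covered but remain in the denominator).

Selection is exact for ≤ 15 distinct eligible rows: a depth-first
enumeration over row subsets, pruned by the fact that degeneracy is
monotone under subset growth, with an immediate shortcut when the full
union already fits the budget (it is then optimal for both coverage and
minimality). Larger groups use a drop-worst heuristic — repeatedly
remove the row whose exclusion most reduces the union degeneracy — with
the exact search retained as the small-instance oracle in the tests.
Ties everywhere prefer earlier input rows, making output order a pure
function of the input.

Accepted candidates satisfy all constraints jointly; the defaults encode
the published design rules: length 18 nt, GC 50–70%, group coverage
≥ 50% at 0 mismatches, degeneracy ≤ 64 (the published primers have 16,
4 and 12; 64 bounds runtime while admitting them comfortably), and an
off-target margin of ≥ 6 mismatches — the strict reading of "more than
five". The margin is the minimum, over every off-target sequence and
both strands, of the best window's mismatch count; an empty off-target
set is an error rather than a silent pass. Ranking is fully specified:
coverage (desc), degeneracy (asc), |GC − midpoint| (asc), leftmost
window.

One consequence surfaced by testing and worth knowing: when a conserved
window is flanked by another conserved column, the one-base-shifted
window can tie on coverage and *win* on degeneracy (the realized union
of a 4-fold position in a finite sample is often narrower than the
designed motif). The planted-recovery tests therefore assert recovery
of the conserved *region*, not byte-equality of one offset.

### GC convention

GC content of a degenerate primer counts only literal `G`/`C` positions
in the numerator while all positions stay in the denominator. This is
the only simple convention consistent with the published values for the
forward (10/18 → 56%) and reverse (9/18 → 50%) primers; an expansion-
averaged or min/max convention reproduces neither.

### Melting temperatures

Two labeled formulas are reported as (min, max) over the expansion
pool: the Wallace rule 2(A+T) + 4(G+C) and 81.5 + 0.41·%GC − 675/N (°C).
Both are additive in the per-position base choice, so the extremes are
computed per position without enumerating the pool; the equivalence is
tested against full enumeration. The melting temperatures printed
alongside the original primer set match no standard formula we tried,
so no attempt is made to reproduce them; the two formulas here are
clearly named in the output instead.

## Coverage evaluation

Coverage tables report, per (lineage group, primer), how many records
the primer targets *within* k mismatches for k = 0…3 — cumulative
tiers, the only reading under which rows rising from m/n at 0 to n/n at
1 are coherent. The search region defaults to the primer's annotated
reference gene (falling back to the whole record, logged), which keeps
counts per gene family rather than crediting chance hits in flanking
DNA. Best hits break ties leftmost.

## In-silico PCR

A product is reported for every (forward site, downstream reverse site)
pair with both mismatch counts ≤ the allowance (default 3, matching the
highest coverage tier) and length within bounds (default 100–2000 bp:
wide enough for intergenic variation around the ~850 bp target, narrow
enough to exclude genome-scale false pairs). Nested and overlapping
products are all reported. Residue anchors translate the binding site's
plus-strand sequence at an explicit frame offset — frame 2 places the
first complete codon at the published anchors, glutamine (CAR) at the
forward site and phenylalanine (TTC) on the reverse site's coding
strand; a codon whose expansions disagree renders `X` and fails the
check. The frame is a parameter, not inferred, because residue- and
nucleotide-numbering conventions for these anchors are easily conflated.

## Synthetic families

The generator emulates a curated operon database at the scale the
workflow was built for: three-gene operons (defaults 753/744/840 nt for
pmoC/pmoA/pmoB — the pmoC length puts the planted forward window 380 bp
before the gene end, reproducing the ~850 bp product arithmetic),
lineage ancestors diverged ~10% from a shared root, records diverged 2%
from their ancestor, a pmoC–pmoA spacer drawn from a truncated normal
with mean 120 bp and sd 15 (the reported average), and planted
conserved windows: the pmoC374 motif at gene position 374 and the
pmoA344 binding motif ending at position 344. Planted windows are
immune to background mutation; each record instantiates a uniform
expansion of the motif and then receives *exactly* the configured
number of extra mismatches (drawn outside the motif's base sets, at
non-N positions, so the count is exact by construction). Every planted
coordinate, mismatch count and spacer draw is recorded in a truth
table, so evaluation and amplification can be checked without
tolerance.

Off-target (amo-like) records descend from the same root at ~35%
divergence and are emitted only after verification that every planted
motif's best window, on both strands, carries at least the configured
margin; windows below the margin are repaired by substituting matching
positions (an unreachable margin, e.g. an all-N motif, is a hard
error). A single numpy generator seeded once drives all draws;
identical configurations are byte-identical.

What the generator does **not** emulate: tree-structured evolution
(divergence is star-shaped per lineage), codon structure and selection
(genes are random sequences, conserved only where planted), horizontal
transfer, multiple operon copies per genome with copy-specific
divergence, and sequencing artifacts. Tests passing on these fixtures
therefore demonstrate that the algorithms do what they claim on inputs
with known truth — not that the published primers cover real, unseen
methanotroph diversity. The original genome database is not enumerated
in print, so its coverage cells are treated as non-reproducible;
property-based checks on planted truth stand in for them.

## Problem sizes and numerics

Default test fixtures use 24-record families (three lineages); the
spacer-statistics check uses 500 records (sd of the sample mean
15/√500 ≈ 0.67 bp, so the observed mean sits within ±2 bp of 120).
Planted-motif recovery is checked across 20 seeds at elevated
divergence (lineage 18%, background 4%), keeping background identity
below 80%. Mismatch profiling is vectorized (4-bit base masks, sliding
windows); subset search packs windows into integers (4 bits per
position) so consensus union is a single OR. All coordinates are
1-based inclusive in interfaces, 0-based internally.
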