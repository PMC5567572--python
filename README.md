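# pmoca

Degenerate primer design, mismatch-tiered coverage evaluation and
in-silico PCR for **pmoCAB-type operon families** — the particulate
methane monooxygenase operons of aerobic methanotrophic bacteria (MOB)
and their homologs in the copper membrane monooxygenase (CuMMO)
superfamily.

## The problem

PCR surveys of methanotroph diversity classically target *pmoA*, but the
standard *pmoA* primers miss entire methanotrophic phyla
(*Verrucomicrobia*, NC10). A broader marker is the region spanning the
3' end of *pmoC*, the variable *pmoC*–*pmoA* intergenic spacer
(~120 bp on average), and the 5' part of *pmoA*: conserved windows in
both genes admit degenerate primers, while the spacer's length variation
makes the amplicon (~850 bp) lineage-diagnostic. Such primers must also
*not* amplify the homologous ammonia monooxygenase (*amo*) genes of
ammonia oxidizers and comammox.

`pmoca` packages that workflow as reusable, testable components:

- **iupac** — IUPAC ambiguity-code algebra: matching, reverse
  complement, degeneracy (product of per-position base-set sizes),
  expansion, positional mismatch counting (gaps always mismatch).
- **seqio** — FASTA, annotation/group TSVs, operon records with 1-based
  gene intervals, alignment column↔coordinate maps, degenerate-aware
  translation.
- **design** — window scan for degenerate consensus primers under
  explicit constraints (default: 18-mers, 50–70% GC, ≥50% group coverage
  at 0 mismatches, degeneracy ≤ 64) with off-target screening (best hit
  anywhere in the *amo*-like set, both strands, must keep > 5
  mismatches).
- **evaluate** — per-lineage coverage tables at 0/1/2/3 mismatches
  (cumulative "within k" tiers).
- **amplify** — in-silico PCR: all admissible forward/reverse site
  pairs, product lengths, intergenic spans, per-lineage length profiles,
  and residue anchors at the binding sites (the forward site encodes
  Gln, the reverse site's coding strand Phe).
- **props** — primer property report: unambiguous-only GC, degeneracy,
  Wallace and GC-formula melting-temperature ranges over the expansion
  pool.
- **synth** — a synthetic operon-family generator with planted conserved
  windows, controlled per-record mismatch counts, truncated-normal
  spacers and a margin-verified off-target family; every planted
  quantity is recorded in a truth table.

The published three-primer set (pmoC374 `AGCARGACGGYACNTGGC`, pmoA189
`GGNGACTGGGACTTCTGG`, pmoA344 `ANGTCCAHCCCCAGAAGT`) ships with the
package.

## Worked example

```bash
# generate a ground-truthed synthetic operon family (3 lineages, 24 records)
pmoca simulate --seed 7 --out-dir fixtures/

# design forward candidates on pmoC, screened against the amo-like set
pmoca design --alignment fixtures/alignment.fasta \
             --annotations fixtures/annotations.tsv \
             --groups fixtures/groups.tsv \
             --target-gene pmoC \
             --offtarget fixtures/offtarget.fasta \
             --out candidates.tsv
```

The top row of `candidates.tsv`:

```
name     sequence            gene  ref_position  coverage0  degeneracy  gc  offtarget_margin
pmoC374  AGCARGACGGYACNTGGC  pmoC  374           1.0        16          56  6
```

i.e. the scan rediscovers the published forward primer at position 374
of *pmoC*: it covers 24/24 records exactly (coverage0 = 1.0), pools 16
concrete variants (R·Y·N = 2·2·4), has 56% GC, and its best hit in the
off-target family still carries 6 mismatches (the "> 5" specificity
rule). In-silico PCR with the packaged pair then yields one product per
record:

```bash
pmoca amplify --sequences fixtures/records.fasta \
              --annotations fixtures/annotations.tsv \
              --groups fixtures/groups.tsv --out amplicons.tsv
```

with product lengths ~780–900 bp (mean ≈ 846 across seeds): 380 bp of
*pmoC* + the record's intergenic spacer + 344 bp of *pmoA*. The primer
property report (`pmoca props`) shows all three packaged primers are
18-mers with degeneracies 16, 4 and 12 and GC 56/56/50 under the
unambiguous-only convention.

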