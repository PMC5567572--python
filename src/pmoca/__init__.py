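"""pmoca: degenerate primer design and in-silico PCR for pmoCAB-type operons.

Toolkit for designing and evaluating degenerate primers on operon
families of the copper membrane monooxygenase superfamily: IUPAC
ambiguity algebra, alignment-window primer design under coverage/GC/
degeneracy/specificity constraints, mismatch-tiered coverage tables,
in-silico PCR across the pmoC-pmoA intergenic region, and a synthetic
operon-family generator for fully ground-truthed testing.
"""

from importlib.resources import files

from .amplify import AmpliconHit, amplicon_length_profile, find_amplicons, residue_anchor_check
from .design import (
    DesignParams,
    PrimerCandidate,
    PrimerPair,
    design_pair,
    offtarget_margin,
    scan_windows,
    window_consensus,
)
from .evaluate import (
    BestHit,
    PrimerSpec,
    best_hit,
    best_hit_both_strands,
    coverage_report,
    coverage_tiers,
    read_primers,
)
from .iupac import DegenerateSequence, matches
from .props import gc_percent, properties_report, tm_gc_bounds, tm_wallace, tm_wallace_bounds
from .seqio import (
    AlignmentSet,
    GeneInterval,
    OperonRecord,
    intergenic_lengths,
    load_records,
    read_fasta,
    translate,
    write_fasta,
)
from .synth import PlantedWindow, SyntheticFamily, SyntheticFamilyConfig, generate_family

__version__ = "0.1.0"


def published_primers() -> list[PrimerSpec]:
    """The packaged pmoC374 / pmoA189 / pmoA344 primer set."""
    return read_primers(files("pmoca").joinpath("data/published_primers.tsv"))
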