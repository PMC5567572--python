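"""Synthetic operon-family generator.

Emulates a curated database of pmoCAB-type operons: per-lineage
ancestors diverge from a common root, records diverge from their
ancestor at a background substitution rate, conserved primer windows are
planted as exact motif expansions (optionally hit with a controlled
number of extra mutations), and the pmoC-pmoA intergenic spacer is drawn
from a truncated normal with a ~120 bp mean.  A diverged amo-like
off-target family is generated alongside, verified to keep a minimum
mismatch margin against every planted motif before emission.

Because gene lengths are fixed within a configuration and only spacer
lengths vary, the generator can emit an exact alignment (spacers padded
with gaps) without running an external aligner.  Every quantity the
generator plants — window coordinates, per-record mismatch counts,
spacer lengths — is recorded in a truth table, so downstream evaluation
and in-silico PCR can be checked against ground truth exactly.

All randomness flows from a single numpy Generator seeded once per run;
identical configurations are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluate import best_hit_both_strands
from .iupac import IUPAC_SETS, DegenerateSequence
from .seqio import AlignmentSet, GeneInterval, OperonRecord, write_fasta

__all__ = [
    "PlantedWindow",
    "SyntheticFamilyConfig",
    "SyntheticFamily",
    "generate_family",
    "generate_offtarget",
]

_BASES = np.array(list("ACGT"))

#: The pmoC374 plus-strand motif and the pmoA344 binding motif (reverse
#: complement of the reverse primer), at their in-gene 1-based starts.
DEFAULT_WINDOWS = (
    ("pmoC", 374, "AGCARGACGGYACNTGGC"),
    ("pmoA", 327, "ACTTCTGGGGDTGGACNT"),
)


@dataclass(frozen=True)
class PlantedWindow:
    """A conserved degenerate motif planted at a fixed in-gene position."""

    gene: str
    start: int  # 1-based within the gene
    motif: str

    def __post_init__(self) -> None:
        DegenerateSequence(self.motif)  # validates the IUPAC string
        if self.start < 1:
            raise ValueError("planted window start must be >= 1")


@dataclass
class SyntheticFamilyConfig:
    """Study conditions for one synthetic operon family.

    Defaults mirror the target system: three-gene operons with ~750 nt
    genes, a pmoC-pmoA spacer of mean 120 bp (sd 15), conserved pmoC374
    and pmoA344 windows, ~10% lineage divergence and 2% within-lineage
    background substitution.
    """

    seed: int = 0
    groups: Sequence[tuple[str, int]] = (
        ("Alphaproteobacteria", 8),
        ("Gammaproteobacteria", 9),
        ("Verrucomicrobia", 7),
    )
    gene_codons: dict[str, int] = field(
        default_factory=lambda: {"pmoC": 251, "pmoA": 248, "pmoB": 280}
    )
    spacer_ca: tuple[float, float] = (120.0, 15.0)  # mean, sd (bp)
    spacer_ab: tuple[float, float] = (30.0, 8.0)
    planted_windows: Sequence[PlantedWindow] = tuple(
        PlantedWindow(*w) for w in DEFAULT_WINDOWS
    )
    lineage_divergence: float = 0.10  # root -> group ancestor, per site
    background_rate: float = 0.02  # ancestor -> record, per site
    #: group -> gene -> per-record extra mutation counts inside the window
    extra_mutations: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    flank: int = 25
    offtarget_n: int = 6
    offtarget_min_mismatches: int = 6
    offtarget_divergence: float = 0.35

    def __post_init__(self) -> None:
        self.planted_windows = tuple(
            w if isinstance(w, PlantedWindow) else PlantedWindow(*w)
            for w in self.planted_windows
        )
        self.groups = tuple((str(g), int(n)) for g, n in self.groups)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticFamilyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "groups" in raw:
            raw["groups"] = [tuple(g) for g in raw["groups"]]
        if "planted_windows" in raw:
            raw["planted_windows"] = [PlantedWindow(*w) for w in raw["planted_windows"]]
        for key in ("spacer_ca", "spacer_ab"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for w in self.planted_windows:
            if w.gene not in self.gene_codons:
                raise ValueError(f"planted window names unknown gene {w.gene!r}")
            gene_len = 3 * self.gene_codons[w.gene]
            if w.start + len(w.motif) - 1 > gene_len:
                raise ValueError(
                    f"planted window {w.gene}:{w.start} (+{len(w.motif)} nt) "
                    f"exceeds gene length {gene_len}"
                )
        for group, per_gene in self.extra_mutations.items():
            labels = {g for g, _ in self.groups}
            if group not in labels:
                raise ValueError(f"extra_mutations names unknown group {group!r}")
            n = dict(self.groups)[group]
            for gene, counts in per_gene.items():
                if len(counts) != n:
                    raise ValueError(
                        f"extra_mutations[{group}][{gene}] has {len(counts)} counts "
                        f"for a {n}-record group"
                    )
                mutable = {
                    w.gene: sum(1 for c in w.motif if len(IUPAC_SETS[c]) < 4)
                    for w in self.planted_windows
                }.get(gene)
                if mutable is None or any(c > mutable for c in counts):
                    raise ValueError(
                        f"mutation counts exceed mutable (non-N) window positions for {gene}"
                    )


@dataclass
class SyntheticFamily:
    """Generated fixture: records, exact alignment, truth table, off-targets."""

    config: SyntheticFamilyConfig
    records: list[OperonRecord]
    alignment: AlignmentSet
    truth: pd.DataFrame
    offtargets: list[tuple[str, str]]

    def write(self, outdir: str | Path) -> None:
        """Emit records.fasta, alignment.fasta, annotations.tsv, groups.tsv,
        truth.tsv and offtarget.fasta under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([(r.id, r.sequence) for r in self.records], outdir / "records.fasta")
        write_fasta(self.alignment.rows.items(), outdir / "alignment.fasta")
        ann_rows = [
            {"record_id": r.id, "gene": g, "start": iv.start, "end": iv.end, "strand": iv.strand}
            for r in self.records
            for g, iv in sorted(r.genes.items())
        ]
        pd.DataFrame(ann_rows).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"record_id": r.id, "group": r.group} for r in self.records]
        ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        path = outdir / "offtarget.fasta"
        if self.offtargets:
            write_fasta(self.offtargets, path)
        else:
            path.write_text("; empty off-target set\n")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float, frozen: np.ndarray) -> np.ndarray:
    """Substitute each non-frozen site with prob ``rate`` (to a different base)."""
    out = seq.copy()
    hit = (rng.random(seq.size) < rate) & ~frozen
    idx = np.flatnonzero(hit)
    out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return out


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def _instantiate_motif(rng: np.random.Generator, motif: str) -> tuple[np.ndarray, str]:
    """Draw one uniform expansion of a degenerate motif."""
    out = []
    for c in motif:
        choices = sorted(IUPAC_SETS[c])
        out.append(choices[rng.integers(0, len(choices))])
    s = "".join(out)
    return np.array(["ACGT".index(c) for c in s]), s


def _apply_extra_mutations(
    rng: np.random.Generator, window: np.ndarray, motif: str, k: int
) -> np.ndarray:
    """Introduce exactly ``k`` mismatches against the motif's base sets.

    Only positions whose base set is not all four bases can mismatch, so
    the k positions are drawn from those (N positions are immutable).
    """
    out = window.copy()
    mutable = [i for i, c in enumerate(motif) if len(IUPAC_SETS[c]) < 4]
    positions = rng.choice(len(mutable), size=k, replace=False)
    for idx in positions:
        p = mutable[idx]
        allowed = IUPAC_SETS[motif[p]]
        forbidden = [i for i, b in enumerate("ACGT") if b not in allowed]
        out[p] = forbidden[rng.integers(0, len(forbidden))]
    return out


def generate_family(config: SyntheticFamilyConfig) -> SyntheticFamily:
    """Generate a synthetic operon family under the configured conditions.

    Per record: genes descend from a group ancestor (itself diverged
    from a shared root) mutated at the background rate outside planted
    windows; each planted window is a fresh uniform expansion of its
    motif plus exactly the configured number of extra mutations; spacers
    are truncated-normal draws.  Fully reproducible from the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_order = ["pmoC", "pmoA", "pmoB"]
    gene_len = {g: 3 * config.gene_codons[g] for g in gene_order}
    windows_by_gene: dict[str, list[PlantedWindow]] = {}
    for w in config.planted_windows:
        windows_by_gene.setdefault(w.gene, []).append(w)
    # frozen masks: planted windows are immune to background mutation
    frozen = {
        g: np.zeros(gene_len[g], dtype=bool) for g in gene_order
    }
    for g, ws in windows_by_gene.items():
        for w in ws:
            frozen[g][w.start - 1 : w.start - 1 + len(w.motif)] = True

    root = {g: _random_seq(rng, gene_len[g]) for g in gene_order}

    records: list[OperonRecord] = []
    aligned_rows: dict[str, str] = {}
    truth_rows: list[dict[str, object]] = []
    max_ca = max_ab = 0
    spacer_draws: dict[str, tuple[int, int, str, str]] = {}

    def draw_spacer(mean: float, sd: float) -> tuple[int, str]:
        n = max(0, int(round(rng.normal(mean, sd))))
        return n, _decode(_random_seq(rng, n))

    parts: dict[str, dict[str, str]] = {}
    for label, n_records in config.groups:
        ancestor = {
            g: _mutate(rng, root[g], config.lineage_divergence, frozen[g])
            for g in gene_order
        }
        for i in range(n_records):
            rid = f"{label}_{i + 1:03d}"
            genes = {}
            planted_info = []
            for g in gene_order:
                arr = _mutate(rng, ancestor[g], config.background_rate, frozen[g])
                for w in windows_by_gene.get(g, []):
                    inst, _ = _instantiate_motif(rng, w.motif)
                    k = config.extra_mutations.get(label, {}).get(g, [0] * n_records)[i]
                    inst = _apply_extra_mutations(rng, inst, w.motif, k)
                    arr[w.start - 1 : w.start - 1 + len(w.motif)] = inst
                    planted_info.append((w, k))
                genes[g] = _decode(arr)
            ca_len, ca_seq = draw_spacer(*config.spacer_ca)
            ab_len, ab_seq = draw_spacer(*config.spacer_ab)
            flank_l = _decode(_random_seq(rng, config.flank))
            flank_r = _decode(_random_seq(rng, config.flank))
            parts[rid] = {
                "flank_l": flank_l,
                "pmoC": genes["pmoC"],
                "ca": ca_seq,
                "pmoA": genes["pmoA"],
                "ab": ab_seq,
                "pmoB": genes["pmoB"],
                "flank_r": flank_r,
            }
            spacer_draws[rid] = (ca_len, ab_len, label, rid)
            max_ca, max_ab = max(max_ca, ca_len), max(max_ab, ab_len)

            pos = config.flank
            intervals = {}
            for g, spacer in (("pmoC", ca_len), ("pmoA", ab_len), ("pmoB", 0)):
                intervals[g] = GeneInterval(pos + 1, pos + gene_len[g])
                pos += gene_len[g] + spacer
            sequence = (
                flank_l + genes["pmoC"] + ca_seq + genes["pmoA"] + ab_seq
                + genes["pmoB"] + flank_r
            )
            rec = OperonRecord(rid, sequence, intervals, group=label)
            records.append(rec)
            for w, k in planted_info:
                truth_rows.append(
                    {
                        "record_id": rid,
                        "group": label,
                        "gene": w.gene,
                        "window_start_gene": w.start,
                        "window_start_record": intervals[w.gene].start + w.start - 1,
                        "window_length": len(w.motif),
                        "planted_mismatches": k,
                        "spacer_ca": ca_len,
                        "spacer_ab": ab_len,
                    }
                )

    # exact alignment: fixed-length segments, spacers right-padded with gaps
    for rec in records:
        p = parts[rec.id]
        ca_len, ab_len, _, _ = spacer_draws[rec.id]
        aligned_rows[rec.id] = (
            p["flank_l"]
            + p["pmoC"]
            + p["ca"] + "-" * (max_ca - ca_len)
            + p["pmoA"]
            + p["ab"] + "-" * (max_ab - ab_len)
            + p["pmoB"]
            + p["flank_r"]
        )

    truth = pd.DataFrame(truth_rows)
    offtargets = generate_offtarget(config, rng, root)
    return SyntheticFamily(
        config=config,
        records=records,
        alignment=AlignmentSet(aligned_rows),
        truth=truth,
        offtargets=offtargets,
    )


def generate_offtarget(
    config: SyntheticFamilyConfig,
    rng: np.random.Generator | None = None,
    root: dict[str, np.ndarray] | None = None,
    max_retries: int = 500,
) -> list[tuple[str, str]]:
    """Generate the amo-like off-target family with a verified margin.

    Each record descends from the family root at the off-target
    divergence (planted windows NOT frozen, so they too diverge).  Before
    emission the record is verified — and repaired where necessary — so
    that its best window against every planted motif, on both strands,
    carries at least the configured mismatch count: any window still
    below the margin has one of its matching positions substituted, for
    at most ``max_retries`` rounds.  An unreachable margin (e.g. an
    all-N motif, which matches everything) fails loudly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    gene_order = ["pmoC", "pmoA", "pmoB"]
    gene_len = {g: 3 * config.gene_codons[g] for g in gene_order}
    if root is None:
        root = {g: _random_seq(rng, gene_len[g]) for g in gene_order}
    motifs = [DegenerateSequence(w.motif) for w in config.planted_windows]
    # scan variants: each motif and its reverse complement, both on the plus
    # strand (equivalent to searching both strands of the record)
    scan_motifs = [m for base in motifs for m in (base, base.reverse_complement())]
    if all(
        all(len(IUPAC_SETS[c]) == 4 for c in m.sequence) for m in motifs
    ) and config.offtarget_min_mismatches >= 1:
        raise RuntimeError(
            "off-target margin unreachable: an all-N motif matches every window"
        )
    no_freeze = {g: np.zeros(gene_len[g], dtype=bool) for g in gene_order}
    out: list[tuple[str, str]] = []
    for i in range(config.offtarget_n):
        seq = "".join(
            _decode(_mutate(rng, root[g], config.offtarget_divergence, no_freeze[g]))
            for g in gene_order
        )
        seq = _repair_margin(rng, seq, scan_motifs, config.offtarget_min_mismatches, max_retries)
        out.append((f"amoLike_{i + 1:03d}", seq))
    return out


def _repair_margin(
    rng: np.random.Generator,
    seq: str,
    scan_motifs: Sequence[DegenerateSequence],
    min_mm: int,
    max_rounds: int,
) -> str:
    """Edit ``seq`` until every motif's best window carries >= ``min_mm``
    mismatches; each round breaks the worst window by substituting one of
    its matching positions with a non-matching base."""
    arr = np.array(list(seq))
    for _ in range(max_rounds):
        worst: tuple[int, DegenerateSequence, int] | None = None
        for m in scan_motifs:
            profile = m.mismatch_profile("".join(arr))
            j = int(np.argmin(profile))
            if worst is None or profile[j] < worst[0]:
                worst = (int(profile[j]), m, j)
        if worst is None or worst[0] >= min_mm:
            return "".join(arr)
        _, motif, start = worst
        matching = [
            p
            for p in range(len(motif))
            if arr[start + p] in IUPAC_SETS[motif.sequence[p]]
        ]
        fixable = [
            p for p in matching if len(IUPAC_SETS[motif.sequence[p]]) < 4
        ]
        if not fixable:
            raise RuntimeError(
                "off-target margin unreachable: window matched only at all-N positions"
            )
        p = fixable[rng.integers(0, len(fixable))]
        allowed = IUPAC_SETS[motif.sequence[p]]
        forbidden = [b for b in "ACGT" if b not in allowed]
        arr[start + p] = forbidden[rng.integers(0, len(forbidden))]
    raise RuntimeError(
        f"off-target generation failed: could not reach a margin of "
        f"{min_mm} mismatches in {max_rounds} repair rounds"
    )
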