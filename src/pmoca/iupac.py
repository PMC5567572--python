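"""IUPAC nucleotide-ambiguity algebra.

A degenerate primer is a pool of concrete oligonucleotides written as a
single string of IUPAC ambiguity codes ("wobbles"): R = A/G, Y = C/T,
N = any base, and so on.  Everything downstream — consensus construction,
coverage tiers, off-target screening, in-silico PCR — reduces to three
primitives defined here: does a symbol match a concrete base, how many
concrete variants does a primer represent (its degeneracy), and how many
positions of a concrete window fall outside the primer's per-position
base sets (the mismatch count).

Matching is positional: no indels inside the primer window, and a gap or
unknown character in the target window always counts as a mismatch (a
primer cannot pair with a deletion).  Input is case-insensitive and U is
normalized to T.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "DegenerateSequence",
    "matches",
    "normalize",
    "encode_concrete",
    "encode_primer_masks",
]

#: IUPAC code -> set of concrete bases it stands for (the 15 nonempty
#: subsets of {A,C,G,T} in bijection with the 15 codes).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse of IUPAC_SETS: base set -> unique code.
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

#: Per-symbol complement (A<->T, C<->G, R<->Y, K<->M, S/W self, B<->V, D<->H).
IUPAC_COMPLEMENT: dict[str, str] = {
    code: SET_TO_CODE[frozenset({"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}

# 4-bit encoding: one bit per concrete base.  A symbol's mask is the OR of
# its base bits; a window position matches iff (window_bit & primer_mask) != 0.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {
    code: int(np.sum([_BASE_BIT[b] for b in bases])) for code, bases in IUPAC_SETS.items()
}

_CONCRETE_LUT = np.zeros(256, dtype=np.uint8)  # unknown chars -> 0 (match nothing)
for _b, _bit in _BASE_BIT.items():
    _CONCRETE_LUT[ord(_b)] = _bit
    _CONCRETE_LUT[ord(_b.lower())] = _bit
_CONCRETE_LUT[ord("U")] = _BASE_BIT["T"]
_CONCRETE_LUT[ord("u")] = _BASE_BIT["T"]


class InvalidSymbolError(ValueError):
    """Raised when a sequence contains a character outside the IUPAC alphabet."""

    def __init__(self, char: str, position: int, context: str = "sequence"):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid IUPAC symbol {char!r} at position {position} (1-based) in {context}"
        )


def normalize(seq: str, *, context: str = "sequence", allow_gaps: bool = False) -> str:
    """Uppercase, map U->T, and validate against the IUPAC alphabet.

    Gap characters '-' and '.' are rejected unless ``allow_gaps`` is set
    (target windows may carry them; primers never do).
    """
    out = []
    for i, ch in enumerate(seq):
        c = ch.upper()
        if c == "U":
            c = "T"
        if c in IUPAC_SETS or (allow_gaps and c in "-."):
            out.append(c)
        else:
            raise InvalidSymbolError(ch, i + 1, context)
    return "".join(out)


def matches(symbol: str, base: str) -> bool:
    """True iff concrete ``base`` is in the symbol's base set."""
    s = normalize(symbol, context="symbol")
    b = normalize(base, context="base")
    if len(s) != 1 or len(b) != 1:
        raise ValueError("matches() takes single characters")
    if b not in "ACGT":
        raise ValueError(f"base must be concrete A/C/G/T, got {base!r}")
    return b in IUPAC_SETS[s]


def encode_concrete(seq: str) -> np.ndarray:
    """Encode a concrete target sequence as per-position base bits (uint8).

    Gaps, N and anything non-ACGT encode to 0, which matches no primer
    symbol — i.e. they count as mismatches everywhere.
    """
    return _CONCRETE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_primer_masks(seq: str) -> np.ndarray:
    """Per-position IUPAC base-set masks of a (normalized) primer string."""
    return np.array([_CODE_MASK[c] for c in seq], dtype=np.uint8)


@dataclass(frozen=True)
class DegenerateSequence:
    """An IUPAC string with 5'->3' polarity; the primer and motif currency.

    Parameters
    ----------
    sequence :
        IUPAC nucleotide string.  Case-insensitive; U is normalized to T;
        gaps are not valid primer symbols.
    name :
        Optional label carried through reports.
    """

    sequence: str
    name: str | None = None
    _masks: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        norm = normalize(self.sequence, context=f"primer {self.name or ''}".strip())
        if not norm:
            raise ValueError("a degenerate sequence must have length >= 1")
        object.__setattr__(self, "sequence", norm)
        object.__setattr__(self, "_masks", encode_primer_masks(norm))

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence

    def base_set(self, i: int) -> frozenset[str]:
        """Base set at 0-based position ``i``."""
        return IUPAC_SETS[self.sequence[i]]

    @property
    def degeneracy(self) -> int:
        """Number of concrete variants: product of per-position set sizes."""
        d = 1
        for c in self.sequence:
            d *= len(IUPAC_SETS[c])
        return d

    def reverse_complement(self) -> "DegenerateSequence":
        """Per-symbol complement then reversal; an involution."""
        rc = "".join(IUPAC_COMPLEMENT[c] for c in reversed(self.sequence))
        return DegenerateSequence(rc, name=self.name)

    def iter_expansions(self) -> Iterator[str]:
        """Yield all concrete variants in lexicographic order."""
        pools = [sorted(IUPAC_SETS[c]) for c in self.sequence]
        for combo in itertools.product(*pools):
            yield "".join(combo)

    def expand(self, cap: int = 4096) -> list[str]:
        """All concrete variants, lexicographically sorted.

        Refuses (with the cap named) when degeneracy exceeds ``cap`` so a
        stray poly-N primer cannot blow up memory.
        """
        d = self.degeneracy
        if d > cap:
            raise ValueError(
                f"degeneracy {d} of {self.sequence!r} exceeds expansion cap {cap}"
            )
        return list(self.iter_expansions())

    def mismatch_count(self, window: str) -> int:
        """Mismatches against an equal-length concrete window.

        A position mismatches when the window base is not in the primer
        symbol's base set; gaps and unknown characters always mismatch.
        Equals the minimum Hamming distance over all expansions when the
        window is concrete.
        """
        if len(window) != len(self.sequence):
            raise ValueError(
                f"window length {len(window)} != primer length {len(self.sequence)}"
            )
        bits = encode_concrete(window)
        return int(np.count_nonzero((bits & self._masks) == 0))

    def mismatch_profile(self, target: str) -> np.ndarray:
        """Mismatch counts of this primer against every window of ``target``.

        Returns an int array of length ``len(target) - len(self) + 1``;
        empty if the target is shorter than the primer.
        """
        L = len(self.sequence)
        if len(target) < L:
            return np.zeros(0, dtype=np.int64)
        bits = encode_concrete(target)
        windows = np.lib.stride_tricks.sliding_window_view(bits, L)
        return np.count_nonzero((windows & self._masks) == 0, axis=1)


def consensus_code(bases: frozenset[str] | set[str]) -> str:
    """The unique IUPAC code for a nonempty subset of {A,C,G,T}."""
    return SET_TO_CODE[frozenset(bases)]
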