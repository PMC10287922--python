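"""Core domain types shared across the pipeline.

All coordinates are 1-based and inclusive, matching the convention used in
the probing literature and in every file this package reads or writes.
Internally, per-position vectors are numpy arrays of length L where index
``i - 1`` holds position ``i``; masked (blind or uncovered) values are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Library tag for fragments ending in a 2',3'-cyclic phosphate (5' cleavage
#: product; its last nucleotide sits immediately upstream of the cleavage site).
LIB_CP = "cP"
#: Library tag for fragments starting with a 5'-hydroxyl (3' cleavage product;
#: its first nucleotide sits immediately downstream of the cleavage site).
LIB_OH = "OH"

LIBRARIES = (LIB_CP, LIB_OH)

#: Number of 5'-terminal positions without cP signal (fragments shorter than
#: the 12-nt mapping floor cannot be placed).
CP_BLIND_5P = 11
#: Number of 3'-terminal positions without OH signal.
OH_BLIND_3P = 12


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence over the RNA alphabet {A, C, G, U}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set("ACGUN")
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains non-RNA characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceStructure:
    """A reference secondary structure in dot-bracket notation.

    ``pairs`` is the set of base pairs (i, j) with i < j, 1-based, derived
    from the dot-bracket string by stack matching.
    """

    transcript_id: str
    dotbracket: str
    pairs: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pairs is None:
            object.__setattr__(self, "pairs", pairs_from_dotbracket(self.dotbracket))

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    def unpaired_mask(self) -> np.ndarray:
        """Boolean vector, True where the position is unpaired."""
        mask = np.ones(self.length, dtype=bool)
        for i, j in self.pairs:
            mask[i - 1] = False
            mask[j - 1] = False
        return mask


def pairs_from_dotbracket(dotbracket: str) -> frozenset:
    """Extract the base-pair set from a dot-bracket string by stack matching.

    Raises ``ValueError`` (with the offending position) on unbalanced
    parentheses or characters outside ``(``, ``)``, ``.``.
    """
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return frozenset(pairs)


@dataclass(frozen=True)
class FragmentRecord:
    """A mapped cleavage fragment in transcript coordinates (1-based, inclusive)."""

    transcript_id: str
    start: int
    end: int
    library: str
    replicate: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(
                f"fragment start must be >= 1 (1-based), got {self.start}"
            )
        if self.end < self.start:
            raise ValueError(
                f"fragment end {self.end} precedes start {self.start}"
            )
        if self.library not in LIBRARIES:
            raise ValueError(
                f"unknown library {self.library!r}; expected one of {LIBRARIES}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RawCountTrack:
    """Per-position cleavage counts for one transcript / library / replicate."""

    transcript_id: str
    library: str
    replicate: str
    counts: np.ndarray  # int, length L

    @property
    def length(self) -> int:
        return len(self.counts)


@dataclass
class NormalizedTrack:
    """Percentile-normalized signal S_i in [0, cap]; NaN at masked positions."""

    transcript_id: str
    library: str
    values: np.ndarray  # float, length L, NaN where masked
    normalizer: float
    replicate: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CoverageReport:
    """Outcome of the per-transcript coverage filter."""

    transcript_id: str
    fraction_covered: float
    mean_read_starts: float
    passes: bool


@dataclass
class UnpairedProfile:
    """Per-position probability q_i of being unpaired, with provenance.

    ``source`` records, per position, which calibrated model produced q:
    "twoD" (both libraries), "cP_only", "OH_only", or "none" (q is NaN).
    """

    transcript_id: str
    q: np.ndarray  # float, length L, NaN where undefined
    source: np.ndarray  # object/str, length L

    @property
    def length(self) -> int:
        return len(self.q)
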