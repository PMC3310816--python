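"""Peptide representation, sliding windows and the indicator-basis encoding.

A length-``N`` peptide offers ``N - S + 1`` candidate binding sites (windows)
of size ``S`` to a peptide-binding module such as an SH3 domain.  Each window
sequence is expanded into an indicator (one-hot style) basis relative to a
per-position *reference* residue: a leading intercept element that is always 1,
followed by one 19-element block per window position.  Within a block the slots
enumerate the 19 non-reference amino acids in alphabetical one-letter order;
the block is all-zero exactly when the position carries its reference residue.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

#: Canonical amino acids, alphabetical by one-letter code.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

#: Indicator slots per window position (all residues minus the reference one).
SLOTS_PER_POSITION: int = len(AA_ALPHABET) - 1


class SequenceError(ValueError):
    """Raised for peptides or windows containing non-canonical residues."""


@dataclass(frozen=True)
class Peptide:
    """A peptide over the 20 canonical amino acids.

    Parameters
    ----------
    id:
        Opaque label (spot id, protein id + offset, ...).
    sequence:
        Uppercase string of canonical one-letter codes.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"peptide {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.sequence):
            if aa not in AA_SET:
                raise SequenceError(
                    f"peptide {self.id!r}: non-canonical residue {aa!r} at "
                    f"position {pos + 1}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Window:
    """A contiguous candidate binding site within a peptide.

    ``start`` is a 0-based offset; the window covers the half-open slice
    ``[start, start + size)`` of the parent peptide.
    """

    peptide_id: str
    start: int
    size: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.size:
            raise ValueError(
                f"window {self.peptide_id!r}@{self.start}: sequence length "
                f"{len(self.sequence)} != size {self.size}"
            )


def enumerate_windows(peptide: Peptide, size: int) -> list[Window]:
    """Enumerate all windows of ``size`` residues, left to right.

    Returns exactly ``N - S + 1`` windows for a length-``N`` peptide when
    ``S <= N`` and an empty list when ``S > N`` (the caller decides whether a
    too-short peptide is an error or is skipped).
    """
    if size < 1:
        raise ValueError(f"window size must be >= 1, got {size}")
    seq = peptide.sequence
    return [
        Window(peptide.id, start, size, seq[start : start + size])
        for start in range(len(seq) - size + 1)
    ]


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-position reference residue for the indicator expansion.

    The reference residue plays the role of the index-zero amino acid: a window
    equal to the reference sequence maps to the all-zero feature blocks and its
    energy is carried entirely by the intercept term.
    """

    residues: tuple[str, ...]
    _slot_maps: tuple[dict, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for pos, aa in enumerate(self.residues):
            if aa not in AA_SET:
                raise SequenceError(
                    f"reference profile: non-canonical residue {aa!r} at "
                    f"position {pos + 1}"
                )
        slot_maps = []
        for ref in self.residues:
            others = [aa for aa in AA_ALPHABET if aa != ref]
            slot_maps.append({aa: i for i, aa in enumerate(others)})
        object.__setattr__(self, "_slot_maps", tuple(slot_maps))

    @property
    def size(self) -> int:
        return len(self.residues)

    def non_reference(self, position: int) -> tuple[str, ...]:
        """The 19 non-reference residues at ``position`` (0-based), in slot order."""
        ref = self.residues[position]
        return tuple(aa for aa in AA_ALPHABET if aa != ref)

    def slot(self, position: int, aa: str) -> int | None:
        """Indicator slot of ``aa`` at ``position``; ``None`` for the reference."""
        if aa == self.residues[position]:
            return None
        try:
            return self._slot_maps[position][aa]
        except KeyError:
            raise SequenceError(
                f"non-canonical residue {aa!r} at window position {position + 1}"
            ) from None


ProfilePolicy = Literal["most_frequent", "fixed_alanine"]


def build_reference_profile(
    windows: Sequence[Window], policy: ProfilePolicy = "most_frequent"
) -> ReferenceProfile:
    """Choose a reference residue per position from training windows.

    ``most_frequent`` takes the modal residue per position (ties broken
    alphabetically); ``fixed_alanine`` uses alanine everywhere.  The choice is
    a parameterization convention only — predicted energies are invariant to it.
    """
    if not windows:
        raise ValueError("cannot build a reference profile from zero windows")
    size = windows[0].size
    if any(w.size != size for w in windows):
        raise ValueError("windows of mixed sizes")
    if policy == "fixed_alanine":
        return ReferenceProfile(("A",) * size)
    if policy != "most_frequent":
        raise ValueError(f"unknown profile policy {policy!r}")
    residues = []
    for pos in range(size):
        counts = Counter(w.sequence[pos] for w in windows)
        best = max(sorted(counts), key=counts.__getitem__)
        residues.append(best)
    return ReferenceProfile(tuple(residues))


def encode_window(window: Window, profile: ReferenceProfile) -> np.ndarray:
    """Indicator feature vector of a window: ``[1, block_1, ..., block_S]``.

    Length is ``1 + 19*S``; block ``s`` holds a single 1 in the slot of the
    observed residue, or is all-zero when the residue equals the reference.
    """
    if window.size != profile.size:
        raise ValueError(
            f"window size {window.size} != profile size {profile.size}"
        )
    vec = np.zeros(1 + SLOTS_PER_POSITION * profile.size, dtype=np.float64)
    vec[0] = 1.0
    for pos, aa in enumerate(window.sequence):
        if aa not in AA_SET:
            raise SequenceError(
                f"window {window.peptide_id!r}@{window.start}: non-canonical "
                f"residue {aa!r} at window position {pos + 1}"
            )
        slot = profile.slot(pos, aa)
        if slot is not None:
            vec[1 + pos * SLOTS_PER_POSITION + slot] = 1.0
    return vec


def design_matrix(
    windows: Iterable[Window],
    profile: ReferenceProfile,
    include_intercept: bool = True,
) -> np.ndarray:
    """Stack window encodings into a dense design matrix (one row per window)."""
    rows = [encode_window(w, profile) for w in windows]
    if not rows:
        ncol = 1 + SLOTS_PER_POSITION * profile.size
        mat = np.empty((0, ncol))
    else:
        mat = np.asarray(rows)
    return mat if include_intercept else mat[:, 1:]
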