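"""MS and SS binding-energy functions.

All energies are dimensionless (RT units): SPOT intensities enter the pipeline
as pseudo-binding energies −ln(BLU), already divided by RT.  The per-window
energy is an additive expansion around a reference sequence,

    G_P(sigma) = J0 + sum_s J[s, a_s],        J[s, ref_s] = 0,

and the Multiple-Site (MS) ensemble energy of a peptide combines all of its
windows as a Boltzmann-weighted free energy,

    G = alpha - ln sum_i exp(-G_P(sigma_i)),

so that adding a binding site can only lower (never raise) the total energy —
extra nearby sites increase the bound population.  The Single-Site (SS) model
instead scores one fixed representative window with the linear expansion.

Identifiability: in the MS model the intercept J0 and the offset alpha are
confounded (alpha - ln sum exp(-J0 - ...) = alpha + J0 - ln sum exp(-...)), so
MS models fix J0 = 0 and let alpha absorb the offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .sequence_space import (
    AA_ALPHABET,
    SLOTS_PER_POSITION,
    Peptide,
    ReferenceProfile,
    Window,
    enumerate_windows,
)

__all__ = [
    "EnergyParams",
    "MSModel",
    "SSModel",
    "EnergyProfile",
    "window_energy",
    "ms_energy",
    "ss_energy",
    "model_to_dict",
    "model_from_dict",
]


@dataclass(frozen=True, eq=False)
class EnergyParams:
    """The J-term table of one window model.

    ``J`` has shape ``(S, 19)``; column ``k`` of row ``s`` is the energy of the
    k-th non-reference residue at window position ``s`` in the slot order of
    ``profile`` (alphabetical with the reference removed).  The reference
    residue's energy is implicitly zero.  ``J0`` is the intercept.
    """

    profile: ReferenceProfile
    J: np.ndarray
    J0: float = 0.0

    def __post_init__(self) -> None:
        J = np.asarray(self.J, dtype=np.float64)
        if J.shape != (self.profile.size, SLOTS_PER_POSITION):
            raise ValueError(
                f"J shape {J.shape} incompatible with window size "
                f"{self.profile.size}"
            )
        if not (np.all(np.isfinite(J)) and np.isfinite(self.J0)):
            raise ValueError("J terms must be finite")
        object.__setattr__(self, "J", J)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnergyParams):
            return NotImplemented
        return (
            self.profile == other.profile
            and self.J0 == other.J0
            and np.array_equal(self.J, other.J)
        )

    @property
    def size(self) -> int:
        return self.profile.size

    def lookup(self, position: int, aa: str) -> float:
        """J value of residue ``aa`` at window ``position`` (0 for the reference)."""
        slot = self.profile.slot(position, aa)
        return 0.0 if slot is None else float(self.J[position, slot])

    def flat(self) -> np.ndarray:
        """``[J0, J_flat]`` — matches the intercept-leading feature vector."""
        return np.concatenate(([self.J0], self.J.ravel()))

    def reparameterized(self, profile: ReferenceProfile) -> "EnergyParams":
        """Equivalent parameters expressed against another reference profile.

        Changing the per-position reference residue shifts the J column block
        by the old energy of the new reference, and folds the total shift into
        the intercept; window energies are unchanged.
        """
        if profile.size != self.size:
            raise ValueError("profile size mismatch")
        J_new = np.zeros_like(self.J)
        shift = 0.0
        for pos in range(self.size):
            base = self.lookup(pos, profile.residues[pos])
            shift += base
            for k, aa in enumerate(profile.non_reference(pos)):
                J_new[pos, k] = self.lookup(pos, aa) - base
        return EnergyParams(profile, J_new, self.J0 + shift)


def window_energy(params: EnergyParams, window: Window) -> float:
    """Additive per-window energy ``J0 + sum_s J[s, a_s]`` (RT units)."""
    if window.size != params.size:
        raise ValueError(
            f"window size {window.size} != model window size {params.size}"
        )
    total = params.J0
    for pos, aa in enumerate(window.sequence):
        total += params.lookup(pos, aa)
    return float(total)


@dataclass(frozen=True)
class EnergyProfile:
    """Per-window energies of a peptide plus the model's total prediction."""

    peptide_id: str
    window_starts: tuple[int, ...]
    window_energies: np.ndarray  # G_P(sigma_i), ordered by window start
    total: float  # predicted ensemble energy (incl. alpha for MS)

    @property
    def argmin_start(self) -> int:
        """Start offset of the minimum-energy window (ties: smaller start)."""
        return self.window_starts[int(np.argmin(self.window_energies))]


@dataclass(frozen=True)
class MSModel:
    """Multiple-Site predictor: log-sum-exp over all windows, plus offset alpha.

    ``alpha`` corrects the imperfect affine mapping from SPOT intensities to
    pseudo-binding energies.  ``params.J0`` must be 0 (see module docstring).
    """

    params: EnergyParams
    alpha: float

    def __post_init__(self) -> None:
        if self.params.J0 != 0.0:
            raise ValueError("MS model requires params.J0 == 0 (alpha absorbs it)")
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")

    @property
    def S(self) -> int:
        return self.params.size

    def predict(self, peptide: Peptide) -> EnergyProfile:
        return ms_energy(self, peptide)

    def reparameterized(self, profile: ReferenceProfile) -> "MSModel":
        """The same predictor expressed against another reference profile."""
        p = self.params.reparameterized(profile)
        return MSModel(
            EnergyParams(profile, p.J, 0.0), self.alpha + p.J0
        )


@dataclass(frozen=True)
class SSModel:
    """Single-Site predictor: linear expansion of one fixed window offset."""

    params: EnergyParams
    site_offset: int

    def __post_init__(self) -> None:
        if self.site_offset < 0:
            raise ValueError("site offset must be >= 0")

    @property
    def S(self) -> int:
        return self.params.size

    def predict(self, peptide: Peptide) -> float:
        return ss_energy(self, peptide)


def ms_energy(model: MSModel, peptide: Peptide) -> EnergyProfile:
    """MS ensemble energy ``alpha - ln sum_i exp(-G_P(sigma_i))``.

    Computed with max-shift stabilization (scipy logsumexp), so window
    energies of order ±1000 RT remain finite.  For a peptide with a single
    window the total reduces exactly to ``alpha + G_P``.
    """
    windows = enumerate_windows(peptide, model.S)
    if not windows:
        raise ValueError(
            f"peptide {peptide.id!r} (length {peptide.length}) is shorter than "
            f"window size {model.S}"
        )
    energies = np.array([window_energy(model.params, w) for w in windows])
    total = model.alpha - logsumexp(-energies)
    return EnergyProfile(
        peptide_id=peptide.id,
        window_starts=tuple(w.start for w in windows),
        window_energies=energies,
        total=float(total),
    )


def ss_energy(model: SSModel, peptide: Peptide) -> float:
    """SS energy: the additive expansion of the window at ``site_offset``."""
    r, S = model.site_offset, model.S
    if r + S > peptide.length:
        raise ValueError(
            f"site offset {r} + window size {S} exceeds length "
            f"{peptide.length} of peptide {peptide.id!r}"
        )
    window = Window(peptide.id, r, S, peptide.sequence[r : r + S])
    return window_energy(model.params, window)


# ---------------------------------------------------------------------------
# Serialization: lossless JSON round-trip (floats via repr -> full precision).
# ---------------------------------------------------------------------------

def _params_to_dict(params: EnergyParams) -> dict:
    table = {}
    for pos in range(params.size):
        table[str(pos + 1)] = {
            aa: params.J[pos, k]
            for k, aa in enumerate(params.profile.non_reference(pos))
        }
    return {
        "S": params.size,
        "reference_profile": "".join(params.profile.residues),
        "amino_acid_order": AA_ALPHABET,
        "J_table": table,
        "J0": params.J0,
    }


def _params_from_dict(d: dict) -> EnergyParams:
    profile = ReferenceProfile(tuple(d["reference_profile"]))
    J = np.zeros((profile.size, SLOTS_PER_POSITION))
    for pos in range(profile.size):
        row = d["J_table"][str(pos + 1)]
        for k, aa in enumerate(profile.non_reference(pos)):
            J[pos, k] = row[aa]
    return EnergyParams(profile, J, float(d["J0"]))


def model_to_dict(model: MSModel | SSModel, provenance: dict | None = None) -> dict:
    """JSON-ready dict for either model kind; round-trip is bit-lossless."""
    d = _params_to_dict(model.params)
    if isinstance(model, MSModel):
        d.update(model_kind="MS", alpha=model.alpha, site_offset=None)
    elif isinstance(model, SSModel):
        d.update(model_kind="SS", alpha=None, site_offset=model.site_offset)
    else:  # pragma: no cover
        raise TypeError(f"not a model: {type(model)}")
    d["provenance"] = provenance or {}
    return d


def model_from_dict(d: dict) -> MSModel | SSModel:
    params = _params_from_dict(d)
    if d["model_kind"] == "MS":
        return MSModel(params, float(d["alpha"]))
    if d["model_kind"] == "SS":
        return SSModel(params, int(d["site_offset"]))
    raise ValueError(f"unknown model_kind {d['model_kind']!r}")


def save_model(model: MSModel | SSModel, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model, provenance), fh, indent=1)


def load_model(path) -> MSModel | SSModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
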