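"""SPOT-array simulator with known ground truth.

Emulates the structure of a per-domain SPOT data set: ~1,000 peptides of
length 13-14 (optionally carrying a proline-rich motif such as PxxP), whose
pseudo-binding energies come from a known multi-site (or single-site) energy
model plus Gaussian noise on the energy scale.  Intensities are back-computed
as BLU = exp(-E), so the noise is log-normal on the intensity scale — the
pipeline's observable -ln(BLU) sees additive error, matching the fitting
model's error term.

The generator is the test bed for every other module: fitting on a simulated
set with the matching window size should recover the true J table (parameter
recovery), and MS-truth vs SS-truth data should separate the two models in
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .energy_models import EnergyParams, MSModel, SSModel, ms_energy, ss_energy
from .sequence_space import (
    AA_ALPHABET,
    AA_SET,
    SLOTS_PER_POSITION,
    Peptide,
    ReferenceProfile,
)
from .spot_io import SpotRecord

__all__ = ["SimConfig", "SyntheticDataset", "simulate", "embed_motif"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated array.

    Defaults mirror the canonical experiment: 1,000 peptides per domain, a
    50/50 mix of 13- and 14-mers, uniform residue usage, an MS truth with
    window size 6, J terms drawn from N(0, 1) RT, offset alpha_true = 5 RT
    (placing ensemble energies in a plausible small-negative range), and
    additive energy noise of sd 0.1 RT.  Motif embedding ('PxxP' style) is
    available but off by default.
    """

    n_peptides: int = 1000
    lengths: tuple[tuple[int, float], ...] = ((13, 0.5), (14, 0.5))
    residue_freqs: Mapping[str, float] | None = None  # None = uniform over 20
    motif: str | None = None  # e.g. "PXXP"; embedded uniformly at random
    truth_kind: str = "MS"  # "MS" or "SS"
    true_S: int = 6
    true_site: int = 0  # SS truth only
    J_mean: float = 0.0
    J_sd: float = 1.0
    alpha_true: float = 5.0
    noise_sd: float = 0.1
    seed: int = 0
    domain: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        props = [p for _, p in self.lengths]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("length proportions must sum to 1")
        if self.truth_kind not in ("MS", "SS"):
            raise ValueError("truth_kind must be 'MS' or 'SS'")
        min_len = min(length for length, _ in self.lengths)
        if self.true_S > min_len:
            raise ValueError("true_S exceeds the shortest peptide length")
        if self.motif is not None and len(self.motif) > min_len:
            raise ValueError("motif longer than the shortest peptide")
        if self.truth_kind == "SS" and self.true_site + self.true_S > min_len:
            raise ValueError("true_site + true_S exceeds the shortest peptide")


@dataclass(frozen=True)
class SyntheticDataset:
    records: tuple[SpotRecord, ...]
    truth: MSModel | SSModel
    config: SimConfig


def embed_motif(
    sequence: str,
    pattern: str,
    start: int | None = None,
    seed: int | None = None,
) -> str:
    """Overwrite literal pattern residues onto a draft sequence.

    Pattern characters are canonical residues or the wildcard 'x'/'X', which
    leaves the draft residue untouched.  With ``start=None`` the placement is
    drawn uniformly over valid offsets using ``seed``.
    """
    for ch in pattern:
        if ch not in AA_SET and ch not in ("x", "X"):
            raise ValueError(f"invalid motif pattern character {ch!r}")
    if len(pattern) > len(sequence):
        raise ValueError("motif pattern longer than the peptide")
    if start is None:
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, len(sequence) - len(pattern) + 1))
    if not (0 <= start <= len(sequence) - len(pattern)):
        raise ValueError(f"motif start {start} out of range")
    chars = list(sequence)
    for i, ch in enumerate(pattern):
        if ch not in ("x", "X"):
            chars[start + i] = ch
    return "".join(chars)


def _truth_model(config: SimConfig, rng: np.random.Generator):
    profile = ReferenceProfile(("A",) * config.true_S)
    J = rng.normal(config.J_mean, config.J_sd, size=(config.true_S, SLOTS_PER_POSITION))
    if config.truth_kind == "MS":
        return MSModel(EnergyParams(profile, J, 0.0), config.alpha_true)
    return SSModel(EnergyParams(profile, J, config.alpha_true), config.true_site)


def simulate(config: SimConfig) -> SyntheticDataset:
    """Draw a reproducible synthetic SPOT data set from a fresh truth model."""
    rng = np.random.default_rng(config.seed)
    truth = _truth_model(config, rng)

    if config.residue_freqs is None:
        alphabet = np.array(list(AA_ALPHABET))
        probs = np.full(len(alphabet), 1.0 / len(alphabet))
    else:
        alphabet = np.array(sorted(config.residue_freqs))
        probs = np.array([config.residue_freqs[aa] for aa in alphabet])
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("residue frequencies must be >= 0 and sum to 1")
        for aa in alphabet:
            if aa not in AA_SET:
                raise ValueError(f"non-canonical residue {aa!r} in frequencies")

    lengths, props = zip(*config.lengths)
    length_draws = rng.choice(lengths, size=config.n_peptides, p=props)

    records = []
    for i, length in enumerate(length_draws):
        seq = "".join(rng.choice(alphabet, size=int(length), p=probs))
        if config.motif is not None:
            start = int(rng.integers(0, int(length) - len(config.motif) + 1))
            seq = embed_motif(seq, config.motif, start=start)
        pep = Peptide(f"pep{i:05d}", seq)
        if config.truth_kind == "MS":
            clean = ms_energy(truth, pep).total
        else:
            clean = ss_energy(truth, pep)
        observed = clean + rng.normal(0.0, config.noise_sd) if config.noise_sd else clean
        records.append(SpotRecord.from_energy(config.domain, pep, float(observed)))
    return SyntheticDataset(records=tuple(records), truth=truth, config=config)
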