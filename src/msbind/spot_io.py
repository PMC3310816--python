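"""SPOT-array tables, pseudo-energy conversion and proteome scanning.

SPOT-synthesis arrays report, per spot, a peptide sequence and a light
intensity in BLU (Boehringer light units).  The pipeline's observable is the
pseudo-binding energy −ln(BLU) in RT units: larger intensity means stronger
binding, hence a lower (more negative) pseudo-energy.

The canonical table format is TSV, UTF-8, header required, '#' comments
allowed, with columns {domain, peptide_id, sequence, intensity, pseudo_energy}
of which only `sequence` plus one of `intensity` / `pseudo_energy` are
mandatory.  Numeric fields are written with 12 significant digits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .sequence_space import Peptide, SequenceError

logger = logging.getLogger(__name__)

__all__ = [
    "SpotRecord",
    "SpotTable",
    "intensity_to_energy",
    "energy_to_intensity",
    "read_spot_table",
    "write_spot_table",
    "iter_fasta_peptides",
]


def intensity_to_energy(blu: float) -> float:
    """Pseudo-binding energy −ln(BLU) in RT units.

    Raises for non-positive or non-finite intensities (a zero spot carries no
    energy information).
    """
    if not math.isfinite(blu) or blu <= 0:
        raise ValueError(f"intensity must be finite and > 0, got {blu!r}")
    return -math.log(blu)


def energy_to_intensity(energy: float) -> float:
    """Inverse map: BLU = exp(−E)."""
    if not math.isfinite(energy):
        raise ValueError(f"pseudo-energy must be finite, got {energy!r}")
    return math.exp(-energy)


@dataclass(frozen=True)
class SpotRecord:
    """One array spot: peptide, intensity (BLU) and pseudo-energy (RT units)."""

    domain: str
    peptide: Peptide
    intensity: float
    pseudo_energy: float

    def __post_init__(self) -> None:
        if not (self.intensity > 0 and math.isfinite(self.intensity)):
            raise ValueError(
                f"record {self.peptide.id!r}: intensity must be finite and > 0"
            )
        if abs(self.pseudo_energy + math.log(self.intensity)) > 1e-9 * max(
            1.0, abs(self.pseudo_energy)
        ):
            raise ValueError(
                f"record {self.peptide.id!r}: pseudo_energy inconsistent with "
                f"-ln(intensity)"
            )

    @classmethod
    def from_intensity(
        cls, domain: str, peptide: Peptide, intensity: float
    ) -> "SpotRecord":
        return cls(domain, peptide, intensity, intensity_to_energy(intensity))

    @classmethod
    def from_energy(
        cls, domain: str, peptide: Peptide, pseudo_energy: float
    ) -> "SpotRecord":
        return cls(domain, peptide, energy_to_intensity(pseudo_energy), pseudo_energy)


@dataclass(frozen=True)
class SpotTable:
    """A validated set of spot records plus ingestion bookkeeping."""

    records: tuple[SpotRecord, ...]
    source: str = "<memory>"
    n_rejected: int = 0
    rejects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        keys = [(rec.domain, rec.peptide.id) for rec in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (domain, peptide_id) keys in table")

    def __len__(self) -> int:
        return len(self.records)

    def energies(self) -> np.ndarray:
        return np.asarray([r.pseudo_energy for r in self.records])


_G12 = "{:.12g}".format


def read_spot_table(path, domain: str | None = None) -> SpotTable:
    """Read a SPOT TSV table, validating and logging rejected rows.

    Rows with non-positive intensity or non-canonical residues are rejected
    (counted and logged with their line context), not fatal.  A table carrying
    only `pseudo_energy` gets intensities back-filled as exp(−E).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = set(df.columns)
    if "sequence" not in cols or not ({"intensity", "pseudo_energy"} & cols):
        raise ValueError(
            f"{path}: need a 'sequence' column plus 'intensity' or "
            f"'pseudo_energy' (found {sorted(cols)})"
        )
    records: list[SpotRecord] = []
    rejects: list[str] = []
    for row_idx, row in df.iterrows():
        pid = (
            str(row["peptide_id"])
            if "peptide_id" in cols and pd.notna(row.get("peptide_id"))
            else str(row_idx)
        )
        dom = (
            str(row["domain"])
            if "domain" in cols and pd.notna(row.get("domain"))
            else (domain or "unknown")
        )
        try:
            pep = Peptide(pid, str(row["sequence"]).strip().upper())
            if "pseudo_energy" in cols and pd.notna(row.get("pseudo_energy")):
                rec = SpotRecord.from_energy(dom, pep, float(row["pseudo_energy"]))
            else:
                rec = SpotRecord.from_intensity(dom, pep, float(row["intensity"]))
            records.append(rec)
        except (ValueError, SequenceError) as exc:
            msg = f"row {row_idx + 2}: {exc}"  # +2: header line, 1-based
            rejects.append(msg)
            logger.warning("%s: rejected %s", path, msg)
    return SpotTable(
        records=tuple(records),
        source=str(path),
        n_rejected=len(rejects),
        rejects=tuple(rejects),
    )


def write_spot_table(table: SpotTable | Sequence[SpotRecord], path) -> None:
    """Write records as canonical TSV (12 significant digits on numerics)."""
    records = table.records if isinstance(table, SpotTable) else tuple(table)
    df = pd.DataFrame(
        {
            "domain": [r.domain for r in records],
            "peptide_id": [r.peptide.id for r in records],
            "sequence": [r.peptide.sequence for r in records],
            "intensity": [_G12(r.intensity) for r in records],
            "pseudo_energy": [_G12(r.pseudo_energy) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def iter_fasta_peptides(
    fasta_path, length: int, step: int = 1
) -> Iterable[Peptide]:
    """Tile each protein in a FASTA file into overlapping L-mers.

    Peptide ids are ``<protein_id>:<start>`` with a 0-based start.  Proteins
    shorter than ``length`` are skipped with a warning; tiles containing
    non-canonical residues are skipped and logged.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    for seqrec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(seqrec.seq).upper()
        if len(seq) < length:
            logger.warning(
                "protein %s (length %d) shorter than %d; skipped",
                seqrec.id, len(seq), length,
            )
            continue
        for start in range(0, len(seq) - length + 1, step):
            tile = seq[start : start + length]
            try:
                yield Peptide(f"{seqrec.id}:{start}", tile)
            except SequenceError:
                logger.warning(
                    "protein %s: tile at %d contains non-canonical residues; "
                    "skipped", seqrec.id, start,
                )
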