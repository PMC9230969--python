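"""Shared structural data model and I/O for the formats the pipeline touches.

Only CA atoms are ever read or written: every computation downstream (TM-score,
core criterion, contact maps) is residue-level.  Residue indexing is 0-based
and positional (file order); author residue numbers are retained only so that
output can refer back to the source file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """Raised when an input file violates the expected format contract."""


@dataclass
class StructureModel:
    """One chain of CA coordinates plus a one-letter sequence.

    Attributes
    ----------
    id : str
        Short unique label for the model.
    seq : str
        One-letter amino-acid sequence, same length as ``coords``.
    coords : (L, 3) float array
        CA coordinates in Angstroms, chain order N to C.
    resnums : list of str
        Author residue numbers (with insertion codes) carried for output only.
    """

    id: str
    seq: str
    coords: np.ndarray
    resnums: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.id:
            raise ValueError("model id must be non-empty")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (L, 3) array")
        if len(self.seq) != len(self.coords):
            raise ValueError(
                f"sequence length {len(self.seq)} != coordinate count {len(self.coords)}"
            )
        if len(self.coords) < 3:
            raise ValueError("a structure model needs at least 3 residues")
        if not self.resnums:
            self.resnums = [str(i + 1) for i in range(len(self.coords))]

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def L(self) -> int:
        return len(self.coords)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "StructureModel":
        """Return a copy with coordinates mapped through x -> R @ x + t."""
        return StructureModel(self.id, self.seq, self.coords @ R.T + t, list(self.resnums))


@dataclass
class SequenceRecord:
    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of non-negative values (distances or scores)."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")

    def __getitem__(self, pair):
        a, b = pair
        return self.values[self.labels.index(a), self.labels.index(b)]

    def to_phylip(self, path) -> None:
        """Write in square PHYLIP distance-matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(f"{lab:<12s}" + " ".join(f"{v:.6f}" for v in row) + "\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join([""] + list(self.labels)) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write("\t".join([lab] + [f"{v:.6f}" for v in row]) + "\n")

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels, np.array(rows))


def read_pdb_ca(path, chain_policy: str = "first", chain_id: str | None = None) -> StructureModel:
    """Read one chain of CA atoms from a PDB file.

    HETATM records are ignored, altloc duplicates collapse to the first seen,
    and for multi-MODEL (NMR-style) files only MODEL 1 is used (with a
    warning).  ``chain_policy`` is ``"first"`` (default: first chain carrying
    a CA) or ``"named"`` (require ``chain_id``).
    """
    path = Path(path)
    seq, coords, resnums = [], [], []
    seen = set()  # (chain, resnum+icode) with a CA already accepted
    selected_chain = chain_id if chain_policy == "named" else None
    if chain_policy == "named" and chain_id is None:
        raise ValueError("chain_policy='named' requires chain_id")
    in_model = 0
    warned_models = False
    for line in path.read_text().splitlines():
        rec = line[:6]
        if rec.startswith("MODEL"):
            in_model += 1
            if in_model > 1:
                if not warned_models:
                    warnings.warn(f"{path.name}: multiple MODELs, using MODEL 1")
                    warned_models = True
                break
        if not rec.startswith("ATOM"):
            continue
        name = line[12:16].strip()
        if name != "CA":
            continue
        chain = line[21]
        if selected_chain is None:
            selected_chain = chain
        if chain != selected_chain:
            continue
        reskey = (chain, line[22:27])
        if reskey in seen:  # altloc duplicate
            continue
        seen.add(reskey)
        resname = line[17:20].strip()
        seq.append(THREE_TO_ONE.get(resname, "X"))
        coords.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
        resnums.append(line[22:27].strip())
    if len(coords) < 3:
        raise FormatError(f"{path}: fewer than 3 CA ATOM records in selected chain")
    return StructureModel(path.stem, "".join(seq), np.array(coords), resnums)


def write_pdb(model: StructureModel, path) -> None:
    """Write a CA-only single-chain (A) PDB file with 3-decimal coordinates."""
    if np.any(np.abs(model.coords) >= 10000):
        raise ValueError("coordinates exceed the fixed-width PDB field (|x| < 10000 A)")
    with open(path, "w") as fh:
        for i, (aa, xyz) in enumerate(zip(model.seq, model.coords)):
            resname = ONE_TO_THREE.get(aa, "UNK")
            fh.write(
                f"ATOM  {i + 1:>5d}  CA  {resname} A{i + 1:>4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("TER\nEND\n")


def read_fasta(path, alignment: bool = False) -> list:
    """Parse a multi-FASTA file; ids truncate at first whitespace.

    Gap characters are only accepted when ``alignment=True``.
    """
    records: list[SequenceRecord] = []
    rid, chunks = None, []

    def flush():
        if rid is not None:
            seq = "".join(chunks)
            if not alignment and "-" in seq:
                raise FormatError(f"record {rid!r}: gap characters in non-alignment FASTA")
            records.append(SequenceRecord(rid, seq))

    for line in Path(path).read_text().splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            rid, chunks = line[1:].split()[0] if line[1:].split() else "", []
            if not rid:
                raise FormatError("FASTA header with empty id")
        else:
            chunks.append(line.strip())
    flush()
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise FormatError(f"duplicate FASTA ids: {', '.join(dupes)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
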