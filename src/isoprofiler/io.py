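"""Reading and writing screening libraries and structure lists."""

from __future__ import annotations

import warnings
from pathlib import Path

from rdkit import Chem

from . import chemstruct
from .chemstruct import StandardizationError, Structure


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """One SMILES per line, optional tab-separated identifier.

    Returns (id, smiles) pairs; ids default to the line number.
    """
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 2:
            out.append((parts[1], parts[0]))
        else:
            out.append((f"L{i}", parts[0]))
    return out


def read_sdf(path: str | Path) -> list[tuple[str, str]]:
    """Read an SDF; returns (id, smiles) pairs (id from the title line)."""
    out = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            warnings.warn(f"unreadable SDF entry #{i} in {path}")
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"M{i}"
        out.append((name or f"M{i}", Chem.MolToSmiles(mol)))
    return out


def read_library(path: str | Path) -> list[tuple[str, str]]:
    """Dispatch on extension: .sdf for SDF, anything else as a SMILES file."""
    if str(path).lower().endswith(".sdf"):
        return read_sdf(path)
    return read_smiles_file(path)


def standardize_library(
    entries: list[tuple[str, str]],
) -> tuple[list[Structure], list[tuple[str, str]]]:
    """Standardize (id, smiles) pairs; returns (structures, failures)."""
    structures, failures = [], []
    for name, smiles in entries:
        try:
            structures.append(chemstruct.standardize(smiles))
        except StandardizationError as exc:
            failures.append((name, str(exc)))
    return structures, failures


def write_smiles_file(path: str | Path, entries: list[tuple[str, str]]) -> None:
    """Write (id, smiles) pairs as ``SMILES<tab>id`` lines."""
    Path(path).write_text("".join(f"{smiles}\t{name}\n" for name, smiles in entries))
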