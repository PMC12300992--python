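"""A fixed dictionary of exactly 881 substructure keys.

Each bit flags a predefined structural motif, in the spirit of the
CACTVS/PubChem key layout: hierarchical element-count thresholds, ring
features, bonded element pairs and linear triples/quadruples, and a block of
named functional groups. The dictionary is generated deterministically at
import time and is versioned by :data:`KEYSET_VERSION`; it is *not*
bit-compatible with the PubChem service's own keys, but obeys the same
contract (fixed length 881, one motif per bit, binary presence/absence).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem

KEYSET_VERSION = "isoprofiler-keys-1"
N_KEYS = 881

_ELEMENTS = ["B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"]
_NUMS = {"B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16, "Cl": 17, "Br": 35, "I": 53}

# (symbol, count thresholds); "H" counts implicit+explicit hydrogens
_ELEMENT_COUNTS = [
    ("H", (4, 8, 16, 24)),
    ("B", (1, 2)),
    ("C", (2, 4, 8, 16, 24, 32)),
    ("N", (1, 2, 4, 6, 8)),
    ("O", (1, 2, 4, 6, 8, 12)),
    ("F", (1, 2, 4)),
    ("P", (1, 2)),
    ("S", (1, 2, 4)),
    ("Cl", (1, 2, 4)),
    ("Br", (1, 2)),
    ("I", (1,)),
]

_RING_SIZES = range(3, 11)
_RING_KINDS = ("any", "aromatic", "saturated", "hetero", "nitrogen")
_RING_COUNTS = (1, 2)

_FUNCTIONAL_GROUPS = [
    ("primary_sulfonamide", "[SX4](=O)(=O)[NX3H2]"),
    ("secondary_sulfonamide", "[SX4](=O)(=O)[NX3H1]"),
    ("sulfone", "[SX4](=O)(=O)([#6])[#6]"),
    ("sulfoxide", "[SX3](=O)([#6])[#6]"),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("ester", "[CX3](=O)[OX2][#6]"),
    ("amide", "[CX3](=O)[NX3]"),
    ("nitro", "[NX3](=O)=O"),
    ("nitrile", "[CX2]#[NX1]"),
    ("primary_amine", "[NX3H2][#6]"),
    ("secondary_amine", "[NX3H1]([#6])[#6]"),
    ("tertiary_amine", "[NX3]([#6])([#6])[#6]"),
    ("phenol", "[OX2H][c]"),
    ("aliphatic_alcohol", "[OX2H][CX4]"),
    ("ether", "[OX2]([#6])[#6]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("thiol", "[SX2H]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("ketone", "[CX3](=O)([#6])[#6]"),
    ("urea", "[NX3][CX3](=O)[NX3]"),
    ("carbamate", "[NX3][CX3](=O)[OX2]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("aryl_halide", "[F,Cl,Br,I][c]"),
    ("trifluoromethyl", "[CX4](F)(F)F"),
    ("phosphate_like", "[PX4](=O)"),
    ("imine", "[CX3]=[NX2]"),
    ("azo", "[NX2]=[NX2]"),
    ("hydrazine_like", "[NX3][NX3]"),
    ("pyridine", "n1ccccc1"),
    ("pyrimidine", "n1ccncc1"),
    ("imidazole", "c1cnc[nH]1"),
    ("pyrazole", "c1cc[nH]n1"),
    ("thiophene", "c1ccsc1"),
    ("furan", "c1ccoc1"),
    ("oxazole", "c1ocnc1"),
    ("thiazole", "c1scnc1"),
    ("triazole", "c1nnc[nH]1"),
    ("tetrazole", "c1nnn[nH]1"),
    ("cyclic_amine", "[NX3;R]"),
    ("benzene_ring", "c1ccccc1"),
]


@dataclass(frozen=True)
class Key:
    """One dictionary entry: a named motif and how to detect it."""

    name: str
    kind: str  # "element", "ring", "smarts"
    payload: tuple


def _pair_smarts() -> list[tuple[str, str]]:
    out = []
    for i, a in enumerate(_ELEMENTS):
        for b in _ELEMENTS[i:]:
            out.append((f"pair_{a}_{b}", f"[#{_NUMS[a]}]~[#{_NUMS[b]}]"))
    return out


def _triple_smarts() -> list[tuple[str, str]]:
    out = []
    for center in ("C", "N", "O", "S", "P"):
        for i, a in enumerate(_ELEMENTS):
            for b in _ELEMENTS[i:]:
                out.append(
                    (
                        f"triple_{a}_{center}_{b}",
                        f"[#{_NUMS[a]}]~[#{_NUMS[center]}]~[#{_NUMS[b]}]",
                    )
                )
    return out


def _quad_smarts(limit: int) -> list[tuple[str, str]]:
    # linear 4-atom paths, canonicalized under reversal, interior atoms C/N/O
    seen = set()
    out = []
    for a in _ELEMENTS:
        for y in ("C", "N", "O"):
            for z in ("C", "N", "O"):
                for b in _ELEMENTS:
                    tup = (a, y, z, b)
                    canon = min(tup, tup[::-1])
                    if canon in seen:
                        continue
                    seen.add(canon)
                    a_, y_, z_, b_ = canon
                    out.append(
                        (
                            f"quad_{a_}_{y_}_{z_}_{b_}",
                            f"[#{_NUMS[a_]}]~[#{_NUMS[y_]}]~[#{_NUMS[z_]}]~[#{_NUMS[b_]}]",
                        )
                    )
    return out[:limit]


def _bond_order_pairs() -> list[tuple[str, str]]:
    out = []
    bonds = [("single", "-"), ("double", "="), ("triple", "#"), ("aromatic", ":")]
    elems = ("C", "N", "O", "S")
    for i, a in enumerate(elems):
        for b in elems[i:]:
            for bname, sym in bonds:
                out.append((f"bond_{a}_{bname}_{b}", f"[#{_NUMS[a]}]{sym}[#{_NUMS[b]}]"))
    return out


def _build_dictionary() -> list[Key]:
    keys: list[Key] = []
    for sym, thresholds in _ELEMENT_COUNTS:
        for t in thresholds:
            keys.append(Key(f"count_{sym}_ge_{t}", "element", (sym, t)))
    for size in _RING_SIZES:
        for kind in _RING_KINDS:
            for count in _RING_COUNTS:
                keys.append(Key(f"ring{size}_{kind}_ge_{count}", "ring", (size, kind, count)))
    for name, sm in _pair_smarts():
        keys.append(Key(name, "smarts", (sm,)))
    for name, sm in _triple_smarts():
        keys.append(Key(name, "smarts", (sm,)))
    for name, sm in _bond_order_pairs():
        keys.append(Key(name, "smarts", (sm,)))
    for name, sm in _FUNCTIONAL_GROUPS:
        keys.append(Key(name, "smarts", (sm,)))
    remaining = N_KEYS - len(keys)
    if remaining < 0:  # pragma: no cover - dictionary is static
        raise RuntimeError("key dictionary overflow")
    for name, sm in _quad_smarts(remaining):
        keys.append(Key(name, "smarts", (sm,)))
    if len(keys) != N_KEYS:  # pragma: no cover
        raise RuntimeError(f"key dictionary has {len(keys)} entries, expected {N_KEYS}")
    return keys


KEYS: list[Key] = _build_dictionary()


@lru_cache(maxsize=1)
def _compiled_smarts() -> dict[int, Chem.Mol]:
    out = {}
    for i, key in enumerate(KEYS):
        if key.kind == "smarts":
            patt = Chem.MolFromSmarts(key.payload[0])
            if patt is None:  # pragma: no cover - all patterns are static and valid
                raise ValueError(f"invalid SMARTS for key {key.name!r}")
            out[i] = patt
    return out


def _element_counts(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    h = 0
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h += atom.GetTotalNumHs()
    counts["H"] = h
    return counts


def _ring_features(mol: Chem.Mol) -> dict[tuple[int, str], int]:
    feats: dict[tuple[int, str], int] = {}
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        size = len(ring)
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        aromatic = all(a.GetIsAromatic() for a in atoms)
        bonds = [
            mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % size]) for i in range(size)
        ]
        saturated = all(
            b.GetBondType() == Chem.BondType.SINGLE and not b.GetIsAromatic() for b in bonds
        )
        hetero = any(a.GetAtomicNum() != 6 for a in atoms)
        nitrogen = any(a.GetAtomicNum() == 7 for a in atoms)
        kinds = ["any"]
        if aromatic:
            kinds.append("aromatic")
        if saturated:
            kinds.append("saturated")
        if hetero:
            kinds.append("hetero")
        if nitrogen:
            kinds.append("nitrogen")
        for kind in kinds:
            feats[(size, kind)] = feats.get((size, kind), 0) + 1
    return feats


def compute_keys(mol: Chem.Mol) -> np.ndarray:
    """Return the 881-bit key vector (dtype uint8) for a molecule."""
    bits = np.zeros(N_KEYS, dtype=np.uint8)
    counts = _element_counts(mol)
    rings = _ring_features(mol)
    smarts = _compiled_smarts()
    for i, key in enumerate(KEYS):
        if key.kind == "element":
            sym, t = key.payload
            if counts.get(sym, 0) >= t:
                bits[i] = 1
        elif key.kind == "ring":
            size, kind, count = key.payload
            if rings.get((size, kind), 0) >= count:
                bits[i] = 1
        else:
            if mol.HasSubstructMatch(smarts[i]):
                bits[i] = 1
    return bits


def key_atom_sets(mol: Chem.Mol, bit_index: int) -> list[frozenset[int]]:
    """Atom-index sets that set a given on-bit in this molecule.

    Element keys map to the atoms of that element, ring keys to the matching
    rings' atoms, SMARTS keys to every substructure match.
    """
    key = KEYS[bit_index]
    if key.kind == "element":
        sym = key.payload[0]
        if sym == "H":
            return [frozenset(a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0)]
        atoms = frozenset(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == sym)
        return [atoms] if atoms else []
    if key.kind == "ring":
        size, kind, _count = key.payload
        out = []
        ri = mol.GetRingInfo()
        feats_needed = kind
        for ring in ri.AtomRings():
            if len(ring) != size:
                continue
            atoms = [mol.GetAtomWithIdx(i) for i in ring]
            ok = {
                "any": True,
                "aromatic": all(a.GetIsAromatic() for a in atoms),
                "saturated": all(
                    mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % size]).GetBondType()
                    == Chem.BondType.SINGLE
                    for i in range(size)
                ),
                "hetero": any(a.GetAtomicNum() != 6 for a in atoms),
                "nitrogen": any(a.GetAtomicNum() == 7 for a in atoms),
            }[feats_needed]
            if ok:
                out.append(frozenset(ring))
        return out
    patt = _compiled_smarts()[bit_index]
    return [frozenset(m) for m in mol.GetSubstructMatches(patt)]
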