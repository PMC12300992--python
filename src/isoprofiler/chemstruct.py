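"""Structure standardization, molecular representations, and similarity primitives.

Four representations are supported:

``CIRCULAR_2048``
    Morgan/extended-connectivity fingerprint, radius 2 (ECFP4-like), hashed to
    2048 binary bits.
``PATH_2048``
    RDKit path/subgraph fingerprint, hashed to 2048 binary bits.
``KEYS_881``
    Fixed 881-bit substructure-key dictionary (see :mod:`isoprofiler.keys881`).
``PHYSCHEM``
    The full RDKit 2D descriptor list as a continuous vector, min-max scaled
    on training data only.

Stereochemistry is retained in canonical SMILES but plays no role in any
representation: enantiomers collide at representation level, which is exactly
the premise of the representation-based deduplication in the curation module.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from . import keys881

#: Elements admissible after standardization (hydrogen plus common organics).
ELEMENT_WHITELIST = frozenset(["H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"])

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
_PATH = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)

#: Ordered physicochemical descriptor names (toolkit-versioned).
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(name for name, _fn in Descriptors._descList)


class StandardizationError(ValueError):
    """Raised when a raw SMILES cannot be turned into a standardized structure."""


class FeaturizationError(ValueError):
    """Raised when a representation cannot be computed for a structure."""


class ReprId(str, enum.Enum):
    """Identifier of one of the four molecular representations."""

    CIRCULAR_2048 = "CIRCULAR_2048"
    PATH_2048 = "PATH_2048"
    KEYS_881 = "KEYS_881"
    PHYSCHEM = "PHYSCHEM"

    @property
    def is_bits(self) -> bool:
        return self is not ReprId.PHYSCHEM

    @property
    def length(self) -> int | None:
        return {"CIRCULAR_2048": 2048, "PATH_2048": 2048, "KEYS_881": 881}.get(self.value)


BIT_REPRS = (ReprId.CIRCULAR_2048, ReprId.PATH_2048, ReprId.KEYS_881)


@dataclass
class Structure:
    """A standardized molecule: largest organic fragment, canonical SMILES."""

    canonical_smiles: str
    num_heavy_atoms: int
    mol_weight: float
    element_set: frozenset[str]
    mol: Chem.Mol = field(repr=False, compare=False)

    def passes_element_whitelist(self) -> bool:
        return self.element_set <= ELEMENT_WHITELIST


@dataclass
class FeatureVector:
    """One representation of a standardized structure.

    ``values`` is read-only: uint8 {0,1} for bit representations, float64 for
    the descriptor representation.
    """

    repr_id: ReprId
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = self.repr_id.length
        if expected is not None and self.values.shape != (expected,):
            raise ValueError(
                f"{self.repr_id.value} vector must have length {expected}, "
                f"got {self.values.shape}"
            )


def _is_organic(frag: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in frag.GetAtoms())


def standardize(raw_smiles: str) -> Structure:
    """Parse, strip salts/counter-ions, and canonicalize a raw SMILES.

    Salt stripping keeps the fragment with the most heavy atoms (tie broken by
    higher molecular weight); a mixture with no carbon-containing fragment is
    rejected.

    Raises
    ------
    StandardizationError
        ``"invalid structure"`` for unparsable SMILES, ``"no organic
        fragment"`` when nothing organic survives salt stripping.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise StandardizationError("invalid structure: empty SMILES")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise StandardizationError(f"invalid structure: {raw_smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags if _is_organic(f)]
    if not organic:
        raise StandardizationError(f"no organic fragment: {raw_smiles!r}")
    best = max(organic, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))
    canonical = Chem.MolToSmiles(best)
    # round-trip through canonical form so downstream atom indices are stable
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical SMILES always reparses
        raise StandardizationError(f"invalid structure: {raw_smiles!r}")
    elements = frozenset(a.GetSymbol() for a in mol.GetAtoms()) | (
        frozenset(["H"]) if any(a.GetTotalNumHs() for a in mol.GetAtoms()) else frozenset()
    )
    return Structure(
        canonical_smiles=canonical,
        num_heavy_atoms=mol.GetNumHeavyAtoms(),
        mol_weight=Descriptors.MolWt(mol),
        element_set=elements,
        mol=mol,
    )


@lru_cache(maxsize=65536)
def _featurize_cached(canonical_smiles: str, repr_id: ReprId) -> np.ndarray:
    mol = Chem.MolFromSmiles(canonical_smiles)
    if repr_id is ReprId.CIRCULAR_2048:
        arr = np.zeros(2048, dtype=np.uint8)
        fp = _MORGAN.GetFingerprint(mol)
        arr[list(fp.GetOnBits())] = 1
    elif repr_id is ReprId.PATH_2048:
        arr = np.zeros(2048, dtype=np.uint8)
        fp = _PATH.GetFingerprint(mol)
        arr[list(fp.GetOnBits())] = 1
    elif repr_id is ReprId.KEYS_881:
        arr = keys881.compute_keys(mol)
    else:
        vals = []
        for name, fn in Descriptors._descList:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    v = float(fn(mol))
            except Exception as exc:  # noqa: BLE001 - surfaced with descriptor name
                raise FeaturizationError(f"descriptor {name!r} failed: {exc}") from exc
            if not np.isfinite(v):
                raise FeaturizationError(f"descriptor {name!r} is not finite")
            vals.append(v)
        arr = np.asarray(vals, dtype=np.float64)
    arr.setflags(write=False)
    return arr


def featurize(structure: Structure, repr_id: ReprId) -> FeatureVector:
    """Compute one of the four representations (pure function of the canonical form)."""
    values = _featurize_cached(structure.canonical_smiles, ReprId(repr_id))
    return FeatureVector(repr_id=ReprId(repr_id), values=values)


def featurize_matrix(structures: list[Structure], repr_id: ReprId) -> np.ndarray:
    """Stack representations of many structures into one matrix."""
    return np.stack([featurize(s, repr_id).values for s in structures])


def _env_atoms(mol: Chem.Mol, center: int, radius: int) -> frozenset[int]:
    if radius == 0:
        return frozenset([center])
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for bid in bond_ids:
        bond = mol.GetBondWithIdx(bid)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return frozenset(atoms)


def bit_atom_map(structure: Structure, repr_id: ReprId) -> dict[int, list[frozenset[int]]]:
    """Map each on-bit to the atom-index sets of the environments that set it.

    Multiple environments may hash to one bit (collisions); all are reported.
    """
    repr_id = ReprId(repr_id)
    mol = structure.mol
    if repr_id is ReprId.CIRCULAR_2048:
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        _MORGAN.GetFingerprint(mol, additionalOutput=ao)
        info = ao.GetBitInfoMap()
        return {
            bit: [_env_atoms(mol, center, radius) for center, radius in envs]
            for bit, envs in info.items()
        }
    if repr_id is ReprId.PATH_2048:
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitPaths()
        _PATH.GetFingerprint(mol, additionalOutput=ao)
        out: dict[int, list[frozenset[int]]] = {}
        for bit, paths in ao.GetBitPaths().items():
            sets = []
            for path in paths:
                atoms: set[int] = set()
                for bid in path:
                    bond = mol.GetBondWithIdx(bid)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
                sets.append(frozenset(atoms))
            out[bit] = sets
        return out
    if repr_id is ReprId.KEYS_881:
        bits = keys881.compute_keys(mol)
        return {
            int(i): sets
            for i in np.flatnonzero(bits)
            if (sets := keys881.key_atom_sets(mol, int(i)))
        }
    raise FeaturizationError("bit_atom_map is undefined for the descriptor representation")


@dataclass
class Scaler:
    """Per-feature min-max scaler fitted on training descriptors only.

    Applying the scaler to its own training data yields values in [0, 1];
    out-of-sample values are deliberately *not* clipped. Constant features
    map to 0.
    """

    mins: np.ndarray
    maxs: np.ndarray
    descriptor_names: tuple[str, ...]


def fit_scaler(
    train_vectors: np.ndarray, descriptor_names: tuple[str, ...] = DESCRIPTOR_NAMES
) -> Scaler:
    train_vectors = np.asarray(train_vectors, dtype=np.float64)
    if train_vectors.ndim != 2 or train_vectors.shape[0] < 2:
        raise ValueError("scaler must be fitted on a matrix with at least 2 rows")
    if train_vectors.shape[1] != len(descriptor_names):
        raise ValueError("descriptor name list does not match matrix width")
    return Scaler(
        mins=train_vectors.min(axis=0),
        maxs=train_vectors.max(axis=0),
        descriptor_names=tuple(descriptor_names),
    )


def apply_scaler(scaler: Scaler, vectors: np.ndarray) -> np.ndarray:
    vectors = np.asarray(vectors, dtype=np.float64)
    squeeze = vectors.ndim == 1
    mat = np.atleast_2d(vectors)
    if mat.shape[1] != scaler.mins.shape[0]:
        raise ValueError(
            f"width mismatch: scaler has {scaler.mins.shape[0]} features, "
            f"data has {mat.shape[1]}"
        )
    span = scaler.maxs - scaler.mins
    out = np.zeros_like(mat)
    nonconst = span > 0
    out[:, nonconst] = (mat[:, nonconst] - scaler.mins[nonconst]) / span[nonconst]
    return out[0] if squeeze else out


def tanimoto(a: FeatureVector | np.ndarray, b: FeatureVector | np.ndarray) -> float:
    """Tanimoto coefficient tn = j / (k + m - j) on binary fingerprints.

    j is the shared on-bit count, k and m the on-bit counts of each
    fingerprint. Both-empty input is the undefined 0/0 case and returns 0
    with a warning.
    """
    va = a.values if isinstance(a, FeatureVector) else np.asarray(a)
    vb = b.values if isinstance(b, FeatureVector) else np.asarray(b)
    if isinstance(a, FeatureVector) and isinstance(b, FeatureVector):
        if a.repr_id is not b.repr_id:
            raise ValueError("tanimoto requires matching representations")
    if va.shape != vb.shape:
        raise ValueError("tanimoto requires equal-length fingerprints")
    va = va.astype(bool)
    vb = vb.astype(bool)
    j = int(np.count_nonzero(va & vb))
    k = int(np.count_nonzero(va))
    m = int(np.count_nonzero(vb))
    if k + m == 0:
        warnings.warn("tanimoto of two empty fingerprints is undefined; returning 0")
        return 0.0
    return j / (k + m - j)


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two continuous descriptor vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("euclidean requires equal widths")
    return float(np.linalg.norm(a - b))
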