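"""Permutation-based Shapley attributions for fingerprint bits, retro-mapped
to atoms.

The explainer estimates Shapley values of the circular-fingerprint bits for
a single prediction by exact telescoping along random feature permutations
against a background set: walking one permutation, each feature's value is
switched from the background's to the molecule's and the change in the
model's active-class probability is credited to that feature. Averaging over
permutations and background rows gives the per-bit values; because each walk
telescopes, additivity (sum of values = prediction minus base value) holds
by construction. Only features where the molecule and a background row
differ can receive credit on that walk, which keeps the number of model
evaluations proportional to their Hamming distance.

Bit values are then mapped to atoms: each on-bit's structural footprint is
the union of the atom environments that hash to it; an atom's weight is the
sum over on-bits containing it of (bit value / footprint size), divided by
the number of distinct on-bits the atom appears in. Positive weights push
toward the active class.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import chemstruct
from .chemstruct import FeaturizationError, ReprId, Structure
from .modeling import TrainedProfilerModel


@dataclass
class BitContribution:
    bit_index: int
    shap_value: float
    atoms: list[frozenset[int]]


@dataclass
class AtomAttribution:
    structure: Structure
    weights: np.ndarray  # signed, one per heavy atom; uncovered atoms are 0
    repr_id: ReprId = ReprId.CIRCULAR_2048


@dataclass
class BitExplanation:
    """Full output of the explainer for one molecule."""

    contributions: list[BitContribution]  # on-bits only, mapped to atoms
    phi: np.ndarray  # Shapley value per feature (all bits)
    base_value: float  # mean model output over the background
    prediction: float  # model output for the molecule


def _predict_matrix(model: TrainedProfilerModel, X: np.ndarray) -> np.ndarray:
    proba = model.estimator.predict_proba(X.astype(bool))
    col = int(np.flatnonzero(model.estimator.classes_ == 1)[0])
    return proba[:, col]


def permutation_shap(
    model: TrainedProfilerModel,
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 4,
    seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Shapley values for one instance against a background set.

    Returns (phi, base_value, prediction). Exact additivity:
    ``phi.sum() == prediction - base_value`` up to float round-off.
    """
    x = np.asarray(x).astype(np.uint8)
    background = np.atleast_2d(np.asarray(background)).astype(np.uint8)
    rng = np.random.default_rng(seed)
    d = x.shape[0]
    phi = np.zeros(d, dtype=np.float64)
    n_walks = 0
    f_bg = _predict_matrix(model, background)
    prediction = float(_predict_matrix(model, x[None, :])[0])
    for _perm in range(n_permutations):
        order = rng.permutation(d)
        for b_idx in range(background.shape[0]):
            b = background[b_idx]
            diff = order[x[order] != b[order]]  # features to flip, in walk order
            if diff.size == 0:
                n_walks += 1
                continue
            # build the chain of intermediate vectors and batch-predict it
            chain = np.tile(b, (diff.size, 1))
            for step, j in enumerate(diff):
                chain[step:, j] = x[j]
            values = _predict_matrix(model, chain)
            prev = np.concatenate(([f_bg[b_idx]], values[:-1]))
            np.add.at(phi, diff, values - prev)
            n_walks += 1
    phi /= max(n_walks, 1)
    return phi, float(f_bg.mean()), prediction


def map_bits_to_atoms(structure: Structure) -> dict[int, list[frozenset[int]]]:
    """On-bit -> atom environments for the circular fingerprint (radius <= 2
    around each center; hash collisions yield multiple environments)."""
    return chemstruct.bit_atom_map(structure, ReprId.CIRCULAR_2048)


def shap_bits(
    model: TrainedProfilerModel,
    structure: Structure,
    background: np.ndarray | None = None,
    n_permutations: int = 4,
    seed: int = 0,
) -> BitExplanation:
    """Per-bit signed contributions to one molecule's predicted activity.

    ``background`` defaults to (a sample of) the model's stored training
    fingerprints in the model's own representation. Positive values push
    toward the active class.
    """
    if not model.spec.repr_id.is_bits:
        raise FeaturizationError(
            "atom mapping is undefined for the descriptor representation"
        )
    x = chemstruct.featurize(structure, model.spec.repr_id).values
    if background is None:
        background = _default_background(model, seed=seed)
    phi, base, pred = permutation_shap(
        model, x, background, n_permutations=n_permutations, seed=seed
    )
    mapping = (
        map_bits_to_atoms(structure)
        if model.spec.repr_id is ReprId.CIRCULAR_2048
        else chemstruct.bit_atom_map(structure, model.spec.repr_id)
    )
    contributions = [
        BitContribution(bit_index=int(bit), shap_value=float(phi[bit]), atoms=envs)
        for bit, envs in sorted(mapping.items())
    ]
    return BitExplanation(contributions=contributions, phi=phi, base_value=base, prediction=pred)


def _default_background(
    model: TrainedProfilerModel, size: int = 100, seed: int = 0
) -> np.ndarray:
    """Seed-controlled sample of training fingerprints as the background set."""
    train = model.train_X
    if train.shape[0] <= size:
        return np.asarray(train)
    rng = np.random.default_rng(seed)
    idx = rng.choice(train.shape[0], size=size, replace=False)
    return np.asarray(train[np.sort(idx)])


def atom_weights(
    contributions: list[BitContribution],
    structure: Structure,
    normalization: str = "footprint_then_occurrence",
) -> AtomAttribution:
    """Fold per-bit values into per-atom weights.

    Default scheme: w(a) = [sum over on-bits f containing a of
    phi_f / |atoms(f)|] / r(a), with atoms(f) the union of f's environments
    and r(a) the number of distinct on-bits covering atom a. The
    ``occurrence_only`` alternative skips the footprint division
    (sensitivity analysis for the ambiguous normalization order).
    Atoms covered by no on-bit keep weight exactly 0.
    """
    n_atoms = structure.num_heavy_atoms
    weights = np.zeros(n_atoms, dtype=np.float64)
    occurrence = np.zeros(n_atoms, dtype=np.int64)
    if not contributions:
        warnings.warn("no bit contributions; attribution is all zeros")
        return AtomAttribution(structure=structure, weights=weights)
    if normalization not in ("footprint_then_occurrence", "occurrence_only"):
        raise ValueError(f"unknown normalization {normalization!r}")
    for contrib in contributions:
        footprint = frozenset().union(*contrib.atoms) if contrib.atoms else frozenset()
        if not footprint:
            continue
        share = (
            contrib.shap_value / len(footprint)
            if normalization == "footprint_then_occurrence"
            else contrib.shap_value
        )
        for atom in footprint:
            weights[atom] += share
            occurrence[atom] += 1
    covered = occurrence > 0
    weights[covered] /= occurrence[covered]
    return AtomAttribution(structure=structure, weights=weights)


def explain_molecule(
    model: TrainedProfilerModel,
    structure: Structure,
    background: np.ndarray | None = None,
    n_permutations: int = 4,
    seed: int = 0,
) -> tuple[BitExplanation, AtomAttribution]:
    """Convenience: per-bit explanation plus the atom-level attribution."""
    explanation = shap_bits(
        model, structure, background=background, n_permutations=n_permutations, seed=seed
    )
    attribution = atom_weights(explanation.contributions, structure)
    return explanation, attribution


def render_attribution(
    attribution: AtomAttribution,
    out_prefix: str | Path,
    explanation: BitExplanation | None = None,
) -> dict[str, Path]:
    """Write a diverging-colormap depiction (SVG) plus numeric sidecars.

    Sidecars: ``<prefix>_atoms.csv`` (atom index, symbol, weight) and, when
    the per-bit explanation is given, ``<prefix>_bits.csv``. Orange/positive
    weights push toward activity, blue/negative away from it.
    """
    import matplotlib

    matplotlib.use("Agg")
    from rdkit.Chem.Draw import MolDraw2DSVG, SimilarityMaps

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    atoms_csv = out_prefix.with_name(out_prefix.name + "_atoms.csv")
    with open(atoms_csv, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["atom_index", "symbol", "weight"])
        for atom in attribution.structure.mol.GetAtoms():
            writer.writerow(
                [atom.GetIdx(), atom.GetSymbol(), f"{attribution.weights[atom.GetIdx()]:.8g}"]
            )
    paths["atoms"] = atoms_csv

    if explanation is not None:
        bits_csv = out_prefix.with_name(out_prefix.name + "_bits.csv")
        with open(bits_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["bit_index", "shap_value", "atom_sets"])
            for c in explanation.contributions:
                sets = "|".join(",".join(map(str, sorted(s))) for s in c.atoms)
                writer.writerow([c.bit_index, f"{c.shap_value:.8g}", sets])
        paths["bits"] = bits_csv

    drawer = MolDraw2DSVG(450, 450)
    SimilarityMaps.GetSimilarityMapFromWeights(
        attribution.structure.mol,
        [float(w) for w in attribution.weights],
        draw2d=drawer,
        colorMap="coolwarm_r",  # positive -> warm/orange, negative -> blue
        contourLines=0,
    )
    drawer.FinishDrawing()
    svg = out_prefix.with_name(out_prefix.name + "_map.svg")
    svg.write_text(drawer.GetDrawingText())
    paths["image"] = svg
    return paths
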