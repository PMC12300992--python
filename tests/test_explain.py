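"""Permutation-Shapley bit contributions and atom-level retro-mapping."""

import numpy as np
import pytest

from isoprofiler import chemstruct, explain
from isoprofiler.chemstruct import FeaturizationError
from isoprofiler.explain import (
    AtomAttribution,
    BitContribution,
    atom_weights,
    map_bits_to_atoms,
    permutation_shap,
    render_attribution,
    shap_bits,
)


class _ToyModel:
    """Linear probability model over the first few bits, for exact checks."""

    def __init__(self, coefs):
        self.coefs = np.asarray(coefs, dtype=float)
        self.classes_ = np.array([0, 1])
        self.estimator = self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        p = 0.1 + X[:, : len(self.coefs)] @ self.coefs
        return np.column_stack([1 - p, p])


class _WrappedToy:
    def __init__(self, coefs):
        self.estimator = _ToyModel(coefs)


class TestPermutationShap:
    def test_additivity_is_exact_for_a_linear_model(self):
        model = _WrappedToy([0.3, 0.2])
        x = np.array([1, 1, 0, 0], dtype=np.uint8)
        background = np.array([[0, 0, 0, 0], [0, 1, 1, 0]], dtype=np.uint8)
        phi, base, pred = permutation_shap(model, x, background, n_permutations=3, seed=0)
        assert phi.sum() + base == pytest.approx(pred, abs=1e-12)
        # linear model: phi is exact regardless of permutation sampling
        assert phi[0] == pytest.approx(0.3)
        assert phi[1] == pytest.approx(0.2 * 0.5)  # bit 1 on in half the background

    def test_constant_model_gives_all_zero_values(self):
        model = _WrappedToy([0.0, 0.0])
        x = np.array([1, 0, 1, 0], dtype=np.uint8)
        background = np.zeros((3, 4), dtype=np.uint8)
        phi, base, pred = permutation_shap(model, x, background, seed=1)
        np.testing.assert_allclose(phi, 0.0)
        assert base == pytest.approx(0.1) and pred == pytest.approx(0.1)

    def test_reproducible_under_fixed_seed(self, svm_circular_model, separable_split):
        _train, test = separable_split
        structure = test[0].structure
        a = shap_bits(svm_circular_model, structure, n_permutations=1, seed=9)
        b = shap_bits(svm_circular_model, structure, n_permutations=1, seed=9)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_additivity_on_the_real_model(self, svm_circular_model, separable_split):
        _train, test = separable_split
        expl = shap_bits(svm_circular_model, test[0].structure, n_permutations=1, seed=2)
        assert expl.phi.sum() + expl.base_value == pytest.approx(expl.prediction, abs=1e-2)

    def test_descriptor_models_are_rejected(self, separable_split):
        from conftest import balanced_subset

        from isoprofiler import modeling

        train, _ = separable_split
        spec = modeling.ModelSpec.make("RF", "PHYSCHEM", {"n_estimators": 30}, seed=0)
        model = modeling.train_final(spec, balanced_subset(train, 40))
        with pytest.raises(FeaturizationError, match="descriptor"):
            shap_bits(model, train[0].structure)


class TestBitToAtomMapping:
    def test_single_heavy_atom_molecule_maps_to_atom_zero(self):
        s = chemstruct.standardize("C")
        mapping = map_bits_to_atoms(s)
        assert mapping  # methane sets at least the radius-0 bit
        for envs in mapping.values():
            assert envs == [frozenset({0})]


class TestAtomWeights:
    def structure(self, smiles="CCCCCCCCCC"):
        return chemstruct.standardize(smiles)

    def test_single_bit_spreads_evenly(self):
        s = self.structure()
        contribs = [BitContribution(5, 0.6, [frozenset({0, 1, 2})])]
        attr = atom_weights(contribs, s)
        np.testing.assert_allclose(attr.weights[:3], 0.2)
        np.testing.assert_allclose(attr.weights[3:], 0.0)

    def test_shared_atom_double_normalization(self):
        # phi1=0.4 over atoms {0,1}; phi2=-0.2 over atom {0} alone:
        # w(0) = (0.4/2 + (-0.2)/1) / 2 = 0.0 ; w(1) = (0.4/2) / 1 = 0.2
        s = self.structure()
        contribs = [
            BitContribution(1, 0.4, [frozenset({0, 1})]),
            BitContribution(2, -0.2, [frozenset({0})]),
        ]
        attr = atom_weights(contribs, s)
        assert attr.weights[0] == pytest.approx(0.0)
        assert attr.weights[1] == pytest.approx(0.2)

    def test_positive_contributions_give_positive_covered_weights(self):
        s = self.structure()
        contribs = [
            BitContribution(1, 0.5, [frozenset({0, 1})]),
            BitContribution(2, 0.1, [frozenset({1, 2, 3})]),
        ]
        attr = atom_weights(contribs, s)
        assert (attr.weights[:4] > 0).all()

    def test_conservation_when_atoms_partition_across_bits(self):
        # each atom in exactly one bit, one environment per bit: the sum of
        # atom weights equals the sum of bit values exactly
        s = self.structure()
        contribs = [
            BitContribution(1, 0.37, [frozenset({0, 1, 2})]),
            BitContribution(2, -0.11, [frozenset({3, 4})]),
            BitContribution(3, 0.25, [frozenset({5, 6, 7, 8, 9})]),
        ]
        attr = atom_weights(contribs, s)
        assert attr.weights.sum() == pytest.approx(0.37 - 0.11 + 0.25, abs=1e-9)

    def test_hash_collision_uses_union_footprint(self):
        s = self.structure()
        contribs = [BitContribution(1, 0.6, [frozenset({0, 1}), frozenset({1, 2})])]
        attr = atom_weights(contribs, s)
        np.testing.assert_allclose(attr.weights[:3], 0.2)  # union {0,1,2}

    def test_empty_contributions_warn_and_zero(self):
        s = self.structure()
        with pytest.warns(UserWarning, match="all zeros"):
            attr = atom_weights([], s)
        np.testing.assert_array_equal(attr.weights, 0.0)

    def test_equivariant_under_atom_renumbering(self, svm_circular_model):
        # the same molecule written from a different atom ordering must give
        # the same weight for corresponding atoms
        a = chemstruct.standardize("NS(=O)(=O)c1ccc(-c2ccc(OC)cc2)cc1")
        from rdkit import Chem

        mol_b = Chem.MolFromSmiles("COc1ccc(-c2ccc(S(N)(=O)=O)cc2)cc1")
        order = tuple(range(mol_b.GetNumAtoms()))[::-1]
        mol_b = Chem.RenumberAtoms(mol_b, order)
        b = chemstruct.standardize(Chem.MolToSmiles(mol_b, canonical=False))
        _ea, attr_a = explain.explain_molecule(svm_circular_model, a, n_permutations=1, seed=4)
        _eb, attr_b = explain.explain_molecule(svm_circular_model, b, n_permutations=1, seed=4)
        match = b.mol.GetSubstructMatch(a.mol)
        assert match
        for ai, bi in enumerate(match):
            assert attr_a.weights[ai] == pytest.approx(attr_b.weights[bi], abs=1e-9)


class TestRender:
    def test_sidecars_consistent_with_attribution(self, tmp_path):
        s = chemstruct.standardize("NS(=O)(=O)c1ccccc1")
        weights = np.linspace(-0.2, 0.3, s.num_heavy_atoms)
        attr = AtomAttribution(structure=s, weights=weights)
        paths = render_attribution(attr, tmp_path / "out")
        lines = paths["atoms"].read_text().strip().splitlines()
        assert len(lines) == 1 + s.num_heavy_atoms
        for i, line in enumerate(lines[1:]):
            idx, _sym, w = line.split(",")
            assert int(idx) == i
            assert float(w) == pytest.approx(weights[i], abs=1e-6)
            # sign in the sidecar matches the attribution sign
            assert np.sign(float(w)) == np.sign(weights[i])
        assert paths["image"].exists() and paths["image"].stat().st_size > 0
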