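"""Activity-table curation: filters, duplicate resolution, labeling, splits."""

import math

import numpy as np
import pytest

from isoprofiler import chemstruct, curation
from isoprofiler.curation import (
    ActivityRecord,
    Label,
    LabeledCompound,
    Relation,
    ki_to_pki,
    resolve_duplicates,
)


def record(ki, relation=Relation.EQ, smiles="NS(=O)(=O)c1ccc(-c2ccccc2)cc1", cid="X"):
    return ActivityRecord(
        compound_id=cid, raw_smiles=smiles, ki_nm=ki, relation=relation, isoform="hCA_I"
    )


class TestKiToPki:
    @pytest.mark.parametrize(
        "ki,expected", [(1000.0, 6.0), (1.0, 9.0), (501.19, 6.30)]
    )
    def test_values(self, ki, expected):
        assert ki_to_pki(ki) == pytest.approx(expected, abs=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ki_to_pki(0.0)


class TestResolveDuplicates:
    def test_singleton_passes_through(self):
        assert resolve_duplicates([record(42.0)]) == 42.0

    def test_two_concordant_values_average(self):
        # (100, 120): mean 110, deviations 9.1% -> keep the mean
        assert resolve_duplicates([record(100.0), record(120.0)]) == pytest.approx(110.0)

    def test_two_discordant_values_discard_compound(self):
        # (100, 200): mean 150, deviations 33% -> both discarded
        assert resolve_duplicates([record(100.0), record(200.0)]) is None

    def test_three_values_single_pass_outlier_exclusion(self):
        # (100, 105, 200): initial mean 135; 100 deviates 25.9%, 200 deviates
        # 48% -> only 105 survives
        assert resolve_duplicates(
            [record(100.0), record(105.0), record(200.0)]
        ) == pytest.approx(105.0)

    def test_all_excluded_discards_compound(self):
        assert resolve_duplicates([record(10.0), record(100.0), record(1000.0)]) is None

    def test_boundary_at_exactly_25_percent_is_kept(self):
        # (75, 125): mean 100, both deviate exactly 25% -> keep
        assert resolve_duplicates([record(75.0), record(125.0)]) == pytest.approx(100.0)

    def test_mixed_relations_rejected(self):
        with pytest.raises(ValueError, match="mixed relations"):
            resolve_duplicates([record(10.0), record(10.0, relation=Relation.GT)])

    def test_merged_value_within_input_range(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            values = rng.lognormal(4, 0.5, size=rng.integers(1, 6))
            merged = resolve_duplicates([record(float(v)) for v in values])
            if merged is not None:
                assert values.min() - 1e-9 <= merged <= values.max() + 1e-9


class TestPrimaryFilter:
    def test_drops_by_weight_heavy_atoms_and_elements(self):
        records = [
            record(10.0, smiles="C" * 60, cid="heavy"),  # MW > 800
            record(10.0, smiles="CCO", cid="small"),  # < 15 heavy atoms
            record(10.0, smiles="C[Si](C)(C)c1ccc(-c2ccccc2)cc1", cid="si"),
            record(10.0, cid="ok"),
        ]
        result = curation.primary_filter(records)
        assert [r.compound_id for r, _s in result.eq] == ["ok"]
        assert result.report.counts["mol_weight_gt_800"] == 1
        assert result.report.counts["heavy_atoms_lt_15"] == 1
        assert result.report.counts["element_not_whitelisted"] == 1

    def test_gt_records_routed_to_separate_pool(self):
        result = curation.primary_filter([record(10.0), record(10.0, relation=Relation.GT)])
        assert len(result.eq) == 1 and len(result.gt) == 1


class TestRepresentationIdentity:
    def test_enantiomers_are_identical(self):
        r = chemstruct.standardize("N[C@@H](C)c1ccc(S(N)(=O)=O)cc1")
        s = chemstruct.standardize("N[C@H](C)c1ccc(S(N)(=O)=O)cc1")
        assert curation.representation_identity(r, s)

    def test_different_molecules_are_not(self):
        assert not curation.representation_identity(
            chemstruct.standardize("c1ccccc1"), chemstruct.standardize("Cc1ccccc1")
        )


class TestLabelAndBand:
    def make(self, pki):
        return (chemstruct.standardize("NS(=O)(=O)c1ccc(-c2ccccc2)cc1"), pki, ("p",))

    def test_threshold_band_assignment(self):
        labeled, excluded = curation.label_and_band(
            [self.make(7.60), self.make(7.40), self.make(7.00)], threshold_pki=7.30
        )
        assert [c.label for c in labeled] == [Label.ACTIVE, Label.INACTIVE]
        assert len(excluded) == 1 and excluded[0][1] == 7.40

    def test_no_survivor_inside_band(self):
        rng = np.random.default_rng(1)
        compounds = [self.make(float(p)) for p in rng.uniform(5.0, 9.0, 100)]
        labeled, _ = curation.label_and_band(compounds, 7.30, 0.25)
        assert all(abs(c.pki - 7.30) > 0.25 for c in labeled)

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError):
            curation.label_and_band([], 7.30, band=-0.1)


class TestGtIntegration:
    def test_informative_bound_becomes_inactive(self):
        # ">10,000 nM" -> bound pKi 5.0 < 6.30 - 0.25
        gt = curation.primary_filter([record(10_000.0, relation=Relation.GT)]).gt
        added = curation.integrate_gt_inactives(gt, [], threshold_pki=6.30)
        assert len(added) == 1
        assert added[0].label is Label.INACTIVE and added[0].is_bound
        assert added[0].pki == pytest.approx(5.0)

    def test_uninformative_bound_dropped(self):
        # ">100 nM" -> bound pKi 7.0 says nothing below a 6.30 cutoff
        gt = curation.primary_filter([record(100.0, relation=Relation.GT)]).gt
        assert curation.integrate_gt_inactives(gt, [], threshold_pki=6.30) == []

    def test_duplicate_of_existing_compound_dropped(self):
        structure = chemstruct.standardize("NS(=O)(=O)c1ccc(-c2ccccc2)cc1")
        existing = [LabeledCompound(structure, 7.0, Label.ACTIVE, ("e",))]
        gt = curation.primary_filter([record(100_000.0, relation=Relation.GT)]).gt
        assert curation.integrate_gt_inactives(gt, existing, threshold_pki=6.30) == []


class TestStratifiedSplit:
    def make_set(self, n_active, n_inactive):
        out = []
        smis = [
            f"NS(=O)(=O)c1ccc(-c2ccc({sub})cc2)cc1"
            for sub in ["C", "CC", "CCC", "F", "Cl", "Br", "OC", "CO", "CN", "N"]
        ] + [
            f"CC(=O)c1ccc(-c2ccc({sub})cc2)cc1"
            for sub in ["C", "CC", "CCC", "F", "Cl", "Br", "OC", "CO", "CN", "N"]
        ]
        for i in range(n_active):
            out.append(
                LabeledCompound(chemstruct.standardize(smis[i]), 8.0, Label.ACTIVE, ("a",))
            )
        for i in range(n_inactive):
            out.append(
                LabeledCompound(chemstruct.standardize(smis[10 + i]), 5.0, Label.INACTIVE, ("i",))
            )
        return out

    def test_exact_80_20_per_class(self):
        train, test = curation.stratified_split(self.make_set(10, 10), seed=1)
        for label in Label:
            assert sum(c.label is label for c in train) == 8
            assert sum(c.label is label for c in test) == 2

    def test_deterministic_given_seed(self):
        compounds = self.make_set(10, 10)
        a = curation.stratified_split(compounds, seed=9)
        b = curation.stratified_split(compounds, seed=9)
        key = lambda cs: [c.structure.canonical_smiles for c in cs]
        assert key(a[0]) == key(b[0]) and key(a[1]) == key(b[1])

    def test_train_test_disjoint(self):
        train, test = curation.stratified_split(self.make_set(8, 6), seed=2)
        assert not (
            {c.structure.canonical_smiles for c in train}
            & {c.structure.canonical_smiles for c in test}
        )

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="insufficient class size"):
            curation.stratified_split(self.make_set(4, 10), seed=0)


class TestPipeline:
    def test_monotone_and_class_ratio(self, activity_table_500):
        _cfg, records, _manifest = activity_table_500
        dataset, report = curation.curate(records, "hCA_I", seed=7)
        n_final = len(dataset.train) + len(dataset.test)
        assert n_final <= len(records)
        # class ratio preserved across the split within one compound per class
        for label in Label:
            n_train = sum(c.label is label for c in dataset.train)
            n_test = sum(c.label is label for c in dataset.test)
            assert abs(n_train - 4 * n_test) <= 4  # floor effects only
        assert not math.isnan(dataset.threshold_pki)
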