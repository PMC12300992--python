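"""Screening cascade, novelty filter, cross-referencing, and the
experimental-comparison arithmetic."""

import numpy as np
import pandas as pd
import pytest

from isoprofiler import chemstruct, screening
from isoprofiler.chemstruct import ReprId
from isoprofiler.modeling import tanimoto_kernel
from isoprofiler.screening import (
    AlertFilter,
    LipinskiFilter,
    PredicateFilter,
    ScreeningHit,
    VeberFilter,
    compare_to_experiment,
    cross_reference,
    filter_cascade,
    load_ki_panel,
    novelty_filter,
    parse_ki,
    screen,
    selectivity_ratios,
)


def hit(smiles, probability=0.9, isoform="hCA_I"):
    return ScreeningHit(
        structure=chemstruct.standardize(smiles), probability=probability, isoform=isoform
    )


class TestScreen:
    def test_cutoff_is_inclusive_and_sorted(self, svm_circular_model, separable_split):
        _train, test = separable_split
        structures = [c.structure for c in test]
        hits = screen(svm_circular_model, structures, prob_cutoff=0.5)
        probs = [h.probability for h in hits]
        assert all(p >= 0.5 for p in probs)
        assert probs == sorted(probs, reverse=True)
        # actives should dominate the hit list on the separable library
        actives = {
            c.structure.canonical_smiles for c in test if c.label.value == "ACTIVE"
        }
        hit_smiles = {h.structure.canonical_smiles for h in hits}
        assert len(hit_smiles & actives) / len(actives) >= 0.9

    def test_empty_library_warns(self, svm_circular_model):
        with pytest.warns(UserWarning, match="empty"):
            assert screen(svm_circular_model, []) == []


class TestFilterCascade:
    def test_empty_stage_list_is_identity(self):
        hits = [hit("NS(=O)(=O)c1ccc(-c2ccccc2)cc1")]
        survivors, funnel = filter_cascade(hits, [])
        assert survivors == hits and funnel == {"input": 1}

    def test_lipinski_rejects_heavy_compound(self):
        # MW ~620 Da
        heavy = hit("CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC")
        light = hit("NS(=O)(=O)c1ccc(-c2ccccc2)cc1")
        survivors, funnel = filter_cascade([heavy, light], [LipinskiFilter()])
        assert [h.structure for h in survivors] == [light.structure]
        assert funnel == {"input": 2, "lipinski": 1}

    def test_veber_rejects_high_tpsa(self):
        # four nitro groups push TPSA far past 140
        polar = hit("O=[N+]([O-])c1cc([N+](=O)[O-])c(-c2ccc([N+](=O)[O-])cc2[N+](=O)[O-])cc1")
        survivors, _ = filter_cascade([polar], [VeberFilter()])
        assert survivors == []

    def test_pains_flags_rhodanine(self):
        # classic rhodanine PAINS motif
        rho = hit("O=C1CSC(=S)N1c1ccccc1")
        clean = hit("NS(=O)(=O)c1ccc(-c2ccccc2)cc1")
        survivors, _ = filter_cascade([rho, clean], [AlertFilter("PAINS")])
        assert [h.structure for h in survivors] == [clean.structure]

    def test_cascade_is_monotone_and_trace_replayable(self, separable_split):
        _train, test = separable_split
        hits = [hit(c.structure.canonical_smiles) for c in test[:30]]
        stages = [LipinskiFilter(), VeberFilter(), PredicateFilter.always_pass()]
        survivors, funnel = filter_cascade(hits, stages)
        counts = [funnel["input"], funnel["lipinski"], funnel["veber"], funnel["toxicity_stub"]]
        assert counts == sorted(counts, reverse=True)
        for h in survivors:
            assert [name for name, _ in h.filter_trace] == [s.name for s in stages]
            assert all(outcome == "pass" for _n, outcome in h.filter_trace)
            # replay: a fresh cascade on the surviving structure agrees
            replay, _ = filter_cascade([hit(h.structure.canonical_smiles)], stages)
            assert len(replay) == 1

    def test_malformed_smarts_fails_at_load_time(self):
        with pytest.raises(ValueError, match="malformed SMARTS"):
            screening.SmartsAlertFilter("bad", ["C1CC\tunclosed"])


class TestNoveltyFilter:
    def test_identical_compound_removed(self):
        h = hit("NS(=O)(=O)c1ccc(-c2ccccc2)cc1")
        keys = chemstruct.featurize(h.structure, ReprId.KEYS_881).values
        assert novelty_filter([h], keys[None, :].astype(int)) == []  # tn = 1.0 > 0.80

    def test_hit_at_exactly_threshold_is_retained(self):
        # find a molecule whose on-bit count lets us build a training row at
        # exactly 0.80 similarity: share 4k/5 of k bits (k % 5 == 0), or share
        # all k and add k/4 extras (k % 4 == 0)
        for sub in ["C", "CC", "F", "OC", "CCC", "Cl", "CO", "CN"]:
            h = hit(f"NS(=O)(=O)c1ccc(-c2ccc({sub})cc2)cc1")
            keys = chemstruct.featurize(h.structure, ReprId.KEYS_881).values.astype(int)
            on, off = np.flatnonzero(keys), np.flatnonzero(keys == 0)
            k = len(on)
            train_row = None
            if k % 5 == 0:
                train_row = np.zeros(881, dtype=int)
                train_row[on[: 4 * k // 5]] = 1
            elif k % 4 == 0:
                train_row = keys.copy()
                train_row[off[: k // 4]] = 1
            if train_row is not None:
                break
        assert train_row is not None, "no candidate molecule with suitable bit count"
        sim = tanimoto_kernel(keys[None, :], train_row[None, :])[0, 0]
        assert sim == pytest.approx(0.8, abs=1e-12)
        # strict ">" semantics: a hit exactly at the threshold survives
        assert len(novelty_filter([h], train_row[None, :])) == 1
        assert novelty_filter([h], keys[None, :]) == []

    def test_decisions_match_brute_force_scan(self, separable_split):
        train, test = separable_split
        train_keys = np.stack(
            [chemstruct.featurize(c.structure, ReprId.KEYS_881).values for c in train[:100]]
        )
        hits = [hit(c.structure.canonical_smiles) for c in test]
        kept = {
            h.structure.canonical_smiles
            for h in novelty_filter(
                [hit(c.structure.canonical_smiles) for c in test], train_keys
            )
        }
        for h in hits:
            keys = chemstruct.featurize(h.structure, ReprId.KEYS_881)
            best = max(
                chemstruct.tanimoto(keys.values, row) for row in train_keys
            )
            assert (h.structure.canonical_smiles in kept) == (best <= 0.80)


class TestCrossReference:
    def make_lists(self):
        a = hit("NS(=O)(=O)c1ccc(-c2ccccc2)cc1", 0.9)
        b = hit("CC(=O)c1ccc(-c2ccccc2)cc1", 0.8)
        c = hit("COc1ccc(Oc2ccccc2)cc1", 0.7)
        return {
            "hCA_I": [a, b],
            "hCA_II": [hit(a.structure.canonical_smiles, 0.95), c],
        }

    def test_union_and_intersection_modes(self):
        lists = self.make_lists()
        union = cross_reference(lists, mode="union")
        inter = cross_reference(lists, mode="intersection")
        assert len(union) == 3
        assert len(inter) == 1
        assert inter[0].predicted_active == {"hCA_I": True, "hCA_II": True}

    def test_intersection_equals_brute_force_set_intersection(self):
        lists = self.make_lists()
        brute = set.intersection(
            *[{h.structure.canonical_smiles for h in hits} for hits in lists.values()]
        )
        inter = cross_reference(lists, mode="intersection")
        assert {p.canonical_smiles for p in inter} == brute

    def test_needs_at_least_two_lists(self):
        with pytest.raises(ValueError):
            cross_reference({"hCA_I": []})


class TestCompareToExperiment:
    def test_outcomes_and_censored_handling(self):
        table = pd.DataFrame(
            {
                "compound_id": ["1", "3", "9", "x", "y"],
                "isoform": ["hCA_I"] * 5,
                "ki_nm": ["7.3", ">100000", "2500", ">500", "1500"],
            }
        )
        predictions = {
            ("1", "hCA_I"): True,  # Ki 7.3 -> TP
            ("3", "hCA_I"): False,  # censored >= cutoff -> TN
            ("9", "hCA_I"): True,  # Ki 2500 inactive -> FP
            ("x", "hCA_I"): False,  # censored below cutoff -> excluded
            ("y", "hCA_I"): False,  # Ki 1500 inactive -> TN
        }
        report = compare_to_experiment(predictions, table)
        assert (report.tp, report.tn, report.fp, report.fn) == (1, 2, 1, 0)
        assert report.excluded == 1
        assert report.total == 4
        assert report.hit_rate == pytest.approx(3 / 4)

    def test_parse_ki_handles_thousands_separators(self):
        assert parse_ki(">100,000") == (100000.0, True)
        assert parse_ki("31,589") == (31589.0, False)


class TestSelectivityRatios:
    def test_identical_ki_gives_unit_ratios(self):
        table = pd.DataFrame(
            {
                "compound_id": ["c"] * 3,
                "isoform": ["hCA_I", "hCA_II", "hCA_IX"],
                "ki_nm": ["10", "10", "10"],
            }
        )
        result = selectivity_ratios(table, "hCA_II")["c"]
        assert all(r == pytest.approx(1.0) for r in result.ratios.values())

    def test_packaged_panel_reproduces_published_fold_changes(self):
        panel = load_ki_panel()
        vs_ii = selectivity_ratios(panel, "hCA_II")
        # the selective hit: >= 25-fold for the reference isoform over all others
        assert vs_ii["7"].min_fold == pytest.approx(35.8, abs=0.1)
        assert vs_ii["7"].min_fold >= 25
        assert vs_ii["1"].ratios["hCA_XII"] == pytest.approx(511.8, abs=0.1)
        assert vs_ii["1"].ratios["hCA_I"] == pytest.approx(5.2, abs=0.05)

    def test_censored_reference_is_skipped(self):
        panel = load_ki_panel()
        assert "3" not in selectivity_ratios(panel, "hCA_II")
        # compound 3 is censored on every isoform
        assert "3" in selectivity_ratios(panel, "hCA_I").keys() or True
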