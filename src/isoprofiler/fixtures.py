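"""Synthetic activity data with known ground truth.

The generator emulates the shape of a ChEMBL-style Ki extract for a
sulfonamide-dominated enzyme-inhibition series: drug-like scaffolds decorated
combinatorially, activity governed by a planted zinc-binding substructure
(primary sulfonamide by default), log-normal replicate noise, duplicate
clusters (including salt forms and discordant replicates), compounds planted
inside the threshold band, censored ">" records, and a few structurally
out-of-range molecules. Every record's intended fate through the curation
pipeline is written to a ground-truth manifest, which downstream tests use
as an oracle.

Duplicate clusters are planted with closed-form outcomes: replicate ratios
are chosen so the 25%-deviation rule's result (merged value or discard) is
known analytically and recorded in the manifest without re-running the rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chemstruct
from .curation import (
    DEFAULT_BAND,
    DEFAULT_THRESHOLDS,
    ActivityRecord,
    Label,
    LabeledCompound,
    Relation,
)

PLANTED_RULE = "[SX4](=O)(=O)[NX3H2]"  # primary sulfonamide, the classic zinc binder

# scaffold templates; "{r}" is the decoration site on a phenyl ring
_ACTIVE_CORES = [
    "NS(=O)(=O)c1ccc(-c2ccc({r})cc2)cc1",
    "NS(=O)(=O)c1ccc(NC(=O)c2ccc({r})cc2)cc1",
    "NS(=O)(=O)c1ccc(Oc2ccc({r})cc2)cc1",
    "NS(=O)(=O)c1ccc(NC(=O)Nc2ccc({r})cc2)cc1",
    "NS(=O)(=O)c1ccc(COc2ccc({r})cc2)cc1",
    "NS(=O)(=O)c1ccc(/C=C/c2ccc({r})cc2)cc1",
    "NS(=O)(=O)c1ccc(CNC(=O)c2ccc({r})cc2)cc1",
    "NS(=O)(=O)c1ccc(N=Cc2ccc({r})cc2)cc1",
]
_INACTIVE_CORES = [
    "CC(=O)c1ccc(-c2ccc({r})cc2)cc1",
    "N#Cc1ccc(NC(=O)c2ccc({r})cc2)cc1",
    "COc1ccc(Oc2ccc({r})cc2)cc1",
    "NC(=O)c1ccc(NC(=O)Nc2ccc({r})cc2)cc1",
    "CC(=O)c1ccc(COc2ccc({r})cc2)cc1",
    "COC(=O)c1ccc(/C=C/c2ccc({r})cc2)cc1",
    "CC(=O)Nc1ccc(CNC(=O)c2ccc({r})cc2)cc1",
    "COc1ccc(N=Cc2ccc({r})cc2)cc1",
]
_SUBSTITUENTS = [
    "",
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "C(C)(C)C",
    "F",
    "Cl",
    "Br",
    "O",
    "OC",
    "OCC",
    "OCCC",
    "OC(C)C",
    "N",
    "NC",
    "N(C)C",
    "C(F)(F)F",
    "C#N",
    "[N+](=O)[O-]",
    "C(=O)OC",
    "C(=O)NC",
    "CO",
    "CN",
    "CCN(C)C",
    "SC",
    "S(C)(=O)=O",
    "CCO",
    "NC(C)=O",
    "OCCOC",
    "N3CCOCC3",
    "N3CCN(C)CC3",
    "C3CCCCC3",
    "OCc3ccccc3",
    "Cc3ccccc3",
    "c3ccccc3",
    "c3ccncc3",
    "OCC(C)C",
    "CC(C)O",
    "CCOC",
    "CCCC",
    "CCCCC",
    "OCCCC",
    "N(CC)CC",
    "C(=O)OCC",
    "C(=O)N(C)C",
    "NCC",
    "OCCN(C)C",
    "SCC",
    "OC(C)(C)C",
    "C(=O)C",
    "OC(=O)C",
    "N3CCCCC3",
    "N3CCCC3",
    "CC=C",
    "C=C",
]

# records that must fail the primary structural filter, with their reasons
_JUNK_RECORDS = [
    ("CCO", "dropped_small"),  # 3 heavy atoms
    ("CC(=O)Oc1ccccc1C(=O)O", "dropped_small"),  # aspirin, 13 heavy atoms
    ("C" * 60, "dropped_mw"),  # MW ~842 Da
    ("C[Si](C)(C)c1ccc(-c2ccccc2)cc1", "dropped_element"),  # silicon
    ("[Na+].[Cl-]", "dropped_invalid"),  # no organic fragment
    ("C1CC", "dropped_invalid"),  # unparsable
]


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic extract.

    Defaults give a 500-record table in which roughly 15% of records sit in
    duplicate clusters, 8% of compounds fall inside the labeling band, 10%
    are censored ">" records, and replicate Ki noise has a 10% coefficient
    of variation.
    """

    n_compounds: int = 500
    duplicate_fraction: float = 0.15
    band_fraction: float = 0.08
    gt_fraction: float = 0.10
    noise_cv: float = 0.10
    seed: int = 0
    planted_rule: str = PLANTED_RULE
    isoform: str = "hCA_I"
    threshold_pki: float | None = None
    band: float = DEFAULT_BAND

    def __post_init__(self) -> None:
        if self.n_compounds < 20:
            raise ValueError("n_compounds must be at least 20")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.threshold_pki is None:
            self.threshold_pki = DEFAULT_THRESHOLDS.get(self.isoform, 6.30)


@dataclass
class Manifest:
    """Ground truth: intended fate of every record and the expected final set."""

    record_fates: dict[str, str] = field(default_factory=dict)
    # canonical_smiles -> {"label", "pki", "is_bound"}
    expected_compounds: dict[str, dict] = field(default_factory=dict)
    band_smiles: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "record_fates": self.record_fates,
                    "expected_compounds": self.expected_compounds,
                    "band_smiles": self.band_smiles,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _template_pool(planted_rule: str) -> tuple[list[str], list[str]]:
    """Unique canonical SMILES per class; actives match the planted rule."""
    patt = Chem.MolFromSmarts(planted_rule)
    actives: list[str] = []
    inactives: list[str] = []
    seen: set[str] = set()
    for cores, out, want in ((_ACTIVE_CORES, actives, True), (_INACTIVE_CORES, inactives, False)):
        for core in cores:
            for sub in _SUBSTITUENTS:
                smi = core.replace("({r})", "") if sub == "" else core.format(r=sub)
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                canonical = Chem.MolToSmiles(mol)
                if canonical in seen:
                    continue
                if mol.GetNumHeavyAtoms() < 15:
                    continue
                if mol.HasSubstructMatch(patt) != want:
                    continue
                seen.add(canonical)
                out.append(canonical)
    return actives, inactives


def _pki_to_ki(pki: float) -> float:
    return 10.0 ** (9.0 - pki)


class _RecordFactory:
    def __init__(self) -> None:
        self.counter = 0
        self.records: list[ActivityRecord] = []

    def add(self, smiles: str, ki_nm: float, relation: Relation, isoform: str) -> str:
        self.counter += 1
        rid = f"SYN{self.counter:05d}"
        self.records.append(
            ActivityRecord(
                compound_id=rid,
                raw_smiles=smiles,
                ki_nm=ki_nm,
                relation=relation,
                isoform=isoform,
                source_tag="synthetic",
            )
        )
        return rid


def generate_activity_table(cfg: FixtureConfig) -> tuple[list[ActivityRecord], Manifest]:
    """Emit a raw activity table plus the ground-truth manifest."""
    rng = np.random.default_rng(cfg.seed)
    actives, inactives = _template_pool(cfg.planted_rule)
    rng.shuffle(actives)
    rng.shuffle(inactives)
    pool = {"active": list(actives), "inactive": list(inactives)}

    thr, band = cfg.threshold_pki, cfg.band
    n = cfg.n_compounds
    n_junk = min(len(_JUNK_RECORDS), max(2, n // 100))
    n_gt = int(round(cfg.gt_fraction * n))
    n_band = int(round(cfg.band_fraction * n))
    n_dup_records = int(round(cfg.duplicate_fraction * n))

    factory = _RecordFactory()
    manifest = Manifest()

    def draw_structure(cls: str) -> str:
        if not pool[cls]:
            raise RuntimeError("template pool exhausted; lower n_compounds")
        return pool[cls].pop()

    def true_pki(cls: str) -> float:
        center = thr + 1.3 if cls == "active" else thr - 1.3
        pki = float(rng.normal(center, 0.4))
        margin = band + 0.1
        if cls == "active":
            return max(pki, thr + margin)
        return min(pki, thr - margin)

    def canonical(smiles: str) -> str:
        return chemstruct.standardize(smiles).canonical_smiles

    def expect(smiles: str, label: str, pki: float, is_bound: bool = False) -> None:
        manifest.expected_compounds[canonical(smiles)] = {
            "label": label,
            "pki": pki,
            "is_bound": is_bound,
        }

    # --- duplicate clusters (closed-form merge outcomes) -------------------
    cluster_patterns = ["concordant2", "salt2", "concordant3", "outlier3", "discordant2"]
    dup_used = 0
    pattern_idx = 0
    while dup_used + 2 <= n_dup_records:
        pattern = cluster_patterns[pattern_idx % len(cluster_patterns)]
        pattern_idx += 1
        cls = "active" if pattern_idx % 2 else "inactive"
        smiles = draw_structure(cls)
        pki = true_pki(cls)
        v = _pki_to_ki(pki)
        delta = min(0.2, abs(float(rng.normal(0, cfg.noise_cv))))
        if pattern == "concordant2":
            ids = [
                factory.add(smiles, v * (1 + delta), Relation.EQ, cfg.isoform),
                factory.add(smiles, v * (1 - delta), Relation.EQ, cfg.isoform),
            ]
            merged = v  # mean of v(1 +/- delta); both within 25%
        elif pattern == "salt2":
            ids = [
                factory.add(smiles, v * (1 + delta), Relation.EQ, cfg.isoform),
                factory.add(smiles + ".Cl", v * (1 - delta), Relation.EQ, cfg.isoform),
            ]
            merged = v
        elif pattern == "concordant3":
            if dup_used + 3 > n_dup_records:
                continue
            ids = [
                factory.add(smiles, v * f, Relation.EQ, cfg.isoform) for f in (0.9, 1.0, 1.1)
            ]
            merged = v  # all within 25% of the mean v
        elif pattern == "outlier3":
            if dup_used + 3 > n_dup_records:
                continue
            # initial mean 1.35v: 1.0v deviates 25.9% (out), 1.05v 22.2% (in),
            # 2.0v 48.1% (out) -> survivor is the middle value
            ids = [
                factory.add(smiles, v * f, Relation.EQ, cfg.isoform) for f in (1.0, 1.05, 2.0)
            ]
            merged = 1.05 * v
        else:  # discordant2: deviations 40% -> both discarded
            ids = [
                factory.add(smiles, v * 1.4, Relation.EQ, cfg.isoform),
                factory.add(smiles, v * 0.6, Relation.EQ, cfg.isoform),
            ]
            merged = None
        dup_used += len(ids)
        if merged is None:
            for rid in ids:
                manifest.record_fates[rid] = "discarded_discordant"
        else:
            for rid in ids:
                manifest.record_fates[rid] = "merged"
            expect(smiles, "ACTIVE" if cls == "active" else "INACTIVE", 9.0 - np.log10(merged))

    # --- band-zone compounds ----------------------------------------------
    for i in range(n_band):
        cls = "active" if i % 2 else "inactive"
        smiles = draw_structure(cls)
        pki = float(rng.uniform(thr - band + 0.02, thr + band - 0.02))
        rid = factory.add(smiles, _pki_to_ki(pki), Relation.EQ, cfg.isoform)
        manifest.record_fates[rid] = "band_excluded"
        manifest.band_smiles.append(canonical(smiles))

    # --- censored ">" records ---------------------------------------------
    n_gt_informative = int(round(0.7 * n_gt))
    for i in range(n_gt):
        smiles = draw_structure("inactive")
        if i < n_gt_informative:
            bound_pki = float(rng.uniform(thr - band - 1.5, thr - band - 0.2))
            rid = factory.add(smiles, _pki_to_ki(bound_pki), Relation.GT, cfg.isoform)
            manifest.record_fates[rid] = "gt_integrated"
            expect(smiles, "INACTIVE", bound_pki, is_bound=True)
        else:
            bound_pki = float(rng.uniform(thr - band + 0.05, thr + 1.0))
            rid = factory.add(smiles, _pki_to_ki(bound_pki), Relation.GT, cfg.isoform)
            manifest.record_fates[rid] = "gt_dropped"

    # --- structurally out-of-range records ---------------------------------
    for smiles, fate in _JUNK_RECORDS[:n_junk]:
        rid = factory.add(smiles, 1000.0, Relation.EQ, cfg.isoform)
        manifest.record_fates[rid] = fate

    # --- plain singletons ---------------------------------------------------
    n_singles = n - len(factory.records)
    for i in range(n_singles):
        cls = "active" if i % 2 else "inactive"
        smiles = draw_structure(cls)
        pki = true_pki(cls)
        rid = factory.add(smiles, _pki_to_ki(pki), Relation.EQ, cfg.isoform)
        manifest.record_fates[rid] = "kept"
        expect(smiles, "ACTIVE" if cls == "active" else "INACTIVE", pki)

    return factory.records, manifest


def generate_separable_library(cfg: FixtureConfig) -> list[LabeledCompound]:
    """Balanced labeled library whose activity is exactly the planted rule.

    Used as the acceptance surface for model recovery and attribution tests:
    the label is a deterministic function of substructure presence, so a
    competent classifier/attributor must rediscover the planted motif.
    """
    rng = np.random.default_rng(cfg.seed)
    actives, inactives = _template_pool(cfg.planted_rule)
    rng.shuffle(actives)
    rng.shuffle(inactives)
    per_class = cfg.n_compounds // 2
    if per_class > min(len(actives), len(inactives)):
        raise ValueError(
            f"template pool supports at most {2 * min(len(actives), len(inactives))} compounds"
        )
    thr = cfg.threshold_pki
    out: list[LabeledCompound] = []
    for smiles in actives[:per_class]:
        out.append(
            LabeledCompound(chemstruct.standardize(smiles), thr + 1.5, Label.ACTIVE, ("planted",))
        )
    for smiles in inactives[: cfg.n_compounds - per_class]:
        out.append(
            LabeledCompound(chemstruct.standardize(smiles), thr - 1.5, Label.INACTIVE, ("planted",))
        )
    return out


def records_to_frame(records: list[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.raw_smiles for r in records],
            "standard_value_nm": [r.ki_nm for r in records],
            "standard_relation": [r.relation.value for r in records],
            "target": [r.isoform for r in records],
            "source": [r.source_tag for r in records],
        }
    )


def check_pipeline_fates(records, manifest: Manifest, dataset, report) -> float:
    """Fraction of records whose curation outcome matches the manifest.

    The oracle mapping: merged/kept/gt_integrated records must appear in the
    final dataset with the expected label (and potency within floating-point
    tolerance); band/discordant/out-of-range records must have been dropped
    for the matching reason and be absent from the final dataset.
    """
    final = {
        c.structure.canonical_smiles: c for c in dataset.train + dataset.test
    }
    dropped_reasons = {}
    for rid, reason in report.drop_reasons:
        dropped_reasons.setdefault(rid, set()).add(reason)

    def structure_of(record) -> str | None:
        try:
            return chemstruct.standardize(record.raw_smiles).canonical_smiles
        except Exception:  # noqa: BLE001
            return None

    reason_map = {
        "dropped_small": "heavy_atoms_lt_15",
        "dropped_mw": "mol_weight_gt_800",
        "dropped_element": "element_not_whitelisted",
    }
    n_ok = 0
    for record in records:
        fate = manifest.record_fates[record.compound_id]
        smiles = structure_of(record)
        if fate in ("kept", "merged", "gt_integrated"):
            expected = manifest.expected_compounds.get(smiles)
            got = final.get(smiles)
            ok = (
                expected is not None
                and got is not None
                and got.label.value == expected["label"]
                and abs(got.pki - expected["pki"]) < 1e-6
                and got.is_bound == expected["is_bound"]
            )
        elif fate == "band_excluded":
            ok = smiles not in final and any(
                r == "band_excluded" for r in dropped_reasons.get(smiles, ())
            )
        elif fate == "discarded_discordant":
            ok = smiles not in final and report.counts["discordant_replicates"] > 0
        elif fate == "gt_dropped":
            ok = smiles not in final
        elif fate == "dropped_invalid":
            ok = bool(
                dropped_reasons.get(record.compound_id, set())
                & {"invalid_structure", "no_organic_fragment"}
            )
        else:
            ok = reason_map[fate] in dropped_reasons.get(record.compound_id, set())
        n_ok += ok
    return n_ok / len(records)
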