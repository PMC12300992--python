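"""Build labeled, deduplicated, split datasets from raw Ki activity tables.

The pipeline mirrors a ChEMBL-style extract workflow for enzyme-inhibition
data: a primary filter on relation type and structural sanity (MW <= 800 Da,
>= 15 heavy atoms, element whitelist), representation-level duplicate
resolution with a 25%-deviation consistency rule on Ki, pKi conversion,
threshold-plus-band labeling, late integration of censored (">") records as
inactives, and a per-class stratified 80/20 split.

Deviation is computed as |x - mean| / mean on Ki in nM. For two replicate
values the mean is kept only if both deviate by at most 25% from it; for
three or more, a single pass removes values deviating by more than 25% from
the initial mean and the survivors are re-averaged. The boundary of exactly
25% counts as "keep" in both branches.
"""

from __future__ import annotations

import enum
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemstruct
from .chemstruct import BIT_REPRS, ReprId, StandardizationError, Structure

#: Default classification thresholds (pKi) per isoform, with the +/-0.25 band.
DEFAULT_THRESHOLDS = {
    "hCA_I": 6.30,
    "hCA_II": 7.30,
    "hCA_IX": 7.30,
    "hCA_XII": 7.45,
}
DEFAULT_BAND = 0.25

MAX_MOL_WEIGHT = 800.0
MIN_HEAVY_ATOMS = 15
DEVIATION_LIMIT = 0.25

REQUIRED_COLUMNS = [
    "compound_id",
    "smiles",
    "standard_value_nm",
    "standard_relation",
    "target",
    "source",
]


class Relation(str, enum.Enum):
    EQ = "="
    GT = ">"


class Label(str, enum.Enum):
    ACTIVE = "ACTIVE"
    INACTIVE = "INACTIVE"


@dataclass
class ActivityRecord:
    """One assay measurement of inhibition potency."""

    compound_id: str
    raw_smiles: str
    ki_nm: float
    relation: Relation
    isoform: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ki_nm) and self.ki_nm > 0):
            raise ValueError(f"ki_nm must be finite and positive, got {self.ki_nm}")
        self.relation = Relation(self.relation)


@dataclass
class LabeledCompound:
    """A unique structure with a consensus potency and a class label.

    ``is_bound`` marks censored records: their ``pki`` is an upper bound on
    the true pKi (Ki > reported value), not a point estimate.
    """

    structure: Structure
    pki: float
    label: Label
    provenance: tuple[str, ...]
    is_bound: bool = False


@dataclass
class CuratedDataset:
    isoform: str
    threshold_pki: float
    band: float
    train: list[LabeledCompound]
    test: list[LabeledCompound]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for split, compounds in (("train", self.train), ("test", self.test)):
            for c in compounds:
                rows.append(
                    {
                        "canonical_smiles": c.structure.canonical_smiles,
                        "pki_or_bound": c.pki,
                        "is_bound": c.is_bound,
                        "label": c.label.value,
                        "split": split,
                        "provenance": ";".join(c.provenance),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CurationReport:
    """Counts of records dropped/retained per pipeline rule."""

    counts: Counter = field(default_factory=Counter)
    drop_reasons: list[tuple[str, str]] = field(default_factory=list)

    def drop(self, record_id: str, reason: str) -> None:
        self.counts[reason] += 1
        self.drop_reasons.append((record_id, reason))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"counts": dict(self.counts)}, indent=2, sort_keys=True)
        )


def read_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read a delimited activity table (CSV or TSV, header required)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"compound_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity table is missing columns: {missing}")
    return [
        ActivityRecord(
            compound_id=str(row.compound_id),
            raw_smiles=str(row.smiles),
            ki_nm=float(row.standard_value_nm),
            relation=Relation(str(row.standard_relation)),
            isoform=str(row.target),
            source_tag="" if pd.isna(row.source) else str(row.source),
        )
        for row in df.itertuples()
    ]


def ki_to_pki(ki_nm: float) -> float:
    """pKi = -log10(Ki in molar) = 9 - log10(Ki in nM)."""
    if not (math.isfinite(ki_nm) and ki_nm > 0):
        raise ValueError(f"Ki must be finite and positive, got {ki_nm}")
    return 9.0 - math.log10(ki_nm)


@dataclass
class FilteredRecords:
    """Output of the primary filter: standardized EQ records, the censored
    (">") pool held back for later integration, and the drop report."""

    eq: list[tuple[ActivityRecord, Structure]]
    gt: list[tuple[ActivityRecord, Structure]]
    report: CurationReport


def _passes_structure_rules(structure: Structure) -> str | None:
    if structure.mol_weight > MAX_MOL_WEIGHT:
        return "mol_weight_gt_800"
    if structure.num_heavy_atoms < MIN_HEAVY_ATOMS:
        return "heavy_atoms_lt_15"
    if not structure.passes_element_whitelist():
        return "element_not_whitelisted"
    return None


def primary_filter(
    records: list[ActivityRecord], source_allowlist: set[str] | None = None
) -> FilteredRecords:
    """Standardize and filter raw records.

    Retains records with relation "=" satisfying the structural rules;
    censored ">" records passing the same structural rules are kept in a
    separate pool for post-threshold integration. Failures are dropped with
    logged reasons, never raised.
    """
    report = CurationReport()
    eq: list[tuple[ActivityRecord, Structure]] = []
    gt: list[tuple[ActivityRecord, Structure]] = []
    for rec in records:
        if source_allowlist is not None and rec.source_tag not in source_allowlist:
            report.drop(rec.compound_id, "source_not_allowed")
            continue
        try:
            structure = chemstruct.standardize(rec.raw_smiles)
        except StandardizationError as exc:
            reason = "no_organic_fragment" if "no organic" in str(exc) else "invalid_structure"
            report.drop(rec.compound_id, reason)
            continue
        rule = _passes_structure_rules(structure)
        if rule is not None:
            report.drop(rec.compound_id, rule)
            continue
        if rec.relation is Relation.EQ:
            eq.append((rec, structure))
            report.counts["retained_eq"] += 1
        else:
            gt.append((rec, structure))
            report.counts["retained_gt_pool"] += 1
    return FilteredRecords(eq=eq, gt=gt, report=report)


def representation_identity(a: Structure, b: Structure, tol: float = 1e-9) -> bool:
    """True iff two structures are indistinguishable across all four
    representations: Tanimoto 1 on the three fingerprints and Euclidean
    distance ~0 on unscaled descriptors."""
    for repr_id in BIT_REPRS:
        fa = chemstruct.featurize(a, repr_id)
        fb = chemstruct.featurize(b, repr_id)
        if not np.array_equal(fa.values, fb.values):
            return False
    da = chemstruct.featurize(a, ReprId.PHYSCHEM).values
    db = chemstruct.featurize(b, ReprId.PHYSCHEM).values
    return chemstruct.euclidean(da, db) <= tol


def resolve_duplicates(group: list[ActivityRecord]) -> float | None:
    """Merge replicate Ki values for one structure; None discards the compound.

    n=1: the value itself. n=2: mean if both values deviate from it by at
    most 25%, else discard. n>=3: one pass removes values deviating by more
    than 25% from the initial mean; survivors are re-averaged (discard if
    none survive).
    """
    relations = {r.relation for r in group}
    if len(relations) > 1:
        raise ValueError("mixed relations in duplicate group; pre-partition by relation")
    values = [r.ki_nm for r in group]
    if len(values) == 1:
        return values[0]
    mean = sum(values) / len(values)
    deviations = [abs(v - mean) / mean for v in values]
    if len(values) == 2:
        return mean if all(d <= DEVIATION_LIMIT for d in deviations) else None
    survivors = [v for v, d in zip(values, deviations) if d <= DEVIATION_LIMIT]
    if not survivors:
        return None
    return sum(survivors) / len(survivors)


def group_duplicates(
    pairs: list[tuple[ActivityRecord, Structure]],
) -> list[tuple[Structure, list[ActivityRecord]]]:
    """Group records whose structures are identical across all four
    representations.

    Canonical SMILES buckets first; cross-bucket merging uses the three
    fingerprint byte-strings as a hash key (near-linear) with the descriptor
    distance verified exactly within each candidate bucket.
    """
    by_smiles: dict[str, list[tuple[ActivityRecord, Structure]]] = {}
    for rec, structure in pairs:
        by_smiles.setdefault(structure.canonical_smiles, []).append((rec, structure))

    by_fp: dict[bytes, list[tuple[Structure, list[ActivityRecord]]]] = {}
    for smiles in sorted(by_smiles):
        bucket = by_smiles[smiles]
        structure = bucket[0][1]
        key = b"".join(
            chemstruct.featurize(structure, r).values.tobytes() for r in BIT_REPRS
        )
        merged = False
        for existing_structure, records in by_fp.get(key, []):
            if representation_identity(existing_structure, structure):
                records.extend(rec for rec, _s in bucket)
                merged = True
                break
        if not merged:
            by_fp.setdefault(key, []).append((structure, [rec for rec, _s in bucket]))
    out: list[tuple[Structure, list[ActivityRecord]]] = []
    for groups in by_fp.values():
        out.extend(groups)
    out.sort(key=lambda g: g[0].canonical_smiles)
    return out


def label_and_band(
    compounds: list[tuple[Structure, float, tuple[str, ...]]],
    threshold_pki: float,
    band: float = DEFAULT_BAND,
) -> tuple[list[LabeledCompound], list[tuple[Structure, float]]]:
    """Assign ACTIVE/INACTIVE labels; exclude compounds inside the +/-band.

    Input tuples are (structure, pKi, provenance ids). Returns (labeled,
    band-excluded).
    """
    if band < 0:
        raise ValueError("band must be non-negative")
    labeled: list[LabeledCompound] = []
    excluded: list[tuple[Structure, float]] = []
    for structure, pki, provenance in compounds:
        if pki > threshold_pki + band:
            labeled.append(LabeledCompound(structure, pki, Label.ACTIVE, provenance))
        elif pki < threshold_pki - band:
            labeled.append(LabeledCompound(structure, pki, Label.INACTIVE, provenance))
        else:
            excluded.append((structure, pki))
    return labeled, excluded


def integrate_gt_inactives(
    gt_pairs: list[tuple[ActivityRecord, Structure]],
    existing: list[LabeledCompound],
    threshold_pki: float,
    band: float = DEFAULT_BAND,
    report: CurationReport | None = None,
) -> list[LabeledCompound]:
    """Turn censored ">" records into confident inactives.

    A record Ki > X implies pKi < pki(X); it is labeled INACTIVE only when
    that bound already lies strictly below the inactive boundary
    (threshold - band), so no band-zone compound can re-enter. Duplicates of
    existing dataset members (by four-representation identity) are dropped.
    """
    report = report if report is not None else CurationReport()
    groups = group_duplicates(gt_pairs)
    added: list[LabeledCompound] = []
    existing_structures = [c.structure for c in existing]
    for structure, records in groups:
        try:
            merged = resolve_duplicates(records)
        except ValueError:
            merged = None
        if merged is None:
            report.drop(records[0].compound_id, "gt_discordant_replicates")
            continue
        bound_pki = ki_to_pki(merged)
        if bound_pki >= threshold_pki - band:
            report.drop(records[0].compound_id, "gt_bound_uninformative")
            continue
        if any(representation_identity(structure, s) for s in existing_structures):
            report.drop(records[0].compound_id, "gt_duplicate_of_existing")
            continue
        added.append(
            LabeledCompound(
                structure,
                bound_pki,
                Label.INACTIVE,
                tuple(r.compound_id for r in records),
                is_bound=True,
            )
        )
        report.counts["gt_integrated"] += 1
    return added


def stratified_split(
    compounds: list[LabeledCompound],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[LabeledCompound], list[LabeledCompound]]:
    """Per-class random split, floor(train_fraction * n) to train per class."""
    rng = np.random.default_rng(seed)
    train: list[LabeledCompound] = []
    test: list[LabeledCompound] = []
    for label in (Label.ACTIVE, Label.INACTIVE):
        members = [c for c in compounds if c.label is label]
        if len(members) < 5:
            raise ValueError(
                f"insufficient class size: {label.value} has {len(members)} < 5"
            )
        order = rng.permutation(len(members))
        n_train = int(math.floor(train_fraction * len(members)))
        train.extend(members[i] for i in sorted(order[:n_train]))
        test.extend(members[i] for i in sorted(order[n_train:]))
    return train, test


def median_threshold(pkis: list[float]) -> float:
    """Median-of-distribution threshold, for targets without a curated default."""
    return float(np.median(pkis))


def curate(
    records: list[ActivityRecord],
    isoform: str,
    threshold_pki: float | None = None,
    band: float = DEFAULT_BAND,
    train_fraction: float = 0.8,
    seed: int = 0,
    source_allowlist: set[str] | None = None,
) -> tuple[CuratedDataset, CurationReport]:
    """End-to-end curation for one isoform: filter, deduplicate, label, split.

    When no threshold is given, the curated default for the isoform is used
    if known, otherwise the median of the merged pKi distribution.
    """
    records = [r for r in records if r.isoform == isoform]
    filtered = primary_filter(records, source_allowlist=source_allowlist)
    report = filtered.report

    merged: list[tuple[Structure, float, tuple[str, ...]]] = []
    for structure, group in group_duplicates(filtered.eq):
        value = resolve_duplicates(group)
        if value is None:
            report.drop(group[0].compound_id, "discordant_replicates")
            continue
        if len(group) > 1:
            report.counts["duplicate_clusters_merged"] += 1
        merged.append(
            (structure, ki_to_pki(value), tuple(r.compound_id for r in group))
        )

    if threshold_pki is None:
        threshold_pki = DEFAULT_THRESHOLDS.get(
            isoform, median_threshold([pki for _s, pki, _p in merged])
        )

    labeled, band_excluded = label_and_band(merged, threshold_pki, band)
    report.counts["band_excluded"] += len(band_excluded)
    for structure, _pki in band_excluded:
        report.drop_reasons.append((structure.canonical_smiles, "band_excluded"))

    labeled += integrate_gt_inactives(
        filtered.gt, labeled, threshold_pki, band, report=report
    )

    train, test = stratified_split(labeled, train_fraction=train_fraction, seed=seed)
    report.counts["train"] = len(train)
    report.counts["test"] = len(test)
    dataset = CuratedDataset(
        isoform=isoform, threshold_pki=threshold_pki, band=band, train=train, test=test
    )
    return dataset, report
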