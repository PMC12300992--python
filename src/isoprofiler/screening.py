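"""Virtual-screening cascade, isoform cross-referencing, and
prediction-versus-experiment bookkeeping.

A screening run scores a standardized library with a trained model, keeps
compounds predicted active at a probability cutoff (0.5 by default), then
pushes the hits through an ordered cascade of filters: substructure-alert
sets (PAINS, Brenk, BMS, Inpharmatica via RDKit's filter catalogs, plus a
shipped NIBR-style SMARTS subset), drug-likeness property rules (Lipinski,
Veber), pluggable external predicates (e.g. toxicity models), allow-lists
(e.g. commercial availability), and a structural-novelty filter against the
training set (strict Tanimoto > 0.80 on the 881-bit keys removes a hit).

Per-isoform hit lists can be cross-referenced into activity profiles, and
profiles compared against experimental Ki panels at a 1 uM activity cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from . import chemstruct
from .chemstruct import ReprId, Structure
from .modeling import TrainedProfilerModel, tanimoto_kernel

ACTIVITY_CUTOFF_NM = 1000.0  # 1 uM: the "biologically relevant" boundary
NOVELTY_MAX_SIMILARITY = 0.80


@dataclass
class ScreeningHit:
    structure: Structure
    probability: float
    isoform: str
    filter_trace: list[tuple[str, str]] = field(default_factory=list)  # (name, pass/fail)


class FilterStage:
    """A named predicate over structures; True means the compound survives."""

    name: str = "filter"

    def passes(self, structure: Structure) -> bool:  # pragma: no cover - interface
        raise NotImplementedError


class AlertFilter(FilterStage):
    """Substructure-alert stage backed by an RDKit filter catalog."""

    _CATALOGS = {
        "PAINS": FilterCatalogParams.FilterCatalogs.PAINS,
        "BRENK": FilterCatalogParams.FilterCatalogs.BRENK,
        "BMS": FilterCatalogParams.FilterCatalogs.CHEMBL_BMS,
        "INPHARMATICA": FilterCatalogParams.FilterCatalogs.CHEMBL_Inpharmatica,
    }

    def __init__(self, catalog: str):
        catalog = catalog.upper()
        if catalog not in self._CATALOGS:
            raise ValueError(f"unknown alert catalog {catalog!r}")
        self.name = f"alerts_{catalog.lower()}"
        params = FilterCatalogParams()
        params.AddCatalog(self._CATALOGS[catalog])
        self._catalog = FilterCatalog(params)

    def passes(self, structure: Structure) -> bool:
        return not self._catalog.HasMatch(structure.mol)


class SmartsAlertFilter(FilterStage):
    """Alert stage from a SMARTS file (one ``SMARTS<tab>name`` per line).

    Malformed SMARTS fail at load time, never per compound.
    """

    def __init__(self, name: str, smarts_lines: Iterable[str]):
        self.name = name
        self._patterns: list[tuple[Chem.Mol, str]] = []
        for line in smarts_lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smarts, label = parts[0], parts[1] if len(parts) > 1 else parts[0]
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"malformed SMARTS in alert set {name!r}: {smarts!r}")
            self._patterns.append((patt, label))

    @classmethod
    def nibr_subset(cls) -> "SmartsAlertFilter":
        text = (
            resources.files("isoprofiler.data")
            .joinpath("nibr_subset_synthetic.smarts")
            .read_text()
        )
        return cls("alerts_nibr_subset", text.splitlines())

    def passes(self, structure: Structure) -> bool:
        return not any(structure.mol.HasSubstructMatch(p) for p, _label in self._patterns)


class LipinskiFilter(FilterStage):
    """Rule of five: MW <= 500, logP <= 5, H-bond donors <= 5, acceptors <= 10.

    Applied strictly (zero violations) by default; ``max_violations=1`` gives
    the common relaxed variant.
    """

    def __init__(self, max_violations: int = 0):
        self.max_violations = max_violations
        self.name = "lipinski"

    def passes(self, structure: Structure) -> bool:
        mol = structure.mol
        violations = sum(
            [
                Descriptors.MolWt(mol) > 500,
                Crippen.MolLogP(mol) > 5,
                Lipinski.NumHDonors(mol) > 5,
                Lipinski.NumHAcceptors(mol) > 10,
            ]
        )
        return violations <= self.max_violations


class VeberFilter(FilterStage):
    """Veber oral-bioavailability rule: rotatable bonds <= 10, TPSA <= 140."""

    name = "veber"

    def passes(self, structure: Structure) -> bool:
        mol = structure.mol
        return (
            Lipinski.NumRotatableBonds(mol) <= 10
            and Descriptors.TPSA(mol) <= 140
        )


class PredicateFilter(FilterStage):
    """Pluggable external predicate (e.g. a toxicity model endpoint)."""

    def __init__(self, name: str, predicate: Callable[[Structure], bool]):
        self.name = name
        self._predicate = predicate

    @classmethod
    def always_pass(cls, name: str = "toxicity_stub") -> "PredicateFilter":
        return cls(name, lambda _s: True)

    def passes(self, structure: Structure) -> bool:
        return bool(self._predicate(structure))


class AllowListFilter(FilterStage):
    """Keep only compounds whose canonical SMILES is in a user allow-list."""

    def __init__(self, name: str, allowed_smiles: Iterable[str]):
        self.name = name
        self._allowed = {
            chemstruct.standardize(s).canonical_smiles for s in allowed_smiles
        }

    def passes(self, structure: Structure) -> bool:
        return structure.canonical_smiles in self._allowed


def screen(
    model: TrainedProfilerModel,
    library: list[Structure],
    prob_cutoff: float = 0.5,
) -> list[ScreeningHit]:
    """Score a library and keep predicted actives (probability >= cutoff).

    Hits are sorted by descending probability, ties broken lexicographically
    by canonical SMILES.
    """
    if not library:
        warnings.warn("empty screening library")
        return []
    probs = model.predict_proba(library)
    hits = [
        ScreeningHit(structure=s, probability=float(p), isoform=model.isoform)
        for s, p in zip(library, probs)
        if p >= prob_cutoff
    ]
    hits.sort(key=lambda h: (-h.probability, h.structure.canonical_smiles))
    return hits


def filter_cascade(
    hits: list[ScreeningHit], stages: list[FilterStage]
) -> tuple[list[ScreeningHit], dict[str, int]]:
    """Apply filter stages in order; returns survivors and per-stage counts.

    Every hit's ``filter_trace`` records each stage it met and the outcome,
    so the funnel is fully replayable.
    """
    funnel: dict[str, int] = {"input": len(hits)}
    current = list(hits)
    for stage in stages:
        survivors = []
        for hit in current:
            ok = stage.passes(hit.structure)
            hit.filter_trace.append((stage.name, "pass" if ok else "fail"))
            if ok:
                survivors.append(hit)
        current = survivors
        funnel[stage.name] = len(current)
    return current, funnel


def novelty_filter(
    hits: list[ScreeningHit],
    train_keys: np.ndarray,
    max_similarity: float = NOVELTY_MAX_SIMILARITY,
) -> list[ScreeningHit]:
    """Drop hits too similar to the training set.

    A hit is removed iff its maximum Tanimoto similarity (881-bit keys) to
    any training compound is strictly greater than ``max_similarity``; a hit
    at exactly the threshold is retained.
    """
    if not hits:
        return []
    hit_keys = chemstruct.featurize_matrix([h.structure for h in hits], ReprId.KEYS_881)
    sims = tanimoto_kernel(hit_keys, train_keys).max(axis=1)
    out = []
    for hit, sim in zip(hits, sims):
        ok = sim <= max_similarity
        hit.filter_trace.append(("novelty", "pass" if ok else "fail"))
        if ok:
            out.append(hit)
    return out


@dataclass
class ActivityProfile:
    """Per-compound membership and probability across isoform hit lists."""

    canonical_smiles: str
    predicted_active: dict[str, bool]
    probability: dict[str, float]


def cross_reference(
    hit_lists: dict[str, list[ScreeningHit]], mode: str = "union", min_isoforms: int = 1
) -> list[ActivityProfile]:
    """Join per-isoform hit lists into activity profiles.

    ``mode``: "union" keeps compounds hit in any list, "intersection" only
    those hit in every list, "at_least" those hit in >= ``min_isoforms``.
    """
    if len(hit_lists) < 2:
        raise ValueError("cross_reference needs hit lists for at least two isoforms")
    isoforms = sorted(hit_lists)
    by_smiles: dict[str, dict[str, float]] = {}
    for isoform in isoforms:
        for hit in hit_lists[isoform]:
            by_smiles.setdefault(hit.structure.canonical_smiles, {})[isoform] = hit.probability
    profiles = []
    for smiles in sorted(by_smiles):
        hits = by_smiles[smiles]
        n = len(hits)
        keep = {
            "union": n >= 1,
            "intersection": n == len(isoforms),
            "at_least": n >= min_isoforms,
        }.get(mode)
        if keep is None:
            raise ValueError(f"unknown join mode {mode!r}")
        if keep:
            profiles.append(
                ActivityProfile(
                    canonical_smiles=smiles,
                    predicted_active={i: i in hits for i in isoforms},
                    probability={i: hits.get(i, float("nan")) for i in isoforms},
                )
            )
    return profiles


def parse_ki(value) -> tuple[float, bool]:
    """Parse a Ki cell: a number, or a censored ">X" lower bound.

    Returns (value_nm, censored).
    """
    if isinstance(value, (int, float)):
        return float(value), False
    text = str(value).strip().replace(",", "")
    if text.startswith(">"):
        return float(text[1:]), True
    return float(text), False


def read_experimental_table(path) -> pd.DataFrame:
    """CSV with columns compound_id, isoform, ki_nm (numbers or ">X")."""
    df = pd.read_csv(path, dtype={"compound_id": str, "isoform": str, "ki_nm": str})
    needed = {"compound_id", "isoform", "ki_nm"}
    if not needed <= set(df.columns):
        raise ValueError(f"experimental table must have columns {sorted(needed)}")
    return df


@dataclass
class AgreementReport:
    tp: int
    tn: int
    fp: int
    fn: int
    excluded: int
    per_pair: list[dict]

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def hit_rate(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


def compare_to_experiment(
    predictions: dict[tuple[str, str], bool],
    experimental: pd.DataFrame,
    activity_cutoff_nm: float = ACTIVITY_CUTOFF_NM,
) -> AgreementReport:
    """Score predicted labels against an experimental Ki panel.

    ``predictions`` maps (compound_id, isoform) to a predicted-active flag.
    Experimental label is ACTIVE iff Ki < cutoff. Censored ">X" rows with
    X >= cutoff are confidently INACTIVE; censored rows with X < cutoff are
    uninformative and excluded (logged in the report).
    """
    tp = tn = fp = fn = excluded = 0
    per_pair = []
    for row in experimental.itertuples():
        key = (str(row.compound_id), str(row.isoform))
        if key not in predictions:
            continue
        ki, censored = parse_ki(row.ki_nm)
        if censored and ki < activity_cutoff_nm:
            excluded += 1
            per_pair.append(
                {"compound_id": key[0], "isoform": key[1], "outcome": "excluded_uninformative"}
            )
            continue
        experimental_active = (not censored) and ki < activity_cutoff_nm
        predicted_active = predictions[key]
        outcome = {
            (True, True): "TP",
            (False, False): "TN",
            (False, True): "FP",
            (True, False): "FN",
        }[(experimental_active, predicted_active)]
        tp += outcome == "TP"
        tn += outcome == "TN"
        fp += outcome == "FP"
        fn += outcome == "FN"
        per_pair.append({"compound_id": key[0], "isoform": key[1], "outcome": outcome})
    return AgreementReport(tp=tp, tn=tn, fp=fp, fn=fn, excluded=excluded, per_pair=per_pair)


@dataclass
class SelectivityResult:
    """Fold-change map for one compound against a reference isoform.

    ``ratios[i] = Ki(i) / Ki(reference)``: values above 1 mean the compound
    is that many fold more potent on (selective for) the reference isoform.
    Censored off-isoform values propagate as lower bounds on the ratio.
    """

    compound_id: str
    reference_isoform: str
    ratios: dict[str, float]
    is_lower_bound: dict[str, bool]

    @property
    def min_fold(self) -> float:
        return min(self.ratios.values()) if self.ratios else float("nan")


def selectivity_ratios(
    experimental: pd.DataFrame, reference_isoform: str
) -> dict[str, SelectivityResult]:
    """Per-compound fold-selectivity for a reference isoform.

    Compounds with a censored reference Ki are skipped (no point estimate to
    form the ratio against).
    """
    out: dict[str, SelectivityResult] = {}
    for compound_id, group in experimental.groupby("compound_id"):
        table = {
            str(r.isoform): parse_ki(r.ki_nm) for r in group.itertuples()
        }
        if reference_isoform not in table:
            continue
        ref_ki, ref_censored = table[reference_isoform]
        if ref_censored:
            continue
        ratios, bounds = {}, {}
        for isoform, (ki, censored) in table.items():
            if isoform == reference_isoform:
                continue
            ratios[isoform] = ki / ref_ki
            bounds[isoform] = censored
        out[str(compound_id)] = SelectivityResult(
            compound_id=str(compound_id),
            reference_isoform=reference_isoform,
            ratios=ratios,
            is_lower_bound=bounds,
        )
    return out


def load_ki_panel() -> pd.DataFrame:
    """The packaged experimental stopped-flow inhibition panel: twelve
    screened compounds plus the acetazolamide reference, Ki in nM against
    the four carbonic anhydrase isoforms."""
    path = resources.files("isoprofiler.data").joinpath("hca_inhibition_panel.csv")
    with resources.as_file(path) as p:
        return read_experimental_table(p)
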