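"""YAML run configuration: schema validation and run provenance.

One master seed per run fans out to per-stage seeds by fixed offsets
(recorded in the run manifest), so every stochastic stage is reproducible
from the single recorded value.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml

STAGE_SEED_OFFSETS = {
    "fixtures": 0,
    "curate": 1,
    "train": 2,
    "evaluate": 3,
    "screen": 4,
    "explain": 5,
    "profile": 6,
}

# section -> {key: (type, default)}
_SCHEMA: dict[str, dict[str, tuple]] = {
    "curation": {
        "threshold_pki": ((int, float), None),
        "band": ((int, float), 0.25),
        "train_fraction": ((int, float), 0.8),
        "source_allowlist": (list, None),
    },
    "grids": {
        "SVM": (list, None),
        "RF": (list, None),
        "KNN": (list, None),
        "GP": (list, None),
    },
    "cv": {
        "folds": (int, 5),
        "cycles": (int, 10),
    },
    "screening": {
        "prob_cutoff": ((int, float), 0.5),
        "filters": (list, ["pains", "lipinski", "veber", "brenk", "bms", "inpharmatica", "nibr"]),
        "novelty_max_similarity": ((int, float), 0.80),
        "lipinski_max_violations": (int, 0),
        "apply_novelty": (bool, True),
    },
    "fixtures": {
        "n_compounds": (int, 500),
        "duplicate_fraction": ((int, float), 0.15),
        "band_fraction": ((int, float), 0.08),
        "gt_fraction": ((int, float), 0.10),
        "noise_cv": ((int, float), 0.10),
        "planted_rule": (str, None),
    },
}


class ConfigError(ValueError):
    """Invalid configuration; the CLI maps this to exit code 2."""


def validate_config(raw: dict) -> dict:
    """Check sections/keys/types against the schema and fill defaults."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    out: dict = {}
    for section, content in raw.items():
        if section == "seed":
            if not isinstance(content, int):
                raise ConfigError("config key 'seed' must be an integer")
            out["seed"] = content
            continue
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(content, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        for key, value in content.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown config key {section}.{key}")
            expected = _SCHEMA[section][key][0]
            if value is not None and not isinstance(value, expected):
                raise ConfigError(
                    f"config key {section}.{key} has wrong type "
                    f"{type(value).__name__}"
                )
        out[section] = dict(content)
    for section, keys in _SCHEMA.items():
        out.setdefault(section, {})
        for key, (_t, default) in keys.items():
            out[section].setdefault(key, default)
    out.setdefault("seed", 0)
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return validate_config({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_manifest(
    out_dir: str | Path,
    command: str,
    cfg: dict,
    seed: int,
    inputs: dict[str, str | Path],
) -> Path:
    """Record provenance for one CLI run.

    The manifest is the only output carrying wall-clock timestamps; all
    computational outputs of a seeded rerun are byte-identical.
    """
    import numpy
    import rdkit
    import sklearn

    from . import __version__

    manifest = {
        "command": command,
        "config_hash": config_hash(cfg),
        "master_seed": seed,
        "versions": {
            "isoprofiler": __version__,
            "rdkit": rdkit.__version__,
            "scikit-learn": sklearn.__version__,
            "numpy": numpy.__version__,
        },
        "inputs": {name: file_digest(p) for name, p in inputs.items() if Path(p).exists()},
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
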