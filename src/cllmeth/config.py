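"""Pipeline configuration: defaults, validation, and aggregated errors.

Every published threshold is a named default, so the reference analysis is
just a run with an empty config file. Unknown keys are rejected with a
closest-match suggestion; all problems are reported at once.
"""

from __future__ import annotations

import difflib
import logging
from copy import deepcopy
from typing import Any

import yaml

from .datatypes import ConfigError

log = logging.getLogger("cllmeth")

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "enabled": True,
        "n_probes": 20000,
        "n_cll": 48,
        "n_control": 28,
        "n_mbl": 2,
        "n_batches": 2,
        "n_dmeg_up": 10,
        "n_dmeg_down": 5,
        "n_random_dmps": 300,
        "dmp_fraction": 0.0,
        "batch_shift": 0.0,
        "sex_effect_x": 0.25,
        "n_subtype_probes": 200,
        "n_bcell_samples": 3,
        "n_bcell_probes": 200,
        "cna_segments": [],
    },
    "inputs": {
        "beta": None, "detection_p": None, "bead_count": None,
        "annotation": None, "sample_sheet": None,
        "meth": None, "unmeth": None, "counts": None, "gmt": None,
    },
    "qc": {
        "detection_p": 0.05,
        "sample_fail_frac": 0.01,
        "probe_fail_frac": 0.01,
        "bead_min": 3,
        "bead_fail_frac": 0.05,
        "drop_sex_chroms": True,
        "drop_flagged": True,
        "sex_check": True,
    },
    "normalize": {"method": "type_aware_quantile", "offset": 100.0},
    "combat": {"enabled": True, "batch_col": "batch", "covariates": ["group"]},
    "dmp": {"delta_beta": 0.2, "fdr": 0.05, "covariates": ["age", "sex"],
            "moderated": False},
    "dmr": {"enabled": True, "min_dmps": 8, "min_len": 51, "merge_gap": 1000},
    "cna": {"enabled": True, "threshold": 0.2, "window": 50},
    "de": {"enabled": True, "min_total": 100000, "lfc": 1.0, "fdr": 0.05},
    "integrate": {"enabled": True, "sign_only": False},
    "subtype": {"enabled": True, "C": 10.0, "gamma": 0.01, "scale": "m"},
    "bcell": {"enabled": True},
    "ora": {"enabled": False, "gmt": None, "fdr": 0.05},
}

_RANGES = {
    ("qc", "detection_p"): (0.0, 1.0),
    ("qc", "sample_fail_frac"): (0.0, 1.0),
    ("qc", "probe_fail_frac"): (0.0, 1.0),
    ("qc", "bead_fail_frac"): (0.0, 1.0),
    ("dmp", "delta_beta"): (0.0, 1.0),
    ("dmp", "fdr"): (0.0, 1.0),
    ("de", "fdr"): (0.0, 1.0),
    ("cna", "threshold"): (0.0, 10.0),
    ("ora", "fdr"): (0.0, 1.0),
}


def validate_config(raw: dict[str, Any] | None) -> dict[str, Any]:
    """Fill defaults, reject unknown keys (with suggestions), check ranges.

    All errors are aggregated into a single ConfigError. Deviations from
    the published defaults are logged at WARN.
    """
    raw = raw or {}
    errors: list[str] = []
    config = deepcopy(DEFAULTS)

    def visit(node: dict, defaults: dict, path: str) -> None:
        for key, value in node.items():
            if key not in defaults:
                candidates = difflib.get_close_matches(str(key), defaults.keys(), n=1)
                hint = f"; did you mean {candidates[0]!r}?" if candidates else ""
                errors.append(f"unknown key {path}{key!r}{hint}")
                continue
            if isinstance(defaults[key], dict) and not isinstance(value, dict) and value is not None:
                errors.append(f"{path}{key} must be a mapping")
            elif isinstance(defaults[key], dict):
                visit(value or {}, defaults[key], f"{path}{key}.")
            else:
                defaults[key] = value

    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    visit(raw, config, "")

    for (section, key), (lo, hi) in _RANGES.items():
        v = config[section][key]
        if not (lo < float(v) < hi):
            errors.append(f"{section}.{key}={v} must be in ({lo:g}, {hi:g})")
    if config["dmr"]["min_dmps"] < 1:
        errors.append("dmr.min_dmps must be >= 1")
    if config["de"]["min_total"] < 0:
        errors.append("de.min_total must be >= 0")

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))

    def warn_deviations(cfg: dict, defaults: dict, path: str) -> None:
        for key, value in cfg.items():
            if isinstance(value, dict):
                warn_deviations(value, defaults[key], f"{path}{key}.")
            elif value != defaults[key]:
                log.warning("config deviates from published default: %s%s=%r (default %r)",
                            path, key, value, defaults[key])

    warn_deviations(config, DEFAULTS, "")
    return config


def load_config(path: str | None) -> dict[str, Any]:
    if path is None:
        return validate_config({})
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)
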