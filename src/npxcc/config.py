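"""Run configuration: YAML in, validated/normalized dict out.

Defaults are the analysis thresholds used throughout: LOD exclusion above
25% censoring, FDR gate 0.05, volcano display cut 0.5 log2, 3-SD outlier
rule on two components, pQTL thresholds 5e-8 / 5e-6, star bins
0.05 / 0.005 / 0.0001.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

from .exceptions import ConfigError

DEFAULTS: dict = {
    "inputs": {
        "npx_a": None,
        "npx_b": None,
        "metadata": None,
        "metabolite_matrix": None,
        "metabolite_annotation": None,
        "genotypes": None,
    },
    "cohort_a": "TZ",
    "cohort_b": "NL",
    "thresholds": {
        "lod_max_frac": 0.25,
        "fdr_cut": 0.05,
        "fc_cut": 0.5,
        "outlier_sd": 3.0,
        "outlier_components": 2,
        "pqtl_genome_wide": 5e-8,
        "pqtl_suggestive": 5e-6,
        "star_bins": [0.05, 0.005, 0.0001],
    },
    "modes": {
        "lod_mode": "per_cohort",
        "moderation": True,
        "clustering_method": "kmeans",
        "cluster_k": 2,
        "cluster_restarts": 100,
        "pca_scale": True,
        "fdr_family": "matrix",
    },
    "covariates": ["age", "sex", "bmi"],
    "seed": 0,
    "output_dir": "npxcc_output",
}

_RANGES = {
    ("thresholds", "lod_max_frac"): (0.0, 1.0, False),
    ("thresholds", "fdr_cut"): (0.0, 1.0, False),
    ("thresholds", "fc_cut"): (0.0, 10.0, True),
    ("thresholds", "outlier_sd"): (0.0, 100.0, False),
    ("thresholds", "pqtl_genome_wide"): (0.0, 1.0, False),
    ("thresholds", "pqtl_suggestive"): (0.0, 1.0, False),
}


def _merge(base: dict, override: dict, path="") -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if key not in out:
            raise ConfigError(f"unknown config key: {path + key!r}")
        if isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge(out[key], val, path=f"{path}{key}.")
        else:
            out[key] = val
    return out


def validate_config(cfg: dict | None) -> dict:
    """Inject defaults, check ranges; idempotent (normalize(normalize(x)) == normalize(x))."""
    norm = _merge(DEFAULTS, cfg or {})
    for (section, key), (lo, hi, inclusive) in _RANGES.items():
        val = norm[section][key]
        ok = lo <= val <= hi if inclusive else lo < val < hi
        if not ok:
            bound = f"[{lo}, {hi}]" if inclusive else f"({lo}, {hi})"
            raise ConfigError(f"{section}.{key} = {val} outside {bound}")
    if norm["modes"]["lod_mode"] not in ("both", "either", "per_cohort"):
        raise ConfigError(f"modes.lod_mode must be both|either|per_cohort")
    if norm["modes"]["clustering_method"] not in ("kmeans", "hierarchical_ward"):
        raise ConfigError("modes.clustering_method must be kmeans|hierarchical_ward")
    if int(norm["modes"]["cluster_k"]) < 1:
        raise ConfigError("modes.cluster_k must be >= 1")
    if not isinstance(norm["seed"], int) or norm["seed"] < 0:
        raise ConfigError("seed must be a non-negative integer")
    return norm


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return validate_config(raw)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
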