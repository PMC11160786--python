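"""Run configuration: documented defaults plus YAML overrides."""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ValidationError

DEFAULTS: dict = {
    "seed": 0,
    # variant discretisation
    "am_benign_max": 0.34,
    "am_pathogenic_min": 0.564,
    "ddg_neutral_band": 2.0,       # triage threshold (kcal/mol)
    "ddg_cis_threshold": 1.5,      # cis-pQTL enrichment threshold
    # structure confidence
    "trim_window": 10,
    "trim_threshold": 50.0,
    "interface_plddt_filter": 70.0,
    # pockets
    "pocket_cutoff": 4.5,
    "pocket_score_threshold": 800.0,
    # interfaces
    "interface_cutoff": 5.0,
    "pdockq_contact_cutoff": 8.0,
    "pdockq_constants": {"L": 0.724, "x0": 152.611, "k": 0.052, "b": 0.018},
    "pdockq_min": 0.23,
    "hub_min_partners": 5,
    "cluster_distance_threshold": 0.7,
    # abundance screen
    "coverage_min": 0.25,
    "concordance_min": 0.3,
    "hypermut_max": 500,
    "fdr_threshold": 0.01,
    # mechanism precedence (configurable; see docs/methods.md)
    "mechanism_precedence": ["stability", "pocket", "interface"],
}


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, shallowly overridden by a YAML mapping if given."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
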