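"""Flat key-value configuration mapped onto the parameter dataclasses.

Config files are YAML with one flat mapping whose keys mirror the model
symbols: ``dt_lbf, eps2, sigma_lbf, mu, v_len, lambda1, lambda2`` (LBF),
``dt_adpls, eps1, sigma_adpls, alpha, beta, c, m`` (ADPLS) and
``d, iter_max, early_stop, stop_tol`` (fusion/driver).  Precedence:
built-in defaults < config file < explicit overrides (CLI flags).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Optional

import yaml

from .adpls import AdplsParams
from .fusion import FusionParams
from .lbf import LbfParams

_ADPLS_KEYS = set(AdplsParams.__dataclass_fields__)
_LBF_KEYS = set(LbfParams.__dataclass_fields__)
_FUSION_KEYS = {"d", "iter_max", "early_stop", "stop_tol"}
KNOWN_KEYS = _ADPLS_KEYS | _LBF_KEYS | _FUSION_KEYS


def params_from_dict(values: dict) -> FusionParams:
    """Build a full parameter set from a flat mapping; unknown keys raise."""
    unknown = set(values) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return FusionParams(
        adpls=AdplsParams(**{k: values[k] for k in _ADPLS_KEYS & set(values)}),
        lbf=LbfParams(**{k: values[k] for k in _LBF_KEYS & set(values)}),
        **{k: values[k] for k in _FUSION_KEYS & set(values)},
    )


def params_to_dict(p: FusionParams) -> dict:
    """Flatten a parameter set back to the flat key-value form."""
    flat = {k: getattr(p, k) for k in _FUSION_KEYS}
    flat.update(asdict(p.adpls))
    flat.update(asdict(p.lbf))
    return flat


def load_params(config_path: Optional[str | Path] = None, overrides: Optional[dict] = None) -> FusionParams:
    """Resolve defaults, an optional YAML config and explicit overrides."""
    values: dict = {}
    if config_path is not None:
        loaded = yaml.safe_load(Path(config_path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {config_path} must be a flat mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    return params_from_dict(values)
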