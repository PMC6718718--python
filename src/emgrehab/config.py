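"""YAML configuration round-tripping for session simulations."""

from __future__ import annotations

from dataclasses import asdict, fields

import yaml

from . import calibration as cal
from . import exo_control as exo
from . import game as gm
from . import kalman as kf
from .session import SessionConfig

_SECTION_TYPES = {
    "game_cfg": gm.GameConfig,
    "filter_params": kf.FilterParams,
    "protocol": cal.CalibrationProtocol,
    "mapping": exo.MappingConfig,
    "gains": exo.ControllerGains,
    "plant": exo.PlantConfig,
}


def session_config_to_dict(cfg: SessionConfig) -> dict:
    d = asdict(cfg)
    d["leg_order"] = list(cfg.leg_order)
    for key in ("integral", "prev_error"):
        d["gains"].pop(key, None)
    return d


def session_config_from_dict(data: dict) -> SessionConfig:
    data = dict(data or {})
    kwargs = {}
    for f in fields(SessionConfig):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name in _SECTION_TYPES and isinstance(value, dict):
            value = _SECTION_TYPES[f.name](**value)
        elif f.name == "leg_order":
            value = tuple(value)
        kwargs[f.name] = value
    return SessionConfig(**kwargs)


def dump_default_config() -> str:
    return yaml.safe_dump(session_config_to_dict(SessionConfig()), sort_keys=False)


def load_session_config(path) -> SessionConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return session_config_from_dict(yaml.safe_load(fh))
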