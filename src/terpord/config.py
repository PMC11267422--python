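"""Run configuration: the analysis constants live here, in one place.

Defaults are the conventions used throughout: ΔG targets at Π = 5, 10, 15,
20, 25 mN/m; z-histogram bin width 0.87 Å; order-parameter plateau over
chain carbons 4-8; isotherm regression window 10-30 mN/m; growth-rate OD
window 0.4-0.75.

A config file is flat ``key = value`` pairs under INI sections (any
section; keys are matched by name). CLI flags override file values.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .errors import TerpordError


def _parse_floats(text: str) -> tuple[float, ...]:
    return tuple(float(x) for x in text.replace(",", " ").split())


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    topology_file: str | None = None  # None -> packaged default
    plateau_range: tuple[int, int] = (4, 8)  # chain carbon numbers
    z_bin_width: float = 0.87  # Å
    dg_targets: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)  # mN/m
    fit_window: tuple[float, float] = (10.0, 30.0)  # mN/m
    od_window: tuple[float, float] = (0.4, 0.75)
    lysis_query: float = 80.0  # % wash buffer
    manova_statistic: str = "pillai"
    round_down: bool = False  # snap MMA queries to recorded pressures below

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_PARSERS = {
    "seed": int,
    "out_dir": str,
    "topology_file": str,
    "plateau_range": lambda s: tuple(int(x) for x in _parse_floats(s)),
    "z_bin_width": float,
    "dg_targets": _parse_floats,
    "fit_window": _parse_floats,
    "od_window": _parse_floats,
    "lysis_query": float,
    "manova_statistic": str,
    "round_down": lambda s: s.strip().lower() in ("1", "true", "yes", "on"),
}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional INI file plus keyword overrides."""
    cfg = RunConfig()
    if path is not None:
        parser = configparser.ConfigParser()
        read = parser.read(str(path))
        if not read:
            raise TerpordError(f"config file not found: {path}")
        for section in parser.sections():
            for key, value in parser.items(section):
                if key not in _PARSERS:
                    raise TerpordError(f"unknown config key {key!r} in {path}")
                setattr(cfg, key, _PARSERS[key](value))
    for key, value in overrides.items():
        if value is None:
            continue
        if not hasattr(cfg, key):
            raise TerpordError(f"unknown config override {key!r}")
        setattr(cfg, key, value)
    return cfg
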