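"""TOML configuration loading.

A config file holds up to six sections — [anatomy], [transport],
[kinetics], [solver], [fit], [synth] — each optional, each overriding
the package defaults.  Anatomy lengths use the unit-suffixed keys
(twall_nm, tcyt_nm, tcyt_inner_nm, tstr_um, lchl_um) so that values can
be written in the units anatomical measurements are reported in.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .datasets import SynthTruth
from .geometry import LeafAnatomy
from .kinetics import KineticParams
from .solver import SolverOptions, TransportParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    anatomy: LeafAnatomy = dc_field(default_factory=LeafAnatomy)
    transport: TransportParams = dc_field(default_factory=TransportParams)
    kinetics: KineticParams = dc_field(default_factory=KineticParams)
    options: SolverOptions = dc_field(default_factory=SolverOptions)
    resolution: tuple[int, int] = (12, 40)
    fit: dict = dc_field(default_factory=dict)
    synth: SynthTruth = dc_field(default_factory=SynthTruth)
    scenario: str = "inner"


def _anatomy_from(section: dict) -> LeafAnatomy:
    kw = {}
    if "twall_nm" in section:
        kw["twall"] = section["twall_nm"] * 1e-9
    if "tcyt_nm" in section:
        kw["tcyt"] = section["tcyt_nm"] * 1e-9
    if "tcyt_inner_nm" in section:
        kw["tcyt_inner"] = section["tcyt_inner_nm"] * 1e-9
    if "tstr_um" in section:
        kw["tstr"] = section["tstr_um"] * 1e-6
    if "lchl_um" in section:
        kw["lchl"] = section["lchl_um"] * 1e-6
    for key in ("sc_sm", "sm_s"):
        if key in section:
            kw[key] = section[key]
    return LeafAnatomy(**kw)


def _kinetics_from(section: dict) -> KineticParams:
    rename = {
        "kmc_pa": "kmc",
        "kmo_kpa": "kmo",
        "sco_kpa_per_pa": "sco",
        "vcmax": "vcmax",
        "rd": "rd",
        "tp": "tp",
        "s_cal": "s_cal",
    }
    kw = {rename[k]: v for k, v in section.items() if k in rename}
    return KineticParams(**kw)


def load_config(path) -> RunConfig:
    """Parse a TOML config into a :class:`RunConfig`."""
    raw = tomllib.loads(Path(path).read_text())
    cfg = RunConfig()
    if "anatomy" in raw:
        cfg.anatomy = _anatomy_from(raw["anatomy"])
    if "transport" in raw:
        cfg.transport = TransportParams(**raw["transport"])
    if "kinetics" in raw:
        cfg.kinetics = _kinetics_from(raw["kinetics"])
    if "solver" in raw:
        sec = dict(raw["solver"])
        nx = sec.pop("nx", cfg.resolution[0])
        ny = sec.pop("ny", cfg.resolution[1])
        cfg.resolution = (nx, ny)
        cfg.scenario = sec.pop("scenario", cfg.scenario)
        if sec:
            cfg.options = SolverOptions(**sec)
    if "fit" in raw:
        cfg.fit = dict(raw["fit"])
    if "synth" in raw:
        sec = dict(raw["synth"])
        sec.setdefault("anatomy", cfg.anatomy)
        sec.setdefault("transport", cfg.transport)
        cfg.synth = SynthTruth(**sec)
    return cfg
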