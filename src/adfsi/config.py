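"""Plain-text (YAML) run configuration: materials, geometry, scenario,
coupling settings.

A run config is a mapping with any of the keys ``material``, ``geometry``,
``scenario``, ``coupling``; unknown keys are rejected.  Material constants
are in MPa (1/MPa for the incompressibility parameter), geometry in mm,
flows in L/min.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .coupling import CannulationScenario, CouplingConfig
from .geometry import BranchSpec, FlapSpec, TearSpec, VesselSpec
from .materials import NeoHookeanParams, OgdenParams

__all__ = [
    "material_to_dict",
    "material_from_dict",
    "vessel_spec_to_dict",
    "vessel_spec_from_dict",
    "load_run_config",
    "save_run_config",
]


def material_to_dict(material) -> dict:
    if isinstance(material, OgdenParams):
        return {
            "model": "ogden3",
            "mu_mpa": list(material.mu),
            "alpha": list(material.alpha),
            "volumetric_d_per_mpa": material.volumetric_d,
        }
    if isinstance(material, NeoHookeanParams):
        return {"model": "neo_hookean", "mu_mpa": material.mu, "d_per_mpa": material.d}
    raise TypeError(f"unsupported material {type(material).__name__}")


def material_from_dict(d: dict):
    kind = d.get("model")
    if kind == "ogden3":
        return OgdenParams(
            mu=tuple(d["mu_mpa"]),
            alpha=tuple(d["alpha"]),
            volumetric_d=d.get("volumetric_d_per_mpa", 0.0),
        )
    if kind == "neo_hookean":
        return NeoHookeanParams(mu=d["mu_mpa"], d=d["d_per_mpa"])
    raise ValueError(f"unknown material model {kind!r}")


def vessel_spec_to_dict(spec: VesselSpec) -> dict:
    d = asdict(spec)
    d["branches"] = [asdict(b) for b in spec.branches]
    d["tears"] = [asdict(t) for t in spec.tears]
    d["flap"] = asdict(spec.flap)
    d["segments"] = [list(s) for s in spec.segments]
    return d


def vessel_spec_from_dict(d: dict) -> VesselSpec:
    d = dict(d)
    d["branches"] = tuple(BranchSpec(**b) for b in d["branches"])
    d["tears"] = tuple(
        TearSpec(**{**t, "semi_axes": tuple(t["semi_axes"])}) for t in d["tears"]
    )
    d["flap"] = FlapSpec(**d["flap"])
    d["segments"] = tuple(tuple(s) for s in d.get("segments", ()))
    return VesselSpec(**d)


_SECTIONS = {"material", "geometry", "scenario", "coupling"}


def load_run_config(path) -> dict:
    """Parse a YAML run config into constructed objects (missing sections
    are simply absent from the result)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = {}
    if "material" in raw:
        out["material"] = material_from_dict(raw["material"])
    if "geometry" in raw:
        out["geometry"] = vessel_spec_from_dict(raw["geometry"])
    if "scenario" in raw:
        out["scenario"] = CannulationScenario(**raw["scenario"])
    if "coupling" in raw:
        out["coupling"] = CouplingConfig(**raw["coupling"])
    return out


def save_run_config(path, material=None, geometry=None, scenario=None, coupling=None):
    doc = {}
    if material is not None:
        doc["material"] = material_to_dict(material)
    if geometry is not None:
        doc["geometry"] = vessel_spec_to_dict(geometry)
    if scenario is not None:
        doc["scenario"] = asdict(scenario)
    if coupling is not None:
        c = asdict(coupling)
        c.pop("fluid_options", None)
        doc["coupling"] = c
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
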