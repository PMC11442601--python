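"""Scenario configuration: sample composition, protocol, geometry, detector.

A scenario bundles everything a simulation run needs. The stock scenario
roster mirrors the chemiluminescence experiments: phosphate buffer (``pb``)
and albumin solution (``bsa``), each optionally with H2O2 prooxidant and
with catalase or superoxide dismutase added.

Stock compositions (all molar): BSA 0.6 mM, dissolved O2 0.3 mM, protein-bound
iron 4 uM (albumin samples only), H2O2 from {0.1, 1, 10 mM}, CAT 3.2e-8 M,
SOD 9.9e-8 M.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from .electrophysics import (
    ChamberGeometry,
    PulseProtocol,
    SampleProperties,
    default_geometry,
    default_protocol,
)

KNOWN_LABELS = ("pb", "pb_h2o2", "bsa", "bsa_h2o2")


@dataclass(frozen=True)
class Composition:
    """Initial concentrations (M), identical in all compartments."""

    bsa: float = 0.0
    h2o2: float = 0.0
    o2: float = 3.0e-4
    cat: float = 0.0
    sod: float = 0.0
    fe_total: float = 0.0
    fe2_fraction: float = 0.5

    def initial_concentrations(self) -> dict[str, float]:
        return {
            "BSA": self.bsa,
            "H2O2": self.h2o2,
            "3O2": self.o2,
            "CAT": self.cat,
            "SOD": self.sod,
            "Fe2+": self.fe_total * self.fe2_fraction,
            "Fe3+": self.fe_total * (1.0 - self.fe2_fraction),
        }


@dataclass(frozen=True)
class Scenario:
    """A full experimental condition for the simulator."""

    label: str
    composition: Composition
    protocol: PulseProtocol = field(default_factory=default_protocol)
    geometry: ChamberGeometry = field(default_factory=default_geometry)
    sample: SampleProperties = field(default_factory=SampleProperties)
    pulse_start: float = 60.0
    t_end: float = 150.0
    current_mode: str = "theoretical"
    constant_current: float | None = None
    boundary_layer: float = 30e-6  # m; diffusion length scale to the bulk
    single_box: bool = False
    channel_options: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def replace(self, **kwargs: Any) -> "Scenario":
        return replace(self, **kwargs)


def make_scenario(label: str, h2o2: float = 1.0e-3, cat: bool = False,
                  sod: bool = False, **kwargs: Any) -> Scenario:
    """Stock scenario factory.

    ``label`` in {pb, pb_h2o2, bsa, bsa_h2o2}; ``h2o2`` applies to the
    *_h2o2 labels. ``cat``/``sod`` add the respective enzyme.
    """
    if label not in KNOWN_LABELS:
        raise ValueError(f"unknown scenario label {label!r}; "
                         f"expected one of {KNOWN_LABELS}")
    with_bsa = label.startswith("bsa")
    with_h2o2 = label.endswith("h2o2")
    comp = Composition(
        bsa=6.0e-4 if with_bsa else 0.0,
        h2o2=h2o2 if with_h2o2 else 0.0,
        fe_total=4.0e-6 if with_bsa else 0.0,
        cat=3.2e-8 if cat else 0.0,
        sod=9.9e-8 if sod else 0.0,
    )
    suffix = ("_cat" if cat else "") + ("_sod" if sod else "")
    return Scenario(label=label + suffix, composition=comp, **kwargs)


def scenario_from_yaml(path: str | Path) -> Scenario:
    """Load a scenario from a YAML config file.

    Recognised sections: ``label``, ``composition``, ``protocol``,
    ``geometry``, ``sample``, plus top-level scalars matching Scenario fields.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    comp = Composition(**cfg.pop("composition", {}))
    protocol = (PulseProtocol(**cfg.pop("protocol"))
                if "protocol" in cfg else default_protocol())
    geometry = (ChamberGeometry(**cfg.pop("geometry"))
                if "geometry" in cfg else default_geometry())
    sample = (SampleProperties(**cfg.pop("sample"))
              if "sample" in cfg else SampleProperties())
    label = cfg.pop("label", "custom")
    return Scenario(label=label, composition=comp, protocol=protocol,
                    geometry=geometry, sample=sample, **cfg)
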