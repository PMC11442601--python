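"""Convert the pulse train into electrode source terms and protein transport.

The pulse current is partitioned among parallel interfacial channels at each
electrode. Each channel is tied to an electrode reaction of the network and
receives a share f_i of the instantaneous current, either fixed or weighted by
the local concentration of its reduced/oxidised partner (water uses a constant
activity weight). Faraday's law then converts the channel current into a molar
event rate, n_dot_i = (I/F) * f_i / z_i, confined to the thin electrode
compartment.

Negatively charged protein additionally electromigrates into the anode layer
while the field is on (flux mu*E*c_bulk), which is the pre-concentration that
makes the anode chemistry protein-dominated late in the pulse train.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import FARADAY
from .electrophysics import (
    ChamberGeometry,
    PulseProtocol,
    SampleProperties,
    field_strength,
    theoretical_current,
)
from .network import ReactionNetwork


class ChannelConfigError(ValueError):
    """No active electrode channel while current flows."""


@dataclass(frozen=True)
class ElectrodeChannel:
    """One parallel charge-transfer channel at an electrode.

    ``weight`` is a constant competition weight; if ``weight_species`` is set
    the weight is ``weight_scale * max(c, 0)`` with c the local concentration
    (M) of that species instead. Shares are the normalised weights.
    """

    id: str
    electrode: str  # "anode" | "cathode"
    reactants: Mapping[str, float]
    products: Mapping[str, float]
    electrons: int
    weight: float = 0.0
    weight_species: str | None = None
    weight_scale: float = 0.0  # M^-1

    def __post_init__(self) -> None:
        if self.electrode not in ("anode", "cathode"):
            raise ValueError("electrode must be 'anode' or 'cathode'")
        if self.electrons < 1:
            raise ValueError("electrons per event must be >= 1")

    def weight_at(self, state: Mapping[str, float]) -> float:
        if self.weight_species is None:
            return self.weight
        return self.weight_scale * max(state.get(self.weight_species, 0.0), 0.0)


def channel_from_reaction(network: ReactionNetwork, reaction_id: str,
                          **kwargs) -> ElectrodeChannel:
    """Build a channel from an electrode reaction row of the network."""
    r = network.reaction(reaction_id)
    if not r.is_electrode:
        raise ValueError(f"reaction {reaction_id} is not an electrode reaction")
    electrode = "anode" if r.kind == "anodic" else "cathode"
    return ElectrodeChannel(
        id=kwargs.pop("id", f"rxn{reaction_id}"),
        electrode=electrode,
        reactants=dict(r.reactants),
        products=dict(r.products),
        electrons=r.electrons,
        **kwargs,
    )


def default_channels(network: ReactionNetwork,
                     water_ros_weight: float = 0.005,
                     h2o2_weight_scale: float = 300.0,
                     bsa_weight_scale: float = 0.1) -> list[ElectrodeChannel]:
    """The shipped electrode-channel roster.

    Anode: a dominant 4-electron water-to-O2 channel (net of the stepwise
    water-oxidation ladder), a small constant-weight ROS escape channel
    releasing HO., concentration-weighted H2O2 electrooxidation and protein
    electrooxidation. Cathode: hydrogen evolution plus concentration-weighted
    O2 and H2O2 reduction. The competition weights are explicit tunables (the
    interfacial partition is not known); they are logged with every run.
    """
    return [
        ElectrodeChannel("water_o2", "anode", {"H2O": 2},
                         {"3O2": 1, "H+": 4}, electrons=4, weight=1.0),
        channel_from_reaction(network, "1", id="water_ros",
                              weight=water_ros_weight),
        channel_from_reaction(network, "10", id="h2o2_ox",
                              weight_species="H2O2",
                              weight_scale=h2o2_weight_scale),
        channel_from_reaction(network, "14", id="bsa_ox",
                              weight_species="BSA",
                              weight_scale=bsa_weight_scale),
        ElectrodeChannel("h2_evolution", "cathode", {"H2O": 2},
                         {"H2": 1, "OH-": 2}, electrons=2, weight=1.0),
        channel_from_reaction(network, "25", id="o2_red",
                              weight_species="3O2", weight_scale=1000.0),
        channel_from_reaction(network, "28", id="h2o2_red",
                              weight_species="H2O2", weight_scale=300.0),
    ]


@dataclass(frozen=True)
class CurrentProfile:
    """Rectangular pulse current train starting at ``start_time``."""

    protocol: PulseProtocol
    amplitude: float  # A
    start_time: float = 60.0

    def __call__(self, t: float) -> float:
        if self.protocol.n_pulses == 0:
            return 0.0
        dt = t - self.start_time
        if dt < 0 or dt >= self.protocol.n_pulses * self.protocol.period:
            return 0.0
        return self.amplitude if (dt % self.protocol.period) < \
            self.protocol.pulse_width else 0.0

    @property
    def total_charge(self) -> float:
        return self.amplitude * self.protocol.total_on_time

    def pulse_edges(self) -> list[tuple[float, float]]:
        """(on, off) times of every pulse."""
        return [
            (self.start_time + k * self.protocol.period,
             self.start_time + k * self.protocol.period
             + self.protocol.pulse_width)
            for k in range(self.protocol.n_pulses)
        ]


def build_current_profile(protocol: PulseProtocol,
                          sample: SampleProperties | None = None,
                          geometry: ChamberGeometry | None = None,
                          mode: str = "theoretical",
                          constant_current: float | None = None,
                          start_time: float = 60.0) -> CurrentProfile:
    """Rectangular current pulses from ohmic theory or a user constant."""
    if mode == "theoretical":
        if sample is None or geometry is None:
            raise ValueError("theoretical mode needs sample and geometry")
        amplitude = theoretical_current(sample, geometry, protocol)
    elif mode == "constant":
        if constant_current is None:
            raise ValueError("constant mode needs constant_current")
        amplitude = constant_current
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CurrentProfile(protocol, amplitude, start_time)


def partition_current(current: float, state: Mapping[str, float],
                      channels: Sequence[ElectrodeChannel],
                      electrode: str) -> dict[str, float]:
    """Per-channel molar event rates (mol s^-1) for one electrode.

    Shares f_i are normalised weights; channel i converts current at
    (I/F) * f_i / z_i events per second. Raises if current flows with all
    weights zero.
    """
    if current < 0:
        raise ValueError("current must be >= 0")
    active = [c for c in channels if c.electrode == electrode]
    if current == 0.0 or not active:
        return {c.id: 0.0 for c in active}
    weights = np.array([c.weight_at(state) for c in active])
    total = weights.sum()
    if total <= 0.0:
        raise ChannelConfigError(
            f"all {electrode} channel weights zero while current flows")
    rates = {}
    for c, w in zip(active, weights):
        rates[c.id] = (current / FARADAY) * (w / total) / c.electrons
    return rates


def partition_anodic_current(current: float, state: Mapping[str, float],
                             channels: Sequence[ElectrodeChannel]
                             ) -> dict[str, float]:
    """Anode-side convenience wrapper for :func:`partition_current`."""
    return partition_current(current, state, channels, "anode")


def bsa_migration_flux(e_field: float, sample: SampleProperties,
                       bulk_concentration_molar: float) -> float:
    """Electromigrative protein flux into the anode layer (mol m^-2 s^-1).

    flux = mu * E * c_bulk while the pulse is on; ``bulk_concentration_molar``
    in M is converted to mol m^-3 internally.
    """
    if e_field < 0:
        raise ValueError("field must be >= 0")
    c_si = bulk_concentration_molar * 1e3  # M -> mol m^-3
    return sample.bsa_mobility * e_field * c_si
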