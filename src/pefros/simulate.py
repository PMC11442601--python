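"""Stiff ODE simulation of the reaction network under the pulse protocol.

Compartment topology
--------------------
Three well-mixed boxes: a thin anode layer (thickness delta), the bulk, and a
thin cathode layer. Electrode source terms act only in their layer; small
species exchange diffusively between each layer and the bulk with a
first-order coefficient k_ex = D / (delta * L_d), where L_d is a
boundary-layer length scale (default 30 um, of order sqrt(D * 1 s)).
Macromolecular species do not exchange: protein accumulated at the anode is
treated as retained there, entering the layer only through the explicit
electromigration term. A single-box mode exists for oracle tests.

The HO2./O2.- acid-base pair is kept at its instantaneous equilibrium at the
clamped pH: rates see the partitioned pool, and the pair's combined time
derivative is redistributed with the same partition.

Photon bookkeeping: every emission reaction carries a cumulative event counter
(moles of emission events summed over the photon-visible compartments, anode
layer + bulk) integrated as extra ODE states, so window integrals of the
emitted light are exact regardless of how spiky the rates are during pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .constants import FARADAY
from .electrophysics import field_strength
from .network import ReactionNetwork, StateError, load_diffusion_table
from .pulse_driver import (
    ChannelConfigError,
    CurrentProfile,
    ElectrodeChannel,
    build_current_profile,
    default_channels,
)
from .scenario import Scenario

__all__ = ["Trajectory", "IntegrationError", "simulate", "assemble_rhs",
           "integrate_network", "KineticsEngine"]

#: concentrations more negative than this abort the run; gentler undershoot
#: is clipped to zero. The bound is far below every composition of interest
#: (enzymes ~1e-8 M, iron ~1e-6 M) but loose enough not to trip on transient
#: solver undershoot of fast-consumed radicals.
NEGATIVE_CLIP = 1.0e-9

#: solver contract: stiff implicit integration at rtol 1e-6, atol 1e-15 M.
#: Source-free segments use BDF with the analytic Jacobian; pulse segments use
#: LSODA with finite differencing (the electrode-channel competition weights
#: are only piecewise smooth in the local concentrations).
DEFAULT_SOLVER = {"rtol": 1.0e-6, "atol": 1.0e-15,
                  "method_on": "LSODA", "method_off": "BDF"}


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the last valid state."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


@dataclass
class Trajectory:
    """Simulation output: concentrations, emission bookkeeping, charge."""

    time: np.ndarray                     # (n_t,) s, strictly increasing
    concentrations: np.ndarray           # (n_t, n_comp, n_species) M
    species: list[str]
    compartments: list[str]
    emission_reaction_ids: list[str]
    emission_wavelengths_nm: list[float]
    emission_flux: np.ndarray            # (n_t, n_em) mol events / s, visible
    cumulative_emission: np.ndarray      # (n_t, n_em) mol events, visible
    charge: np.ndarray                   # (n_t,) C
    label: str = ""
    meta: dict = field(default_factory=dict)

    def concentration(self, species: str, compartment: str = "bulk"
                      ) -> np.ndarray:
        i = self.compartments.index(compartment)
        j = self.species.index(species)
        return self.concentrations[:, i, j]

    def binned_emission_events(self, bin_edges: np.ndarray) -> np.ndarray:
        """Emission events (mol) per time bin, from the cumulative counters."""
        out = np.empty((len(bin_edges) - 1, len(self.emission_reaction_ids)))
        for k in range(out.shape[1]):
            cum = np.interp(bin_edges, self.time, self.cumulative_emission[:, k])
            out[:, k] = np.diff(cum)
        return out

    def to_tsv(self, path: str | Path) -> None:
        """One time column, one column per species per compartment, one
        cumulative-emission column per emission reaction."""
        header = ["time_s"]
        cols = [self.time]
        for i, comp in enumerate(self.compartments):
            for j, sid in enumerate(self.species):
                header.append(f"{comp}:{sid}")
                cols.append(self.concentrations[:, i, j])
        for k, rid in enumerate(self.emission_reaction_ids):
            header.append(f"emission:{rid}_mol")
            cols.append(self.cumulative_emission[:, k])
        header.append("charge_C")
        cols.append(self.charge)
        data = np.column_stack(cols)
        np.savetxt(path, data, delimiter="\t", header="\t".join(header),
                   comments="")


class KineticsEngine:
    """Assembles the ODE right-hand side for a network + compartment model."""

    def __init__(self, network: ReactionNetwork,
                 compartments: Sequence[str] = ("anode", "bulk", "cathode"),
                 volumes_l: Sequence[float] | None = None,
                 exchange: Mapping[str, float] | None = None,
                 channels: Sequence[ElectrodeChannel] | None = None,
                 current_amplitude: float = 0.0,
                 migration: dict | None = None,
                 visible: Sequence[str] = ("anode", "bulk")):
        self.network = network
        self.compartments = list(compartments)
        self.species = list(network.species)
        self.n_c = len(self.compartments)
        self.n_s = len(self.species)
        self._s_idx = {s: j for j, s in enumerate(self.species)}
        if volumes_l is None:
            volumes_l = [1.0] * self.n_c
        self.volumes_l = np.asarray(volumes_l, dtype=float)

        reactions = network.reactions
        self.bulk_reactions = [r for r in reactions if not r.is_electrode]
        n_r = len(self.bulk_reactions)
        # exponent matrix over non-fixed reactants; net stoichiometry matrix
        self._E = np.zeros((n_r, self.n_s))
        self._N = np.zeros((n_r, self.n_s))
        self._k = np.array([r.rate_constant for r in self.bulk_reactions])
        for i, r in enumerate(self.bulk_reactions):
            for sid, nu in r.reactants.items():
                if sid not in network.fixed_species:
                    self._E[i, self._s_idx[sid]] += nu
            for sid, nu in r.net_stoichiometry().items():
                if sid not in network.fixed_species:
                    self._N[i, self._s_idx[sid]] = nu

        self.emission_reactions = [r for r in self.bulk_reactions
                                   if r.emission_wavelength_nm is not None]
        self._em_idx = [self.bulk_reactions.index(r)
                        for r in self.emission_reactions]
        self.n_em = len(self.emission_reactions)
        self._visible = np.array([c in visible for c in self.compartments])

        # superoxide acid-base pair held at equilibrium partition
        self._f_ho2 = network.superoxide_acid_fraction()
        self._i_ho2 = self._s_idx.get("HO2.")
        self._i_o2m = self._s_idx.get("O2.-")

        # diffusive exchange layer<->bulk (zero in single-box mode)
        self._kex = np.zeros(self.n_s)
        if exchange is not None and self.n_c == 3:
            for sid, kex in exchange.items():
                if sid in self._s_idx:
                    self._kex[self._s_idx[sid]] = kex

        self.channels = list(channels) if channels else []
        self.current_amplitude = current_amplitude
        self.migration = migration or {}
        # precompiled channel data: (electrode, net stoich indices/coeffs,
        # weight spec) for the fast source-term path
        self._chan: list[tuple] = []
        for ch in self.channels:
            net: dict[int, float] = {}
            for sid, nu in ch.products.items():
                if sid not in network.fixed_species:
                    net[self._s_idx[sid]] = net.get(self._s_idx[sid], 0.0) + nu
            for sid, nu in ch.reactants.items():
                if sid not in network.fixed_species:
                    net[self._s_idx[sid]] = net.get(self._s_idx[sid], 0.0) - nu
            w_idx = (self._s_idx[ch.weight_species]
                     if ch.weight_species is not None else -1)
            self._chan.append((
                ch.electrode,
                np.fromiter(net.keys(), dtype=int),
                np.fromiter(net.values(), dtype=float),
                w_idx, ch.weight, ch.weight_scale, ch.electrons))
        self._i_bulk = (self.compartments.index("bulk")
                        if "bulk" in self.compartments else 0)
        self._i_anode = (self.compartments.index("anode")
                         if "anode" in self.compartments else 0)
        self._i_cathode = (self.compartments.index("cathode")
                           if "cathode" in self.compartments else None)

        # state layout: concentrations | emission counters | charge | Gamma_mig
        self.n_states = self.n_c * self.n_s + self.n_em + 2
        self._q_idx = self.n_c * self.n_s + self.n_em
        self._mig_idx = self._q_idx + 1

        # constant pieces of the analytic Jacobian
        self._P = self._partition_matrix()
        self._NT = self._N.T.copy()
        n_cs = self.n_c * self.n_s
        j_exch = np.zeros((n_cs, n_cs))
        if self.n_c == 3 and self._kex.any():
            kp = np.diag(self._kex) @ self._P
            ib = self._i_bulk
            slb = slice(ib * self.n_s, (ib + 1) * self.n_s)
            for il in (self._i_anode, self._i_cathode):
                sll = slice(il * self.n_s, (il + 1) * self.n_s)
                w = self.volumes_l[il] / self.volumes_l[ib]
                j_exch[sll, slb] += kp
                j_exch[sll, sll] -= kp
                j_exch[slb, sll] += w * kp
                j_exch[slb, slb] -= w * kp
            # exchange feeds through the final equilibrium redistribution
            big_p = np.eye(n_cs)
            for ic in range(self.n_c):
                sl = slice(ic * self.n_s, (ic + 1) * self.n_s)
                big_p[sl, sl] = self._P
            j_exch = big_p @ j_exch
        self._j_exch = j_exch

    # -- state helpers -------------------------------------------------------

    def initial_state(self, concentrations: Mapping[str, float]) -> np.ndarray:
        """Uniform initial concentrations (M) in every compartment; the
        superoxide pair is partitioned to its acid-base equilibrium."""
        y = np.zeros(self.n_states)
        conc = np.zeros(self.n_s)
        for sid, c in concentrations.items():
            if c < 0:
                raise StateError(f"negative initial concentration for {sid}")
            if sid in self._s_idx:
                conc[self._s_idx[sid]] = c
        # fixed species at their buffered values
        conc[self._s_idx["H2O"]] = 55.34
        conc[self._s_idx["H+"]] = 10.0 ** (-self.network.ph)
        conc[self._s_idx["OH-"]] = 10.0 ** (-(14.0 - self.network.ph))
        if self._i_ho2 is not None and self._i_o2m is not None:
            pool = conc[self._i_ho2] + conc[self._i_o2m]
            conc[self._i_ho2] = self._f_ho2 * pool
            conc[self._i_o2m] = (1.0 - self._f_ho2) * pool
        for i in range(self.n_c):
            y[i * self.n_s:(i + 1) * self.n_s] = conc
        return y

    def _partition(self, conc: np.ndarray) -> np.ndarray:
        if self._i_ho2 is None or self._i_o2m is None:
            return conc
        pool = conc[:, self._i_ho2] + conc[:, self._i_o2m]
        conc = conc.copy()
        conc[:, self._i_ho2] = self._f_ho2 * pool
        conc[:, self._i_o2m] = (1.0 - self._f_ho2) * pool
        return conc

    def reaction_rates(self, conc: np.ndarray) -> np.ndarray:
        """Mass-action rates (M/s), shape (n_c, n_r); conc shape (n_c, n_s)."""
        c = np.clip(conc, 0.0, None)
        return self._k * np.prod(c[:, None, :] ** self._E[None, :, :], axis=2)

    # -- right-hand side -----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, sources_on: bool = False
            ) -> np.ndarray:
        conc = y[: self.n_c * self.n_s].reshape(self.n_c, self.n_s)
        conc = self._partition(conc)
        rates = self.reaction_rates(conc)
        dconc = rates @ self._N

        # layer <-> bulk diffusive exchange, volume-weighted for the bulk
        if self.n_c == 3 and self._kex.any():
            ib = self._i_bulk
            for il in (self._i_anode, self._i_cathode):
                flux = self._kex * (conc[ib] - conc[il])
                dconc[il] += flux
                dconc[ib] -= flux * (self.volumes_l[il] / self.volumes_l[ib])

        dy = np.zeros_like(y)
        charge_rate = 0.0
        if sources_on and self.current_amplitude > 0.0:
            charge_rate = self.current_amplitude
            self._apply_sources(conc, dconc)
        if sources_on and self.migration:
            self._apply_migration(conc, dconc, y, dy)

        # keep the HO2./O2.- pool at its acid-base equilibrium: redistribute
        # the pair's combined derivative (kinetics + exchange + sources) with
        # the fixed-pH partition so the states never leave the equilibrium ray
        if self._i_ho2 is not None and self._i_o2m is not None:
            pool = dconc[:, self._i_ho2] + dconc[:, self._i_o2m]
            dconc[:, self._i_ho2] = self._f_ho2 * pool
            dconc[:, self._i_o2m] = (1.0 - self._f_ho2) * pool

        dy[: self.n_c * self.n_s] = dconc.ravel()
        # emission event counters over photon-visible compartments (mol/s)
        vis_vol = self.volumes_l * self._visible
        for k, ir in enumerate(self._em_idx):
            dy[self.n_c * self.n_s + k] = float(rates[:, ir] @ vis_vol)
        dy[self._q_idx] = charge_rate
        return dy

    def _apply_sources(self, conc: np.ndarray, dconc: np.ndarray) -> None:
        i_e = self.current_amplitude / FARADAY
        for electrode, i_comp in (("anode", self._i_anode),
                                  ("cathode", self._i_cathode)):
            if i_comp is None:
                continue
            local = conc[i_comp]
            weights = [
                (w_const if w_idx < 0 else w_scale * max(local[w_idx], 0.0))
                for (elec, _, _, w_idx, w_const, w_scale, _) in self._chan
                if elec == electrode]
            total = sum(weights)
            if total <= 0.0:
                raise ChannelConfigError(
                    f"all {electrode} channel weights zero while current "
                    "flows")
            vol = self.volumes_l[i_comp]
            k = 0
            for (elec, idx, nu, _, _, _, z) in self._chan:
                if elec != electrode:
                    continue
                n_dot = i_e * (weights[k] / total) / z
                k += 1
                if n_dot:
                    dconc[i_comp, idx] += nu * (n_dot / vol)

    def _apply_migration(self, conc: np.ndarray, dconc: np.ndarray,
                         y: np.ndarray, dy: np.ndarray) -> None:
        m = self.migration
        if y[self._mig_idx] >= m["cap"]:
            return
        j = self._s_idx["BSA"]
        flux = m["mobility"] * m["field"] * max(conc[self._i_bulk, j], 0.0) * 1e3
        mol_per_s = flux * m["area"]
        dconc[self._i_anode, j] += mol_per_s / self.volumes_l[self._i_anode]
        dconc[self._i_bulk, j] -= mol_per_s / self.volumes_l[self._i_bulk]
        dy[self._mig_idx] = flux

    def _partition_matrix(self) -> np.ndarray:
        """Linear map applying the superoxide equilibrium partition to one
        compartment's species vector (also redistributes derivative pairs)."""
        p = np.eye(self.n_s)
        if self._i_ho2 is not None and self._i_o2m is not None:
            i1, i2, f = self._i_ho2, self._i_o2m, self._f_ho2
            p[i1, i1] = f
            p[i1, i2] = f
            p[i2, i1] = 1.0 - f
            p[i2, i2] = 1.0 - f
        return p

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the source-free RHS (kinetics + exchange).

        Used for the long inter-pulse and pre/post segments; pulse segments
        fall back to finite differences because the electrode-channel
        competition weights are only piecewise smooth.
        """
        n_cs = self.n_c * self.n_s
        jac = np.zeros((self.n_states, self.n_states))
        p = self._P
        conc = y[:n_cs].reshape(self.n_c, self.n_s)
        conc_eff = self._partition(conc)
        c_safe = np.maximum(conc_eff, 1.0e-20)
        rates_safe = self._k * np.prod(c_safe[:, None, :] ** self._E[None],
                                       axis=2)
        vis_vol = self.volumes_l * self._visible
        for ic in range(self.n_c):
            dr = self._E * (rates_safe[ic][:, None] / c_safe[ic][None, :])
            sl = slice(ic * self.n_s, (ic + 1) * self.n_s)
            # redistribution P acts on rows, partition P on columns
            jac[sl, sl] = p @ ((self._NT @ dr) @ p)
            for k, ir in enumerate(self._em_idx):
                jac[n_cs + k, sl] = vis_vol[ic] * (dr[ir] @ p)
        jac[:n_cs, :n_cs] += self._j_exch
        return jac

    def emission_flux_at(self, conc: np.ndarray) -> np.ndarray:
        """Instantaneous visible emission event flux (mol/s) per emission
        reaction for one saved state of shape (n_c, n_s)."""
        rates = self.reaction_rates(self._partition(conc))
        vis_vol = self.volumes_l * self._visible
        return rates[:, self._em_idx].T @ vis_vol


def assemble_rhs(network: ReactionNetwork, **engine_kwargs):
    """Return ``f(t, y, sources_on=False)`` for the given network.

    Thin wrapper over :class:`KineticsEngine`; see the engine for the state
    layout and source-term semantics.
    """
    engine = KineticsEngine(network, **engine_kwargs)
    return engine.rhs, engine


def _atol_vector(engine: KineticsEngine, conc_atol: float) -> np.ndarray:
    atol = np.full(engine.n_states, conc_atol)
    atol[engine.n_c * engine.n_s:] = 1.0e-18   # counters: mol, C, mol m^-2
    atol[engine._q_idx] = 1.0e-9
    return atol


def _run_segment(engine, t0, t1, y0, sources_on, t_eval, solver, max_step):
    fun = lambda t, y: engine.rhs(t, y, sources_on)
    solver = dict(solver)
    if sources_on:
        method = solver.pop("method_on", "LSODA")
        solver.pop("method_off", None)
        jac = None
    else:
        method = solver.pop("method_off", "BDF")
        solver.pop("method_on", None)
        jac = engine.jac
    method = solver.pop("method", method)
    sol = solve_ivp(fun, (t0, t1), y0, t_eval=t_eval, method=method,
                    max_step=max_step, jac=jac, **solver)
    if not sol.success:
        t_arr = np.asarray(sol.t)
        t_last = float(t_arr[-1]) if t_arr.size else t0
        y_last = np.asarray(sol.y)[:, -1] if t_arr.size else y0
        raise IntegrationError(
            f"integrator failed in [{t0}, {t1}]: {sol.message}", t_last, y_last)
    return sol


def simulate(network: ReactionNetwork, scenario: Scenario,
             solver_options: Mapping | None = None) -> Trajectory:
    """Run one scenario and return its :class:`Trajectory`.

    The time axis is integrated piecewise between pulse edges so the
    rectangular source terms are exact; during pulses the maximum step is
    pulse_width/10.
    """
    geom = scenario.geometry
    prot = scenario.protocol
    delta = geom.electrode_layer_thickness
    area = geom.cross_section_area

    if scenario.single_box:
        compartments = ["bulk"]
        volumes_l = [geom.volume * 1e3]
        exchange = None
        visible = ("bulk",)
    else:
        compartments = ["anode", "bulk", "cathode"]
        v_layer = area * delta * 1e3
        volumes_l = [v_layer, (geom.volume - 2 * area * delta) * 1e3, v_layer]
        diffusion = load_diffusion_table()
        default_d = diffusion.get("__default__", 1e-9)
        exchange = {
            sid: diffusion.get(sid, default_d) / (delta * scenario.boundary_layer)
            for sid in network.species
        }
        visible = ("anode", "bulk")

    profile = build_current_profile(
        prot, scenario.sample, geom, mode=scenario.current_mode,
        constant_current=scenario.constant_current,
        start_time=scenario.pulse_start)
    channels = default_channels(network, **scenario.channel_options)

    e_field = field_strength(prot, geom)
    migration = None
    if not scenario.single_box and scenario.composition.bsa > 0:
        migration = {
            "mobility": scenario.sample.bsa_mobility,
            "field": e_field,
            "area": area,
            "cap": scenario.composition.bsa * 1e3 * geom.electrode_gap,
        }

    engine = KineticsEngine(
        network, compartments=compartments, volumes_l=volumes_l,
        exchange=exchange, channels=channels,
        current_amplitude=profile.amplitude, migration=migration,
        visible=visible)

    y0 = engine.initial_state(scenario.composition.initial_concentrations())

    solver = dict(DEFAULT_SOLVER)
    if solver_options:
        solver.update(solver_options)
    conc_atol = solver.pop("atol")
    solver["atol"] = _atol_vector(engine, conc_atol)

    # piecewise segments: (t0, t1, sources_on)
    segments: list[tuple[float, float, bool]] = []
    t_end = scenario.t_end
    edges = profile.pulse_edges() if prot.n_pulses else []
    cursor = 0.0
    for t_on, t_off in edges:
        if t_on >= t_end:
            break
        if t_on > cursor:
            segments.append((cursor, t_on, False))
        segments.append((t_on, min(t_off, t_end), True))
        cursor = min(t_off, t_end)
    if cursor < t_end:
        segments.append((cursor, t_end, False))

    dt_save = 0.5
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    y = y0.copy()
    running_max = np.abs(y)
    for (t0, t1, on) in segments:
        if on:
            t_eval = np.array([t0, 0.5 * (t0 + t1), t1])
            max_step = prot.pulse_width / 10.0
        else:
            interior = np.arange(np.ceil(t0 / dt_save) * dt_save, t1, dt_save)
            t_eval = np.unique(np.concatenate(([t0], interior, [t1])))
            max_step = np.inf
        sol = _run_segment(engine, t0, t1, y, on, t_eval, dict(solver),
                           max_step)
        y = sol.y[:, -1].copy()
        running_max = np.maximum(running_max, np.abs(sol.y).max(axis=1))
        # negativity guard: absolute floor, or half the state's own historical
        # peak (stiffly-decaying radicals can undershoot by a sizeable
        # fraction of their tiny scale; true divergence still trips this)
        bound = np.maximum(NEGATIVE_CLIP, 0.5 * running_max)
        if np.any(y < -bound):
            j = int(np.argmin(y + bound))
            raise IntegrationError(
                f"state {j} went negative ({y[j]:.3e}) at t={t1}", t1, y)
        y = np.clip(y, 0.0, None)
        start = 1 if times else 0  # drop duplicated segment boundary
        times.append(sol.t[start:])
        states.append(sol.y[:, start:])

    t = np.concatenate(times)
    ys = np.concatenate(states, axis=1)
    n_cs = engine.n_c * engine.n_s
    conc = np.clip(ys[:n_cs].T.reshape(len(t), engine.n_c, engine.n_s),
                   0.0, None)
    cum_em = np.maximum.accumulate(
        np.clip(ys[n_cs:n_cs + engine.n_em].T, 0.0, None), axis=0)
    flux = np.array([engine.emission_flux_at(conc[i]) for i in range(len(t))])

    return Trajectory(
        time=t,
        concentrations=conc,
        species=engine.species,
        compartments=engine.compartments,
        emission_reaction_ids=[r.id for r in engine.emission_reactions],
        emission_wavelengths_nm=[r.emission_wavelength_nm
                                 for r in engine.emission_reactions],
        emission_flux=flux,
        cumulative_emission=cum_em,
        charge=ys[engine._q_idx],
        label=scenario.label,
        meta={
            "volumes_l": list(engine.volumes_l),
            "current_A": profile.amplitude,
            "total_charge_C": profile.total_charge,
            "pulse_start_s": scenario.pulse_start,
            "boundary_layer_m": scenario.boundary_layer,
            "layer_thickness_m": delta,
            "channel_options": dict(scenario.channel_options),
            "migration_cap_mol_m2": migration["cap"] if migration else 0.0,
            "delivered_mol_m2": float(y[engine._mig_idx]),
        },
    )


def integrate_network(network: ReactionNetwork,
                      initial: Mapping[str, float],
                      t_eval: np.ndarray,
                      rtol: float = 1.0e-6,
                      atol: float = 1.0e-15,
                      method: str = "BDF") -> dict[str, np.ndarray]:
    """Integrate a (sub)network in a single well-mixed box with no sources.

    Convenience API for closed-form and cross-integrator checks; returns
    ``{"t": t, "<species>": c(t), ...}`` in M.
    """
    engine = KineticsEngine(network, compartments=["bulk"], volumes_l=[1.0],
                            visible=("bulk",))
    y0 = engine.initial_state(initial)
    sol = solve_ivp(lambda t, y: engine.rhs(t, y, False),
                    (float(t_eval[0]), float(t_eval[-1])), y0,
                    t_eval=t_eval, method=method, rtol=rtol,
                    atol=_atol_vector(engine, atol))
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else 0.0,
                               sol.y[:, -1] if sol.t.size else y0)
    out = {"t": sol.t}
    for sid, j in engine._s_idx.items():
        out[sid] = sol.y[j, :]
    return out
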