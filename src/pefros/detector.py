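"""Band-resolved photon rates and photomultiplier count expectations.

The photomultiplier views the chamber through the perforated cathode and
covers 300-650 nm. Singlet-oxygen dimol emission falls at 634 nm (the 550-650
band, mean quantum efficiency 0.55 %), triplet-carbonyl emission at 350-500 nm
(the 300-550 band, mean QE 12.2 %); the 1278 nm monomolecular singlet-oxygen
line is outside the photocathode response (QE 0) and never contributes to
counts. Absolute photon yields per reaction event (phi) are not known for this
system: the defaults below are order-of-magnitude placeholders, so only
relative and ordering statements about simulated counts are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .constants import AVOGADRO
from .simulate import Trajectory


class BandError(ValueError):
    """Unknown band, overlapping bands, or non-invertible (QE 0) band."""


@dataclass(frozen=True)
class DetectorModel:
    """Photon-counting detector: bands, efficiencies, dark rate."""

    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"uv_vis": (300.0, 550.0),
                                 "red": (550.0, 650.0)})
    quantum_efficiency: Mapping[str, float] = field(
        default_factory=lambda: {"uv_vis": 0.122, "red": 0.0055})
    collection_efficiency: float = 0.01
    dark_rate: float = 21.0  # counts s^-1
    bin_width: float = 1.0   # s

    def __post_init__(self) -> None:
        if self.dark_rate < 0:
            raise ValueError("dark rate must be >= 0")
        for label, qe in self.quantum_efficiency.items():
            if not (0.0 <= qe <= 1.0):
                raise ValueError(f"QE for band {label!r} outside [0, 1]")
        intervals = sorted(self.bands.values())
        for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
            if hi1 > lo2:
                raise BandError("bands overlap")

    def band_of(self, wavelength_nm: float) -> str | None:
        for label, (lo, hi) in self.bands.items():
            if lo <= wavelength_nm < hi:
                return label
        return None


@dataclass(frozen=True)
class EmissionAssignment:
    """reaction id -> (wavelength nm, photons per reaction event phi)."""

    assignments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "8": (1278.0, 1.0),   # 1O2 monomolecular; IR, undetectable
            "9": (634.0, 1.0),    # 1O2 dimol
            "18": (425.0, 0.01),  # triplet carbonyl
        })

    def __post_init__(self) -> None:
        for rid, (_, phi) in self.assignments.items():
            if not (0.0 <= phi <= 1.0):
                raise ValueError(f"phi for reaction {rid} outside [0, 1]")


def default_detector() -> DetectorModel:
    return DetectorModel()


def default_assignment() -> EmissionAssignment:
    return EmissionAssignment()


def photon_rates(emission_flux: Mapping[str, float],
                 assignment: EmissionAssignment,
                 detector: DetectorModel | None = None
                 ) -> dict[str, float]:
    """Per-band photon emission rates (photons s^-1).

    ``emission_flux`` maps emission-reaction id -> event flux (mol s^-1)
    summed over photon-visible compartments. Photons outside every detector
    band are dropped (keyed ``None`` rates are not returned).
    """
    detector = detector or default_detector()
    rates = {label: 0.0 for label in detector.bands}
    for rid, flux in emission_flux.items():
        if rid not in assignment.assignments:
            raise KeyError(f"no emission assignment for reaction {rid!r}")
        wavelength, phi = assignment.assignments[rid]
        band = detector.band_of(wavelength)
        if band is None:
            continue
        rates[band] += AVOGADRO * phi * flux
    return rates


def expected_counts(band_rates: Mapping[str, float],
                    detector: DetectorModel | None = None) -> float:
    """Expected counts per bin: bin * (dark + collection * sum QE_b * rate_b)."""
    detector = detector or default_detector()
    signal = 0.0
    for label, rate in band_rates.items():
        if rate < 0:
            raise ValueError("photon rates must be >= 0")
        signal += detector.quantum_efficiency[label] * rate
    return detector.bin_width * (detector.dark_rate
                                 + detector.collection_efficiency * signal)


def qe_correct(counts_per_bin: float, band: str,
               detector: DetectorModel | None = None) -> float:
    """Invert :func:`expected_counts` for one band: counts -> photons s^-1.

    Dark counts are subtracted first; a zero-QE band is not invertible.
    """
    detector = detector or default_detector()
    qe = detector.quantum_efficiency[band]
    if qe <= 0.0:
        raise BandError(f"band {band!r} has zero quantum efficiency")
    net = counts_per_bin / detector.bin_width - detector.dark_rate
    return net / (detector.collection_efficiency * qe)


def trajectory_band_rates(trajectory: Trajectory,
                          assignment: EmissionAssignment | None = None,
                          detector: DetectorModel | None = None
                          ) -> dict[str, np.ndarray]:
    """Time series of per-band photon rates (photons s^-1) for a trajectory."""
    assignment = assignment or default_assignment()
    detector = detector or default_detector()
    out = {label: np.zeros(len(trajectory.time)) for label in detector.bands}
    for k, rid in enumerate(trajectory.emission_reaction_ids):
        wavelength, phi = assignment.assignments[rid]
        band = detector.band_of(wavelength)
        if band is None:
            continue
        out[band] += AVOGADRO * phi * trajectory.emission_flux[:, k]
    return out


def expected_counts_transient(trajectory: Trajectory,
                              detector: DetectorModel | None = None,
                              assignment: EmissionAssignment | None = None,
                              t_start: float = 0.0,
                              t_end: float | None = None):
    """Expected counts per time bin from a trajectory's cumulative emission.

    Uses the integrated emission-event counters, so each bin receives exactly
    the photons emitted during it. Returns a
    :class:`pefros.transients.LuminescenceTransient` with real-valued counts.
    """
    from .transients import LuminescenceTransient  # local: avoid cycle

    detector = detector or default_detector()
    assignment = assignment or default_assignment()
    if t_end is None:
        t_end = float(trajectory.time[-1])
    edges = np.arange(t_start, t_end + 0.5 * detector.bin_width,
                      detector.bin_width)
    events = trajectory.binned_emission_events(edges)  # mol per bin
    counts = np.full(len(edges) - 1, detector.dark_rate * detector.bin_width)
    for k, rid in enumerate(trajectory.emission_reaction_ids):
        wavelength, phi = assignment.assignments[rid]
        band = detector.band_of(wavelength)
        if band is None:
            continue
        qe = detector.quantum_efficiency[band]
        counts += (AVOGADRO * phi * events[:, k]
                   * detector.collection_efficiency * qe)
    return LuminescenceTransient(
        time=edges[:-1], counts=counts, band="300-650",
        scenario=trajectory.label, replicate=0, expected=True)
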