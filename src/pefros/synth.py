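"""Synthetic photon-count transients and assay absorbances.

Emulates the structure of the chemiluminescence experiment so the whole
analysis pipeline is testable without any measured data: 1 s photon-count
bins over 0-500 s (the informative 0-150 s subset by default), a 60 s
pre-pulsing baseline, a 30 s pulsing period, a post-pulsing relaxation, a
dark-count floor of 21 counts/s, Poisson counting noise, and replicates.

Two expected-curve sources are supported: fast parametric templates per
scenario (no ODE solve) and full simulator trajectories. Template parameters
encode only the qualitative shapes the conditions produce: buffer-only runs
are flat during pulsing, albumin runs rise as protein accumulates at the
anode, prooxidant-containing albumin runs add an elevated, slowly decaying
pre-pulse level and a large residual after pulsing. It does not emulate
instrument drift or cosmic-ray spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .scenario import KNOWN_LABELS
from .transients import (
    AssayMeasurement,
    ELLMAN_EXTINCTION,
    ELLMAN_PATH_CM,
    BRADY_EXTINCTION_MM,
    BRADY_PATH_CM,
    LuminescenceTransient,
)

PULSE_START = 60.0
PULSE_END = 90.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic transient set."""

    scenario: str = "bsa_h2o2"
    h2o2: float = 1.0e-3          # M
    cat: bool = False
    sod: bool = False
    dark_rate: float = 21.0       # counts s^-1
    n_replicates: int = 3
    seed: int = 0
    t_end: float = 150.0
    bin_width: float = 1.0
    band: str = "300-650"
    expected_curve: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need n_replicates >= 1")
        if self.dark_rate < 0:
            raise ValueError("dark rate must be >= 0")


def _saturation(c: float, k: float) -> float:
    return c / (c + k) if c > 0 else 0.0


def parametric_template(scenario: str, h2o2: float = 1.0e-3,
                        cat: bool = False, sod: bool = False
                        ) -> Callable[[np.ndarray], np.ndarray]:
    """Expected chemiluminescence rate (counts/s above dark) vs time.

    Piecewise per period: a constant-or-decaying pre segment, a flat
    (buffer-like) or saturating-rise (albumin-like) pulsing segment, and an
    exponential post-pulse relaxation back to the pre-pulse baseline.
    """
    if scenario not in KNOWN_LABELS:
        raise ValueError(f"unknown scenario label {scenario!r}")
    with_bsa = scenario.startswith("bsa")
    with_h2o2 = scenario.endswith("h2o2")
    c = h2o2 if with_h2o2 else 0.0

    # prooxidant-dependent amplitudes; CAT removes most of the H2O2 pool,
    # SOD intercepts superoxide feeding the pulsing/post-pulse signal
    h2o2_factor = 0.35 if cat else 1.0
    if with_bsa:
        pre_amp = 40.0 * _saturation(c, 1.0e-3) * h2o2_factor
        pre_tau = 200.0
        rise_amp = (25.0 + 160.0 * _saturation(c, 1.0e-3) * h2o2_factor)
        rise_tau = 15.0
        post_tau = 25.0
    else:
        pre_amp = 5.0 * _saturation(c, 20.0e-3) * h2o2_factor
        pre_tau = np.inf
        rise_amp = 2.0 + 20.0 * _saturation(c, 2.0e-3) * h2o2_factor
        rise_tau = 0.0  # flat: amplitude reached instantly
        post_tau = 5.0
    if sod:
        rise_amp *= 0.75
        post_residual_factor = 0.65
        pre_factor = 0.97
    else:
        post_residual_factor = 1.0
        pre_factor = 1.0

    def pre_level(t: np.ndarray) -> np.ndarray:
        return pre_factor * pre_amp * np.exp(-t / pre_tau)

    def rise(dt: np.ndarray) -> np.ndarray:
        if rise_tau == 0.0:
            return np.full_like(dt, rise_amp)
        return rise_amp * (1.0 - np.exp(-dt / rise_tau))

    def rate(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = pre_level(t)
        pulsing = (t >= PULSE_START) & (t < PULSE_END)
        out = np.where(pulsing, pre_level(t) + rise(t - PULSE_START), out)
        post = t >= PULSE_END
        residual = (rise(np.array([PULSE_END - PULSE_START]))[0]
                    * post_residual_factor)
        out = np.where(
            post,
            pre_level(t) + residual * np.exp(-(t - PULSE_END) / post_tau),
            out)
        return out

    return rate


def generate_transient(spec: SyntheticSpec) -> list[LuminescenceTransient]:
    """Poisson-sampled replicate transients for one synthetic condition.

    counts[t] ~ Poisson(bin * (dark + expected(t))); one seeded generator
    stream drives all replicates, so a fixed seed reproduces byte-identical
    output.
    """
    expected = spec.expected_curve or parametric_template(
        spec.scenario, spec.h2o2, spec.cat, spec.sod)
    rng = np.random.default_rng(spec.seed)
    edges = np.arange(0.0, spec.t_end + 0.5 * spec.bin_width, spec.bin_width)
    starts = edges[:-1]
    centers = starts + 0.5 * spec.bin_width
    mu = spec.bin_width * (spec.dark_rate
                           + np.clip(expected(centers), 0.0, None))
    label = (spec.scenario + ("_cat" if spec.cat else "")
             + ("_sod" if spec.sod else ""))
    out = []
    for rep in range(spec.n_replicates):
        counts = rng.poisson(mu).astype(float)
        out.append(LuminescenceTransient(
            time=starts.copy(), counts=counts, band=spec.band,
            scenario=label, replicate=rep))
    return out


def generate_assay_data(true_concentration: float, noise_sd: float,
                        seed: int, assay: str = "ellman",
                        n_replicates: int = 3,
                        dilution: float = 1.0) -> list[AssayMeasurement]:
    """Forward Beer-Lambert absorbances with Gaussian noise.

    ``true_concentration`` in the assay's units (M for Ellman, mM for Brady);
    the assay calculators recover it to within the noise.
    """
    if true_concentration < 0:
        raise ValueError("concentration must be >= 0")
    if assay == "ellman":
        eps, path = ELLMAN_EXTINCTION, ELLMAN_PATH_CM
    elif assay == "brady":
        eps, path = BRADY_EXTINCTION_MM, BRADY_PATH_CM
    else:
        raise ValueError(f"unknown assay {assay!r}")
    rng = np.random.default_rng(seed)
    a_true = eps * path * true_concentration / dilution
    out = []
    for _ in range(n_replicates):
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        out.append(AssayMeasurement(absorbance=a_true + noise,
                                    blank_absorbance=0.0, dilution=dilution))
    return out
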