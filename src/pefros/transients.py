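"""Quantification of luminescence transients and Beer-Lambert assay readouts.

The experiment records photon counts in 1 s bins over three periods:
pre-pulsing (background), pulsing, and post-pulsing (remanent signal). Each
period's signal is summarised by integrating the counts over a common time
basis (30 s), which is what all cross-condition comparisons use. Window
integrals are taken on raw counts (no dark subtraction), matching how
baseline-level transients are compared; dark subtraction happens only in the
quantum-efficiency correction of the detector module.

The module also implements the two Beer-Lambert assay calculators: free
sulfhydryl groups via Ellman's reagent (TNB, epsilon = 14150 M^-1 cm^-1 at
412 nm) and protein carbonyls via Brady's reagent (hydrazone adduct,
epsilon = 22 mM^-1 cm^-1 at 375 nm, 0.2893 cm path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ELLMAN_EXTINCTION = 14150.0   # M^-1 cm^-1
ELLMAN_PATH_CM = 1.0
BRADY_EXTINCTION_MM = 22.0    # mM^-1 cm^-1
BRADY_PATH_CM = 0.2893


class AlignmentError(ValueError):
    """Transients do not share a common time grid."""


class WindowRangeError(ValueError):
    """Integration interval lies outside the transient support."""


@dataclass
class LuminescenceTransient:
    """Binned photon counts vs time.

    ``time`` holds uniform bin start times (s); ``counts`` are per-bin counts,
    integers for measured/synthetic data or reals for expected curves
    (``expected=True``).
    """

    time: np.ndarray
    counts: np.ndarray
    band: str = "300-650"
    scenario: str = ""
    replicate: int = 0
    expected: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.counts.shape:
            raise ValueError("time and counts must be equal-length 1-D arrays")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("bin width must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def bin_width(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 1.0

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# band={self.band}\n")
            fh.write(f"# scenario={self.scenario}\n")
            fh.write(f"# replicate={self.replicate}\n")
            fh.write("time_s\tcounts\n")
            for t, c in zip(self.time, self.counts):
                fh.write(f"{t:g}\t{c:g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LuminescenceTransient":
        meta = {"band": "300-650", "scenario": "", "replicate": 0}
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, _, value = line.lstrip("# ").partition("=")
                    if key in meta:
                        meta[key] = value
                    continue
                if not line or line.startswith("time"):
                    continue
                t, c = line.split("\t")
                rows.append((float(t), float(c)))
        data = np.array(rows)
        return cls(time=data[:, 0], counts=data[:, 1], band=meta["band"],
                   scenario=meta["scenario"], replicate=int(meta["replicate"]))


@dataclass(frozen=True)
class WindowScheme:
    """Pre/pulsing/post intervals and the common integration basis (s).

    Defaults place symmetric 30 s windows around the 60-90 s pulsing block.
    """

    pre: tuple[float, float] = (30.0, 60.0)
    pulsing: tuple[float, float] = (60.0, 90.0)
    post: tuple[float, float] = (90.0, 120.0)
    basis: float = 30.0

    def __post_init__(self) -> None:
        intervals = [self.pre, self.pulsing, self.post]
        for (a, b) in intervals:
            if b <= a:
                raise ValueError("window intervals must have positive length")
        for (_, b1), (a2, _) in zip(intervals, intervals[1:]):
            if b1 > a2:
                raise ValueError("windows must be disjoint and ordered")
        if any(self.basis > b - a for (a, b) in intervals):
            raise ValueError("basis exceeds a window length")

    def items(self):
        return (("pre", self.pre), ("pulsing", self.pulsing),
                ("post", self.post))


def integrate_window(transient: LuminescenceTransient,
                     interval: tuple[float, float],
                     basis: float | None = None,
                     method: str = "sum") -> float:
    """Integrated counts over the first ``basis`` seconds of ``interval``.

    ``method="sum"`` adds bin counts (counting data); ``method="trapezoid"``
    treats counts as rate samples at bin starts and integrates (for
    real-valued expected curves).
    """
    a, b = interval
    basis = (b - a) if basis is None else basis
    if basis > b - a:
        raise ValueError("basis exceeds the interval length")
    end = a + basis
    t, dt = transient.time, transient.bin_width
    if a < t[0] - 1e-9 or end > t[-1] + dt + 1e-9:
        raise WindowRangeError(
            f"interval [{a}, {end}) outside data support "
            f"[{t[0]}, {t[-1] + dt})")
    mask = (t >= a - 1e-9) & (t < end - 1e-9)
    if method == "sum":
        return float(transient.counts[mask].sum())
    if method == "trapezoid":
        return float(np.trapezoid(transient.counts[mask] / dt, t[mask]))
    raise ValueError(f"unknown method {method!r}")


def window_integrals(transient: LuminescenceTransient,
                     scheme: WindowScheme | None = None,
                     method: str = "sum") -> dict[str, float]:
    """Pre/pulsing/post window integrals on the scheme's common basis."""
    scheme = scheme or WindowScheme()
    return {name: integrate_window(transient, interval, scheme.basis, method)
            for name, interval in scheme.items()}


def average_replicates(transients: Sequence[LuminescenceTransient]
                       ) -> tuple[LuminescenceTransient, np.ndarray]:
    """Element-wise mean transient and per-bin sample (n-1) SD.

    A single replicate yields SD 0 and a warning.
    """
    if not transients:
        raise ValueError("need at least one replicate")
    t0 = transients[0].time
    for tr in transients[1:]:
        if tr.time.shape != t0.shape or not np.allclose(tr.time, t0):
            raise AlignmentError("replicates are not on a common time grid")
    stack = np.vstack([tr.counts for tr in transients])
    mean = stack.mean(axis=0)
    if len(transients) == 1:
        warnings.warn("single replicate: standard deviation reported as 0",
                      stacklevel=2)
        sd = np.zeros_like(mean)
    else:
        sd = stack.std(axis=0, ddof=1)
    out = LuminescenceTransient(
        time=t0.copy(), counts=mean, band=transients[0].band,
        scenario=transients[0].scenario, replicate=-1, expected=True)
    return out, sd


def difference_transient(a: LuminescenceTransient,
                         b: LuminescenceTransient) -> np.ndarray:
    """Per-bin difference a - b (e.g. signal without vs with SOD)."""
    if a.time.shape != b.time.shape or not np.allclose(a.time, b.time):
        raise AlignmentError("transients are not on a common time grid")
    return a.counts - b.counts


def dose_response(concentrations: Sequence[float],
                  integrals: Sequence[float],
                  linearity_tol: float = 0.10) -> pd.DataFrame:
    """Order window integrals by prooxidant concentration.

    Returns a DataFrame sorted by concentration with attrs ``monotone``
    (strictly increasing integrals) and ``nonlinear`` (the integral is not
    proportional to concentration within ``linearity_tol`` relative spread of
    the integral/concentration ratio).
    """
    conc = np.asarray(concentrations, dtype=float)
    integ = np.asarray(integrals, dtype=float)
    if len(conc) < 2:
        raise ValueError("need at least two concentrations")
    if len(np.unique(conc)) != len(conc):
        raise ValueError("duplicate concentrations")
    order = np.argsort(conc)
    conc, integ = conc[order], integ[order]
    table = pd.DataFrame({"concentration": conc, "integral": integ})
    table.attrs["monotone"] = bool(np.all(np.diff(integ) > 0))
    with np.errstate(divide="ignore"):
        ratios = integ / conc
    spread = (ratios.max() - ratios.min()) / ratios.mean()
    table.attrs["nonlinear"] = bool(spread > linearity_tol)
    return table


@dataclass(frozen=True)
class AssayMeasurement:
    """One spectrophotometric reading for a Beer-Lambert calculator."""

    absorbance: float
    blank_absorbance: float = 0.0
    extinction: float = 0.0    # in the calculator's units; 0 -> default
    path_cm: float = 0.0       # 0 -> calculator default
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.extinction < 0 or self.path_cm < 0:
            raise ValueError("extinction and path length must be >= 0")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


def _beer_lambert(m: AssayMeasurement, default_extinction: float,
                  default_path: float) -> float:
    eps = m.extinction or default_extinction
    path = m.path_cm or default_path
    net = m.absorbance - m.blank_absorbance
    if net < 0:
        warnings.warn("absorbance below blank; clamping concentration to 0",
                      stacklevel=3)
        return 0.0
    return m.dilution * net / (eps * path)


def ellman_sh_concentration(m: AssayMeasurement) -> float:
    """Free sulfhydryl concentration (mol L^-1) from a TNB absorbance at 412 nm."""
    return _beer_lambert(m, ELLMAN_EXTINCTION, ELLMAN_PATH_CM)


def brady_carbonyl_concentration(m: AssayMeasurement) -> float:
    """Protein carbonyl concentration (mmol L^-1) from a hydrazone absorbance
    at 375 nm in the 0.2893 cm multiwell path."""
    return _beer_lambert(m, BRADY_EXTINCTION_MM, BRADY_PATH_CM)
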