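"""Optical-quality metrics: MTFa, simulated acuity, defocus curves, foci.

MTFa is the area under the meridian-averaged MTF from 0 to a cutoff
frequency (50 lp/mm ≈ 15 cyc/deg by default), *normalized by the same area of
the diffraction-limited MTF* at the matching aperture and reference
wavelength, so MTFa ∈ [0, 1].  Note that the acuity literature often quotes
the unnormalized area (lp/mm units); the normalized convention is used
throughout this package and the simVA mapping coefficients are calibrated for
it (see the packaged ``simva.yaml``).

Simulated visual acuity uses the exponential map

    simVA(x) = a + b·exp(−c·x)   [logMAR],

a monotone non-increasing function of the normalized MTFa ``x``.

Foci are located on the 0.25 D through-focus grid by discrete peak
prominence; a secondary focus whose peak cannot be separated (prominence
below threshold, or merged with a neighbouring focus) is reported
``present=False`` with no distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.signal import find_peaks

from . import model_eye
from .iol_designs import IOLDesign
from .model_eye import ModelEyeCondition, add_to_viewing_distance
from .optics_engine import ThroughFocusMTF, diffraction_limited_mtf, through_focus

__all__ = [
    "MTFaCurve",
    "DefocusVACurve",
    "FocusPoint",
    "FociReport",
    "mtfa",
    "tf_mtfa",
    "simva",
    "default_simva_coefficients",
    "defocus_va_curve",
    "find_foci",
    "pupil_dependency",
    "condition_loss",
]


@dataclass(frozen=True)
class MTFaCurve:
    """Normalized area under the MTF per defocus value."""

    defocus_grid: np.ndarray              # D, spectacle plane
    mtfa: np.ndarray                      # [0, 1]
    cutoff: float = 50.0                  # lp/mm
    lens: str = ""
    condition: str = ""
    aperture: float = float("nan")        # mm

    def __post_init__(self):
        object.__setattr__(self, "defocus_grid",
                           np.asarray(self.defocus_grid, dtype=float))
        object.__setattr__(self, "mtfa", np.asarray(self.mtfa, dtype=float))
        if self.defocus_grid.shape != self.mtfa.shape:
            raise ValueError("defocus grid and MTFa values must align")
        if np.any(self.mtfa < -1e-9) or np.any(self.mtfa > 1 + 1e-9):
            raise ValueError("normalized MTFa must lie in [0, 1]")


@dataclass(frozen=True)
class DefocusVACurve:
    """Simulated visual acuity (logMAR) per defocus value."""

    defocus_grid: np.ndarray
    simva: np.ndarray                     # logMAR
    mapping: Mapping[str, float] = None
    lens: str = ""
    condition: str = ""
    aperture: float = float("nan")

    def __post_init__(self):
        object.__setattr__(self, "defocus_grid",
                           np.asarray(self.defocus_grid, dtype=float))
        object.__setattr__(self, "simva", np.asarray(self.simva, dtype=float))
        if self.defocus_grid.shape != self.simva.shape:
            raise ValueError("defocus grid and acuity values must align")
        if not np.all(np.isfinite(self.simva)):
            raise ValueError("simVA must be finite")


@dataclass(frozen=True)
class FocusPoint:
    defocus_spec: float | None            # D at the spectacle plane
    distance_cm: float | None             # object distance; None for far/absent
    value: float | None                   # metric value at the peak
    present: bool


@dataclass(frozen=True)
class FociReport:
    far: FocusPoint
    intermediate: FocusPoint
    near: FocusPoint
    lens: str = ""
    condition: str = ""
    metric: str = "mtfa"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# MTFa
# ---------------------------------------------------------------------------

def mtfa(frequencies_lpmm, mtf_curve, reference_curve, cutoff: float = 50.0) -> float:
    """Trapezoidal area of ``mtf_curve`` on [0, cutoff], normalized by the
    same area of ``reference_curve`` (the diffraction-limited MTF)."""
    nu = np.asarray(frequencies_lpmm, dtype=float)
    if nu[-1] < cutoff:
        raise ValueError(f"MTF curve ends at {nu[-1]:.1f} lp/mm, "
                         f"short of the {cutoff} lp/mm cutoff")
    curve = np.asarray(mtf_curve, dtype=float)
    ref = np.asarray(reference_curve, dtype=float)
    sel = nu <= cutoff
    num = np.trapezoid(curve[sel], nu[sel])
    den = np.trapezoid(ref[sel], nu[sel])
    if den <= 0:
        raise ValueError("reference area must be positive")
    return float(num / den)


def tf_mtfa(tf: ThroughFocusMTF, eye: ModelEyeCondition, cutoff: float = 50.0
            ) -> MTFaCurve:
    """Normalized MTFa per defocus column of a through-focus record."""
    ref = diffraction_limited_mtf(tf.frequencies, tf.aperture,
                                  eye.spectrum.reference_wavelength, eye)
    vals = [mtfa(tf.frequencies, row, ref, cutoff) for row in tf.mtf_mean]
    return MTFaCurve(tf.defocus_grid, np.clip(vals, 0.0, 1.0), cutoff,
                     lens=tf.lens, condition=tf.condition, aperture=tf.aperture)


# ---------------------------------------------------------------------------
# simulated visual acuity
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def default_simva_coefficients() -> dict:
    text = (resources.files("trifocal_bench") / "data" / "simva.yaml").read_text()
    return yaml.safe_load(text)["default"]


def simva(mtfa_value, coefficients: Mapping[str, float] | None = None):
    """Simulated visual acuity (logMAR) from a normalized MTFa value."""
    c = coefficients if coefficients is not None else default_simva_coefficients()
    try:
        a, b, k = float(c["a"]), float(c["b"]), float(c["c"])
    except (KeyError, TypeError) as exc:
        raise ValueError("simVA mapping requires coefficients a, b, c") from exc
    x = np.asarray(mtfa_value, dtype=float)
    if np.any(x < -1e-9) or np.any(x > 1 + 1e-9):
        raise ValueError("MTFa input to the acuity map must lie in [0, 1]")
    out = a + b * np.exp(-k * x)
    return float(out) if np.isscalar(mtfa_value) else out


def defocus_va_curve(curve: MTFaCurve,
                     coefficients: Mapping[str, float] | None = None
                     ) -> DefocusVACurve:
    """Elementwise simVA of an MTFa defocus curve."""
    c = dict(coefficients if coefficients is not None
             else default_simva_coefficients())
    return DefocusVACurve(curve.defocus_grid, simva(curve.mtfa, c), c,
                          lens=curve.lens, condition=curve.condition,
                          aperture=curve.aperture)


# ---------------------------------------------------------------------------
# foci localization
# ---------------------------------------------------------------------------

def _peak_candidates(grid, values, prominence):
    idx, _ = find_peaks(values, prominence=prominence)
    # an endpoint can host the far peak when the sweep starts near best focus
    if values.size >= 2 and values[-1] > values[-2]:
        idx = np.append(idx, values.size - 1)
    if values.size >= 2 and values[0] > values[1]:
        idx = np.append(np.array([0]), idx)
    return idx


def find_foci(curve: MTFaCurve | DefocusVACurve, design: IOLDesign,
              eye: ModelEyeCondition, prominence: float | None = None,
              max_mismatch: float = 0.5) -> FociReport:
    """Locate the far/intermediate/near peaks of a defocus curve.

    Peaks are discrete local maxima of the metric (minima for an acuity
    curve) with at least ``prominence`` of prominence — by default 0.02
    normalized-MTFa units, or 0.01 logMAR for an acuity curve (the MTFa
    threshold mapped through the typical slope of the acuity model).  The far
    focus is the peak nearest 0 D; the secondary foci are the peaks nearest
    the design adds expressed at the spectacle plane.  A focus is reported
    absent when no distinct peak lands within ``max_mismatch`` D of its
    expected position or when it merges with a neighbouring focus.
    """
    grid = curve.defocus_grid
    if isinstance(curve, DefocusVACurve):
        values, metric = -curve.simva, "simva"
        prominence = 0.01 if prominence is None else prominence
    else:
        values, metric = curve.mtfa, "mtfa"
        prominence = 0.02 if prominence is None else prominence
    idx = _peak_candidates(grid, values, prominence)
    if idx.size < 1:
        raise ValueError("no peak found in the defocus curve")

    expected = {
        "far": 0.0,
        "intermediate": -model_eye.iol_to_spectacle_defocus(design.add_intermediate, eye),
        "near": -model_eye.iol_to_spectacle_defocus(design.add_near, eye),
    }
    assigned: dict[str, int | None] = {}
    for focus in ("far", "near", "intermediate"):   # far and near claim peaks first
        best, best_d = None, np.inf
        for i in idx:
            if i in assigned.values():
                continue
            d = abs(grid[i] - expected[focus])
            if d < best_d - 1e-12:
                best, best_d = int(i), d
        if best is not None and best_d <= max_mismatch:
            assigned[focus] = best
        else:
            assigned[focus] = None

    def point(focus):
        i = assigned[focus]
        if i is None:
            return FocusPoint(None, None, None, False)
        d_spec = float(grid[i])
        raw = float(curve.simva[i]) if metric == "simva" else float(values[i])
        if focus == "far" or d_spec >= -1e-9:
            return FocusPoint(d_spec, None, raw, True)
        dist = add_to_viewing_distance(-d_spec * eye.plane_factor, eye)
        return FocusPoint(d_spec, dist, raw, True)

    return FociReport(point("far"), point("intermediate"), point("near"),
                      lens=curve.lens, condition=curve.condition, metric=metric)


# ---------------------------------------------------------------------------
# pupil dependency and condition comparison
# ---------------------------------------------------------------------------

def pupil_dependency(designs: Iterable[IOLDesign], eye: ModelEyeCondition,
                     apertures: Sequence[float] = (2.0, 3.0, 4.0, 5.0),
                     frequency: float = 50.0, defocus_grid=None,
                     grid_size: int = 1024, **tf_kwargs) -> pd.DataFrame:
    """Through-focus discrete MTF at one frequency for a set of apertures.

    Returns a tidy table with columns lens, aperture_mm, defocus_spec_D and
    mtf_at_frequency, mirroring the bench's pupil-dependency analysis.
    """
    rows = []
    for design in designs:
        for ap in apertures:
            tf = through_focus(eye, design, ap, defocus_grid=defocus_grid,
                               grid_size=grid_size, **tf_kwargs)
            vals = tf.mtf_at(frequency)
            for d, v in zip(tf.defocus_grid, vals):
                rows.append((design.name, float(ap), float(d), float(v)))
    return pd.DataFrame(rows, columns=["lens", "aperture_mm", "defocus_spec_D",
                                       "mtf_at_frequency"])


def condition_loss(c1: MTFaCurve, c2: MTFaCurve, design: IOLDesign,
                   eye: ModelEyeCondition, focus: str = "far",
                   prominence: float | None = None) -> float:
    """Percent MTFa loss at a named focus between two conditions.

    ``100 · (peak₁ − peak₂) / peak₁``; negative values mean condition 2
    outperforms condition 1 at that focus.
    """
    if not np.allclose(c1.defocus_grid, c2.defocus_grid):
        raise ValueError("curves must share one defocus grid")
    vals = []
    for curve in (c1, c2):
        rep = find_foci(curve, design, eye, prominence=prominence)
        pt = getattr(rep, focus)
        if not pt.present:
            raise ValueError(f"{focus} focus not present in curve "
                             f"({curve.condition or 'unnamed'})")
        vals.append(pt.value)
    base, other = vals
    if base == 0:
        raise ValueError("zero baseline peak; loss undefined")
    return float(100.0 * (base - other) / base)
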