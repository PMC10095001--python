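"""Parametric trifocal phase-profile families and their order-energy splits.

A diffractive multifocal IOL is modelled as a thin phase screen that is
periodic in ρ = r² (Fresnel-zone spacing): a structure of period ``T`` in
ρ-space adds ``m·2λ/T`` diopters of power in diffraction order ``m``, so the
coexisting orders form the far/intermediate/near foci.  Exact groove
geometries are proprietary; each preset therefore stores the *printed* add
powers and energy splits, and the step heights (and, for the pupil-adaptive
design, the radial amplitude taper) are fitted so that the scalar-theory
unit-cell efficiencies reproduce those splits.

Three profile families are provided:

* ``sawtooth_trifocal`` — a stack of sawtooth (kinoform) gratings with
  harmonically related periods; heights in waves at the reference wavelength.
* ``zone_limited_trifocal`` — the same construction, used by designs whose
  diffractive pattern stops at a given diameter with a plain refractive zone
  beyond.
* ``sinusoidal`` — a smooth two-harmonic sinusoid (parameters ``A``, ``B`` in
  radians and a relative phase ``δ``), producing orders −1/0/+1 that are
  remapped to far/intermediate/near through a refractive power offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import yaml
from scipy.optimize import minimize

__all__ = [
    "REFERENCE_WAVELENGTH_NM",
    "IOLDesign",
    "OrderEfficiencyTable",
    "preset",
    "preset_names",
    "build_phase_profile",
    "diffraction_efficiency",
    "split_by_focus",
    "fit_step_heights",
    "apodize",
]

REFERENCE_WAVELENGTH_NM = 546.0

#: sample points per zone period used by the unit-cell integrals
_CELL_SAMPLES = 1024

_FAMILIES = ("sawtooth_trifocal", "sinusoidal", "zone_limited_trifocal")


@dataclass(frozen=True)
class IOLDesign:
    """Parametric description of one (tri)focal diffractive lens design."""

    name: str
    add_intermediate: float               # D at the IOL plane
    add_near: float                       # D at the IOL plane
    profile_family: str
    step_heights: tuple[float, ...]       # waves at 546 nm (sinusoid: A, B rad and δ)
    order_map: Mapping[str, int]          # focus label -> diffraction order
    base_power: float = 20.0
    diffractive_extent: float = 6.0       # mm diameter of the diffractive pattern
    peripheral_family: str = "none"       # 'none' (flat) or 'bifocal' beyond the extent
    peripheral_heights: tuple[float, ...] = ()
    apodization: str = "none"             # 'none' or 'pupil_adaptive'
    apodization_params: tuple[float, float, float] = (0.0, 0.0, 1.0)  # r_start, r_full (mm), s_end
    sa_correction: float = 0.0            # µm of Z(4,0), ≤ 0
    abbe_number: float = 50.0
    refractive_index: float = 1.5
    target_split: tuple[float, ...] = ()
    split_normalization: str = "relative"
    achromatization: float = 0.0          # 0 = none, 1 = full ocular-LCA cancellation
    optic_diameter: float = 6.0           # mm
    inferred: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self):
        if self.profile_family not in _FAMILIES:
            raise ValueError(f"unknown profile family {self.profile_family!r}")
        if not (0 < self.add_intermediate < self.add_near):
            raise ValueError("need 0 < add_intermediate < add_near")
        if self.diffractive_extent > self.optic_diameter:
            raise ValueError("diffractive extent cannot exceed the optic diameter")
        if self.sa_correction > 0:
            raise ValueError("lens asphericity (sa_correction) must be ≤ 0 µm")
        if self.target_split and (min(self.target_split) < 0
                                  or sum(self.target_split) > 1 + 1e-9):
            raise ValueError("target_split entries must be non-negative, sum ≤ 1")

    @property
    def refractive_offset(self) -> float:
        """Refractive add (D) folded into the profile so order_map['far'] is far."""
        m_far = self.order_map["far"]
        return -m_far * self.zone_add if m_far != 0 else 0.0

    @property
    def zone_add(self) -> float:
        """Add power (D) of the first diffraction order of the zone structure."""
        m_far, m_near = self.order_map["far"], self.order_map["near"]
        return self.add_near / (m_near - m_far)

    @property
    def zone_period(self) -> float:
        """Zone period in ρ = r² space, m², at the reference wavelength."""
        return 2.0 * REFERENCE_WAVELENGTH_NM * 1e-9 / self.zone_add

    def focus_add(self, focus: str) -> float:
        """Nominal IOL-plane add power of a focus label at 546 nm."""
        m = self.order_map[focus]
        return (m - self.order_map["far"]) * self.zone_add


@dataclass(frozen=True)
class OrderEfficiencyTable:
    """Aperture-averaged light-energy fractions per diffraction order."""

    orders: tuple[int, ...]
    efficiencies: tuple[float, ...]
    aperture_diameter: float
    wavelength: float

    def __post_init__(self):
        eff = np.asarray(self.efficiencies)
        if np.any(eff < -1e-12) or np.any(eff > 1 + 1e-9):
            raise ValueError("efficiencies must lie in [0, 1]")
        if eff.sum() > 1 + 1e-9:
            raise ValueError("order efficiencies cannot sum above 1")

    def efficiency(self, order: int) -> float:
        try:
            return self.efficiencies[self.orders.index(order)]
        except ValueError:
            raise KeyError(f"order {order} not tabulated") from None


def split_by_focus(table: OrderEfficiencyTable, design: IOLDesign,
                   normalization: str | None = None) -> dict[str, float]:
    """Far/intermediate/near energy fractions from an order table.

    ``normalization='relative'`` rescales the three fractions to sum to one
    (the convention of the printed manufacturer splits); ``'absolute'`` leaves
    them as fractions of all light entering the pupil.
    """
    norm = normalization or design.split_normalization
    vals = {f: table.efficiency(design.order_map[f])
            for f in ("far", "intermediate", "near")}
    if norm == "relative":
        tot = sum(vals.values())
        if tot <= 0:
            raise ValueError("no energy in the design orders")
        vals = {k: v / tot for k, v in vals.items()}
    elif norm != "absolute":
        raise ValueError(f"unknown normalization {norm!r}")
    return vals


# ---------------------------------------------------------------------------
# phase-profile construction
# ---------------------------------------------------------------------------

def _cell_phase(family: str, u, heights) -> np.ndarray:
    """Phase (radians, at the reference wavelength) of one unit cell, u ∈ [0, 1)."""
    u = np.asarray(u, dtype=float)
    if family in ("sawtooth_trifocal", "zone_limited_trifocal"):
        ph = np.zeros_like(u)
        for k, h in enumerate(heights, start=1):
            ph += 2.0 * np.pi * h * np.mod(k * u, 1.0)
        return ph
    if family == "sinusoidal":
        a, b, delta = heights
        return a * np.sin(2 * np.pi * u) + b * np.sin(4 * np.pi * u + delta)
    raise ValueError(f"unknown profile family {family!r}")


def _taper(r_mm, params) -> np.ndarray:
    """Raised-cosine amplitude taper s(r): 1 up to r_start, s_end beyond r_full."""
    r_start, r_full, s_end = params
    r = np.asarray(r_mm, dtype=float)
    s = np.ones_like(r)
    if s_end == 1.0 or r_full <= r_start:
        return s
    hi = r >= r_full
    mid = (r > r_start) & ~hi
    s[hi] = s_end
    s[mid] = 1.0 + (s_end - 1.0) * (1 - np.cos(np.pi * (r[mid] - r_start)
                                               / (r_full - r_start))) / 2.0
    return s


def _periodic_phase(rho_m2, wavelength_nm, family, heights, period,
                    extent_mm, peripheral_family, peripheral_heights,
                    apod_params) -> np.ndarray:
    """Diffractive (periodic) phase at ρ = r² [m²], excluding refractive offset."""
    rho = np.asarray(rho_m2, dtype=float)
    u = np.mod(rho / period, 1.0)
    central = _cell_phase(family, u, heights)
    rho_ext = (extent_mm * 1e-3 / 2.0) ** 2
    if peripheral_family == "none":
        periph = np.zeros_like(central)
    elif peripheral_family == "bifocal":
        periph = _cell_phase("sawtooth_trifocal", u, peripheral_heights)
    else:
        raise ValueError(f"unknown peripheral family {peripheral_family!r}")
    ph = np.where(rho <= rho_ext, central, periph)
    r_mm = np.sqrt(np.maximum(rho, 0.0)) * 1e3
    ph = _taper(r_mm, apod_params) * ph
    return ph * (REFERENCE_WAVELENGTH_NM / wavelength_nm)


class PhaseProfile:
    """Radial diffractive phase function of a design at one wavelength.

    Calling the profile with radii in mm returns the phase in radians,
    including the kinoform λ-scaling of the step heights and, for remapped
    order conventions, the refractive power offset that places the design's
    far focus at zero add.
    """

    def __init__(self, design: IOLDesign, wavelength_nm: float):
        if wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        m_int = design.order_map["intermediate"] - design.order_map["far"]
        implied = m_int * design.zone_add
        if abs(implied - design.add_intermediate) > 0.02:
            raise ValueError(
                f"zone period inconsistent with adds: intermediate order implies "
                f"{implied:.3f} D, design states {design.add_intermediate:.3f} D")
        self.design = design
        self.wavelength_nm = float(wavelength_nm)

    def __call__(self, r_mm) -> np.ndarray:
        d = self.design
        r = np.asarray(r_mm, dtype=float)
        rho = (r * 1e-3) ** 2
        lam = self.wavelength_nm * 1e-9
        ph = _periodic_phase(rho, self.wavelength_nm, d.profile_family,
                             d.step_heights, d.zone_period, d.diffractive_extent,
                             d.peripheral_family, d.peripheral_heights,
                             d.apodization_params)
        if d.refractive_offset:
            # refractive add: power is achromatic, phase scales as 1/λ
            ph = ph + np.pi * d.refractive_offset * rho / lam
        return ph


def build_phase_profile(design: IOLDesign, wavelength_nm: float = REFERENCE_WAVELENGTH_NM
                        ) -> PhaseProfile:
    """Radial phase function (radians vs radius in mm) of a design at λ."""
    return PhaseProfile(design, wavelength_nm)


def apodize(design: IOLDesign, aperture_diameter: float | None = None
            ) -> Callable[[np.ndarray], np.ndarray]:
    """Radial step-height scaling s(r_mm) of a pupil-adaptive design.

    For non-apodized designs an identity scaling is returned with a notice.
    """
    if design.apodization != "pupil_adaptive":
        warnings.warn(f"design {design.name!r} is not apodized; "
                      "returning identity scaling", stacklevel=2)
        return lambda r_mm: np.ones_like(np.asarray(r_mm, dtype=float))
    if aperture_diameter is not None and aperture_diameter > design.optic_diameter:
        raise ValueError("aperture exceeds the lens optic")
    params = design.apodization_params
    return lambda r_mm: _taper(r_mm, params)


# ---------------------------------------------------------------------------
# unit-cell diffraction efficiencies
# ---------------------------------------------------------------------------

def _avg_efficiency(aperture_mm, wavelength_nm, family, heights, period,
                    extent_mm, peripheral_family, peripheral_heights,
                    apod_params, orders, samples: int | None = None) -> np.ndarray:
    """Aperture-averaged |c_m|² over the zone cells covering the pupil.

    Each zone period is sampled uniformly in ρ (cells have equal area); the
    order coefficients come from a DFT of exp(iφ) per cell, the final partial
    cell entering with its covered fraction.  By Parseval the efficiencies over
    all orders sum to exactly one for a phase-only profile.
    """
    rho_max = (aperture_mm * 1e-3 / 2.0) ** 2
    n_cells = int(np.ceil(rho_max / period - 1e-12))
    m = samples or _CELL_SAMPLES
    j = np.arange(n_cells)[:, None]
    rho = (j + (np.arange(m)[None, :] + 0.5) / m) * period
    mask = rho <= rho_max
    ph = _periodic_phase(rho, wavelength_nm, family, heights, period,
                         extent_mm, peripheral_family, peripheral_heights,
                         apod_params)
    cell = np.where(mask, np.exp(1j * ph), 0.0)
    c = np.fft.fft(cell, axis=1) / m
    coverage = mask.mean(axis=1).sum()
    orders = np.asarray(orders, dtype=int)
    return (np.abs(c[:, orders % m]) ** 2).sum(axis=0) / coverage


def diffraction_efficiency(design: IOLDesign, aperture_diameter: float,
                           wavelength_nm: float = REFERENCE_WAVELENGTH_NM,
                           orders=range(-4, 8)) -> OrderEfficiencyTable:
    """Per-order light-energy fractions averaged over the pupil."""
    if aperture_diameter > design.optic_diameter:
        raise ValueError(
            f"aperture {aperture_diameter} mm exceeds the "
            f"{design.optic_diameter} mm optic")
    if aperture_diameter <= 0:
        raise ValueError("aperture must be positive")
    orders = tuple(int(m) for m in orders)
    eff = _avg_efficiency(aperture_diameter, wavelength_nm, design.profile_family,
                          design.step_heights, design.zone_period,
                          design.diffractive_extent, design.peripheral_family,
                          design.peripheral_heights, design.apodization_params,
                          orders)
    return OrderEfficiencyTable(orders, tuple(float(v) for v in eff),
                                float(aperture_diameter), float(wavelength_nm))


# ---------------------------------------------------------------------------
# fitting step heights (and the pupil-adaptive taper) to printed splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepHeightFit:
    heights: tuple[float, ...]
    achieved: dict
    residual: float
    within_tolerance: bool


def _single_cell_eta(family, heights, orders) -> np.ndarray:
    u = (np.arange(_CELL_SAMPLES) + 0.5) / _CELL_SAMPLES
    c = np.fft.fft(np.exp(1j * _cell_phase(family, u, heights))) / _CELL_SAMPLES
    return np.abs(c[np.asarray(orders, dtype=int) % _CELL_SAMPLES]) ** 2


def _starts(n, lo, hi, n_random=8):
    fixed = [np.full(n, 0.35), np.full(n, 0.2),
             np.linspace(0.1, 0.4, n), np.linspace(0.4, 0.1, n)]
    rng = np.random.default_rng(12345)
    return fixed + [rng.uniform(lo, hi, n) for _ in range(n_random)]


def fit_step_heights(target_split, family: str = "sawtooth_trifocal",
                     order_map: Mapping[str, int] | None = None,
                     normalization: str = "relative",
                     n_heights: int = 2, tolerance: float = 0.02,
                     aperture_mm: float | None = 3.0,
                     zone_add: float | None = None, extent_mm: float = 6.0,
                     peripheral_family: str = "none",
                     peripheral_heights: tuple = ()) -> StepHeightFit:
    """Fit cell step heights so the order efficiencies match a target split.

    ``target_split`` is (far, intermediate, near).  With ``'relative'``
    normalization the split is matched as shares over the three design orders
    (with a mild reward for total useful efficiency); with ``'absolute'`` the
    raw fractions are matched.  When ``zone_add`` (D) is given, the achieved
    split is evaluated aperture-averaged at ``aperture_mm`` — manufacturer
    splits are quoted for a pupil, and with only a handful of Fresnel zones
    inside it the partial outer zone shifts the balance appreciably.  With
    ``zone_add=None`` the idealized single-unit-cell efficiencies are fitted
    instead.  Derivative-free (Nelder–Mead) with a fixed multi-start list, so
    the result is deterministic.
    """
    target = np.asarray(target_split, dtype=float)
    if target.min() < 0 or target.sum() > 1 + 1e-9:
        raise ValueError("target fractions must be non-negative and sum ≤ 1")
    om = dict(order_map or {"far": 0, "intermediate": 1, "near": 2})
    orders = [om["far"], om["intermediate"], om["near"]]

    if zone_add is None:
        def achieved_eta(x):
            return _single_cell_eta(family, x, orders)
    else:
        period = 2.0 * REFERENCE_WAVELENGTH_NM * 1e-9 / zone_add

        def achieved_eta(x):
            return _avg_efficiency(aperture_mm, REFERENCE_WAVELENGTH_NM,
                                   family, x, period, extent_mm,
                                   peripheral_family, peripheral_heights,
                                   (0.0, 0.0, 1.0), orders)

    if family == "sinusoidal":
        lo, hi, n = 0.0, 2.2, 3
        starts = [np.array([1.6, 0.1, 0.0]), np.array([1.2, 0.4, 1.0]),
                  np.array([1.8, 0.3, 0.5])]
        rng = np.random.default_rng(12345)
        starts += [np.array([rng.uniform(0.5, 2.2), rng.uniform(0, 0.9),
                             rng.uniform(-2, 2)]) for _ in range(8)]
    else:
        lo, hi = 0.0, 1.1
        starts = _starts(n_heights, lo, hi)

    def objective(x):
        e = achieved_eta(x)
        if normalization == "relative":
            s = e.sum()
            return float(np.sum((e / s - target) ** 2) + 0.02 * (1 - s) ** 2)
        return float(np.sum((e - target) ** 2))

    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options=dict(xatol=1e-8, fatol=1e-16, maxfev=6000))
        if best is None or res.fun < best.fun:
            best = res
    heights = tuple(float(v) for v in best.x)
    eta = achieved_eta(heights)
    achieved = {"absolute": dict(zip(("far", "intermediate", "near"), map(float, eta))),
                "relative": dict(zip(("far", "intermediate", "near"),
                                     map(float, eta / eta.sum())))}
    ach = np.asarray(list(achieved[normalization].values()))
    residual = float(np.max(np.abs(ach - target)))
    return StepHeightFit(heights, achieved, residual, residual <= tolerance)


def _fit_pupil_adaptive(zone_add: float, split_3mm, split_45mm, extent_mm: float
                        ) -> tuple[tuple[float, float, float],
                                   tuple[float, float, float]]:
    """Jointly fit the sinusoid cell and amplitude taper of a pupil-adaptive lens.

    ``split_3mm`` and ``split_45mm`` are the printed absolute
    (intermediate, near) fractions at 3.0 and 4.5 mm.  The taper is a
    raised cosine running from 1 at ``r_start`` to ``s_end`` at 2.25 mm, flat
    on either side.  A small reward keeps the far order populated.
    """
    period = 2.0 * REFERENCE_WAVELENGTH_NM * 1e-9 / zone_add
    i3, n3 = split_3mm
    i45, n45 = split_45mm
    orders = (-1, 0, 1)

    def make_objective(samples):
        def objective(p):
            a, b, d, r_start, s_end = p
            if not (0 <= r_start <= 2.0 and 0.3 <= s_end <= 1.0
                    and 0.5 <= a <= 2.2 and abs(b) <= 0.45):
                return 10.0
            f3, e_i3, e_n3 = _avg_efficiency(
                3.0, REFERENCE_WAVELENGTH_NM, "sinusoidal", (a, b, d), period,
                extent_mm, "none", (), (r_start, 2.25, s_end), orders, samples)
            _, e_i45, e_n45 = _avg_efficiency(
                4.5, REFERENCE_WAVELENGTH_NM, "sinusoidal", (a, b, d), period,
                extent_mm, "none", (), (r_start, 2.25, s_end), orders, samples)
            tot3 = f3 + e_i3 + e_n3
            return ((e_i3 - i3) ** 2 + (e_n3 - n3) ** 2
                    + (e_i45 - i45) ** 2 + (e_n45 - n45) ** 2
                    + 5.0 * max(0.0, 0.82 - tot3) ** 2
                    + 0.2 * max(0.0, 0.27 - f3) ** 2)
        return objective

    # coarse multi-start, then polish the best basins at full resolution
    rng = np.random.default_rng(3)
    coarse = make_objective(256)
    stage1 = []
    for _ in range(20):
        p0 = np.array([rng.uniform(1.2, 2.0), rng.uniform(-0.45, 0.45),
                       rng.uniform(-2, 2), rng.uniform(0.3, 1.8),
                       rng.uniform(0.4, 1.0)])
        stage1.append(minimize(coarse, p0, method="Nelder-Mead",
                               options=dict(xatol=1e-5, fatol=1e-12, maxfev=1500)))
    stage1.sort(key=lambda r: r.fun)
    fine = make_objective(_CELL_SAMPLES)
    best = None
    for res in stage1[:3]:
        polished = minimize(fine, res.x, method="Nelder-Mead",
                            options=dict(xatol=1e-7, fatol=1e-15, maxfev=4000))
        if best is None or polished.fun < best.fun:
            best = polished
    a, b, d, r_start, s_end = (float(v) for v in best.x)
    return (a, b, d), (r_start, 2.25, s_end)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _load_preset_data() -> dict:
    text = (resources.files("trifocal_bench") / "data" / "presets.yaml").read_text()
    return yaml.safe_load(text)["presets"]


def preset_names() -> list[str]:
    return sorted(_load_preset_data())


@lru_cache(maxsize=None)
def preset(name: str) -> IOLDesign:
    """Built-in design for one of the five study lenses.

    Step heights (and the Trinova amplitude taper) are fitted at first use so
    that the unit-cell efficiencies reproduce the printed energy splits; the
    fit is deterministic.
    """
    data = _load_preset_data()
    key = str(name).lower()
    if key not in data:
        raise KeyError(f"unknown preset {name!r}; valid presets: {sorted(data)}")
    p = data[key]
    order_map = dict(p["order_map"])
    common = dict(
        name=key,
        label=p.get("label", key),
        base_power=float(p["base_power_D"]),
        add_intermediate=float(p["add_intermediate_D"]),
        add_near=float(p["add_near_D"]),
        profile_family=p["profile_family"],
        order_map=order_map,
        diffractive_extent=float(p["diffractive_extent_mm"]),
        peripheral_family=p["peripheral_family"],
        apodization=p["apodization"],
        sa_correction=float(p["sa_correction_um"]),
        abbe_number=float(p["abbe_number"]),
        refractive_index=float(p["refractive_index"]),
        target_split=tuple(float(v) for v in p["target_split"]),
        split_normalization=p["split_normalization"],
        achromatization=float(p.get("achromatization", 0.0)),
        inferred=tuple(p.get("inferred", ())),
    )
    if p["apodization"] == "pupil_adaptive":
        zone_add = common["add_near"] / (order_map["near"] - order_map["far"])
        heights, apod = _fit_pupil_adaptive(
            zone_add, tuple(p["target_split"]), tuple(p["target_split_large"]),
            common["diffractive_extent"])
        return IOLDesign(step_heights=heights, apodization_params=apod,
                         peripheral_heights=(), **common)
    peripheral_heights = ()
    if p["peripheral_family"] == "bifocal":
        # equal-split far/near kinoform beyond the extent (half-wave step on
        # the doubled-frequency harmonic)
        peripheral_heights = (0.0, 0.5)
    zone_add = common["add_near"] / (order_map["near"] - order_map["far"])
    fit = fit_step_heights(common["target_split"], p["profile_family"],
                           order_map, p["split_normalization"],
                           n_heights=int(p["n_step_heights"]),
                           aperture_mm=3.0, zone_add=zone_add,
                           extent_mm=common["diffractive_extent"],
                           peripheral_family=p["peripheral_family"],
                           peripheral_heights=peripheral_heights)
    return IOLDesign(step_heights=fit.heights, peripheral_heights=peripheral_heights,
                     **common)
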