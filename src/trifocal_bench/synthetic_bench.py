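"""Synthetic bench-measurement generator and the shared CSV dialect.

Stands in for the optical bench: takes a noiseless through-focus MTF record
(from the simulator, or supplied directly) and emits per-sample tables with
the statistical structure of instrument output — two lens samples per model
by default, independent Gaussian measurement noise per cell, and a small
random sagittal/tangential asymmetry.  All randomness is seeded.

The CSV dialect (shared with the optics engine and the metrics pipeline) has
columns::

    lens, sample_id, condition, aperture_mm, defocus_spec_D,
    frequency_lpmm, mtf_sagittal, mtf_tangential, mtf_mean
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import iol_designs, model_eye, optics_engine
from .optics_engine import ThroughFocusMTF

__all__ = [
    "BenchRunConfig",
    "generate_bench_run",
    "average_samples",
    "write_bench_csv",
    "read_bench_csv",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = ("lens", "sample_id", "condition", "aperture_mm",
                    "defocus_spec_D", "frequency_lpmm", "mtf_sagittal",
                    "mtf_tangential", "mtf_mean")


@dataclass(frozen=True)
class BenchRunConfig:
    """One synthetic measurement session for a lens/condition/aperture."""

    lens: str
    condition: str
    aperture: float                        # mm
    n_samples: int = 2
    noise_sd: float = 0.01                 # MTF units
    meridian_asymmetry_sd: float = 0.005   # MTF units
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("need at least one lens sample")
        if self.noise_sd < 0 or self.meridian_asymmetry_sd < 0:
            raise ValueError("noise levels must be non-negative")


def generate_bench_run(cfg: BenchRunConfig, truth: ThroughFocusMTF | None = None,
                       grid_size: int = 1024, **tf_kwargs
                       ) -> list[ThroughFocusMTF]:
    """Per-sample noisy through-focus tables for one bench configuration.

    ``truth`` is the noiseless record; when omitted it is simulated for the
    named preset and condition.  Noise is additive Gaussian, independent
    across samples, meridians, defocus values and frequencies, with a shared
    per-cell meridian-asymmetry term; results are clipped to [0, 1].  The
    zero-frequency column is left untouched (the instrument normalizes the
    MTF there).  The same seed reproduces the output bitwise.
    """
    if truth is None:
        design = iol_designs.preset(cfg.lens)
        eye = model_eye.condition(cfg.condition)
        truth = optics_engine.through_focus(eye, design, cfg.aperture,
                                            grid_size=grid_size, **tf_kwargs)
    rng = np.random.default_rng(cfg.seed)
    zero = truth.frequencies <= 1e-12
    out = []
    for k in range(cfg.n_samples):
        shape = truth.mtf_sagittal.shape
        asym = rng.normal(0.0, cfg.meridian_asymmetry_sd, shape)
        sag = truth.mtf_sagittal + rng.normal(0.0, cfg.noise_sd, shape) + asym / 2
        tan = truth.mtf_tangential + rng.normal(0.0, cfg.noise_sd, shape) - asym / 2
        sag[:, zero] = truth.mtf_sagittal[:, zero]
        tan[:, zero] = truth.mtf_tangential[:, zero]
        out.append(replace(
            truth,
            mtf_sagittal=np.clip(sag, 0.0, 1.0),
            mtf_tangential=np.clip(tan, 0.0, 1.0),
            samples=(f"sample{k + 1}",),
        ))
    return out


def average_samples(records: Sequence[ThroughFocusMTF]) -> ThroughFocusMTF:
    """Pointwise mean across lens samples (the solid-line curves of a bench report)."""
    if len(records) == 0:
        raise ValueError("no records to average")
    first = records[0]
    for r in records[1:]:
        if (not np.allclose(r.defocus_grid, first.defocus_grid)
                or not np.allclose(r.frequencies, first.frequencies)):
            raise ValueError("records must share defocus and frequency grids")
    sag = np.mean([r.mtf_sagittal for r in records], axis=0)
    tan = np.mean([r.mtf_tangential for r in records], axis=0)
    samples = tuple(s for r in records for s in r.samples)
    return replace(first, mtf_sagittal=sag, mtf_tangential=tan, samples=samples)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_bench_csv(records: Sequence[ThroughFocusMTF] | ThroughFocusMTF,
                    path) -> None:
    """Write one or more through-focus records in the shared CSV dialect."""
    if isinstance(records, ThroughFocusMTF):
        records = [records]
    frames = [r.to_frame() for r in records]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.12g")


def read_bench_csv(path) -> list[ThroughFocusMTF]:
    """Read bench CSV back into per-sample through-focus records.

    Malformed input is rejected with diagnostics naming the offending cells
    (line numbers count the header as line 1).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no data in {path}") from None
    if df.empty:
        raise ValueError(f"no data in {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    for col in ("mtf_sagittal", "mtf_tangential", "mtf_mean"):
        bad = df.index[(df[col] < -1e-9) | (df[col] > 1 + 1e-9)]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ValueError(f"MTF out of [0, 1] in column {col} "
                             f"(line{'s' if len(bad) > 1 else ''} {lines})")

    records = []
    for (lens, sample, cond, ap), g in df.groupby(
            ["lens", "sample_id", "condition", "aperture_mm"], sort=False):
        piv_s = g.pivot_table(index="defocus_spec_D", columns="frequency_lpmm",
                              values="mtf_sagittal", sort=True)
        piv_t = g.pivot_table(index="defocus_spec_D", columns="frequency_lpmm",
                              values="mtf_tangential", sort=True)
        if piv_s.isna().any().any() or piv_t.isna().any().any():
            raise ValueError(f"incomplete defocus × frequency grid for "
                             f"{lens}/{sample}")
        grid = piv_s.index.to_numpy(dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError(f"non-monotone defocus grid for {lens}/{sample}")
        records.append(ThroughFocusMTF(
            defocus_grid=grid,
            frequencies=piv_s.columns.to_numpy(dtype=float),
            mtf_sagittal=piv_s.to_numpy(dtype=float),
            mtf_tangential=piv_t.to_numpy(dtype=float),
            condition=str(cond), lens=str(lens), aperture=float(ap),
            samples=(str(sample),)))
    return records
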