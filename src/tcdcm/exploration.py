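"""Forward exploration of the condition-effect space.

Two reports: a two-axis sweep of normalized beta power over condition
effects on selected connections (how joint coupling changes move the
circuit between low- and high-beta regimes), and per-population source
spectra for both conditions.

Normalized beta power is the 15–35 Hz integral of the high-beta neural
output spectrum divided by the same integral for the low-beta baseline, so
the all-zero cell equals 1 exactly.  The observation-noise floor is
excluded: the quantity of interest is the circuit's spectral output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import CircuitParameters, ModelSpec
from .forward import (
    BETA_BAND,
    UnstableRegimeError,
    band_power,
    default_freqs,
    predict_csd,
    predict_source_spectra,
)
from .circuit import POPULATIONS

__all__ = ["SweepResult", "sweep_beta_power", "population_spectra_report"]


@dataclass
class SweepResult:
    """Grid of normalized beta power; unstable cells are NaN and flagged."""

    axis1: tuple[str, str]
    axis2: tuple[str, str]
    grid: np.ndarray
    power: np.ndarray  # (len(grid), len(grid)); [i, j] -> axis1=grid[i], axis2=grid[j]
    unstable: np.ndarray  # boolean mask, same shape
    fixed: dict


def sweep_beta_power(
    spec: ModelSpec,
    params: CircuitParameters | None = None,
    axis1: tuple[str, str] = ("MP", "SP"),
    axis2: tuple[str, str] = ("REL", "DP"),
    fixed: dict | None = None,
    grid: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] = BETA_BAND,
) -> SweepResult:
    """Normalized beta power over a grid of two condition effects.

    The default configuration varies the MP→SP and REL→DP effects with the
    REL→RET effect clamped via ``fixed`` (the weak/strong scenarios are
    ``fixed={("REL","RET"): -1.0}`` and ``{("REL","RET"): +1.0}``); passing
    different axes reproduces the alternative reading in which MP→SP and
    REL→RET themselves are swept.  Cells whose high-beta linearization is
    unstable are flagged, not dropped.
    """
    if params is None:
        params = CircuitParameters.defaults()
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 21)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.abs(grid) > 1.0 + 1e-12):
        raise ValueError("sweep grid must lie within [-1, 1]")
    if freqs is None:
        freqs = default_freqs()
    fixed = dict(fixed or {})
    modulated = set(spec.modulated_edges)
    for edge in (axis1, axis2, *fixed):
        if tuple(edge) not in modulated:
            raise ValueError(f"edge {edge} is not modulated under {spec.label}")

    base = params.copy()
    base.B = {}
    g_lb = predict_csd(spec, base, freqs, "LB", include_channel_noise=False)
    bp_lb = band_power(freqs, g_lb, band=band)

    power = np.full((grid.size, grid.size), np.nan)
    unstable = np.zeros((grid.size, grid.size), dtype=bool)
    for i, b1 in enumerate(grid):
        for j, b2 in enumerate(grid):
            p = params.copy()
            p.B = dict(fixed)
            p.B[tuple(axis1)] = float(b1)
            p.B[tuple(axis2)] = float(b2)
            try:
                g_hb = predict_csd(spec, p, freqs, "HB", include_channel_noise=False)
            except UnstableRegimeError:
                unstable[i, j] = True
                continue
            power[i, j] = band_power(freqs, g_hb, band=band) / bp_lb
    return SweepResult(
        axis1=tuple(axis1),
        axis2=tuple(axis2),
        grid=grid,
        power=power,
        unstable=unstable,
        fixed=fixed,
    )


def population_spectra_report(
    spec: ModelSpec,
    params_LB: CircuitParameters,
    params_HB: CircuitParameters | None = None,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] = BETA_BAND,
):
    """Per-population source spectra for both conditions plus a summary table.

    ``params_HB`` defaults to ``params_LB`` (whose B effects then produce
    the high-beta condition).  Returns ``(spectra, table)`` where
    ``spectra[cond]`` has shape (n_freqs, 6) and the table lists peak
    frequency and beta-band power per population and condition.
    """
    if freqs is None:
        freqs = default_freqs()
    if params_HB is None:
        params_HB = params_LB
    spectra = {}
    rows = []
    for cond, p in (("LB", params_LB), ("HB", params_HB)):
        try:
            S = predict_source_spectra(spec, p, freqs, condition=cond)
        except UnstableRegimeError as err:
            raise UnstableRegimeError(f"{cond} condition unstable: {err}") from err
        spectra[cond] = S
        for k, pop in enumerate(POPULATIONS):
            g = S[:, k]
            rows.append(
                {
                    "population": pop,
                    "condition": cond,
                    "peak_freq": float(freqs[np.argmax(g)]),
                    "beta_power": band_power(freqs, g, band=band),
                }
            )
    return spectra, pd.DataFrame(rows)
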