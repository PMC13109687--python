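"""Synthetic data generation with known ground truth.

This module stands in for the study's raw data sources — MD umbrella-sampling
trajectories, fluorescence titrations, and catalytic-triad distance
trajectories — so that every downstream estimator can be validated against a
known truth.

The model free-energy landscape reproduces the landmark features of the
open/closed conformational profile along the Bpy-Bpy N-N distance:

* a broad open-state minimum near 25 A,
* without metal, a narrow closed-state minimum ~15 kcal/mol above the open
  minimum near 2.5 A,
* with metal, a deep narrow well at 2.5 A several kcal/mol below the open
  minimum,
* an intervening barrier plateau.

The functional form is a Boltzmann-weight mixture: the unbiased density is a
sum of a broad quartic-exponential open basin, a narrow Gaussian closed well
whose amplitude encodes its free-energy offset, and a constant floor encoding
the barrier height; W(x) = -kT ln(density). This makes the landmark energies
exact by construction instead of emergent from a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, kt
from .profiles import PMFProfile, UmbrellaWindow
from .binding import (EquilibriumSystem, ResponseModel, TitrationSeries,
                      predict_signal)
from .fret import ConformerEnsemble


@dataclass
class ModelPMFParams:
    """Parameters of the two-basin model landscape.

    Energies in kcal/mol, distances in angstroms. ``open_width`` is the
    quartic length scale of the open basin; ``closed_well_width`` is the
    Gaussian sd of the closed well (sub-angstrom: the metal-chelated state is
    tightly confined).
    """

    open_center: float = 25.0
    open_width: float = 6.0
    closed_center: float = 2.5
    closed_offset_no_metal: float = 15.0
    closed_well_depth_metal: float = 9.0
    closed_well_width: float = 0.10
    barrier_height: float = 18.0
    grid_min: float = 2.0
    grid_max: float = 37.8
    grid_step: float = 0.05
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if not (self.grid_min < self.closed_center < self.open_center
                < self.grid_max):
            raise ValueError(
                "require grid_min < closed_center < open_center < grid_max")
        if self.closed_offset_no_metal < 0:
            raise ValueError("closed_offset_no_metal must be >= 0")
        if self.closed_well_depth_metal < 0:
            raise ValueError("closed_well_depth_metal must be >= 0 "
                             "(depth below the open minimum)")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.open_width <= 0 or self.closed_well_width <= 0:
            raise ValueError("widths must be positive")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        if n <= 2:
            raise ValueError("degenerate grid: need more than 2 points")
        return self.grid_min + self.grid_step * np.arange(n)


def make_pmf(params: ModelPMFParams, metal_bound: bool) -> PMFProfile:
    """Build the model PMF on the parameter grid.

    Without metal the closed-well amplitude is exp(-offset/kT); with metal it
    is exp(+depth/kT), placing the well below the open minimum. The returned
    profile is anchored so its global minimum is 0.
    """
    x = params.grid
    kbt = kt(params.temperature)
    # log-amplitudes of the three density components
    log_open = -((x - params.open_center) / params.open_width) ** 4
    closed_level = (params.closed_well_depth_metal if metal_bound
                    else -params.closed_offset_no_metal)
    log_closed = (closed_level / kbt
                  - 0.5 * ((x - params.closed_center)
                           / params.closed_well_width) ** 2)
    log_floor = np.full_like(x, -params.barrier_height / kbt)
    log_density = logsumexp(np.stack([log_open, log_closed, log_floor]),
                            axis=0)
    w = -kbt * log_density
    if not np.all(np.isfinite(w)):
        raise FloatingPointError("model PMF is non-finite on the grid")
    w -= w.min()
    return PMFProfile(x, w, temperature=params.temperature)


@dataclass
class SimulationPlan:
    """Umbrella-sampling protocol: window centers, harmonic force constant
    (kcal/mol/A^2), samples per window, temperature and seed."""

    window_centers: np.ndarray
    force_constant: float = 125.0
    samples_per_window: int = 2000
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self):
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        if self.window_centers.size == 0:
            raise ValueError("need at least one window center")
        if np.any(np.diff(self.window_centers) <= 0):
            raise ValueError("window centers must be strictly increasing")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.samples_per_window < 1:
            raise ValueError("samples_per_window must be >= 1")

    @classmethod
    def spaced(cls, start: float, stop: float, spacing: float,
               **kwargs) -> "SimulationPlan":
        """Evenly spaced window centers from ``start`` to at most ``stop``."""
        n = int(np.floor((stop - start) / spacing + 1e-9)) + 1
        return cls(start + spacing * np.arange(n), **kwargs)


def sample_windows(pmf: PMFProfile, plan: SimulationPlan) -> list[UmbrellaWindow]:
    """Draw biased samples for each window by grid inverse-CDF sampling.

    For window center c the target density is proportional to
    exp(-[W(x) + 0.5 k (x-c)^2] / kT). The PMF is linearly interpolated onto
    an internal grid fine enough to resolve the bias width (step <= sigma/5
    where sigma = sqrt(kT/k)), so the piecewise-uniform inverse-CDF draw does
    not distort the sample variance. Identical (pmf, plan) => identical output.
    """
    lo, hi = pmf.grid[0], pmf.grid[-1]
    if np.any(plan.window_centers < lo) or np.any(plan.window_centers > hi):
        raise ValueError("window centers must lie within the PMF grid range")
    kbt = kt(plan.temperature)
    step = pmf.step
    if plan.force_constant > 0:
        sigma = np.sqrt(kbt / plan.force_constant)
        step = min(step, sigma / 5.0)
    # a piecewise-linear CDF means piecewise-uniform density: refine well
    # below both the bias width and the PMF resolution so the within-cell
    # approximation is negligible even for sharply curved profiles
    step /= 4.0
    n_fine = int(np.ceil((hi - lo) / step)) + 1
    xf = np.linspace(lo, hi, n_fine)
    wf = pmf.interp(xf)

    rng = np.random.default_rng(plan.seed)
    windows = []
    for i, c in enumerate(plan.window_centers):
        bias = 0.5 * plan.force_constant * (xf - c) ** 2
        logp = -(wf + bias) / kbt
        norm = logsumexp(logp)
        if not np.isfinite(norm):
            raise FloatingPointError(
                f"window at {c} A: biased density vanishes on the whole grid")
        p = np.exp(logp - norm)
        # interval probabilities (trapezoid), then piecewise-linear CDF
        p_int = 0.5 * (p[:-1] + p[1:])
        cdf = np.concatenate([[0.0], np.cumsum(p_int)])
        cdf /= cdf[-1]
        u = rng.random(plan.samples_per_window)
        idx = np.clip(np.searchsorted(cdf, u, side="right") - 1, 0,
                      len(p_int) - 1)
        frac = (u - cdf[idx]) / np.maximum(cdf[idx + 1] - cdf[idx], 1e-300)
        samples = xf[idx] + frac * (xf[idx + 1] - xf[idx])
        windows.append(UmbrellaWindow(window_id=f"w{i:04d}", center=float(c),
                                      force_constant=plan.force_constant,
                                      samples=samples))
    return windows


def simulate_titration(system: EquilibriumSystem, response: ResponseModel,
                       metal_totals, replicates: int, noise_sd: float,
                       seed: int) -> list[TitrationSeries]:
    """Forward-simulate competition-titration fluorescence data.

    Each replicate's signal is the exact mass-action speciation pushed through
    the linear response model, plus homoscedastic Gaussian noise of sd
    ``noise_sd`` (signal units). The generating parameters are recorded in
    each series' metadata under ``ground_truth``.
    """
    metal_totals = np.asarray(metal_totals, dtype=float)
    if np.any(metal_totals < 0):
        raise ValueError("metal totals must be non-negative")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    truth = {
        "kd_protein_nM": system.kd_protein,
        "kd_chelator_nM": system.kd_chelator,
        "protein_total_nM": system.protein_total,
        "chelator_total_nM": system.chelator_total,
        "signal_free_chelator": response.signal_free_chelator,
        "signal_bound_chelator": response.signal_bound_chelator,
        "baseline": response.baseline,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    clean = np.array([
        predict_signal(system.with_metal_total(m), response)
        for m in metal_totals
    ])
    rng = np.random.default_rng(seed)
    series = []
    for r in range(replicates):
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.size)
        series.append(TitrationSeries(
            replicate_id=f"rep{r + 1}", metal_totals=metal_totals.copy(),
            signals=noisy, metadata={"ground_truth": dict(truth)}))
    return series


def simulate_conformer_traj(weights, means, sds, n: int,
                            seed: int) -> ConformerEnsemble:
    """Draw a two-state (or k-state) Gaussian-mixture distance trajectory.

    Emulates the bimodal catalytic-triad S477(OG)-H592(HE2) distance
    distributions: a 'near' (catalysis-competent) and a 'distant' mode.
    True component labels are retained for classifier scoring.
    """
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if np.any(weights < 0) or np.any(means <= 0) or np.any(sds <= 0):
        raise ValueError("weights must be >= 0; means and sds positive")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(weights), size=n, p=weights)
    distances = rng.normal(means[labels], sds[labels])
    return ConformerEnsemble(distances=distances, true_labels=labels)
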