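"""Core containers shared across the pipeline: gridded free-energy profiles
and umbrella-sampling windows.

A :class:`PMFProfile` holds a potential of mean force W(x) on a uniform grid
of reaction-coordinate values (here the N-N distance between the two
bipyridine nitrogen-pair centers of mass, in angstroms). Bins that received
no samples are masked with NaN rather than zero so that downstream Boltzmann
integrals never see spurious free energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE


@dataclass
class PMFProfile:
    """Free-energy profile W(x) on a uniform grid.

    Parameters
    ----------
    grid : ndarray
        Bin centers in angstroms, strictly increasing, uniformly spaced.
    values : ndarray
        Free energy in kcal/mol per bin; NaN marks masked (unsampled) bins.
        Anchored so the minimum over unmasked bins is 0.
    counts : ndarray, optional
        Total sample counts per bin (all zeros for analytic profiles).
    temperature : float
        Temperature in K at which the profile is defined.
    """

    grid: np.ndarray
    values: np.ndarray
    counts: np.ndarray = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 3:
            raise ValueError("grid must be 1-D with more than 2 points")
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        steps = np.diff(self.grid)
        if np.any(steps <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("grid must be uniformly spaced")
        if self.counts is None:
            self.counts = np.zeros_like(self.grid)
        else:
            self.counts = np.asarray(self.counts, dtype=float)

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the profile is defined (unmasked)."""
        return np.isfinite(self.values)

    def anchored(self) -> "PMFProfile":
        """Return a copy shifted so the minimum over unmasked bins is 0."""
        vals = self.values.copy()
        m = self.mask
        if not m.any():
            raise ValueError("profile is fully masked")
        vals[m] -= np.nanmin(vals[m])
        return PMFProfile(self.grid.copy(), vals, self.counts.copy(),
                          self.temperature)

    def interp(self, x) -> np.ndarray:
        """Linearly interpolate W at positions ``x`` (unmasked bins only)."""
        m = self.mask
        return np.interp(np.asarray(x, dtype=float), self.grid[m],
                         self.values[m])


@dataclass
class UmbrellaWindow:
    """One biased umbrella-sampling window.

    The bias is harmonic, ``0.5 * force_constant * (x - center)**2``, with
    the force constant in kcal/mol/A^2.
    """

    window_id: str
    center: float
    force_constant: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.samples.size == 0:
            raise ValueError(f"window {self.window_id} has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"window {self.window_id} has non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def bias_energy(self, x) -> np.ndarray:
        """Harmonic bias energy at positions ``x`` in kcal/mol."""
        x = np.asarray(x, dtype=float)
        return 0.5 * self.force_constant * (x - self.center) ** 2
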