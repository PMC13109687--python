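"""Weighted Histogram Analysis Method for umbrella-sampling data.

Given windows biased by harmonic potentials b_i(x) = k_i/2 (x - c_i)^2, the
unbiased bin probabilities and per-window free energies satisfy the coupled
fixed point

    p_j = ( sum_i n_ij ) / ( sum_i N_i exp[(F_i - b_ij) / kT] )
    F_i = -kT ln sum_j p_j exp(-b_ij / kT)

which is iterated directly (Picard) until the largest per-window free-energy
change falls below the requested tolerance. The gauge freedom (all F_i plus
a constant) is removed by pinning F_1 = 0; the recovered profile
W(x_j) = -kT ln p_j is anchored so its minimum over sampled bins is zero.
Bins that received no samples are masked (NaN), never reported as zero free
energy.

Samples are treated as statistically independent — appropriate for the
synthetic generator's draws; correlated MD data should be decorrelated
upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt
from .profiles import PMFProfile, UmbrellaWindow

__all__ = ["WhamSolution", "OverlapReport", "solve_wham",
           "overlap_diagnostics"]


@dataclass
class WhamSolution:
    pmf: PMFProfile
    window_free_energies: np.ndarray
    iterations: int
    converged: bool
    tolerance_achieved: float
    delta_history: np.ndarray = field(repr=False, default=None)
    bin_probabilities: np.ndarray = field(repr=False, default=None)

    def statistical_error(self) -> np.ndarray:
        """Crude per-bin error estimate, kT/sqrt(count): Poisson counting
        noise propagated through W = -kT ln p. Masked bins get NaN."""
        kbt = kt(self.pmf.temperature)
        with np.errstate(divide="ignore"):
            err = kbt / np.sqrt(self.pmf.counts)
        return np.where(self.pmf.counts > 0, err, np.nan)


@dataclass
class OverlapReport:
    pairs: list  # (id_a, id_b, overlap coefficient)
    floor: float

    @property
    def flagged(self) -> list:
        return [p for p in self.pairs if p[2] < self.floor]

    @property
    def min_overlap(self) -> float:
        return min(p[2] for p in self.pairs)


def _bin_edges(windows, bin_width):
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    # snap to a bin-width-aligned origin so identical data give identical bins
    first = np.floor(lo / bin_width) * bin_width
    n_bins = int(np.ceil((hi - first) / bin_width)) + 1
    return first + bin_width * np.arange(n_bins + 1)


def solve_wham(windows: list[UmbrellaWindow], bin_width: float = 0.1,
               temperature: float = DEFAULT_TEMPERATURE,
               tolerance: float = 1e-7,
               max_iterations: int = 100_000) -> WhamSolution:
    """Reconstruct the unbiased PMF from biased umbrella windows.

    Parameters
    ----------
    bin_width : float
        Histogram bin width in A (default 0.1, half the study's window
        spacing).
    tolerance : float
        Convergence threshold on max |delta F_i| per iteration, kcal/mol.

    Warns if any adjacent window pair shares no occupied bin (the chain is
    then disconnected and the relative free energies across the gap are
    meaningless); such runs are returned with ``converged=False`` if the
    iteration does not settle.
    """
    if not windows:
        raise ValueError("need at least one window")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    windows = sorted(windows, key=lambda w: w.center)
    if len(windows) > 1:
        rep = overlap_diagnostics(windows, bin_width, floor=0.0)
        zero_pairs = [p for p in rep.pairs if p[2] == 0.0]
        if zero_pairs:
            warnings.warn(
                "adjacent windows share no occupied bins: "
                + ", ".join(f"{a}-{b}" for a, b, _ in zero_pairs),
                stacklevel=2)

    kbt = kt(temperature)
    edges = _bin_edges(windows, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_win = len(windows)
    counts = np.empty((n_win, centers.size))
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.samples, bins=edges)
    n_i = counts.sum(axis=1)
    m_j = counts.sum(axis=0)
    occupied = m_j > 0

    bias = np.stack([w.bias_energy(centers) for w in windows])
    with np.errstate(under="ignore"):
        boltz = np.exp(-bias / kbt)  # underflow to 0 is the correct limit

    f = np.zeros(n_win)
    deltas = []
    converged = False
    it = 0
    p = np.zeros_like(centers)
    for it in range(1, max_iterations + 1):
        with np.errstate(over="ignore", invalid="ignore"):
            denom = (n_i * np.exp(f / kbt)) @ boltz
            p = np.where(occupied & (denom > 0), m_j / denom, 0.0)
            p_sum = p.sum()
            if not np.isfinite(p_sum) or p_sum <= 0:
                raise FloatingPointError(
                    "WHAM iteration produced a degenerate distribution")
            p /= p_sum
            f_new = -kbt * np.log(boltz @ p)
        f_new -= f_new[0]  # pin F_1 = 0 (gauge)
        delta = float(np.max(np.abs(f_new - f)))
        deltas.append(delta)
        f = f_new
        if delta <= tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {it} iterations "
            f"(last max|dF| = {deltas[-1]:.3g} kcal/mol); check window "
            "overlap diagnostics", stacklevel=2)

    with np.errstate(divide="ignore"):
        w_vals = np.where(occupied, -kbt * np.log(np.where(occupied, p, 1.0)),
                          np.nan)
    w_vals = w_vals - np.nanmin(w_vals)
    pmf = PMFProfile(centers, w_vals, counts=m_j, temperature=temperature)
    return WhamSolution(pmf=pmf, window_free_energies=f, iterations=it,
                        converged=converged,
                        tolerance_achieved=deltas[-1] if deltas else 0.0,
                        delta_history=np.asarray(deltas),
                        bin_probabilities=p)


def overlap_diagnostics(windows: list[UmbrellaWindow],
                        bin_width: float = 0.1,
                        floor: float = 0.05) -> OverlapReport:
    """Histogram-overlap coefficient for each adjacent window pair.

    The coefficient is sum_j min(p_j, q_j) of the two normalized sample
    histograms on shared bins — 1 for identical distributions, 0 for
    disjoint ones. Pairs below ``floor`` are flagged.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    windows = sorted(windows, key=lambda w: w.center)
    edges = _bin_edges(windows, bin_width)
    pairs = []
    hists = [np.histogram(w.samples, bins=edges)[0] / w.n_samples
             for w in windows]
    for (wa, ha), (wb, hb) in zip(zip(windows, hists),
                                  zip(windows[1:], hists[1:])):
        ovl = float(np.minimum(ha, hb).sum())
        pairs.append((wa.window_id, wb.window_id, ovl))
    return OverlapReport(pairs=pairs, floor=floor)
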