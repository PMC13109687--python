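"""Mass-action speciation and affinity fitting for the Ni(II) /
chelator / protein competition assay.

The study measures protein metal affinity by competition with the
fluorescent chelator magfura-2 (Mf2), whose emission is quenched on Ni(II)
binding. Ni(II) is titrated into a mix of protein and chelator; the free
chelator fraction (hence the fluorescence) falls as metal partitions between
the two ligands. With the chelator Kd known from a direct titration, a
global fit of the competition curves yields the protein's apparent Kd.

Speciation treats each ligand class as an independent 1:1 site (two Bpy
side chains plus Ni jointly form one Bpy2-Ni site, so the protein is one
binding event; 1:1 Mf2:Ni likewise). Conservation of metal gives a strictly
increasing function of free metal m,

    g(m) = m + sum_s S_tot * m / (Kd_s + m) - M_tot,

whose unique root in [0, M_tot] is found by bracketed bisection, vectorized
over titration points.

Fitting exploits that the fluorescence model is linear in its response
parameters: for any candidate Kd the optimal nuisances solve a linear
least-squares problem, so the global fit reduces to a one-dimensional
profile-SSE search over log10 Kd. Confidence intervals come from a seeded
residual (or replicate) bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "EquilibriumSystem", "Speciation", "TitrationSeries", "ResponseModel",
    "FitResult", "solve_speciation", "predict_signal", "fit_competition",
    "fit_direct_quench", "fit_isotherm_depletion", "isotherm_fraction_bound",
]


@dataclass
class EquilibriumSystem:
    """Totals and dissociation constants for one titration point (nM).

    ``kd_nonspecific`` (with ``nonspecific_sites`` sites per protein) models
    an optional weak independent-site class, motivated by the secondary
    binding seen at excess Ni(II).
    """

    metal_total: float
    chelator_total: float = 0.0
    protein_total: float = 0.0
    kd_chelator: float = 100.0
    kd_protein: float = 41.5
    kd_nonspecific: float | None = None
    nonspecific_sites: int = 1

    def __post_init__(self):
        for name in ("metal_total", "chelator_total", "protein_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("kd_chelator", "kd_protein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kd_nonspecific is not None and self.kd_nonspecific <= 0:
            raise ValueError("kd_nonspecific must be > 0")

    def with_metal_total(self, metal_total: float) -> "EquilibriumSystem":
        return replace(self, metal_total=metal_total)

    def site_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(site totals, Kds) for every 1:1 class in the system."""
        totals = [self.chelator_total, self.protein_total]
        kds = [self.kd_chelator, self.kd_protein]
        if self.kd_nonspecific is not None:
            totals.append(self.nonspecific_sites * self.protein_total)
            kds.append(self.kd_nonspecific)
        return np.array(totals), np.array(kds)


@dataclass
class Speciation:
    free_metal: float
    free_chelator: float
    bound_chelator: float
    free_protein: float
    bound_protein: float
    nonspecific_bound: float = 0.0


@dataclass
class TitrationSeries:
    """One replicate's signal-vs-total-metal curve."""

    replicate_id: str
    metal_totals: np.ndarray
    signals: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.metal_totals = np.asarray(self.metal_totals, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.metal_totals.shape != self.signals.shape:
            raise ValueError("metal_totals and signals must match in length")
        if np.any(self.metal_totals < 0):
            raise ValueError("metal totals must be non-negative")


@dataclass
class ResponseModel:
    """Linear fluorescence response: signal = baseline
    + signal_free_chelator*[Mf2_free] + signal_bound_chelator*[Mf2.Ni]."""

    signal_free_chelator: float = 1.0
    signal_bound_chelator: float = 0.1
    baseline: float = 0.0

    def __post_init__(self):
        if self.signal_bound_chelator > self.signal_free_chelator:
            raise ValueError("quench-on-binding requires "
                             "signal_bound_chelator <= signal_free_chelator")


@dataclass
class FitResult:
    kd_estimate: float
    confidence_interval: tuple[float, float] | None
    nuisances: dict
    residual_sd: float
    n_points: int
    converged: bool
    pinned_at_bounds: bool = False
    bootstrap_estimates: np.ndarray | None = None

    def __post_init__(self):
        if self.confidence_interval is not None:
            lo, hi = self.confidence_interval
            if not (lo <= self.kd_estimate <= hi):
                raise ValueError("CI must bracket the point estimate")


_NEWTON_ITERS = 20  # quadratic convergence; machine precision in < 10


def _free_metal(metal_totals: np.ndarray, site_totals: np.ndarray,
                kds: np.ndarray) -> np.ndarray:
    """Vectorized root-finding for free metal at each titration point.

    g(m) = m + sum_s S_s m/(K_s+m) - M is strictly increasing and concave
    with g(0) = -M <= 0 and g(M) >= 0, so [0, M] always brackets the unique
    root and Newton started at the upper bracket end descends monotonically
    to it (concavity keeps every iterate inside the bracket).
    """
    m_tot = np.asarray(metal_totals, dtype=float)
    s = site_totals[:, None]
    k = kds[:, None]
    m = m_tot.copy()
    for _ in range(_NEWTON_ITERS):
        km = k + m
        g = m + np.sum(s * m / km, axis=0) - m_tot
        gp = 1.0 + np.sum(s * k / (km * km), axis=0)
        m = np.maximum(m - g / gp, 0.0)
    return m


def solve_speciation(system: EquilibriumSystem) -> Speciation:
    """Solve the coupled 1:1 equilibria exactly; mass balance is verified to
    1e-10 relative."""
    totals, kds = system.site_classes()
    m = float(_free_metal(np.array([system.metal_total]), totals, kds)[0])
    bound = totals * m / (kds + m)
    bound_chel = float(bound[0])
    bound_prot = float(bound[1])
    nonspec = float(bound[2]) if bound.size > 2 else 0.0
    total_check = m + bound.sum()
    scale = max(system.metal_total, 1.0)
    if abs(total_check - system.metal_total) > 1e-10 * scale:
        raise ArithmeticError(
            f"mass balance violated: {total_check} vs {system.metal_total}")
    return Speciation(
        free_metal=m,
        free_chelator=system.chelator_total - bound_chel,
        bound_chelator=bound_chel,
        free_protein=system.protein_total - bound_prot,
        bound_protein=bound_prot,
        nonspecific_bound=nonspec,
    )


def predict_signal(system: EquilibriumSystem, response: ResponseModel) -> float:
    """Fluorescence predicted for one titration point."""
    spec = solve_speciation(system)
    return (response.baseline
            + response.signal_free_chelator * spec.free_chelator
            + response.signal_bound_chelator * spec.bound_chelator)


def _free_chelator_curve(metal_totals: np.ndarray, chelator_total: float,
                         protein_total: float, kd_chelator: float,
                         kd_protein: float) -> np.ndarray:
    """Free-chelator concentration along a titration (vectorized)."""
    totals = np.array([chelator_total, protein_total])
    kds = np.array([kd_chelator, kd_protein])
    m = _free_metal(metal_totals, totals, kds)
    return chelator_total - chelator_total * m / (kd_chelator + m)


def _profile_sse(kd: float, series, curve_fn):
    """SSE at a candidate Kd after exactly solving the linear nuisances.

    Free and metal-bound chelator sum to the chelator total, so the three
    response coefficients collapse to two identifiable nuisances per
    replicate: an intercept and a slope on free chelator. ``curve_fn``
    maps (metal_totals, kd) to the free-chelator curve.
    """
    sse = 0.0
    coefs = []
    free_c = None
    prev_totals = None
    for s in series:
        if free_c is None or not (s.metal_totals is prev_totals
                                  or np.array_equal(s.metal_totals,
                                                    prev_totals)):
            free_c = curve_fn(s.metal_totals, kd)
            prev_totals = s.metal_totals
        # closed-form simple linear regression (intercept + slope)
        xbar = free_c.mean()
        ybar = s.signals.mean()
        dx = free_c - xbar
        sxx = dx @ dx
        slope = (dx @ s.signals) / sxx if sxx > 0 else 0.0
        intercept = ybar - slope * xbar
        resid = s.signals - intercept - slope * free_c
        sse += float(resid @ resid)
        coefs.append(np.array([intercept, slope]))
    return sse, coefs


def _minimize_kd(series, curve_fn, kd_bounds, hint: float | None = None):
    """Profile-SSE minimization over log10 Kd: coarse bracket scan, then
    bounded Brent. A ``hint`` (e.g. the point estimate, during bootstrap)
    narrows the initial scan; the scan widens again if the optimum lands on
    the narrowed bracket's edge."""
    lo, hi = np.log10(kd_bounds[0]), np.log10(kd_bounds[1])
    if hint is not None:
        scan_lo = max(lo, np.log10(hint) - 1.0)
        scan_hi = min(hi, np.log10(hint) + 1.0)
        grid = np.linspace(scan_lo, scan_hi, 9)
    else:
        grid = np.linspace(lo, hi, 30)
    sse_grid = [_profile_sse(10.0 ** g, series, curve_fn)[0] for g in grid]
    i = int(np.argmin(sse_grid))
    if hint is not None and (i == 0 or i == len(grid) - 1) \
            and (grid[0] > lo or grid[-1] < hi):
        return _minimize_kd(series, curve_fn, kd_bounds, hint=None)
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda g: _profile_sse(10.0 ** g, series, curve_fn)[0],
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-7})
    return 10.0 ** float(res.x)


def _global_fit(series, curve_fn, kd_bounds, bootstrap_n, seed,
                bootstrap_over, ci_level):
    """Shared profile-fit + bootstrap engine for competition and direct fits."""
    kd_hat = _minimize_kd(series, curve_fn, kd_bounds)
    sse, coefs = _profile_sse(kd_hat, series, curve_fn)
    n_points = sum(s.metal_totals.size for s in series)
    n_params = 1 + 2 * len(series)
    dof = max(n_points - n_params, 1)
    residual_sd = float(np.sqrt(sse / dof))
    log_span = np.log10(kd_bounds[1] / kd_bounds[0])
    pinned = (abs(np.log10(kd_hat / kd_bounds[0])) < 1e-3 * log_span
              or abs(np.log10(kd_bounds[1] / kd_hat)) < 1e-3 * log_span)

    ci = None
    boots = None
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        fitted = [c[0] + c[1] * curve_fn(s.metal_totals, kd_hat)
                  for s, c in zip(series, coefs)]
        resids = [s.signals - f for s, f in zip(series, fitted)]
        pooled = np.concatenate(resids)
        boots = np.empty(bootstrap_n)
        for b in range(bootstrap_n):
            if bootstrap_over == "residuals":
                fake = [
                    TitrationSeries(s.replicate_id, s.metal_totals,
                                    f + rng.choice(pooled, size=f.size))
                    for s, f in zip(series, fitted)
                ]
            else:
                idx = rng.integers(0, len(series), size=len(series))
                fake = [series[i] for i in idx]
            boots[b] = _minimize_kd(fake, curve_fn, kd_bounds, hint=kd_hat)
        alpha = 0.5 * (1.0 - ci_level)
        lo_q, hi_q = np.quantile(boots, [alpha, 1.0 - alpha])
        # percentile CI; widened to include the point estimate if quantile
        # discreteness leaves it marginally outside
        ci = (float(min(lo_q, kd_hat)), float(max(hi_q, kd_hat)))

    nuis = {s.replicate_id: {"intercept": float(c[0]),
                             "slope_free_chelator": float(c[1])}
            for s, c in zip(series, coefs)}
    return FitResult(kd_estimate=float(kd_hat), confidence_interval=ci,
                     nuisances=nuis, residual_sd=residual_sd,
                     n_points=n_points, converged=True,
                     pinned_at_bounds=pinned, bootstrap_estimates=boots)


def fit_competition(series: list[TitrationSeries], chelator_total: float,
                    protein_total: float, kd_chelator: float, *,
                    bootstrap_n: int = 1000, seed: int = 0,
                    bootstrap_over: str = "residuals",
                    kd_bounds: tuple[float, float] = (1e-3, 1e6),
                    ci_level: float = 0.95) -> FitResult:
    """Global competition fit: one shared protein Kd across replicates,
    per-replicate response nuisances, chelator Kd held fixed (two-step
    procedure: the chelator is calibrated first by direct titration).

    The bootstrap (residual resampling by default, replicate resampling with
    ``bootstrap_over='replicates'``) is seeded and gives a percentile CI.
    """
    if not series:
        raise ValueError("need at least one titration series")
    if kd_chelator <= 0:
        raise ValueError("kd_chelator must be > 0")
    if bootstrap_over not in ("residuals", "replicates"):
        raise ValueError("bootstrap_over must be 'residuals' or 'replicates'")

    def curve_fn(metal_totals, kd_protein):
        return _free_chelator_curve(metal_totals, chelator_total,
                                    protein_total, kd_chelator, kd_protein)

    return _global_fit(series, curve_fn, kd_bounds, bootstrap_n, seed,
                       bootstrap_over, ci_level)


def fit_direct_quench(series: TitrationSeries | list[TitrationSeries],
                      chelator_total: float, *, bootstrap_n: int = 1000,
                      seed: int = 0,
                      kd_bounds: tuple[float, float] = (1e-3, 1e6),
                      ci_level: float = 0.95) -> FitResult:
    """Direct chelator-quench titration fit (no protein): estimates the
    chelator Kd with ligand depletion included, using the same speciation
    core and profile machinery as the competition fit at protein_total = 0.
    """
    if isinstance(series, TitrationSeries):
        series = [series]

    def curve_fn(metal_totals, kd_chelator):
        return _free_chelator_curve(metal_totals, chelator_total, 0.0,
                                    kd_chelator, 1.0)

    return _global_fit(series, curve_fn, kd_bounds, bootstrap_n, seed,
                       "residuals", ci_level)


def isotherm_fraction_bound(metal_totals, protein_total: float,
                            kd: float) -> np.ndarray:
    """Exact single-site fraction bound with ligand depletion:
    f = (P+M+Kd - sqrt((P+M+Kd)^2 - 4 P M)) / (2 P)."""
    m = np.asarray(metal_totals, dtype=float)
    p = protein_total
    if p <= 0:
        raise ValueError("protein_total must be > 0")
    s = p + m + kd
    disc = np.maximum(s * s - 4.0 * p * m, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * p)


def fit_isotherm_depletion(protein_total: float, metal_totals,
                           fraction_bound, *, bootstrap_n: int = 0,
                           seed: int = 0,
                           kd_bounds: tuple[float, float] = (1e-4, 1e6)
                           ) -> FitResult:
    """Fit Kd to a fraction-bound isotherm (e.g. 19F-NMR populations) with
    the exact ligand-depletion quadratic. Concentrations in any single
    consistent unit (the study's weak-site isotherm is in uM)."""
    m = np.asarray(metal_totals, dtype=float)
    f = np.asarray(fraction_bound, dtype=float)
    if m.shape != f.shape:
        raise ValueError("metal_totals and fraction_bound must match")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")

    def sse(log_kd):
        r = f - isotherm_fraction_bound(m, protein_total, 10.0 ** log_kd)
        return float(r @ r)

    lo, hi = np.log10(kd_bounds[0]), np.log10(kd_bounds[1])
    grid = np.linspace(lo, hi, 60)
    i = int(np.argmin([sse(g) for g in grid]))
    res = minimize_scalar(sse, bounds=(grid[max(i - 1, 0)],
                                       grid[min(i + 1, len(grid) - 1)]),
                          method="bounded", options={"xatol": 1e-9})
    kd_hat = 10.0 ** float(res.x)
    resid = f - isotherm_fraction_bound(m, protein_total, kd_hat)
    dof = max(f.size - 1, 1)

    ci = None
    boots = None
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        fitted = f - resid
        boots = np.empty(bootstrap_n)
        for b in range(bootstrap_n):
            fake = np.clip(fitted + rng.choice(resid, size=resid.size), 0, 1)
            g = np.linspace(lo, hi, 60)
            j = int(np.argmin([float(np.sum(
                (fake - isotherm_fraction_bound(m, protein_total,
                                                10.0 ** gg)) ** 2))
                for gg in g]))
            r2 = minimize_scalar(
                lambda gg: float(np.sum(
                    (fake - isotherm_fraction_bound(
                        m, protein_total, 10.0 ** gg)) ** 2)),
                bounds=(g[max(j - 1, 0)], g[min(j + 1, len(g) - 1)]),
                method="bounded", options={"xatol": 1e-9})
            boots[b] = 10.0 ** float(r2.x)
        lo_q, hi_q = np.quantile(boots, [0.025, 0.975])
        ci = (float(min(lo_q, kd_hat)), float(max(hi_q, kd_hat)))

    return FitResult(kd_estimate=kd_hat, confidence_interval=ci,
                     nuisances={}, residual_sd=float(np.sqrt(resid @ resid
                                                             / dof)),
                     n_points=int(f.size), converged=True,
                     bootstrap_estimates=boots)
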