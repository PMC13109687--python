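"""Förster-transfer predictions, label-site screening, and two-state
conformer classification.

The switch is expected to move a donor/acceptor label pair (EDANS/DABCYL,
Förster radius ~33 A) from a long open-state separation to a short
closed-state separation; the sixth-power Förster law converts those
distances into predicted transfer efficiencies. Because DABCYL is a dark
quencher, measured efficiency comes from donor quenching alone.

Candidate label sites are screened by regressing their pair distance against
the open/close reaction coordinate (the Bpy-Bpy N-N distance): a positive
slope means the pair distance tracks the motion and the pair can report it.

Catalytic-triad geometry (the S477 OG - H592 HE2 distance) is bimodal:
a 'near', catalysis-competent arrangement and a 'distant' one. The
classifier assigns samples to the two states by a distance threshold or a
two-Gaussian mixture fit and reports state populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FretPair", "ConformerEnsemble", "SiteScreenResult",
    "forster_efficiency", "efficiency_from_quench",
    "distance_from_efficiency", "site_pair_screen", "classify_conformers",
    "conformer_histogram",
]

#: Literature Förster radius (A) of the EDANS/DABCYL pair.
DEFAULT_FORSTER_RADIUS = 33.0


@dataclass
class FretPair:
    """A donor/acceptor label-site pair with predicted state distances."""

    donor_site: str
    acceptor_site: str
    distance_open: float
    distance_closed: float
    forster_radius: float = DEFAULT_FORSTER_RADIUS

    def __post_init__(self):
        if self.forster_radius <= 0:
            raise ValueError("forster_radius must be > 0")
        if self.distance_open <= 0 or self.distance_closed <= 0:
            raise ValueError("distances must be > 0")

    def predicted_efficiencies(self) -> dict:
        return {
            "open": forster_efficiency(self.distance_open,
                                       self.forster_radius),
            "closed": forster_efficiency(self.distance_closed,
                                         self.forster_radius),
        }


@dataclass
class ConformerEnsemble:
    """Scalar distance samples with optional known and assigned state labels.

    Label convention: state 0 is the component with the smaller mean
    ('near'), state 1 the larger ('distant').
    """

    distances: np.ndarray
    condition: str | None = None
    true_labels: np.ndarray | None = None
    assigned_labels: np.ndarray | None = None
    populations: np.ndarray | None = None
    classifier_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 1 or self.distances.size == 0:
            raise ValueError("distances must be a non-empty 1-D array")
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=float)
            if not np.isclose(self.populations.sum(), 1.0):
                raise ValueError("populations must sum to 1")

    @property
    def n(self) -> int:
        return int(self.distances.size)


@dataclass
class SiteScreenResult:
    pair: tuple[str, str]
    slope: float
    intercept: float
    correlation: float
    slope_stderr: float
    suitable: bool


def forster_efficiency(r, forster_radius: float = DEFAULT_FORSTER_RADIUS):
    """Transfer efficiency E = 1 / (1 + (r/R0)^6)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or forster_radius <= 0:
        raise ValueError("distance and Förster radius must be > 0")
    out = 1.0 / (1.0 + (r / forster_radius) ** 6)
    return float(out) if out.ndim == 0 else out


def efficiency_from_quench(f_da: float, f_d: float) -> float:
    """Donor-quenching estimator E = 1 - F_DA/F_D.

    F_D is the donor-only emission, F_DA the donor emission with the (dark)
    acceptor present. Values outside [0, F_D] warn rather than fail, since
    noisy spectra can stray slightly.
    """
    if f_d <= 0:
        raise ValueError("donor-only intensity must be > 0")
    if not (0.0 <= f_da <= f_d):
        import warnings
        warnings.warn("F_DA outside [0, F_D]; efficiency outside [0, 1]",
                      stacklevel=2)
    return 1.0 - f_da / f_d


def distance_from_efficiency(e: float,
                             forster_radius: float = DEFAULT_FORSTER_RADIUS
                             ) -> float:
    """Invert the Förster law: r = R0 * ((1-E)/E)^(1/6)."""
    if not (0.0 < e < 1.0):
        raise ValueError("efficiency must lie strictly in (0, 1)")
    return forster_radius * ((1.0 - e) / e) ** (1.0 / 6.0)


def site_pair_screen(reaction_coordinate, pair_distance,
                     pair=("site_a", "site_b")) -> SiteScreenResult:
    """Least-squares screen of a candidate label pair against the open/close
    coordinate; a positive slope marks the pair as a suitable reporter."""
    x = np.asarray(reaction_coordinate, dtype=float)
    y = np.asarray(pair_distance, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    fit = stats.linregress(x, y)
    return SiteScreenResult(pair=tuple(pair), slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            correlation=float(fit.rvalue),
                            slope_stderr=float(fit.stderr),
                            suitable=fit.slope > 0)


def _order_by_mean(labels: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Relabel so state 0 has the smaller mean."""
    order = np.argsort(means)
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    return remap[labels]


def classify_conformers(ensemble: ConformerEnsemble,
                        method: str = "mixture", *, cut: float | None = None,
                        seed: int = 0) -> ConformerEnsemble:
    """Assign near/distant states and populations.

    method='threshold' cuts at ``cut`` A (required). method='mixture' fits a
    two-Gaussian model by EM and assigns by posterior; if the components
    collapse (means closer than twice the smaller sd, or a vanishing weight)
    the fit is flagged degenerate and the classifier falls back to a
    threshold at the sample mean.
    """
    d = ensemble.distances
    if d.size < 10:
        raise ValueError("need at least 10 samples to classify")
    info = {"method": method, "degenerate": False}

    if method == "threshold":
        if cut is None:
            raise ValueError("threshold method requires a cut distance")
        labels = (d >= cut).astype(int)
        info["cut"] = float(cut)
    elif method == "mixture":
        from sklearn.mixture import GaussianMixture
        gm = GaussianMixture(n_components=2, n_init=3, random_state=seed)
        labels_raw = gm.fit_predict(d[:, None])
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.ravel()
        # a single mode fitted by two components leaves them overlapping
        # (separation < ~1.5 sd); true bimodality separates them by several
        degenerate = (abs(means[0] - means[1]) < 2.0 * sds.min()
                      or weights.min() < 0.02)
        if degenerate:
            info["degenerate"] = True
            fallback = float(cut) if cut is not None else float(d.mean())
            info["cut"] = fallback
            labels = (d >= fallback).astype(int)
        else:
            labels = _order_by_mean(labels_raw, means)
            order = np.argsort(means)
            info.update(means=means[order].tolist(),
                        sds=sds[order].tolist(),
                        weights=weights[order].tolist())
    else:
        raise ValueError(f"unknown method {method!r}")

    pops = np.array([(labels == 0).mean(), (labels == 1).mean()])
    return ConformerEnsemble(distances=d, condition=ensemble.condition,
                             true_labels=ensemble.true_labels,
                             assigned_labels=labels, populations=pops,
                             classifier_info=info)


def conformer_histogram(ensemble: ConformerEnsemble,
                        bin_width: float = 0.2) -> dict:
    """Fixed-bin-width histogram of the distance samples.

    Returns bin centers and counts; counts sum exactly to the sample size.
    """
    d = ensemble.distances
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return {"bin_centers": 0.5 * (edges[:-1] + edges[1:]),
            "counts": counts, "condition": ensemble.condition}
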