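"""Summary statistics of simulation runs.

Covers the localization analysis of the high-energy gamma imaging study:
1D slice/projection profiles of production and annihilation coordinates,
the Lorentzian-plus-exponential profile fit and its FWHM, positron
kinetic-energy and range statistics, first-interaction channel fractions
(with an analytic direction-integration oracle for homogeneous cubes),
and the per-material pair-production efficiency in a central region of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import nucdata
from .transport import (
    CHANNEL_COMPTON,
    CHANNEL_NONE,
    CHANNEL_PAIR,
    CHANNEL_PHOTOELECTRIC,
    EventLog,
)

__all__ = [
    "ProfileHistogram",
    "ProfileFit",
    "PositronStats",
    "EfficiencySummary",
    "slice_profile",
    "fit_profile",
    "positron_stats",
    "interaction_fractions",
    "first_interaction_oracle",
    "pair_efficiency",
    "efficiency_table",
]


@dataclass
class ProfileHistogram:
    """1D histogram of an event coordinate within a slab or projection."""

    edges: np.ndarray  # mm, strictly increasing
    counts: np.ndarray
    axis: int | None = 0  # None = pooled over all axes
    half_thickness_mm: float | None = None  # None = projection mode
    normalized: bool = False

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def peak_normalized(self) -> "ProfileHistogram":
        peak = self.counts.max()
        if peak == 0:
            raise ValueError("cannot normalize an empty profile")
        return ProfileHistogram(
            self.edges, self.counts / peak, self.axis, self.half_thickness_mm, True
        )

    def raw_fwhm(self) -> float:
        """Half-max crossing width of the raw histogram (linear interp)."""
        c = self.counts
        x = self.centers
        half = c.max() / 2.0
        above = np.flatnonzero(c >= half)
        if len(above) == 0:
            return 0.0
        i0, i1 = above[0], above[-1]
        left = x[i0]
        if i0 > 0:
            left = np.interp(half, [c[i0 - 1], c[i0]], [x[i0 - 1], x[i0]])
        right = x[i1]
        if i1 < len(c) - 1:
            right = np.interp(half, [c[i1 + 1], c[i1]], [x[i1 + 1], x[i1]])
        return float(right - left)


@dataclass
class ProfileFit:
    """Parameters of f(x) = A [1 + (x/sigma)^2]^-1 + B exp(-C |x|).

    ``fwhm_mm`` is 2*sigma, the FWHM of the Lorentzian component (the
    exponential term plays the role of a broad background);
    ``fwhm_total_mm`` is the numeric half-max width of the full fitted
    curve, reported for transparency.
    """

    A: float
    sigma_mm: float
    B: float
    C_per_mm: float
    fwhm_mm: float
    fwhm_total_mm: float
    rss: float
    converged: bool = True

    def __call__(self, x):
        return profile_model(np.asarray(x, dtype=float), self.A, self.sigma_mm,
                             self.B, self.C_per_mm)


def profile_model(x, a, sigma, b, c):
    """Lorentzian with exponential background."""
    return a / (1.0 + (x / sigma) ** 2) + b * np.exp(-c * np.abs(x))


def slice_profile(
    positions: np.ndarray,
    axis: int | None = 0,
    half_thickness_mm: float | None = 0.5,
    bin_width_mm: float = 0.25,
    extent_mm: float | None = None,
    normalize: bool = False,
) -> ProfileHistogram:
    """Histogram one coordinate of event positions within a central slab.

    With ``half_thickness_mm`` set, only events whose two other
    coordinates both lie within the slab are kept (slice mode); ``None``
    aggregates the whole volume (projection mode, which broadens the
    displayed profile).  ``axis=None`` pools the three coordinate axes
    into one profile -- for a source that is isotropic about the origin
    the axes are statistically equivalent, so pooling only reduces
    variance.  Bins are centered on zero.
    """
    p = np.atleast_2d(np.asarray(positions, dtype=float))
    if p.shape[0] == 0:
        raise ValueError("no events supplied")
    axes = range(p.shape[1]) if axis is None else [axis]
    coords = []
    for ax in axes:
        coord = p[:, ax]
        if half_thickness_mm is not None:
            others = [i for i in range(p.shape[1]) if i != ax]
            keep = np.all(np.abs(p[:, others]) <= half_thickness_mm, axis=1)
            coord = coord[keep]
        coords.append(coord)
    coord = np.concatenate(coords)
    if half_thickness_mm is not None and coord.size == 0:
        raise ValueError(
            "no events inside the slab; widen it or use projection mode "
            "(half_thickness_mm=None)"
        )
    if extent_mm is None:
        extent_mm = float(np.max(np.abs(coord))) + bin_width_mm
    nbins = max(1, int(np.ceil(extent_mm / bin_width_mm)))
    edges = (np.arange(-nbins, nbins + 1) + 0.5) * bin_width_mm  # zero-centered bin
    counts, _ = np.histogram(coord, bins=edges)
    hist = ProfileHistogram(edges, counts.astype(float), axis, half_thickness_mm)
    return hist.peak_normalized() if normalize else hist


def fit_profile(hist: ProfileHistogram) -> ProfileFit:
    """Nonlinear least-squares fit of the Lorentzian + exponential model.

    The profile is peak-normalized and fitted by ordinary least squares
    over the full histogram, so the many tail bins pin the exponential
    background and the Lorentzian describes the core.  Initialization
    from the raw histogram: sigma0 = half the raw half-max width, A0 =
    peak, B0 = 10% of peak, C0 = 1/(5 sigma0).  All parameters are
    constrained nonnegative; the reported FWHM is 2 sigma.
    """
    if np.count_nonzero(hist.counts) < 10:
        raise ValueError("need at least 10 occupied bins to fit a profile")
    h = hist.peak_normalized()
    x, y = h.centers, h.counts
    if np.ptp(y) == 0:
        raise ValueError("degenerate flat profile")
    sigma0 = max(hist.raw_fwhm() / 2.0, np.diff(h.edges).min() / 2.0)
    p0 = [1.0, sigma0, 0.1, 1.0 / (5.0 * sigma0)]
    try:
        popt, _ = optimize.curve_fit(
            profile_model,
            x,
            y,
            p0=p0,
            bounds=([0, 1e-9, 0, 0], [np.inf] * 4),
            maxfev=20000,
        )
        converged = True
    except RuntimeError as err:
        raise RuntimeError(f"profile fit did not converge (p0={p0})") from err
    a, sigma, b, c = (float(v) for v in popt)
    resid = y - profile_model(x, *popt)
    # numeric FWHM of the total fitted curve
    xs = np.linspace(0, x.max() if x.max() > 0 else 10 * sigma, 20001)
    ys = profile_model(xs, *popt)
    peak = profile_model(0.0, *popt)
    below = np.flatnonzero(ys <= peak / 2.0)
    fwhm_total = 2.0 * float(xs[below[0]]) if len(below) else float("inf")
    return ProfileFit(
        A=a,
        sigma_mm=sigma,
        B=b,
        C_per_mm=c,
        fwhm_mm=2.0 * sigma,
        fwhm_total_mm=fwhm_total,
        rss=float(np.sum(resid**2)),
        converged=converged,
    )


@dataclass
class PositronStats:
    """Positron kinetic-energy and range summary of a run."""

    mean_ke_mev: float
    ke_symmetry_center_mev: float
    mean_range_mm: float
    range_percentiles_mm: dict[float, float]
    n_pairs: int
    n_annihilations: int


def positron_stats(log: EventLog, min_events: int = 100) -> PositronStats:
    """Kinetic-energy and displacement statistics of the positron sample.

    The symmetry center is (T+ + T-)/2 averaged over pair events (equal
    to (E_gamma - 1.022 MeV)/2 for a monoenergetic source); displacement
    percentiles 50/90/99/99.9 characterize the range distribution, the
    99.9th serving as a stable surrogate for the distribution end-point.
    """
    if log.n_pairs < min_events:
        raise ValueError(
            f"need >= {min_events} pair events, got {log.n_pairs}"
        )
    ranges = np.linalg.norm(log.positron_range_vectors, axis=1)
    pct = {q: float(np.percentile(ranges, q)) for q in (50.0, 90.0, 99.0, 99.9)}
    return PositronStats(
        mean_ke_mev=float(log.pair_t_plus.mean()),
        ke_symmetry_center_mev=float(
            (log.pair_t_plus + log.pair_t_minus).mean() / 2.0
        ),
        mean_range_mm=float(ranges.mean()) if len(ranges) else 0.0,
        range_percentiles_mm=pct,
        n_pairs=log.n_pairs,
        n_annihilations=log.n_annihilations,
    )


def interaction_fractions(log: EventLog) -> dict[str, float]:
    """First-interaction channel fractions over primaries (sum to 1)."""
    n = log.n_primaries
    if n == 0:
        return {"none": 0.0, "photoelectric": 0.0, "compton": 0.0, "pair": 0.0}
    ch = log.first_channel
    return {
        "none": float(np.sum(ch == CHANNEL_NONE)) / n,
        "photoelectric": float(np.sum(ch == CHANNEL_PHOTOELECTRIC)) / n,
        "compton": float(np.sum(ch == CHANNEL_COMPTON)) / n,
        "pair": float(np.sum(ch == CHANNEL_PAIR)) / n,
    }


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic near-uniform directions on the sphere."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def first_interaction_oracle(
    side_mm: float,
    material: str = "water",
    energy_mev: float = 2.617,
    n_directions: int = 10_000,
) -> dict[str, float]:
    """Analytic first-interaction fractions for a centered cube source.

    Integrates 1 - exp(-mu s(omega)) over directions (s is the distance
    from the cube center to its surface) and splits interactions by
    channel with mu_i / mu_total.  Serves as an independent check on the
    Monte Carlo interaction budget.
    """
    mu_pe, mu_c, mu_pp = nucdata.get_coefficients(material, energy_mev)
    mu_tot = mu_pe + mu_c + mu_pp
    dirs = _fibonacci_directions(n_directions)
    s_mm = (side_mm / 2.0) / np.abs(dirs).max(axis=1)
    p_none = float(np.mean(np.exp(-mu_tot * s_mm / 10.0)))
    p_int = 1.0 - p_none
    return {
        "none": p_none,
        "photoelectric": p_int * mu_pe / mu_tot,
        "compton": p_int * mu_c / mu_tot,
        "pair": p_int * mu_pp / mu_tot,
    }


@dataclass
class EfficiencySummary:
    """Production/annihilation events per primary inside a centered cube."""

    roi_side_mm: float
    production_efficiency: float
    annihilation_efficiency: float
    n_primaries: int


def pair_efficiency(
    log: EventLog, roi_side_mm: float = 10.0, grid=None
) -> EfficiencySummary:
    """Count pair-production and annihilation events in the central ROI.

    The region of interest is a cube of ``roi_side_mm`` centered on the
    source; efficiencies are events per primary.  Pass the phantom grid
    to validate that the ROI fits inside it.
    """
    if grid is not None and np.any(roi_side_mm / 2.0 > grid.extent):
        raise ValueError("ROI larger than the phantom")
    half = roi_side_mm / 2.0
    in_roi_p = np.all(np.abs(log.pair_r_p) <= half, axis=1) if log.n_pairs else []
    in_roi_a = (
        np.all(np.abs(log.ann_r_a) <= half, axis=1) if log.n_annihilations else []
    )
    return EfficiencySummary(
        roi_side_mm=roi_side_mm,
        production_efficiency=float(np.sum(in_roi_p)) / log.n_primaries,
        annihilation_efficiency=float(np.sum(in_roi_a)) / log.n_primaries,
        n_primaries=log.n_primaries,
    )


def efficiency_table(
    logs: dict[str, EventLog], roi_side_mm: float = 10.0
):
    """Per-material efficiency summary with ratios relative to water.

    Returns a pandas DataFrame indexed by material with production and
    annihilation efficiencies and their ratios to the water row (when a
    ``water`` entry is present).
    """
    import pandas as pd

    rows = {}
    for name, log in logs.items():
        s = pair_efficiency(log, roi_side_mm)
        rows[name] = {
            "production_efficiency": s.production_efficiency,
            "annihilation_efficiency": s.annihilation_efficiency,
            "n_primaries": s.n_primaries,
        }
    df = pd.DataFrame(rows).T
    if "water" in df.index:
        ref = df.loc["water", "production_efficiency"]
        if ref > 0:
            df["production_ratio_to_water"] = df["production_efficiency"] / ref
        ref_a = df.loc["water", "annihilation_efficiency"]
        if ref_a > 0:
            df["annihilation_ratio_to_water"] = df["annihilation_efficiency"] / ref_a
    return df
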