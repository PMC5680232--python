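"""Experimental-style data analysis: tensile-curve cohorts and FTIR spectra.

Tensile curves from fiber tests are grouped into five cross-section-area
(CSA) sorts — the categories produced by reeling the fiber at different
speeds; faster reeling gives thinner fibers — and each sort is summarized
as mean +/- sd of modulus and toughness.

Infrared spectra are analyzed by amide-I band deconvolution: the spectrum
is normalized at the 1450 cm^-1 methyl band (conformation-insensitive),
component centers are located as minima of the Savitzky-Golay second
derivative inside the amide-I window (1595-1705 cm^-1) and then *fixed*,
and Gaussian amplitudes/widths are fitted by bounded least squares.  The
beta-sheet fraction is the area share of components whose centers fall in
the standard beta ranges (1600-1640 and 1690-1705 cm^-1 by default;
overridable).  The deconvolution is exposed statsmodels-style:
``AmideIModel(spectrum).fit() -> AmideIResults`` with a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter, find_peaks

from .mechanics import StressStrainCurve, MechanicalSummary, summarize_curve

__all__ = [
    "CsaSortScheme",
    "sort_curves",
    "FTIRSpectrum",
    "second_derivative_peaks",
    "AmideIModel",
    "AmideIResults",
    "fit_amide_I",
    "dichroic_ratio",
    "BETA_RANGES",
    "AMIDE_I_WINDOW",
    "PeakPickError",
]

AMIDE_I_WINDOW = (1595.0, 1705.0)
#: standard amide-I assignment ranges (cm^-1) by component center
BETA_RANGES = ((1600.0, 1640.0), (1690.0, 1705.0))
ASSIGNMENTS = (
    ("beta-sheet", BETA_RANGES),
    ("random coil/helix", ((1640.0, 1662.0),)),
    ("turn", ((1662.0, 1690.0),)),
)


# ---------------------------------------------------------------------------
# CSA sorting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CsaSortScheme:
    """Five CSA categories (mm^2): center +/- sd, assignment by nearest center.

    Ties break toward the smaller center.
    """

    centers: tuple = (0.002, 0.007, 0.014, 0.018, 0.024)
    sds: tuple = (0.001, 0.001, 0.003, 0.002, 0.003)

    def __post_init__(self):
        if list(self.centers) != sorted(self.centers):
            raise ValueError("sort centers must increase strictly")

    def assign(self, csa: float) -> int:
        """1-based sort label for a positive CSA."""
        if not csa > 0:
            raise ValueError("CSA must be positive")
        d = [abs(csa - c) for c in self.centers]
        return int(np.argmin(d)) + 1   # argmin takes the first (smaller) on ties


def sort_curves(curves: list[StressStrainCurve],
                scheme: CsaSortScheme | None = None,
                fit_window=None) -> dict:
    """Per-sort aggregates (mean +/- sd of modulus and toughness).

    Returns ``{sort_label: {"n": ..., "modulus_mean": ..., ...,
    "summaries": [...]}}`` for the non-empty sorts.
    """
    if not curves:
        raise ValueError("no curves supplied")
    scheme = scheme or CsaSortScheme()
    kw = {"fit_window": fit_window} if fit_window else {}
    by_sort: dict[int, list[MechanicalSummary]] = {}
    for c in curves:
        if not np.isfinite(c.nominal_csa) or c.nominal_csa <= 0:
            raise ValueError("every curve must carry a positive CSA")
        by_sort.setdefault(scheme.assign(c.nominal_csa), []).append(
            summarize_curve(c, **kw))
    out = {}
    for label in sorted(by_sort):
        rows = by_sort[label]
        agg = MechanicalSummary.aggregate(rows)
        agg["summaries"] = rows
        agg["center_csa"] = scheme.centers[label - 1]
        out[label] = agg
    return out


# ---------------------------------------------------------------------------
# FTIR
# ---------------------------------------------------------------------------

class PeakPickError(RuntimeError):
    pass


@dataclass
class FTIRSpectrum:
    """Absorbance spectrum; stored ascending in wavenumber.

    ``normalize()`` scales by the absorbance at the 1450 cm^-1 methyl
    reference band when the grid covers it.
    """

    wavenumber: np.ndarray
    absorbance: np.ndarray
    normalization_anchor: float = 1450.0

    def __post_init__(self):
        w = np.asarray(self.wavenumber, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.shape != a.shape or w.ndim != 1 or len(w) < 9:
            raise ValueError("need matching 1D wavenumber/absorbance arrays")
        if not (np.isfinite(w).all() and np.isfinite(a).all()):
            raise ValueError("spectrum must be finite")
        order = np.argsort(w)
        self.wavenumber, self.absorbance = w[order], a[order]

    def covers(self, window=AMIDE_I_WINDOW) -> bool:
        return self.wavenumber[0] <= window[0] and self.wavenumber[-1] >= window[1]

    def normalize(self) -> "FTIRSpectrum":
        if not (self.wavenumber[0] <= self.normalization_anchor
                <= self.wavenumber[-1]):
            return self
        ref = float(np.interp(self.normalization_anchor, self.wavenumber,
                              self.absorbance))
        if ref <= 0:
            return self
        return FTIRSpectrum(self.wavenumber, self.absorbance / ref,
                            self.normalization_anchor)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("wavenumber_cm-1,absorbance\n")
            for w, a in zip(self.wavenumber, self.absorbance):
                fh.write(f"{w:.6g},{a:.8g}\n")

    @classmethod
    def from_csv(cls, path) -> "FTIRSpectrum":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(wavenumber=arr[:, 0], absorbance=arr[:, 1])


def second_derivative_peaks(spectrum: FTIRSpectrum, window=AMIDE_I_WINDOW,
                            sg_window: int = 21, sg_order: int = 3,
                            prominence_frac: float = 0.05) -> np.ndarray:
    """Component centers: minima of the smoothed second derivative.

    Centers are local minima of the Savitzky-Golay second derivative with
    prominence at least ``prominence_frac`` of the strongest minimum,
    restricted to ``window``.  Raises :class:`PeakPickError` when nothing
    qualifies (e.g. pure noise below the prominence floor).
    """
    if not spectrum.covers(window):
        raise ValueError(f"spectrum does not cover the amide-I window {window}")
    w, a = spectrum.wavenumber, spectrum.absorbance
    if len(w) <= sg_window:
        raise ValueError("spectrum too short for the smoothing window")
    dw = float(np.median(np.diff(w)))
    # a band is only analyzable when it stands clear of the grid noise
    noise = float(np.std(np.diff(a))) / math.sqrt(2.0)
    wm = (w >= window[0]) & (w <= window[1])
    if a[wm].max() - np.median(a[wm]) < 10.0 * noise:
        raise PeakPickError("amide-I band indistinguishable from noise")
    d2 = savgol_filter(a, sg_window, sg_order, deriv=2, delta=dw)
    neg = -d2
    floor = prominence_frac * float(neg.max()) if neg.max() > 0 else np.inf
    idx, _ = find_peaks(neg, prominence=max(floor, 1e-300))
    idx = idx[(w[idx] >= window[0]) & (w[idx] <= window[1]) & (d2[idx] < 0)]
    # discard shoulders whose band absorbance is negligible
    idx = idx[a[idx] > 0.02 * a[(w >= window[0]) & (w <= window[1])].max()]
    if len(idx) == 0:
        raise PeakPickError("no second-derivative minima found in the amide-I window")
    # sub-grid refinement: parabola through the minimum and its neighbors
    centers = []
    for i in idx:
        if 0 < i < len(w) - 1:
            y0, y1, y2 = d2[i - 1], d2[i], d2[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if abs(denom) > 0 else 0.0
            centers.append(w[i] + np.clip(shift, -1.0, 1.0) * dw)
        else:
            centers.append(w[i])
    return np.asarray(centers)


def _gaussian(w, amp, center, sd):
    return amp * np.exp(-0.5 * ((w - center) / sd) ** 2)


@dataclass
class AmideIResults:
    """Fitted amide-I decomposition."""

    centers: np.ndarray
    amplitudes: np.ndarray
    widths: np.ndarray            # Gaussian sd, cm^-1
    areas: np.ndarray
    assignments: list
    beta_fraction: float          # percent
    residual_fraction: float      # residual norm / band area on the window
    flagged: bool                 # True when the residual exceeds the threshold
    window: tuple = AMIDE_I_WINDOW

    def components(self, w):
        return np.stack([_gaussian(w, a, c, s) for a, c, s in
                         zip(self.amplitudes, self.centers, self.widths)])

    def summary(self) -> str:
        lines = ["Amide-I deconvolution",
                 "=" * 54,
                 f"{'center':>8} {'width':>7} {'area':>9} {'share%':>7}  assignment"]
        tot = self.areas.sum()
        for c, s, ar, asg in zip(self.centers, self.widths, self.areas,
                                 self.assignments):
            lines.append(f"{c:8.1f} {s:7.2f} {ar:9.4f} {100 * ar / tot:7.1f}  {asg}")
        lines.append("-" * 54)
        lines.append(f"beta-sheet fraction: {self.beta_fraction:.1f} %")
        lines.append(f"residual: {100 * self.residual_fraction:.2f} % of band area"
                     + ("  [FLAGGED]" if self.flagged else ""))
        return "\n".join(lines)


def assign_center(center: float) -> str:
    for name, ranges in ASSIGNMENTS:
        if any(lo <= center <= hi for lo, hi in ranges):
            return name
    return "side chain"


class AmideIModel:
    """Gaussian band model of the amide-I region with fixed centers.

    Parameters
    ----------
    spectrum : FTIRSpectrum
    centers : array-like, optional
        Fixed component centers; located from the second derivative when
        omitted.
    beta_ranges : tuple of (lo, hi), optional
        Assignment ranges for the beta-sheet class.
    """

    def __init__(self, spectrum: FTIRSpectrum, centers=None,
                 beta_ranges=BETA_RANGES, window=AMIDE_I_WINDOW,
                 normalize: bool = True):
        self.spectrum = spectrum.normalize() if normalize else spectrum
        self.window = window
        self.beta_ranges = beta_ranges
        if centers is None:
            centers = second_derivative_peaks(self.spectrum, window=window)
        self.centers = np.sort(np.asarray(centers, dtype=float))
        if len(self.centers) == 0:
            raise ValueError("need at least one fixed center")

    def fit(self, width_bounds=(3.0, 25.0), residual_threshold=0.05,
            center_slack: float = 2.0) -> AmideIResults:
        """Bounded least squares over amplitudes (>= 0), widths and centers.

        The component *set* and nominal positions come from the second
        derivative and stay fixed; ``center_slack`` (cm^-1) permits a small
        bounded numerical refinement of each center during the fit (0
        pins them exactly).  A residual above ``residual_threshold`` of
        the band area flags the result rather than failing silently.
        """
        w_all, a_all = self.spectrum.wavenumber, self.spectrum.absorbance
        m = (w_all >= self.window[0]) & (w_all <= self.window[1])
        w, a = w_all[m], a_all[m]
        k = len(self.centers)
        slack = max(center_slack, 1e-9)

        def model(theta):
            amps, sds, cens = theta[:k], theta[k:2 * k], theta[2 * k:]
            return sum(_gaussian(w, amps[i], cens[i], sds[i])
                       for i in range(k))

        amp0 = np.clip(np.interp(self.centers, w, a), 1e-6, None)
        x0 = np.concatenate([amp0, np.full(k, 10.0), self.centers])
        lo = np.concatenate([np.zeros(k), np.full(k, width_bounds[0]),
                             self.centers - slack])
        hi = np.concatenate([np.full(k, max(2.0 * a.max(), 1e-3)),
                             np.full(k, width_bounds[1]),
                             self.centers + slack])
        sol = least_squares(lambda t: model(t) - a, x0, bounds=(lo, hi))
        amps, sds = sol.x[:k], sol.x[k:2 * k]
        fitted_centers = sol.x[2 * k:]
        areas = amps * sds * math.sqrt(2.0 * math.pi)
        assignments = []
        for c in fitted_centers:
            if any(lo_ <= c <= hi_ for lo_, hi_ in self.beta_ranges):
                assignments.append("beta-sheet")
            else:
                assignments.append(assign_center(c))
        beta_area = sum(ar for ar, asg in zip(areas, assignments)
                        if asg == "beta-sheet")
        total = areas.sum()
        beta_fraction = 100.0 * beta_area / total if total > 0 else 0.0
        band_area = float(np.trapezoid(a, w))
        resid = float(np.trapezoid(np.abs(model(sol.x) - a), w))
        resid_frac = resid / band_area if band_area > 0 else np.inf
        return AmideIResults(
            centers=fitted_centers, amplitudes=amps, widths=sds, areas=areas,
            assignments=assignments, beta_fraction=float(beta_fraction),
            residual_fraction=resid_frac,
            flagged=resid_frac > residual_threshold, window=self.window)


def fit_amide_I(spectrum: FTIRSpectrum, centers=None, **kw) -> AmideIResults:
    """Functional wrapper around :class:`AmideIModel`."""
    return AmideIModel(spectrum, centers=centers).fit(**kw)


def dichroic_ratio(parallel: FTIRSpectrum, perpendicular: FTIRSpectrum,
                   band: float = 1620.0) -> float:
    """A_parallel / A_perpendicular at a stated band, on normalized spectra."""
    p, q = parallel.normalize(), perpendicular.normalize()
    ap = float(np.interp(band, p.wavenumber, p.absorbance))
    aq = float(np.interp(band, q.wavenumber, q.absorbance))
    if aq <= 0:
        raise ValueError("perpendicular absorbance non-positive at the band")
    return ap / aq
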