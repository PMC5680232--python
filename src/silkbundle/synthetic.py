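"""Ground-truth generators for every analysis stage.

Nothing here is measured data: these generators emulate the *shape* of
fiber tensile tests and amide-I spectra with exactly known summary
statistics, so the analysis operations can be validated by round-trip
recovery.  All generators are deterministic under (spec, seed) and attach
their truth records.

Tensile curves are piecewise linear-plateau: a linear rise at the target
modulus to a yield strain, a flat plateau, and an instant break placed so
the area under the curve equals the target toughness exactly.  Cohort
defaults follow the five CSA sorts of the tensile study: modulus falling
from 11 to 8 GPa and toughness rising from 2 to 14 MJ m^-3 as the CSA
grows from 0.002 to 0.024 mm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .experiment import CsaSortScheme, FTIRSpectrum, _gaussian
from .geometry import BundleGeometry, pack_bundle_n, insert_defects
from .mechanics import StressStrainCurve

__all__ = [
    "gen_bundle_fixture",
    "gen_tensile_curve",
    "SyntheticCohortSpec",
    "gen_cohort",
    "gen_ftir_spectrum",
    "DEFAULT_PEAK_LAYOUT",
]


def gen_bundle_fixture(n_fibrils: int = 7, n_beads: int = 20,
                       defect_rate: float = 0.0, seed: int = 0,
                       sigma: float = 10.0, spacing: float = 7.1) -> BundleGeometry:
    """Miniature bundle exercising every topology feature.

    The default 7 x 20 bundle has an interior fibril with six lattice
    neighbors, both boundary types, and (optionally) defects.
    """
    bundle = pack_bundle_n(n_fibrils, sigma=sigma, spacing=spacing,
                           n_beads=n_beads)
    if defect_rate:
        insert_defects(bundle, defect_rate, seed=seed)
    return bundle


def gen_tensile_curve(modulus_gpa: float, toughness_mj_m3: float,
                      csa: float = 0.002, yield_strain: float = 0.01,
                      noise_sd: float = 0.0, break_jitter: float = 0.0,
                      seed: int = 0, d_eps: float = 1e-4) -> StressStrainCurve:
    """Linear rise + plateau + instant break, with exact target statistics.

    At zero noise the analyzed modulus equals ``modulus_gpa`` exactly and
    the trapezoidal toughness equals ``toughness_mj_m3`` up to grid error
    (< 0.5%).  ``noise_sd`` applies multiplicative stress noise;
    ``break_jitter`` scales the plateau length by ``1 + jitter * N(0,1)``.
    The truth record is attached as ``curve.truth``.
    """
    if modulus_gpa <= 0 or toughness_mj_m3 <= 0:
        raise ValueError("targets must be positive")
    rng = np.random.default_rng(seed)
    e_mod = modulus_gpa * 1e3                   # MPa per strain
    sigma_y = e_mod * yield_strain
    rise_area = 0.5 * sigma_y * yield_strain
    if toughness_mj_m3 <= rise_area:
        # brittle target: pure linear rise, break before yield
        eps_b = math.sqrt(2.0 * toughness_mj_m3 / e_mod)
        plateau = False
    else:
        eps_b = yield_strain + (toughness_mj_m3 - rise_area) / sigma_y
        plateau = True
    if break_jitter:
        eps_b *= max(0.1, 1.0 + break_jitter * rng.standard_normal())
    # grid with exact knots
    knots = [0.0, eps_b] + ([yield_strain] if plateau else [])
    eps = np.unique(np.concatenate([np.arange(0.0, eps_b, d_eps), knots]))
    stress = np.where(eps <= (yield_strain if plateau else eps_b),
                      e_mod * eps, sigma_y)
    # instant break: one extra sample at ~zero stress
    eps = np.append(eps, eps_b + d_eps * 1e-3)
    stress = np.append(stress, 0.0)
    if noise_sd:
        # leave the small-strain fit region noise-free in relative terms:
        # multiplicative noise preserves the zero-intercept linearity
        stress = stress * (1.0 + noise_sd * rng.standard_normal(len(stress)))
        stress = np.clip(stress, 0.0, None)
    curve = StressStrainCurve(strain=eps, stress=stress, nominal_csa=csa,
                              source="synthetic")
    curve.truth = {"modulus_gpa": modulus_gpa,
                   "toughness_mj_m3": toughness_mj_m3,
                   "break_strain": eps_b}
    return curve


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Per-sort targets for an experimental-style tensile cohort.

    Defaults mirror the five-sort tensile study: CSA centers/sds from the
    sort scheme, modulus means interpolating 11 -> 8 GPa and toughness
    2 -> 14 MJ m^-3 across the sorts, with the reported spreads.
    """

    scheme: CsaSortScheme = field(default_factory=CsaSortScheme)
    modulus_mean: tuple = (11.0, 10.0, 9.0, 8.5, 8.0)     # GPa
    modulus_sd: tuple = (4.0, 3.0, 2.0, 1.5, 1.0)
    toughness_mean: tuple = (2.0, 5.0, 9.0, 12.0, 14.0)   # MJ m^-3
    toughness_sd: tuple = (2.0, 4.0, 6.0, 8.0, 9.0)
    n_per_sort: int = 10
    noise_sd: float = 0.02
    break_jitter: float = 0.05

    def __post_init__(self):
        if self.n_per_sort < 1:
            raise ValueError("need at least one curve per sort")


def gen_cohort(spec: SyntheticCohortSpec | None = None, seed: int = 0):
    """Curves for all five sorts; returns (curves, truth dict per sort)."""
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(seed)
    curves, truth = [], {}
    for s, center in enumerate(spec.scheme.centers):
        truth[s + 1] = {"modulus_gpa": spec.modulus_mean[s],
                        "toughness_mj_m3": spec.toughness_mean[s],
                        "csa": center}
        for k in range(spec.n_per_sort):
            # truncated draws keep targets positive and CSA inside its sort
            mod = -1.0
            while mod <= 0.5:
                mod = spec.modulus_mean[s] + spec.modulus_sd[s] * rng.standard_normal()
            tough = -1.0
            while tough <= 0.1:
                tough = (spec.toughness_mean[s]
                         + spec.toughness_sd[s] * rng.standard_normal())
            csa = -1.0
            while not (0 < csa) or spec.scheme.assign(max(csa, 1e-9)) != s + 1:
                csa = center + spec.scheme.sds[s] * rng.standard_normal()
            curves.append(gen_tensile_curve(
                mod, tough, csa=csa, noise_sd=spec.noise_sd,
                break_jitter=spec.break_jitter,
                seed=int(rng.integers(2**31 - 1))))
    return curves, truth


#: (center cm^-1, Gaussian sd cm^-1, class) — well-separated three-component
#: layout; the beta component sits in the low beta range, the coil and turn
#: components in their standard ranges.
DEFAULT_PEAK_LAYOUT = (
    (1620.0, 11.0, "beta-sheet"),
    (1652.0, 12.0, "random coil/helix"),
    (1680.0, 10.0, "turn"),
)


def gen_ftir_spectrum(beta_fraction: float, peak_layout=DEFAULT_PEAK_LAYOUT,
                      noise_sd: float = 0.0, seed: int = 0,
                      grid=(1400.0, 1750.0, 1.0),
                      reference_height: float = 0.35) -> FTIRSpectrum:
    """Sum-of-Gaussians amide-I spectrum with exact area bookkeeping.

    ``beta_fraction`` (percent) is split over the beta components of the
    layout; the remainder is split 65/35 over coil and turn components.
    A 1450 cm^-1 methyl reference band is added so normalization is
    exercised.  ``noise_sd`` is additive, relative to the band maximum.
    The truth record is attached as ``spectrum.truth``.
    """
    if not 0.0 <= beta_fraction <= 100.0:
        raise ValueError("beta_fraction must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    w = np.arange(*grid)
    f = beta_fraction / 100.0
    beta_peaks = [pl for pl in peak_layout if pl[2] == "beta-sheet"]
    other = [pl for pl in peak_layout if pl[2] != "beta-sheet"]
    areas = {}
    for i, pl in enumerate(beta_peaks):
        areas[pl] = f / len(beta_peaks)
    shares = {"random coil/helix": 0.65, "turn": 0.35}
    tot_other = sum(shares.get(pl[2], 0.0) for pl in other)
    for pl in other:
        areas[pl] = (1.0 - f) * shares.get(pl[2], 0.0) / max(tot_other, 1e-12)
    a = np.zeros_like(w)
    for (center, sd, _cls), area in areas.items():
        amp = area / (sd * math.sqrt(2.0 * math.pi))
        a = a + _gaussian(w, amp, center, sd)
    band_max = a.max() if a.max() > 0 else 1.0
    # methyl reference band (kept away from the amide-I window)
    a = a + _gaussian(w, reference_height * band_max, 1450.0, 9.0)
    if noise_sd:
        a = a + noise_sd * band_max * rng.standard_normal(len(w))
    spec = FTIRSpectrum(wavenumber=w, absorbance=a)
    spec.truth = {"beta_fraction": beta_fraction,
                  "areas": {pl[0]: areas[pl] for pl in peak_layout}}
    return spec
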