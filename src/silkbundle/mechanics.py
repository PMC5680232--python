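"""Stress-strain observables: modulus, toughness, failure mode, critical CSA.

The common currency between simulation and experiment-style analysis is
the :class:`StressStrainCurve` (engineering strain vs engineering stress
in MPa, with the nominal CSA attached).  From it:

* **Young's modulus** — OLS slope over a small-strain window (default
  0.02-0.2% strain, the initial-slope convention; the Morse bond softens
  measurably beyond that).
* **toughness** — trapezoidal area under the curve up to the break point
  (1 MPa x unit strain = 1 MJ m^-3).  The break point is the first point
  after the stress peak where stress falls below 10% of the peak, which
  makes the integral finite and insensitive to post-failure ringing for
  both brittle and ductile curves.
* **failure mode** — computed from the trajectory, not the curve: a run is
  *brittle* when bond ruptures localize in one axial window of width
  ``5 r0`` (>= 80% of breaks) with little inter-fibril sliding, *ductile*
  when neighboring fibrils have slid by >= 20% of the pulled-end
  displacement; anything else is *mixed* and counted as ductile when
  bracketing the brittle-to-ductile transition.

The brittle-to-ductile critical cross-section area A_c is reported as the
midpoint of the bracket between the largest majority-brittle CSA and the
smallest majority-ductile CSA of a replicate sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units as u
from .dynamics import Trajectory, SimulationConfig, run_tension
from .forcefield import ForceFieldParams, DEFAULT_FIT_WINDOW
from .geometry import pack_bundle, insert_defects, lattice_neighbor_pairs

__all__ = [
    "StressStrainCurve",
    "MechanicalSummary",
    "stress_strain_from_trajectory",
    "young_modulus",
    "toughness",
    "break_index",
    "classify_failure",
    "FailureDiagnostics",
    "summarize_curve",
    "critical_csa_sweep",
    "SweepResult",
    "NoTransitionError",
]

BRITTLE, DUCTILE, MIXED = "brittle", "ductile", "mixed"


@dataclass
class StressStrainCurve:
    """Engineering stress (MPa) vs strain, with nominal CSA (mm^2)."""

    strain: np.ndarray
    stress: np.ndarray
    nominal_csa: float
    source: str = "simulation"    # simulation | experiment | synthetic

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must have equal length")
        if len(self.strain) < 2:
            raise ValueError("curve needs at least 2 points")
        if self.strain[0] != 0.0 or np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must start at 0 and increase strictly")
        if not np.isfinite(self.stress).all():
            raise ValueError("stress must be finite")

    def to_csv(self, path, metadata: dict | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# nominal_csa_mm2: {self.nominal_csa}\n")
            fh.write(f"# source: {self.source}\n")
            for k, v in (metadata or {}).items():
                fh.write(f"# {k}: {v}\n")
            fh.write("strain,stress_mpa\n")
            for e, s in zip(self.strain, self.stress):
                fh.write(f"{e:.8g},{s:.8g}\n")

    @classmethod
    def from_csv(cls, path) -> "StressStrainCurve":
        meta, rows = {}, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    if ":" in line:
                        k, v = line[1:].split(":", 1)
                        meta[k.strip()] = v.strip()
                elif line and not line[0].isalpha():
                    e, s = line.split(",")[:2]
                    rows.append((float(e), float(s)))
        arr = np.asarray(rows)
        return cls(strain=arr[:, 0], stress=arr[:, 1],
                   nominal_csa=float(meta.get("nominal_csa_mm2", "nan")),
                   source=meta.get("source", "experiment"))


def stress_strain_from_trajectory(traj: Trajectory,
                                  csa: float | None = None) -> StressStrainCurve:
    """Pulled-set constraint force / nominal CSA, as a curve in MPa."""
    if len(traj.force_pull) < 2:
        raise ValueError("trajectory has no force records")
    csa = traj.bundle.nominal_csa if csa is None else csa
    stress_mpa = traj.force_pull * u.UN_TO_N / (csa * 1e-6) * u.PA_TO_MPA
    return StressStrainCurve(strain=traj.strain, stress=stress_mpa,
                             nominal_csa=csa, source="simulation")


def young_modulus(curve: StressStrainCurve,
                  fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW) -> float:
    """OLS slope of stress vs strain over ``fit_window``, in GPa."""
    lo, hi = fit_window
    m = (curve.strain >= lo) & (curve.strain <= hi)
    if m.sum() < 5:
        raise ValueError(
            f"fit window {fit_window} covers only {int(m.sum())} points (need >= 5)")
    slope = np.polyfit(curve.strain[m], curve.stress[m], 1)[0]
    return float(slope) * u.MPA_TO_GPA


def break_index(curve: StressStrainCurve, drop_fraction: float = 0.1) -> int:
    """Index of the break point: first post-peak sample below ``drop_fraction``x peak."""
    i_peak = int(np.argmax(curve.stress))
    peak = curve.stress[i_peak]
    if peak <= 0:
        return len(curve.stress) - 1
    below = np.flatnonzero(curve.stress[i_peak:] < drop_fraction * peak)
    return int(i_peak + below[0]) if len(below) else len(curve.stress) - 1


def toughness(curve: StressStrainCurve, drop_fraction: float = 0.1) -> float:
    """Area under the curve up to the break point, MJ m^-3."""
    i = break_index(curve, drop_fraction)
    return float(np.trapezoid(curve.stress[:i + 1], curve.strain[:i + 1]))


@dataclass
class FailureDiagnostics:
    mode: str
    localization: float      # fraction of breaks within one 5*r0 window
    slide_fraction: float    # mean neighbor slide / pulled-end displacement
    n_broken: int


def classify_failure(traj: Trajectory, loc_threshold: float = 0.8,
                     slide_threshold: float = 0.2,
                     window_r0: float = 5.0) -> FailureDiagnostics:
    """Brittle vs ductile from rupture localization and inter-fibril sliding."""
    ran_out = traj.strain[-1] >= traj.metadata.get("max_strain", np.inf) * (1 - 1e-9)
    if not traj.failed and not ran_out:
        raise ValueError("run did not reach failure; cannot classify")
    bundle = traj.bundle
    r0 = bundle.spacing
    # rupture localization around the modal break position
    nb = len(traj.break_x)
    if nb == 0:
        localization = 0.0
    else:
        half = 0.5 * window_r0 * r0
        centers = traj.break_x
        localization = max(
            float(np.mean(np.abs(centers - c) <= half)) for c in centers)
    # inter-fibril sliding: relative mean axial displacement of lattice neighbors
    disp = traj.final_positions[:, 0] - traj.initial_positions[:, 0]
    mean_u = np.zeros(bundle.n_fibrils)
    for f in range(1, bundle.n_fibrils + 1):
        ids = np.flatnonzero((bundle.fibril_index == f) & bundle.alive)
        mean_u[f - 1] = disp[ids].mean()
    pulled_disp = max(traj.pulled_displacement, 1e-12)
    pairs = lattice_neighbor_pairs(bundle)
    if pairs:
        slide = float(np.mean([abs(mean_u[i - 1] - mean_u[j - 1])
                               for i, j in pairs])) / pulled_disp
    else:
        slide = 0.0
    if localization >= loc_threshold and slide < slide_threshold:
        mode = BRITTLE
    elif slide >= slide_threshold:
        mode = DUCTILE
    else:
        mode = MIXED
    return FailureDiagnostics(mode=mode, localization=localization,
                              slide_fraction=slide, n_broken=nb)


@dataclass
class MechanicalSummary:
    """Per-replicate mechanics plus aggregation helpers."""

    csa: float
    modulus: float            # GPa
    toughness: float          # MJ m^-3
    strength: float           # MPa
    strain_at_break: float
    failure_mode: str = "unknown"
    seed: int | None = None

    @staticmethod
    def aggregate(rows: list["MechanicalSummary"]) -> dict:
        mods = np.array([r.modulus for r in rows])
        tough = np.array([r.toughness for r in rows])
        out = {
            "n": len(rows),
            "modulus_mean": float(mods.mean()),
            "toughness_mean": float(tough.mean()),
        }
        if len(rows) >= 2:
            out["modulus_sd"] = float(mods.std(ddof=1))
            out["toughness_sd"] = float(tough.std(ddof=1))
        return out


def summarize_curve(curve: StressStrainCurve, fit_window=DEFAULT_FIT_WINDOW,
                    failure_mode: str = "unknown",
                    seed: int | None = None) -> MechanicalSummary:
    i_b = break_index(curve)
    return MechanicalSummary(
        csa=curve.nominal_csa,
        modulus=young_modulus(curve, fit_window),
        toughness=toughness(curve),
        strength=float(curve.stress.max()),
        strain_at_break=float(curve.strain[i_b]),
        failure_mode=failure_mode,
        seed=seed,
    )


class NoTransitionError(RuntimeError):
    """Raised when a CSA sweep never flips failure mode; carries the labels."""

    def __init__(self, msg, labels=None):
        super().__init__(msg)
        self.labels = labels


@dataclass
class SweepResult:
    csa_values: list
    labels: dict              # csa -> list of per-seed mode strings
    majority: dict            # csa -> brittle | ductile
    bracket: tuple            # (largest majority-brittle CSA, smallest majority-ductile CSA)
    a_c: float                # midpoint of the bracket
    summaries: list = field(default_factory=list)


def majority_mode(modes: list[str]) -> str:
    """Majority label for one CSA; mixed counts toward ductile."""
    n_brittle = sum(1 for m in modes if m == BRITTLE)
    return BRITTLE if n_brittle * 2 > len(modes) else DUCTILE


def locate_transition(majority: dict) -> tuple[tuple, float]:
    """Bracket and midpoint A_c from per-CSA majority labels."""
    csas = sorted(majority)
    brittle_csas = [c for c in csas if majority[c] == BRITTLE]
    ductile_csas = [c for c in csas if majority[c] == DUCTILE]
    if not brittle_csas or not ductile_csas:
        raise NoTransitionError(
            f"no brittle-to-ductile transition inside the sweep: {majority}",
            labels=majority)
    lo, hi = max(brittle_csas), min(ductile_csas)
    return (lo, hi), 0.5 * (lo + hi)


def critical_csa_sweep(csa_list, replicates: int = 3,
                       p: ForceFieldParams | None = None,
                       cfg: SimulationConfig | None = None,
                       fibril_length: float = 1000.0,
                       defect_rate: float = 0.0,
                       seeds=None) -> SweepResult:
    """Replicate tension runs across CSAs; A_c from the majority-label flip.

    ``csa_list`` must span both regimes; otherwise :class:`NoTransitionError`
    is raised with the per-CSA labels attached.
    """
    p = p or ForceFieldParams()
    cfg = cfg or SimulationConfig()
    seeds = list(seeds) if seeds is not None else list(range(replicates))
    labels, summaries = {}, []
    for csa in csa_list:
        modes = []
        for seed in seeds:
            bundle = pack_bundle(csa, fibril_length=fibril_length,
                                 sigma=p.sigma * 1e6, spacing=p.r0 * 1e6)
            if defect_rate:
                insert_defects(bundle, defect_rate, seed=seed + 7919)
            traj = run_tension(bundle, p, cfg.with_(seed=seed))
            diag = classify_failure(traj)
            modes.append(diag.mode)
            curve = stress_strain_from_trajectory(traj)
            summaries.append(summarize_curve(curve, failure_mode=diag.mode,
                                             seed=seed))
        labels[csa] = modes
    majority = {csa: majority_mode(modes) for csa, modes in labels.items()}
    bracket, a_c = locate_transition(majority)
    return SweepResult(csa_values=list(csa_list), labels=labels,
                       majority=majority, bracket=bracket, a_c=a_c,
                       summaries=summaries)
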