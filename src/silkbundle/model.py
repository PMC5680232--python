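"""High-level model objects: build once, run, inspect results.

:class:`TensionSimulation` bundles geometry + force field + loading
protocol the way a statsmodels model bundles data + design;
``run()`` returns a :class:`TensionResults` carrying the stress-strain
curve, the mechanical summary, failure diagnostics and a ``summary()``
table.  Replicates and CSA sweeps hang off the same objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SimulationConfig, Trajectory, run_tension
from .forcefield import ForceFieldParams, DEFAULT_FIT_WINDOW
from .geometry import BundleGeometry, pack_bundle, insert_defects
from .mechanics import (FailureDiagnostics, MechanicalSummary,
                        StressStrainCurve, classify_failure,
                        stress_strain_from_trajectory, summarize_curve)

__all__ = ["TensionSimulation", "TensionResults", "ReplicateResults"]


@dataclass
class TensionResults:
    """Everything measured from one tension run."""

    trajectory: Trajectory
    curve: StressStrainCurve
    mechanics: MechanicalSummary
    diagnostics: FailureDiagnostics | None

    @property
    def modulus(self) -> float:
        return self.mechanics.modulus

    @property
    def toughness(self) -> float:
        return self.mechanics.toughness

    @property
    def failure_mode(self) -> str:
        return self.mechanics.failure_mode

    def summary(self) -> str:
        m = self.mechanics
        meta = self.trajectory.metadata
        lines = [
            "Bundle tension run",
            "=" * 46,
            f"{'fibrils':<28}{meta['n_fibrils']}",
            f"{'nominal CSA [mm^2]':<28}{m.csa:.5f}",
            f"{'strain rate [1/s]':<28}{meta['strain_rate']}",
            f"{'inter-fibril eps [J]':<28}{meta['eps']:.3e}",
            "-" * 46,
            f"{'Young modulus [GPa]':<28}{m.modulus:.3f}",
            f"{'toughness [MJ/m^3]':<28}{m.toughness:.3f}",
            f"{'strength [MPa]':<28}{m.strength:.1f}",
            f"{'strain at break':<28}{m.strain_at_break:.4f}",
            f"{'failure mode':<28}{m.failure_mode}",
        ]
        if self.diagnostics is not None:
            d = self.diagnostics
            lines += [
                f"{'rupture localization':<28}{d.localization:.2f}",
                f"{'slide fraction':<28}{d.slide_fraction:.2f}",
                f"{'broken bonds':<28}{d.n_broken}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve.strain, self.curve.stress)
        ax.set_xlabel("engineering strain")
        ax.set_ylabel("stress [MPa]")
        ax.set_title(f"CSA {self.curve.nominal_csa:.4f} mm$^2$ "
                     f"({self.mechanics.failure_mode})")
        return ax


@dataclass
class ReplicateResults:
    results: list
    aggregate: dict

    @property
    def modes(self):
        return [r.failure_mode for r in self.results]


class TensionSimulation:
    """A bundle under constant-strain-rate tension.

    Parameters
    ----------
    bundle : BundleGeometry
    params : ForceFieldParams, optional
    config : SimulationConfig, optional
    fit_window : (lo, hi) strain window for the modulus fit.
    """

    def __init__(self, bundle: BundleGeometry,
                 params: ForceFieldParams | None = None,
                 config: SimulationConfig | None = None,
                 fit_window=DEFAULT_FIT_WINDOW):
        self.bundle = bundle
        self.params = params or ForceFieldParams()
        self.config = config or SimulationConfig()
        self.fit_window = fit_window

    @classmethod
    def from_csa(cls, csa: float, fibril_length: float = 1000.0,
                 defect_rate: float = 0.0, defect_seed: int = 0,
                 params: ForceFieldParams | None = None,
                 config: SimulationConfig | None = None,
                 **kw) -> "TensionSimulation":
        p = params or ForceFieldParams()
        bundle = pack_bundle(csa, fibril_length=fibril_length,
                             sigma=p.sigma * 1e6, spacing=p.r0 * 1e6)
        if defect_rate:
            insert_defects(bundle, defect_rate, seed=defect_seed)
        return cls(bundle, params=p, config=config, **kw)

    def run(self, seed: int | None = None, classify: bool = True,
            snapshot_every: int = 0) -> TensionResults:
        cfg = self.config if seed is None else self.config.with_(seed=seed)
        traj = run_tension(self.bundle, self.params, cfg,
                           snapshot_every=snapshot_every)
        curve = stress_strain_from_trajectory(traj)
        diag = None
        mode = "unknown"
        if classify:
            try:
                diag = classify_failure(traj)
                mode = diag.mode
            except ValueError:
                pass
        mech = summarize_curve(curve, fit_window=self.fit_window,
                               failure_mode=mode, seed=cfg.seed)
        return TensionResults(trajectory=traj, curve=curve, mechanics=mech,
                              diagnostics=diag)

    def run_replicates(self, seeds) -> ReplicateResults:
        results = [self.run(seed=s) for s in seeds]
        agg = MechanicalSummary.aggregate([r.mechanics for r in results])
        agg["modes"] = [r.failure_mode for r in results]
        return ReplicateResults(results=results, aggregate=agg)
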