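"""Constant-strain-rate tension runs on microfibril bundles.

The loading protocol is displacement-controlled: the pulled terminal beads
translate along +x at ``strain_rate * L`` while the fixed terminal beads
are immobile; every other bead follows damped Newtonian dynamics (athermal
BAOAB — velocity Verlet with viscous drag, zero temperature).  The
measured observable is the constraint force on the pulled set, normalized
to engineering stress by the nominal CSA downstream.

Two standard quasistatic devices are used and verified by convergence
properties rather than assumed:

* **mass scaling** (default 1e4) lifts the bond vibration period so the
  reference time step of 5e-8 s satisfies the stability bound
  ``dt <= T/20``;
* **near-critical damping of the fundamental stretch mode**
  (``gamma = pi sqrt(k/m_eff)/n_beads``) removes loading transients
  without biasing the quasistatic force (drag scales with bead velocity,
  which is ~1e-4 of the bond sound speed here).

Bonds stretched beyond the rupture strain are deleted irreversibly; the
default rupture strain is calibrated so a homogeneous fibril stores
3.0 MJ m^-3 at rupture (see :mod:`silkbundle.forcefield`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _kernels as K
from . import units as u
from .forcefield import (ForceFieldParams, epsilon_of_radius,
                         rupture_strain_for_toughness,
                         DEFAULT_RUPTURE_TOUGHNESS, LJ_CUTOFF_FACTOR)
from .geometry import BundleGeometry

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "stability_bound",
    "run_tension",
    "SimulationError",
]


#: curvature of the 12-6 well at its minimum, in units of eps/sigma^2
JUNCTION_CURVATURE = 72.0 / 2.0 ** (1.0 / 3.0)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Loading protocol and integrator settings (SI units).

    ``damping=None`` resolves to critical damping of the fundamental
    stretch mode; ``rupture_strain=None`` resolves to the work-to-rupture
    calibrated value (~0.0278 for the default force field); ``eps=None``
    resolves to eps(R) of the bundle being run.
    """

    strain_rate: float = 10.0          #: applied engineering strain rate, 1/s
    dt: float = 5e-8                   #: time step, s
    max_strain: float = 0.3            #: hard stop for the strain ramp
    mass_scaling: float = 1e4          #: quasistatic mass scaling factor
    damping: float | None = None       #: viscous coefficient, 1/s (None = auto)
    rupture_strain: float | None = None  #: bond strain deleting a bond (None = auto)
    eps: float | None = None           #: inter-fibril well depth override, J
    pair_mode: str = "dense"           #: inter-fibril coupling: dense | junction | contact
    boundary_k: float | None = None    #: anchor-spring stiffness, N/m (None = auto)
    neighbor_skin: float | None = None  #: Verlet skin, m (None = 0.5 sigma)
    record_every: int = 100            #: steps between observable records
    chunk_steps: int = 200             #: kernel steps per Python-level chunk
    equil_steps: int = 2000            #: damped zero-load steps before the ramp
    relax_lattice: bool = True         #: pre-scale the transverse lattice to its LJ optimum
    jitter: float = 0.0001             #: initial position noise, fraction of r0
    failure_fraction: float = 0.01     #: stop when force < this fraction of its peak
    seed: int = 0

    def resolve(self, bundle: BundleGeometry, p: ForceFieldParams) -> dict:
        """Echo of every default resolved against a concrete bundle (SI)."""
        d = asdict(self)
        d["damping"] = self.resolved_damping(bundle, p)
        d["rupture_strain"] = self.resolved_rupture_strain(p)
        d["eps"] = self.resolved_eps(bundle, p)
        d["neighbor_skin"] = self.resolved_skin(p)
        d["boundary_k"] = self.resolved_boundary_k(bundle, p)
        return d

    def resolved_damping(self, bundle: BundleGeometry, p: ForceFieldParams) -> float:
        if self.damping is not None:
            return self.damping
        n_per_fibril = int(np.bincount(bundle.fibril_index).max())
        omega = math.sqrt(p.bond_stiffness / (p.m * 1e-3 * self.mass_scaling))
        return math.pi * omega / n_per_fibril

    def resolved_rupture_strain(self, p: ForceFieldParams) -> float:
        if self.rupture_strain is not None:
            return self.rupture_strain
        return rupture_strain_for_toughness(DEFAULT_RUPTURE_TOUGHNESS, p)

    def resolved_eps(self, bundle: BundleGeometry, p: ForceFieldParams) -> float:
        if self.eps is not None:
            return self.eps
        return epsilon_of_radius(bundle.bundle_radius, p)

    def resolved_boundary_k(self, bundle: BundleGeometry,
                            p: ForceFieldParams) -> float:
        """Soft anchors (bond-stiffness springs) for bundles, rigid grips
        for the homogeneous single-fibril run."""
        if self.boundary_k is not None:
            return self.boundary_k
        return 0.0 if bundle.n_fibrils == 1 else p.bond_stiffness

    def resolved_skin(self, p: ForceFieldParams) -> float:
        return self.neighbor_skin if self.neighbor_skin is not None else 0.5 * p.sigma

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def _fibril_bead_lists(bundle: BundleGeometry):
    """Per-fibril live bead ids in axial order, flattened with offsets."""
    beads, offsets = [], [0]
    for f in range(1, bundle.n_fibrils + 1):
        ids = np.flatnonzero((bundle.fibril_index == f) & bundle.alive)
        ids = ids[np.argsort(bundle.positions[ids, 0], kind="stable")]
        beads.append(ids)
        offsets.append(offsets[-1] + len(ids))
    return (np.concatenate(beads).astype(np.int64),
            np.asarray(offsets, dtype=np.int64))


def _candidate_fibril_pairs(bundle: BundleGeometry, rc_um: float,
                            scale: float = 1.0) -> np.ndarray:
    """0-based fibril index pairs close enough transversely to touch."""
    lat = bundle.lattice_positions * scale
    out = []
    for i in range(len(lat)):
        for j in range(i + 1, len(lat)):
            if np.linalg.norm(lat[i] - lat[j]) < rc_um:
                out.append((i, j))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _junction_pairs(bundle: BundleGeometry, rc_um: float,
                    scale: float) -> np.ndarray:
    """Construction-aligned bead pairs between transversely adjacent fibrils.

    Bead k of fibril f is paired with bead k of every fibril whose center
    lies within the LJ cutoff; the pairing is *persistent* — fixed at
    construction like the junctions of a bonded network — so a pair acts
    as a sacrificial inter-fibril bond that detaches smoothly once sliding
    stretches it past the cutoff.  Dead (defect) beads carry no junctions.
    """
    counts = np.bincount(bundle.fibril_index)[1:]
    if len(set(counts.tolist())) != 1:
        raise ValueError("junction pairing requires equal bead counts per fibril")
    nb = int(counts[0])
    # junctions exist only between *touching* fibrils (nearest lattice
    # shell): adhesion is a contact property.  Including farther shells
    # compresses the nearest junctions onto the repulsive LJ wall at the
    # relaxed pitch, which makes axial alignment anti-restoring and
    # destabilizes the bundle.
    cand = _candidate_fibril_pairs(bundle, 1.5 * bundle.sigma, 1.0)
    out = []
    for f0, g0 in cand:
        for k in range(nb):
            i, j = f0 * nb + k, g0 * nb + k
            if bundle.alive[i] and bundle.alive[j]:
                out.append((i, j))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _pair_builder(bundle: BundleGeometry, mobility, cfg: SimulationConfig,
                  rc_um: float, skin_um: float, scale: float):
    """Returns a ``build(pos) -> pairs`` closure for the configured mode."""
    if cfg.pair_mode == "junction":
        static = _junction_pairs(bundle, rc_um, scale)

        def build(pos):
            return static
    elif cfg.pair_mode == "contact":
        fibril_beads, offsets = _fibril_bead_lists(bundle)
        cand = _candidate_fibril_pairs(bundle, rc_um + skin_um, scale)

        def build(pos):
            return K.build_contact_pairs(pos, fibril_beads, offsets, cand,
                                         rc_um + skin_um)
    elif cfg.pair_mode == "dense":
        def build(pos):
            return K.build_pairs(pos, bundle.fibril_index, mobility,
                                 rc_um + skin_um)
    else:
        raise ValueError(f"unknown pair_mode '{cfg.pair_mode}'")
    return build


def _relaxed_lattice_scale(bundle: BundleGeometry, p: ForceFieldParams,
                           eps_joule: float, cfg: SimulationConfig) -> float:
    """Uniform transverse scale factor minimizing the inter-fibril energy.

    The bundle is constructed at pitch sigma, which sits on the repulsive
    wall of the 12-6 potential (minimum at 1.12 sigma); loading from there
    releases an energy per bead comparable to the bond rupture energy.
    Scaling the transverse lattice to its energy optimum removes that
    shock; the remaining non-uniform relaxation is handled by the damped
    equilibration phase.
    """
    from scipy.optimize import minimize_scalar
    ip = p.internal
    rc = LJ_CUTOFF_FACTOR * ip.sigma
    eps_pj = eps_joule * u.J_TO_PJ
    pos0 = bundle.positions
    mobility = np.where(bundle.alive, 0, 3).astype(np.int8)

    def energy(scale):
        pos = pos0.copy()
        pos[:, 1:] *= scale
        builder = _pair_builder(bundle, mobility, cfg, rc, 0.0, scale)
        pairs = builder(pos)
        no_bonds = np.zeros(0, dtype=np.bool_)
        return K.potential_energy(
            pos, np.zeros((0, 2), dtype=np.int64), no_bonds,
            np.zeros((0, 3), dtype=np.int64), np.zeros((0, 2), dtype=np.int64),
            pairs, ip.D, ip.alpha, ip.r0, ip.kb, eps_pj, ip.sigma, rc)

    res = minimize_scalar(energy, bounds=(1.0, 1.25), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def stability_bound(p: ForceFieldParams, cfg: SimulationConfig) -> float:
    """Largest stable time step, s: one twentieth of the bond vibration period.

    ``T = 2 pi sqrt(m_eff / (2 D alpha^2))`` with ``m_eff = m * mass_scaling``.
    """
    m_eff_kg = p.m * 1e-3 * cfg.mass_scaling
    return 2.0 * math.pi * math.sqrt(m_eff_kg / p.bond_stiffness) / 20.0


@dataclass
class Trajectory:
    """Recorded observables of one tension run (forces in uN internally)."""

    strain: np.ndarray            # applied engineering strain per record
    force_pull: np.ndarray        # constraint force on the pulled set, uN
    force_react: np.ndarray       # reaction force on the fixed set, uN
    broken_count: np.ndarray      # cumulative broken bonds per record
    break_bond: np.ndarray        # bond id per rupture event
    break_x: np.ndarray           # axial midpoint at rupture, um
    break_strain: np.ndarray      # applied strain at rupture
    initial_positions: np.ndarray
    final_positions: np.ndarray
    bundle: BundleGeometry
    metadata: dict = field(default_factory=dict)
    frames: list = field(default_factory=list)   # sparse (strain, positions) snapshots

    @property
    def failed(self) -> bool:
        return bool(self.metadata.get("failed", False))

    @property
    def pulled_displacement(self) -> float:
        """Final pulled-end displacement, um."""
        return float(self.strain[-1]) * self.metadata["chain_length_um"]

    def write_xyz(self, path) -> None:
        with open(path, "w") as fh:
            for strain, pos in self.frames:
                self.bundle.write_xyz_frame(fh, positions=pos,
                                            comment=f"strain={strain:.6f}")

    def write_csv(self, path) -> None:
        import pandas as pd
        csa = self.bundle.nominal_csa
        stress = self.force_pull * u.UN_TO_N / (csa * 1e-6) * u.PA_TO_MPA
        pd.DataFrame({"strain": self.strain, "stress_mpa": stress,
                      "broken_count": self.broken_count}).to_csv(path, index=False)


def run_tension(bundle: BundleGeometry, p: ForceFieldParams | None = None,
                cfg: SimulationConfig | None = None,
                snapshot_every: int = 0) -> Trajectory:
    """Pull a bundle at constant strain rate until failure or ``max_strain``.

    Failure is declared when the pulling force drops below
    ``failure_fraction`` of its running maximum (evaluated only once the
    ramp is past one quarter of the rupture strain, so both brittle and
    ductile runs terminate).  Deterministic for a fixed config and seed.
    """
    p = p or ForceFieldParams()
    cfg = cfg or SimulationConfig()
    if len(bundle.fixed_ids) == 0 or len(bundle.pulled_ids) == 0:
        raise SimulationError("bundle has no boundary assignment")
    bound = stability_bound(p, cfg)
    if cfg.dt > bound:
        raise SimulationError(
            f"dt = {cfg.dt:.3e} s exceeds the stability bound {bound:.3e} s "
            f"(raise mass_scaling or lower dt)")

    ip = p.internal
    rng = np.random.default_rng(cfg.seed)

    pos = bundle.positions.copy()
    n = len(pos)
    mobility = np.zeros(n, dtype=np.int8)
    mobility[~bundle.alive] = K.DEAD
    mobility[bundle.fixed_ids] = K.FIXED
    mobility[bundle.pulled_ids] = K.PULLED
    # junction mode anchors each pair at its construction offset, so the
    # built lattice is already an exact equilibrium; the LJ pair modes are
    # pre-relaxed to the 12-6 optimum to avoid a swelling shock
    lattice_scale = 1.0
    if (cfg.relax_lattice and bundle.n_fibrils > 1
            and cfg.pair_mode != "junction"):
        lattice_scale = _relaxed_lattice_scale(bundle, p,
                                               cfg.resolved_eps(bundle, p), cfg)
        pos[:, 1:] *= lattice_scale
    if cfg.jitter > 0:
        noise = rng.normal(0.0, cfg.jitter * ip.r0, size=(n, 3))
        noise[mobility != K.FREE] = 0.0
        pos += noise

    vel = np.zeros_like(pos)
    frc = np.zeros_like(pos)
    bond_alive = np.ones(len(bundle.bonds), dtype=np.bool_)

    # internal-unit scalars
    dt = cfg.dt * u.S_TO_US
    rate = cfg.strain_rate * u.PER_S_TO_PER_US
    L = bundle.fibril_length
    v_pull = rate * L                       # um/us
    m_eff = ip.m * cfg.mass_scaling         # ng
    gamma = cfg.resolved_damping(bundle, p) * u.PER_S_TO_PER_US
    rupture_strain = cfg.resolved_rupture_strain(p)
    rupt_r = ip.r0 * (1.0 + rupture_strain)
    eps = (cfg.resolved_eps(bundle, p)) * u.J_TO_PJ
    rc = LJ_CUTOFF_FACTOR * ip.sigma
    skin = cfg.resolved_skin(p) * u.M_TO_UM

    nb_max = max(1, len(bundle.bonds))
    break_bond = np.zeros(nb_max, dtype=np.int64)
    break_x = np.zeros(nb_max, dtype=np.float64)
    break_strain_arr = np.zeros(nb_max, dtype=np.float64)
    n_broken = 0

    builder = _pair_builder(bundle, mobility, cfg, rc, skin, lattice_scale)
    contact_mode = cfg.pair_mode == "contact"
    pairs = (builder(pos) if bundle.n_fibrils > 1
             else np.empty((0, 2), dtype=np.int64))
    pos_ref = pos.copy()

    # sacrificial-junction parameters: harmonic stiffness = LJ well
    # curvature, detachment where the stored energy equals the well depth
    if cfg.pair_mode == "junction" and len(pairs):
        jun_k = JUNCTION_CURVATURE * eps / ip.sigma**2       # uN/um
        jun_uc = ip.sigma * math.sqrt(2.0 / JUNCTION_CURVATURE)
        jun_rest = (bundle.positions[pairs[:, 0]]
                    - bundle.positions[pairs[:, 1]]).astype(np.float64)
        jun_alive = np.ones(len(pairs), dtype=np.bool_)
    else:
        jun_k, jun_uc = 0.0, 0.0
        jun_rest = np.zeros((0, 3), dtype=np.float64)
        jun_alive = np.zeros(0, dtype=np.bool_)

    # boundary handling: soft anchor springs let the terminal beads take
    # part in the lattice relaxation instead of concentrating it in the
    # first bond; internal uN/um equals N/m numerically
    anchor_k = cfg.resolved_boundary_k(bundle, p)
    anchor0 = pos.copy()

    def maybe_rebuild(pairs):
        # junction pairs are static; contact pairing is cheap and
        # position-dependent (refresh every chunk); the dense cell list
        # refreshes on the skin criterion
        if bundle.n_fibrils == 1 or cfg.pair_mode == "junction":
            return pairs
        if contact_mode or np.abs(pos - pos_ref).max() > 0.5 * skin:
            pos_ref[:] = pos
            return builder(pos)
        return pairs

    # initial forces (strain 0; nothing can rupture at equilibrium)
    n_broken = K.compute_forces(pos, frc, bundle.bonds, bond_alive,
                                bundle.angles, bundle.angle_bonds, pairs,
                                ip.D, ip.alpha, ip.r0, rupt_r, ip.kb, eps,
                                ip.sigma, rc, 0.0,
                                break_bond, break_x, break_strain_arr, n_broken,
                                jun_rest, jun_alive, jun_k, jun_uc,
                                mobility, anchor0, anchor_k, L)

    # zero-load equilibration settles the residual lattice stress left by
    # the uniform pre-relaxation.  Run it overdamped (critical at the bond
    # frequency): an underdamped relaxation converts the released energy
    # into kinetic energy comparable to the bond rupture energy, snapping
    # bonds and shaking the fibrils out of axial registry.
    gamma_eq = 2.0 * math.sqrt(2.0 * ip.D * ip.alpha**2 / m_eff)
    equil_done = 0
    while equil_done < cfg.equil_steps:
        n_chunk = min(cfg.chunk_steps, cfg.equil_steps - equil_done)
        n_broken = K.run_chunk(pos, vel, frc, mobility, bundle.bonds,
                               bond_alive, bundle.angles, bundle.angle_bonds,
                               pairs, ip.D, ip.alpha, ip.r0, rupt_r, ip.kb,
                               eps, ip.sigma, rc, m_eff, gamma_eq, dt, 0.0,
                               0.0, 0, n_chunk,
                               break_bond, break_x, break_strain_arr, n_broken,
                               jun_rest, jun_alive, jun_k, jun_uc,
                               anchor0, anchor_k, L)
        equil_done += n_chunk
        pairs = maybe_rebuild(pairs)
    if not np.isfinite(pos).all():
        raise SimulationError("equilibration blew up (geometry degenerate?)")
    if n_broken:
        raise SimulationError(
            f"{n_broken} bonds ruptured during equilibration; geometry or "
            f"jitter is inconsistent with the rupture strain")
    vel[:] = 0.0
    pos_after_equil = pos.copy()

    total_steps = int(math.ceil(cfg.max_strain / (rate * dt))) if rate > 0 else cfg.chunk_steps
    rec_strain, rec_pull, rec_react, rec_broken = [0.0], [0.0], [0.0], [0]
    frames = []
    step = 0
    peak = 0.0
    failed = False
    min_term_strain = 0.25 * rupture_strain

    while step < total_steps:
        n_chunk = min(cfg.record_every, total_steps - step)
        n_broken = K.run_chunk(pos, vel, frc, mobility, bundle.bonds,
                               bond_alive, bundle.angles, bundle.angle_bonds,
                               pairs, ip.D, ip.alpha, ip.r0, rupt_r, ip.kb,
                               eps, ip.sigma, rc, m_eff, gamma, dt, v_pull,
                               rate, step, n_chunk,
                               break_bond, break_x, break_strain_arr, n_broken,
                               jun_rest, jun_alive, jun_k, jun_uc,
                               anchor0, anchor_k, L)
        step += n_chunk
        if not np.isfinite(pos).all():
            raise SimulationError(
                f"integration blew up at strain {step * dt * rate:.4f} "
                f"(dt too large or geometry degenerate)")
        strain = step * dt * rate
        if anchor_k > 0:
            disp = strain * L
            f_pull = float(anchor_k * (anchor0[bundle.pulled_ids, 0] + disp
                                       - pos[bundle.pulled_ids, 0]).sum())
            f_react = float(anchor_k * (pos[bundle.fixed_ids, 0]
                                        - anchor0[bundle.fixed_ids, 0]).sum())
        else:
            f_pull = float(-frc[bundle.pulled_ids, 0].sum())
            f_react = float(frc[bundle.fixed_ids, 0].sum())
        rec_strain.append(strain)
        rec_pull.append(f_pull)
        rec_react.append(f_react)
        rec_broken.append(n_broken)
        if snapshot_every and (len(rec_strain) - 1) % snapshot_every == 0:
            frames.append((strain, pos.copy()))
        peak = max(peak, f_pull)
        if strain > min_term_strain and peak > 0 and f_pull < cfg.failure_fraction * peak:
            failed = True
            break
        pairs = maybe_rebuild(pairs)

    meta = cfg.resolve(bundle, p)
    meta.update(failed=failed, chain_length_um=L, n_steps=step,
                csa_mm2=bundle.nominal_csa, n_fibrils=bundle.n_fibrils,
                rupture_strain=rupture_strain,
                forcefield={k: v for k, v in asdict(p).items()})
    if snapshot_every:
        frames.append((rec_strain[-1], pos.copy()))
    return Trajectory(
        strain=np.asarray(rec_strain),
        force_pull=np.asarray(rec_pull),
        force_react=np.asarray(rec_react),
        broken_count=np.asarray(rec_broken),
        break_bond=break_bond[:n_broken].copy(),
        break_x=break_x[:n_broken].copy(),
        break_strain=break_strain_arr[:n_broken].copy(),
        initial_positions=pos_after_equil,
        final_positions=pos,
        bundle=bundle,
        metadata=meta,
        frames=frames,
    )


def total_energy(bundle: BundleGeometry, p: ForceFieldParams,
                 pos: np.ndarray, vel: np.ndarray, mobility: np.ndarray,
                 bond_alive: np.ndarray, pairs: np.ndarray,
                 m_eff: float, eps_pj: float) -> float:
    """Kinetic + potential energy in pJ (used by conservation checks)."""
    ip = p.internal
    rc = LJ_CUTOFF_FACTOR * ip.sigma
    pe = K.potential_energy(pos, bundle.bonds, bond_alive, bundle.angles,
                            bundle.angle_bonds, pairs, ip.D, ip.alpha, ip.r0,
                            ip.kb, eps_pj, ip.sigma, rc)
    ke = K.kinetic_energy(vel, mobility, m_eff)
    return pe + ke
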