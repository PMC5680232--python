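"""Bundle construction: close-packed microfibril lattices, defects, boundaries.

A regenerated silk fiber (RSF) is modeled as a bundle of straight
microfibrils (SMFs), each a 1D chain of mass beads at spacing ``r0`` along
the loading axis (x).  Fibril centers occupy a triangular lattice of pitch
``sigma`` (the fibril diameter) in the transverse y-z plane, filled
spiralling outward from the bundle axis, which yields near-circular
cross-sections.

Conventions
-----------
* Nominal cross-section area (CSA) = ``n_fibrils * pi sigma^2 / 4`` — the
  solid-fibril footprint, ignoring packing voids, so that stress normalized
  by nominal CSA is commensurate between a single fibril and a bundle.
* Fibril indices are 1-based in lattice fill order; the asymmetric loading
  scheme fixes the left terminal bead of odd-index fibrils and pulls the
  right terminal bead of even-index fibrils, which permits inter-fibril
  sliding.  A single-fibril bundle is flagged *homogeneous*: left end
  fixed, right end pulled.
* Defects delete randomly chosen non-boundary beads together with every
  bond and angle touching them.

Lengths are micrometres throughout this module; CSA and bundle radius are
reported in mm^2 / mm to match the tensile-test convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "FibrilChain",
    "BundleGeometry",
    "build_fibril",
    "triangular_lattice",
    "pack_bundle",
    "pack_bundle_n",
    "assign_boundaries",
    "insert_defects",
]


class InvalidGeometryError(ValueError):
    pass


@dataclass
class FibrilChain:
    """One straight bead-spring chain (positions in um)."""

    fibril_index: int
    bead_positions: np.ndarray   # (n, 3)
    bead_spacing: float

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    @property
    def length(self) -> float:
        return self.bead_spacing * (self.n_beads - 1)


@dataclass
class BundleGeometry:
    """Complete bundle topology.

    Bead ids are row indices into ``positions``; ``alive`` marks beads not
    deleted as defects (dead beads keep their row but participate in
    nothing).
    """

    positions: np.ndarray          # (N, 3) um
    fibril_index: np.ndarray       # (N,) 1-based
    bonds: np.ndarray              # (M, 2) bead ids
    angles: np.ndarray             # (K, 3) bead ids (i-j-k, j central)
    angle_bonds: np.ndarray        # (K, 2) bond ids forming each angle
    sigma: float                   # fibril diameter / lattice pitch, um
    spacing: float                 # bead spacing r0, um
    lattice_positions: np.ndarray  # (n_fibrils, 2) transverse centers, um
    alive: np.ndarray = None       # (N,) bool
    defect_ids: set = field(default_factory=set)
    fixed_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    pulled_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    homogeneous: bool = False      # single-fibril mode flag

    def __post_init__(self):
        if self.alive is None:
            self.alive = np.ones(len(self.positions), dtype=bool)

    # -- derived ----------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_fibrils(self) -> int:
        return len(self.lattice_positions)

    @property
    def fibril_length(self) -> float:
        """Initial chain length (um), common to all fibrils."""
        n_per = np.bincount(self.fibril_index).max()
        return float(self.spacing * (n_per - 1))

    @property
    def nominal_csa(self) -> float:
        """n_fibrils * pi sigma^2/4, in mm^2."""
        return self.n_fibrils * math.pi * (self.sigma / 1e3) ** 2 / 4.0

    @property
    def bundle_radius(self) -> float:
        """R = sqrt(nominal CSA / pi), in mm."""
        return math.sqrt(self.nominal_csa / math.pi)

    def validate(self) -> None:
        """Topology hygiene: no bond/angle may reference a dead bead."""
        if len(self.bonds) and not self.alive[self.bonds].all():
            raise InvalidGeometryError("bond references a deleted bead")
        if len(self.angles) and not self.alive[self.angles].all():
            raise InvalidGeometryError("angle references a deleted bead")
        if len(self.fixed_ids) and not self.alive[self.fixed_ids].all():
            raise InvalidGeometryError("fixed bead was deleted")
        if len(self.pulled_ids) and not self.alive[self.pulled_ids].all():
            raise InvalidGeometryError("pulled bead was deleted")

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "sigma_um": self.sigma,
            "spacing_um": self.spacing,
            "n_fibrils": self.n_fibrils,
            "nominal_csa_mm2": self.nominal_csa,
            "homogeneous": self.homogeneous,
            "positions_um": self.positions.tolist(),
            "fibril_index": self.fibril_index.tolist(),
            "bonds": self.bonds.tolist(),
            "angles": self.angles.tolist(),
            "angle_bonds": self.angle_bonds.tolist(),
            "lattice_positions_um": self.lattice_positions.tolist(),
            "alive": self.alive.astype(int).tolist(),
            "defect_ids": sorted(int(i) for i in self.defect_ids),
            "fixed_ids": self.fixed_ids.tolist(),
            "pulled_ids": self.pulled_ids.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "BundleGeometry":
        with open(path) as fh:
            doc = json.load(fh)
        b = cls(
            positions=np.asarray(doc["positions_um"], dtype=float),
            fibril_index=np.asarray(doc["fibril_index"], dtype=np.int64),
            bonds=np.asarray(doc["bonds"], dtype=np.int64).reshape(-1, 2),
            angles=np.asarray(doc["angles"], dtype=np.int64).reshape(-1, 3),
            angle_bonds=np.asarray(doc["angle_bonds"], dtype=np.int64).reshape(-1, 2),
            sigma=doc["sigma_um"],
            spacing=doc["spacing_um"],
            lattice_positions=np.asarray(doc["lattice_positions_um"],
                                         dtype=float).reshape(-1, 2),
            alive=np.asarray(doc["alive"], dtype=bool),
            defect_ids=set(doc["defect_ids"]),
            fixed_ids=np.asarray(doc["fixed_ids"], dtype=np.int64),
            pulled_ids=np.asarray(doc["pulled_ids"], dtype=np.int64),
            homogeneous=doc["homogeneous"],
        )
        b.validate()
        return b

    def write_xyz_frame(self, fh, positions=None, comment="") -> None:
        """Append one frame in the XYZ-with-comments dialect."""
        pos = self.positions if positions is None else positions
        live = np.flatnonzero(self.alive)
        fh.write(f"{len(live)}\n{comment}\n")
        for i in live:
            x, y, z = pos[i]
            fh.write(f"{i} {self.fibril_index[i]} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_fibril(n_beads: int, spacing: float, origin=(0.0, 0.0, 0.0),
                 axis=(1.0, 0.0, 0.0), fibril_index: int = 1) -> FibrilChain:
    """A straight chain of ``n_beads`` at exact spacing along ``axis``."""
    if n_beads < 3:
        raise InvalidGeometryError("a fibril needs at least 3 beads (one angle)")
    if spacing <= 0:
        raise InvalidGeometryError("bead spacing must be positive")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.arange(n_beads)[:, None] * spacing
    pos = np.asarray(origin, dtype=float)[None, :] + t * axis[None, :]
    return FibrilChain(fibril_index=fibril_index, bead_positions=pos,
                       bead_spacing=spacing)


def triangular_lattice(n_sites: int, pitch: float) -> np.ndarray:
    """First ``n_sites`` sites of a triangular lattice, spiral fill order.

    Sites are sorted by distance from the origin, ties broken by polar
    angle, giving a near-circular, deterministic fill.
    """
    if n_sites < 1:
        raise InvalidGeometryError("need at least one lattice site")
    k = max(2, int(math.ceil(2.0 * math.sqrt(n_sites))) + 2)
    a1 = np.array([pitch, 0.0])
    a2 = np.array([pitch / 2.0, pitch * math.sqrt(3.0) / 2.0])
    ii, jj = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1))
    pts = ii.ravel()[:, None] * a1 + jj.ravel()[:, None] * a2
    r2 = np.einsum("ij,ij->i", pts, pts)
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.lexsort((ang, np.round(r2, 6)))
    if n_sites > len(order):
        raise InvalidGeometryError("lattice generation window too small")
    return pts[order[:n_sites]]


def stagger_offsets(lattice: np.ndarray, pitch: float,
                    spacing: float) -> np.ndarray:
    """Axial offset per fibril for the close-packed (staggered) arrangement.

    The triangular lattice is 3-colored (color = (i - j) mod 3 in lattice
    coordinates, so every nearest-neighbor pair has different colors) and
    each color class is shifted axially by a third of the bead spacing.
    Every adjacent fibril pair then sits at a relative offset of +-a/3 — a
    symmetric, frustration-free equilibrium of the inter-fibril
    corrugation with positive shear stiffness, unlike the bead-aligned
    arrangement, which is a corrugation maximum.
    """
    j = np.round(lattice[:, 1] / (pitch * math.sqrt(3.0) / 2.0)).astype(int)
    i = np.round(lattice[:, 0] / pitch - j / 2.0).astype(int)
    color = np.mod(i - j, 3)
    return color * spacing / 3.0


def _assemble(lattice: np.ndarray, n_beads: int, spacing: float,
              sigma: float, staggered: bool = True) -> BundleGeometry:
    n_f = len(lattice)
    offsets = (stagger_offsets(lattice, sigma, spacing) if staggered
               else np.zeros(n_f))
    positions = np.empty((n_f * n_beads, 3), dtype=float)
    fibril_index = np.empty(n_f * n_beads, dtype=np.int64)
    bonds, angles, angle_bonds = [], [], []
    for f in range(n_f):
        base = f * n_beads
        positions[base:base + n_beads, 0] = (np.arange(n_beads) * spacing
                                             + offsets[f])
        positions[base:base + n_beads, 1] = lattice[f, 0]
        positions[base:base + n_beads, 2] = lattice[f, 1]
        fibril_index[base:base + n_beads] = f + 1
        b0 = len(bonds)
        for i in range(n_beads - 1):
            bonds.append((base + i, base + i + 1))
        for i in range(n_beads - 2):
            angles.append((base + i, base + i + 1, base + i + 2))
            angle_bonds.append((b0 + i, b0 + i + 1))
    return BundleGeometry(
        positions=positions,
        fibril_index=fibril_index,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        angle_bonds=np.asarray(angle_bonds, dtype=np.int64).reshape(-1, 2),
        sigma=sigma,
        spacing=spacing,
        lattice_positions=lattice,
    )


def n_fibrils_for_csa(target_csa: float, sigma: float) -> int:
    """Number of fibrils realizing a CSA (mm^2) under the solid-footprint convention."""
    footprint = math.pi * (sigma / 1e3) ** 2 / 4.0
    if target_csa < footprint * (1.0 - 1e-9):
        raise InvalidGeometryError(
            f"target CSA {target_csa} mm^2 is below one fibril footprint {footprint:.3e}")
    return max(1, int(round(target_csa / footprint)))


def pack_bundle(target_csa: float, fibril_length: float = 1000.0,
                sigma: float = 10.0, spacing: float = 7.1,
                staggered: bool = True) -> BundleGeometry:
    """Close-packed bundle realizing ``target_csa`` (mm^2).

    ``n_fibrils = round(CSA / (pi sigma^2/4))``; bead count per fibril is
    ``floor(L/r0) + 1`` so the equilibrium spacing is preserved exactly
    (the realized length is then <= the requested one).  Boundary beads are
    assigned on return.
    """
    return pack_bundle_n(n_fibrils_for_csa(target_csa, sigma),
                         fibril_length=fibril_length, sigma=sigma,
                         spacing=spacing, staggered=staggered)


def pack_bundle_n(n_fibrils: int, fibril_length: float = 1000.0,
                  sigma: float = 10.0, spacing: float = 7.1,
                  n_beads: int | None = None,
                  staggered: bool = True) -> BundleGeometry:
    """As :func:`pack_bundle` but with the fibril count given directly."""
    if n_fibrils < 1:
        raise InvalidGeometryError("need at least one fibril")
    if spacing <= 0 or sigma <= 0:
        raise InvalidGeometryError("sigma and spacing must be positive")
    if n_beads is None:
        n_beads = int(math.floor(fibril_length / spacing)) + 1
    if n_beads < 3:
        raise InvalidGeometryError("fibril too short for the bead spacing")
    lattice = triangular_lattice(n_fibrils, sigma)
    bundle = _assemble(lattice, n_beads, spacing, sigma, staggered=staggered)
    return assign_boundaries(bundle)


def assign_boundaries(bundle: BundleGeometry) -> BundleGeometry:
    """Tag terminal beads for the asymmetric fixed/pulled loading scheme.

    Odd-index fibrils: left (min-x) terminal bead fixed.  Even-index
    fibrils: right (max-x) terminal bead pulled.  With a single fibril the
    scheme degenerates; both ends of that fibril are used and the bundle is
    flagged homogeneous.
    """
    fixed, pulled = [], []
    for f in range(1, bundle.n_fibrils + 1):
        ids = np.flatnonzero(bundle.fibril_index == f)
        left = ids[np.argmin(bundle.positions[ids, 0])]
        right = ids[np.argmax(bundle.positions[ids, 0])]
        if bundle.n_fibrils == 1:
            fixed.append(left)
            pulled.append(right)
        elif f % 2 == 1:
            fixed.append(left)
        else:
            pulled.append(right)
    bundle.fixed_ids = np.asarray(fixed, dtype=np.int64)
    bundle.pulled_ids = np.asarray(pulled, dtype=np.int64)
    bundle.homogeneous = bundle.n_fibrils == 1
    return bundle


def insert_defects(bundle: BundleGeometry, rate: float, seed: int) -> BundleGeometry:
    """Delete each eligible bead independently with probability ``rate``.

    Eligible beads are the live, non-boundary beads (fixed/pulled beads are
    protected so loading stays well-posed).  Every bond and angle touching
    a deleted bead is removed.  Deterministic for a fixed seed; the bundle
    is modified in place and returned.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("defect rate must lie in [0, 1)")
    if rate == 0.0:
        return bundle
    rng = np.random.default_rng(seed)
    eligible = bundle.alive.copy()
    eligible[bundle.fixed_ids] = False
    eligible[bundle.pulled_ids] = False
    hit = eligible & (rng.random(bundle.n_beads) < rate)
    ids = np.flatnonzero(hit)
    if len(ids) == 0:
        return bundle
    bundle.alive[ids] = False
    bundle.defect_ids |= set(int(i) for i in ids)
    bond_ok = bundle.alive[bundle.bonds].all(axis=1)
    # remap surviving bond ids for the angle->bond table
    new_bond_id = -np.ones(len(bundle.bonds), dtype=np.int64)
    new_bond_id[bond_ok] = np.arange(bond_ok.sum())
    angle_ok = (bundle.alive[bundle.angles].all(axis=1)
                & bond_ok[bundle.angle_bonds].all(axis=1))
    bundle.bonds = bundle.bonds[bond_ok]
    bundle.angle_bonds = new_bond_id[bundle.angle_bonds[angle_ok]]
    bundle.angles = bundle.angles[angle_ok]
    bundle.validate()
    return bundle


def lattice_neighbor_pairs(bundle: BundleGeometry, tol: float = 1e-6):
    """Pairs of fibril indices (1-based) whose centers sit one pitch apart."""
    lat = bundle.lattice_positions
    pairs = []
    for i in range(len(lat)):
        for j in range(i + 1, len(lat)):
            if abs(np.linalg.norm(lat[i] - lat[j]) - bundle.sigma) < tol * bundle.sigma + 1e-9:
                pairs.append((i + 1, j + 1))
    return pairs
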