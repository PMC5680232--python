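"""Bundle construction, defects, boundaries, serialization."""

import math

import numpy as np
import pytest

from silkbundle import geometry as G


class TestBuildFibril:
    def test_bead_and_topology_counts(self):
        # 1000 um at 7.1 um spacing -> 141 beads, 994 um, 140 bonds, 139 angles
        n = math.floor(1000 / 7.1) + 1
        assert n == 141
        chain = G.build_fibril(n, 7.1)
        assert chain.n_beads == 141
        assert chain.length == pytest.approx(994.0, rel=1e-12)

    def test_spacing_exact_and_collinear(self):
        chain = G.build_fibril(10, 7.1, origin=(1, 2, 3), axis=(0, 0, 1))
        d = np.diff(chain.bead_positions, axis=0)
        assert np.allclose(np.linalg.norm(d, axis=1), 7.1, rtol=1e-9)
        assert np.allclose(chain.bead_positions[:, :2], [1, 2])

    def test_minimal_chain(self):
        assert G.build_fibril(3, 7.1).n_beads == 3

    @pytest.mark.parametrize("n,spacing", [(2, 7.1), (3, 0.0), (1, 1.0)])
    def test_invalid_inputs(self, n, spacing):
        with pytest.raises(G.InvalidGeometryError):
            G.build_fibril(n, spacing)


class TestPackBundle:
    def test_thin_bundle_count_and_radius(self):
        b = G.pack_bundle(0.002)
        assert b.n_fibrils == 25
        assert b.bundle_radius == pytest.approx(0.025, rel=0.01)

    def test_thick_bundle_count(self):
        assert G.pack_bundle(0.025).n_fibrils == 318

    def test_single_fibril_footprint(self):
        footprint = math.pi * (10 / 1e3) ** 2 / 4
        b = G.pack_bundle(footprint)
        assert b.n_fibrils == 1
        assert b.homogeneous
        assert np.allclose(b.lattice_positions, 0.0)

    def test_csa_convention_exact(self):
        b = G.pack_bundle(0.002)
        assert b.nominal_csa / b.n_fibrils == pytest.approx(
            math.pi * (10 / 1e3) ** 2 / 4, rel=1e-12)

    def test_below_one_fibril_raises(self):
        with pytest.raises(G.InvalidGeometryError):
            G.pack_bundle(1e-6)

    def test_interior_fibril_has_six_neighbors(self):
        for n in (7, 25):
            b = G.pack_bundle_n(n, n_beads=5)
            lat = b.lattice_positions
            d = np.linalg.norm(lat[None] - lat[:, None], axis=-1)
            nn_counts = ((np.abs(d - b.sigma) < 1e-6 * b.sigma).sum(axis=1))
            assert nn_counts.max() == 6

    def test_lattice_pitch(self):
        b = G.pack_bundle_n(7, n_beads=5)
        pairs = G.lattice_neighbor_pairs(b)
        lat = b.lattice_positions
        for i, j in pairs:
            assert np.linalg.norm(lat[i - 1] - lat[j - 1]) == pytest.approx(
                b.sigma, rel=1e-9)

    def test_stagger_offsets_separate_all_neighbors(self):
        b = G.pack_bundle_n(25, n_beads=5)
        off = G.stagger_offsets(b.lattice_positions, b.sigma, b.spacing)
        for i, j in G.lattice_neighbor_pairs(b):
            assert off[i - 1] != off[j - 1]

    def test_aligned_construction_available(self):
        b = G.pack_bundle_n(7, n_beads=5, staggered=False)
        x0 = [b.positions[b.fibril_index == f, 0].min() for f in range(1, 8)]
        assert np.allclose(x0, 0.0)


class TestBoundaries:
    def test_odd_even_split(self):
        b = G.pack_bundle(0.002)
        assert len(b.fixed_ids) == 13     # odd indices among 1..25
        assert len(b.pulled_ids) == 12
        for i in b.fixed_ids:
            assert b.fibril_index[i] % 2 == 1
            ids = np.flatnonzero(b.fibril_index == b.fibril_index[i])
            assert b.positions[i, 0] == b.positions[ids, 0].min()
        for i in b.pulled_ids:
            assert b.fibril_index[i] % 2 == 0

    def test_two_fibril_bundle(self):
        b = G.pack_bundle_n(2, n_beads=5)
        assert b.fibril_index[b.fixed_ids[0]] == 1
        assert b.fibril_index[b.pulled_ids[0]] == 2

    def test_single_fibril_homogeneous_mode(self):
        b = G.pack_bundle_n(1, n_beads=5)
        assert len(b.fixed_ids) == 1 and len(b.pulled_ids) == 1
        assert b.homogeneous


class TestDefects:
    def test_zero_rate_noop(self):
        b = G.pack_bundle_n(7, n_beads=10)
        G.insert_defects(b, 0.0, seed=1)
        assert b.alive.all() and not b.defect_ids

    def test_determinism(self):
        b1 = G.insert_defects(G.pack_bundle_n(7, n_beads=30), 0.05, seed=42)
        b2 = G.insert_defects(G.pack_bundle_n(7, n_beads=30), 0.05, seed=42)
        assert b1.defect_ids == b2.defect_ids

    def test_counts_match_binomial(self):
        # mean deletions over seeds must sit inside the binomial 99% CI
        rate, reps = 0.005, 100
        counts = []
        for seed in range(reps):
            b = G.insert_defects(G.pack_bundle_n(7, n_beads=50), rate, seed=seed)
            counts.append(len(b.defect_ids))
        n_eligible = 7 * 50 - 7  # boundary beads are protected
        mean_expected = n_eligible * rate
        se = math.sqrt(n_eligible * rate * (1 - rate) / reps)
        assert abs(np.mean(counts) - mean_expected) < 2.58 * se

    def test_boundary_beads_protected(self):
        b = G.insert_defects(G.pack_bundle_n(7, n_beads=10), 0.5, seed=3)
        assert b.alive[b.fixed_ids].all()
        assert b.alive[b.pulled_ids].all()

    def test_topology_hygiene(self):
        b = G.insert_defects(G.pack_bundle_n(7, n_beads=30), 0.1, seed=7)
        assert b.alive[b.bonds].all()
        assert b.alive[b.angles].all()
        # angle->bond map must still point at the angle's own beads
        for (i, j, k), (b1, b2) in zip(b.angles, b.angle_bonds):
            assert tuple(b.bonds[b1]) == (i, j)
            assert tuple(b.bonds[b2]) == (j, k)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            G.insert_defects(G.pack_bundle_n(7, n_beads=10), 1.0, seed=0)


def test_json_round_trip(tmp_path):
    b = G.insert_defects(G.pack_bundle_n(7, n_beads=12), 0.05, seed=5)
    path = tmp_path / "bundle.json"
    b.to_json(path)
    b2 = G.BundleGeometry.from_json(path)
    assert np.allclose(b.positions, b2.positions)
    assert np.array_equal(b.bonds, b2.bonds)
    assert b.defect_ids == b2.defect_ids
    assert np.array_equal(b.fixed_ids, b2.fixed_ids)


def test_xyz_frame_format(tmp_path):
    b = G.pack_bundle_n(2, n_beads=4)
    path = tmp_path / "frame.xyz"
    with open(path, "w") as fh:
        b.write_xyz_frame(fh, comment="strain=0.0")
    lines = path.read_text().splitlines()
    assert lines[0] == "8"
    assert lines[1] == "strain=0.0"
    assert len(lines) == 2 + 8
    cols = lines[2].split()
    assert len(cols) == 5
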