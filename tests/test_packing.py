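import numpy as np
import pytest

from lipscan import fixtures as fx
from lipscan.packing import (PackingResult, VolumeSet, mc_power_volumes,
                             mc_volume_oracle, packing_density,
                             power_cell_volumes, voronoi_volumes)
from lipscan.sasa import InterfaceBurial


class TestPowerCells:
    def test_lattice_central_cell_exact(self, lattice3):
        vols, bounded = power_cell_volumes(
            lattice3.coords, lattice3.radii,
            box=(lattice3.coords.min(0) - 5, lattice3.coords.max(0) + 5))
        ci = fx.lattice_center_index(3)
        assert bounded[ci]
        assert vols[ci] == pytest.approx(8.0, abs=1e-6)

    def test_symmetric_pair_equal_volumes(self):
        pts = np.array([[-1.5, 0, 0], [1.5, 0, 0.]])
        # 2-site tessellation needs padding sites to reach the minimum count
        pad = np.array([[0, 8, 0], [0, -8, 0], [0, 0, 8.]])
        allp = np.vstack([pts, pad])
        vols, _ = power_cell_volumes(allp, np.full(5, 1.87),
                                     box=((-4, -4, -4), (4, 4, 4)),
                                     targets=[0, 1])
        assert vols[0] == pytest.approx(vols[1], rel=1e-9)

    def test_modes_agree_for_equal_radii(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 10, size=(40, 3))
        box = ((-2, -2, -2), (12, 12, 12))
        v1, _ = power_cell_volumes(pts, np.full(40, 1.7), mode="radical",
                                   box=box)
        v2, _ = power_cell_volumes(pts, None, mode="bisector", box=box)
        np.testing.assert_allclose(v1, v2, rtol=1e-9)

    def test_conservation_in_closed_box(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10, size=(60, 3))
        radii = rng.uniform(1.2, 2.0, size=60)
        box = ((0, 0, 0), (10, 10, 10))
        vols, _ = power_cell_volumes(pts, radii, box=box)
        assert vols.sum() == pytest.approx(1000.0, rel=0.005)

    def test_deleting_neighbor_never_shrinks_cells(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 8, size=(30, 3))
        radii = rng.uniform(1.3, 1.9, size=30)
        box = ((-1, -1, -1), (9, 9, 9))
        v_all, _ = power_cell_volumes(pts, radii, box=box)
        keep = np.arange(30) != 7
        v_del, _ = power_cell_volumes(pts[keep], radii[keep], box=box)
        assert (v_del >= v_all[keep] - 1e-9).all()

    def test_too_few_sites(self):
        with pytest.raises(ValueError, match="at least 5"):
            power_cell_volumes(np.zeros((3, 3)))

    def test_coplanar_structure_rejected(self):
        from lipscan.structure_io import Atom, Residue, Structure
        atoms, residues = [], []
        for i in range(6):
            atoms.append(Atom(i + 1, "CA", "C", (i + 1, ""), "LAT",
                              (float(i % 3) * 2, float(i // 3) * 2, 0.0),
                              1.87, "apolar", 20.0))
            residues.append(Residue(i + 1, "", "LAT", (i,)))
        flat = Structure("A", residues, atoms, protein_id="flat")
        with pytest.raises(ValueError, match="coplanar|degenerate"):
            voronoi_volumes(flat)


class TestVoronoiVolumes:
    def test_capping_closes_all_helix_cells(self, helix20):
        v = voronoi_volumes(helix20)
        assert v.n_solvent_sites > 0
        assert v.bounded.all()
        assert np.isfinite(v.volumes).all()
        assert (v.volumes > 0).all()

    def test_lattice_center_insensitive_to_capping(self, lattice3):
        v = voronoi_volumes(lattice3)
        ci = fx.lattice_center_index(3)
        assert v.volumes[ci] == pytest.approx(8.0, abs=1e-6)

    def test_rigid_invariance(self, helix20):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [17, 122, -44], degrees=True)
        moved = helix20.transformed(R.as_matrix(), np.array([3.0, -9.0, 2.5]))
        v1 = voronoi_volumes(helix20)
        v2 = voronoi_volumes(moved)
        np.testing.assert_allclose(v1.volumes, v2.volumes, atol=1e-6)

    def test_minimum_atom_count(self):
        with pytest.raises(ValueError, match="at least 5"):
            voronoi_volumes(fx.make_two_body(3.0))


class TestMonteCarloOracle:
    def test_lattice_central_cell(self, lattice3):
        vs = voronoi_volumes(lattice3)
        ci = fx.lattice_center_index(3)
        ctr = np.asarray(vs.sites[ci])   # sites live in the canonical frame
        vols, se = mc_volume_oracle(lattice3, box=(ctr - 1.8, ctr + 1.8),
                                    n_samples=500_000, seed=7,
                                    volume_set=vs)
        assert vols[ci] == pytest.approx(8.0, abs=5 * se[ci] + 0.02)

    def test_sample_conservation(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 6, size=(20, 3))
        box = ((0, 0, 0), (6, 6, 6))
        vols, _ = mc_power_volumes(pts, np.full(20, 1.6), box, 200_000, 3)
        assert vols.sum() == pytest.approx(216.0, rel=1e-9)

    def test_interior_helix_cells_vs_tessellation(self, helix20):
        vs = voronoi_volumes(helix20)
        # pick two backbone atoms near the chain middle: small closed cells
        mid = len(helix20.atoms) // 2
        targets = [mid, mid + 1]
        for t in targets:
            ctr = np.asarray(vs.sites[t])
            vols, se = mc_power_volumes(vs.sites, vs.site_radii,
                                        (ctr - 4.0, ctr + 4.0),
                                        2_000_000, 13, targets=[t])
            rel = abs(vols[0] - vs.volumes[t]) / vs.volumes[t]
            assert rel < 0.01, (t, vols[0], vs.volumes[t])

    def test_minimum_samples_enforced(self):
        with pytest.raises(ValueError):
            mc_power_volumes(np.zeros((5, 3)), np.ones(5),
                             ((0, 0, 0), (1, 1, 1)), 10, 0)


class TestPackingDensity:
    def _burial(self, serials):
        return InterfaceBurial(1, np.array(serials), np.ones(len(serials)),
                               frozenset(serials), 1.0, 1.0)

    def test_identity_and_arithmetic(self, lattice3):
        n = len(lattice3.atoms)
        # every real volume equal to the standard volume -> rho exactly 1
        v_eq = VolumeSet(np.full(n, 20.0), np.ones(n, bool), "radical", 0,
                         2.8, lattice3.coords, lattice3.radii, n,
                         ((0, 0, 0), (1, 1, 1)))
        r = packing_density(self._burial([1, 2]), v_eq, lattice3)
        assert r.rho == pytest.approx(1.0)
        # standard {10, 20} over real {12.5, 25} -> 30/37.5 = 0.8
        vols = np.full(n, np.nan)
        vols[0], vols[1] = 12.5, 25.0
        v = VolumeSet(vols, np.ones(n, bool), "radical", 0, 2.8,
                      lattice3.coords, lattice3.radii, n, ((0,) * 3, (1,) * 3))
        from dataclasses import replace
        s = lattice3
        s.atoms[0] = replace(s.atoms[0], standard_volume=10.0)
        try:
            r = packing_density(self._burial([1, 2]), v, s)
            assert r.rho == pytest.approx(0.8)
        finally:
            s.atoms[0] = replace(s.atoms[0], standard_volume=20.0)

    def test_unbounded_cells_excluded_pairwise(self, lattice3):
        n = len(lattice3.atoms)
        vols = np.full(n, 25.0)
        bounded = np.ones(n, bool)
        bounded[1] = False
        v = VolumeSet(vols, bounded, "radical", 0, 2.8, lattice3.coords,
                      lattice3.radii, n, ((0,) * 3, (1,) * 3))
        r = packing_density(self._burial([1, 2]), v, lattice3)
        # atom serial 2 (index 1) dropped from numerator AND denominator
        assert r.rho == pytest.approx(20.0 / 25.0)
        assert r.n_excluded_atoms == 1

    def test_all_excluded_gives_missing(self, lattice3):
        n = len(lattice3.atoms)
        v = VolumeSet(np.full(n, 25.0), np.zeros(n, bool), "radical", 0,
                      2.8, lattice3.coords, lattice3.radii, n,
                      ((0,) * 3, (1,) * 3))
        r = packing_density(self._burial([1, 2]), v, lattice3)
        assert np.isnan(r.rho)

    def test_empty_interface_rejected(self, lattice3):
        n = len(lattice3.atoms)
        v = VolumeSet(np.full(n, 25.0), np.ones(n, bool), "radical", 0,
                      2.8, lattice3.coords, lattice3.radii, n,
                      ((0,) * 3, (1,) * 3))
        with pytest.raises(ValueError, match="empty interface"):
            packing_density(self._burial([]), v, lattice3)
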