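import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from secsans.abinitio import (
    AnnealConfig,
    BeadModel,
    align_models,
    average_models,
    bead_intensity,
    lattice_sites,
    nsd,
    read_beads_pdb,
    reconstruct_shape,
    write_beads_pdb,
)
from secsans.curves import ScatteringCurve
from secsans.formfactor import intensity_sphere

Q = np.linspace(0.01, 0.25, 30)


def random_model(rng, n=40, span=25.0, r=3.0):
    pts = rng.uniform(-1, 1, (3 * n, 3))
    pts = pts[(pts**2).sum(1) <= 1][:n] * span
    return BeadModel(pts, r)


class TestBeadIntensity:
    def test_single_bead_is_form_factor_and_backends_agree(self):
        m = BeadModel(np.zeros((1, 3)), 3.0)
        ff = intensity_sphere(Q, 3.0)
        np.testing.assert_allclose(bead_intensity(m, Q, "debye"), ff, rtol=1e-12)
        np.testing.assert_allclose(bead_intensity(m, Q, "multipole"), ff, rtol=1e-10)

    def test_two_beads_closed_form(self):
        d = 20.0
        m = BeadModel(np.array([[0, 0, -d / 2], [0, 0, d / 2]]), 3.0)
        expected = intensity_sphere(Q, 3.0) * 2.0 * (1.0 + np.sinc(Q * d / np.pi))
        np.testing.assert_allclose(bead_intensity(m, Q, "debye"), expected, rtol=1e-12)
        np.testing.assert_allclose(bead_intensity(m, Q, "multipole"), expected, rtol=1e-6)

    def test_backend_cross_agreement_on_random_cloud(self):
        rng = np.random.default_rng(1)
        m = random_model(rng, n=50, span=25.0)
        i_mp = bead_intensity(m, Q, "multipole")
        i_db = bead_intensity(m, Q, "debye")
        assert np.max(np.abs(i_mp - i_db) / i_db) < 0.01

    def test_low_lmax_warned_and_raised(self):
        rng = np.random.default_rng(2)
        m = random_model(rng)
        with pytest.warns(UserWarning, match="sampling-theorem"):
            i = bead_intensity(m, Q, "multipole", lmax=2)
        i_db = bead_intensity(m, Q, "debye")
        assert np.max(np.abs(i - i_db) / i_db) < 0.01


class TestNSD:
    def test_identical_models_zero(self):
        rng = np.random.default_rng(3)
        m = random_model(rng)
        assert nsd(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = random_model(rng), random_model(rng)
        assert nsd(a, b) == pytest.approx(nsd(b, a), rel=1e-12)

    def test_single_bead_closed_form(self):
        # two one-bead models at distance d with explicit reference spacing s
        d, s = 7.0, 4.0
        a = BeadModel(np.array([[0.0, 0.0, 0.0]]), 2.0)
        b = BeadModel(np.array([[d, 0.0, 0.0]]), 2.0)
        assert nsd(a, b, spacing=s) == pytest.approx(d / s)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            BeadModel(np.zeros((0, 3)), 2.0)


class TestAlignAverage:
    def test_self_alignment_after_random_rotation(self):
        rng = np.random.default_rng(5)
        m = random_model(rng, n=60)
        R = Rotation.random(random_state=7).as_matrix()
        rotated = BeadModel(m.coordinates @ R.T + np.array([5.0, -3.0, 2.0]), m.bead_radius)
        aligned = align_models([m, rotated])
        assert nsd(aligned[0], aligned[1]) < 0.05

    def test_single_model_centered(self):
        rng = np.random.default_rng(6)
        m = random_model(rng)
        out = align_models([m])
        np.testing.assert_allclose(out[0].coordinates.mean(0), 0.0, atol=1e-9)

    def test_alignment_idempotent(self):
        rng = np.random.default_rng(7)
        models = [random_model(rng), random_model(rng)]
        once = align_models(models)
        twice = align_models(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.coordinates, b.coordinates, atol=1e-8)

    def test_average_of_identical_models(self):
        # reconstruction outputs live on a lattice; averaging snaps to cells
        # of one bead diameter, so lattice models round-trip exactly
        rng = np.random.default_rng(8)
        sites = lattice_sites(50.0, 3.0)
        m = BeadModel(sites[rng.choice(len(sites), 40, replace=False)], 3.0).centered()
        avg = average_models([m, m, m])
        assert len(avg) == len(m)
        np.testing.assert_allclose(np.sort(avg.occupancy), 1.0)
        # same bead set (order may differ)
        d, _ = cKDTree(m.coordinates).query(avg.coordinates)
        assert d.max() < 1e-9

    def test_outlier_run_removed_at_half_cut(self):
        rng = np.random.default_rng(9)
        core = random_model(rng, n=30).centered()
        outlier = BeadModel(
            np.vstack([core.coordinates, core.coordinates + np.array([60.0, 0, 0])]),
            core.bead_radius,
        )
        avg = average_models([core, core, core, outlier], occupancy_cut=0.5)
        # displaced duplicate appears in 1/4 of models only
        assert avg.coordinates[:, 0].max() < 40.0

    def test_single_model_passthrough(self):
        rng = np.random.default_rng(10)
        m = random_model(rng)
        avg = average_models([m])
        assert len(avg) == len(m)


DMAX = 60.0
R_BEAD = 60.0 / 14  # coarse for unit-test speed


@pytest.fixture(scope="module")
def sphere_target():
    q = np.linspace(0.01, 0.25, 50)
    return ScatteringCurve(q, intensity_sphere(q, 30.0), label="sphere")


@pytest.fixture(scope="module")
def sphere_recon(sphere_target):
    return reconstruct_shape(
        sphere_target, DMAX, "P1", AnnealConfig(seed=1), bead_radius=R_BEAD
    )


class TestReconstruction:
    DMAX = DMAX
    R_BEAD = R_BEAD

    def test_sphere_recovered_below_nsd_one(self, sphere_recon):
        true = BeadModel(lattice_sites(self.DMAX, self.R_BEAD), self.R_BEAD)
        assert nsd(sphere_recon, true) < 1.0

    def test_fit_quality_of_final_model(self, sphere_target, sphere_recon):
        i = bead_intensity(sphere_recon, sphere_target.q, "debye")
        s = np.sum(i * sphere_target.intensity) / np.sum(i**2)
        rel = np.linalg.norm(sphere_target.intensity - s * i) / np.linalg.norm(sphere_target.intensity)
        assert rel < 0.05

    def test_backend_agreement_on_final_model(self, sphere_recon):
        i_mp = bead_intensity(sphere_recon, Q, "multipole")
        i_db = bead_intensity(sphere_recon, Q, "debye")
        assert np.max(np.abs(i_mp - i_db) / i_db) < 0.01

    def test_connected_single_component(self, sphere_recon):
        # neighbour graph of the final model has one component
        coords = sphere_recon.coordinates
        tree = cKDTree(coords)
        pairs = tree.query_pairs(2.0 * sphere_recon.bead_radius * 1.001)
        import networkx as nx  # noqa: PLC0415 - test-only dependency

        g = nx.Graph()
        g.add_nodes_from(range(len(coords)))
        g.add_edges_from(pairs)
        assert nx.number_connected_components(g) == 1

    def test_seed_reproducibility(self, sphere_target):
        a = reconstruct_shape(sphere_target, self.DMAX, "P1", AnnealConfig(seed=3), bead_radius=self.R_BEAD)
        b = reconstruct_shape(sphere_target, self.DMAX, "P1", AnnealConfig(seed=3), bead_radius=self.R_BEAD)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_p2_symmetry_exact(self, sphere_target):
        m = reconstruct_shape(sphere_target, self.DMAX, "P2", AnnealConfig(seed=2), bead_radius=self.R_BEAD)
        image = m.coordinates * np.array([-1.0, -1.0, 1.0])
        d, _ = cKDTree(m.coordinates).query(image)
        assert d.max() == 0.0

    def test_short_curve_rejected(self):
        q = np.linspace(0.01, 0.1, 10)
        c = ScatteringCurve(q, intensity_sphere(q, 30.0))
        with pytest.raises(ValueError, match="20 points"):
            reconstruct_shape(c, 60.0)


class TestPdbIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(11)
        m = BeadModel(random_model(rng).coordinates, 3.5, occupancy=rng.uniform(0.5, 1.0, 40))
        path = tmp_path / "beads.pdb"
        write_beads_pdb(m, path)
        back = read_beads_pdb(path)
        np.testing.assert_allclose(back.coordinates, m.coordinates, atol=1e-3)
        np.testing.assert_allclose(back.occupancy, m.occupancy, atol=0.005)
        assert back.bead_radius == pytest.approx(3.5, abs=0.01)
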