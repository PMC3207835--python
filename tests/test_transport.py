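"""Transport kernel: interaction sampling, collimator, detection, tagging."""

import numpy as np
import pytest

from scintcam import materials
from scintcam._kernel import (
    F_LEAD_XRAY,
    F_PENETRATED,
    F_SCAT_CAMERA,
    F_SCAT_PHANTOM,
)
from scintcam.camera import COLLIMATORS, EnergyWindow, make_camera
from scintcam.transport import (
    Biasing,
    EventList,
    Scene,
    classify,
    classify_flags,
    collimator_pass,
    fractions,
    sample_interaction,
    trace,
)

from conftest import SEED


def bare_crystal_camera(**kw):
    defaults = dict(al_window_thickness=0.0, backscatter_thickness=0.0,
                    crystal_gap=0.0, intrinsic_resolution_fwhm=0.0,
                    energy_resolution_fraction=0.0)
    defaults.update(kw)
    return make_camera("VXGP", EnergyWindow(130, 151), **defaults)


class TestSampleInteraction:
    def test_compton_kinematic_bounds(self, rng):
        for e in (80.0, 140.0, 511.0, 2000.0):
            for _ in range(300):
                out = sample_interaction(e, "water", rng)
                if out[0] == "compton":
                    e_min = e / (1.0 + 2.0 * e / 511.0)
                    assert e_min - 1e-9 <= out[1] <= e + 1e-9

    def test_lead_photoelectric_dominates_at_140(self, rng):
        """Channel frequencies reproduce the embedded cross-section table."""
        mat = materials.LEAD
        mus = np.array([mat.mu(140.0, c) for c in range(4)])
        p_photo = mus[0] / mus.sum()
        assert p_photo > 0.5
        n = 4000
        hits = sum(sample_interaction(140.0, "lead", rng)[0] == "photoelectric"
                   for _ in range(n))
        se = np.sqrt(p_photo * (1 - p_photo) / n)
        assert hits / n == pytest.approx(p_photo, abs=4 * se)

    def test_compton_angles_match_klein_nishina_quadrature(self, rng):
        """Sampled cos(theta) histogram matches the KN density by quadrature."""
        e = 140.0
        k = e / 511.0
        mu_grid = np.linspace(-1, 1, 4001)
        eps = 1.0 / (1.0 + k * (1.0 - mu_grid))
        dens = eps**2 * (eps + 1.0 / eps - (1.0 - mu_grid**2))
        dens /= np.trapezoid(dens, mu_grid)
        draws = []
        while len(draws) < 3000:
            out = sample_interaction(e, "water", rng)
            if out[0] == "compton":
                draws.append(out[2])
        draws = np.array(draws[:3000])
        edges = np.linspace(-1, 1, 9)
        hist, _ = np.histogram(draws, bins=edges)
        for j in range(edges.size - 1):
            sel = (mu_grid >= edges[j]) & (mu_grid <= edges[j + 1])
            p = np.trapezoid(dens[sel], mu_grid[sel])
            se = np.sqrt(p * (1 - p) / draws.size)
            assert hist[j] / draws.size == pytest.approx(p, abs=4 * se + 5e-3)

    def test_out_of_table_energy_raises(self, rng):
        with pytest.raises(ValueError, match="keV"):
            sample_interaction(5.0, "water", rng)


class TestCollimatorPass:
    def test_hole_center_normal_ray_passes_clean(self, rng):
        coll = COLLIMATORS["VXGP"]
        outcome, path = collimator_pass((0, 0, 0), (0, 0, 1), 140.0, coll, rng)
        assert outcome == "through-hole"
        assert path == 0.0

    def test_septal_crossing_survival_matches_attenuation(self):
        """Survival of a ray with fixed lead path equals exp(-mu*path)."""
        coll = COLLIMATORS["VXGP"]
        ray = ((0.6, 0.0, 0.0), (np.sin(0.06), 0.0, np.cos(0.06)))
        probe = collimator_pass(ray[0], ray[1], 140.0, coll,
                                np.random.default_rng(0))
        lead_path = probe[1]
        assert lead_path > 0.05  # the ray does cross septal lead
        mu = materials.LEAD.mu(140.0)
        p_surv = np.exp(-mu * lead_path)
        rng = np.random.default_rng(SEED)
        n = 3000
        survived = sum(
            collimator_pass(ray[0], ray[1], 140.0, coll, rng)[0] == "penetrated"
            for _ in range(n)
        )
        se = np.sqrt(p_surv * (1 - p_surv) / n)
        assert survived / n == pytest.approx(p_surv, abs=4 * se)

    def test_beta_sensitivity_collimator_ordering(self):
        """For the same beta isotope and window the medium-energy collimator
        is more sensitive than the high-energy one (penetration-driven)."""
        from scintcam.nema_metrics import simulated_sensitivity
        from scintcam.phantoms import petri_scene

        sens = {}
        for cid in ("MEGP", "HEGP"):
            cam = make_camera(cid, EnergyWindow(50, 250))
            ev = trace(petri_scene(10, "Y90"), cam, 400_000, seed=SEED,
                       biasing=Biasing(b1=0.5, b2=0.4, cone1_deg=30.0,
                                       cone2_deg=75.0))
            sens[cid] = simulated_sensitivity(ev, cam.window)
        assert sens["MEGP"] > sens["HEGP"]


class TestTrace:
    def test_crystal_efficiency_matches_closed_form(self):
        """Pencil beam on the bare crystal: P(detect) = 1 - exp(-mu*t)."""
        cam = bare_crystal_camera()
        scene = Scene(isotope="Tc99m", volumes=(),
                      source={"kind": "point", "pencil": True}, distance_mm=50.0)
        n = 150_000
        ev = trace(scene, cam, n, seed=SEED, collimator_enabled=False)
        mu = materials.NAI.mu(140.5)
        expected = 1.0 - np.exp(-mu * cam.crystal_thickness)
        se = np.sqrt(expected * (1 - expected) / n)
        assert len(ev) / n == pytest.approx(expected, abs=4 * se)

    def test_same_seed_replays_bit_identically(self, tc_camera):
        from scintcam.phantoms import line_source_scene

        scene = line_source_scene(2, 2, "Tc99m")
        a = trace(scene, tc_camera, 50_000, seed=77)
        b = trace(scene, tc_camera, 50_000, seed=77)
        for name in ("weight", "birth_energy", "deposit_energy",
                     "measured_energy", "x", "y", "flags"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_blur_disabled_positions_are_exact(self):
        """With intrinsic blur off, photo-absorbed pencil photons land at
        exactly the beam position."""
        cam = bare_crystal_camera()
        scene = Scene(isotope="Tc99m", volumes=(),
                      source={"kind": "point", "pencil": True}, distance_mm=10.0)
        ev = trace(scene, cam, 20_000, seed=3, collimator_enabled=False)
        exact = (ev.x == 0.0) & (ev.y == 0.0)
        assert exact.mean() > 0.5  # photoelectric-first events

    def test_rejects_iq_scene(self, tc_camera):
        from scintcam.phantoms import iq_phantom_scene

        with pytest.raises(ValueError, match="slab"):
            trace(iq_phantom_scene("Tc99m", 137.0, 9.0), tc_camera, 10, seed=0)

    def test_hdf5_roundtrip(self, tc_camera, tmp_path):
        scene = Scene(isotope="Tc99m", volumes=(),
                      source={"kind": "point", "pencil": True}, distance_mm=10.0)
        ev = trace(scene, bare_crystal_camera(), 5_000, seed=5,
                   collimator_enabled=False)
        path = str(tmp_path / "events.h5")
        ev.to_hdf5(path)
        back = EventList.from_hdf5(path)
        assert np.array_equal(ev.x, back.x)
        assert back.n_emitted == ev.n_emitted
        assert back.config == ev.config


class TestClassification:
    def test_clean_history_is_primary(self):
        assert classify(0) == "primary"

    def test_penetration_wins_over_scatter(self):
        assert classify(F_SCAT_PHANTOM | F_PENETRATED) == "penetrated"
        assert classify(F_SCAT_CAMERA | F_PENETRATED) == "penetrated"

    def test_lead_xray_is_scatter(self):
        assert classify(F_LEAD_XRAY) == "scatter"

    def test_undetected_history_raises(self):
        with pytest.raises(ValueError):
            classify(None)

    def test_all_primary_toy_list(self):
        ev = EventList(
            weight=np.ones(5), birth_energy=np.full(5, 140.5),
            deposit_energy=np.full(5, 140.0), measured_energy=np.full(5, 140.0),
            x=np.zeros(5), y=np.zeros(5), flags=np.zeros(5, dtype=np.uint8),
            n_emitted=5, seed=0, photons_per_decay=0.89,
        )
        rep = fractions(ev)
        assert (rep.pf, rep.sf, rep.cpf) == (100.0, 0.0, 0.0)

    def test_fractions_partition_sums_to_100(self, tc_fraction_events, tc_camera):
        rep = fractions(tc_fraction_events, tc_camera.window)
        assert rep.pf + rep.sf + rep.cpf == pytest.approx(100.0, abs=1e-9)

    def test_empty_event_list_raises(self):
        ev = EventList(
            weight=np.zeros(0), birth_energy=np.zeros(0),
            deposit_energy=np.zeros(0), measured_energy=np.zeros(0),
            x=np.zeros(0), y=np.zeros(0), flags=np.zeros(0, dtype=np.uint8),
            n_emitted=10, seed=0, photons_per_decay=0.89,
        )
        with pytest.raises(ValueError):
            fractions(ev)


def test_variance_reduction_agrees_with_analog():
    """Biased and analog emission give the same detected fraction and
    class fractions within 3 sigma on a small scene."""
    cam = make_camera("VXGP", EnergyWindow(130, 151))
    scene = Scene(isotope="Tc99m", volumes=(), source={"kind": "point"},
                  distance_mm=20.0)
    n = 400_000
    analog = trace(scene, cam, n, seed=SEED + 1, biasing=Biasing.analog())
    biased = trace(scene, cam, n, seed=SEED + 2,
                   biasing=Biasing(b1=0.8, b2=0.1, cone1_deg=10.0,
                                   cone2_deg=60.0))
    m_a = analog.in_window(cam.window)
    m_b = biased.in_window(cam.window)
    f_a = analog.weight[m_a].sum() / n
    f_b = biased.weight[m_b].sum() / n
    var_a = (analog.weight[m_a] ** 2).sum() / n**2
    var_b = (biased.weight[m_b] ** 2).sum() / n**2
    assert abs(f_a - f_b) < 3.0 * np.sqrt(var_a + var_b)

    cls_a = classify_flags(analog.flags[m_a])
    pf_a = analog.weight[m_a][cls_a == 0].sum() / analog.weight[m_a].sum()
    cls_b = classify_flags(biased.flags[m_b])
    pf_b = biased.weight[m_b][cls_b == 0].sum() / biased.weight[m_b].sum()
    se = np.sqrt(pf_a * (1 - pf_a) / max(m_a.sum(), 1)
                 + pf_b * (1 - pf_b) / max(m_b.sum(), 1))
    assert abs(pf_a - pf_b) < max(3.0 * se, 0.02)
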