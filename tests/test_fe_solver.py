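"""FE solver verification: patch tests, viscoelastic relaxation,
frequency limits and load-mode behaviour."""

import numpy as np
import pytest

from cytomech.fe import (
    CYTOPLASM,
    LoadSpec,
    SingularSystemError,
    assemble_viscoelastic,
    build_box_mesh,
    build_cell_mesh,
    max_principal_strain,
    reaction_force,
    solve_transient,
    stress_history,
)
from cytomech.pipeline import simulate_cell

TAU = CYTOPLASM.tau


def _uniaxial_box_system(nx=2, ny=2, nz=2):
    """Box under top pressure, free lateral faces: bottom held in z only,
    two pins kill the in-plane rigid modes, so the stress state is
    homogeneous uniaxial."""
    mesh = build_box_mesh(1, 1, 1, nx, ny, nz)
    n = mesh.nodes
    fixed = [3 * i + 2 for i in np.where(n[:, 2] < 1e-12)[0]]
    origin = int(np.where((np.abs(n) < 1e-12).all(axis=1))[0][0])
    xn = int(np.where((np.abs(n - [1, 0, 0]) < 1e-12).all(axis=1))[0][0])
    fixed += [3 * origin, 3 * origin + 1, 3 * xn + 1]
    return mesh, assemble_viscoelastic(
        mesh, {"cytoplasm": CYTOPLASM}, fixed_dofs=np.array(fixed)
    )


class TestAssembly:
    def test_stiffness_symmetric(self):
        _, sys_ = _uniaxial_box_system()
        K = sys_.elastic_stiffness()
        d = abs(K - K.T)
        assert d.max() <= 1e-9 * abs(K).max()

    def test_rigid_translation_zero_force(self):
        _, sys_ = _uniaxial_box_system()
        K = sys_.elastic_stiffness()
        for comp in range(3):
            u = np.zeros(sys_.ndof)
            u[comp::3] = 1.0
            assert np.abs(K @ u).max() <= 1e-9 * abs(K).max()

    def test_unconstrained_system_rejected(self):
        mesh = build_box_mesh(1, 1, 1, 1, 1, 1)
        with pytest.raises(SingularSystemError):
            assemble_viscoelastic(mesh, {"cytoplasm": CYTOPLASM},
                                  fixed_dofs=np.array([], dtype=int))


P_PATCH = 100.0


@pytest.fixture(scope="module")
def instantaneous():
    _, sys_ = _uniaxial_box_system()
    rep = solve_transient(sys_, LoadSpec(P_PATCH, duration=TAU / 100),
                          dt=TAU / 100, record="all")
    return rep.strain_history[0]


@pytest.fixture(scope="module")
def longterm():
    _, sys_ = _uniaxial_box_system()
    rep = solve_transient(sys_, LoadSpec(P_PATCH, duration=15 * TAU),
                          dt=TAU / 4, record="all")
    return rep.strain_history[-1]


class TestPatchTest:
    """Uniform uniaxial stress reproduced exactly at both elastic limits."""

    P = P_PATCH

    def test_instantaneous_limit(self, instantaneous):
        E0, nu = CYTOPLASM.E0_pa, CYTOPLASM.poisson_ratio
        np.testing.assert_allclose(instantaneous[:, 2], -self.P / E0, rtol=0.01)
        np.testing.assert_allclose(instantaneous[:, 0], nu * self.P / E0, rtol=0.01)
        np.testing.assert_allclose(instantaneous[:, 3:], 0.0, atol=1e-12)

    def test_instantaneous_strain_homogeneous(self, instantaneous):
        assert instantaneous[:, 2].std() < 1e-12

    def test_longterm_limit(self, longterm):
        K, G = CYTOPLASM.bulk_modulus_pa, CYTOPLASM.G_inf_pa
        E_inf = 9 * K * G / (3 * K + G)
        nu_inf = (3 * K - 2 * G) / (2 * (3 * K + G))
        np.testing.assert_allclose(longterm[:, 2], -self.P / E_inf, rtol=0.01)
        np.testing.assert_allclose(longterm[:, 0], nu_inf * self.P / E_inf,
                                   rtol=0.01)

    def test_lateral_strain_is_poisson_expansion(self, instantaneous):
        """Free uniaxial compression: max principal strain is the lateral
        Poisson expansion nu * |eps_axial|."""
        nu = CYTOPLASM.poisson_ratio
        mp = max_principal_strain(instantaneous)
        np.testing.assert_allclose(mp, nu * np.abs(instantaneous[:, 2]),
                                   rtol=0.01)


class TestRelaxation:
    def test_confined_step_strain_relaxes_to_half(self):
        """Held strain state: deviatoric stress decays by G_inf/G0 = 0.5.

        Confined compression (all lateral motion blocked) holds the strain
        tensor constant, so the deviatoric stress follows G(t) exactly.
        """
        mesh = build_box_mesh(1, 1, 1, 2, 2, 2)
        n = mesh.nodes
        fixed = []
        for i in range(len(n)):
            fixed += [3 * i, 3 * i + 1]  # confined: no lateral motion
        fixed += [3 * i + 2 for i in np.where(n[:, 2] < 1e-12)[0]]
        top = np.where(np.abs(n[:, 2] - 1.0) < 1e-12)[0]
        presc = np.array([3 * i + 2 for i in top])
        sys_ = assemble_viscoelastic(
            mesh, {"cytoplasm": CYTOPLASM}, fixed_dofs=np.array(fixed),
            prescribed_dofs=presc, prescribed_unit=-np.ones(len(presc)),
        )
        dt = TAU / 200
        rep = solve_transient(sys_, LoadSpec(0.02, duration=8 * TAU),
                              dt=dt, record="all")
        # strain is held constant after the first step
        np.testing.assert_allclose(rep.strain_history[-1],
                                   rep.strain_history[0], atol=1e-12)
        sig = stress_history(sys_, rep.strain_history, dt)
        s = sig[:, :, 2] - sig[:, :, :3].mean(axis=2)  # deviatoric zz
        ratio = s[-1] / s[0]
        np.testing.assert_allclose(
            ratio, CYTOPLASM.G_inf / CYTOPLASM.G0, rtol=0.01
        )

    def test_reaction_force_relaxes(self):
        """Support force under held displacement decays monotonically."""
        mesh = build_box_mesh(1, 1, 1, 2, 2, 2)
        n = mesh.nodes
        fixed = [3 * i for i in range(len(n))]
        fixed += [3 * i + 1 for i in range(len(n))]
        fixed += [3 * i + 2 for i in np.where(n[:, 2] < 1e-12)[0]]
        top = np.where(np.abs(n[:, 2] - 1.0) < 1e-12)[0]
        presc = np.array([3 * i + 2 for i in top])
        sys_ = assemble_viscoelastic(
            mesh, {"cytoplasm": CYTOPLASM}, fixed_dofs=np.array(fixed),
            prescribed_dofs=presc, prescribed_unit=-np.ones(len(presc)),
        )
        dt = TAU / 50
        rep = solve_transient(sys_, LoadSpec(0.02, duration=6 * TAU),
                              dt=dt, record="all")
        sig = stress_history(sys_, rep.strain_history, dt)
        forces = [reaction_force(sys_, sig[k], presc)
                  for k in range(0, len(sig), 20)]
        diffs = np.diff(np.abs(forces))
        assert np.all(diffs <= 1e-9 * abs(forces[0]))


class TestTransient:
    def test_zero_amplitude_cyclic_equals_static(self):
        _, s1 = _uniaxial_box_system(1, 1, 1)
        _, s2 = _uniaxial_box_system(1, 1, 1)
        r_cyc = solve_transient(s1, LoadSpec(100.0, 0.0, 1.0, duration=2.0),
                                dt=0.05, record="all")
        r_sta = solve_transient(s2, LoadSpec(100.0, 0.0, 0.0, duration=2.0),
                                dt=0.05, record="all")
        np.testing.assert_allclose(r_cyc.strain_history, r_sta.strain_history,
                                   atol=1e-14)

    def test_zero_load_zero_strain(self):
        _, sys_ = _uniaxial_box_system(1, 1, 1)
        rep = solve_transient(sys_, LoadSpec(0.0, duration=0.5), dt=0.1,
                              record="all")
        np.testing.assert_allclose(rep.strain_history, 0.0, atol=1e-15)
        assert rep.avg_max_principal == pytest.approx(0.0, abs=1e-15)

    def test_static_converges_to_longterm_elastic(self):
        """After many relaxation times the transient solution matches the
        purely elastic solution with the long-term modulus."""
        from scipy.sparse.linalg import spsolve

        _, sys_ = _uniaxial_box_system()
        rep = solve_transient(sys_, LoadSpec(100.0, duration=15 * TAU),
                              dt=TAU / 4, record="all")
        K = sys_.elastic_stiffness("longterm")
        u = np.zeros(sys_.ndof)
        u[sys_.free] = spsolve(K[sys_.free][:, sys_.free].tocsc(),
                               100.0 * sys_.f_unit[sys_.free])
        eps_el = np.einsum("eij,ej->ei", sys_.B, u[sys_.dofmap])
        np.testing.assert_allclose(rep.strain_history[-1], eps_el,
                                   rtol=0.01, atol=1e-9)

    def test_dt_too_coarse_for_cycle_rejected(self):
        _, sys_ = _uniaxial_box_system(1, 1, 1)
        with pytest.raises(ValueError):
            solve_transient(sys_, LoadSpec(100.0, 50.0, 1.0), dt=0.2)

    def test_frequency_sweep_monotone_between_elastic_limits(self):
        """Cyclic strain amplitude falls from the long-term to the
        instantaneous elastic response as frequency grows."""
        amps = []
        for f, ncyc in [(0.05, 3), (1.0, 5), (20.0, 40)]:
            _, sys_ = _uniaxial_box_system(1, 1, 1)
            rep = solve_transient(sys_, LoadSpec(100.0, 50.0, f),
                                  n_cycles=ncyc, record="all")
            last = rep.times > rep.times[-1] - 1.0 / f
            ezz = rep.strain_history[last, 0, 2]
            amps.append((ezz.max() - ezz.min()) / 2.0)
        assert amps[0] > amps[1] > amps[2]
        K, G = CYTOPLASM.bulk_modulus_pa, CYTOPLASM.G_inf_pa
        E_inf = 9 * K * G / (3 * K + G)
        assert amps[0] == pytest.approx(50.0 / E_inf, rel=0.10)
        assert amps[2] == pytest.approx(50.0 / CYTOPLASM.E0_pa, rel=0.10)


@pytest.fixture(scope="module")
def small_static():
    return simulate_cell(45.0, LoadSpec(100.0), target_elements=1200)


class TestCellRun:
    def test_membrane_summary_sane(self, small_static):
        rep = small_static
        assert np.isfinite(rep.avg_max_principal)
        assert rep.peak_max_principal >= rep.avg_max_principal
        assert rep.avg_max_principal > 0
        assert rep.interior_mask.sum() > 0
        assert len(rep.membrane_strains_at_eval()) == rep.interior_mask.sum()

    def test_filament_effect_direction(self):
        """Perpendicular filaments increase the average membrane strain
        relative to parallel ones — the reorientation mechanism."""
        r0 = simulate_cell(0.0, LoadSpec(100.0), target_elements=1200)
        r90 = simulate_cell(90.0, LoadSpec(100.0), target_elements=1200)
        assert r90.avg_max_principal >= r0.avg_max_principal

    def test_platen_calibration_independent_of_filaments(self):
        from cytomech.fe import add_filaments

        m1 = build_cell_mesh(target_elements=1200, seed=0)
        s1 = assemble_viscoelastic(m1, contact="platen")
        m2 = add_filaments(build_cell_mesh(target_elements=1200, seed=0),
                           alpha=45.0)
        s2 = assemble_viscoelastic(m2, contact="platen")
        assert s1.delta_per_pa == pytest.approx(s2.delta_per_pa, rel=1e-12)
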