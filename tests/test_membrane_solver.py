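"""Forward solver: assembly consistency, Newton continuation, linear path."""

import numpy as np
import pytest

from conftest import square_membrane
from lungifea.constitutive import MaterialField, MooneyRivlinParams
from lungifea.membrane_solver import (
    BoundarySeries,
    LinearMembraneSystem,
    MembraneSystem,
    PressureProfile,
    StageSolution,
    principal_strains,
    run_inflation,
)
from lungifea.synthetic_lung import generate_pressure_profile

MR = MooneyRivlinParams(136.5, 1.0, 13.43e-4)


class TestPressureProfile:
    def test_validation(self):
        with pytest.raises(ValueError):
            PressureProfile([0, 1, 1], [0, 1, 2])  # non-increasing times
        with pytest.raises(ValueError):
            PressureProfile([0, 1], [0, -1])       # negative pressure

    def test_default_stage_times_are_five_even_increments(self):
        p = PressureProfile([0.0, 2.0], [0.0, 1.0])
        assert np.allclose(p.stage_times, [0.4, 0.8, 1.2, 1.6, 2.0])

    def test_csv_roundtrip(self, tmp_path):
        p = generate_pressure_profile(2.0, 2.0, n_samples=11)
        p.to_csv(tmp_path / "p.csv")
        back = PressureProfile.from_csv(tmp_path / "p.csv")
        assert np.allclose(back.times, p.times)
        assert np.allclose(back.pressures, p.pressures)


class TestBoundarySeries:
    def test_linear_interpolation_and_zero_start(self):
        b = BoundarySeries([0, 1], [1.0, 2.0],
                           [[[1, 0, 0], [0, 1, 0]], [[2, 0, 0], [0, 2, 0]]])
        assert np.allclose(b.at(0.0), 0.0)
        assert np.allclose(b.at(0.5), [[0.5, 0, 0], [0, 0.5, 0]])
        assert np.allclose(b.at(1.5), [[1.5, 0, 0], [0, 1.5, 0]])
        assert np.allclose(b.at(9.0), b.displacements[-1])

    def test_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        b = BoundarySeries(np.arange(4), [0.5, 1.0], rng.normal(size=(2, 4, 3)))
        b.to_csv(tmp_path / "b.csv")
        back = BoundarySeries.from_csv(tmp_path / "b.csv")
        assert np.allclose(back.displacements, b.displacements)
        assert np.array_equal(back.node_ids, b.node_ids)


class TestAssembly:
    def test_zero_state_equilibrium(self, cap40):
        system = MembraneSystem(cap40, MaterialField("homo/iso/hyper", MR))
        resid, K, _ = system.assemble(np.zeros((cap40.n_nodes, 3)), 0.0)
        assert np.abs(resid).max() < 1e-9  # zero to solver tolerance

    def test_tangent_matches_global_residual_differencing(self, cap40):
        system = MembraneSystem(cap40, MaterialField("homo/iso/hyper", MR))
        rng = np.random.default_rng(0)
        u = rng.normal(0, 0.05, (cap40.n_nodes, 3))
        pressure = 0.5
        resid, K, _ = system.assemble(u, pressure)
        K = K.toarray()
        h = 1e-6
        free = rng.choice(system.M, 25, replace=False)  # spot-check columns
        for j in free:
            up = u.ravel().copy()
            up[j] += h
            um = u.ravel().copy()
            um[j] -= h
            rp, _ = system._residual_only(up.reshape(-1, 3), pressure)
            rm, _ = system._residual_only(um.reshape(-1, 3), pressure)
            col_fd = -(rp - rm) / (2 * h)
            assert np.abs(K[:, j] - col_fd).max() < 1e-5 * max(
                np.abs(col_fd).max(), 1.0
            )


class TestSolveStage:
    def test_null_load_gives_null_displacement(self, cap40):
        system = MembraneSystem(cap40, MaterialField("homo/iso/hyper", MR))
        nb = len(system.perimeter)
        sol = system.solve_stage(0.0, np.zeros((nb, 3)))
        assert np.abs(sol.u).max() < 1e-10
        assert sol.converged

    def test_boundary_data_must_cover_perimeter(self, cap40):
        system = MembraneSystem(cap40, MaterialField("homo/iso/hyper", MR))
        with pytest.raises(ValueError):
            system.solve_stage(0.1, np.zeros((2, 3)))

    def test_rigid_translation_of_boundary_translates_solution(self, cap40):
        system = MembraneSystem(cap40, MaterialField("homo/iso/hyper", MR))
        nb = len(system.perimeter)
        p = 0.8
        sol = system.solve_stage(p, np.zeros((nb, 3)), n_increments=2)
        shift = np.array([1.3, -0.4, 2.0])
        sol2 = system.solve_stage(p, np.tile(shift, (nb, 1)), n_increments=2)
        assert np.abs(sol2.u - (sol.u + shift)).max() < 1e-6

    def test_strain_energy_increases_along_pressure_ramp(self, cap120):
        profile = generate_pressure_profile(2.0, 2.0)
        sols = run_inflation(cap120, MaterialField("homo/iso/hyper", MR), profile)
        energies = [s.strain_energy for s in sols]
        assert energies[0] > 0
        assert np.all(np.diff(energies) > 0)

    def test_monotone_pressure_gives_monotone_volume(self, cap120):
        profile = generate_pressure_profile(2.0, 2.0)
        sols = run_inflation(cap120, MaterialField("homo/iso/hyper", MR), profile)
        vols = [s.volume_change for s in sols]
        assert np.all(np.diff(vols) > 0)

    def test_rerun_is_deterministic(self, cap40):
        profile = generate_pressure_profile(1.0, 2.0)
        f = MaterialField("homo/iso/hyper", MR)
        a = run_inflation(cap40, f, profile)
        b = run_inflation(cap40, f, profile)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.u, sb.u)


class TestLinearSystem:
    def test_zero_load_zero_solution(self, cap40):
        system = LinearMembraneSystem(cap40)
        u = system.solve_linear(np.tile([300.0, 0.43], cap40.n_elems),
                                np.zeros(system.M))
        assert np.abs(u).max() < 1e-14

    def test_solution_satisfies_linear_system(self, cap40):
        system = LinearMembraneSystem(cap40, pretension=5.0)
        p = np.tile([300.0, 0.43], cap40.n_elems)
        f = system.pressure_load(1.0)
        u = system.solve_linear(p, f)
        K = system.assemble(p)
        free = system.free_dofs
        Kff = K[free][:, free]
        import scipy.sparse as sp

        Kff = Kff + system._eps * sp.identity(len(free), format="csr")
        r = Kff @ u.ravel()[free] - f[free]
        assert np.linalg.norm(r) / np.linalg.norm(f[free]) < 1e-10

    def test_agrees_with_dense_solve(self, cap40):
        system = LinearMembraneSystem(cap40, pretension=5.0)
        p = np.tile([300.0, 0.43], cap40.n_elems)
        f = system.pressure_load(1.0)
        u = system.solve_linear(p, f)
        K = system.assemble(p).toarray()
        free = system.free_dofs
        Kd = K[np.ix_(free, free)] + system._eps * np.eye(len(free))
        ud = np.linalg.solve(Kd, f[free])
        assert np.abs(u.ravel()[free] - ud).max() < 1e-10 * max(
            1.0, np.abs(ud).max()
        )

    def test_doubling_stiffness_halves_displacement(self, cap40):
        system = LinearMembraneSystem(cap40)
        f = system.pressure_load(1.0)
        E = np.full(cap40.n_elems, 300.0)
        nu = np.full(cap40.n_elems, 0.43)
        p1 = np.empty(2 * cap40.n_elems)
        p1[0::2], p1[1::2] = E, nu
        p2 = p1.copy()
        p2[0::2] *= 2
        u1 = system.solve_linear(p1, f)
        u2 = system.solve_linear(p2, f)
        assert np.allclose(u2, 0.5 * u1, rtol=1e-8, atol=1e-12)

    def test_scaling_invariance_E_and_load(self, cap40):
        system = LinearMembraneSystem(cap40)
        f = system.pressure_load(1.0)
        p1 = np.tile([300.0, 0.43], cap40.n_elems)
        c = 3.7
        p2 = p1.copy()
        p2[0::2] *= c
        u1 = system.solve_linear(p1, f)
        u2 = system.solve_linear(p2, c * f)
        assert np.allclose(u1, u2, rtol=1e-8, atol=1e-12)

    def test_pretensioned_patch_matches_series_solution(self):
        # classical membrane Poisson problem: T lap w = -p on a square
        L, T, p = 100.0, 10.0, 0.01
        n = 16
        mesh = square_membrane(n, L)
        system = LinearMembraneSystem(mesh, pretension=T)
        u = system.solve_linear(np.tile([100.0, 0.3], mesh.n_elems),
                                system.pressure_load(p))
        w = u[(n // 2) * (n + 1) + n // 2, 2]
        s = sum(
            np.sin(m * np.pi / 2) * np.sin(k * np.pi / 2) / (m * k * (m**2 + k**2))
            for m in range(1, 60, 2)
            for k in range(1, 60, 2)
        )
        w_ref = 16 * p * L**2 / (np.pi**4 * T) * s
        assert w == pytest.approx(w_ref, rel=0.02)

    def test_patch_test_mesh_refinement_convergence(self):
        L, T, p = 100.0, 10.0, 0.01
        s = sum(
            np.sin(m * np.pi / 2) * np.sin(k * np.pi / 2) / (m * k * (m**2 + k**2))
            for m in range(1, 60, 2)
            for k in range(1, 60, 2)
        )
        w_ref = 16 * p * L**2 / (np.pi**4 * T) * s
        errs = []
        for n in (8, 16, 32):
            mesh = square_membrane(n, L)
            system = LinearMembraneSystem(mesh, pretension=T)
            u = system.solve_linear(np.tile([100.0, 0.3], mesh.n_elems),
                                    system.pressure_load(p))
            errs.append(abs(u[(n // 2) * (n + 1) + n // 2, 2] - w_ref))
        # roughly second-order: each refinement shrinks the error ~4x
        assert errs[1] < errs[0] / 2.5
        assert errs[2] < errs[1] / 2.5


class TestPrincipalStrains:
    def _solution_with_C(self, mesh, C2d):
        return StageSolution(
            stage=0, time=0.0, pressure=0.0,
            u=np.zeros((mesh.n_nodes, 3)), C2d=C2d,
            cauchy=np.zeros((mesh.n_elems, 3, 3)), strain_energy=0.0,
            volume_change=0.0, converged=True, n_iter=0,
        )

    def test_equibiaxial_degenerate_eigenvalues(self, cap40):
        lam = 1.15
        C = np.tile(lam**2 * np.eye(2), (cap40.n_elems, 1, 1))
        sf = principal_strains(cap40, self._solution_with_C(cap40, C))
        assert np.allclose(sf.major, lam - 1, atol=1e-12)
        assert np.allclose(sf.minor, lam - 1, atol=1e-12)
        # directions arbitrary but orthonormal and tangent to the plane
        assert np.abs(np.einsum("ij,ij->i", sf.dir_major, sf.dir_minor)).max() < 1e-10

    def test_uniaxial_major_direction_is_local_x(self, cap40):
        from lungifea.surface_mesh import compute_local_frames

        lam = 1.2
        C = np.tile(np.diag([lam**2, 1.0]), (cap40.n_elems, 1, 1))
        sf = principal_strains(cap40, self._solution_with_C(cap40, C))
        fr = compute_local_frames(cap40)
        align = np.abs(np.einsum("ij,ij->i", sf.dir_major, fr.x_axis))
        assert np.all(align > 1 - 1e-10)
        assert np.allclose(sf.major, lam - 1, atol=1e-12)
        assert np.allclose(sf.minor, 0.0, atol=1e-12)

    def test_random_states_match_bruteforce_eigensolver(self, cap40):
        rng = np.random.default_rng(0)
        A = rng.normal(0, 0.1, (cap40.n_elems, 2, 2))
        C = np.eye(2) + A @ np.swapaxes(A, 1, 2)
        sf = principal_strains(cap40, self._solution_with_C(cap40, C))
        for e in range(cap40.n_elems):
            w = np.sqrt(np.linalg.eigvalsh(C[e]))
            assert sf.minor[e] == pytest.approx(w[0] - 1, abs=1e-10)
            assert sf.major[e] == pytest.approx(w[1] - 1, abs=1e-10)
        assert np.all(sf.major >= sf.minor)
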