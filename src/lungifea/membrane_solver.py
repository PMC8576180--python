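"""Forward membrane mechanics: quasi-static inflation and the linear solve.

Two solution paths share the mesh/element infrastructure:

* **Nonlinear path** (homogeneous hyperelastic cases): quasi-static Newton
  continuation under a follower pressure (normal to the deforming surface)
  with prescribed perimeter displacements.  The element internal force is the
  exact gradient of the membrane strain energy; the consistent tangent is
  assembled by central differencing the element force vectors (element-local,
  so the cost is 18 vectorised force evaluations per assembly and the tangent
  includes material, geometric and follower-pressure contributions).

* **Linear path** (heterogeneous linear-elastic case): the small-strain
  membrane stiffness ``K(p) u = f`` with per-element (E, nu), an optional
  isotropic pre-tension (geometric) stiffness, dead pressure load along
  reference normals, and exact sparse factorisation with multi-stage
  right-hand sides.  This is the operator the adjoint gradient differentiates.

A small stabilisation term (scaled identity on free DOFs, default 1e-6 of the
mean stiffness diagonal) regularises wrinkling-prone/flat configurations; it
enters only the iteration matrix of the nonlinear path, so converged states
are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (
    ElementInversionError,
    MaterialField,
    PlaneStressError,
    hgo_stress_batch,
    linear_plane_stress_matrix_batch,
    linear_plane_stress_matrix_dnu,
    mr_stress_batch,
)
from .surface_mesh import SurfaceMesh, compute_local_frames, enclosed_volume_change, perimeter_nodes

__all__ = [
    "PressureProfile",
    "BoundarySeries",
    "StageSolution",
    "StrainField",
    "MembraneSystem",
    "LinearMembraneSystem",
    "run_inflation",
    "principal_strains",
    "SolverError",
]


class SolverError(RuntimeError):
    """Newton continuation failed; carries last iterate diagnostics."""

    def __init__(self, message, u_last=None):
        super().__init__(message)
        self.u_last = u_last


# ---------------------------------------------------------------------------
# Loading


@dataclass
class PressureProfile:
    """Sampled pressure-time loading with the stage times for error evaluation.

    ``times`` in s (strictly increasing), ``pressures`` in kPa (non-negative).
    ``stage_times`` default to the five 20%-increments of the time span,
    matching the convention of evaluating displacement error at five evenly
    spaced points of the inflation cycle.
    """

    times: np.ndarray
    pressures: np.ndarray
    stage_times: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.pressures = np.asarray(self.pressures, float)
        if self.times.ndim != 1 or self.times.shape != self.pressures.shape:
            raise ValueError("times and pressures must be equal-length 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.pressures < 0):
            raise ValueError("pressures must be non-negative")
        if self.stage_times is None:
            t0, t1 = self.times[0], self.times[-1]
            self.stage_times = t0 + (t1 - t0) * np.linspace(0.2, 1.0, 5)
        self.stage_times = np.asarray(self.stage_times, float)
        if np.any(self.stage_times < self.times[0]) or np.any(
            self.stage_times > self.times[-1]
        ):
            raise ValueError("stage_times must lie within the sampled span")

    def pressure_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.pressures)

    @classmethod
    def from_csv(cls, path, stage_times=None) -> "PressureProfile":
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "time" not in cols or "pressure" not in cols:
            raise ValueError("pressure CSV needs 'time' and 'pressure' columns")
        return cls(df[cols["time"]].to_numpy(), df[cols["pressure"]].to_numpy(),
                   stage_times=stage_times)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "pressure": self.pressures}).to_csv(
            path, index=False
        )


@dataclass
class BoundarySeries:
    """Prescribed displacement time-series for the perimeter nodes.

    ``displacements`` has shape (n_stages, n_nodes_b, 3); between stage times
    the prescribed values are interpolated linearly, and ramp from zero at
    t = 0 up to the first stage.
    """

    node_ids: np.ndarray
    stage_times: np.ndarray
    displacements: np.ndarray

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, np.int64)
        self.stage_times = np.asarray(self.stage_times, float)
        self.displacements = np.asarray(self.displacements, float)
        if self.displacements.shape != (
            len(self.stage_times),
            len(self.node_ids),
            3,
        ):
            raise ValueError("displacements must be (n_stages, n_nodes_b, 3)")

    def at(self, t: float) -> np.ndarray:
        """(n_nodes_b, 3) prescribed displacement at time t."""
        ts = np.concatenate([[0.0], self.stage_times])
        us = np.concatenate(
            [np.zeros((1,) + self.displacements.shape[1:]), self.displacements]
        )
        t = float(np.clip(t, ts[0], ts[-1]))
        i = int(np.searchsorted(ts, t, side="right") - 1)
        if i >= len(ts) - 1:
            return us[-1]
        w = (t - ts[i]) / (ts[i + 1] - ts[i])
        return (1 - w) * us[i] + w * us[i + 1]

    @classmethod
    def zeros(cls, node_ids, stage_times) -> "BoundarySeries":
        return cls(
            node_ids,
            stage_times,
            np.zeros((len(stage_times), len(node_ids), 3)),
        )

    @classmethod
    def from_csv(cls, path) -> "BoundarySeries":
        df = pd.read_csv(path)
        need = {"node_id", "stage", "time", "ux", "uy", "uz"}
        if not need.issubset(df.columns):
            raise ValueError(f"boundary CSV needs columns {sorted(need)}")
        stages = np.sort(df["stage"].unique())
        nodes = np.sort(df[df["stage"] == stages[0]]["node_id"].unique())
        times = np.empty(len(stages))
        disp = np.empty((len(stages), len(nodes), 3))
        for si, s in enumerate(stages):
            sub = df[df["stage"] == s].set_index("node_id").loc[nodes]
            times[si] = sub["time"].iloc[0]
            disp[si] = sub[["ux", "uy", "uz"]].to_numpy()
        return cls(nodes, times, disp)

    def to_csv(self, path) -> None:
        rows = []
        for si, t in enumerate(self.stage_times):
            for ni, n in enumerate(self.node_ids):
                rows.append(
                    (int(n), si, t, *self.displacements[si, ni])
                )
        pd.DataFrame(
            rows, columns=["node_id", "stage", "time", "ux", "uy", "uz"]
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Solutions


@dataclass
class StageSolution:
    """Converged state of one inflation stage."""

    stage: int
    time: float
    pressure: float
    u: np.ndarray                 # (n_nodes, 3) mm
    C2d: np.ndarray               # (n_elems, 2, 2) in-plane Cauchy-Green
    cauchy: np.ndarray            # (n_elems, 3, 3) Cauchy stress, kPa
    strain_energy: float          # mN mm
    volume_change: float          # mm^3
    converged: bool
    n_iter: int


@dataclass
class StrainField:
    """Per-element principal technical strains and global directions."""

    major: np.ndarray             # (n_elems,)
    minor: np.ndarray
    dir_major: np.ndarray         # (n_elems, 3) unit, tangent to element
    dir_minor: np.ndarray


# ---------------------------------------------------------------------------
# Shared element precomputation


class _ElementOps:
    """Reference-configuration element operators shared by both paths."""

    def __init__(self, mesh: SurfaceMesh):
        self.mesh = mesh
        self.frames = compute_local_frames(mesh)
        X = mesh.tri_coords()
        E1 = X[:, 1] - X[:, 0]
        E2 = X[:, 2] - X[:, 0]
        ex, ey = self.frames.x_axis, self.frames.y_axis
        DX = np.empty((mesh.n_elems, 2, 2))
        DX[:, 0, 0] = np.einsum("ij,ij->i", E1, ex)
        DX[:, 1, 0] = np.einsum("ij,ij->i", E1, ey)
        DX[:, 0, 1] = np.einsum("ij,ij->i", E2, ex)
        DX[:, 1, 1] = np.einsum("ij,ij->i", E2, ey)
        self.Ginv = np.linalg.inv(DX)          # (E, 2, 2)
        self.area = mesh.areas()
        self.ref_normals = mesh.normals()
        # shape-function gradients in the local tangent plane: rows of Ginv
        gn23 = np.swapaxes(self.Ginv, 1, 2)    # grad N2 = Ginv[:,0,:] etc.
        g2 = self.Ginv[:, 0, :]
        g3 = self.Ginv[:, 1, :]
        self.gradN = np.stack([-(g2 + g3), g2, g3], axis=1)  # (E, 3node, 2)
        del gn23
        # global dof indices per element (E, 9)
        tri = mesh.triangles
        self.edofs = (3 * tri[:, :, None] + np.arange(3)[None, None, :]).reshape(
            mesh.n_elems, 9
        )
        self.char_len = float(np.linalg.norm(np.ptp(mesh.node_coords, axis=0)))


# ---------------------------------------------------------------------------
# Nonlinear (hyperelastic) path


class MembraneSystem:
    """Nonlinear quasi-static membrane under follower pressure.

    Degrees of freedom are the 3 translations of every node (M = 3 n_nodes);
    perimeter nodes are driven by prescribed displacements.
    """

    def __init__(
        self,
        mesh: SurfaceMesh,
        material_field: MaterialField,
        stabilization: float = 1e-6,
        newton_rtol: float = 1e-8,
        newton_atol: float = 1e-10,
        max_newton: int = 30,
    ):
        if material_field.case == "hetero/iso/linear":
            raise ValueError("use LinearMembraneSystem for the linear case")
        self.mesh = mesh
        self.field = material_field
        self.ops = _ElementOps(mesh)
        self.stabilization = stabilization
        self.newton_rtol = newton_rtol
        self.newton_atol = newton_atol
        self.max_newton = max_newton
        self.M = 3 * mesh.n_nodes
        self.perimeter = perimeter_nodes(mesh)
        pdofs = (3 * self.perimeter[:, None] + np.arange(3)).ravel()
        self.prescribed_dofs = pdofs
        self.free_dofs = np.setdiff1d(np.arange(self.M), pdofs)
        # fiber directions: a0 along the local x (medial-lateral) direction,
        # expressed in-plane; for the HGO batch call the 2-D components are
        # (a0 . ex, a0 . ey) = params.a0 rotated by nothing = params.a0.
        self._rows = np.repeat(self.ops.edofs, 9, axis=1).ravel()
        self._cols = np.tile(self.ops.edofs, (1, 9)).ravel()

    # -- element-level forces ------------------------------------------

    def _stress(self, C2d):
        if self.field.case == "homo/iso/hyper":
            return mr_stress_batch(self.field.params, C2d)
        return hgo_stress_batch(self.field.params, C2d)

    def _elem_residual(self, xe, pressure):
        """g_e = f_int - f_ext per element, from current node positions.

        ``xe``: (E, 3, 3) current element node positions.  Returns (E, 9)
        element residual contributions plus (W, C2d, lambda3) diagnostics.
        """
        d1 = xe[:, 1] - xe[:, 0]
        d2 = xe[:, 2] - xe[:, 0]
        dx = np.stack([d1, d2], axis=-1)                   # (E, 3, 2)
        F = dx @ self.ops.Ginv                             # (E, 3, 2)
        C = np.einsum("eki,ekj->eij", F, F)
        W, S, lam3 = self._stress(C)
        At = (self.ops.area * self.mesh.thickness)[:, None]
        P = np.einsum("eab,ebc,edc->ead", F, S, self.ops.Ginv)  # F S Ginv^T
        g = np.empty((len(xe), 3, 3))
        g[:, 1] = At * P[:, :, 0]
        g[:, 2] = At * P[:, :, 1]
        g[:, 0] = -(g[:, 1] + g[:, 2])
        # follower pressure: current area vector, equal nodal thirds
        An = 0.5 * np.cross(d1, d2)
        fp = (pressure / 3.0) * An
        g -= fp[:, None, :]
        return g.reshape(len(xe), 9), (W, C, lam3)

    def assemble(self, u: np.ndarray, pressure: float):
        """Global residual (f_ext - f_int) and consistent tangent at u.

        The tangent is the element-local central difference of the element
        residual (step 1e-7 of the mesh diagonal), which captures material,
        geometric and follower-pressure stiffness consistently.
        """
        xe = self.mesh.tri_coords() + u[self.mesh.triangles]
        g, aux = self._elem_residual(xe, pressure)
        resid = np.zeros(self.M)
        np.add.at(resid, self.ops.edofs.ravel(), -g.ravel())
        h = 1e-7 * max(self.ops.char_len, 1.0)
        Kblk = np.empty((len(xe), 9, 9))
        for j in range(9):
            a, comp = divmod(j, 3)
            xp = xe.copy()
            xp[:, a, comp] += h
            gp, _ = self._elem_residual(xp, pressure)
            xm = xe.copy()
            xm[:, a, comp] -= h
            gm, _ = self._elem_residual(xm, pressure)
            Kblk[:, :, j] = (gp - gm) / (2.0 * h)
        K = sp.coo_matrix(
            (Kblk.ravel(), (self._rows, self._cols)), shape=(self.M, self.M)
        ).tocsr()
        return resid, K, aux

    # -- Newton continuation -------------------------------------------

    def _newton(self, u, pressure, ub, scale_f):
        """Newton iterations at fixed load; ub are prescribed values."""
        uflat = u.ravel().copy()
        uflat[self.prescribed_dofs] = ub
        free = self.free_dofs
        for it in range(self.max_newton):
            resid, K, _ = self.assemble(uflat.reshape(-1, 3), pressure)
            r = resid[free]
            rn = np.linalg.norm(r)
            tol = self.newton_rtol * scale_f + self.newton_atol
            if rn < tol:
                return uflat.reshape(-1, 3), True, it
            Kff = K[free][:, free]
            if self.stabilization > 0:
                eps = self.stabilization * Kff.diagonal().mean()
                Kff = Kff + eps * sp.identity(len(free), format="csr")
            try:
                du = spla.spsolve(Kff.tocsc(), r)
            except Exception:
                return uflat.reshape(-1, 3), False, it
            # backtracking line search on the residual norm
            step = 1.0
            for _ in range(8):
                trial = uflat.copy()
                trial[free] += step * du
                try:
                    resid_t, _ = self._residual_only(trial.reshape(-1, 3), pressure)
                except (ElementInversionError, PlaneStressError):
                    step *= 0.5
                    continue
                if np.linalg.norm(resid_t[free]) < rn * (1 - 1e-4 * step) or step < 0.1:
                    uflat = trial
                    break
                step *= 0.5
            else:
                return uflat.reshape(-1, 3), False, it
        return uflat.reshape(-1, 3), False, self.max_newton

    def _residual_only(self, u, pressure):
        xe = self.mesh.tri_coords() + u[self.mesh.triangles]
        g, aux = self._elem_residual(xe, pressure)
        resid = np.zeros(self.M)
        np.add.at(resid, self.ops.edofs.ravel(), -g.ravel())
        return resid, aux

    def solve_stage(
        self,
        pressure: float,
        boundary_values: np.ndarray,
        u0: np.ndarray | None = None,
        start_pressure: float = 0.0,
        start_boundary: np.ndarray | None = None,
        n_increments: int = 1,
        max_halvings: int = 5,
        stage: int = 0,
        time: float = 0.0,
    ) -> StageSolution:
        """March from (start_pressure, start_boundary) to the target load.

        ``boundary_values``: (n_perimeter, 3) prescribed displacements in the
        order of ``perimeter_nodes(mesh)``.  Load is interpolated linearly in
        the continuation parameter; increments halve adaptively on divergence.
        """
        nb = len(self.perimeter)
        if boundary_values.shape != (nb, 3):
            raise ValueError("boundary data must cover all perimeter nodes")
        u = np.zeros((self.mesh.n_nodes, 3)) if u0 is None else u0.copy()
        ub0 = (
            np.zeros((nb, 3)) if start_boundary is None else start_boundary
        ).ravel()
        ub1 = boundary_values.ravel()
        # load scale for the relative convergence test
        f_probe, _ = self._residual_only(np.zeros_like(u), max(pressure, 1e-12))
        scale_f = max(np.linalg.norm(f_probe[self.free_dofs]), 1e-12)
        s = 0.0
        ds = 1.0 / max(n_increments, 1)
        halvings = 0
        total_it = 0
        while s < 1.0 - 1e-12:
            s_next = min(1.0, s + ds)
            p = start_pressure + (pressure - start_pressure) * s_next
            ub = ub0 + (ub1 - ub0) * s_next
            u_trial, ok, it = self._newton(u, p, ub, scale_f)
            total_it += it
            if ok:
                u = u_trial
                s = s_next
                continue
            halvings += 1
            ds *= 0.5
            if halvings > max_halvings:
                raise SolverError(
                    f"stage {stage}: Newton failed at s={s_next:.3g} "
                    f"after {max_halvings} halvings",
                    u_last=u_trial,
                )
        resid, (W, C2d, lam3) = self._residual_only(u, pressure)
        sigma = self._cauchy(u, C2d, lam3)
        return StageSolution(
            stage=stage,
            time=time,
            pressure=pressure,
            u=u,
            C2d=C2d,
            cauchy=sigma,
            strain_energy=float(
                np.sum(W * self.ops.area * self.mesh.thickness)
            ),
            volume_change=enclosed_volume_change(self.mesh, u),
            converged=True,
            n_iter=total_it,
        )

    def _cauchy(self, u, C2d, lam3):
        xe = self.mesh.tri_coords() + u[self.mesh.triangles]
        dx = np.stack([xe[:, 1] - xe[:, 0], xe[:, 2] - xe[:, 0]], axis=-1)
        F = dx @ self.ops.Ginv
        _, S, _ = self._stress(C2d)
        J = np.sqrt(np.linalg.det(C2d)) * lam3
        return np.einsum("eai,eij,ebj->eab", F, S, F) / J[:, None, None]


def run_inflation(
    mesh: SurfaceMesh,
    material_field: MaterialField,
    profile: PressureProfile,
    boundary: BoundarySeries | None = None,
    n_increments: int = 1,
    stabilization: float = 1e-6,
) -> list[StageSolution]:
    """Solve one converged stage per ``profile.stage_times``.

    ``boundary=None`` holds the perimeter fixed.  Boundary displacements are
    interpolated linearly between stage times.  Returns the stage solutions
    (each carrying its pressure-volume sample via ``volume_change``).
    """
    system = MembraneSystem(mesh, material_field, stabilization=stabilization)
    perim = system.perimeter
    if boundary is None:
        boundary = BoundarySeries.zeros(perim, profile.stage_times)
    order = _match_boundary(perim, boundary.node_ids)
    sols = []
    u = None
    prev_p = 0.0
    prev_ub = np.zeros((len(perim), 3))
    for k, t in enumerate(profile.stage_times):
        p = float(profile.pressure_at(t))
        ub = boundary.at(t)[order]
        sol = system.solve_stage(
            p,
            ub,
            u0=u,
            start_pressure=prev_p,
            start_boundary=prev_ub,
            n_increments=n_increments,
            stage=k,
            time=float(t),
        )
        sols.append(sol)
        u, prev_p, prev_ub = sol.u, p, ub
    return sols


def _match_boundary(perim, node_ids):
    idx = {int(n): i for i, n in enumerate(node_ids)}
    try:
        return np.array([idx[int(n)] for n in perim])
    except KeyError as exc:
        raise ValueError(f"boundary data missing perimeter node {exc}") from exc


# ---------------------------------------------------------------------------
# Principal strains


def principal_strains(mesh: SurfaceMesh, solution: StageSolution) -> StrainField:
    """Major/minor in-plane principal technical strains with global directions.

    Technical strain is the principal in-plane stretch minus one; directions
    are the (reference tangent plane) principal stretch directions mapped to
    global coordinates.
    """
    ops = _ElementOps(mesh)
    C = solution.C2d
    a = C[:, 0, 0]
    b = C[:, 1, 1]
    c = C[:, 0, 1]
    mean = 0.5 * (a + b)
    rad = np.sqrt(np.maximum(0.25 * (a - b) ** 2 + c * c, 0.0))
    lam_max = np.sqrt(np.maximum(mean + rad, 0.0))
    lam_min = np.sqrt(np.maximum(mean - rad, 0.0))
    # eigenvector for the larger eigenvalue of [[a, c], [c, b]]
    v = np.where(
        (np.abs(c) > 1e-14)[:, None],
        np.stack([mean + rad - b, c], axis=1),
        np.where((a >= b)[:, None], [[1.0, 0.0]], [[0.0, 1.0]]),
    )
    nv = np.linalg.norm(v, axis=1, keepdims=True)
    v = v / np.where(nv > 0, nv, 1.0)
    ex, ey = ops.frames.x_axis, ops.frames.y_axis
    dmaj = v[:, :1] * ex + v[:, 1:] * ey
    w = np.stack([-v[:, 1], v[:, 0]], axis=1)
    dmin = w[:, :1] * ex + w[:, 1:] * ey
    return StrainField(
        major=lam_max - 1.0, minor=lam_min - 1.0, dir_major=dmaj, dir_minor=dmin
    )


# ---------------------------------------------------------------------------
# Linear heterogeneous path


class LinearMembraneSystem:
    """Small-strain membrane operator K(p) u = f with per-element (E, nu).

    ``pretension`` (kPa·mm = mN/mm, a membrane tension per unit length) adds
    the geometric stiffness of a uniform isotropic pre-stress, which carries
    transverse load on flat regions; it is parameter-independent, as is the
    stabilisation (frozen at construction so that K depends on p only through
    the material matrices — the property the adjoint gradient relies on).
    Pressure loads are dead loads along reference normals, so df/dp = 0.
    """

    def __init__(
        self,
        mesh: SurfaceMesh,
        pretension: float = 0.0,
        stabilization: float = 0.0,
        ref_E: float = 100.0,
        ref_nu: float = 0.3,
    ):
        self.mesh = mesh
        self.ops = _ElementOps(mesh)
        self.M = 3 * mesh.n_nodes
        self.perimeter = perimeter_nodes(mesh)
        pdofs = (3 * self.perimeter[:, None] + np.arange(3)).ravel()
        self.prescribed_dofs = pdofs
        self.free_dofs = np.setdiff1d(np.arange(self.M), pdofs)
        self.pretension = pretension
        self.solve_count = 0  # sparse factorisations performed

        # global strain-displacement operator Bg: (E, 3strain, 9dof)
        ex, ey = self.ops.frames.x_axis, self.ops.frames.y_axis
        g = self.ops.gradN  # (E, 3node, 2)
        Bg = np.zeros((mesh.n_elems, 3, 9))
        for a in range(3):
            bx = g[:, a, 0][:, None]
            by = g[:, a, 1][:, None]
            Bg[:, 0, 3 * a : 3 * a + 3] = bx * ex
            Bg[:, 1, 3 * a : 3 * a + 3] = by * ey
            Bg[:, 2, 3 * a : 3 * a + 3] = by * ex + bx * ey
        self.Bg = Bg
        self._rows = np.repeat(self.ops.edofs, 9, axis=1).ravel()
        self._cols = np.tile(self.ops.edofs, (1, 9)).ravel()

        # parameter-independent geometric (pre-tension) blocks
        if pretension > 0:
            gg = np.einsum("eai,ebi->eab", g, g)  # (E, 3, 3) gradN dot gradN
            kg = self.ops.area[:, None, None] * pretension * gg
            self.Kgeo_blocks = np.einsum(
                "eab,ij->eaibj", kg, np.eye(3)
            ).reshape(mesh.n_elems, 9, 9)
        else:
            self.Kgeo_blocks = None

        # frozen stabilisation magnitude from a reference homogeneous field
        Kref = self._assemble_raw(np.full(mesh.n_elems, ref_E), np.full(mesh.n_elems, ref_nu))
        self._eps = stabilization * Kref.diagonal().mean() if stabilization > 0 else 0.0

    # -- assembly -------------------------------------------------------

    def material_blocks(self, E, nu):
        """(E, 9, 9) per-element material stiffness blocks."""
        D = linear_plane_stress_matrix_batch(E, nu)
        At = (self.ops.area * self.mesh.thickness)[:, None, None]
        return At * np.einsum("esi,est,etj->eij", self.Bg, D, self.Bg)

    def dK_blocks(self, E, nu):
        """Analytic per-element (dK/dE, dK/dnu) 9x9 blocks."""
        kmat = self.material_blocks(E, nu)
        dK_dE = kmat / np.asarray(E, float)[:, None, None]
        dD = linear_plane_stress_matrix_dnu(E, nu)
        At = (self.ops.area * self.mesh.thickness)[:, None, None]
        dK_dnu = At * np.einsum("esi,est,etj->eij", self.Bg, dD, self.Bg)
        return dK_dE, dK_dnu

    def _assemble_raw(self, E, nu) -> sp.csr_matrix:
        blocks = self.material_blocks(E, nu)
        if self.Kgeo_blocks is not None:
            blocks = blocks + self.Kgeo_blocks
        return sp.coo_matrix(
            (blocks.ravel(), (self._rows, self._cols)), shape=(self.M, self.M)
        ).tocsr()

    def assemble(self, field_or_p) -> sp.csr_matrix:
        """Global stiffness K(p) (full DOF set, symmetric)."""
        E, nu = self._unpack(field_or_p)
        return self._assemble_raw(E, nu)

    def _unpack(self, field_or_p):
        if isinstance(field_or_p, MaterialField):
            return field_or_p.E, field_or_p.nu
        p = np.asarray(field_or_p, float)
        return p[0::2], p[1::2]

    def pressure_load(self, pressure: float) -> np.ndarray:
        """Dead pressure load along reference normals (length M)."""
        fp = (pressure / 3.0) * self.ops.area[:, None] * self.ops.ref_normals
        f = np.zeros(self.M)
        for a in range(3):
            np.add.at(
                f.reshape(-1, 3), self.mesh.triangles[:, a], fp
            )
        return f

    # -- solving --------------------------------------------------------

    def solve(self, field_or_p, loads, boundary_values) -> np.ndarray:
        """Solve K u = f for one or many load cases with ONE factorisation.

        ``loads``: (M,) or (n_cases, M); ``boundary_values``: matching
        (n_perimeter, 3) or (n_cases, n_perimeter, 3) prescribed values.
        Returns full displacement vectors (n_cases, n_nodes, 3) (squeezed for
        a single case).  ``solve_count`` increments by one per call.
        """
        loads = np.atleast_2d(np.asarray(loads, float))
        bv = np.asarray(boundary_values, float)
        if bv.ndim == 2:
            bv = bv[None]
        if len(bv) != len(loads):
            raise ValueError("loads and boundary_values case counts differ")
        K = self.assemble(field_or_p)
        free, pres = self.free_dofs, self.prescribed_dofs
        Kff = K[free][:, free]
        if self._eps > 0:
            Kff = Kff + self._eps * sp.identity(len(free), format="csr")
        Kfp = K[free][:, pres]
        try:
            lu = spla.splu(Kff.tocsc())
        except RuntimeError as exc:
            raise SolverError(f"singular reduced system: {exc}") from exc
        self.solve_count += 1
        out = np.zeros((len(loads), self.M))
        for i, (f, b) in enumerate(zip(loads, bv)):
            ub = b.ravel()
            rhs = f[free] - Kfp @ ub
            out[i, free] = lu.solve(rhs)
            out[i, pres] = ub
        res = out.reshape(len(loads), -1, 3)
        return res[0] if len(loads) == 1 else res

    def solve_linear(self, p, f, boundary_values=None) -> np.ndarray:
        """Single-case convenience wrapper around :meth:`solve`."""
        if boundary_values is None:
            boundary_values = np.zeros((len(self.perimeter), 3))
        return self.solve(p, f, boundary_values)

    def stage_solutions(
        self,
        field_or_p,
        profile: PressureProfile,
        boundary: BoundarySeries | None = None,
    ) -> list[StageSolution]:
        """Per-stage linear solves sharing one factorisation."""
        perim = self.perimeter
        if boundary is None:
            boundary = BoundarySeries.zeros(perim, profile.stage_times)
        order = _match_boundary(perim, boundary.node_ids)
        loads = []
        bvs = []
        for t in profile.stage_times:
            loads.append(self.pressure_load(float(profile.pressure_at(t))))
            bvs.append(boundary.at(float(t))[order])
        us = self.solve(field_or_p, np.array(loads), np.array(bvs))
        if us.ndim == 2:
            us = us[None]
        sols = []
        for k, t in enumerate(profile.stage_times):
            u = us[k]
            C2d = self._linear_C2d(u)
            sols.append(
                StageSolution(
                    stage=k,
                    time=float(t),
                    pressure=float(profile.pressure_at(t)),
                    u=u,
                    C2d=C2d,
                    cauchy=np.zeros((self.mesh.n_elems, 3, 3)),
                    strain_energy=0.0,
                    volume_change=enclosed_volume_change(self.mesh, u),
                    converged=True,
                    n_iter=1,
                )
            )
        return sols

    def _linear_C2d(self, u):
        """In-plane Cauchy-Green from the (small) displacement field."""
        xe = self.mesh.tri_coords() + u[self.mesh.triangles]
        dx = np.stack([xe[:, 1] - xe[:, 0], xe[:, 2] - xe[:, 0]], axis=-1)
        F = dx @ self.ops.Ginv
        return np.einsum("eki,ekj->eij", F, F)
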