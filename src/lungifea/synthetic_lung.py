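"""Self-contained synthetic inflation scenarios with known ground truth.

No public lung-surface DIC dataset exists, so verification rests on the
classic inverse-problem paradigm: generate probe displacement data from the
forward model with *known* material parameters, then require calibration to
recover them.  This module builds every ingredient of such a scenario:

* a lobe-like open surface — an ellipsoidal cap triangulated with an exact
  target element count (457 for the coarse / heterogeneous studies, ~5,000
  for fine homogeneous ones);
* a smooth concave-down pressure ramp over a 2 s inflation (15
  breaths-per-minute) with stage times at the five 20% increments;
* ground-truth material fields (homogeneous parameter sets at the canonical
  calibrated values, or a smooth posterior-to-anterior stiffness gradient);
* probe displacement fields sampled quasi-uniformly on the surface through
  the same kNN operator the calibration objective uses, plus optional i.i.d.
  Gaussian noise (a realistic DIC accuracy scale is ~0.11 mm).

Everything is seeded and reproducible; outputs carry a scenario hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .constitutive import HGOParams, MaterialField, MooneyRivlinParams
from .dic_field import ProbeField, interpolation_matrix
from .membrane_solver import (
    BoundarySeries,
    LinearMembraneSystem,
    PressureProfile,
    run_inflation,
)
from .surface_mesh import SurfaceMesh, perimeter_nodes

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "generate_cap_mesh",
    "generate_pressure_profile",
    "make_ground_truth_field",
    "synthesize_probe_data",
]

# canonical homogeneous parameter sets used as generator ground truth
CANONICAL_MR = dict(C10=136.5, C01=1.0, D1=13.43e-4)
CANONICAL_HGO = dict(C10=116.4, D=43.6e-4, k1=1.0, k2=0.12, kappa=0.33)
# heterogeneous field: E gradient (kPa) along the AP axis, constant nu
DEFAULT_E_BOUNDS = (300.0, 900.0)
DEFAULT_NU = 0.43
#: default pre-tension (mN/mm) of the linear heterogeneous scenario
DEFAULT_PRETENSION = 5.0


# ---------------------------------------------------------------------------
# Cap mesh with an exact element count


def generate_cap_mesh(
    n_target: int,
    semi_axes=(60.0, 45.0, 35.0),
    seed: int = 0,
    cap_angle_deg: float = 70.0,
) -> SurfaceMesh:
    """Open ellipsoidal-cap triangulation with exactly ``n_target`` elements.

    The cap is built as concentric rings in a polar parameter plane (center
    fan plus ring strips) and mapped onto the upper cap of an ellipsoid with
    the given semi-axes (mm).  Ring populations are chosen for near-uniform
    element size; the outermost ring count absorbs the remainder so the
    element count is met exactly (possible for every ``n_target >= 4``).
    Winding is consistently outward (away from the ellipsoid center); the
    stored AP axis is global y.  Deterministic for a fixed seed.
    """
    if n_target < 4:
        raise ValueError("n_target must be at least 4")
    rng = np.random.default_rng(seed)

    # ring sizes: n_i ~ 6 i gives near-equilateral triangles; pick the ring
    # count R so the base total is just below target, then fix the last ring
    def total_for(R, last=None):
        ns = [6 * i for i in range(1, R + 1)]
        if last is not None:
            ns[-1] = last
        tot = ns[0] + sum(ns[i - 1] + ns[i] for i in range(1, R))
        return tot, ns

    R = 1
    while True:
        tot, _ = total_for(R + 1)
        # minimal achievable with R+1 rings (last ring can shrink to 3)
        tot_min, _ = total_for(R + 1, last=3)
        if tot_min > n_target:
            break
        R += 1
    # with R rings, solve for the last-ring count
    if R == 1:
        ns = [n_target]
    else:
        base, ns = total_for(R)
        delta = n_target - base
        ns[-1] += delta
        if ns[-1] < 3:
            raise ValueError(f"cannot reach exactly {n_target} elements")

    # nodes: center + rings; ring radii uniform in the polar parameter
    theta_off = rng.uniform(0, 2 * np.pi, size=R)  # seeded ring phase
    nodes2d = [np.zeros((1, 2))]
    ring_start = [None] * (R + 1)
    count = 1
    for i in range(1, R + 1):
        n_i = ns[i - 1]
        th = theta_off[i - 1] + 2 * np.pi * np.arange(n_i) / n_i
        r = i / R
        nodes2d.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        ring_start[i] = count
        count += n_i
    nodes2d = np.concatenate(nodes2d)

    tris = []
    # center fan
    s1, n1 = ring_start[1], ns[0]
    for j in range(n1):
        tris.append((0, s1 + j, s1 + (j + 1) % n1))
    # strips between consecutive rings, stitched by angular order
    for i in range(2, R + 1):
        sa, na = ring_start[i - 1], ns[i - 2]
        sb, nb = ring_start[i], ns[i - 1]
        ang_a = np.arctan2(nodes2d[sa : sa + na, 1], nodes2d[sa : sa + na, 0])
        ang_b = np.arctan2(nodes2d[sb : sb + nb, 1], nodes2d[sb : sb + nb, 0])
        tris.extend(_stitch_rings(sa, na, ang_a, sb, nb, ang_b))
    tris = np.array(tris, dtype=np.int64)
    assert len(tris) == n_target, (len(tris), n_target)

    # map polar parameter onto the ellipsoid cap
    rho = np.linalg.norm(nodes2d, axis=1)
    theta = np.arctan2(nodes2d[:, 1], nodes2d[:, 0])
    phi = np.deg2rad(cap_angle_deg) * rho  # colatitude
    a, b, c = semi_axes
    coords = np.column_stack(
        [
            a * np.sin(phi) * np.cos(theta),
            b * np.sin(phi) * np.sin(theta),
            c * np.cos(phi),
        ]
    )
    mesh = SurfaceMesh(coords, tris, thickness=1.0, ap_axis=np.array([0.0, 1.0, 0.0]))
    # ensure outward winding (normals away from the ellipsoid center)
    cen = coords[tris].mean(axis=1)
    flip = np.einsum("ij,ij->i", mesh.normals(), cen) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return SurfaceMesh(coords, tris, thickness=1.0, ap_axis=np.array([0.0, 1.0, 0.0]))


def _stitch_rings(sa, na, ang_a, sb, nb, ang_b):
    """Triangulate the strip between two rings; yields na + nb triangles.

    Walks both rings in increasing angle, always advancing the pointer whose
    next node comes first, which keeps the strip triangles well shaped.
    Inner-ring node order in each triangle is chosen counter-clockwise in the
    parameter plane.
    """
    oa = np.argsort(ang_a)
    ob = np.argsort(ang_b)
    ia = ib = 0
    tris = []
    while ia < na or ib < nb:
        A0 = sa + oa[ia % na]
        B0 = sb + ob[ib % nb]
        next_a = ang_a[oa[(ia + 1) % na]] + (2 * np.pi if ia + 1 >= na else 0)
        next_b = ang_b[ob[(ib + 1) % nb]] + (2 * np.pi if ib + 1 >= nb else 0)
        advance_a = ia < na and (ib >= nb or next_a <= next_b)
        if advance_a:
            A1 = sa + oa[(ia + 1) % na]
            tris.append((A0, B0, A1))
            ia += 1
        else:
            B1 = sb + ob[(ib + 1) % nb]
            tris.append((A0, B0, B1))
            ib += 1
    return tris


# ---------------------------------------------------------------------------
# Pressure profile


def generate_pressure_profile(
    peak_kPa: float = 2.0, duration_s: float = 2.0, n_samples: int = 101
) -> PressureProfile:
    """Smooth monotone concave-down ramp from 0 to the peak pressure.

    Shape p(t) = peak * sin(pi t / 2 T): zero at t = 0, flat-topped at the
    end of the inflation, qualitatively matching an inflating-lung pressure
    trace at 15 breaths per minute (2 s inflation).  Stage times sit at the
    five 20% increments of the duration.
    """
    if peak_kPa <= 0 or duration_s <= 0:
        raise ValueError("peak and duration must be positive")
    t = np.linspace(0.0, duration_s, n_samples)
    p = peak_kPa * np.sin(0.5 * np.pi * t / duration_s)
    stage_times = duration_s * np.linspace(0.2, 1.0, 5)
    return PressureProfile(t, p, stage_times=stage_times)


# ---------------------------------------------------------------------------
# Ground-truth material fields


def make_ground_truth_field(
    mesh: SurfaceMesh, case: str, spec: dict | None = None, seed: int = 0
) -> MaterialField:
    """Ground-truth parameters for a scenario.

    Homogeneous cases return the canonical calibrated parameter sets (or the
    values in ``spec``).  The heterogeneous case returns a smooth per-element
    Young's-modulus field along the AP axis between ``E_bounds`` — linear by
    default, or a sigmoid with ``profile='sigmoid'`` — emulating tissue that
    softens from posterior to anterior, with constant Poisson ratio.
    """
    spec = dict(spec or {})
    if case == "homo/iso/hyper":
        vals = {**CANONICAL_MR, **{k: spec[k] for k in spec if k in CANONICAL_MR}}
        return MaterialField(case, MooneyRivlinParams(**vals))
    if case == "homo/aniso/hyper":
        vals = {**CANONICAL_HGO, **{k: spec[k] for k in spec if k in CANONICAL_HGO}}
        return MaterialField(case, HGOParams(**vals))
    if case == "hetero/iso/linear":
        lo, hi = spec.get("E_bounds", DEFAULT_E_BOUNDS)
        nu = spec.get("nu", DEFAULT_NU)
        profile = spec.get("profile", "linear")
        cen = mesh.tri_coords().mean(axis=1)
        s = cen @ mesh.ap_axis
        s = (s - s.min()) / max(s.max() - s.min(), 1e-30)
        if profile == "sigmoid":
            raw = 1.0 / (1.0 + np.exp(-8.0 * (s - 0.5)))
            s = (raw - raw.min()) / (raw.max() - raw.min())
        elif profile != "linear":
            raise ValueError(f"unknown profile {profile!r}")
        E = lo + (hi - lo) * s
        return MaterialField(case, E=E, nu=np.full(mesh.n_elems, nu))
    raise ValueError(f"unknown case {case!r}")


# ---------------------------------------------------------------------------
# Probe sampling and forward-simulated data


def _sample_surface_points(mesh: SurfaceMesh, n: int, seed: int) -> np.ndarray:
    """Seeded quasi-uniform (blue-noise) points on the triangulated surface.

    Dart throwing with a spatial hash: area-weighted random candidates are
    accepted if no previously accepted point lies within ~0.7 of the mean
    spacing; remaining slots are filled with unconstrained candidates.
    """
    rng = np.random.default_rng(seed)
    areas = mesh.areas()
    total = areas.sum()
    rmin = 0.7 * np.sqrt(total / max(n, 1))

    def candidates(m):
        tri = rng.choice(mesh.n_elems, size=m, p=areas / total)
        r1 = rng.random(m)
        r2 = rng.random(m)
        s1 = np.sqrt(r1)
        b0, b1, b2 = 1 - s1, s1 * (1 - r2), s1 * r2
        x = mesh.tri_coords()[tri]
        return b0[:, None] * x[:, 0] + b1[:, None] * x[:, 1] + b2[:, None] * x[:, 2]

    cell = rmin / np.sqrt(3.0)
    grid: dict[tuple, list[int]] = {}
    accepted: list[np.ndarray] = []

    def ok(p):
        key = tuple((p // cell).astype(np.int64))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        if np.linalg.norm(accepted[j] - p) < rmin:
                            return False
        return True

    pool = candidates(8 * n)
    for p in pool:
        if len(accepted) >= n:
            break
        if ok(p):
            key = tuple((p // cell).astype(np.int64))
            grid.setdefault(key, []).append(len(accepted))
            accepted.append(p)
    while len(accepted) < n:  # fill any shortfall without the spacing rule
        accepted.extend(candidates(n - len(accepted)))
    return np.array(accepted[:n])


@dataclass
class GroundTruth:
    """The known answer a synthetic scenario must allow recovering."""

    material_field: MaterialField
    p_true: np.ndarray
    stage_solutions: list
    probe_displacements: np.ndarray     # (n_stages, n_probes, 3), pre-noise


def synthesize_probe_data(
    mesh: SurfaceMesh,
    material_field: MaterialField,
    profile: PressureProfile,
    n_probes: int = 7000,
    noise_sd: float = 0.0,
    seed: int = 0,
    boundary: BoundarySeries | None = None,
    pretension: float = DEFAULT_PRETENSION,
    n_increments: int = 1,
) -> tuple[ProbeField, BoundarySeries, GroundTruth]:
    """Forward-simulate the scenario and sample probe displacement data.

    Hyperelastic cases run the nonlinear inflation (fixed perimeter unless a
    boundary series is given); the heterogeneous linear case uses the linear
    pre-tensioned operator.  Probe displacements are the nodal solution
    mapped through the k = 5 nearest-neighbor operator (the same operator the
    calibration objective uses), plus i.i.d. Gaussian noise per component.
    The returned boundary series is the perimeter displacement of the truth
    run — the boundary condition a calibration must apply.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    perim = perimeter_nodes(mesh)
    if material_field.case == "hetero/iso/linear":
        system = LinearMembraneSystem(mesh, pretension=pretension)
        sols = system.stage_solutions(material_field, profile, boundary=boundary)
    else:
        sols = run_inflation(
            mesh, material_field, profile, boundary=boundary,
            n_increments=n_increments,
        )
    probes = _sample_surface_points(mesh, n_probes, seed)
    W = interpolation_matrix(mesh.node_coords, probes, k=5)
    u_true = np.stack([W @ sol.u for sol in sols])
    rng = np.random.default_rng(seed + 1)
    noise = rng.normal(0.0, noise_sd, size=u_true.shape) if noise_sd > 0 else 0.0
    probe_field = ProbeField(coords=probes, u_exp=u_true + noise)
    out_boundary = BoundarySeries(
        perim,
        profile.stage_times,
        np.stack([sol.u[perim] for sol in sols]),
    )
    truth = GroundTruth(
        material_field=material_field,
        p_true=material_field.flatten(),
        stage_solutions=sols,
        probe_displacements=u_true,
    )
    return probe_field, out_boundary, truth


# ---------------------------------------------------------------------------
# Scenario bundle


@dataclass
class SyntheticScenario:
    """A fully specified, reproducible test scenario.

    Defaults describe the standard study conditions: a 457-element cap with
    lobe-like semi-axes, a 2 s inflation to 2 kPa, 7,000 probes, no noise.
    """

    case: str = "homo/iso/hyper"
    n_elements: int = 457
    semi_axes: tuple = (60.0, 45.0, 35.0)
    peak_pressure: float = 2.0      # kPa
    duration: float = 2.0           # s
    n_probes: int = 7000
    noise_sd: float = 0.0           # mm
    seed: int = 0
    material_spec: dict = field(default_factory=dict)
    pretension: float = DEFAULT_PRETENSION
    boundary_amplitude: float = 0.0  # mm, radial perimeter motion at t = T

    def scenario_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def build(self):
        """Generate (mesh, profile, material_field, probe_field, boundary,
        ground_truth) for this scenario."""
        mesh = generate_cap_mesh(self.n_elements, self.semi_axes, seed=self.seed)
        profile = generate_pressure_profile(self.peak_pressure, self.duration)
        fieldt = make_ground_truth_field(
            mesh, self.case, self.material_spec, seed=self.seed
        )
        boundary = None
        if self.boundary_amplitude > 0:
            boundary = self._radial_boundary(mesh, profile)
        probe_field, out_boundary, truth = synthesize_probe_data(
            mesh,
            fieldt,
            profile,
            n_probes=self.n_probes,
            noise_sd=self.noise_sd,
            seed=self.seed,
            boundary=boundary,
            pretension=self.pretension,
        )
        return mesh, profile, fieldt, probe_field, out_boundary, truth

    def _radial_boundary(self, mesh, profile) -> BoundarySeries:
        """Outward radial perimeter motion growing linearly in time.

        Deliberately *not* proportional to the concave pressure ramp, so the
        five stages probe independent load combinations (this is what makes
        the two-per-element heterogeneous parameters identifiable from
        surface data).
        """
        perim = perimeter_nodes(mesh)
        xy = mesh.node_coords[perim].copy()
        xy[:, 2] = 0.0
        nrm = np.linalg.norm(xy, axis=1, keepdims=True)
        dirs = np.where(nrm > 1e-12, xy / np.maximum(nrm, 1e-12), 0.0)
        ts = profile.stage_times
        amps = self.boundary_amplitude * ts / ts[-1]
        disp = amps[:, None, None] * dirs[None]
        return BoundarySeries(perim, ts, disp)
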