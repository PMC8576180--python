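"""Membrane constitutive laws for the reduced-order lung surface model.

Three material cases are supported, mirroring the modelling choices the
surface model is built around:

* ``homo/iso/hyper`` — compressible Mooney–Rivlin,
  ``W = C10 (I1b - 3) + C01 (I2b - 3) + (1/D1) (J - 1)^2``,
  with the through-thickness stretch condensed so the normal stress vanishes
  (plane stress).
* ``homo/aniso/hyper`` — Holzapfel–Gasser–Ogden with a single dispersed fiber
  family.  The membrane formulation treats the response as isochoric
  (``J = 1`` sets the thickness stretch), so the compressibility coefficient
  ``D`` is inert and is excluded from calibration sensitivity.
* ``hetero/iso/linear`` — per-element linear isotropic elasticity (E, nu)
  under plane stress; this is the case the adjoint gradient machinery
  operates on.

All stresses are second Piola–Kirchhoff, expressed in the element's local
in-plane frame; units are kPa (= mN/mm^2).  Everything here is vectorised
over elements: a "batch" argument ``C2d`` has shape (n, 2, 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MooneyRivlinParams",
    "HGOParams",
    "LinearElasticParams",
    "DeformationState",
    "MaterialField",
    "deformation_state",
    "mr_stress",
    "hgo_stress",
    "linear_plane_stress_matrix",
    "initial_moduli",
    "DEFAULT_BOUNDS",
]


class PlaneStressError(RuntimeError):
    """Plane-stress thickness-stretch solve failed to converge."""


class ElementInversionError(RuntimeError):
    """In-plane Jacobian of an element is non-positive."""


# Calibration search ranges (kPa, kPa^-1, dimensionless), shared defaults.
DEFAULT_BOUNDS = {
    "C10": (1.0, 200.0),
    "C01": (1.0, 200.0),
    "D1": (1e-4, 1e-2),
    "D": (1e-4, 1e-2),
    "k1": (1.0, 200.0),
    "k2": (0.0, 1.0),
    "kappa": (0.0, 0.33),
}


@dataclass
class MooneyRivlinParams:
    """Compressible Mooney–Rivlin: C10, C01 in kPa, D1 in kPa^-1."""

    C10: float
    C01: float
    D1: float

    def __post_init__(self):
        if not self.C10 > 0:
            raise ValueError("C10 must be positive")
        if not self.C01 >= 0:
            raise ValueError("C01 must be non-negative")
        if not self.D1 > 0:
            raise ValueError("D1 must be positive")


@dataclass
class HGOParams:
    """HGO fiber-reinforced law.

    ``kappa`` is the fiber dispersion (0 = perfectly aligned, 1/3 = random,
    i.e. isotropic).  ``a0`` is the unit fiber direction in the element local
    frame (in-plane components only are used; default: local x, the
    medial–lateral direction).  ``D`` is carried for interface parity but is
    inert in the membrane formulation.
    """

    C10: float
    D: float
    k1: float
    k2: float
    kappa: float
    a0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self):
        if not self.C10 > 0:
            raise ValueError("C10 must be positive")
        if not 0 <= self.kappa <= 1 / 3 + 1e-12:
            raise ValueError("kappa must lie in [0, 1/3]")
        if self.k1 < 0:
            raise ValueError("k1 must be non-negative")
        if self.k2 < 0:
            raise ValueError("k2 must be non-negative")
        a = np.asarray(self.a0, dtype=float)[:2]
        n = np.linalg.norm(a)
        if not n > 0:
            raise ValueError("a0 must be nonzero")
        self.a0 = a / n


@dataclass
class LinearElasticParams:
    """Linear isotropic elasticity: E in kPa, Poisson ratio nu."""

    E: float
    nu: float

    def __post_init__(self):
        if not self.E > 0:
            raise ValueError("E must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")

    @property
    def mu(self) -> float:
        """Shear modulus mu = E / (2 (1 + nu))."""
        return self.E / (2.0 * (1.0 + self.nu))


@dataclass
class DeformationState:
    """Kinematic state of one membrane element (local-frame quantities)."""

    F: np.ndarray           # (3, 2) mapping local 2-D reference to 3-D current
    C: np.ndarray           # (2, 2) in-plane right Cauchy-Green
    J2d: float              # in-plane area stretch, sqrt(det C)
    lambda3: float = 1.0    # through-thickness stretch (set by condensation)

    @property
    def J(self) -> float:
        return self.J2d * self.lambda3

    def invariants(self, a0=np.array([1.0, 0.0])):
        """(I1bar, I2bar, I4bar, lambda_fiber) at the current lambda3."""
        a = float(np.trace(self.C))
        d = float(np.linalg.det(self.C))
        c = self.lambda3 ** 2
        J2 = d * c
        I1 = a + c
        I2 = d + c * a
        I1b = I1 * J2 ** (-1 / 3)
        I2b = I2 * J2 ** (-2 / 3)
        a0 = np.asarray(a0, float)[:2]
        I4b = float(a0 @ self.C @ a0) * J2 ** (-1 / 3)
        return I1b, I2b, I4b, np.sqrt(I4b)


def deformation_state(ref_coords, elem_displacements, frame_x, frame_y) -> DeformationState:
    """Constant in-plane deformation gradient of a linear triangle.

    ``ref_coords`` (3, 3): the element's reference node positions;
    ``elem_displacements`` (3, 3): nodal displacements; ``frame_x``/``frame_y``
    span the element's reference tangent plane.  ``lambda3`` is initialised to
    1 and later overwritten by the stress routines' condensation.
    """
    X = np.asarray(ref_coords, float)
    x = X + np.asarray(elem_displacements, float)
    E1, E2 = X[1] - X[0], X[2] - X[0]
    DX = np.column_stack([[E1 @ frame_x, E1 @ frame_y], [E2 @ frame_x, E2 @ frame_y]])
    det = np.linalg.det(DX)
    if abs(det) < 1e-14:
        raise ValueError("reference nodes are collinear")
    dx = np.column_stack([x[1] - x[0], x[2] - x[0]])  # (3, 2)
    F = dx @ np.linalg.inv(DX)
    C = F.T @ F
    d = np.linalg.det(C)
    if d <= 0:
        raise ElementInversionError("in-plane Jacobian non-positive")
    # orientation check: current normal vs reference winding
    n_cur = np.cross(x[1] - x[0], x[2] - x[0])
    n_ref = np.cross(E1, E2)
    if det * float(n_cur @ n_ref) < 0:
        raise ElementInversionError("element inverted")
    return DeformationState(F=F, C=C, J2d=float(np.sqrt(d)))


# ---------------------------------------------------------------------------
# Mooney-Rivlin (compressible) with plane-stress condensation


def _mr_g(c, a, d, C10, C01, D1):
    """Normal 2nd-PK stress component: g(c) = dW/dc, c = lambda3^2."""
    u = (d * c) ** (-1 / 3)
    v = u * u
    t1 = u * (1.0 - (a + c) / (3.0 * c))
    t2 = v * (a / 3.0 - 2.0 * d / (3.0 * c))
    g3 = (d - np.sqrt(d / c)) / D1
    return C10 * t1 + C01 * t2 + g3


def _mr_gprime(c, a, d, C10, C01, D1):
    u = (d * c) ** (-1 / 3)
    v = u * u
    h = 1.0 - (a + c) / (3.0 * c)
    t1p = u * (-h / (3.0 * c) + a / (3.0 * c * c))
    m = a / 3.0 - 2.0 * d / (3.0 * c)
    t2p = v * (-2.0 * m / (3.0 * c) + 2.0 * d / (3.0 * c * c))
    g3p = 0.5 * np.sqrt(d) * c ** (-1.5) / D1
    return C10 * t1p + C01 * t2p + g3p


def _mr_lambda3sq(a, d, C10, C01, D1, tol=1e-13, maxit=80):
    """Vectorised safeguarded Newton for the plane-stress condition g(c)=0."""
    a = np.asarray(a, float)
    d = np.asarray(d, float)
    lo = np.full_like(a, 1e-8)
    hi = np.full_like(a, 1e6)
    c = 1.0 / d  # incompressible guess
    scale = C10 + C01 + 1.0 / D1
    for _ in range(maxit):
        g = _mr_g(c, a, d, C10, C01, D1)
        if np.all(np.abs(g) < tol * scale):
            return c
        # g is increasing in c near the root (material stability)
        lo = np.where(g < 0, np.maximum(lo, c), lo)
        hi = np.where(g > 0, np.minimum(hi, c), hi)
        gp = _mr_gprime(c, a, d, C10, C01, D1)
        c_new = c - np.where(gp != 0, g / np.where(gp == 0, 1.0, gp), 0.0)
        # fall back to bisection when Newton leaves the bracket
        bad = (c_new <= lo) | (c_new >= hi) | ~np.isfinite(c_new)
        c = np.where(bad, 0.5 * (lo + hi), c_new)
    g = _mr_g(c, a, d, C10, C01, D1)
    if np.any(np.abs(g) > 1e-6 * scale):
        raise PlaneStressError(
            f"plane-stress root find did not converge (max |g| = {np.abs(g).max():.3e}, "
            f"a range [{a.min():.3g}, {a.max():.3g}])"
        )
    return c


def mr_stress_batch(params: MooneyRivlinParams, C2d: np.ndarray):
    """Energy density W (kPa), in-plane S (kPa) and lambda3 for a batch.

    ``C2d``: (n, 2, 2) in-plane right Cauchy-Green tensors.  lambda3 is
    condensed so the through-thickness normal stress vanishes; S is the exact
    derivative 2 dW/dC of the condensed energy (envelope theorem).
    """
    C2d = np.asarray(C2d, float)
    a = np.trace(C2d, axis1=-2, axis2=-1)
    d = np.linalg.det(C2d)
    if np.any(d <= 0):
        raise ElementInversionError(
            f"element {int(np.argmin(d))} has non-positive in-plane Jacobian"
        )
    C10, C01, D1 = params.C10, params.C01, params.D1
    c = _mr_lambda3sq(a, d, C10, C01, D1)
    dc = d * c
    J = np.sqrt(dc)
    I1b = (a + c) * dc ** (-1 / 3)
    I2b = (d + c * a) * dc ** (-2 / 3)
    W = C10 * (I1b - 3) + C01 * (I2b - 3) + (J - 1) ** 2 / D1

    Cinv = np.linalg.inv(C2d)
    eye = np.broadcast_to(np.eye(2), C2d.shape)
    u13 = (dc ** (-1 / 3))[..., None, None]
    u23 = (dc ** (-2 / 3))[..., None, None]
    dI1b = u13 * eye - (((a + c) / 3.0)[..., None, None] * u13) * Cinv
    dI2b = u23 * (d[..., None, None] * Cinv + c[..., None, None] * eye) \
        - (2.0 / 3.0) * (I2b[..., None, None]) * Cinv
    dJ = 0.5 * J[..., None, None] * Cinv
    S = 2.0 * (C10 * dI1b + C01 * dI2b + (2.0 / D1) * (J - 1)[..., None, None] * dJ)
    return W, S, np.sqrt(c)


def mr_stress(params: MooneyRivlinParams, state: DeformationState):
    """Single-element wrapper: returns (W, S) and updates state.lambda3."""
    W, S, lam3 = mr_stress_batch(params, state.C[None])
    state.lambda3 = float(lam3[0])
    return float(W[0]), S[0]


# ---------------------------------------------------------------------------
# Holzapfel-Gasser-Ogden membrane (isochoric: J = 1 sets lambda3)


def hgo_stress_batch(params: HGOParams, C2d: np.ndarray, a0_2d=None):
    """W, S, lambda3 for the HGO membrane over a batch of elements.

    The thickness stretch follows from incompressibility, lambda3 = 1/J2d;
    the anisotropic exponential term is active only under fiber tension
    (positive strain-like argument).  ``a0_2d`` may supply per-element fiber
    directions (n, 2); defaults to ``params.a0`` for every element.
    """
    C2d = np.asarray(C2d, float)
    a = np.trace(C2d, axis1=-2, axis2=-1)
    d = np.linalg.det(C2d)
    if np.any(d <= 0):
        raise ElementInversionError(
            f"element {int(np.argmin(d))} has non-positive in-plane Jacobian"
        )
    if a0_2d is None:
        a0_2d = np.broadcast_to(params.a0, C2d.shape[:-2] + (2,))
    a0_2d = np.asarray(a0_2d, float)

    I1b = a + 1.0 / d
    I4b = np.einsum("...i,...ij,...j->...", a0_2d, C2d, a0_2d)
    k, k1, k2 = params.kappa, params.k1, params.k2
    Ef = k * (I1b - 3.0) + (1.0 - 3.0 * k) * (I4b - 1.0)
    tension = Ef > 0

    Wiso = params.C10 * (I1b - 3.0)
    if k2 > 0:
        Wani = np.where(tension, k1 / (2.0 * k2) * np.expm1(k2 * Ef * Ef), 0.0)
    else:  # series limit of (exp(k2 x^2) - 1)/(2 k2) as k2 -> 0
        Wani = np.where(tension, 0.5 * k1 * Ef * Ef, 0.0)
    W = Wiso + Wani
    dWdEf = np.where(tension, k1 * Ef * np.exp(k2 * Ef * Ef), 0.0)

    Cinv = np.linalg.inv(C2d)
    eye = np.broadcast_to(np.eye(2), C2d.shape)
    dI1b = eye - (1.0 / d)[..., None, None] * Cinv
    A0 = np.einsum("...i,...j->...ij", a0_2d, a0_2d)
    S = 2.0 * (
        params.C10 * dI1b
        + dWdEf[..., None, None] * (k * dI1b + (1.0 - 3.0 * k) * A0)
    )
    return W, S, 1.0 / np.sqrt(d)


def hgo_stress(params: HGOParams, state: DeformationState):
    """Single-element wrapper: returns (W, S) and updates state.lambda3."""
    W, S, lam3 = hgo_stress_batch(params, state.C[None])
    state.lambda3 = float(lam3[0])
    return float(W[0]), S[0]


# ---------------------------------------------------------------------------
# Linear elasticity (plane stress)


def linear_plane_stress_matrix(params: LinearElasticParams) -> np.ndarray:
    """3x3 plane-stress matrix mapping (exx, eyy, gxy) to (sxx, syy, sxy)."""
    E, nu = params.E, params.nu
    f = E / (1.0 - nu * nu)
    return f * np.array([[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]])


def linear_plane_stress_matrix_batch(E, nu):
    """(n, 3, 3) plane-stress matrices for per-element E, nu arrays."""
    E = np.asarray(E, float)
    nu = np.asarray(nu, float)
    if np.any(nu >= 0.5) or np.any(nu < 0):
        raise ValueError("nu must lie in [0, 0.5)")
    n = np.broadcast_shapes(E.shape, nu.shape)
    D = np.zeros(n + (3, 3))
    f = E / (1.0 - nu * nu)
    D[..., 0, 0] = D[..., 1, 1] = f
    D[..., 0, 1] = D[..., 1, 0] = f * nu
    D[..., 2, 2] = f * (1.0 - nu) / 2.0
    return D


def linear_plane_stress_matrix_dnu(E, nu):
    """Analytic d(D-matrix)/d(nu), same shape as the batch matrix."""
    E = np.asarray(E, float)
    nu = np.asarray(nu, float)
    n = np.broadcast_shapes(E.shape, nu.shape)
    dD = np.zeros(n + (3, 3))
    g = 1.0 - nu * nu
    dD[..., 0, 0] = dD[..., 1, 1] = E * 2.0 * nu / g**2
    dD[..., 0, 1] = dD[..., 1, 0] = E * (1.0 + nu * nu) / g**2
    dD[..., 2, 2] = -E / (2.0 * (1.0 + nu) ** 2)
    return dD


# ---------------------------------------------------------------------------
# Derived initial moduli


def initial_moduli(material) -> tuple[float, float | None]:
    """Small-strain shear and bulk moduli (mu0, K0) implied by a material.

    Mooney–Rivlin: mu0 = 2 (C10 + C01), K0 = 2 / D1.
    HGO membrane:  mu0 = 2 C10; K0 is None — the isochoric membrane
    formulation carries no meaningful compressibility.
    Linear:        mu = E / (2 (1 + nu)), K = E / (3 (1 - 2 nu)).
    """
    if isinstance(material, MooneyRivlinParams):
        return 2.0 * (material.C10 + material.C01), 2.0 / material.D1
    if isinstance(material, HGOParams):
        return 2.0 * material.C10, None
    if isinstance(material, LinearElasticParams):
        return material.mu, material.E / (3.0 * (1.0 - 2.0 * material.nu))
    raise TypeError(f"unknown material type {type(material)!r}")


# ---------------------------------------------------------------------------
# Material fields and the flattened unknown vector p


@dataclass
class MaterialField:
    """Constitutive parameters over the mesh, flattenable to the unknown p.

    ``case`` is one of ``homo/iso/hyper`` (Mooney–Rivlin),
    ``homo/aniso/hyper`` (HGO) or ``hetero/iso/linear``.  Homogeneous cases
    hold one parameter record; the heterogeneous case holds per-element
    (E, nu) arrays and flattens to p = [E_0, nu_0, E_1, nu_1, ...] with
    N = 2 x n_elems.
    """

    case: str
    params: object = None          # MooneyRivlinParams or HGOParams
    E: np.ndarray | None = None    # hetero: (n_elems,) kPa
    nu: np.ndarray | None = None   # hetero: (n_elems,)

    CASES = ("homo/iso/hyper", "homo/aniso/hyper", "hetero/iso/linear")

    def __post_init__(self):
        if self.case not in self.CASES:
            raise ValueError(f"unknown case {self.case!r}")
        if self.case == "hetero/iso/linear":
            self.E = np.asarray(self.E, float)
            self.nu = np.broadcast_to(np.asarray(self.nu, float), self.E.shape).copy()
            LinearElasticParams(float(self.E.min()), float(self.nu.max()))  # validate

    @property
    def N(self) -> int:
        if self.case == "homo/iso/hyper":
            return 3
        if self.case == "homo/aniso/hyper":
            return 5
        return 2 * len(self.E)

    def flatten(self) -> np.ndarray:
        if self.case == "homo/iso/hyper":
            p = self.params
            return np.array([p.C10, p.C01, p.D1])
        if self.case == "homo/aniso/hyper":
            p = self.params
            return np.array([p.C10, p.D, p.k1, p.k2, p.kappa])
        out = np.empty(2 * len(self.E))
        out[0::2] = self.E
        out[1::2] = self.nu
        return out

    def unflatten(self, p: np.ndarray) -> "MaterialField":
        """Inverse of :meth:`flatten`; returns a new field, self untouched."""
        p = np.asarray(p, float)
        if p.shape != (self.N,):
            raise ValueError(f"expected parameter vector of length {self.N}")
        if self.case == "homo/iso/hyper":
            return MaterialField(self.case, MooneyRivlinParams(*p))
        if self.case == "homo/aniso/hyper":
            old = self.params
            return MaterialField(
                self.case, HGOParams(p[0], p[1], p[2], p[3], p[4], a0=old.a0)
            )
        return MaterialField(self.case, E=p[0::2].copy(), nu=p[1::2].copy())

    def shear_modulus_map(self) -> np.ndarray:
        """Per-element shear modulus (kPa); scalar cases broadcast."""
        if self.case == "hetero/iso/linear":
            return self.E / (2.0 * (1.0 + self.nu))
        mu0, _ = initial_moduli(self.params)
        return np.asarray(mu0)
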