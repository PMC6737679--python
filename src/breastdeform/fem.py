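"""Quasi-static soft-tissue mechanics by total-Lagrangian explicit dynamics.

The breast is modeled as a nearly incompressible neo-Hookean solid with
per-element tissue parameters (fat / fibroglandular). All kinematic
quantities are referred to the reference configuration: per element the
deformation gradient F comes from the cached inverse reference edge
matrix, the second Piola-Kirchhoff stress S from the stored-energy
density

    Psi = mu/2 (J^(-2/3) I1 - 3) + K/2 (J - 1)^2,      J = det F,

and nodal internal forces from the first Piola stress P = F S. Static
equilibrium under a gravity body force is found by dynamic relaxation:
damped central-difference time stepping with a lumped mass matrix,
run until nodal velocities and the residual force vanish.

Units: meshes are in mm (world coordinates); mechanics runs in SI
(m, kg, s, Pa) internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .meshing import FAT, FGT, LabeledTetMesh

log = logging.getLogger(__name__)

__all__ = [
    "TissueParams",
    "MaterialParams",
    "SolverOptions",
    "DeformationState",
    "neo_hookean_stress",
    "neo_hookean_energy_density",
    "internal_forces",
    "solve_static",
]

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class TissueParams:
    """Neo-Hookean constants of one tissue.

    The shear modulus is derived from the bulk modulus and Poisson
    ratio via the linear-elastic identity mu = 3K(1-2nu)/(2(1+nu)).
    """

    K: float            # bulk modulus, Pa
    nu: float = 0.45    # Poisson ratio
    rho: float = 1000.0  # density, kg/m^3

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("bulk modulus K must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.rho <= 0:
            raise ValueError("density must be positive")

    @property
    def mu(self) -> float:
        return 3.0 * self.K * (1.0 - 2.0 * self.nu) / (2.0 * (1.0 + self.nu))

    @property
    def youngs_modulus(self) -> float:
        return 2.0 * self.mu * (1.0 + self.nu)


@dataclass(frozen=True)
class MaterialParams:
    """Per-tissue material table (defaults: fat 3.4 kPa, FGT 50 kPa bulk)."""

    fat: TissueParams = field(default_factory=lambda: TissueParams(K=3400.0))
    fgt: TissueParams = field(default_factory=lambda: TissueParams(K=50000.0))

    def for_labels(self, labels: np.ndarray):
        """(mu, K, rho) arrays aligned with the element label array."""
        mu = np.where(labels == FGT, self.fgt.mu, self.fat.mu)
        K = np.where(labels == FGT, self.fgt.K, self.fat.K)
        rho = np.where(labels == FGT, self.fgt.rho, self.fat.rho)
        return mu.astype(float), K.astype(float), rho.astype(float)

    def with_poisson(self, nu: float) -> "MaterialParams":
        return MaterialParams(
            fat=TissueParams(self.fat.K, nu, self.fat.rho),
            fgt=TissueParams(self.fgt.K, nu, self.fgt.rho),
        )

    @classmethod
    def from_youngs(cls, E_fat: float = 3400.0, E_fgt: float = 50000.0,
                    nu: float = 0.49, rho: float = 1000.0) -> "MaterialParams":
        """Alternative parameterization: the tissue constants as Young's
        moduli, with K = E / (3(1 - 2nu)).

        Under this reading the bulk modulus grows as nu -> 1/2, so a
        nu = 0.49 material is genuinely near-incompressible even at
        gravity-scale stresses (with the constants read as bulk moduli,
        K itself is only a few kPa and gravity stress produces a few
        percent of physical volumetric strain).
        """
        K_fat = E_fat / (3.0 * (1.0 - 2.0 * nu))
        K_fgt = E_fgt / (3.0 * (1.0 - 2.0 * nu))
        return cls(fat=TissueParams(K_fat, nu, rho), fgt=TissueParams(K_fgt, nu, rho))


@dataclass
class SolverOptions:
    dt_safety: float = 0.3
    damping: float | None = None       # mass-proportional; None -> auto estimate
    tol_v: float = 1e-6                # max nodal speed, m/s
    tol_f_rel: float = 1e-4            # residual tolerance x total load
    max_steps: int = 200_000
    ramp_steps: int = 1500             # load ramp to avoid shock excitation
    check_every: int = 200
    log_every: int = 0                 # 0 -> no progress logging


@dataclass
class DeformationState:
    """Reference and current nodal positions (mm) plus diagnostics."""

    reference_nodes: np.ndarray
    current_nodes: np.ndarray
    velocities: np.ndarray            # m/s
    load_factor: float = 1.0
    steps: int = 0
    kinetic_energy: float = 0.0       # J
    max_residual_force: float = 0.0   # N
    converged: bool = True

    @property
    def displacements_mm(self) -> np.ndarray:
        return self.current_nodes - self.reference_nodes


# ---------------------------------------------------------------------------
# element kinematics and constitutive law
# ---------------------------------------------------------------------------

def _det33(A: np.ndarray) -> np.ndarray:
    return (A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
            - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
            + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]))


def _inv33(A: np.ndarray, det: np.ndarray) -> np.ndarray:
    inv = np.empty_like(A)
    inv[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    inv[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    inv[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    inv[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    inv[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    inv[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    inv[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    inv[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    inv[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return inv / det[..., None, None]


def neo_hookean_energy_density(F: np.ndarray, mu: float, K: float) -> float:
    """Psi(F) for a single deformation gradient (oracle for the stress)."""
    F = np.asarray(F, float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise ValueError("det F must be positive")
    I1 = float(np.trace(F.T @ F))
    return 0.5 * mu * (J ** (-2.0 / 3.0) * I1 - 3.0) + 0.5 * K * (J - 1.0) ** 2


def neo_hookean_stress(F: np.ndarray, mu: float, K: float) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dPsi/dC.

    S = mu J^(-2/3) (I - I1/3 C^(-1)) + K J (J - 1) C^(-1); symmetric,
    zero for any rotation. Raises on element inversion (det F <= 0).
    """
    F = np.asarray(F, float)
    single = F.ndim == 2
    if single:
        F = F[None]
    J = _det33(F)
    if np.any(J <= 0):
        bad = int(np.argmax(J <= 0))
        raise ValueError(f"element inversion: det F <= 0 (first at element {bad})")
    C = np.swapaxes(F, -1, -2) @ F
    Cinv = _inv33(C, _det33(C))
    I1 = np.trace(C, axis1=-2, axis2=-1)
    mu = np.asarray(mu, float)
    K = np.asarray(K, float)
    eye = np.eye(3)
    S = (mu[..., None, None] * J[..., None, None] ** (-2.0 / 3.0)
         * (eye - (I1 / 3.0)[..., None, None] * Cinv)
         + (K * J * (J - 1.0))[..., None, None] * Cinv)
    return S[0] if single else S


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class _Cache:
    """Reference-configuration element cache (TLED precomputation)."""

    def __init__(self, mesh: LabeledTetMesh, params: MaterialParams,
                 reference_nodes_mm: np.ndarray | None = None):
        X = (mesh.nodes if reference_nodes_mm is None else reference_nodes_mm) * MM
        self.tets = mesh.tets
        self.n_nodes = len(mesh.nodes)
        edges = X[self.tets[:, 1:]] - X[self.tets[:, :1]]     # (m, 3, 3) rows
        Dm = np.swapaxes(edges, -1, -2)                       # columns = edges
        detDm = _det33(Dm)
        if np.any(detDm <= 0):
            raise ValueError("reference mesh contains non-positive tets")
        self.Bm = _inv33(Dm, detDm)                           # (m, 3, 3)
        self.V0 = detDm / 6.0                                 # m^3
        self.mu, self.K, self.rho = params.for_labels(mesh.tissue_label)
        # lumped nodal mass
        self.mass = np.zeros(self.n_nodes)
        np.add.at(self.mass, self.tets.ravel(),
                  np.repeat(self.rho * self.V0 / 4.0, 4))
        self.free = ~mesh.fixed_mask

    def deformation_gradients(self, x_m: np.ndarray) -> np.ndarray:
        edges = x_m[self.tets[:, 1:]] - x_m[self.tets[:, :1]]
        Ds = np.swapaxes(edges, -1, -2)
        return Ds @ self.Bm

    def internal_forces(self, x_m: np.ndarray) -> np.ndarray:
        """Nodal internal forces (N) at current positions (meters)."""
        F = self.deformation_gradients(x_m)
        S = neo_hookean_stress(F, self.mu, self.K)
        P = F @ S
        H = -self.V0[:, None, None] * (P @ np.swapaxes(self.Bm, -1, -2))
        f = np.zeros((self.n_nodes, 3))
        # columns of H are forces on nodes 1..3; node 0 balances them
        f123 = np.swapaxes(H, -1, -2)                          # (m, 3nodes, 3)
        np.add.at(f, self.tets[:, 1:].ravel(), f123.reshape(-1, 3))
        np.add.at(f, self.tets[:, 0], -f123.sum(axis=1))
        return f

    def gravity_forces(self, gravity: np.ndarray) -> np.ndarray:
        f = np.zeros((self.n_nodes, 3))
        per_node = (self.rho * self.V0 / 4.0)[:, None] * gravity[None, :]
        np.add.at(f, self.tets.ravel(), np.repeat(per_node, 4, axis=0))
        return f

    def stable_dt(self, min_altitude_m: float, safety: float) -> float:
        # dilatational wave speed per tissue governs the CFL limit
        c = np.sqrt((self.K + 4.0 * self.mu / 3.0) / self.rho)
        return safety * min_altitude_m / float(c.max())


def internal_forces(mesh: LabeledTetMesh, current_nodes_mm: np.ndarray,
                    params: MaterialParams,
                    reference_nodes_mm: np.ndarray | None = None) -> np.ndarray:
    """Nodal internal force array (N) for a deformed configuration (mm)."""
    cache = _Cache(mesh, params, reference_nodes_mm)
    return cache.internal_forces(np.asarray(current_nodes_mm, float) * MM)


# ---------------------------------------------------------------------------
# dynamic relaxation
# ---------------------------------------------------------------------------

def solve_static(mesh: LabeledTetMesh, params: MaterialParams,
                 gravity: np.ndarray, options: SolverOptions | None = None,
                 reference_nodes_mm: np.ndarray | None = None,
                 initial_nodes_mm: np.ndarray | None = None) -> DeformationState:
    """Static equilibrium under a body force by damped explicit stepping.

    ``gravity`` is the acceleration vector in m/s^2 (scale it by a load
    factor externally). The reference configuration defaults to
    ``mesh.nodes``; pass ``reference_nodes_mm`` to simulate from a
    different rest shape over the same topology. Convergence requires
    both the peak nodal speed below ``tol_v`` and the peak residual
    force below ``tol_f_rel`` times the total gravity load.
    """
    options = options or SolverOptions()
    if not mesh.fixed_mask.any():
        raise ValueError("mesh has no fixed boundary nodes")
    gravity = np.asarray(gravity, float)
    ref_mm = np.asarray(mesh.nodes if reference_nodes_mm is None else reference_nodes_mm,
                        float)
    cache = _Cache(mesh, params, ref_mm)

    x = (ref_mm if initial_nodes_mm is None else np.asarray(initial_nodes_mm, float)) * MM
    x = x.copy()
    v = np.zeros_like(x)
    free = cache.free

    f_grav = cache.gravity_forces(gravity)
    total_load = float(np.linalg.norm(f_grav[free], axis=1).sum())
    if total_load == 0.0:
        return DeformationState(ref_mm.copy(), x / MM, v, steps=0,
                                max_residual_force=0.0, converged=True)
    tol_f = options.tol_f_rel * total_load

    # min altitude of the reference mesh (meters) for the CFL estimate
    p = ref_mm[mesh.tets] * MM
    vols = _det33(np.swapaxes(p[:, 1:] - p[:, :1], -1, -2)) / 6.0
    amax = np.zeros(len(mesh.tets))
    for a, b, c in [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]:
        area = 0.5 * np.linalg.norm(np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a]), axis=1)
        amax = np.maximum(amax, area)
    h_min = float((3.0 * vols / amax).min())
    dt = cache.stable_dt(h_min, options.dt_safety)

    if options.damping is None:
        # near-critical damping of the estimated lowest shear mode
        c_shear = np.sqrt(cache.mu / cache.rho).min()
        L = float((ref_mm.max(axis=0) - ref_mm.min(axis=0)).max()) * MM
        omega = np.pi * c_shear / (2.0 * L)
        damping = 2.0 * omega
    else:
        damping = options.damping

    from ._kernels import relax_block

    minv = 1.0 / cache.mass
    fbuf = np.zeros_like(x)
    converged = False
    step = 0
    residual = np.inf
    ramp = max(1, options.ramp_steps)
    while step < options.max_steps:
        n_block = min(options.check_every, options.max_steps - step)
        done, bad = relax_block(x, v, fbuf, cache.tets, cache.Bm, cache.V0,
                                cache.mu, cache.K, minv, free, f_grav,
                                dt, damping, n_block, step, ramp)
        step += done
        if bad >= 0:
            raise RuntimeError(f"element inversion (det F <= 0) at element {bad}, "
                               f"step {step}")
        if step >= ramp:
            residual = float(np.linalg.norm(fbuf[free], axis=1).max()) if free.any() else 0.0
            vmax = float(np.linalg.norm(v, axis=1).max())
            if options.log_every and step % options.log_every < options.check_every:
                log.info("step %d: residual %.3e N, vmax %.3e m/s", step, residual, vmax)
            if residual < tol_f and vmax < options.tol_v:
                converged = True
                break
    ke = float(0.5 * (cache.mass[:, None] * v * v).sum())
    state = DeformationState(
        reference_nodes=ref_mm.copy(),
        current_nodes=x / MM,
        velocities=v,
        steps=step,
        kinetic_energy=ke,
        max_residual_force=residual if np.isfinite(residual) else float("nan"),
        converged=converged,
    )
    if not converged:
        raise RuntimeError(
            f"dynamic relaxation did not converge in {step} steps "
            f"(residual {residual:.3e} N vs tol {tol_f:.3e} N)"
        )
    return state
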