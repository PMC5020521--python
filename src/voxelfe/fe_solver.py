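"""Linear-elastic solver for voxel hexahedral meshes.

One element type: an axis-aligned cube of edge ``h`` with trilinear shape
functions and full 2x2x2 Gauss integration, isotropic material.  Because
every element shares the same geometry and Poisson ratio, the global
stiffness is assembled from a single unit-modulus element matrix scaled
per element, and the reduced (free-DOF) system is solved with Jacobi- or
ILU-preconditioned conjugate gradients.

Per-element fields are recovered as the average over the 8 Gauss points:
strain, stress, von Mises stress, strain-energy density
``U = 1/2 e^T C e`` and the energy-equivalent strain
``eps_eq = sqrt(2 U / E)`` evaluated with the element's own modulus (so
doubling E halves the strain limit an element can sustain at equal
energy, which is the logic behind the dual-tissue failure limit).
Voigt order is ``(xx, yy, zz, xy, yz, zx)`` with engineering shear.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg, spilu

from .fe_model import BCSpec, ConstrainedSystem, HexMesh, apply_bc

_GAUSS = 1.0 / np.sqrt(3.0)


@dataclass
class SolverConfig:
    rel_tolerance: float = 1e-6
    max_iterations: int = 20000
    preconditioner: str = "jacobi"   # jacobi | ilu | none

    def validate(self) -> None:
        if not 0 < self.rel_tolerance < 1:
            raise ValueError("rel_tolerance must be in (0, 1)")
        if self.preconditioner not in ("jacobi", "ilu", "none"):
            raise ValueError(f"unknown preconditioner {self.preconditioner!r}")


@dataclass
class FESolution:
    nodal_displacements: np.ndarray   # (n_nodes, 3) mm
    element_strain: np.ndarray        # (nel, 6)
    element_stress: np.ndarray        # (nel, 6) MPa
    von_mises: np.ndarray             # (nel,) MPa
    sed: np.ndarray                   # (nel,) MPa (= N mm / mm^3)
    eeq_strain: np.ndarray            # (nel,)
    reaction_distal: float            # N, axial
    reaction_proximal: float          # N, axial
    solver_iterations: int
    residual: float

    def summary(self) -> dict:
        return {
            "reaction_distal_N": self.reaction_distal,
            "reaction_proximal_N": self.reaction_proximal,
            "iterations": self.solver_iterations,
            "residual": self.residual,
        }


def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """Isotropic 6x6 stiffness in Voigt notation (engineering shear)."""
    if not -1.0 < nu < 0.5:
        raise ValueError("Poisson ratio must lie in (-1, 0.5)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    return C


@lru_cache(maxsize=8)
def _b_matrices(h: float) -> np.ndarray:
    """(8, 6, 24) strain-displacement matrices at the 2x2x2 Gauss points
    of an axis-aligned cube with edge h (constant Jacobian h/2)."""
    # Local node coordinates in the parent cube [-1, 1]^3, matching the
    # element-local numbering used by the mesh.
    nodes = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                      [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
                     dtype=float)
    gauss = np.array([[sx, sy, sz] for sz in (-_GAUSS, _GAUSS)
                      for sy in (-_GAUSS, _GAUSS)
                      for sx in (-_GAUSS, _GAUSS)])
    B = np.zeros((8, 6, 24))
    for g, (xi, eta, zeta) in enumerate(gauss):
        for a in range(8):
            xa, ya, za = nodes[a]
            # dN/dxi etc., then * 2/h for physical derivatives
            dx = 0.125 * xa * (1 + eta * ya) * (1 + zeta * za) * 2 / h
            dy = 0.125 * ya * (1 + xi * xa) * (1 + zeta * za) * 2 / h
            dz = 0.125 * za * (1 + xi * xa) * (1 + eta * ya) * 2 / h
            c = 3 * a
            B[g, 0, c] = dx
            B[g, 1, c + 1] = dy
            B[g, 2, c + 2] = dz
            B[g, 3, c] = dy
            B[g, 3, c + 1] = dx
            B[g, 4, c + 1] = dz
            B[g, 4, c + 2] = dy
            B[g, 5, c] = dz
            B[g, 5, c + 2] = dx
    return B


def element_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """24x24 stiffness of one cubic 8-node brick (full 2x2x2 Gauss)."""
    if E < 0:
        raise ValueError("E must be non-negative")
    if not h > 0:
        raise ValueError("edge length must be positive")
    C = elasticity_matrix(E, nu)
    B = _b_matrices(h)
    detJ = (h / 2.0) ** 3
    K = np.einsum("gia,ij,gjb->ab", B, C, B) * detJ
    return 0.5 * (K + K.T)


def assemble(mesh: HexMesh) -> sparse.csr_matrix:
    """Global stiffness (3*n_nodes square, CSR) from per-element moduli."""
    mesh.validate()
    if mesh.E_per_element is None:
        raise ValueError("mesh has no assigned moduli")
    K_unit = element_stiffness(1.0, mesh.poisson, mesh.edge_length)
    edofs = (mesh.node_ids[:, :, None] * 3 +
             np.arange(3)[None, None, :]).reshape(mesh.n_elements, 24)
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    data = (mesh.E_per_element[:, None, None] * K_unit[None]).ravel()
    n = 3 * mesh.n_nodes
    K = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    return K


def _make_preconditioner(K_ff: sparse.csr_matrix, kind: str):
    if kind == "none":
        return None
    if kind == "jacobi":
        d = K_ff.diagonal()
        d[d <= 0] = 1.0
        inv = 1.0 / d
        return LinearOperator(K_ff.shape, matvec=lambda x: inv * x)
    ilu = spilu(K_ff.tocsc(), drop_tol=1e-5, fill_factor=12.0)
    return LinearOperator(K_ff.shape, matvec=ilu.solve)


def solve(mesh: HexMesh, bc: BCSpec | None = None,
          cfg: SolverConfig | None = None,
          system: ConstrainedSystem | None = None) -> FESolution:
    """Solve the constrained compression test and recover element fields."""
    cfg = cfg or SolverConfig()
    cfg.validate()
    sysd = system or apply_bc(mesh, bc)
    K = assemble(mesh)
    n = K.shape[0]
    presc = sysd.prescribed_dofs
    free = np.setdiff1d(np.arange(n), presc, assume_unique=False)
    if free.size and K[free][:, free].diagonal().min() <= 0:
        raise ValueError("singular system: isolated nodes in the mesh")

    u = np.zeros(n)
    u[presc] = sysd.prescribed_values
    K_ff = K[free][:, free].tocsr()
    rhs = -K[free][:, presc] @ sysd.prescribed_values

    iterations = 0
    if free.size and np.linalg.norm(rhs) > 0:
        M = _make_preconditioner(K_ff, cfg.preconditioner)

        def count(_):
            nonlocal iterations
            iterations += 1

        u_f, info = cg(K_ff, rhs, rtol=cfg.rel_tolerance, atol=0.0,
                       maxiter=cfg.max_iterations, M=M, callback=count)
        residual = float(np.linalg.norm(K_ff @ u_f - rhs) /
                         np.linalg.norm(rhs))
        if info > 0:
            raise RuntimeError(
                f"CG did not converge in {cfg.max_iterations} iterations "
                f"(relative residual {residual:.3e})")
        u[free] = u_f
    else:
        residual = 0.0

    # Reactions: full stiffness times the solution, summed over each face.
    f = K @ u
    rd = float(f[sysd.distal_nodes * 3 + 2].sum())
    rp = float(f[sysd.proximal_nodes * 3 + 2].sum())

    strain, stress, vm, sed, eeq = recover_fields(mesh, u)
    return FESolution(nodal_displacements=u.reshape(-1, 3),
                      element_strain=strain, element_stress=stress,
                      von_mises=vm, sed=sed, eeq_strain=eeq,
                      reaction_distal=rd, reaction_proximal=rp,
                      solver_iterations=iterations, residual=residual)


def recover_fields(mesh: HexMesh, u: np.ndarray):
    """Gauss-point-averaged strain/stress/energy fields per element."""
    B = _b_matrices(mesh.edge_length)        # (8, 6, 24)
    B_mean = B.mean(axis=0)                  # averaging is linear
    edofs = (mesh.node_ids[:, :, None] * 3 +
             np.arange(3)[None, None, :]).reshape(mesh.n_elements, 24)
    u_e = u.ravel()[edofs]                   # (nel, 24)
    strain = u_e @ B_mean.T                  # (nel, 6)
    C_unit = elasticity_matrix(1.0, mesh.poisson)
    stress = (strain @ C_unit.T) * mesh.E_per_element[:, None]
    sxx, syy, szz, sxy, syz, szx = stress.T
    vm = np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                 + 3.0 * (sxy ** 2 + syz ** 2 + szx ** 2))
    # Energy must be averaged over Gauss points (it is quadratic in strain).
    strain_g = np.einsum("gij,ej->egi", B, u_e)          # (nel, 8, 6)
    stress_g = np.einsum("ij,egj->egi", C_unit, strain_g) * \
        mesh.E_per_element[:, None, None]
    sed = 0.5 * np.einsum("egi,egi->e", strain_g, stress_g) / B.shape[0]
    sed = np.maximum(sed, 0.0)
    eeq = np.sqrt(2.0 * sed / mesh.E_per_element)
    return strain, stress, vm, sed, eeq
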