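"""Finite-difference Poisson-Boltzmann solver for polar solvation energies.

Solves the linearized PB equation on a regular grid with a two-dielectric
(solute/solvent) map built from inflated atomic spheres:

    div( eps(r) grad phi ) - eps(r) kappa2(r) phi = -4 pi f rho(r)

with phi in kJ mol^-1 e^-1, charges in e, lengths in nm and
f = 138.935458 kJ mol^-1 nm e^-2, so that a point charge in a uniform
dielectric recovers phi = f q / (eps r). Face dielectrics use harmonic
averaging; charges are spread trilinearly; Dirichlet boundary values come
from the (Debye-Hueckel screened) Coulomb potential in the solvent
dielectric. The reaction-field (polar solvation) energy is

    E = 1/2 sum_i q_i [ phi_het(x_i) - phi_homo(x_i) ]

where the homogeneous reference solve uses the solute dielectric
everywhere on the same grid, cancelling the grid self-energy.

This is a validation-scale solver (checked against the Born ion closed
form); parity with production nonlinear-PB engines is out of scope and the
linearized form is flagged wherever polar values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .constants import F_COULOMB

__all__ = ["PBSettings", "PBConvergenceError", "polar_energy_fdpb", "born_energy"]


class PBConvergenceError(RuntimeError):
    pass


@dataclass
class PBSettings:
    """Grid and dielectric settings for the FD-PB solve.

    Defaults follow common MM/PBSA practice for protein complexes: solute
    dielectric 4, solvent dielectric 78.5, 0.0325 nm grid spacing. Ionic
    strength defaults to 0 (pure Poisson); a nonzero value adds linearized
    Debye screening in the solvent region.
    """

    spacing: float = 0.0325           # nm
    eps_solute: float = 4.0
    eps_solvent: float = 78.5
    ionic_strength: float = 0.0       # mol/L
    padding: float = 1.0              # nm beyond solute bounding box
    temperature: float = 310.0        # K, enters the Debye length only
    cg_tol: float = 1e-8
    max_iter: int = 20000

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.eps_solute < 1 or self.eps_solvent < 1:
            raise ValueError("dielectric constants must be >= 1")

    def kappa2(self) -> float:
        """Squared inverse Debye length (nm^-2) in the solvent."""
        if self.ionic_strength <= 0:
            return 0.0
        from .constants import KB
        # kappa^2 = 8 pi f beta I_number, I in particles/nm^3 for 1:1 salt
        n_per_nm3 = self.ionic_strength * 6.02214076e23 * 1e-24
        beta = 1.0 / (KB * self.temperature)
        return 8.0 * np.pi * F_COULOMB * beta * n_per_nm3 / self.eps_solvent


def _solute_mask(points, centers, radii):
    """Boolean inside-solute test for an array of points (N,3)."""
    inside = np.zeros(len(points), dtype=bool)
    for c, r in zip(centers, radii):
        d2 = ((points - c) ** 2).sum(axis=1)
        inside |= d2 <= r * r
    return inside


def _boundary_potential(points, centers, charges, eps, kappa):
    phi = np.zeros(len(points))
    for c, q in zip(centers, charges):
        r = np.sqrt(((points - c) ** 2).sum(axis=1))
        r = np.maximum(r, 1e-6)
        screen = np.exp(-kappa * r) if kappa > 0 else 1.0
        phi += F_COULOMB * q * screen / (eps * r)
    return phi


def _solve_grid(centers, charges, radii, settings: PBSettings, homogeneous: bool):
    h = settings.spacing
    lo = centers.min(axis=0) - settings.padding
    hi = centers.max(axis=0) + settings.padding
    n = np.ceil((hi - lo) / h).astype(int) + 1
    nx, ny, nz = int(n[0]), int(n[1]), int(n[2])
    origin = lo
    if np.any(centers - origin < settings.padding - 1e-9) or \
       np.any(origin + (n - 1) * h - centers < settings.padding - 1e-9):
        raise ValueError("atom within padding distance of the grid boundary")

    xs = origin[0] + np.arange(nx) * h
    ys = origin[1] + np.arange(ny) * h
    zs = origin[2] + np.arange(nz) * h

    # face dielectrics via harmonic mean of cell-midpoint values
    def eps_at(points):
        if homogeneous:
            return np.full(len(points), settings.eps_solute)
        inside = _solute_mask(points, centers, radii)
        return np.where(inside, settings.eps_solute, settings.eps_solvent)

    def node_grid():
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    # midpoints of faces between node (i,j,k) and (i+1,j,k) etc.
    def face_eps(axis):
        shape = [nx, ny, nz]
        shape[axis] -= 1
        axes = [xs, ys, zs]
        mids = [xs, ys, zs].copy()
        mids[axis] = axes[axis][:-1] + h / 2.0
        X, Y, Z = np.meshgrid(*mids, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        return eps_at(pts).reshape(shape)

    ex = face_eps(0)  # (nx-1, ny, nz)
    ey = face_eps(1)
    ez = face_eps(2)

    # screening term on nodes (solvent region only)
    kappa2 = settings.kappa2()
    if kappa2 > 0 and not homogeneous:
        nodes = node_grid()
        inside = _solute_mask(nodes, centers, radii).reshape(nx, ny, nz)
        screen = np.where(inside, 0.0, settings.eps_solvent * kappa2 * h * h)
    else:
        screen = np.zeros((nx, ny, nz))

    # trilinear charge spreading onto nodes
    rho = np.zeros((nx, ny, nz))
    for cpos, q in zip(centers, charges):
        g = (cpos - origin) / h
        i0 = np.floor(g).astype(int)
        frac = g - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((1 - frac[0]) if dx == 0 else frac[0]) * \
                        ((1 - frac[1]) if dy == 0 else frac[1]) * \
                        ((1 - frac[2]) if dz == 0 else frac[2])
                    rho[i0[0] + dx, i0[1] + dy, i0[2] + dz] += q * w

    # Dirichlet boundary values
    phi_full = np.zeros((nx, ny, nz))
    bmask = np.zeros((nx, ny, nz), dtype=bool)
    bmask[0], bmask[-1] = True, True
    bmask[:, 0], bmask[:, -1] = True, True
    bmask[:, :, 0], bmask[:, :, -1] = True, True
    nodes = node_grid()
    bpoints = nodes[bmask.ravel()]
    eps_bc = settings.eps_solute if homogeneous else settings.eps_solvent
    kap = 0.0 if homogeneous else np.sqrt(kappa2) if kappa2 > 0 else 0.0
    phi_full[bmask] = _boundary_potential(bpoints, centers, charges, eps_bc, kap)

    # assemble interior system: for node c, sum_f eps_f (phi_n - phi_c)
    #   - screen_c phi_c = -4 pi f q_c / h
    interior = ~bmask
    idx = -np.ones((nx, ny, nz), dtype=int)
    idx[interior] = np.arange(interior.sum())
    N = interior.sum()
    # -sum_f eps_f phi_n + (sum_f eps_f + screen) phi_c = 4 pi f q_c / h
    b = (4.0 * np.pi * F_COULOMB / h) * rho.copy()

    diag = screen.copy()
    rows, cols, vals = [], [], []

    def couple(eps_face, shift_axis):
        """Add coupling across faces between node (i,j,k) and its +1
        neighbour along ``shift_axis``; known boundary values go to the RHS."""
        sl_c = [slice(None)] * 3
        sl_n = [slice(None)] * 3
        sl_c[shift_axis] = slice(0, -1)
        sl_n[shift_axis] = slice(1, None)
        sl_c, sl_n = tuple(sl_c), tuple(sl_n)
        e = eps_face
        idc, idn = idx[sl_c], idx[sl_n]
        both = (idc >= 0) & (idn >= 0)
        rows.append(idc[both]); cols.append(idn[both]); vals.append(-e[both])
        rows.append(idn[both]); cols.append(idc[both]); vals.append(-e[both])
        # every face contributes eps to the diagonal of both its nodes
        dc = np.zeros_like(diag)
        dc[sl_c] += e
        dc[sl_n] += e
        diag[...] += dc
        cb = (idc >= 0) & (idn < 0)
        if cb.any():
            contrib = np.zeros_like(b)
            contrib[sl_c] = np.where(cb, e * phi_full[sl_n], 0.0)
            b[...] += contrib
        nb = (idn >= 0) & (idc < 0)
        if nb.any():
            contrib = np.zeros_like(b)
            contrib[sl_n] = np.where(nb, e * phi_full[sl_c], 0.0)
            b[...] += contrib

    couple(ex, 0)
    couple(ey, 1)
    couple(ez, 2)

    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N)).tocsr()
    A = A + sparse.diags(diag[interior])
    rhs = b[interior]

    M = sparse.diags(1.0 / A.diagonal())
    phi_int, info = cg(A, rhs, rtol=settings.cg_tol, maxiter=settings.max_iter, M=M)
    if info != 0:
        residual = np.linalg.norm(A @ phi_int - rhs) / max(np.linalg.norm(rhs), 1e-30)
        raise PBConvergenceError(
            f"FD-PB conjugate gradient did not converge (info={info}, relative "
            f"residual {residual:.2e})")
    phi_full[interior] = phi_int

    # trilinear interpolation of phi at charge sites
    site_phi = np.empty(len(centers))
    for a, cpos in enumerate(centers):
        g = (cpos - origin) / h
        i0 = np.floor(g).astype(int)
        frac = g - i0
        acc = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((1 - frac[0]) if dx == 0 else frac[0]) * \
                        ((1 - frac[1]) if dy == 0 else frac[1]) * \
                        ((1 - frac[2]) if dz == 0 else frac[2])
                    acc += w * phi_full[i0[0] + dx, i0[1] + dy, i0[2] + dz]
        site_phi[a] = acc
    return site_phi


def polar_energy_fdpb(coords: np.ndarray, charges: np.ndarray, radii: np.ndarray,
                      settings: PBSettings = None) -> float:
    """Electrostatic (reaction-field) solvation energy in kJ/mol.

    ``coords`` (n,3) nm, ``charges`` e, ``radii`` nm (inflated-sphere solute
    volume). Two linear solves on the same grid -- heterogeneous dielectric
    and a solute-dielectric reference -- so grid self-energies cancel.
    """
    settings = settings or PBSettings()
    coords = np.asarray(coords, float)
    charges = np.asarray(charges, float)
    radii = np.asarray(radii, float)
    if np.all(charges == 0.0):
        return 0.0
    phi_het = _solve_grid(coords, charges, radii, settings, homogeneous=False)
    phi_hom = _solve_grid(coords, charges, radii, settings, homogeneous=True)
    return float(0.5 * np.sum(charges * (phi_het - phi_hom)))


def born_energy(q: float, radius: float, eps_in: float, eps_out: float) -> float:
    """Closed-form Born ion solvation energy, kJ/mol."""
    return -(F_COULOMB * q * q / (2.0 * radius)) * (1.0 / eps_in - 1.0 / eps_out)
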