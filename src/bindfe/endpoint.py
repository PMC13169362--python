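"""End-point MM/PB(GB)SA binding-energy estimator.

Single-trajectory protocol: protein and ligand frames are sub-selections of
the complex trajectory, so intramolecular (bonded) terms cancel and the
enthalpic part reduces to the protein-ligand interaction energy.  The polar
solvation term comes either from a finite-difference linearised
Poisson-Boltzmann solve or from a generalized-Born model of the OBC-II
(igb=5) lineage; the nonpolar term is linear in the Shrake-Rupley
solvent-accessible surface area; the entropic penalty is quasi-harmonic.

dG_bind = dE_MM + dG_Polar + dG_NonPolar - T dS
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import (
    ConvergenceError,
    EstimationError,
    GeometryError,
    SelectionError,
    SnapshotEnsemble,
    ThermoContext,
    ToySolute,
)

# physical constants for the quasi-harmonic frequencies (SI)
_HBAR_J_S = 1.054571817e-34
_KB_J_PER_K = 1.380649e-23
_AMU_KG = 1.66053906892e-27
_A2_M2 = 1e-20
#: Avogadro-scaled number density of a 1 M solution, ions/Å^3.
_IONS_PER_A3_PER_M = 6.02214076e-4


# --------------------------------------------------------------------------
# molecular-mechanics interaction terms
# --------------------------------------------------------------------------

def mm_interaction_energy(
    frame: ToySolute,
    protein_mask: np.ndarray,
    ligand_mask: np.ndarray,
    ctx: ThermoContext,
    min_distance: float = 0.1,
) -> tuple[float, float]:
    """Protein-ligand Coulomb and Lennard-Jones interaction energies, kcal/mol.

    No cutoff and no periodic images (desk-scale solutes).  LJ parameters are
    combined with Lorentz-Berthelot rules; electrostatics use the in-vacuo
    Coulomb constant (the solvent response lives in the polar solvation term).
    """
    pm = np.asarray(protein_mask)
    lm = np.asarray(ligand_mask)
    if np.any(pm & lm):
        raise SelectionError("protein and ligand selections overlap")
    if not pm.any() or not lm.any():
        raise SelectionError("protein and ligand selections must be non-empty")
    rp = frame.coords[pm]
    rl = frame.coords[lm]
    d = np.linalg.norm(rp[:, None, :] - rl[None, :, :], axis=2)
    if np.any(d < min_distance):
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise GeometryError(
            f"overlapping atoms: pair distance {d[i, j]:.3f} Å < {min_distance} Å")
    qp = np.asarray(frame.charges, dtype=float)[pm]
    ql = np.asarray(frame.charges, dtype=float)[lm]
    elec = ctx.coulomb_constant * float((qp[:, None] * ql[None, :] / d).sum())
    sig = 0.5 * (np.asarray(frame.lj_sigmas, dtype=float)[pm][:, None]
                 + np.asarray(frame.lj_sigmas, dtype=float)[lm][None, :])
    eps = np.sqrt(np.asarray(frame.lj_epsilons, dtype=float)[pm][:, None]
                  * np.asarray(frame.lj_epsilons, dtype=float)[lm][None, :])
    sr6 = (sig / d) ** 6
    vdw = float((4.0 * eps * (sr6 ** 2 - sr6)).sum())
    return elec, vdw


# --------------------------------------------------------------------------
# finite-difference linearised Poisson-Boltzmann
# --------------------------------------------------------------------------

@dataclass
class PBGrid:
    """Uniform 3D grid carrying the dielectric map, gridded charge and the
    solved electrostatic potential (kcal/(mol e))."""

    origin: np.ndarray
    h: float
    shape: tuple[int, int, int]
    eps: np.ndarray                  # (nx, ny, nz) cell-centre dielectric
    rho: np.ndarray                  # (nx, ny, nz) charge per node, e
    kappa2: np.ndarray               # (nx, ny, nz) screening eps_out*kappa^2
    phi: np.ndarray | None = None


def debye_kappa(ionic_strength: float, eps_out: float, ctx: ThermoContext) -> float:
    """Inverse Debye length kappa (1/Å) of a 1:1 electrolyte."""
    if ionic_strength <= 0:
        return 0.0
    n = ionic_strength * _IONS_PER_A3_PER_M
    kappa2 = 8.0 * np.pi * ctx.coulomb_constant * n / (eps_out * ctx.kT)
    return float(np.sqrt(kappa2))


def _spread_charges(coords, charges, origin, h, shape) -> np.ndarray:
    """Trilinear (cloud-in-cell) spreading of point charges to grid nodes."""
    rho = np.zeros(shape)
    frac = (coords - origin) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wx = t[:, 0] if dx else 1 - t[:, 0]
                wy = t[:, 1] if dy else 1 - t[:, 1]
                wz = t[:, 2] if dz else 1 - t[:, 2]
                np.add.at(rho, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz),
                          charges * wx * wy * wz)
    return rho


def _trilinear_sample(grid_vals, coords, origin, h) -> np.ndarray:
    frac = (coords - origin) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    out = np.zeros(len(coords))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wx = t[:, 0] if dx else 1 - t[:, 0]
                wy = t[:, 1] if dy else 1 - t[:, 1]
                wz = t[:, 2] if dz else 1 - t[:, 2]
                out += grid_vals[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz] \
                    * wx * wy * wz
    return out


def _face_eps(dist: np.ndarray, axis: int, eps_in: float, eps_out: float) -> np.ndarray:
    """Harmonic-mean face dielectrics with fractional boundary smoothing.

    The solute boundary position along each grid edge is located by linear
    interpolation of the signed distance to the van der Waals envelope; the
    edge's dielectric is the harmonic average weighted by the inside fraction
    (the flux-consistent rule for a series of two dielectric slabs).
    """
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    d0 = dist[tuple(sl_lo)]
    d1 = dist[tuple(sl_hi)]
    f = np.empty_like(d0)
    both_in = (d0 <= 0) & (d1 <= 0)
    both_out = (d0 > 0) & (d1 > 0)
    f[both_in] = 1.0
    f[both_out] = 0.0
    crossing = ~(both_in | both_out)
    if crossing.any():
        dn = np.where(d0[crossing] <= 0, d0[crossing], d1[crossing])
        dp = np.where(d0[crossing] <= 0, d1[crossing], d0[crossing])
        f[crossing] = np.clip(-dn / (dp - dn), 0.0, 1.0)
    return 1.0 / (f / eps_in + (1.0 - f) / eps_out)


def _solve_fd(faces, kappa2_cell, rho, h, phi_boundary, coul, rtol=1e-8):
    """Solve  -div(eps grad phi) + kappa2 phi = 4 pi C rho / h^3  on the grid.

    7-point flux stencil with the face dielectrics in ``faces = (ex, ey, ez)``;
    Dirichlet boundary values folded into the RHS.  CG on the SPD system.
    """
    ex, ey, ez = faces
    nx, ny, nz = kappa2_cell.shape

    idx = -np.ones((nx, ny, nz), dtype=int)
    interior = np.zeros((nx, ny, nz), dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    n_int = interior.sum()
    idx[interior] = np.arange(n_int)

    rhs = 4.0 * np.pi * coul * rho / h  # (4 pi C q / h^3) * h^2 flux scaling
    rhs = rhs[interior].astype(float)

    diag = np.zeros(n_int)
    rows, cols, vals = [], [], []
    ii, jj, kk = np.nonzero(interior)
    me = idx[ii, jj, kk]

    # assemble the six faces; eface arrays are indexed at the lower cell
    neigh = [
        (ex[ii - 1, jj, kk], -1, 0, 0),
        (ex[ii, jj, kk], +1, 0, 0),
        (ey[ii, jj - 1, kk], 0, -1, 0),
        (ey[ii, jj, kk], 0, +1, 0),
        (ez[ii, jj, kk - 1], 0, 0, -1),
        (ez[ii, jj, kk], 0, 0, +1),
    ]
    for ef, oi, oj, ok in neigh:
        ni, nj, nk = ii + oi, jj + oj, kk + ok
        nb_int = interior[ni, nj, nk]
        diag += ef
        rows.append(me[nb_int])
        cols.append(idx[ni, nj, nk][nb_int])
        vals.append(-ef[nb_int])
        b = ~nb_int
        if b.any():
            rhs[me[b]] += ef[b] * phi_boundary[ni[b], nj[b], nk[b]]

    diag += kappa2_cell[interior] * h * h
    rows.append(me)
    cols.append(me)
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_int, n_int),
    )
    M = spla.LinearOperator((n_int, n_int), matvec=lambda x: x / diag)
    phi_int, info = spla.cg(A, rhs, rtol=rtol, atol=0.0, maxiter=20000, M=M)
    if info != 0:
        res = float(np.linalg.norm(A @ phi_int - rhs) / max(np.linalg.norm(rhs), 1e-300))
        raise ConvergenceError(f"PB conjugate-gradient solve failed (info={info})",
                               residual=res)
    phi = phi_boundary.copy()
    phi[interior] = phi_int
    return phi


def pb_polar_energy(
    solute: ToySolute,
    h: float = 0.5,
    padding: float = 8.0,
    eps_in: float = 1.0,
    eps_out: float = 80.0,
    ionic_strength: float = 0.0,
    ctx: ThermoContext | None = None,
    rtol: float = 1e-8,
) -> float:
    """Polar solvation energy from the finite-difference linearised PB equation.

    Two solves on the identical grid and charge distribution: the solvated
    system (eps_in inside the van der Waals envelope, eps_out with
    Debye-Hückel screening outside) and a uniform eps_in / kappa=0 reference.
    dG_Polar = 1/2 sum_i q_i [phi_solv(r_i) - phi_ref(r_i)]; the grid
    self-energy cancels exactly in the difference.
    """
    ctx = ctx or ThermoContext()
    coords = solute.coords
    charges = np.asarray(solute.charges, dtype=float)
    radii = np.asarray(solute.radii, dtype=float)
    if np.all(charges == 0.0):
        return 0.0
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    n = np.ceil((hi - lo) / h).astype(int) + 1
    origin = lo
    shape = tuple(int(v) for v in n)
    # node coordinates
    axes = [origin[d] + h * np.arange(shape[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")

    # signed distance to the van der Waals envelope (negative inside)
    dist = np.full(shape, np.inf)
    for r0, rad in zip(coords, radii):
        d = np.sqrt((X - r0[0]) ** 2 + (Y - r0[1]) ** 2 + (Z - r0[2]) ** 2) - rad
        np.minimum(dist, d, out=dist)
    inside = dist <= 0
    faces = tuple(_face_eps(dist, ax, eps_in, eps_out) for ax in range(3))

    kappa = debye_kappa(ionic_strength, eps_out, ctx)
    kappa2 = np.zeros(shape)
    kappa2[~inside] = eps_out * kappa * kappa

    rho = _spread_charges(coords, charges, origin, h, shape)
    leak = abs(rho.sum() - charges.sum())
    if leak > 1e-6:
        raise EstimationError(f"charge leak {leak:.2e} e during gridding")

    nodes_flat = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    C = ctx.coulomb_constant

    def dh_boundary(kap, eps_ref):
        phi = np.zeros(shape).ravel()
        mask = np.zeros(shape, dtype=bool)
        mask[0, :, :] = mask[-1, :, :] = True
        mask[:, 0, :] = mask[:, -1, :] = True
        mask[:, :, 0] = mask[:, :, -1] = True
        mflat = mask.ravel()
        pts = nodes_flat[mflat]
        acc = np.zeros(len(pts))
        for q, r0 in zip(charges, coords):
            d = np.maximum(np.linalg.norm(pts - r0[None, :], axis=1), 1e-6)
            acc += q * np.exp(-kap * d) / d
        phi[mflat] = C * acc / eps_ref
        return phi.reshape(shape)

    phi_solv = _solve_fd(faces, kappa2, rho, h, dh_boundary(kappa, eps_out), C, rtol)
    ref_faces = tuple(np.full_like(f, eps_in) for f in faces)
    phi_ref = _solve_fd(ref_faces, np.zeros(shape), rho, h,
                        dh_boundary(0.0, eps_in), C, rtol)
    dphi = phi_solv - phi_ref
    at_atoms = _trilinear_sample(dphi, coords, origin, h)
    return 0.5 * float(np.dot(charges, at_atoms))


def pb_polar_energy_richardson(
    solute: ToySolute,
    h_coarse: float = 0.8,
    h_fine: float = 0.4,
    order: float = 2.0,
    **kwargs,
) -> float:
    """Richardson extrapolation of the FD-PB energy over two grid spacings."""
    e_c = pb_polar_energy(solute, h=h_coarse, **kwargs)
    e_f = pb_polar_energy(solute, h=h_fine, **kwargs)
    r = (h_coarse / h_fine) ** order
    return float(e_f + (e_f - e_c) / (r - 1.0))


def born_energy(q: float, a: float, eps_in: float, eps_out: float,
                ctx: ThermoContext | None = None, kappa: float = 0.0) -> float:
    """Closed-form Born (and Debye-Hückel screened) solvation energy of a
    charged sphere of radius ``a`` - the analytic oracle for the PB solver."""
    ctx = ctx or ThermoContext()
    C = ctx.coulomb_constant
    e = -(C * q * q / (2.0 * a)) * (1.0 / eps_in - 1.0 / eps_out)
    if kappa > 0:
        e += -(C * q * q / (2.0 * eps_out)) * kappa / (1.0 + kappa * a)
    return float(e)


# --------------------------------------------------------------------------
# generalized Born (OBC-II lineage)
# --------------------------------------------------------------------------

_OBC2 = (1.0, 0.8, 4.85)  # alpha, beta, gamma


def _hct_integral(r: np.ndarray, rho_i: np.ndarray, rho_j: np.ndarray) -> np.ndarray:
    """Pairwise HCT descreening integral of sphere j seen from atom i.

    Piecewise closed form of (1/4pi) * int_{sphere j} dV / s^4 over the region
    outside radius rho_i around atom i; vanishes when sphere j is engulfed.
    """
    out = np.zeros_like(r)
    # sphere j entirely inside the rho_i sphere: no descreening
    engulfed = r + rho_j <= rho_i
    L = np.maximum(np.abs(r - rho_j), rho_i)
    U = r + rho_j
    valid = (~engulfed) & (U > L)
    Lv, Uv, rv, pj = L[valid], U[valid], r[valid], np.broadcast_to(rho_j, r.shape)[valid]
    term = (1.0 / Lv - 1.0 / Uv
            + (rv / 4.0) * (1.0 / Uv ** 2 - 1.0 / Lv ** 2)
            + (1.0 / (2.0 * rv)) * np.log(Lv / Uv)
            + (pj ** 2 / (4.0 * rv)) * (1.0 / Lv ** 2 - 1.0 / Uv ** 2))
    out[valid] = 0.5 * term
    # atom i inside sphere j: add the enclosed correction 2(1/rho_i - 1/L)
    inside = (rv + np.broadcast_to(rho_i, r.shape)[valid]) < pj
    if np.any(inside):
        add = 2.0 * (1.0 / np.broadcast_to(rho_i, r.shape)[valid][inside] - 1.0 / Lv[inside])
        out_valid = out[valid]
        out_valid[inside] += 0.5 * add
        out[valid] = out_valid
    return out


def gb_born_radii(solute: ToySolute, offset: float = 0.0,
                  obc_params: tuple[float, float, float] = _OBC2) -> np.ndarray:
    """Effective Born radii by pairwise descreening with OBC-II rescaling.

    1/R_i = 1/rho~_i - tanh(a Psi - b Psi^2 + c Psi^3) / rho_i with
    Psi = rho~_i * I_i and rho~_i = rho_i - offset.  The dielectric-radius
    offset defaults to zero so an isolated atom has R_i exactly equal to its
    intrinsic radius.
    """
    alpha, beta, gamma = obc_params
    rho = np.asarray(solute.radii, dtype=float)
    rho_t = rho - offset
    if np.any(rho_t <= 0):
        raise EstimationError("dielectric offset exceeds an atomic radius")
    n = solute.n_atoms
    coords = solute.coords
    I = np.zeros(n)
    for i in range(n):
        mask = np.arange(n) != i
        if not mask.any():
            break
        r = np.linalg.norm(coords[mask] - coords[i], axis=1)
        I[i] = _hct_integral(r, rho_t[i], rho_t[mask]).sum()
    psi = rho_t * I
    inv_R = 1.0 / rho_t - np.tanh(alpha * psi - beta * psi ** 2 + gamma * psi ** 3) / rho
    if np.any(inv_R <= 0):
        bad = int(np.argmax(inv_R <= 0))
        raise EstimationError(f"GB model breakdown: non-positive Born radius for atom {bad}")
    return 1.0 / inv_R


def gb_polar_energy(
    solute: ToySolute,
    eps_in: float = 1.0,
    eps_out: float = 80.0,
    ctx: ThermoContext | None = None,
    offset: float = 0.0,
) -> float:
    """Generalized-Born polar solvation energy (OBC-II effective radii).

    E = -C/2 (1/eps_in - 1/eps_out) sum_ij q_i q_j / f_GB(r_ij, R_i, R_j)
    with f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / 4 R_i R_j)); the i=j term is the
    Born self-energy with f_GB = R_i.
    """
    ctx = ctx or ThermoContext()
    R = gb_born_radii(solute, offset=offset)
    q = np.asarray(solute.charges, dtype=float)
    d2 = ((solute.coords[:, None, :] - solute.coords[None, :, :]) ** 2).sum(axis=2)
    RR = R[:, None] * R[None, :]
    f = np.sqrt(d2 + RR * np.exp(-d2 / (4.0 * RR)))
    pref = -0.5 * ctx.coulomb_constant * (1.0 / eps_in - 1.0 / eps_out)
    return pref * float((q[:, None] * q[None, :] / f).sum())


# --------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)
# --------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point set (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def sasa(solute: ToySolute, probe: float = 1.4, n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Test points on each atom's expanded sphere (r_i + probe) count as
    accessible iff they fall outside every other atom's expanded sphere.
    Returns (per-atom areas, total), Å^2.
    """
    if n_points < 32:
        raise EstimationError("n_points < 32 gives unusable SASA precision")
    radii = np.asarray(solute.radii, dtype=float) + probe
    coords = solute.coords
    n = solute.n_atoms
    unit = _fibonacci_sphere(n_points)
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        d_centers = np.linalg.norm(coords - coords[i], axis=1)
        neighbours = np.flatnonzero((d_centers < radii[i] + radii) & (np.arange(n) != i))
        for j in neighbours:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas, float(areas.sum())


def nonpolar_energy(total_sasa: float, gamma: float = 0.00542, b: float = 0.92) -> float:
    """Nonpolar (hydrophobic) solvation term gamma * SASA + b, kcal/mol."""
    if total_sasa < 0:
        raise EstimationError("SASA must be non-negative")
    return gamma * total_sasa + b


# --------------------------------------------------------------------------
# quasi-harmonic entropy
# --------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning P onto Q (both pre-centred, mass weights)."""
    H = (weights[:, None] * P).T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose_frames(frames: np.ndarray, masses: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Least-squares (mass-weighted) superposition of all frames onto their
    iteratively refined mean structure."""
    out = frames.copy()
    w = masses / masses.sum()
    for _ in range(n_iter):
        mean = out.mean(axis=0)
        mean_c = mean - (w[:, None] * mean).sum(axis=0)
        for f in range(out.shape[0]):
            x = out[f]
            xc = x - (w[:, None] * x).sum(axis=0)
            R = _kabsch(xc, mean_c, w)
            out[f] = xc @ R.T
    return out


def _ho_entropy_per_mode(u: np.ndarray) -> np.ndarray:
    """Quantum harmonic-oscillator entropy per mode, units of R."""
    with np.errstate(over="ignore"):
        return u / np.expm1(u) - np.log1p(-np.exp(-u))


def quasiharmonic_entropy(
    ensemble: SnapshotEnsemble,
    ctx: ThermoContext,
    superpose: bool = True,
    eig_rtol: float = 1e-10,
) -> float:
    """Quasi-harmonic configurational entropy S, kcal/(mol K).

    Mass-weighted coordinate covariance -> eigenvalues lambda_i ->
    quasi-harmonic frequencies omega_i = sqrt(k_B T / lambda_i) -> quantum HO
    entropy summed over modes.  Near-zero eigenvalues (rigid-body modes after
    superposition, or genuinely frozen coordinates) are infinitely stiff and
    contribute zero entropy; their count is not an error (identical frames
    give S = 0).

    Superposition is skipped for fewer than 3 atoms: translating a 1-particle
    ensemble onto its mean would erase the very fluctuations being measured.
    """
    frames = ensemble.frames
    n_atoms = ensemble.solute.n_atoms
    if frames.shape[0] < 3 * n_atoms + 1:
        raise EstimationError(
            f"need >= 3N+1 = {3 * n_atoms + 1} frames for QHA, got {frames.shape[0]}")
    masses = np.asarray(ensemble.solute.masses, dtype=float)
    if superpose and n_atoms >= 3:
        frames = superpose_frames(frames, masses)
    X = frames.reshape(frames.shape[0], -1)          # (F, 3N)
    X = X - X.mean(axis=0)
    sqrt_m = np.sqrt(np.repeat(masses, 3))
    Xw = X * sqrt_m[None, :]
    cov = Xw.T @ Xw / (X.shape[0] - 1)               # amu Å^2
    lam = np.linalg.eigvalsh(cov)
    lam_max = lam.max() if lam.size else 0.0
    keep = lam > max(eig_rtol * max(lam_max, 1.0), 0.0)
    if not keep.any():
        return 0.0
    lam_si = lam[keep] * _AMU_KG * _A2_M2            # kg m^2
    kT_si = _KB_J_PER_K * ctx.temperature
    omega = np.sqrt(kT_si / lam_si)                  # 1/s
    u = _HBAR_J_S * omega / kT_si
    s_modes = _ho_entropy_per_mode(u)
    return float(ctx.gas_constant * s_modes.sum())


def minus_T_delta_S(
    complex_ens: SnapshotEnsemble,
    protein_ens: SnapshotEnsemble,
    ligand_ens: SnapshotEnsemble,
    ctx: ThermoContext,
    superpose: bool = True,
) -> float:
    """Entropic penalty -T (S_complex - S_protein - S_ligand), kcal/mol."""
    s_c = quasiharmonic_entropy(complex_ens, ctx, superpose=superpose)
    s_p = quasiharmonic_entropy(protein_ens, ctx, superpose=superpose)
    s_l = quasiharmonic_entropy(ligand_ens, ctx, superpose=superpose)
    return -ctx.temperature * (s_c - s_p - s_l)


# --------------------------------------------------------------------------
# the averaged decomposition
# --------------------------------------------------------------------------

@dataclass
class EnergyDecomposition:
    """Frame-averaged MM/PB(GB)SA decomposition, kcal/mol.

    The bookkeeping identity total = dE_MM + dG_Polar + dG_NonPolar +
    minus_TdS holds exactly by construction; in the single-trajectory
    protocol dH = dE_MM (bonded terms cancel).
    """

    dE_elec: float
    dE_vdw: float
    dG_polar: float
    dG_nonpolar: float
    minus_TdS: float
    per_frame: dict = field(default_factory=dict)
    solvent_model: str = "PB"
    n_frames: int = 0

    @property
    def dE_MM(self) -> float:
        return self.dE_elec + self.dE_vdw

    @property
    def dG_solvation(self) -> float:
        return self.dG_polar + self.dG_nonpolar

    @property
    def dH(self) -> float:
        return self.dE_MM

    @property
    def total(self) -> float:
        return self.dE_MM + self.dG_polar + self.dG_nonpolar + self.minus_TdS


def mmpbsa_decompose(
    ensemble: SnapshotEnsemble,
    protein_mask: np.ndarray,
    ligand_mask: np.ndarray,
    ctx: ThermoContext,
    solvent: str = "PB",
    entropy: bool = True,
    gamma: float = 0.00542,
    b: float = 0.92,
    eps_in: float = 1.0,
    eps_out: float = 80.0,
    ionic_strength: float = 0.15,
    pb_h: float = 0.6,
    pb_padding: float = 8.0,
    sasa_points: int = 240,
    superpose: bool = True,
    max_failed_fraction: float = 0.05,
) -> EnergyDecomposition:
    """Single-trajectory MM/PB(GB)SA decomposition averaged over an ensemble.

    Protein and ligand species are sub-selections of the complex frames, so
    solvation differences are (complex - protein - ligand) per frame.  The
    entropy term is added once from the quasi-harmonic estimator when
    ``entropy`` is on; toggling it changes the total by exactly minus_TdS.
    """
    if solvent not in ("PB", "GB"):
        raise EstimationError("solvent model must be PB or GB")
    pm = np.asarray(protein_mask)
    lm = np.asarray(ligand_mask)
    elec_s, vdw_s, pol_s, np_s = [], [], [], []
    errors: list[tuple[int, str]] = []
    for i in range(ensemble.n_frames):
        frame = ensemble.frame(i)
        try:
            e, v = mm_interaction_energy(frame, pm, lm, ctx)
            prot = frame.subset(pm)
            lig = frame.subset(lm)
            if solvent == "PB":
                pol = (pb_polar_energy(frame, h=pb_h, padding=pb_padding,
                                       eps_in=eps_in, eps_out=eps_out,
                                       ionic_strength=ionic_strength, ctx=ctx)
                       - pb_polar_energy(prot, h=pb_h, padding=pb_padding,
                                         eps_in=eps_in, eps_out=eps_out,
                                         ionic_strength=ionic_strength, ctx=ctx)
                       - pb_polar_energy(lig, h=pb_h, padding=pb_padding,
                                         eps_in=eps_in, eps_out=eps_out,
                                         ionic_strength=ionic_strength, ctx=ctx))
            else:
                pol = (gb_polar_energy(frame, eps_in, eps_out, ctx)
                       - gb_polar_energy(prot, eps_in, eps_out, ctx)
                       - gb_polar_energy(lig, eps_in, eps_out, ctx))
            _, sasa_c = sasa(frame, n_points=sasa_points)
            _, sasa_p = sasa(prot, n_points=sasa_points)
            _, sasa_l = sasa(lig, n_points=sasa_points)
            npol = (nonpolar_energy(sasa_c, gamma, b)
                    - nonpolar_energy(sasa_p, gamma, b)
                    - nonpolar_energy(sasa_l, gamma, b))
        except (GeometryError, EstimationError, ConvergenceError) as exc:
            errors.append((i, str(exc)))
            continue
        elec_s.append(e)
        vdw_s.append(v)
        pol_s.append(pol)
        np_s.append(npol)
    n_ok = len(elec_s)
    if n_ok == 0 or len(errors) > max_failed_fraction * ensemble.n_frames:
        raise EstimationError(
            f"{len(errors)}/{ensemble.n_frames} frames failed: {errors[:3]}")
    mtds = 0.0
    if entropy:
        mtds = minus_T_delta_S(
            ensemble,
            ensemble.subset(pm, origin="protein"),
            ensemble.subset(lm, origin="ligand"),
            ctx, superpose=superpose,
        )
    return EnergyDecomposition(
        dE_elec=float(np.mean(elec_s)),
        dE_vdw=float(np.mean(vdw_s)),
        dG_polar=float(np.mean(pol_s)),
        dG_nonpolar=float(np.mean(np_s)),
        minus_TdS=mtds,
        per_frame={"elec": np.asarray(elec_s), "vdw": np.asarray(vdw_s),
                   "polar": np.asarray(pol_s), "nonpolar": np.asarray(np_s),
                   "errors": errors},
        solvent_model=solvent,
        n_frames=n_ok,
    )
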