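"""Synthetic-data generators with analytic ground truth.

Each generator emulates the statistical structure of one stage's input —
Boltzmann samples in biased umbrella windows over a known 1D potential,
harmonic-oscillator λ ladders with closed-form free energies, Gaussian work
distributions, toy charged complexes with positional noise, and noisy IC50
tables consistent with a known selectivity vector — so the full pipeline can
be exercised and validated without any molecular-dynamics data.  Every
generator takes an explicit seed, is bit-reproducible, and stamps its seed
and parameters into the bundled :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .alchemical import ReducedPotentialMatrix
from .core import CoverageError, EstimationError, GeometryError, SnapshotEnsemble, ThermoContext, ToySolute
from .selectivity import AffinityRecord, IC50Record, dG_to_ic50
from .umbrella import UmbrellaWindow


@dataclass
class GroundTruth:
    """Analytic truth bundled with a generated dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    payload: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# 1D potentials for umbrella sampling
# --------------------------------------------------------------------------

def harmonic_potential(kappa: float, center: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    return lambda z: 0.5 * kappa * (np.asarray(z, dtype=float) - center) ** 2


def double_well_potential(height: float, tilt: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    """U(z) = h (z^2 - 1)^2 + tilt * z — two basins at z = ±1 separated by a
    barrier of ~h; a nonzero tilt makes the basins inequivalent."""
    def u(z):
        z = np.asarray(z, dtype=float)
        return height * (z * z - 1.0) ** 2 + tilt * z
    return u


def square_well_potential(depth: float, half_width: float,
                          wall: float = 50.0) -> Callable[[np.ndarray], np.ndarray]:
    def u(z):
        z = np.asarray(z, dtype=float)
        return np.where(np.abs(z) <= half_width, -depth, 0.0) + wall * np.clip(np.abs(z) - 3 * half_width, 0, None) ** 2
    return u


def tabulated_potential(z_tab: np.ndarray, u_tab: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    z_tab = np.asarray(z_tab, dtype=float)
    u_tab = np.asarray(u_tab, dtype=float)
    return lambda z: np.interp(np.asarray(z, dtype=float), z_tab, u_tab)


def _inverse_cdf_sample(log_density: np.ndarray, grid: np.ndarray,
                        n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. samples from an unnormalised log density tabulated on a
    dense grid by inverting the trapezoid-rule CDF."""
    log_density = log_density - log_density.max()
    p = np.exp(log_density)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(grid))])
    if cdf[-1] <= 0:
        raise EstimationError("degenerate density: zero total mass")
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, grid)


def sample_umbrella_windows(
    potential: Callable[[np.ndarray], np.ndarray],
    centers: np.ndarray,
    k: float | np.ndarray,
    n_per_window: int,
    ctx: ThermoContext,
    seed: int,
    grid_span: tuple[float, float] | None = None,
    n_grid: int = 10000,
) -> tuple[list[UmbrellaWindow], GroundTruth]:
    """I.i.d. Boltzmann samples from each biased window density
    p_i(z) ∝ exp(-beta [U(z) + 0.5 k_i (z - z_i)^2]), by inverse-CDF on a
    dense grid.  Ground truth carries U(z) tabulated up to a constant.

    Raises :class:`CoverageError` when a window's density does not decay on
    the grid (bias too weak to confine the samples).
    """
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    ks = np.broadcast_to(np.asarray(k, dtype=float), centers.shape)
    if np.any(ks <= 0):
        raise EstimationError("window force constants must be positive")
    beta = ctx.beta
    if grid_span is None:
        spread = 6.0 * np.sqrt(1.0 / (beta * ks.min()))
        grid_span = (centers.min() - spread, centers.max() + spread)
    grid = np.linspace(grid_span[0], grid_span[1], n_grid)
    u_grid = potential(grid)
    rng = np.random.default_rng(seed)
    windows = []
    for z0, ki in zip(centers, ks):
        log_p = -beta * (u_grid + 0.5 * ki * (grid - z0) ** 2)
        edge = max(log_p[0], log_p[-1]) - log_p.max()
        if edge > -5.0:
            raise CoverageError(
                f"window at z={z0}: biased density not confined on the grid "
                f"(edge log-density {edge:.2f})")
        samples = _inverse_cdf_sample(log_p, grid, n_per_window, rng)
        windows.append(UmbrellaWindow(center=float(z0), k=float(ki), samples=samples))
    truth = GroundTruth(
        generator="sample_umbrella_windows", seed=seed,
        params={"centers": centers.tolist(), "k": ks.tolist(),
                "n_per_window": n_per_window, "temperature": ctx.temperature},
        payload={"grid": grid, "potential": u_grid - u_grid.min()},
    )
    return windows, truth


# --------------------------------------------------------------------------
# alchemical ladders and work distributions
# --------------------------------------------------------------------------

def harmonic_ladder_ensemble(
    spring_constants: np.ndarray,
    n_per_state: int,
    seed: int,
    ctx: ThermoContext | None = None,
) -> tuple[ReducedPotentialMatrix, GroundTruth]:
    """Reduced-potential matrix for a ladder of 1D harmonic oscillators.

    State k has reduced potential u_k(x) = 0.5 K_k x^2 (K in units of
    kT/Å^2); exact dimensionless free energies are
    f_k = 0.5 ln(K_k / 2π) up to the gauge constant.
    """
    K = np.asarray(spring_constants, dtype=float)
    if np.any(K <= 0):
        raise EstimationError("spring constants must be positive")
    rng = np.random.default_rng(seed)
    xs = [rng.normal(0.0, 1.0 / np.sqrt(k), size=n_per_state) for k in K]
    x = np.concatenate(xs)
    u = 0.5 * K[:, None] * x[None, :] ** 2
    matrix = ReducedPotentialMatrix(u=u, counts=np.full(len(K), n_per_state))
    f_exact = 0.5 * np.log(K / (2.0 * np.pi))
    truth = GroundTruth(
        generator="harmonic_ladder_ensemble", seed=seed,
        params={"K": K.tolist(), "n_per_state": n_per_state},
        payload={"f": f_exact - f_exact[0]},
    )
    return matrix, truth


def gaussian_work_samples(m: float, s: float, n: int, seed: int
                          ) -> tuple[np.ndarray, GroundTruth]:
    """I.i.d. Normal(m, s^2) dimensionless work samples; for a Gaussian work
    distribution the exponential average has the closed form
    beta*dG = m - s^2/2."""
    if s < 0:
        raise EstimationError("s must be >= 0")
    if n < 1:
        raise EstimationError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    w = rng.normal(m, s, size=n)
    truth = GroundTruth(generator="gaussian_work_samples", seed=seed,
                        params={"m": m, "s": s, "n": n},
                        payload={"beta_dG": m - 0.5 * s * s})
    return w, truth


# --------------------------------------------------------------------------
# toy complexes and snapshot ensembles
# --------------------------------------------------------------------------

_SIDECHAIN_GEOM = {
    # offsets of side-chain heavy atoms from CA, crude but deterministic
    "ALA": [("CB", "C", 1.5)],
    "SER": [("CB", "C", 1.5), ("OG", "O", 2.4)],
    "GLY": [],
}


def build_toy_complex(
    n_residues: int = 8,
    n_ligand_atoms: int = 5,
    shell_radius: float = 8.0,
    ligand_charge: float = 0.0,
    protein_charge: float = 0.0,
    seed: int = 0,
    scripted_contact_distance: float | None = None,
    min_separation: float = 1.5,
) -> tuple[ToySolute, GroundTruth]:
    """Deterministic toy binding pocket: a shell of pseudo-residues (chain A)
    around a compact ligand cluster (chain L), with per-atom charges, radii,
    LJ parameters and masses assigned.

    ``scripted_contact_distance``, when given, places every residue's single
    side-chain atom exactly that far from the nearest ligand atom (drives
    exact contact-frequency tests).  Total charges are distributed uniformly
    over each species' atoms.  Raises :class:`GeometryError` if the layout
    produces overlapping atoms (choose a different seed or geometry).
    """
    if n_residues * 5 + n_ligand_atoms > 500:
        raise EstimationError("toy complex limited to 500 atoms")
    rng = np.random.default_rng(seed)
    records = []

    def add(element, res_name, res_id, chain, name, role, xyz, q, r, m, eps, sig):
        records.append((element, res_name, res_id, chain, name, role,
                        xyz, q, r, m, eps, sig))

    # ligand: one atom at the origin, the rest quasi-uniform on a 2.2 Å shell
    lig_q = ligand_charge / n_ligand_atoms
    golden_lig = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n_ligand_atoms):
        if i == 0:
            xyz = np.zeros(3)
        else:
            zf = 1.0 - 2.0 * (i - 0.5) / max(n_ligand_atoms - 1, 1)
            rad = np.sqrt(max(1.0 - zf * zf, 0.0))
            th = golden_lig * i
            xyz = 2.2 * np.array([np.cos(th) * rad, np.sin(th) * rad, zf])
        xyz = xyz + rng.normal(0.0, 0.03, size=3)
        add("C", "LIG", 1, "L", f"C{i+1}", "ligand", xyz, lig_q, 1.7, 12.011, 0.086, 3.4)

    # protein: pseudo-residues (N, CA, C, O backbone + CB side chain) on a shell
    prot_q = protein_charge / n_residues  # put net charge on side-chain atoms
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for ri in range(n_residues):
        zfrac = 1.0 - 2.0 * (ri + 0.5) / n_residues
        rad = np.sqrt(1.0 - zfrac * zfrac)
        theta = golden * ri
        u = np.array([np.cos(theta) * rad, np.sin(theta) * rad, zfrac])
        ca = u * shell_radius
        # local frame for backbone placement
        t = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(t) < 1e-8:
            t = np.array([1.0, 0.0, 0.0])
        t /= np.linalg.norm(t)
        s = np.cross(u, t)
        rid = ri + 1
        add("N", "ALA", rid, "A", "N", "backbone", ca + 1.46 * t, -0.3, 1.55, 14.007, 0.17, 3.25)
        add("C", "ALA", rid, "A", "CA", "backbone", ca, 0.1, 1.7, 12.011, 0.086, 3.4)
        add("C", "ALA", rid, "A", "C", "backbone", ca - 1.52 * t, 0.5, 1.7, 12.011, 0.086, 3.4)
        add("O", "ALA", rid, "A", "O", "backbone", ca - 1.52 * t + 1.23 * s, -0.5, 1.52, 15.999, 0.21, 2.96)
        if scripted_contact_distance is not None:
            # place CB exactly d away from the nearest ligand atom, inward
            lig_xyz = np.array([rec[6] for rec in records if rec[5] == "ligand"])
            nearest = lig_xyz[np.argmin(np.linalg.norm(lig_xyz - ca, axis=1))]
            direction = (ca - nearest) / np.linalg.norm(ca - nearest)
            cb = nearest + direction * scripted_contact_distance
        else:
            cb = ca - u * 1.5
        add("C", "ALA", rid, "A", "CB", "sidechain", cb, prot_q, 1.7, 12.011, 0.086, 3.4)

    coords = np.array([r[6] for r in records], dtype=float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    # bonded (same-residue) atoms sit closer than any nonbonded clash cutoff;
    # only inter-residue pairs are checked for overlap
    res_key = np.array([f"{r[3]}:{r[2]}" for r in records])
    same_res = res_key[:, None] == res_key[None, :]
    d[same_res] = np.inf
    if d.min() < min_separation:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise GeometryError(
            f"toy complex atoms {i} and {j} overlap ({d.min():.2f} Å); "
            "reseed or change the geometry spec")
    solute = ToySolute(
        elements=np.array([r[0] for r in records]),
        res_names=np.array([r[1] for r in records]),
        res_ids=np.array([r[2] for r in records]),
        chain_ids=np.array([r[3] for r in records]),
        atom_names=np.array([r[4] for r in records]),
        roles=np.array([r[5] for r in records]),
        coords=coords,
        charges=np.array([r[7] for r in records], dtype=float),
        radii=np.array([r[8] for r in records], dtype=float),
        masses=np.array([r[9] for r in records], dtype=float),
        lj_epsilons=np.array([r[10] for r in records], dtype=float),
        lj_sigmas=np.array([r[11] for r in records], dtype=float),
    )
    truth = GroundTruth(
        generator="build_toy_complex", seed=seed,
        params={"n_residues": n_residues, "n_ligand_atoms": n_ligand_atoms,
                "shell_radius": shell_radius,
                "scripted_contact_distance": scripted_contact_distance},
        payload={"contact_residues": list(range(1, n_residues + 1))
                 if scripted_contact_distance is not None else []},
    )
    return solute, truth


def perturb_ensemble(
    solute: ToySolute,
    noise_sd: float,
    n_frames: int,
    seed: int,
    origin: str = "complex",
) -> tuple[SnapshotEnsemble, GroundTruth]:
    """Frames = base coordinates + isotropic Gaussian positional noise.

    Ground-truth coordinate covariance is noise_sd^2 * I per atom, which is
    the analytic reference for the quasi-harmonic entropy tests.
    """
    if noise_sd < 0:
        raise EstimationError("noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    frames = solute.coords[None, :, :] + rng.normal(
        0.0, noise_sd, size=(n_frames, solute.n_atoms, 3))
    ens = SnapshotEnsemble(solute=solute, frames=frames, origin=origin)
    truth = GroundTruth(generator="perturb_ensemble", seed=seed,
                        params={"noise_sd": noise_sd, "n_frames": n_frames},
                        payload={"covariance_diag": noise_sd ** 2})
    return ens, truth


# --------------------------------------------------------------------------
# synthetic selectivity studies
# --------------------------------------------------------------------------

def synthetic_affinity_study(
    true_ddG: np.ndarray,
    method_noise: dict[str, float],
    ic50_target1: np.ndarray | None = None,
    dG_target1: float = -12.0,
    targets: tuple[str, str] = ("PARP1", "PARP2"),
    ctx: ThermoContext | None = None,
    seed: int = 0,
    ic50_sigma_fraction: float = 0.2,
) -> tuple[list[IC50Record], list[AffinityRecord], GroundTruth]:
    """A full ligand panel with known selectivity and controlled method noise.

    Experimental IC50 pairs are constructed to be exactly consistent with the
    true ddG vector through the RT ln(IC50) conversion; each computational
    method's per-target dG is the truth plus Normal(0, SD_method) noise.
    Feeds :func:`bindfe.selectivity.method_comparison_table` end to end.
    """
    ctx = ctx or ThermoContext()
    true_ddG = np.asarray(true_ddG, dtype=float)
    n = len(true_ddG)
    ligands = [f"lig{i+1}" for i in range(n)]
    rng = np.random.default_rng(seed)
    t1, t2 = targets
    if ic50_target1 is None:
        ic50_target1 = np.full(n, dG_to_ic50(dG_target1, ctx))
    ic50_target1 = np.asarray(ic50_target1, dtype=float)
    dg1 = ctx.kT * np.log(ic50_target1)
    dg2 = dg1 - true_ddG                       # ddG = dG1 - dG2
    ic50_target2 = np.exp(dg2 / ctx.kT)
    ic50s, affinities = [], []
    for i, lig in enumerate(ligands):
        for tgt, ic in ((t1, ic50_target1[i]), (t2, ic50_target2[i])):
            ic50s.append(IC50Record(ligand=lig, target=tgt, ic50=float(ic),
                                    sigma=float(ic50_sigma_fraction * ic),
                                    provenance="synthetic"))
        for method, sd in method_noise.items():
            g1 = dg1[i] + rng.normal(0.0, sd)
            g2 = dg2[i] + rng.normal(0.0, sd)
            affinities.append(AffinityRecord(ligand=lig, target=t1, dG=float(g1),
                                             sigma=sd, method=method))
            affinities.append(AffinityRecord(ligand=lig, target=t2, dG=float(g2),
                                             sigma=sd, method=method))
    truth = GroundTruth(
        generator="synthetic_affinity_study", seed=seed,
        params={"method_noise": dict(method_noise), "targets": list(targets),
                "ic50_sigma_fraction": ic50_sigma_fraction},
        payload={"ligands": ligands, "true_ddG": true_ddG,
                 "dG_target1": dg1, "dG_target2": dg2},
    )
    return ic50s, affinities, truth
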