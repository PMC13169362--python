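"""Shared physical constants, thermodynamic context and the structural data model.

Unit conventions are fixed package-wide: lengths in Å, energies in kcal/mol,
charges in elementary charges, masses in amu, temperatures in kelvin.
Reaction coordinates read from GROMACS-style files are converted from nm to Å
at the I/O boundary so that every estimator sees a single unit system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Molar gas constant R in kcal/(mol K).
GAS_CONSTANT = 1.9872036e-3
#: Volume per molecule at the 1 M standard state, Å^3.
STANDARD_VOLUME = 1660.5392
#: Coulomb constant in kcal Å / (mol e^2).
COULOMB_CONSTANT = 332.0637

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class BindFEError(Exception):
    """Base class for package errors."""


class InvalidContextError(BindFEError, ValueError):
    """Thermodynamic context violates its invariants."""


class SelectionError(BindFEError, ValueError):
    """An atom/residue selection is empty or inconsistent."""


class EstimationError(BindFEError, ValueError):
    """A free-energy estimator received unusable input."""


class ConvergenceError(BindFEError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CoverageError(BindFEError, ValueError):
    """Histogram/window coverage of the reaction coordinate is insufficient."""


class GeometryError(BindFEError, ValueError):
    """Atomic geometry is unphysical (overlapping atoms, non-finite coordinates)."""


class PairingError(BindFEError, ValueError):
    """Records that must refer to the same ligand/method/target do not."""


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and the fixed physical constants every estimator shares.

    ``thermal_energy`` (k_B T, here R T in molar units) and ``beta`` satisfy
    beta * thermal_energy == 1 exactly.
    """

    temperature: float = 300.0
    gas_constant: float = GAS_CONSTANT
    standard_volume: float = STANDARD_VOLUME
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if not np.isfinite(self.temperature) or self.temperature <= 0:
            raise InvalidContextError(
                f"temperature must be positive and finite, got {self.temperature}"
            )

    @property
    def kT(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return self.gas_constant * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(R*T) in mol/kcal."""
        return 1.0 / self.kT


def thermal_energy(ctx: ThermoContext) -> float:
    """Thermal energy k_B T (= R T in molar units), kcal/mol."""
    return ctx.kT


def reduced_potential(u: float | np.ndarray, ctx: ThermoContext) -> float | np.ndarray:
    """Convert an energy in kcal/mol to dimensionless (units of k_B T).

    Raises
    ------
    EstimationError
        If any input energy is non-finite.
    """
    arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise EstimationError("reduced_potential requires finite energies")
    out = arr * ctx.beta
    return float(out) if np.isscalar(u) or out.ndim == 0 else out


@dataclass
class ToySolute:
    """Struct-of-arrays atom model for desk-scale solutes.

    Roles distinguish backbone, side-chain and ligand atoms; per-atom
    nonbonded parameters (charge q in e, radius in Å, LJ epsilon in kcal/mol,
    LJ sigma in Å, mass in amu) travel with the topology.
    """

    elements: np.ndarray          # (N,) str
    res_names: np.ndarray         # (N,) str
    res_ids: np.ndarray           # (N,) int
    chain_ids: np.ndarray         # (N,) str
    atom_names: np.ndarray        # (N,) str
    roles: np.ndarray             # (N,) str in {backbone, sidechain, ligand}
    coords: np.ndarray            # (N, 3) float, Å
    charges: np.ndarray           # (N,) float, e
    radii: np.ndarray             # (N,) float, Å
    masses: np.ndarray            # (N,) float, amu
    lj_epsilons: np.ndarray       # (N,) float, kcal/mol
    lj_sigmas: np.ndarray         # (N,) float, Å

    def __post_init__(self) -> None:
        n = len(self.elements)
        for name in ("res_names", "res_ids", "chain_ids", "atom_names", "roles",
                     "charges", "radii", "masses", "lj_epsilons", "lj_sigmas"):
            if len(getattr(self, name)) != n:
                raise SelectionError(f"field {name} length mismatch with elements")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise SelectionError(f"coords must be ({n}, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")
        if np.any(np.asarray(self.radii, dtype=float) <= 0):
            raise GeometryError("all atomic radii must be positive")
        if np.any(np.asarray(self.masses, dtype=float) <= 0):
            raise GeometryError("all atomic masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e.upper() != "H" for e in self.elements])

    def mask(self, *, chain: str | None = None, role: str | None = None,
             heavy_only: bool = False) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            m &= np.asarray(self.chain_ids) == chain
        if role is not None:
            m &= np.asarray(self.roles) == role
        if heavy_only:
            m &= self.heavy_mask
        return m

    def subset(self, mask: np.ndarray) -> "ToySolute":
        mask = np.asarray(mask)
        if mask.dtype == bool and not mask.any():
            raise SelectionError("empty atom selection")
        return ToySolute(
            elements=np.asarray(self.elements)[mask],
            res_names=np.asarray(self.res_names)[mask],
            res_ids=np.asarray(self.res_ids)[mask],
            chain_ids=np.asarray(self.chain_ids)[mask],
            atom_names=np.asarray(self.atom_names)[mask],
            roles=np.asarray(self.roles)[mask],
            coords=self.coords[mask],
            charges=np.asarray(self.charges, dtype=float)[mask],
            radii=np.asarray(self.radii, dtype=float)[mask],
            masses=np.asarray(self.masses, dtype=float)[mask],
            lj_epsilons=np.asarray(self.lj_epsilons, dtype=float)[mask],
            lj_sigmas=np.asarray(self.lj_sigmas, dtype=float)[mask],
        )

    def with_coords(self, coords: np.ndarray) -> "ToySolute":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class SnapshotEnsemble:
    """An ordered series of frames sharing one :class:`ToySolute` topology."""

    solute: ToySolute
    frames: np.ndarray            # (F, N, 3) float, Å
    stride: int = 1
    origin: str = "complex"       # complex | protein | ligand

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise SelectionError("ensemble needs >= 1 frame of shape (N, 3)")
        if self.frames.shape[1:] != (self.solute.n_atoms, 3):
            raise SelectionError(
                f"frame shape {self.frames.shape[1:]} does not match topology "
                f"({self.solute.n_atoms}, 3)"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> ToySolute:
        return self.solute.with_coords(self.frames[i])

    def subset(self, mask: np.ndarray, origin: str | None = None) -> "SnapshotEnsemble":
        return SnapshotEnsemble(
            solute=self.solute.subset(mask),
            frames=self.frames[:, np.asarray(mask), :],
            stride=self.stride,
            origin=origin or self.origin,
        )


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of a set of atoms, Å.

    Raises
    ------
    SelectionError
        On an empty selection.
    GeometryError
        If any mass is non-positive.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    if coords.shape[0] == 0:
        raise SelectionError("center_of_mass of an empty atom set")
    if np.any(masses <= 0):
        raise GeometryError("masses must be positive")
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()
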