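"""Residue-level contact analysis over snapshot ensembles.

A residue contacts the ligand in a frame when the minimum distance from any
ligand heavy atom to the residue's side-chain centre of mass is within the
cutoff.  Contact maps from two paralogues are compared through a supplied
residue correspondence and partitioned into shared and exclusive contacts;
a per-residue Coulomb + Lennard-Jones decomposition identifies the residues
that stabilise the ligand most strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BACKBONE_ATOMS,
    SelectionError,
    SnapshotEnsemble,
    ThermoContext,
    ToySolute,
    center_of_mass,
)


@dataclass
class ContactMap:
    """Per-residue contact frequency over a frame series."""

    frequencies: dict[int, float]       # residue id -> fraction of frames
    cutoff: float
    n_frames: int
    ligand_atoms: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SelectionError("contact map needs >= 1 frame")
        for res, f in self.frequencies.items():
            if not (0.0 <= f <= 1.0):
                raise SelectionError(f"frequency for residue {res} out of [0,1]: {f}")


@dataclass
class ParalogueMapping:
    """One-to-one correspondence between residues of two paralogues."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise SelectionError("paralogue mapping must be one-to-one")

    @property
    def a_to_b(self) -> dict[int, int]:
        return dict(self.pairs)


@dataclass
class ContactClassification:
    """Disjoint partition of contacting residue pairs across two paralogues."""

    shared: set[tuple[int, int]]
    exclusive_a: set[int]
    exclusive_b: set[int]
    unmapped_a: set[int] = field(default_factory=set)
    unmapped_b: set[int] = field(default_factory=set)
    threshold: float = 0.5


def sidechain_com(solute: ToySolute, res_id: int, chain: str | None = None) -> np.ndarray:
    """Mass-weighted centre of the residue's heavy side-chain atoms.

    Backbone atoms are N, CA, C, O; glycine (no side-chain heavy atom) falls
    back to its CA position.
    """
    mask = np.asarray(solute.res_ids) == res_id
    if chain is not None:
        mask &= np.asarray(solute.chain_ids) == chain
    if not mask.any():
        raise SelectionError(f"residue {res_id} not present")
    names = np.asarray(solute.atom_names)[mask]
    heavy = solute.heavy_mask[mask]
    side = np.asarray([n not in BACKBONE_ATOMS for n in names]) & heavy
    coords = solute.coords[mask]
    masses = np.asarray(solute.masses, dtype=float)[mask]
    if side.any():
        return center_of_mass(coords[side], masses[side])
    ca = names == "CA"
    if ca.any():
        return coords[ca][0].copy()
    raise SelectionError(
        f"residue {res_id} has no heavy side-chain atoms and no CA fallback")


def contact_frequencies(
    ensemble: SnapshotEnsemble,
    ligand_mask: np.ndarray,
    residues: list[int] | None = None,
    cutoff: float = 5.0,
    stride: int = 1,
) -> ContactMap:
    """Contact frequency per residue: fraction of (strided) frames where the
    minimum ligand-heavy-atom to side-chain-COM distance is <= cutoff."""
    lm = np.asarray(ligand_mask) & ensemble.solute.heavy_mask
    if not lm.any():
        raise SelectionError("ligand heavy-atom selection is empty")
    solute = ensemble.solute
    if residues is None:
        not_lig = ~np.asarray(ligand_mask)
        residues = sorted(set(np.asarray(solute.res_ids)[not_lig].tolist()))
    frame_ids = range(0, ensemble.n_frames, stride)
    counts = {r: 0 for r in residues}
    n_used = 0
    for fi in frame_ids:
        frame = solute.with_coords(ensemble.frames[fi])
        lig_xyz = frame.coords[lm]
        n_used += 1
        for r in residues:
            com = sidechain_com(frame, r)
            dmin = float(np.min(np.linalg.norm(lig_xyz - com[None, :], axis=1)))
            if dmin <= cutoff:
                counts[r] += 1
    freqs = {r: counts[r] / n_used for r in residues}
    return ContactMap(frequencies=freqs, cutoff=cutoff, n_frames=n_used,
                      ligand_atoms=int(lm.sum()))


def classify_contacts(
    map_a: ContactMap,
    map_b: ContactMap,
    mapping: ParalogueMapping,
    threshold: float = 0.5,
) -> ContactClassification:
    """Partition mapped residue pairs into shared / exclusive-to-A /
    exclusive-to-B by thresholding both paralogues' contact frequencies.

    Contacting residues absent from the mapping are reported separately,
    never silently dropped.
    """
    if map_a.cutoff != map_b.cutoff:
        raise SelectionError("contact maps were computed at different cutoffs")
    fa, fb = map_a.frequencies, map_b.frequencies
    for a, b in mapping.pairs:
        if a not in fa:
            raise SelectionError(f"mapping references residue {a} absent from map A")
        if b not in fb:
            raise SelectionError(f"mapping references residue {b} absent from map B")
    shared, excl_a, excl_b = set(), set(), set()
    for a, b in mapping.pairs:
        ca = fa[a] >= threshold
        cb = fb[b] >= threshold
        if ca and cb:
            shared.add((a, b))
        elif ca:
            excl_a.add(a)
        elif cb:
            excl_b.add(b)
    mapped_a = {a for a, _ in mapping.pairs}
    mapped_b = {b for _, b in mapping.pairs}
    unmapped_a = {r for r, f in fa.items() if f >= threshold and r not in mapped_a}
    unmapped_b = {r for r, f in fb.items() if f >= threshold and r not in mapped_b}
    return ContactClassification(shared=shared, exclusive_a=excl_a,
                                 exclusive_b=excl_b, unmapped_a=unmapped_a,
                                 unmapped_b=unmapped_b, threshold=threshold)


def per_residue_interaction_energy(
    ensemble: SnapshotEnsemble,
    ligand_mask: np.ndarray,
    ctx: ThermoContext,
    residues: list[int] | None = None,
) -> pd.DataFrame:
    """Frame-averaged ligand-residue Coulomb and LJ energies per residue.

    The per-residue terms sum exactly to the total protein-ligand interaction
    energy of the same frames (partition identity).  Sorted most-stabilising
    (lowest total) first.
    """
    lm = np.asarray(ligand_mask)
    if not lm.any():
        raise SelectionError("ligand selection is empty")
    solute = ensemble.solute
    res_ids = np.asarray(solute.res_ids)
    if residues is None:
        residues = sorted(set(res_ids[~lm].tolist()))
    q = np.asarray(solute.charges, dtype=float)
    sig = np.asarray(solute.lj_sigmas, dtype=float)
    eps = np.asarray(solute.lj_epsilons, dtype=float)
    acc = {r: np.zeros(2) for r in residues}
    for fi in range(ensemble.n_frames):
        xyz = ensemble.frames[fi]
        lig_xyz = xyz[lm]
        for r in residues:
            rm = (res_ids == r) & ~lm
            if not rm.any():
                continue
            d = np.linalg.norm(xyz[rm][:, None, :] - lig_xyz[None, :, :], axis=2)
            elec = ctx.coulomb_constant * float(
                (q[rm][:, None] * q[lm][None, :] / d).sum())
            s_ij = 0.5 * (sig[rm][:, None] + sig[lm][None, :])
            e_ij = np.sqrt(eps[rm][:, None] * eps[lm][None, :])
            sr6 = (s_ij / d) ** 6
            vdw = float((4.0 * e_ij * (sr6 ** 2 - sr6)).sum())
            acc[r] += (elec, vdw)
    rows = [{"res_id": r, "elec": v[0] / ensemble.n_frames,
             "vdw": v[1] / ensemble.n_frames,
             "total": (v[0] + v[1]) / ensemble.n_frames}
            for r, v in acc.items()]
    return pd.DataFrame(rows).sort_values("total").reset_index(drop=True)
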