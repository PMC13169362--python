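"""Readers and writers for the formats the pipeline touches.

Multi-model PDB files (biotite-backed), GROMACS XVG time series (``#``/``@``
comment dialect, nm converted to Å at read time), sidecar TSV tables with
per-atom nonbonded parameters, and the CSV schemas for IC50 and affinity
records.  Coordinates are Å everywhere past this boundary.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .core import BACKBONE_ATOMS, SelectionError, SnapshotEnsemble, ToySolute
from .selectivity import AffinityRecord, IC50Record
from .umbrella import UmbrellaWindow

NM_TO_ANGSTROM = 10.0

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "X": 12.011,
}


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


def _element_mass(element: str) -> float:
    return _ELEMENT_MASSES.get(element.upper(), 12.011)


def read_pdb(
    path: str | Path,
    params: pd.DataFrame | None = None,
    ligand_chain: str | None = None,
) -> tuple[ToySolute, SnapshotEnsemble]:
    """Read a (multi-model) PDB into a topology plus frame ensemble.

    MODEL/ENDMDL blocks delimit frames; all models must share one topology.
    Roles: atoms on ``ligand_chain`` (or hetero atoms when no chain is given)
    are ``ligand``; N/CA/C/O are ``backbone``; everything else ``sidechain``.
    Nonbonded parameters come from a sidecar table (columns: serial, q, r,
    eps, sigma) when provided; otherwise zero charges and element defaults.
    """
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise ParseError(f"cannot read {path}: {exc}") from None
    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    n = stack.array_length()
    if n == 0:
        raise ParseError(f"{path} contains no atoms")
    elements = np.asarray(stack.element)
    chain_ids = np.asarray(stack.chain_id)
    atom_names = np.asarray(stack.atom_name)
    hetero = np.asarray(stack.hetero)
    if ligand_chain is not None:
        is_lig = chain_ids == ligand_chain
    else:
        is_lig = hetero
    roles = np.where(
        is_lig, "ligand",
        np.where(np.isin(atom_names, sorted(BACKBONE_ATOMS)), "backbone", "sidechain"),
    )
    charges = np.zeros(n)
    radii = np.full(n, 1.7)
    epsilons = np.full(n, 0.1)
    sigmas = np.full(n, 3.4)
    masses = np.array([_element_mass(e) for e in elements])
    if params is not None:
        required = {"serial", "q", "r", "eps", "sigma"}
        missing = required - set(params.columns)
        if missing:
            raise ParseError(f"parameter table missing columns: {sorted(missing)}")
        by_serial = params.set_index("serial")
        serials = np.arange(1, n + 1)
        for i, s in enumerate(serials):
            if s in by_serial.index:
                row = by_serial.loc[s]
                charges[i] = row["q"]
                radii[i] = row["r"]
                epsilons[i] = row["eps"]
                sigmas[i] = row["sigma"]
                if "mass" in params.columns:
                    masses[i] = row["mass"]
    solute = ToySolute(
        elements=elements,
        res_names=np.asarray(stack.res_name),
        res_ids=np.asarray(stack.res_id),
        chain_ids=chain_ids,
        atom_names=atom_names,
        roles=roles,
        coords=np.asarray(stack.coord[0]),
        charges=charges,
        radii=radii,
        masses=masses,
        lj_epsilons=epsilons,
        lj_sigmas=sigmas,
    )
    ensemble = SnapshotEnsemble(solute=solute, frames=np.asarray(stack.coord))
    return solute, ensemble


def write_pdb(ensemble: SnapshotEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame)."""
    if ensemble.n_frames < 1:
        raise SelectionError("cannot write an empty ensemble")
    s = ensemble.solute
    n = s.n_atoms
    arrays = []
    for f in range(ensemble.n_frames):
        arr = bst.AtomArray(n)
        arr.coord = ensemble.frames[f]
        arr.chain_id = np.asarray(s.chain_ids)
        arr.res_id = np.asarray(s.res_ids)
        arr.res_name = np.asarray(s.res_names)
        arr.atom_name = np.asarray(s.atom_names)
        arr.element = np.asarray(s.elements)
        arr.hetero = np.asarray(s.roles) == "ligand"
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(bst.stack(arrays))
    pdb.write(str(path))


def write_params_tsv(solute: ToySolute, path: str | Path) -> None:
    df = pd.DataFrame({
        "serial": np.arange(1, solute.n_atoms + 1),
        "q": solute.charges,
        "r": solute.radii,
        "eps": solute.lj_epsilons,
        "sigma": solute.lj_sigmas,
        "mass": solute.masses,
    })
    df.to_csv(path, sep="\t", index=False)


def read_params_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_xvg(path: str | Path, unit_policy: str = "angstrom") -> np.ndarray:
    """Parse a GROMACS XVG file into a (rows, cols) float array.

    Lines starting with ``#`` or ``@`` are comments/legends.  Under the
    ``angstrom`` policy every column after the first (time, ps, passed
    through) is multiplied by 10 (nm -> Å); ``raw`` leaves values untouched.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "@")):
                continue
            try:
                rows.append([float(tok) for tok in stripped.split()])
            except ValueError:
                raise ParseError(f"non-numeric data row: {stripped!r}", line=ln) from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    if unit_policy == "angstrom" and arr.shape[1] > 1:
        arr[:, 1:] *= NM_TO_ANGSTROM
    elif unit_policy not in ("angstrom", "raw"):
        raise ValueError(f"unknown unit policy {unit_policy!r}")
    return arr


def write_xvg(path: str | Path, data: np.ndarray, comment: str = "") -> None:
    """Write a time series in XVG form (values after column 1 in nm)."""
    data = np.asarray(data, dtype=float)
    out = data.copy()
    if out.ndim != 2:
        raise ValueError("expect a (rows, cols) array")
    out[:, 1:] /= NM_TO_ANGSTROM
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("@    title \"reaction coordinate\"\n")
        np.savetxt(fh, out, fmt="%.8g")


def read_windows(meta_path: str | Path, unit_policy: str = "angstrom"
                 ) -> list[UmbrellaWindow]:
    """Read umbrella windows from a TSV metadata file.

    Columns: ``center`` (Å), ``k`` (kcal/mol/Å^2), ``file`` (XVG pullx path,
    relative to the metadata file), optional ``equilibration_fraction``.
    """
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"center", "k", "file"}
    missing = required - set(meta.columns)
    if missing:
        raise ParseError(f"window table missing columns: {sorted(missing)}")
    windows = []
    for _, row in meta.iterrows():
        series = read_xvg(meta_path.parent / row["file"], unit_policy)
        eq = float(row.get("equilibration_fraction", 0.0) or 0.0)
        windows.append(UmbrellaWindow(center=float(row["center"]), k=float(row["k"]),
                                      samples=series[:, 1],
                                      equilibration_fraction=eq))
    return windows


def read_u_kn(potentials_path: str | Path, counts_path: str | Path
              ) -> tuple[np.ndarray, np.ndarray]:
    """Read a wide reduced-potential table (rows = samples, columns = states)
    and the per-state sample counts."""
    u = pd.read_csv(potentials_path, sep="\t").to_numpy(dtype=float).T
    counts = pd.read_csv(counts_path, sep="\t")["n"].to_numpy(dtype=int)
    return u, counts


def write_u_kn(u: np.ndarray, counts: np.ndarray,
               potentials_path: str | Path, counts_path: str | Path) -> None:
    pd.DataFrame(np.asarray(u).T,
                 columns=[f"state_{k}" for k in range(np.asarray(u).shape[0])]
                 ).to_csv(potentials_path, sep="\t", index=False)
    pd.DataFrame({"n": np.asarray(counts)}).to_csv(counts_path, sep="\t", index=False)


def read_ic50_csv(path: str | Path) -> list[IC50Record]:
    """IC50 table: columns ligand, target, ic50_nM, optional sigma_nM, source."""
    df = pd.read_csv(path)
    required = {"ligand", "target", "ic50_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"IC50 table missing columns: {sorted(missing)}")
    recs = []
    for _, row in df.iterrows():
        sigma = None
        if "sigma_nM" in df.columns and pd.notna(row.get("sigma_nM")):
            sigma = float(row["sigma_nM"]) * 1e-9
        recs.append(IC50Record(
            ligand=str(row["ligand"]), target=str(row["target"]),
            ic50=float(row["ic50_nM"]) * 1e-9, sigma=sigma,
            provenance=str(row.get("source", "")),
        ))
    return recs


def read_affinity_csv(path: str | Path) -> list[AffinityRecord]:
    """Affinity table: columns ligand, target, dG_kcal, sigma, method."""
    df = pd.read_csv(path)
    required = {"ligand", "target", "dG_kcal", "method"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"affinity table missing columns: {sorted(missing)}")
    return [
        AffinityRecord(ligand=str(r["ligand"]), target=str(r["target"]),
                       dG=float(r["dG_kcal"]),
                       sigma=float(r["sigma"]) if "sigma" in df.columns and pd.notna(r.get("sigma")) else 0.0,
                       method=str(r["method"]))
        for _, r in df.iterrows()
    ]


def write_affinity_csv(records: list[AffinityRecord], path: str | Path) -> None:
    pd.DataFrame([
        {"ligand": r.ligand, "target": r.target, "dG_kcal": r.dG,
         "sigma": r.sigma, "method": r.method} for r in records
    ]).to_csv(path, index=False)


def read_mapping_tsv(path: str | Path) -> list[tuple[int, int]]:
    """Paralogue residue correspondence: two integer columns resA, resB."""
    df = pd.read_csv(path, sep="\t")
    if not {"resA", "resB"} <= set(df.columns):
        raise ParseError("mapping table needs columns resA, resB")
    return [(int(a), int(b)) for a, b in zip(df["resA"], df["resB"])]


@dataclass
class RunConfig:
    """Full provenance of one CLI run: every defaulted field serialises out."""

    command: str = ""
    temperature: float = 300.0
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
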