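"""Conformational-ensemble container and trajectory I/O.

An ensemble is an ordered set of frames (snapshots) of a two-chain
coiled-coil, with identical atom ordering in every frame.  Coordinates are
stored in nanometres throughout the package; PDB files (Angstrom) are
converted on read and write.  Two on-disk formats are supported:

* multi-model PDB (``MODEL``/``ENDMDL`` records), read and written through
  :mod:`biotite.structure`;
* a plain tab-separated "xyz table" with one row per atom per frame and
  columns ``frame_index, time_ps, chain_id, residue_index, residue_name,
  atom_name, x_nm, y_nm, z_nm`` — lossless, used mainly by the synthetic
  generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Frame",
    "ConformationEnsemble",
    "SelectionSpec",
    "read_ensemble",
    "write_ensemble",
    "trim_equilibration",
    "superpose",
    "rmsd_timecourse",
]

XYZ_COLUMNS = [
    "frame_index",
    "time_ps",
    "chain_id",
    "residue_index",
    "residue_name",
    "atom_name",
    "x_nm",
    "y_nm",
    "z_nm",
]


@dataclass(frozen=True)
class Frame:
    """A single snapshot: an atom table plus one coordinate set (nm)."""

    atoms: pd.DataFrame
    coords: np.ndarray  # (n_atoms, 3), nm
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError("coords shape does not match atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in frame")


@dataclass
class ConformationEnsemble:
    """Ordered frames of a two-chain system with fixed atom ordering.

    Parameters
    ----------
    atoms
        Atom table with columns ``chain_id, residue_index, residue_name,
        atom_name``; one row per atom, shared by all frames.
    coords
        Array ``(n_frames, n_atoms, 3)`` in nm.
    times
        Frame timestamps in ps, strictly increasing.
    chain_ids
        The two chain labels under analysis.
    temperature
        Simulation temperature in K (used for the stiffness conversion).
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    times: np.ndarray
    chain_ids: tuple[str, str]
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table does not match coordinate array")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length does not match frame count")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if len(self.chain_ids) != 2:
            raise ValueError("exactly two chain ids are required")
        present = set(self.atoms["chain_id"])
        for cid in self.chain_ids:
            if cid not in present:
                raise ValueError(f"chain {cid} not found")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in ensemble")

    # -- basic accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def frame_spacing(self) -> float:
        """Median time step between consecutive frames (ps)."""
        if self.n_frames < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    def frame(self, index: int) -> Frame:
        return Frame(self.atoms, self.coords[index], float(self.times[index]))

    def atom_indices(
        self,
        chain_id: str | None = None,
        residue_range: tuple[int, int] | None = None,
        atom_names: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Integer indices of atoms matching the given filters (file order)."""
        mask = np.ones(len(self.atoms), dtype=bool)
        if chain_id is not None:
            mask &= (self.atoms["chain_id"] == chain_id).to_numpy()
        if residue_range is not None:
            lo, hi = residue_range
            res = self.atoms["residue_index"].to_numpy()
            mask &= (res >= lo) & (res <= hi)
        if atom_names is not None:
            mask &= self.atoms["atom_name"].isin(list(atom_names)).to_numpy()
        return np.flatnonzero(mask)

    def with_coords(self, coords: np.ndarray) -> "ConformationEnsemble":
        return dataclasses.replace(self, coords=coords)


@dataclass(frozen=True)
class SelectionSpec:
    """Atom selection: both chains, an inclusive residue interval, atom names.

    Residue intervals follow author numbering and are inclusive on both
    ends, e.g. ``(106, 216)`` selects residues 106 through 216.
    """

    chain_ids: tuple[str, str]
    residue_range: tuple[int, int]
    atom_names: frozenset[str] = frozenset({"CA"})

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if hi < lo:
            raise ValueError("residue_range is empty")
        if len(self.chain_ids) != 2:
            raise ValueError("SelectionSpec needs exactly two chains")

    def indices(self, ens: ConformationEnsemble) -> np.ndarray:
        idx = [
            ens.atom_indices(cid, self.residue_range, self.atom_names)
            for cid in self.chain_ids
        ]
        for cid, ix in zip(self.chain_ids, idx):
            if len(ix) == 0:
                raise ValueError(
                    f"selection matches no atoms in chain {cid} "
                    f"(residues {self.residue_range[0]}-{self.residue_range[1]})"
                )
        return np.concatenate(idx)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _read_pdb(path: Path, frame_spacing: float) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    try:
        stack = pdb.get_structure(model=None)
        coords = stack.coord * 0.1  # A -> nm
        first = stack[0]
    except Exception:
        # diagnose which models disagree in atom count
        counts = [
            pdb.get_structure(model=m + 1).array_length() for m in range(n_models)
        ]
        ref = counts[0]
        bad = [i for i, c in enumerate(counts) if c != ref]
        raise ValueError(
            f"frames differ in atom count (reference {ref} atoms); "
            f"offending frame indices: {bad}"
        ) from None
    atoms = pd.DataFrame(
        {
            "chain_id": first.chain_id,
            "residue_index": first.res_id.astype(int),
            "residue_name": first.res_name,
            "atom_name": first.atom_name,
        }
    )
    times = np.arange(len(coords), dtype=float) * frame_spacing
    return atoms, np.asarray(coords, dtype=float), times


def _read_xyz_table(path: Path) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in XYZ_COLUMNS if c not in df.columns and c != "residue_name"]
    if missing:
        raise ValueError(f"xyz table is missing columns: {missing}")
    if "residue_name" not in df.columns:
        df["residue_name"] = "ALA"
    df = df.sort_values("frame_index", kind="stable")
    frame_ids = df["frame_index"].unique()
    groups = [df[df["frame_index"] == f] for f in frame_ids]
    n0 = len(groups[0])
    bad = [int(f) for f, g in zip(frame_ids, groups) if len(g) != n0]
    if bad:
        raise ValueError(
            f"frames differ in atom count (reference {n0} atoms); "
            f"offending frame indices: {bad}"
        )
    key_cols = ["chain_id", "residue_index", "atom_name"]
    ref_key = groups[0][key_cols].to_numpy()
    for f, g in zip(frame_ids, groups):
        if not np.array_equal(g[key_cols].to_numpy(), ref_key):
            raise ValueError(f"atom ordering differs in frame {int(f)}")
    atoms = groups[0][["chain_id", "residue_index", "residue_name", "atom_name"]]
    atoms = atoms.reset_index(drop=True)
    coords = np.stack([g[["x_nm", "y_nm", "z_nm"]].to_numpy(float) for g in groups])
    times = np.array([g["time_ps"].iloc[0] for g in groups], dtype=float)
    return atoms, coords, times


def read_ensemble(
    path: str | Path,
    format: str = "pdb",
    chain_ids: tuple[str, str] | None = None,
    temperature: float = 300.0,
    frame_spacing: float = 10.0,
) -> ConformationEnsemble:
    """Read a conformational ensemble from disk.

    ``format`` is ``"pdb"`` (multi-model PDB) or ``"xyz"`` (TSV dialect).
    PDB files carry no timestamps; frames are assigned times
    ``0, frame_spacing, 2*frame_spacing, ...`` ps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "pdb":
        atoms, coords, times = _read_pdb(path, frame_spacing)
    elif format == "xyz":
        atoms, coords, times = _read_xyz_table(path)
    else:
        raise ValueError(f"unknown format {format!r} (use 'pdb' or 'xyz')")
    if chain_ids is None:
        uniq = list(dict.fromkeys(atoms["chain_id"]))
        if len(uniq) != 2:
            raise ValueError(
                f"file contains chains {uniq}; pass chain_ids to pick two"
            )
        chain_ids = (uniq[0], uniq[1])
    return ConformationEnsemble(
        atoms=atoms,
        coords=coords,
        times=times,
        chain_ids=tuple(chain_ids),
        temperature=temperature,
    )


def write_ensemble(ens: ConformationEnsemble, path: str | Path, format: str = "pdb") -> None:
    """Write an ensemble as multi-model PDB or as the TSV xyz table."""
    path = Path(path)
    if format == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        n = ens.n_atoms
        arr = struc.AtomArray(n)
        arr.chain_id = ens.atoms["chain_id"].to_numpy(str)
        arr.res_id = ens.atoms["residue_index"].to_numpy(int)
        arr.res_name = ens.atoms["residue_name"].to_numpy(str)
        arr.atom_name = ens.atoms["atom_name"].to_numpy(str)
        arr.element = np.array(
            [name.strip()[0] for name in ens.atoms["atom_name"]], dtype="U2"
        )
        stack = struc.stack([arr] * ens.n_frames)
        stack.coord = ens.coords * 10.0  # nm -> A
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    elif format == "xyz":
        n_frames, n_atoms = ens.n_frames, ens.n_atoms
        rep = lambda col: np.tile(ens.atoms[col].to_numpy(), n_frames)
        flat = ens.coords.reshape(-1, 3)
        df = pd.DataFrame(
            {
                "frame_index": np.repeat(np.arange(n_frames), n_atoms),
                "time_ps": np.repeat(ens.times, n_atoms),
                "chain_id": rep("chain_id"),
                "residue_index": rep("residue_index"),
                "residue_name": rep("residue_name"),
                "atom_name": rep("atom_name"),
                "x_nm": flat[:, 0],
                "y_nm": flat[:, 1],
                "z_nm": flat[:, 2],
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    else:
        raise ValueError(f"unknown format {format!r} (use 'pdb' or 'xyz')")


# ---------------------------------------------------------------------------
# Trimming, superposition, RMSD
# ---------------------------------------------------------------------------

def trim_equilibration(ens: ConformationEnsemble, t_start: float) -> ConformationEnsemble:
    """Drop the equilibration phase: keep frames with ``time >= t_start`` (ps)."""
    if t_start > ens.times[-1]:
        raise ValueError(
            f"t_start={t_start} ps is beyond the last frame time {ens.times[-1]} ps"
        )
    keep = ens.times >= t_start
    if keep.sum() == 0:
        raise ValueError("trimming removed every frame")
    return dataclasses.replace(ens, coords=ens.coords[keep], times=ens.times[keep])


def _check_not_degenerate(ref: np.ndarray) -> None:
    if len(ref) < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("selected atoms are collinear; superposition is degenerate")


def superpose(
    ens: ConformationEnsemble,
    selection: SelectionSpec,
    n_passes: int = 2,
) -> ConformationEnsemble:
    """Remove rigid-body motion by least-squares fit onto the mean structure.

    Every frame is rotated and translated (a proper isometry — no scaling or
    reflection) to minimise the mean-square deviation of the selected atoms
    from a reference that is iteratively refined: the first pass fits onto
    frame 0, subsequent passes onto the mean of the previously aligned
    selection.  Internal geometry of each frame is untouched.
    """
    idx = selection.indices(ens)
    _check_not_degenerate(ens.coords[0, idx])
    coords = ens.coords.copy()
    ref = coords[0, idx] - coords[0, idx].mean(axis=0)
    for _ in range(max(1, n_passes)):
        for f in range(ens.n_frames):
            sel = coords[f, idx]
            cen = sel.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref, sel - cen)
            coords[f] = rot.apply(coords[f] - cen)
        ref = coords[:, idx].mean(axis=0)
        ref = ref - ref.mean(axis=0)
    return ens.with_coords(coords)


def rmsd_timecourse(
    ens: ConformationEnsemble,
    selection: SelectionSpec,
    reference: Frame | None = None,
) -> pd.DataFrame:
    """Best-fit RMSD of every frame to a reference structure.

    The reference defaults to frame 0 (the starting structure); each frame is
    optimally superposed onto it before the RMSD is taken, so the series
    reflects internal deformation only.  Returns a DataFrame with columns
    ``time_ps`` and ``rmsd_nm``.
    """
    idx = selection.indices(ens)
    if reference is None:
        reference = ens.frame(0)
    ref = reference.coords[idx]
    if len(ref) == 0:
        raise ValueError("selection matches no atoms in the reference")
    ref_c = ref - ref.mean(axis=0)
    n = len(idx)
    rmsds = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        mob = ens.coords[f, idx]
        mob_c = mob - mob.mean(axis=0)
        _, rssd = Rotation.align_vectors(ref_c, mob_c)
        rmsds[f] = rssd / np.sqrt(n)
    return pd.DataFrame({"time_ps": ens.times, "rmsd_nm": rmsds})
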