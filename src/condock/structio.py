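"""Structure I/O and the pose data model.

Reads and writes fixed-column PDB files through :mod:`gemmi`, resolves
alternate locations deterministically (highest occupancy, ties broken by the
lexicographically first altloc id), and loads pose manifests that attach
docking provenance (engine, rank, refinement protocol) to each structure.

Hydrogens are kept on read; downstream selections default to heavy atoms
only, so protonation differences between refinement outputs do not affect
clustering or contact analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import EmptyStructureError, ManifestError, RosterError

logger = logging.getLogger(__name__)

#: Three-letter codes treated as protein residues.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

_WATERS = {"HOH", "WAT", "DOD", "H2O"}

#: Docking engines recognized for report formatting; the vocabulary is open.
KNOWN_ENGINES = ("ZDOCK", "ClusPro", "HDOCK", "HADDOCK", "GRAMM-X")


@dataclass(frozen=True)
class Atom:
    """One atom with PDB identity and coordinates (Å)."""

    serial: int
    name: str
    element: str
    resname: str
    chain: str
    resseq: int
    icode: str
    xyz: tuple[float, float, float]

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)

    @property
    def atom_key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.resseq, self.icode, self.name)


class Structure:
    """An ordered collection of atoms with cached coordinate access."""

    def __init__(self, atoms: Sequence[Atom], name: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.name = name
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"Structure({self.name!r}, {len(self)} atoms, chains={self.chains})"

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        if self._coords is None:
            self._coords = np.array([a.xyz for a in self.atoms], dtype=float)
        return self._coords

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    @property
    def residues(self) -> list[tuple[str, int, str, str]]:
        """Ordered unique (chain, resseq, icode, resname) tuples."""
        seen: dict[tuple[str, int, str, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.resseq, a.icode, a.resname), None)
        return list(seen)

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} != ({len(self.atoms)}, 3)"
            )
        atoms = [
            Atom(a.serial, a.name, a.element, a.resname, a.chain, a.resseq,
                 a.icode, tuple(float(v) for v in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, name=self.name if name is None else name)

    def subset(self, indices: Iterable[int], name: str | None = None) -> "Structure":
        idx = list(indices)
        return Structure([self.atoms[i] for i in idx],
                         name=self.name if name is None else name)

    def atom_keys(self) -> list[tuple[str, int, str, str]]:
        return [a.atom_key for a in self.atoms]


@dataclass
class Trajectory:
    """An ordered series of frames sharing one atom roster."""

    frames: list[Structure]
    frame_times: list[float] | None = None  # ns

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyStructureError("trajectory has no frames")
        roster = self.frames[0].atom_keys()
        for i, fr in enumerate(self.frames[1:], start=2):
            if fr.atom_keys() != roster:
                raise RosterError(
                    f"frame {i} atom roster differs from frame 1 "
                    f"({len(fr)} vs {len(self.frames[0])} atoms)"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack."""
        return np.stack([f.coords for f in self.frames])


@dataclass(frozen=True)
class PoseRecord:
    """A docked pose with provenance.

    ``rank`` is the pose's position in its engine's output (1 = top);
    ``protocol`` indexes the refinement run, with 1-5 produced under distance
    restraints only and 6-10 under distance plus position restraints.
    """

    structure: Structure
    engine: str
    rank: int
    protocol: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ManifestError(f"rank must be >= 1, got {self.rank}")
        if not 1 <= self.protocol <= 10:
            raise ManifestError(f"protocol must be in 1..10, got {self.protocol}")

    @property
    def label(self) -> str:
        return f"{self.engine}_{self.rank}_{self.protocol}"


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> first altloc."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in residue:
        by_name.setdefault(at.name, []).append(at)
    kept = []
    for name, group in by_name.items():
        if len(group) == 1:
            kept.append(group[0])
        else:
            best = sorted(group, key=lambda a: (-a.occ, a.altloc))[0]
            kept.append(best)
    return kept


def read_pdb(path: str | Path, model_policy: str = "first"):
    """Read a PDB file into a :class:`Structure` or :class:`Trajectory`.

    Parameters
    ----------
    path : path to a fixed-column PDB file.
    model_policy : ``"first"`` returns the first MODEL as a Structure;
        ``"all"`` returns every MODEL as a Trajectory (rosters must match).

    Waters and non-protein HETATM records are excluded; hydrogens are kept.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    frames: list[Structure] = []
    for model in st:
        atoms: list[Atom] = []
        for chain in model:
            for residue in chain:
                resname = residue.name.strip()
                if resname in _WATERS:
                    continue
                if residue.het_flag == "H" and resname not in AMINO_ACIDS:
                    continue
                for at in _resolve_altlocs(residue):
                    atoms.append(Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        resname=resname,
                        chain=chain.name,
                        resseq=residue.seqid.num,
                        icode=residue.seqid.icode.strip() or " ",
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                    ))
        if atoms:
            frames.append(Structure(atoms, name=path.stem))
        if model_policy == "first":
            break
    if not frames:
        raise EmptyStructureError(f"no protein atoms in {path}")
    if model_policy == "first":
        return frames[0]
    return Trajectory(frames)


def _to_gemmi(frames: Sequence[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    n_total = sum(len(f) for f in frames)
    if n_total > 99999:
        logger.warning(
            "structure has %d atoms (> 99999); serials written in gemmi's "
            "wide-serial convention", n_total,
        )
    for mi, frame in enumerate(frames, start=1):
        model = gemmi.Model(mi)
        serial = 0
        chain_obj: gemmi.Chain | None = None
        res_obj: gemmi.Residue | None = None
        last_res: tuple | None = None
        for a in frame.atoms:
            if chain_obj is None or chain_obj.name != a.chain:
                if chain_obj is not None:
                    model.add_chain(chain_obj)
                chain_obj = gemmi.Chain(a.chain)
                last_res = None
            rk = (a.chain, a.resseq, a.icode, a.resname)
            if rk != last_res:
                if res_obj is not None and last_res is not None:
                    pass
                res_obj = gemmi.Residue()
                res_obj.name = a.resname
                res_obj.seqid = gemmi.SeqId(a.resseq, a.icode if a.icode.strip() else " ")
                res_obj.het_flag = "A"
                chain_obj.add_residue(res_obj)
                last_res = rk
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.xyz)
            at.occ = 1.0
            serial += 1
            at.serial = serial
            # gemmi takes a reference to the last residue added
            chain_obj[len(chain_obj) - 1].add_atom(at)
        if chain_obj is not None:
            model.add_chain(chain_obj)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(obj, path: str | Path) -> Path:
    """Write a Structure, Trajectory, or composite to a PDB file.

    Round-trip safe: re-reading reproduces atom count, names, residue
    numbering and coordinates to PDB precision (3 decimals).
    """
    path = Path(path)
    if isinstance(obj, Trajectory):
        frames = obj.frames
    elif isinstance(obj, Structure):
        frames = [obj]
    elif hasattr(obj, "structure"):  # CompositeComplex duck type
        frames = [obj.structure]
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    if not frames or not len(frames[0]):
        raise EmptyStructureError("refusing to write an empty structure")
    st = _to_gemmi(frames)
    path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path))
    return path


def load_manifest(path: str | Path, base_dir: str | Path | None = None) -> list[PoseRecord]:
    """Load a pose manifest (columns: path, engine, rank, protocol).

    Comma- or tab-delimited with a header row. Relative pose paths resolve
    against ``base_dir`` (default: the manifest's own directory). Records are
    returned in file order; (engine, rank, protocol) must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such manifest: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"path", "engine", "rank", "protocol"}
    if not required.issubset(df.columns):
        raise ManifestError(
            f"manifest must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        raise ManifestError(f"manifest {path} has no rows")
    keys = list(zip(df["engine"], df["rank"], df["protocol"]))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ManifestError(f"duplicate (engine, rank, protocol) entries: {dupes[:5]}")
    base = Path(base_dir) if base_dir is not None else path.parent
    records = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        structure = read_pdb(p, model_policy="first")
        records.append(PoseRecord(
            structure=structure,
            engine=str(row.engine),
            rank=int(row.rank),
            protocol=int(row.protocol),
        ))
    logger.info("loaded %d poses from %s", len(records), path)
    return records
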