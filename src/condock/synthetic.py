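"""Synthetic fixtures: toy complexes, perturbed pose pools, trajectories.

Emulates what a multi-engine docking study feeds the consensus pipeline —
a two-chain complex, rigid-body perturbed decoys with planted cluster
structure and engine labels, and multi-model trajectories — without any
external downloads. Everything is deterministic per seed.

The toy complex is a poly-alanine two-chain model with ideal backbone
geometry built by natural extension of internal coordinates (bond lengths,
angles, and phi/psi torsions of an ideal helix or strand). Pose pools place
cluster centers by distinct rigid-body displacements of the ligand chain
(mirroring how docking engines disagree about the binding mode) and members
by small Gaussian jitter about each center.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import RecipeError
from .structio import Atom, KNOWN_ENGINES, PoseRecord, Structure, Trajectory, write_pdb

logger = logging.getLogger(__name__)

# ideal backbone internal coordinates (Engh & Huber averages)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8

_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom d with bond c-d, angle b-c-d and torsion a-b-c-d."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.cos(tor) * math.sin(ang),
                        bond * math.sin(tor) * math.sin(ang)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(n_residues: int, phi: float, psi: float) -> list[dict]:
    """Per-residue dicts of backbone atom positions (N, CA, C, O, CB)."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_residues):
        prev = res[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"],
                          _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i,
                           _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        c_i = _place_atom(prev["C"], n_i, ca_i,
                          _BOND_CA_C, _ANGLE_N_CA_C, phi)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O (torsion N-CA-C-O = psi + 180) and CB
    for i, r in enumerate(res):
        psi_i = psi if i < n_residues - 1 else psi  # uniform secondary structure
        r["O"] = _place_atom(r["N"], r["CA"], r["C"],
                             _BOND_C_O, _ANGLE_CA_C_O, psi_i + 180.0)
        r["CB"] = _place_atom(r["C"], r["N"], r["CA"], 1.53, 110.6, -122.6)
    return res


def _principal_axis_align(coords: np.ndarray) -> np.ndarray:
    """Rotate so the dominant axis of the point cloud lies along +x."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[0] < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors(np.array([[1.0, 0, 0]]), axis[None, :])
    return centered @ rot.as_matrix().T


_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C",
            "CG": "C", "CD": "C", "CE": "C", "NZ": "N",
            "OE1": "O", "OE2": "O"}


def make_toy_complex(
    n_residues_per_chain: int,
    geometry: str = "helix",
    seed: int = 0,
    chain_separation: float = 8.0,
    charged: bool = False,
) -> Structure:
    """Two-chain poly-alanine complex with ideal backbone geometry.

    Chain B is a copy of chain A shifted perpendicular to the chain axis by
    ``chain_separation`` Å; the default leaves closest heavy atoms around
    3-4.5 Å, i.e. a bound interface whose contacts sit well inside the 5 Å
    contact cutoff, as in a docked complex. With ``charged=True`` the middle residue of
    chain A becomes a glutamate and chain B's a lysine, with side chains
    built toward each other across the interface (a planted salt bridge).
    A small seeded coordinate jitter (0.01 Å) makes distinct seeds produce
    distinct but equivalent structures.
    """
    if n_residues_per_chain < 4:
        raise ValueError("need at least 4 residues per chain")
    if geometry not in _TORSIONS:
        raise ValueError(f"geometry must be one of {sorted(_TORSIONS)}")
    phi, psi = _TORSIONS[geometry]
    backbone = _build_backbone(n_residues_per_chain, phi, psi)
    order = ("N", "CA", "C", "O", "CB")
    raw = np.array([r[name] for r in backbone for name in order])
    aligned = _principal_axis_align(raw)
    rng = np.random.default_rng(seed)
    aligned = aligned + rng.normal(0.0, 0.01, size=aligned.shape)

    atoms: list[Atom] = []
    serial = 0
    mid = n_residues_per_chain // 2 + 1
    for chain, offset in (("A", np.zeros(3)),
                          ("B", np.array([0.0, chain_separation, 0.0]))):
        for ri in range(n_residues_per_chain):
            resseq = ri + 1
            resname = "ALA"
            if charged and resseq == mid:
                resname = "GLU" if chain == "A" else "LYS"
            for k, name in enumerate(order):
                serial += 1
                xyz = aligned[ri * len(order) + k] + offset
                atoms.append(Atom(serial, name, _ELEMENT[name], resname,
                                  chain, resseq, " ", tuple(xyz)))
    st = Structure(atoms, name=f"toy_{geometry}_{n_residues_per_chain}")
    if charged:
        st = _plant_salt_bridge(st, mid, chain_separation)
    return st


def _plant_salt_bridge(st: Structure, resseq: int, separation: float) -> Structure:
    """Build GLU/LYS side chains meeting between the chains (~3 Å N-O)."""
    ca_a = next(a for a in st.atoms if a.chain == "A" and a.resseq == resseq
                and a.name == "CA")
    ca_b = next(a for a in st.atoms if a.chain == "B" and a.resseq == resseq
                and a.name == "CA")
    mid = (np.array(ca_a.xyz) + np.array(ca_b.xyz)) / 2
    atoms = list(st.atoms)
    serial = max(a.serial for a in atoms)

    def chain_path(start: np.ndarray, end: np.ndarray, names: list[str],
                   chain: str, resname: str) -> list[Atom]:
        nonlocal serial
        out = []
        for i, name in enumerate(names, start=1):
            frac = i / (len(names) + 0.5)
            pos = start + frac * (end - start)
            pos = pos + np.array([0.4 * ((i % 2) * 2 - 1), 0.0, 0.3])
            serial += 1
            out.append(Atom(serial, name, _ELEMENT[name], resname, chain,
                            resseq, " ", tuple(pos)))
        return out

    oe_site = mid + np.array([0.0, -1.5, 0.0])
    nz_site = mid + np.array([0.0, 1.5, 0.0])
    atoms += chain_path(np.array(ca_a.xyz), oe_site, ["CG", "CD"], "A", "GLU")
    serial += 1
    atoms.append(Atom(serial, "OE1", "O", "GLU", "A", resseq, " ",
                      tuple(oe_site + np.array([0.6, 0, 0]))))
    serial += 1
    atoms.append(Atom(serial, "OE2", "O", "GLU", "A", resseq, " ",
                      tuple(oe_site + np.array([-0.6, 0, 0]))))
    atoms += chain_path(np.array(ca_b.xyz), nz_site, ["CG", "CD", "CE"], "B", "LYS")
    serial += 1
    atoms.append(Atom(serial, "NZ", "N", "LYS", "B", resseq, " ",
                      tuple(nz_site)))
    # keep chain/residue ordering stable
    atoms.sort(key=lambda a: (a.chain, a.resseq, a.serial))
    return Structure(atoms, name=st.name)


def perturb_pose(
    base: Structure,
    rotation_deg: float,
    translation_ang: float,
    jitter_ang: float,
    seed: int,
    ligand_chain: str = "B",
) -> Structure:
    """Rigid-body move of the ligand chain plus per-atom Gaussian jitter.

    The ligand chain is rotated by ``rotation_deg`` about a seeded random
    axis through its centroid, translated ``translation_ang`` Å along a
    seeded random direction, then each ligand atom receives isotropic
    Gaussian jitter of standard deviation ``jitter_ang`` per coordinate.
    The receptor chain is untouched.
    """
    if min(rotation_deg, translation_ang, jitter_ang) < 0:
        raise ValueError("perturbation magnitudes must be >= 0")
    rng = np.random.default_rng(seed)
    lig = np.array([a.chain == ligand_chain for a in base.atoms])
    if not lig.any():
        raise ValueError(f"no atoms in ligand chain {ligand_chain!r}")
    coords = base.coords.copy()
    lig_xyz = coords[lig]
    centroid = lig_xyz.mean(axis=0)

    def unit(v):
        return v / np.linalg.norm(v)

    axis = unit(rng.normal(size=3))
    rot = Rotation.from_rotvec(np.radians(rotation_deg) * axis)
    moved = rot.apply(lig_xyz - centroid) + centroid
    moved = moved + unit(rng.normal(size=3)) * translation_ang
    moved = moved + rng.normal(0.0, jitter_ang, size=moved.shape)
    coords[lig] = moved
    return base.with_coords(coords)


@dataclass
class PoolRecipe:
    """A planted-cluster pose pool.

    Cluster centers are distinct rigid displacements of the ligand chain;
    members add Gaussian jitter of ``intra_spread`` (Å, per coordinate)
    about their center. ``inter_separation`` is the minimum distance (Å)
    between cluster-center ligand displacements and must exceed twice the
    intra-cluster spread for a separable pool. ``engine_assignment`` maps a
    cluster index (0-based) to an engine name or an engine->proportion map;
    ``None`` assigns engines round-robin over the standard five.
    """

    base: Structure
    n_clusters: int = 3
    members_per_cluster: Sequence[int] = (10, 10, 10)
    intra_spread: float = 0.3
    inter_separation: float = 20.0
    engine_assignment: dict | None = None
    seed: int = 0
    ligand_chain: str = "B"

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise RecipeError("need at least one cluster")
        if len(self.members_per_cluster) != self.n_clusters:
            raise RecipeError("members_per_cluster length != n_clusters")
        if any(m < 1 for m in self.members_per_cluster):
            raise RecipeError("member counts must be positive")
        if self.inter_separation <= 2 * self.intra_spread:
            raise RecipeError("inter_separation must exceed 2 x intra_spread")


def _cluster_offsets(n: int, separation: float) -> np.ndarray:
    """Ligand displacement per cluster: a radial ladder along +y.

    Centers differ in receptor-ligand distance by multiples of
    ``separation``. A rigid motion of a whole complex cannot change its
    internal receptor-ligand separation, so any two cluster centers remain
    at least ~separation/2 apart in superposed RMSD — the planted structure
    is separable by construction, not merely in displacement space.
    """
    return np.array([[0.0, i * separation, 0.0] for i in range(n)])


def _engine_counts(recipe: PoolRecipe, cluster: int, members: int) -> list[str]:
    """Engine label per member of one cluster."""
    spec = None if recipe.engine_assignment is None else \
        recipe.engine_assignment.get(cluster)
    if spec is None:
        return [KNOWN_ENGINES[(cluster + j) % len(KNOWN_ENGINES)]
                for j in range(members)]
    if isinstance(spec, str):
        return [spec] * members
    if not spec or any(v < 0 for v in spec.values()) or sum(spec.values()) <= 0:
        raise RecipeError(f"infeasible engine proportions for cluster {cluster}")
    engines = sorted(spec)
    total = sum(spec.values())
    exact = {e: spec[e] / total * members for e in engines}
    counts = {e: int(np.floor(exact[e])) for e in engines}
    # largest remainder
    leftover = members - sum(counts.values())
    for e in sorted(engines, key=lambda e: -(exact[e] - counts[e]))[:leftover]:
        counts[e] += 1
    out = []
    for e in engines:
        out += [e] * counts[e]
    return out


def generate_pool(
    recipe: PoolRecipe,
    out_dir: str | Path | None = None,
) -> tuple[list[PoseRecord], pd.DataFrame]:
    """Generate a planted-cluster pose pool with engine labels.

    Returns (pose records, ground-truth table with columns label,
    true_cluster). When ``out_dir`` is given, pose PDBs, a ``manifest.csv``
    and a ``ground_truth.csv`` sidecar are written there as well.
    """
    rng = np.random.default_rng(recipe.seed)
    offsets = _cluster_offsets(recipe.n_clusters, recipe.inter_separation)
    lig = np.array([a.chain == recipe.ligand_chain for a in recipe.base.atoms])
    if not lig.any():
        raise RecipeError(f"base has no chain {recipe.ligand_chain!r}")
    records: list[PoseRecord] = []
    truth_rows = []
    engine_counter: dict[str, int] = {}
    # distinct ligand orientation per binding mode, as docking engines give
    mode_rotations = [Rotation.from_rotvec(np.radians(25.0 * ci) *
                                           np.array([0.0, 0.0, 1.0]))
                      for ci in range(recipe.n_clusters)]
    for ci in range(recipe.n_clusters):
        engines = _engine_counts(recipe, ci, recipe.members_per_cluster[ci])
        for engine in engines:
            coords = recipe.base.coords.copy()
            lig_xyz = coords[lig]
            centroid = lig_xyz.mean(axis=0)
            coords[lig] = mode_rotations[ci].apply(lig_xyz - centroid) + centroid
            coords[lig] += offsets[ci]
            coords[lig] += rng.normal(0.0, recipe.intra_spread,
                                      size=(int(lig.sum()), 3))
            c = engine_counter.get(engine, 0)
            engine_counter[engine] = c + 1
            rank, protocol = c // 10 + 1, c % 10 + 1
            structure = recipe.base.with_coords(
                coords, name=f"{engine}_{rank}_{protocol}")
            rec = PoseRecord(structure=structure, engine=engine,
                             rank=rank, protocol=protocol)
            records.append(rec)
            truth_rows.append({"label": rec.label, "true_cluster": ci})
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        pose_dir = out_dir / "poses"
        pose_dir.mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        for rec in records:
            fname = f"{rec.label}.pdb"
            write_pdb(rec.structure, pose_dir / fname)
            manifest_rows.append({"path": f"poses/{fname}",
                                  "engine": rec.engine, "rank": rec.rank,
                                  "protocol": rec.protocol})
        pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv", index=False)
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
        logger.info("wrote %d poses to %s", len(records), out_dir)
    return records, truth


def generate_trajectory(
    base: Structure,
    mode: str = "stable",
    n_frames: int = 10,
    seed: int = 0,
    jitter_ang: float = 0.03,
    step_ang: float = 2.5,
    ligand_chain: str = "B",
    out_path: str | Path | None = None,
) -> Trajectory:
    """Synthetic multi-frame trajectory with a constant atom roster.

    ``stable`` jitters all atoms about the base structure with an amplitude
    small against the contact-cutoff margin of the default toy interface,
    so a bound complex stays bound; ``dissociating`` adds a monotone
    per-frame ligand translation of ``step_ang`` Å (large against the
    jitter), so native contacts can only break.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if mode not in ("stable", "dissociating"):
        raise ValueError(f"mode must be 'stable' or 'dissociating', got {mode!r}")
    rng = np.random.default_rng(seed)
    lig = np.array([a.chain == ligand_chain for a in base.atoms])
    frames = []
    for f in range(n_frames):
        coords = base.coords.copy()
        coords += rng.normal(0.0, jitter_ang, size=coords.shape)
        if mode == "dissociating":
            coords[lig] += np.array([0.0, step_ang * f, 0.0])
        frames.append(base.with_coords(coords, name=f"{base.name}_f{f}"))
    traj = Trajectory(frames=frames,
                      frame_times=[float(f) for f in range(n_frames)])
    if out_path is not None:
        write_pdb(traj, out_path)
    return traj
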