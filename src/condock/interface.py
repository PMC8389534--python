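"""Interface characterization and trajectory analysis.

Contacts are residue pairs across a declared chain partition whose closest
heavy atoms lie within a cutoff (default 5 Å). Native contacts restrict the
pair set to those anchored on hot-spot residues — residues whose alanine
substitution changes binding affinity (ΔAff) beyond a threshold (default
> 10 kcal/mol); ΔAff values are consumed from a table, never computed here.
Retention of the native contacts over a trajectory measures how well a
docked interface survives dynamics.

Hydrogen bonds and salt bridges use geometric criteria (donor-acceptor
distance, optional D-H···A angle when hydrogens are present; carboxylate-O
to basic-N distance). The thresholds are common literature defaults and are
exposed as parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import PartitionError
from .geometry import AtomSelection, CA_SELECTION, kabsch_rmsd
from .structio import Structure, Trajectory

logger = logging.getLogger(__name__)

ResidueId = tuple[str, int]  # (chain, resseq)


@dataclass(frozen=True)
class PartnerPartition:
    """The two sides of a binding interface, as disjoint chain sets."""

    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise PartitionError("both partition sides must be non-empty")
        if self.side_a & self.side_b:
            raise PartitionError(
                f"partition sides overlap: {sorted(self.side_a & self.side_b)}"
            )

    @classmethod
    def of(cls, side_a, side_b) -> "PartnerPartition":
        return cls(frozenset(side_a), frozenset(side_b))

    def swapped(self) -> "PartnerPartition":
        return PartnerPartition(self.side_b, self.side_a)


@dataclass
class ContactSet:
    """Cross-partition residue contacts with minimum heavy-atom distances."""

    pairs: dict[tuple[ResidueId, ResidueId], float]
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return pair in self.pairs

    def canonical(self) -> frozenset[frozenset]:
        """Order-free view of the pair set, for side-symmetry comparisons."""
        return frozenset(frozenset(p) for p in self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chain_a": a[0], "resseq_a": a[1], "chain_b": b[0],
             "resseq_b": b[1], "min_distance": d}
            for (a, b), d in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows, columns=["chain_a", "resseq_a", "chain_b",
                                           "resseq_b", "min_distance"])


@dataclass
class RetentionSeries:
    """Per-frame survival of a native contact set over a trajectory."""

    fractions: np.ndarray
    survivors: list[list[tuple[ResidueId, ResidueId]]]
    n_native: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.fractions)),
                             "fraction_native": self.fractions,
                             "n_surviving": [len(s) for s in self.survivors]})


def load_hotspots(path: str | Path) -> pd.DataFrame:
    """Read a hot-spot table (columns: chain, resseq, resname, delta_aff)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"chain", "resseq", "resname", "delta_aff"}
    if not required.issubset(df.columns):
        raise ValueError(f"hotspot table needs columns {sorted(required)}")
    if not np.isfinite(df["delta_aff"]).all():
        raise ValueError("delta_aff values must be finite")
    return df


def _side_atoms(structure: Structure, chains: frozenset[str]) -> np.ndarray:
    idx = [i for i, a in enumerate(structure.atoms)
           if a.chain in chains and a.is_heavy]
    return np.array(idx, dtype=int)


def detect_contacts(
    structure: Structure,
    partition: PartnerPartition,
    cutoff: float = 5.0,
) -> ContactSet:
    """Residue pairs across the partition with any heavy-atom pair <= cutoff.

    The minimum heavy-atom distance of each contacting pair is recorded.
    """
    ia = _side_atoms(structure, partition.side_a)
    ib = _side_atoms(structure, partition.side_b)
    if len(ia) == 0 or len(ib) == 0:
        raise PartitionError("a partition side selects no heavy atoms")
    xa = structure.coords[ia]
    xb = structure.coords[ib]
    tree = cKDTree(xb)
    pairs: dict[tuple[ResidueId, ResidueId], float] = {}
    neighbor_lists = tree.query_ball_point(xa, cutoff)
    for ai, neighbors in zip(ia, neighbor_lists):
        if not neighbors:
            continue
        atom_a = structure.atoms[ai]
        ra = (atom_a.chain, atom_a.resseq)
        for nj in neighbors:
            bi = ib[nj]
            atom_b = structure.atoms[bi]
            rb = (atom_b.chain, atom_b.resseq)
            d = float(np.linalg.norm(structure.coords[ai] - structure.coords[bi]))
            key = (ra, rb)
            if key not in pairs or d < pairs[key]:
                pairs[key] = d
    return ContactSet(pairs=pairs, cutoff=cutoff)


def native_contacts(
    structure: Structure,
    partition: PartnerPartition,
    hotspots: pd.DataFrame,
    threshold: float = 10.0,
    cutoff: float = 5.0,
) -> ContactSet:
    """Contacts anchored on hot-spot residues.

    A contact is kept when at least one of its residues appears in the
    hot-spot table with delta_aff > threshold — hot spots on either side
    count, paired against all residues of the other side.
    """
    hot = {(str(r.chain), int(r.resseq))
           for r in hotspots.itertuples(index=False)
           if float(r.delta_aff) > threshold}
    if not hot:
        logger.warning("no hotspot exceeds threshold %.3g kcal/mol; "
                       "native contact set is empty", threshold)
        return ContactSet(pairs={}, cutoff=cutoff)
    all_contacts = detect_contacts(structure, partition, cutoff)
    kept = {pair: d for pair, d in all_contacts.pairs.items()
            if pair[0] in hot or pair[1] in hot}
    return ContactSet(pairs=kept, cutoff=cutoff)


def contact_retention(
    trajectory: Trajectory,
    native: ContactSet,
    partition: PartnerPartition,
    cutoff: float | None = None,
) -> RetentionSeries:
    """Per-frame fraction of native contacts still present.

    A native pair survives in a frame when its minimum heavy-atom distance
    is still <= cutoff (default: the native set's own cutoff).
    """
    if len(native) == 0:
        raise ValueError("native contact set is empty")
    if cutoff is None:
        cutoff = native.cutoff
    # atom indices per residue, fixed roster across frames
    frame0 = trajectory.frames[0]
    res_atoms: dict[ResidueId, list[int]] = {}
    for i, a in enumerate(frame0.atoms):
        if a.is_heavy:
            res_atoms.setdefault((a.chain, a.resseq), []).append(i)
    for ra, rb in native.pairs:
        if ra not in res_atoms or rb not in res_atoms:
            raise ValueError(f"native contact residue {ra} or {rb} missing "
                             "from the trajectory roster")
    fractions = []
    survivors: list[list[tuple[ResidueId, ResidueId]]] = []
    coords = trajectory.coords
    for f in range(len(trajectory)):
        x = coords[f]
        alive = []
        for (ra, rb) in native.pairs:
            da = x[res_atoms[ra]]
            db = x[res_atoms[rb]]
            dmin = np.sqrt(
                ((da[:, None, :] - db[None, :, :]) ** 2).sum(-1)
            ).min()
            if dmin <= cutoff:
                alive.append((ra, rb))
        survivors.append(alive)
        fractions.append(len(alive) / len(native))
    return RetentionSeries(fractions=np.array(fractions), survivors=survivors,
                           n_native=len(native))


# ---------------------------------------------------------------------------
# hydrogen bonds and salt bridges

#: Side-chain donor heavy atoms per residue (backbone N is always a donor).
_SC_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "TRP": {"NE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

#: Side-chain acceptor heavy atoms (backbone O/OXT always accepts).
_SC_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

_ACIDIC = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_BASIC = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
          "HIS": {"ND1", "NE2"}}


@dataclass
class BondSet:
    """Detected polar interactions (H-bonds or salt bridges)."""

    bonds: pd.DataFrame
    used_hydrogen_angles: bool = False

    @property
    def count(self) -> int:
        return len(self.bonds)


def _in_scope(atom_a, atom_b, scope: str,
              partition: PartnerPartition | None) -> bool:
    if scope == "all":
        return True
    if scope == "within-chain":
        return atom_a.chain == atom_b.chain
    if scope == "cross-partition":
        if partition is None:
            raise ValueError("cross-partition scope needs a partition")
        return ((atom_a.chain in partition.side_a and
                 atom_b.chain in partition.side_b) or
                (atom_a.chain in partition.side_b and
                 atom_b.chain in partition.side_a))
    raise ValueError(f"unknown scope {scope!r}")


def _attached_hydrogens(structure: Structure, donor_idx: int) -> list[int]:
    donor = structure.atoms[donor_idx]
    out = []
    for i, a in enumerate(structure.atoms):
        if a.is_heavy or a.residue_key != donor.residue_key:
            continue
        if np.linalg.norm(structure.coords[i] - structure.coords[donor_idx]) < 1.3:
            out.append(i)
    return out


def detect_hbonds(
    structure: Structure,
    scope: str = "all",
    partition: PartnerPartition | None = None,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> BondSet:
    """Geometric hydrogen bonds.

    Criterion: donor-acceptor heavy-atom distance <= ``distance_cutoff`` and,
    when hydrogens are present on the donor, at least one D-H···A angle
    >= ``angle_cutoff`` degrees. Without hydrogens the distance criterion
    alone applies and the result is flagged. Pairs within the same or an
    adjacent residue of the same chain are excluded (covalent neighbors).
    """
    donors, acceptors = [], []
    for i, a in enumerate(structure.atoms):
        if not a.is_heavy:
            continue
        if a.name == "N" or a.name in _SC_DONORS.get(a.resname, ()):
            donors.append(i)
        if a.name in ("O", "OXT") or a.name in _SC_ACCEPTORS.get(a.resname, ()):
            acceptors.append(i)
    has_h = any(not a.is_heavy for a in structure.atoms)
    coords = structure.coords
    acc_tree = cKDTree(coords[acceptors]) if acceptors else None
    rows = []
    for di in donors:
        if acc_tree is None:
            break
        d_atom = structure.atoms[di]
        hs = _attached_hydrogens(structure, di) if has_h else []
        for nj in acc_tree.query_ball_point(coords[di], distance_cutoff):
            ai = acceptors[nj]
            a_atom = structure.atoms[ai]
            if (d_atom.chain == a_atom.chain and
                    abs(d_atom.resseq - a_atom.resseq) <= 1):
                continue
            if not _in_scope(d_atom, a_atom, scope, partition):
                continue
            dist = float(np.linalg.norm(coords[di] - coords[ai]))
            angle = None
            if has_h and hs:
                best = -1.0
                for hi in hs:
                    v1 = coords[di] - coords[hi]
                    v2 = coords[ai] - coords[hi]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) *
                                               np.linalg.norm(v2))
                    best = max(best, float(np.degrees(
                        np.arccos(np.clip(cosang, -1, 1)))))
                angle = best
                if angle < angle_cutoff:
                    continue
            rows.append({
                "donor_chain": d_atom.chain, "donor_resseq": d_atom.resseq,
                "donor_resname": d_atom.resname, "donor_atom": d_atom.name,
                "acceptor_chain": a_atom.chain,
                "acceptor_resseq": a_atom.resseq,
                "acceptor_resname": a_atom.resname,
                "acceptor_atom": a_atom.name,
                "distance": dist, "angle": angle,
            })
    cols = ["donor_chain", "donor_resseq", "donor_resname", "donor_atom",
            "acceptor_chain", "acceptor_resseq", "acceptor_resname",
            "acceptor_atom", "distance", "angle"]
    df = pd.DataFrame(rows, columns=cols)
    if not has_h:
        logger.info("no hydrogens in structure: H-bond detection used the "
                    "distance-only criterion")
    return BondSet(bonds=df, used_hydrogen_angles=has_h)


def detect_salt_bridges(
    structure: Structure,
    scope: str = "all",
    partition: PartnerPartition | None = None,
    cutoff: float = 4.0,
) -> BondSet:
    """Salt bridges: Asp/Glu carboxylate O within ``cutoff`` of a Lys/Arg/His
    side-chain N. Counted once per residue pair (closest atom pair kept)."""
    acidic, basic = [], []
    for i, a in enumerate(structure.atoms):
        if a.name in _ACIDIC.get(a.resname, ()):
            acidic.append(i)
        if a.name in _BASIC.get(a.resname, ()):
            basic.append(i)
    coords = structure.coords
    best: dict[tuple, dict] = {}
    if acidic and basic:
        tree = cKDTree(coords[basic])
        for ai in acidic:
            a_atom = structure.atoms[ai]
            for nj in tree.query_ball_point(coords[ai], cutoff):
                bi = basic[nj]
                b_atom = structure.atoms[bi]
                if not _in_scope(a_atom, b_atom, scope, partition):
                    continue
                dist = float(np.linalg.norm(coords[ai] - coords[bi]))
                key = (a_atom.residue_key, b_atom.residue_key)
                if key not in best or dist < best[key]["distance"]:
                    best[key] = {
                        "acid_chain": a_atom.chain,
                        "acid_resseq": a_atom.resseq,
                        "acid_resname": a_atom.resname,
                        "acid_atom": a_atom.name,
                        "base_chain": b_atom.chain,
                        "base_resseq": b_atom.resseq,
                        "base_resname": b_atom.resname,
                        "base_atom": b_atom.name,
                        "distance": dist,
                    }
    cols = ["acid_chain", "acid_resseq", "acid_resname", "acid_atom",
            "base_chain", "base_resseq", "base_resname", "base_atom",
            "distance"]
    df = pd.DataFrame(sorted(best.values(), key=lambda r: (
        r["acid_chain"], r["acid_resseq"], r["base_chain"], r["base_resseq"])),
        columns=cols)
    return BondSet(bonds=df)


# ---------------------------------------------------------------------------
# trajectory observables

def rmsd_timeseries(
    trajectory: Trajectory,
    reference_frame: int = 0,
    selection: AtomSelection = CA_SELECTION,
) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference frame after optimal superposition."""
    n = len(trajectory)
    if not -n <= reference_frame < n:
        raise IndexError(f"reference frame {reference_frame} out of range "
                         f"for {n} frames")
    idx = selection.indices(trajectory.frames[0])
    if len(idx) == 0:
        raise ValueError("selection matches no atoms")
    coords = trajectory.coords[:, idx, :]
    ref = coords[reference_frame]
    refc = ref - ref.mean(axis=0)
    out = np.empty(n)
    for f in range(n):
        x = coords[f]
        _, out[f] = kabsch_rmsd(x - x.mean(axis=0), refc)
    return out


def rmsf(
    trajectory: Trajectory,
    selection: AtomSelection = CA_SELECTION,
    refinement_passes: int = 2,
) -> pd.DataFrame:
    """Per-residue RMSF (Å) about the iteratively refined mean structure.

    Frames are superposed to the running mean (``refinement_passes``
    refinements after an initial fit to frame 0); each residue's RMSF is the
    root-mean-square deviation of its selected-atom centroid from its
    time-average position.
    """
    if len(trajectory) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = selection.indices(trajectory.frames[0])
    if len(idx) == 0:
        raise ValueError("selection matches no atoms")
    coords = trajectory.coords[:, idx, :].copy()
    # initial fit to frame 0, then refine against the mean
    ref = coords[0]
    for _ in range(refinement_passes + 1):
        refc = ref - ref.mean(axis=0)
        for f in range(len(coords)):
            x = coords[f]
            xc = x - x.mean(axis=0)
            rot, _ = Rotation.align_vectors(refc, xc)
            coords[f] = rot.apply(xc)
        ref = coords.mean(axis=0)
    # per-residue centroid fluctuation
    atoms = [trajectory.frames[0].atoms[i] for i in idx]
    res_of_atom = [(a.chain, a.resseq) for a in atoms]
    residues = list(dict.fromkeys(res_of_atom))
    rows = []
    for res in residues:
        cols = [i for i, r in enumerate(res_of_atom) if r == res]
        cent = coords[:, cols, :].mean(axis=1)  # (n_frames, 3)
        mean_pos = cent.mean(axis=0)
        fluct = float(np.sqrt(((cent - mean_pos) ** 2).sum(axis=1).mean()))
        rows.append({"chain": res[0], "resseq": res[1], "rmsf": fluct})
    return pd.DataFrame(rows)
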