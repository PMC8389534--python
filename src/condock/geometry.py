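"""Superposition, RMSD and chain-correspondence machinery.

The least-squares rigid superposition (Kabsch) is delegated to
``scipy.spatial.transform.Rotation.align_vectors``, which returns the optimal
proper rotation (det = +1; mirror solutions are never produced). Chain
correspondence between two structures is explicit: a :class:`ChainMapping`
states which chain in one structure pairs with which in the other, and may
declare groups of chemically identical chains (e.g. the two protomers of a
homodimer) as permutable, in which case all allowed permutations are
evaluated and the minimum-RMSD one returned. Identical chains are never
permuted automatically.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateSuperpositionError, RosterError
from .structio import Structure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AtomSelection:
    """Which atoms enter a superposition or RMSD.

    mode : ``"ca"`` (Cα only), ``"heavy"`` (all non-hydrogen), ``"all"``,
        or ``"custom"`` with an explicit set of atom names.
    residue_filter : optional list of (chain, first_resseq, last_resseq)
        inclusive ranges; ``None`` keeps every residue.
    """

    mode: str = "heavy"
    atom_names: frozenset[str] | None = None
    residue_filter: tuple[tuple[str, int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("ca", "heavy", "all", "custom"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "custom" and not self.atom_names:
            raise ValueError("custom selection requires atom_names")

    def indices(self, structure: Structure) -> np.ndarray:
        """Indices of atoms in ``structure`` passing this selection."""
        out = []
        for i, a in enumerate(structure.atoms):
            if self.mode == "ca" and a.name != "CA":
                continue
            if self.mode == "heavy" and not a.is_heavy:
                continue
            if self.mode == "custom" and a.name not in self.atom_names:
                continue
            if self.residue_filter is not None:
                ok = any(
                    a.chain == ch and lo <= a.resseq <= hi
                    for ch, lo, hi in self.residue_filter
                )
                if not ok:
                    continue
            out.append(i)
        return np.array(out, dtype=int)


CA_SELECTION = AtomSelection(mode="ca")
HEAVY_SELECTION = AtomSelection(mode="heavy")


@dataclass(frozen=True)
class ChainMapping:
    """Bijective chain correspondence between two structures.

    pairs : (chain_in_A, chain_in_B) tuples; empty means identity mapping
        over the chains the structures share.
    permutable_groups : chain-id sets (in A's naming) whose members are
        chemically identical and may be swapped to minimize RMSD.
    """

    pairs: tuple[tuple[str, str], ...] = ()
    permutable_groups: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("chain mapping must be a bijection")

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def variants(self, chains: Sequence[str] = ()) -> list[dict[str, str]]:
        """All chain maps allowed by the permutable groups (identity first).

        ``chains`` supplies the mobile structure's chain ids for the default
        (identity) correspondence when no explicit pairs are declared.
        """
        base = self.as_dict() or {c: c for c in chains}
        if not self.permutable_groups:
            return [base]
        per_group: list[list[dict[str, str]]] = []
        for group in self.permutable_groups:
            members = sorted(group)
            swaps = []
            for perm in itertools.permutations(members):
                swaps.append(dict(zip(members, perm)))
            per_group.append(swaps)
        variants = []
        for combo in itertools.product(*per_group):
            remap: dict[str, str] = {}
            for swap in combo:
                remap.update(swap)
            # permute A-side chains before applying the base correspondence
            var = {a: base[remap.get(a, a)] for a in base if remap.get(a, a) in base}
            variants.append(var)
        return variants


IDENTITY_MAPPING = ChainMapping()


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform of mobile onto reference, and its RMSD."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # Å
    rmsd: float  # Å
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def transform_structure(self, structure: Structure) -> Structure:
        return structure.with_coords(self.apply(structure.coords))


def _paired_indices(
    a: Structure,
    b: Structure,
    selection: AtomSelection,
    chain_map: dict[str, str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of atoms of ``a`` and ``b`` paired by (chain, resseq, icode, name)."""
    sel_a = selection.indices(a)
    sel_b = selection.indices(b)
    b_lookup = {b.atoms[i].atom_key: i for i in sel_b}
    ia, ib = [], []
    for i in sel_a:
        at = a.atoms[i]
        ch = chain_map.get(at.chain) if chain_map else at.chain
        if chain_map and ch is None:
            continue
        key = (ch, at.resseq, at.icode, at.name)
        j = b_lookup.get(key)
        if j is not None:
            ia.append(i)
            ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def common_atom_roster(
    structures: Sequence[Structure],
    selection: AtomSelection = HEAVY_SELECTION,
) -> list[np.ndarray]:
    """Per-structure indices of atoms present in every structure.

    Atoms are matched by (chain, resseq, icode, name) after the selection;
    atoms missing from any structure are dropped everywhere (and logged).
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    key_sets = []
    for s in structures:
        sel = selection.indices(s)
        key_sets.append({s.atoms[i].atom_key: i for i in sel})
    common = set(key_sets[0])
    for ks in key_sets[1:]:
        common &= set(ks)
    if not common:
        raise RosterError("no atoms shared by all structures under this selection")
    n_sel = len(key_sets[0])
    if len(common) < n_sel:
        logger.info("common roster dropped %d of %d selected atoms",
                    n_sel - len(common), n_sel)
    # order follows the first structure
    ordered = [k for i, k in
               sorted(((key_sets[0][k], k) for k in common))]
    return [np.array([ks[k] for k in ordered], dtype=int) for ks in key_sets]


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> tuple[Rotation, float]:
    """Optimal-rotation RMSD between centered copies of two (n, 3) arrays."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(yc, xc)
    return rot, float(rssd / np.sqrt(len(x)))


def _check_degenerate(coords: np.ndarray) -> None:
    if len(coords) < 3:
        raise DegenerateSuperpositionError(
            f"need >= 3 paired atoms, got {len(coords)}"
        )
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateSuperpositionError("paired atoms are collinear")


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    selection: AtomSelection = HEAVY_SELECTION,
    mapping: ChainMapping = IDENTITY_MAPPING,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    With permutable groups declared in ``mapping``, every allowed chain
    permutation is evaluated and the minimum-RMSD solution returned.
    """
    best: SuperpositionResult | None = None
    for chain_map in mapping.variants(mobile.chains):
        ia, ib = _paired_indices(mobile, reference, selection, chain_map or None)
        if len(ia) == 0:
            continue
        x = mobile.coords[ia]
        y = reference.coords[ib]
        _check_degenerate(x)
        rot, rmsd_val = kabsch_rmsd(x, y)
        R = rot.as_matrix()
        t = y.mean(axis=0) - R @ x.mean(axis=0)
        res = SuperpositionResult(rotation=R, translation=t,
                                  rmsd=rmsd_val, n_atoms=len(ia))
        if best is None or res.rmsd < best.rmsd:
            best = res
    if best is None:
        raise RosterError("no paired atoms between mobile and reference")
    return best


def rmsd(
    a: Structure,
    b: Structure,
    selection: AtomSelection = HEAVY_SELECTION,
    mapping: ChainMapping = IDENTITY_MAPPING,
    superpose: bool = True,
) -> float:
    """RMSD between two structures over the paired selection, in Å.

    ``superpose=True`` (default) removes the optimal rigid transform first;
    ``superpose=False`` measures in the frames as given (still minimized over
    any permutable-group chain assignments).
    """
    if superpose:
        return kabsch_superpose(a, b, selection, mapping).rmsd
    best = None
    for chain_map in mapping.variants(a.chains):
        ia, ib = _paired_indices(a, b, selection, chain_map or None)
        if len(ia) == 0:
            continue
        d = a.coords[ia] - b.coords[ib]
        val = float(np.sqrt((d * d).sum() / len(ia)))
        if best is None or val < best:
            best = val
    if best is None:
        raise RosterError("no paired atoms between structures")
    return best
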