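"""Consensus pose selection over a multi-engine docking pool.

The meta-approach: pool the refined poses of several docking engines, build
the all-pairs heavy-atom RMSD matrix, cluster it hierarchically, pick the
number of clusters N that minimizes the Kelley penalty, and return the
member nearest the centroid of the most populated cluster as the consensus
pose Q. A per-engine component analysis reports how much each engine
contributes to any cluster.

Kelley penalty (Kelley, Gardner & Sutcliffe 1996): at each level of the
merge tree, the average spread (mean pairwise distance) of the multi-member
clusters is computed, the averages are linearly normalized across levels to
span [1, P-1] (P = pool size), and the penalty at a level with k clusters is
the normalized spread plus k. The level minimizing the penalty balances
tight clusters against their number; ties go to the smaller k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .errors import MatrixError
from .geometry import (AtomSelection, ChainMapping, HEAVY_SELECTION,
                       CA_SELECTION, IDENTITY_MAPPING, common_atom_roster,
                       kabsch_rmsd, kabsch_superpose)
from .structio import PoseRecord, Structure

logger = logging.getLogger(__name__)


@dataclass
class RMSDMatrix:
    """Symmetric all-pairs RMSD (Å) over a labeled pose pool."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixError(f"matrix must be square, got shape {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise MatrixError("label count does not match matrix size")
        if np.isnan(v).any():
            raise MatrixError("matrix contains NaN")
        if not np.allclose(v, v.T, atol=1e-9):
            raise MatrixError("matrix is not symmetric to 1e-9")
        if not np.allclose(np.diag(v), 0.0):
            raise MatrixError("matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise MatrixError("matrix has negative entries")
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class ClusteringResult:
    """Agglomerative merge tree over a pose pool.

    ``assignments_at(k)`` returns the nested partition with k clusters;
    cluster ids are renumbered 1..k in order of first appearance.
    """

    labels: list[str]
    merge_tree: np.ndarray  # scipy linkage matrix
    linkage_method: str

    def assignments_at(self, k: int) -> np.ndarray:
        p = len(self.labels)
        if not 1 <= k <= p:
            raise ValueError(f"k must be in 1..{p}, got {k}")
        raw = cut_tree(self.merge_tree, n_clusters=k).ravel()
        # renumber in order of first appearance for determinism
        order: dict[int, int] = {}
        out = np.empty_like(raw)
        for i, c in enumerate(raw):
            if c not in order:
                order[c] = len(order) + 1
            out[i] = order[c]
        return out


@dataclass
class KelleyProfile:
    """Per-level Kelley penalty and the optimal number of clusters."""

    levels: pd.DataFrame  # columns: k, mean_spread, normalized_spread, penalty
    optimal_k: int
    degenerate: bool = False


@dataclass
class ClusterStats:
    """Per-cluster population, centroid and spread statistics.

    ``table`` columns: cluster, population, centroid, avg_rmsd_to_centroid,
    std_rmsd_to_centroid, rmsd_to_main_centroid. The main cluster is the most
    populated one (ties: smaller average member-centroid RMSD, then smaller
    cluster id); its rmsd_to_main_centroid is 0 by construction.
    """

    table: pd.DataFrame
    main_cluster: int

    @property
    def main_centroid(self) -> str:
        row = self.table[self.table["cluster"] == self.main_cluster]
        return str(row["centroid"].iloc[0])


@dataclass
class ComponentReport:
    """Per-engine membership of one cluster."""

    cluster: int
    population: int
    counts: pd.DataFrame  # columns: engine, count, fraction, percent
    nearest_to_centroid: str


def build_rmsd_matrix(
    pool: Sequence[PoseRecord],
    selection: AtomSelection = HEAVY_SELECTION,
    mapping: ChainMapping = IDENTITY_MAPPING,
    superpose: bool = True,
) -> RMSDMatrix:
    """All-pairs RMSD over the pool on the common atom roster.

    Every pose is reduced to the atoms shared by all poses under the
    selection, so each pair is measured over the same roster. With
    ``superpose=True`` each pair is optimally superposed first.
    """
    if len(pool) < 2:
        raise ValueError("pool must contain at least 2 poses")
    labels = [p.label for p in pool]
    if len(set(labels)) != len(labels):
        raise ValueError("pose labels are not unique")
    structures = [p.structure for p in pool]
    rosters = common_atom_roster(structures, selection)
    coords = [s.coords[idx] for s, idx in zip(structures, rosters)]
    if mapping.permutable_groups:
        # permutation-aware path: go through the full machinery per pair
        subsets = [s.subset(idx) for s, idx in zip(structures, rosters)]
        n = len(pool)
        values = np.zeros((n, n))
        from .geometry import rmsd as _rmsd
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = _rmsd(
                    subsets[i], subsets[j], AtomSelection(mode="all"),
                    mapping, superpose=superpose)
        return RMSDMatrix(labels, values)
    n = len(pool)
    values = np.zeros((n, n))
    centered = [c - c.mean(axis=0) for c in coords]
    for i in range(n):
        for j in range(i + 1, n):
            if superpose:
                _, val = kabsch_rmsd(centered[i], centered[j])
            else:
                d = coords[i] - coords[j]
                val = float(np.sqrt((d * d).sum() / len(d)))
            values[i, j] = values[j, i] = val
    return RMSDMatrix(labels, values)


def cluster(matrix: RMSDMatrix, linkage_method: str = "average") -> ClusteringResult:
    """Hierarchical agglomerative clustering of the RMSD matrix.

    ``linkage_method`` is one of ``average`` (default), ``complete`` or
    ``single``. The merge order is deterministic for a given matrix.
    """
    if linkage_method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    condensed = squareform(matrix.values, checks=False)
    tree = linkage(condensed, method=linkage_method)
    return ClusteringResult(labels=list(matrix.labels), merge_tree=tree,
                            linkage_method=linkage_method)


def kelley(matrix: RMSDMatrix, clustering: ClusteringResult) -> KelleyProfile:
    """Kelley penalty profile over all levels of the merge tree.

    Levels whose clusters are all singletons carry no spread and are
    excluded from the normalization. If every retained level has zero
    spread (e.g. an all-zero matrix) the profile is degenerate and the
    optimum defaults to a single cluster.
    """
    p = len(matrix)
    if p < 3:
        raise ValueError("Kelley profile needs a pool of at least 3 poses")
    v = matrix.values
    rows = []
    for k in range(1, p + 1):
        assign = clustering.assignments_at(k)
        spreads = []
        for c in np.unique(assign):
            members = np.where(assign == c)[0]
            if len(members) < 2:
                continue
            sub = v[np.ix_(members, members)]
            iu = np.triu_indices(len(members), k=1)
            spreads.append(float(sub[iu].mean()))
        if spreads:
            rows.append((k, float(np.mean(spreads))))
    if not rows:
        logger.warning("no multi-member cluster at any level; degenerate profile")
        levels = pd.DataFrame(columns=["k", "mean_spread", "normalized_spread",
                                       "penalty"])
        return KelleyProfile(levels=levels, optimal_k=1, degenerate=True)
    ks = np.array([r[0] for r in rows])
    spreads_arr = np.array([r[1] for r in rows])
    smin, smax = spreads_arr.min(), spreads_arr.max()
    if smax - smin < 1e-12:
        logger.warning("all levels have identical spread; degenerate profile, "
                       "optimal_k = 1")
        norm = np.ones_like(spreads_arr)
        penalty = norm + ks
        levels = pd.DataFrame({"k": ks, "mean_spread": spreads_arr,
                               "normalized_spread": norm, "penalty": penalty})
        return KelleyProfile(levels=levels, optimal_k=1, degenerate=True)
    norm = (spreads_arr - smin) / (smax - smin) * (p - 2) + 1.0
    penalty = norm + ks
    levels = pd.DataFrame({"k": ks, "mean_spread": spreads_arr,
                           "normalized_spread": norm, "penalty": penalty})
    best = levels.loc[levels["penalty"].idxmin()]
    # idxmin returns the first minimum; rows are ordered by increasing k,
    # so ties already resolve to the smaller k
    return KelleyProfile(levels=levels, optimal_k=int(best["k"]))


def cluster_stats(matrix: RMSDMatrix, assignments: np.ndarray) -> ClusterStats:
    """Population, centroid and spread statistics per cluster.

    The centroid of a cluster is the member minimizing the mean RMSD to its
    co-members (ties: lexicographically first label). The main cluster is
    the most populated; ties prefer the tighter (smaller average
    member-centroid RMSD) then the smaller cluster id.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(matrix):
        raise ValueError("assignments length does not match matrix size")
    v = matrix.values
    labels = matrix.labels
    recs = []
    centroid_idx: dict[int, int] = {}
    for c in np.unique(assignments):
        members = np.where(assignments == c)[0]
        if len(members) == 1:
            ci = members[0]
            avg = std = 0.0
        else:
            sub = v[np.ix_(members, members)]
            mean_to_others = sub.sum(axis=1) / (len(members) - 1)
            best = np.lexsort((
                [labels[m] for m in members],
                np.round(mean_to_others, 12),
            ))[0]
            ci = members[best]
            dists = v[ci, members[members != ci]]
            avg = float(dists.mean())
            std = float(dists.std())
        centroid_idx[int(c)] = int(ci)
        recs.append({"cluster": int(c), "population": int(len(members)),
                     "centroid": labels[ci],
                     "avg_rmsd_to_centroid": avg,
                     "std_rmsd_to_centroid": std})
    table = pd.DataFrame(recs)
    main = table.sort_values(
        by=["population", "avg_rmsd_to_centroid", "cluster"],
        ascending=[False, True, True], kind="stable",
    )["cluster"].iloc[0]
    main_ci = centroid_idx[int(main)]
    table["rmsd_to_main_centroid"] = [
        float(v[centroid_idx[int(c)], main_ci]) for c in table["cluster"]
    ]
    return ClusterStats(table=table.reset_index(drop=True), main_cluster=int(main))


def select_final_pose(stats: ClusterStats) -> str:
    """The consensus pose Q: centroid member of the most populated cluster."""
    return stats.main_centroid


def component_analysis(
    assignments: np.ndarray,
    pool: Sequence[PoseRecord],
    cluster_id: int,
    stats: ClusterStats | None = None,
    matrix: RMSDMatrix | None = None,
) -> ComponentReport:
    """Per-engine membership of one cluster.

    Percentages are rounded half-up to integers (raw fractions are kept in
    the table). The nearest-to-centroid label comes from ``stats`` when
    supplied, else it is recomputed from ``matrix``.
    """
    assignments = np.asarray(assignments)
    members = np.where(assignments == cluster_id)[0]
    if len(members) == 0:
        raise ValueError(f"cluster {cluster_id} has no members")
    engines = [pool[i].engine for i in members]
    counts = pd.Series(engines).value_counts()
    pop = int(len(members))
    df = pd.DataFrame({
        "engine": counts.index,
        "count": counts.values,
        "fraction": counts.values / pop,
    })
    df["percent"] = np.floor(df["fraction"] * 100 + 0.5).astype(int)
    if stats is None:
        if matrix is None:
            raise ValueError("need stats or matrix for the centroid label")
        stats = cluster_stats(matrix, assignments)
    row = stats.table[stats.table["cluster"] == cluster_id]
    nearest = str(row["centroid"].iloc[0])
    return ComponentReport(cluster=int(cluster_id), population=pop,
                           counts=df.reset_index(drop=True),
                           nearest_to_centroid=nearest)


def engine_percentages(counts: Sequence[int]) -> list[int]:
    """Half-up integer percentages of per-engine member counts."""
    total = sum(counts)
    if total == 0:
        raise ValueError("empty cluster")
    return [int(np.floor(c / total * 100 + 0.5)) for c in counts]


def compare_to_reference(
    pose: Structure,
    reference: Structure,
    mapping: ChainMapping = IDENTITY_MAPPING,
) -> float:
    """Cα RMSD (Å) of a pose superposed onto a reference complex."""
    return kabsch_superpose(pose, reference, CA_SELECTION, mapping).rmsd


def consensus_pipeline(
    pool: Sequence[PoseRecord],
    selection: AtomSelection = HEAVY_SELECTION,
    mapping: ChainMapping = IDENTITY_MAPPING,
    linkage_method: str = "average",
    superpose: bool = True,
):
    """Matrix -> tree -> Kelley optimum -> stats -> consensus pose Q.

    Returns (matrix, clustering, profile, assignments, stats, q_label).
    """
    matrix = build_rmsd_matrix(pool, selection, mapping, superpose=superpose)
    tree = cluster(matrix, linkage_method)
    profile = kelley(matrix, tree)
    assignments = tree.assignments_at(profile.optimal_k)
    stats = cluster_stats(matrix, assignments)
    q = select_final_pose(stats)
    logger.info("pool=%d optimal_k=%d main_cluster=%d Q=%s",
                len(pool), profile.optimal_k, stats.main_cluster, q)
    return matrix, tree, profile, assignments, stats, q
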