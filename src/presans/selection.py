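"""Restraint-energy scoring, outlier picking, o-RMSD clustering and
final-ensemble selection for rigid-body docking candidates.

The selection protocol operates in two screens.  First, candidates are
ranked by their restraint violation energy E_exp (flat-bottom quadratic
over the distance restraints) and the structures with significantly low
ln(E_exp) are flagged as outliers of a box-and-whisker analysis with a
whisker length of twice the inter-quartile range.  Second, candidates are
scored against the scattering data (consensus fitness), clustered by
orientational RMSD (o-RMSD: superpose on the fixed subunit, measure
backbone RMSD over the mobile subunit) with respect to the best-fitness
structure, and the final ensemble is drawn from the best-ranked cluster,
keeping only members whose fitness beats every member of the second-best
cluster.  The ensemble's centre is the member with the lowest mean
backbone RMSD to all members.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .pre import DistanceRestraint
from .structures import AtomSelection, Structure, superpose

__all__ = [
    "RestraintEnergyRecord",
    "ClusterResult",
    "restraint_energy",
    "flag_low_energy_outliers",
    "orientational_rmsd",
    "cluster_structures",
    "select_final_ensemble",
    "find_center",
]

LN_EPSILON = 1e-12  # guard added to E_exp before taking the logarithm


@dataclasses.dataclass
class RestraintEnergyRecord:
    structure_id: str
    e_exp: float

    @property
    def ln_e(self) -> float:
        return float(np.log(self.e_exp + LN_EPSILON))


@dataclasses.dataclass
class ClusterResult:
    """Cluster labels and selection state for a candidate ensemble."""

    structure_ids: list[str]
    labels: np.ndarray  # per-structure cluster label (int)
    reference_id: str  # best-fitness structure the o-RMSDs refer to
    ormsd_to_reference: np.ndarray  # A
    ranking: list[int] | None = None  # cluster labels, best first
    selected: np.ndarray | None = None  # final-ensemble flags
    center_id: str | None = None

    def members(self, label: int) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == label]


def restraint_energy(structure: Structure, restraints: Sequence[DistanceRestraint],
                     weight: float = 1.0, form: str = "flat-bottom",
                     tail_start: float = 2.0) -> float:
    """Violation energy of a structure against flat-bottom distance restraints.

    Per restraint, the violation v = max(0, d - upper, lower - d) enters
    quadratically, E = sum w * v^2.  ``form='soft-square'`` switches to a
    linear tail beyond ``tail_start`` A of violation (slope continuous),
    which caps the influence of gross violations the way docking codes do.
    """
    if form not in ("flat-bottom", "soft-square"):
        raise ValueError(f"unknown energy form {form!r}")
    e = 0.0
    for r in restraints:
        ia = structure.atom_index(r.chain_a, r.resid_a, r.atom_a)
        ib = structure.atom_index(r.chain_b, r.resid_b, r.atom_b)
        d = float(np.linalg.norm(structure.coords[ia] - structure.coords[ib]))
        v = max(0.0, d - r.upper, r.lower - d)
        if form == "soft-square" and v > tail_start:
            e += weight * (tail_start**2 + 2.0 * tail_start * (v - tail_start))
        else:
            e += weight * v * v
    return e


def flag_low_energy_outliers(records: Sequence[RestraintEnergyRecord],
                             whisker: float = 2.0) -> list[str]:
    """Structures with significantly low ln(E_exp).

    Box-and-whisker rule on ln(E_exp + eps): quartiles by linear
    interpolation, outliers below Q1 - whisker*IQR.  Only the low side is
    reported (low violation energy = good structures).
    """
    if len(records) < 4:
        raise ValueError("need >= 4 records for a quartile-based outlier rule")
    ln_e = np.array([r.ln_e for r in records])
    q1, q3 = np.percentile(ln_e, [25, 75])  # linear interpolation (type 7)
    cut = q1 - whisker * (q3 - q1)
    return [r.structure_id for r, v in zip(records, ln_e) if v < cut]


def orientational_rmsd(a: Structure, b: Structure, reference_chains: Sequence[str],
                       mobile_chains: Sequence[str]) -> float:
    """Backbone RMSD over the mobile chains after superposing on the
    reference chains (no second fit) -- measures the relative orientation
    of the mobile subunit between two poses."""
    ref = set(reference_chains)
    mob = set(mobile_chains)
    if not ref or not mob:
        raise ValueError("both chain sets must be non-empty")
    if ref & mob:
        raise ValueError(f"reference and mobile chain sets overlap: {ref & mob}")
    fit_sel = AtomSelection.backbone(chains=ref)
    rot, trans, _ = superpose(b, a, fit_sel)
    meas_sel = AtomSelection.backbone(chains=mob)
    ib = meas_sel.indices(b)
    ia = meas_sel.indices(a)
    if meas_sel.keys(a) != meas_sel.keys(b):
        raise ValueError("mobile-chain backbone does not pair between structures")
    moved = b.coords[ib] @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - a.coords[ia]) ** 2, axis=1))))


def _gap_clusters_1d(values: np.ndarray, cutoff: float) -> np.ndarray:
    """Single-linkage grouping of scalars: split where a sorted gap > cutoff."""
    order = np.argsort(values, kind="stable")
    labels = np.empty(len(values), dtype=int)
    current = 0
    prev = None
    for idx in order:
        if prev is not None and values[idx] - prev > cutoff:
            current += 1
        labels[idx] = current
        prev = values[idx]
    return labels


def cluster_structures(structures: Sequence[Structure], fitness: Sequence[float],
                       reference_chains: Sequence[str], mobile_chains: Sequence[str],
                       structure_ids: Sequence[str] | None = None,
                       mode: str = "reference", cutoff: float = 5.0) -> ClusterResult:
    """Cluster candidate poses by o-RMSD.

    ``reference`` mode (default): o-RMSD of every structure to the
    best-fitness structure, grouped by 1-D single linkage with a gap
    threshold of ``cutoff`` A.  ``pairwise`` mode: complete-linkage
    hierarchical clustering of the full o-RMSD matrix cut at ``cutoff``.
    Fitness ties break toward the earlier structure id.
    """
    if len(structures) == 0:
        raise ValueError("empty ensemble")
    if len(structures) != len(fitness):
        raise ValueError("fitness must be available for every structure")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("reference", "pairwise"):
        raise ValueError(f"unknown clustering mode {mode!r}")
    ids = [str(i) for i in (structure_ids if structure_ids is not None
                            else range(len(structures)))]
    fit = np.asarray(fitness, float)
    ref_idx = int(np.lexsort((ids, fit))[0])  # argmin fitness, ties by id order

    ormsd = np.array([
        0.0 if i == ref_idx else orientational_rmsd(
            structures[ref_idx], s, reference_chains, mobile_chains)
        for i, s in enumerate(structures)
    ])
    if len(structures) == 1:
        labels = np.zeros(1, dtype=int)
    elif mode == "reference":
        labels = _gap_clusters_1d(ormsd, cutoff)
    else:
        n = len(structures)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = orientational_rmsd(
                    structures[i], structures[j], reference_chains, mobile_chains)
        link = hierarchy.linkage(squareform(mat, checks=False), method="complete")
        labels = hierarchy.fcluster(link, t=cutoff, criterion="distance") - 1
    return ClusterResult(ids, labels, ids[ref_idx], ormsd)


def select_final_ensemble(clusters: ClusterResult, fitness: Sequence[float]) -> ClusterResult:
    """Rank clusters and flag the final ensemble.

    Clusters are ranked by mean member fitness (lower is better; ties go to
    the larger cluster, then to the smaller label).  The final ensemble is
    the subset of the top cluster whose fitness is better than the best
    fitness found anywhere in the second-ranked cluster.  A single cluster
    selects all of its members, with a warning.
    """
    fit = np.asarray(fitness, float)
    if len(fit) != len(clusters.labels):
        raise ValueError("fitness must pair with cluster labels")
    unique = sorted(set(int(l) for l in clusters.labels))
    stats = []
    for lab in unique:
        members = clusters.members(lab)
        stats.append((float(fit[members].mean()), -len(members), lab))
    stats.sort()
    ranking = [lab for _, _, lab in stats]
    selected = np.zeros(len(fit), dtype=bool)
    top = clusters.members(ranking[0])
    if len(ranking) == 1:
        warnings.warn("single cluster: selecting all members", stacklevel=2)
        selected[top] = True
    else:
        second_best = fit[clusters.members(ranking[1])].min()
        for i in top:
            if fit[i] < second_best:
                selected[i] = True
    clusters.ranking = ranking
    clusters.selected = selected
    return clusters


def find_center(structures: Sequence[Structure],
                structure_ids: Sequence[str] | None = None) -> str:
    """Member with the lowest mean backbone RMSD to all members (self included).

    Ties resolve to the earliest id in input order.
    """
    if len(structures) < 2:
        raise ValueError("need >= 2 structures to define a centre")
    ids = [str(i) for i in (structure_ids if structure_ids is not None
                            else range(len(structures)))]
    from .structures import rmsd_between

    sel = AtomSelection.backbone()
    n = len(structures)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = rmsd_between(structures[i], structures[j], sel)
    means = mat.mean(axis=1)
    best = int(np.argmin(means))  # argmin takes the first minimum = earliest id
    return ids[best]
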