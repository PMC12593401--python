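"""Energy–density landscapes, stability ranking, and agreement metrics.

Relative lattice energies are reported in kJ/mol per molecule above the
landscape's global minimum.  Model-vs-reference agreement uses MAE, RMSE,
tie-aware Kendall τ-b over rankings, the fraction of structures whose
relaxed geometry still matches its reference counterpart, and a
configurable-size molecular-cluster RMSD in the spirit of the packing
similarity measures used for crystal-structure comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau

from .constants import EV_TO_KJMOL
from .optimization import MatchTolerances, structures_match
from .nmer_sampling import ShellSpec, molecular_shell
from .structures import CrystalStructure, density

__all__ = [
    "LandscapeEntry",
    "RankingReport",
    "landscape_table",
    "ranking_metrics",
    "relative_reduction",
    "cluster_rmsd",
]


@dataclass(frozen=True)
class LandscapeEntry:
    structure_id: str
    density: float  # g/cm³
    E_rel: float  # kJ/mol per molecule above the global minimum
    rank: int
    space_group: int | None = None


@dataclass(frozen=True)
class RankingReport:
    MAE: float  # kJ/mol
    RMSE: float  # kJ/mol
    kendall_tau: float | None
    matched_fraction: float | None = None  # %
    mean_cluster_rmsd: float | None = None  # Å
    std_cluster_rmsd: float | None = None  # Å

    def __post_init__(self):
        if self.RMSE + 1e-12 < self.MAE or self.MAE < 0:
            raise ValueError("require RMSE >= MAE >= 0")


def landscape_table(structures: list[CrystalStructure],
                    energies_per_molecule: list[float],
                    ids: list[str] | None = None) -> list[LandscapeEntry]:
    """Energy–density landscape entries sorted by relative energy.

    ``energies_per_molecule`` is in eV per molecule; relative energies are
    (E − min E)·96.48533 kJ/mol.  Ties are broken by structure id.
    """
    if not structures:
        raise ValueError("empty landscape")
    if len(structures) != len(energies_per_molecule):
        raise ValueError("structures/energies length mismatch")
    if ids is None:
        ids = [f"s{i:04d}" for i in range(len(structures))]
    e = np.asarray(energies_per_molecule, dtype=float)
    e_rel = (e - e.min()) * EV_TO_KJMOL
    order = sorted(range(len(e)), key=lambda i: (e_rel[i], ids[i]))
    return [LandscapeEntry(ids[i], density(structures[i]), float(e_rel[i]),
                           rank + 1, structures[i].space_group)
            for rank, i in enumerate(order)]


def ranking_metrics(model_E_rel, reference_E_rel,
                    matched_fraction: float | None = None,
                    cluster_rmsds=None) -> RankingReport:
    """MAE/RMSE (kJ/mol), Kendall τ-b, and optional geometric agreement.

    Inputs are paired relative energies for common structures; with fewer
    than two pairs the rank correlation is undefined and reported as None.
    """
    m = np.asarray(model_E_rel, dtype=float)
    r = np.asarray(reference_E_rel, dtype=float)
    if m.shape != r.shape:
        raise ValueError("model/reference length mismatch")
    resid = m - r
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    if len(m) >= 2:
        tau = float(kendalltau(m, r).statistic)
    else:
        tau = None
    mean_rmsd = std_rmsd = None
    if cluster_rmsds is not None and len(cluster_rmsds):
        arr = np.asarray(cluster_rmsds, dtype=float)
        mean_rmsd = float(arr.mean())
        std_rmsd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return RankingReport(mae, rmse, tau, matched_fraction,
                         mean_rmsd, std_rmsd)


def matched_percentage(model_structures, reference_structures,
                       tolerances: MatchTolerances = MatchTolerances()
                       ) -> float:
    """% of paired structures whose geometries still match the reference."""
    if len(model_structures) != len(reference_structures):
        raise ValueError("pairing length mismatch")
    hits = sum(structures_match(a, b, tolerances)
               for a, b in zip(model_structures, reference_structures))
    return 100.0 * hits / len(model_structures)


def relative_reduction(baseline: float, value: float) -> float:
    """100·(baseline − value)/baseline, rounded to one decimal."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (baseline - value) / baseline, 1)


def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of P onto Q."""
    p = P - P.mean(axis=0)
    q = Q - Q.mean(axis=0)
    H = p.T @ q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = p @ R.T - q
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _cluster(structure: CrystalStructure, n_molecules: int,
             exclude_h: bool) -> list[np.ndarray]:
    """Positions of the central molecule and its n−1 nearest neighbors."""
    cutoff = 2.5 * structure.lattice.lengths.max()
    shell = molecular_shell(structure, ShellSpec(0, cutoff))
    center = shell[0]
    rest = sorted(shell[1:], key=lambda m: float(
        np.linalg.norm(m.centroid - center.centroid)))
    mols = [center] + rest[: n_molecules - 1]
    out = []
    for m in mols:
        pos = m.positions
        if exclude_h:
            keep = [i for i, s in enumerate(m.symbols) if s != "H"]
            pos = pos[keep]
        out.append(pos)
    return out


def cluster_rmsd(struct_a: CrystalStructure, struct_b: CrystalStructure,
                 n_molecules: int = 15, exclude_hydrogens: bool = True
                 ) -> float:
    """Molecular-cluster RMSD between two crystal packings (Å).

    A cluster of ``n_molecules`` around a central molecule is built in each
    structure; the second cluster is pre-aligned on its central molecule,
    molecules are matched greedily by centroid distance, and the RMSD of the
    optimal rigid superposition over all matched atoms is returned.  Both
    directions are computed and the larger value reported.  Unequal shell
    sizes are compared over the common count.
    """

    def match_and_rmsd(ca, cb_rot):
        """Greedy centroid pairing followed by full-cluster superposition."""
        k = len(ca)
        cent_a = [m.mean(axis=0) for m in ca]
        cent_b = [m.mean(axis=0) for m in cb_rot]
        unused = list(range(k))
        pairs = []
        for i in range(k):
            j = min(unused, key=lambda jj: float(
                np.linalg.norm(cent_a[i] - cent_b[jj])))
            unused.remove(j)
            if ca[i].shape == cb_rot[j].shape:
                pairs.append((i, j))
        P = np.vstack([ca[i] for i, _ in pairs])
        Q = np.vstack([cb_rot[j] for _, j in pairs])
        return _kabsch_rmsd(P, Q), pairs

    def principal_axes(cloud):
        x = cloud - cloud.mean(axis=0)
        _, vecs = np.linalg.eigh(x.T @ x)
        v = vecs[:, ::-1]  # descending variance
        if np.linalg.det(v) < 0:
            v[:, -1] *= -1
        return v

    def one_way(sa, sb):
        ca = _cluster(sa, n_molecules, exclude_hydrogens)
        cb = _cluster(sb, n_molecules, exclude_hydrogens)
        k = min(len(ca), len(cb))
        ca, cb = ca[:k], cb[:k]
        all_a = np.vstack(ca)
        all_b = np.vstack(cb)
        com_a = all_a.mean(axis=0)
        com_b = all_b.mean(axis=0)
        va = principal_axes(all_a)
        vb = principal_axes(all_b)
        best = math.inf
        # candidate orientations: proper sign combinations of the principal
        # axes (degenerate central molecules make single-molecule alignment
        # ambiguous, so the whole cluster frames the trial rotations)
        for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
            R = va @ np.diag(signs) @ vb.T
            cb_rot = [(m - com_b) @ R.T + com_a for m in cb]
            rmsd, pairs = match_and_rmsd(ca, cb_rot)
            # refine: re-superpose on the matched atoms, then re-match
            for _ in range(3):
                P = np.vstack([ca[i] for i, _ in pairs])
                Q = np.vstack([cb_rot[j] for _, j in pairs])
                p0, q0 = P.mean(axis=0), Q.mean(axis=0)
                H = (Q - q0).T @ (P - p0)
                U, _, Vt = np.linalg.svd(H)
                d = np.sign(np.linalg.det(Vt.T @ U.T))
                Rf = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
                cb_rot = [(m - q0) @ Rf.T + p0 for m in cb_rot]
                new_rmsd, pairs = match_and_rmsd(ca, cb_rot)
                if new_rmsd >= rmsd - 1e-12:
                    rmsd = min(rmsd, new_rmsd)
                    break
                rmsd = new_rmsd
            best = min(best, rmsd)
        return best

    return max(one_way(struct_a, struct_b), one_way(struct_b, struct_a))
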