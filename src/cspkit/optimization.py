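"""Crystal relaxation, symmetrization, and duplicate removal.

Relaxation is a BFGS with backtracking line search over cell vectors and
fractional coordinates simultaneously; the gradient with respect to the
cell is obtained from the stress tensor (dE/dh = h⁻ᵀ·V·σ), so forces and
stress share one quasi-Newton step.  A fixed-volume variable-cell mode
renormalizes the cell determinant exactly at every evaluation and projects
the volume-changing component out of the gradient, as required by the
quasi-harmonic volume scan.

Symmetrization searches for lattice-compatible integer rotations plus
translations that map the structure onto itself within ``symprec``, averages
sites over the found orbit, and identifies the space group by matching the
operator set against the tabulated groups (falling back to P1).

Deduplication Niggli-reduces both lattices, compares lengths and angles,
and then searches origin translations with species-aware optimal site
assignment; two structures match when the best site RMS is below ``stol``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.optimize import linear_sum_assignment

from .structures import CrystalStructure, Lattice, min_image_vectors

__all__ = [
    "RelaxSettings",
    "RelaxResult",
    "MatchTolerances",
    "relax",
    "symmetrize",
    "niggli_reduce",
    "structures_match",
    "deduplicate",
]


@dataclass
class RelaxSettings:
    rms_force_tol: float = 0.001  # eV/Å
    max_steps: int = 500
    mode: str = "variable_cell"  # | fixed_volume_variable_cell | fixed_cell
    external_pressure: float = 0.0  # eV/Å³

    def __post_init__(self):
        if self.rms_force_tol <= 0:
            raise ValueError("rms_force_tol must be positive")
        if self.mode not in ("variable_cell", "fixed_volume_variable_cell",
                             "fixed_cell"):
            raise ValueError(f"unknown relax mode {self.mode!r}")


@dataclass
class RelaxResult:
    structure: CrystalStructure
    energy: float
    converged: bool
    n_steps: int
    rms_force: float
    energy_trace: list[float] = field(default_factory=list)


def _pack(cell, frac, mode):
    if mode == "fixed_cell":
        return frac.reshape(-1)
    return np.concatenate([cell.reshape(-1), frac.reshape(-1)])


def _objective(calc, species, template, mode, v0, pressure):
    """Return f(x) -> (value, gradient, diagnostics dict)."""

    def fun(x):
        if mode == "fixed_cell":
            cell = template.lattice.cell
            frac = x.reshape(-1, 3)
        else:
            cell = x[:9].reshape(3, 3)
            frac = x[9:].reshape(-1, 3)
        scale = 1.0
        if mode == "fixed_volume_variable_cell":
            det = np.linalg.det(cell)
            scale = (v0 / det) ** (1.0 / 3.0)
            cell = cell * scale
        lat = Lattice(cell)
        s = CrystalStructure(lat, species, np.mod(frac, 1.0))
        energy, forces = calc.energy_forces(s)
        vol = lat.volume
        value = energy + pressure * vol
        grad_frac = (-forces) @ cell.T
        diag = {"rms_force": float(np.sqrt(np.mean(forces**2))),
                "structure": s, "energy": energy}
        if mode == "fixed_cell":
            return value, grad_frac.reshape(-1), diag
        sigma = calc.stress(s) + pressure * np.eye(3)
        g_cell = vol * np.linalg.inv(cell).T @ sigma  # dE/dh, eV/Å
        if mode == "fixed_volume_variable_cell":
            # chain rule through the determinant renormalization, which
            # removes the volume-changing gradient component exactly
            g_cell = scale * g_cell - (scale / 3.0) * float(
                np.sum(g_cell * cell)) * np.linalg.inv(cell).T
        diag["g_cell_rms"] = float(np.sqrt(np.mean(g_cell**2)))
        return value, np.concatenate([g_cell.reshape(-1),
                                      grad_frac.reshape(-1)]), diag

    return fun


def relax(structure: CrystalStructure, calculator,
          settings: RelaxSettings = RelaxSettings()) -> RelaxResult:
    """Relax a crystal with BFGS + backtracking line search.

    Converges when the RMS atomic force is at or below ``rms_force_tol``
    (and, in cell modes, the RMS cell-vector gradient as well).  Accepted
    steps never increase the objective; in ``fixed_volume_variable_cell``
    mode the cell determinant is preserved exactly while the cell shape and
    positions relax.  External pressure adds +p·V to the objective.
    """
    mode = settings.mode
    v0 = structure.lattice.volume
    species = list(structure.species)
    fun = _objective(calculator, species, structure, mode, v0,
                     settings.external_pressure)
    x = _pack(structure.lattice.cell, structure.frac_coords, mode)
    f0, g0, diag = fun(x)
    trace = [diag["energy"]]

    def converged_now(d):
        ok = d["rms_force"] <= settings.rms_force_tol
        if mode != "fixed_cell":
            # the cell is the slow degree of freedom; a tighter criterion on
            # its gradient keeps relaxed lattice constants reproducible
            ok = ok and d.get("g_cell_rms", 0.0) <= 0.1 * settings.rms_force_tol
        return ok

    n = len(x)
    H = np.eye(n)  # inverse-Hessian approximation
    steps = 0
    converged = converged_now(diag)
    while not converged and steps < settings.max_steps:
        p = -H @ g0
        if p @ g0 > 0:
            p = -g0
            H = np.eye(n)
        # backtracking Armijo line search
        alpha = 1.0
        pnorm = np.linalg.norm(p)
        if pnorm > 0.5 * math.sqrt(n):  # cap the raw step length
            alpha = 0.5 * math.sqrt(n) / pnorm
        accepted = False
        for _ in range(30):
            x_new = x + alpha * p
            try:
                f1, g1, d1 = fun(x_new)
            except Exception:
                alpha *= 0.25
                continue
            if f1 <= f0 + 1e-4 * alpha * (g0 @ p):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            if not np.array_equal(H, np.eye(n)):
                H = np.eye(n)  # curvature estimate went bad; restart steepest
                continue
            break
        s = x_new - x
        yv = g1 - g0
        sy = s @ yv
        if sy > 1e-12:
            rho = 1.0 / sy
            I = np.eye(n)
            H = (I - rho * np.outer(s, yv)) @ H @ (I - rho * np.outer(yv, s)) \
                + rho * np.outer(s, s)
        x, f0, g0, diag = x_new, f1, g1, d1
        trace.append(diag["energy"])
        steps += 1
        converged = converged_now(diag)

    out = diag["structure"].copy()
    out.Z = structure.Z
    out.space_group = structure.space_group
    out.molecule_of_site = structure.molecule_of_site
    out.site_charges = structure.site_charges
    return RelaxResult(out, diag["energy"], converged, steps,
                       diag["rms_force"], trace)


# ------------------------------------------------------------- symmetrize


def _lattice_rotations(cell: np.ndarray, tol: float = 1e-3):
    """Integer fractional matrices W (entries −1..1) preserving the metric."""
    G = cell @ cell.T
    rots = []
    for entries in itertools.product((-1, 0, 1), repeat=9):
        W = np.array(entries).reshape(3, 3)
        if abs(round(np.linalg.det(W))) != 1:
            continue
        if np.allclose(W @ G @ W.T, G, atol=tol * np.abs(G).max()):
            rots.append(W)
    return rots


def _find_ops(structure: CrystalStructure, symprec: float):
    """Symmetry operations (W, w) mapping the structure onto itself."""
    frac = structure.frac_coords
    species = structure.species
    lat = structure.lattice
    n = len(frac)
    ops = []
    i0 = 0
    cands = [j for j in range(n) if species[j] == species[i0]]
    for W in _lattice_rotations(lat.cell):
        xf = frac @ W.T
        for j in cands:
            w = frac[j] - xf[i0]
            new = np.mod(xf + w, 1.0)
            # map each transformed site to an original site
            perm = np.full(n, -1)
            ok = True
            for a in range(n):
                d = new[a] - frac
                vec = min_image_vectors(lat, d)
                dist = np.linalg.norm(vec, axis=1)
                dist[[b for b in range(n) if species[b] != species[a]]] = np.inf
                b = int(np.argmin(dist))
                if dist[b] > symprec or b in perm[:a][perm[:a] >= 0]:
                    ok = False
                    break
                perm[a] = b
            if ok and len(set(perm)) == n:
                ops.append((W, np.mod(w, 1.0), perm))
    return ops


def _identify_group(ops, origin_candidates):
    """Match the found operator set against tabulated space groups."""
    best = None
    for shift in origin_candidates:
        gops = []
        valid = True
        for W, w, _ in ops:
            w2 = np.mod(w + W @ shift - shift, 1.0)
            tr = np.round(w2 * 24).astype(int)
            if np.max(np.abs(w2 * 24 - tr)) > 0.05 * 24:
                valid = False
                break
            op = gemmi.Op()
            op.rot = (np.array([[int(x) for x in row] for row in W]) * 24).tolist()
            op.tran = [int(t) % 24 for t in tr]
            gops.append(op)
        if not valid:
            continue
        try:
            sg = gemmi.find_spacegroup_by_ops(gemmi.GroupOps(gops))
        except Exception:
            sg = None
        if sg is not None and (best is None or sg.number > best):
            best = sg.number
    return best if best is not None else 1


def symmetrize(structure: CrystalStructure, symprec: float = 0.2
               ) -> tuple[int, CrystalStructure]:
    """Detect the space group within ``symprec`` and symmetrize the sites.

    Sites are averaged over the orbit of the detected operations, so the
    result is exactly invariant under them (idempotent).  If the operator
    set cannot be matched to a tabulated group, P1 (1) is reported while the
    site averaging still applies.
    """
    ops = _find_ops(structure, symprec)
    frac = structure.frac_coords
    lat = structure.lattice
    n = len(frac)
    acc = np.zeros_like(frac)
    for W, w, perm in ops:
        Winv = np.linalg.inv(W)
        for i in range(n):
            cand = Winv @ (frac[perm[i]] - w)
            d = cand - frac[i]
            acc[i] += frac[i] + (d - np.round(d))
    sym_frac = np.mod(acc / len(ops), 1.0)

    dev = np.linalg.norm(
        min_image_vectors(lat, sym_frac - frac), axis=1)
    if dev.max() > symprec:  # averaging drifted too far; keep input
        sym_frac = frac

    origin_candidates = [np.zeros(3)]
    for W, w, _ in ops:
        if np.array_equal(W, -np.eye(3, dtype=int)):
            origin_candidates.append(w / 2.0)
    origin_candidates.extend(sym_frac[: min(n, 4)])
    number = _identify_group(ops, origin_candidates)

    out = structure.copy()
    out.frac_coords = sym_frac
    out.space_group = int(number)
    return int(number), out


# ---------------------------------------------------------- lattice reduction


def niggli_reduce(lattice: Lattice, eps: float = 1e-5,
                  max_iter: int = 200) -> Lattice:
    """Krivy–Gruber Niggli reduction of a lattice (canonical short cell)."""
    a_v, b_v, c_v = [np.array(v, dtype=float) for v in lattice.cell]

    def params():
        A = a_v @ a_v
        B = b_v @ b_v
        C = c_v @ c_v
        xi = 2 * (b_v @ c_v)
        eta = 2 * (a_v @ c_v)
        zeta = 2 * (a_v @ b_v)
        return A, B, C, xi, eta, zeta

    for _ in range(max_iter):
        A, B, C, xi, eta, zeta = params()
        # A1
        if A > B + eps or (abs(A - B) < eps and abs(xi) > abs(eta) + eps):
            a_v, b_v = b_v.copy(), a_v.copy()
            a_v, b_v = -a_v, -b_v
            continue
        # A2
        if B > C + eps or (abs(B - C) < eps and abs(eta) > abs(zeta) + eps):
            b_v, c_v = c_v.copy(), b_v.copy()
            b_v, c_v = -b_v, -c_v
            continue
        # A3/A4: fix signs of xi, eta, zeta
        pos = sum(1 for t in (xi, eta, zeta) if t > eps)
        neg_or_zero = all(t <= eps for t in (xi, eta, zeta))
        if xi * eta * zeta > 0 or pos == 3:
            i = 1.0 if xi > -eps else -1.0
            j = 1.0 if eta > -eps else -1.0
            k = 1.0 if zeta > -eps else -1.0
            a_v, b_v, c_v = i * a_v, j * b_v, k * c_v
        else:
            signs = [1.0, 1.0, 1.0]
            if xi > eps:
                signs[0] = -1.0
            if eta > eps:
                signs[1] = -1.0
            if zeta > eps:
                signs[2] = -1.0
            if np.prod(signs) < 0:
                if abs(xi) < eps:
                    signs[0] = -1.0
                elif abs(eta) < eps:
                    signs[1] = -1.0
                elif abs(zeta) < eps:
                    signs[2] = -1.0
            a_v = a_v * signs[1] * signs[2]
            b_v = b_v * signs[0] * signs[2]
            c_v = c_v * signs[0] * signs[1]
        A, B, C, xi, eta, zeta = params()
        # A5
        if abs(xi) > B + eps or (abs(xi - B) < eps and 2 * eta < zeta - eps) \
                or (abs(xi + B) < eps and zeta < -eps):
            c_v = c_v - np.sign(xi) * b_v
            continue
        # A6
        if abs(eta) > A + eps or (abs(eta - A) < eps and 2 * xi < zeta - eps) \
                or (abs(eta + A) < eps and zeta < -eps):
            c_v = c_v - np.sign(eta) * a_v
            continue
        # A7
        if abs(zeta) > A + eps or (abs(zeta - A) < eps and 2 * xi < eta - eps) \
                or (abs(zeta + A) < eps and eta < -eps):
            b_v = b_v - np.sign(zeta) * a_v
            continue
        # A8
        if xi + eta + zeta + A + B < -eps or \
                (abs(xi + eta + zeta + A + B) < eps and 2 * (A + eta) + zeta > eps):
            c_v = c_v + a_v + b_v
            continue
        break
    cell = np.array([a_v, b_v, c_v])
    if np.linalg.det(cell) < 0:
        cell = -cell
    return Lattice(cell)


# --------------------------------------------------------------- matching


@dataclass
class MatchTolerances:
    stol: float = 0.2  # Å, site RMS
    ltol: float = 0.2  # fractional length tolerance
    angle_tol: float = 5.0  # degrees
    symprec: float = 0.2  # Å, used by symmetrization upstream

    def __post_init__(self):
        if min(self.stol, self.ltol, self.angle_tol, self.symprec) <= 0:
            raise ValueError("tolerances must be positive")


def _site_rms(struct_a: CrystalStructure, struct_b: CrystalStructure,
              tols: MatchTolerances) -> float | None:
    """Best species-aware site RMS of B onto A over origin translations."""
    lat = struct_a.lattice
    fa, fb = struct_a.frac_coords, struct_b.frac_coords
    spa = np.array(struct_a.species)
    spb = np.array(struct_b.species)
    best = None
    anchors = [j for j in range(len(fb)) if spb[j] == spa[0]]
    for j0 in anchors:
        t = fa[0] - fb[j0]
        shifted = fb + t
        for _ in range(3):  # translation refinement passes
            total = np.zeros(3)
            sq = 0.0
            count = 0
            pairs = []
            for sp in np.unique(spa):
                ia = np.flatnonzero(spa == sp)
                ib = np.flatnonzero(spb == sp)
                if len(ia) != len(ib):
                    return None
                d = shifted[ib][None, :, :] - fa[ia][:, None, :]
                vec = min_image_vectors(lat, d)
                cost = np.linalg.norm(vec, axis=-1)
                ri, ci = linear_sum_assignment(cost)
                for r, c in zip(ri, ci):
                    pairs.append(vec[r, c])
            pairs = np.asarray(pairs)
            mean = pairs.mean(axis=0)
            shifted = shifted - mean @ np.linalg.inv(lat.cell)
            sq = float(np.mean(np.sum((pairs - mean) ** 2, axis=1)))
        rms = math.sqrt(sq)
        if best is None or rms < best:
            best = rms
        if best <= tols.stol * 0.25:
            break
    return best


def structures_match(a: CrystalStructure, b: CrystalStructure,
                     tols: MatchTolerances = MatchTolerances()) -> bool:
    """True if a and b describe the same packing within the tolerances."""
    if sorted(a.species) != sorted(b.species):
        return False
    ra = niggli_reduce(a.lattice)
    rb = niggli_reduce(b.lattice)
    la, lb = np.sort(ra.lengths), np.sort(rb.lengths)
    if np.any(np.abs(la - lb) / la > tols.ltol):
        return False
    aa, ab = np.sort(ra.angles), np.sort(rb.angles)
    if np.any(np.abs(aa - ab) > tols.angle_tol):
        return False
    rms = _site_rms(a, b, tols)
    if rms is None:
        rms_rev = None
    else:
        rms_rev = _site_rms(b, a, tols)
    if rms is None or rms_rev is None:
        return False
    return max(rms, rms_rev) <= tols.stol


def deduplicate(structures: list[CrystalStructure],
                tolerances: MatchTolerances = MatchTolerances(),
                energies: list[float] | None = None):
    """Cluster structures by pairwise matching; pick one representative each.

    Representatives are the lowest-energy member of each cluster when
    energies are supplied, else the first seen.  Returns (representatives,
    cluster_map) where cluster_map[i] is the cluster index of input i.
    """
    if not structures:
        raise ValueError("no structures to deduplicate")
    n = len(structures)
    cluster = np.full(n, -1)
    reps: list[int] = []
    for i in range(n):
        for ci, r in enumerate(reps):
            if structures_match(structures[i], structures[r], tolerances):
                cluster[i] = ci
                break
        else:
            cluster[i] = len(reps)
            reps.append(i)
    if energies is not None:
        energies = np.asarray(energies, dtype=float)
        reps = [int(min(np.flatnonzero(cluster == ci),
                        key=lambda k: energies[k]))
                for ci in range(len(reps))]
    return [structures[r] for r in reps], cluster.tolist()
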