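"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — plain Python loops, direct formulas,
grid searches — and shares no code path with the production implementations
it validates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


# -- clustering -------------------------------------------------------------


def naive_agglomerative(values, k: int, linkage: str) -> set[frozenset[int]]:
    """O(N^3) bottom-up agglomeration, recomputing every linkage from scratch.

    Ties on the merge distance resolve to the first (i, j) pair with clusters
    kept sorted by minimum member index.  Returns the partition as a set of
    frozen member-index sets.
    """
    values = np.asarray(values, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(values))]

    def link(a: list[int], b: list[int]) -> float:
        pairwise = [values[i][j] for i in a for j in b]
        if linkage == "single":
            return min(pairwise)
        if linkage == "complete":
            return max(pairwise)
        return sum(pairwise) / len(pairwise)

    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = link(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
        clusters.sort(key=lambda c: c[0])
    return {frozenset(c) for c in clusters}


def naive_agglomerative_trace(values, linkage: str) -> dict[int, set[frozenset[int]]]:
    """Partitions at every K from one naive agglomeration (same rules as above)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    clusters: list[list[int]] = [[i] for i in range(n)]

    def link(a: list[int], b: list[int]) -> float:
        pairwise = [values[i][j] for i in a for j in b]
        if linkage == "single":
            return min(pairwise)
        if linkage == "complete":
            return max(pairwise)
        return sum(pairwise) / len(pairwise)

    trace = {n: {frozenset(c) for c in clusters}}
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = link(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
        clusters.sort(key=lambda c: c[0])
        trace[len(clusters)] = {frozenset(c) for c in clusters}
    return trace


def medoid_by_enumeration(values, members: list[int]) -> int:
    """Member index minimizing the summed distance to its co-members."""
    values = np.asarray(values, dtype=float)
    best, best_sum = None, None
    for m in members:
        s = sum(values[m][o] for o in members)
        if best_sum is None or s < best_sum:
            best, best_sum = m, s
    return best


# -- superposition ----------------------------------------------------------


def svd_superpose(P: np.ndarray, Q: np.ndarray):
    """Textbook Kabsch via numpy SVD with explicit reflection correction."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return R, t


def plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def grid_search_min_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD over rotations found by a refined Euler-angle grid search."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def best_on(alphas, betas, gammas):
        angles = np.stack(np.meshgrid(alphas, betas, gammas, indexing="ij"), -1).reshape(-1, 3)
        mats = Rotation.from_euler("zyx", angles).as_matrix()
        moved = np.einsum("mij,nj->mni", mats, Pc)
        rms = np.sqrt(((moved - Qc) ** 2).sum(-1).mean(-1))
        i = int(np.argmin(rms))
        return float(rms[i]), angles[i]

    step = np.deg2rad(15.0)
    _, centre = best_on(
        np.arange(-np.pi, np.pi, step),
        np.arange(-np.pi / 2, np.pi / 2 + 1e-9, step),
        np.arange(-np.pi, np.pi, step),
    )
    for width, n in ((np.deg2rad(16.0), 33), (np.deg2rad(1.0), 41)):
        grids = [np.linspace(c - width, c + width, n) for c in centre]
        value, centre = best_on(*grids)
    return value


# -- clashes ----------------------------------------------------------------


def brute_force_clash_count(structure, radii, fraction, chain_pair=None, backbone=True):
    """All-pairs clash count with explicit loops; no spatial indexing."""
    entries = []
    for c_i, chain in enumerate(structure.chains):
        for r_i, res in enumerate(chain.residues):
            atoms = res.backbone() if backbone else res.atoms
            for a in atoms:
                entries.append((c_i, chain.id, r_i, a))
    count = 0
    for x in range(len(entries)):
        for y in range(x + 1, len(entries)):
            ci, cid_i, ri, ai = entries[x]
            cj, cid_j, rj, aj = entries[y]
            if ci == cj and abs(ri - rj) <= 1:
                continue
            if chain_pair is not None and {cid_i, cid_j} != set(chain_pair):
                continue
            threshold = fraction * (radii.radius(ai.element) + radii.radius(aj.element))
            if float(np.linalg.norm(ai.coord - aj.coord)) < threshold:
                count += 1
    return count


# -- contacts and CAPRI -----------------------------------------------------


def brute_force_contacts(structure, receptor_chains, ligand_chains, cutoff):
    """All-pairs residue contact enumeration across the partition."""
    contacts = set()
    for rc in receptor_chains:
        for res_r in structure.chain(rc).residues:
            for lc in ligand_chains:
                for res_l in structure.chain(lc).residues:
                    hit = any(
                        np.linalg.norm(a.coord - b.coord) <= cutoff
                        for a in res_r.atoms
                        for b in res_l.atoms
                    )
                    if hit:
                        contacts.add((res_r.key, res_l.key))
    return frozenset(contacts)


CAPRI_RULES = (
    ("high", 0.5, 1.0, 1.0),
    ("medium", 0.3, 5.0, 2.0),
    ("acceptable", 0.1, 10.0, 4.0),
)


def capri_class_by_table(fnat, lrmsd, irmsd) -> str:
    """Decision-table lookup: the best rule whose three thresholds are all met."""
    satisfied = [
        name
        for name, fmin, lmax, imax in CAPRI_RULES
        if fnat >= fmin and (lrmsd <= lmax or irmsd <= imax)
    ]
    return satisfied[0] if satisfied else "incorrect"


# -- misc -------------------------------------------------------------------


def pearson_by_formula(pairs) -> float:
    """Pearson r from the raw covariance/sd formula, no library call."""
    arr = np.asarray(pairs, float)
    x, y = arr[:, 0], arr[:, 1]
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def random_rigid_transform(rng: np.random.Generator, scale: float = 30.0):
    """A uniformly random proper rotation and a translation of magnitude ~scale."""
    R = Rotation.random(random_state=int(rng.integers(2**31 - 1))).as_matrix()
    t = rng.uniform(-scale, scale, size=3)
    return R, t
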