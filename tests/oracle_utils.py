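"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own search/cluster code paths:
correspondence enumeration by exhaustive injection, consensus by pairwise
cluster-and-count, AUC by Mann-Whitney pair counting, hydrogen-bond /
contact detection by a flat all-pairs scan.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from phoreseek._geometry import kabsch
from phoreseek.errors import DegenerateAlignmentError


def enumerate_mappings_bruteforce(model, conformer, settings):
    """All maximal kind- and distance-consistent injections, exhaustively."""
    mpos = model.positions()
    cpos = np.array([f.position for f in conformer])
    tol = np.array([f.tolerance for f in model.features]) * settings.tolerance_scale
    kinds_m = model.kinds()
    kinds_c = [f.kind for f in conformer]

    def consistent(pairs):
        for (i, j), (k, l) in itertools.combinations(pairs, 2):
            dm = np.linalg.norm(mpos[i] - mpos[k])
            dc = np.linalg.norm(cpos[j] - cpos[l])
            if abs(dm - dc) > tol[i] + tol[k]:
                return False
        return True

    n_m, n_c = len(kinds_m), len(kinds_c)
    all_consistent = set()
    for size in range(1, min(n_m, n_c) + 1):
        for m_sub in itertools.combinations(range(n_m), size):
            for c_perm in itertools.permutations(range(n_c), size):
                pairs = tuple(sorted(zip(m_sub, c_perm)))
                if any(kinds_m[i] != kinds_c[j] for i, j in pairs):
                    continue
                if consistent(pairs):
                    all_consistent.add(pairs)
    maximal = [
        p
        for p in all_consistent
        if not any(q != p and set(p) < set(q) for q in all_consistent)
    ]
    return sorted(
        p for p in maximal if len(p) >= settings.min_required_features
    )


def best_match_bruteforce(model, conformer, settings):
    """Best (score, -rmsd) over every maximal mapping, via exhaustive search."""
    best = None
    for mapping in enumerate_mappings_bruteforce(model, conformer, settings):
        P = np.array([model.features[i].position for i, _ in mapping])
        Q = np.array([conformer[j].position for _, j in mapping])
        try:
            R, t, rmsd = kabsch(P, Q)
        except DegenerateAlignmentError:
            continue
        moved = Q @ R.T + t
        d = np.linalg.norm(moved - P, axis=1)
        tols = np.array([model.features[i].tolerance for i, _ in mapping])
        valid = d <= tols * settings.tolerance_scale
        nv = int(valid.sum())
        if nv:
            score = nv - float(np.sqrt((d[valid] ** 2).mean())) / float(tols[valid].mean())
        else:
            score = float("-inf")
        key = (score, -rmsd)
        if best is None or key > best[0]:
            best = (key, mapping, nv)
    return best  # ((score, -rmsd), mapping, n_valid) or None


def overlay_rmsd_bruteforce(model, reference):
    """Minimum superposition RMSD over all maximal same-kind assignments."""
    kinds = sorted(set(model.kinds()) & set(reference.kinds()))
    per_kind = []
    for k in kinds:
        mi = [i for i, f in enumerate(model.features) if f.kind == k]
        ri = [i for i, f in enumerate(reference.features) if f.kind == k]
        size = min(len(mi), len(ri))
        opts = [
            tuple(zip(ms, rp))
            for ms in itertools.combinations(mi, size)
            for rp in itertools.permutations(ri, size)
        ]
        per_kind.append(opts)
    best = None
    for combo in itertools.product(*per_kind):
        mapping = [p for grp in combo for p in grp]
        if len(mapping) < 3:
            continue
        P = np.array([reference.features[j].position for _, j in mapping])
        Q = np.array([model.features[i].position for i, _ in mapping])
        try:
            _, _, rmsd = kabsch(P, Q)
        except DegenerateAlignmentError:
            continue
        if best is None or rmsd < best:
            best = rmsd
    return best


def consensus_count_bruteforce(feature_sets, merge_radius):
    """Pairwise single-pass clustering: how many distinct source models share
    each feature site.  ``feature_sets`` is a list (per model) of
    (kind, position) lists.  Returns a list of (kind, n_distinct_models)."""
    items = [
        (kind, np.asarray(pos, float), src)
        for src, feats in enumerate(feature_sets)
        for kind, pos in feats
    ]
    clusters: list[list] = []
    for kind, pos, src in sorted(items, key=lambda x: (x[0], tuple(np.round(x[1], 6)), x[2])):
        for cl in clusters:
            if cl[0] != kind:
                continue
            centroid = np.mean([p for _, p, _ in cl[1]], axis=0)
            if np.linalg.norm(pos - centroid) <= merge_radius:
                cl[1].append((kind, pos, src))
                break
        else:
            clusters.append([kind, [(kind, pos, src)]])
    return [(cl[0], len({s for _, _, s in cl[1]})) for cl in clusters]


def auc_mannwhitney(scores, labels):
    """AUC as the Mann-Whitney pair statistic with ties counted 1/2."""
    pos = [scores[i] for i in scores if labels[i] == "active"]
    neg = [scores[i] for i in scores if labels[i] != "active"]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def detect_bruteforce(structure, selector, rules):
    """Flat all-pairs scan re-deriving the (kind, residue) contact set.

    Implements the same thresholds with independent code: for every ligand
    atom x protein atom pair (or ring pair / charge-center pair), test the
    rule directly and collect (kind, protein residue) identities.
    """
    from phoreseek import interactions as ia

    lig = [a for a in structure.atoms if selector(a)]
    prot = [a for a in structure.atoms if not selector(a)]
    found = set()

    lig_h = [a for a in lig if a.element == "H"]

    def attached_h(atom):
        return [
            h
            for h in lig_h
            if np.linalg.norm(h.position - atom.position) < 1.3
        ]

    residues = {}
    for a in prot:
        residues.setdefault((a.chain_id, a.residue_name, a.residue_number), []).append(a)

    for reskey, res_atoms in residues.items():
        resname = reskey[1]
        acc_names = {"O", "OXT"} | set(ia.SIDECHAIN_ACCEPTORS.get(resname, ()))
        don_names = {"N"} | set(ia.SIDECHAIN_DONORS.get(resname, ()))
        for la in lig:
            if la.element not in ("N", "O"):
                continue
            hs = attached_h(la)
            for pa in res_atoms:
                d = np.linalg.norm(la.position - pa.position)
                if d > rules.hbond_heavy_dist_max:
                    continue
                if pa.name in acc_names and pa.element in ("N", "O") and hs:
                    ang = max(_angle(la.position, h.position, pa.position) for h in hs)
                    if ang >= rules.hbond_angle_min:
                        found.add(("HBOND_LIG_DONOR", reskey))
                if pa.name in don_names and pa.element in ("N", "O") and la.formal_charge <= 0:
                    p_hs = [
                        h
                        for h in res_atoms
                        if h.element == "H"
                        and np.linalg.norm(h.position - pa.position) < 1.3
                    ]
                    if p_hs:
                        ang = max(
                            _angle(pa.position, h.position, la.position) for h in p_hs
                        )
                        if ang >= rules.hbond_angle_min:
                            found.add(("HBOND_LIG_ACCEPTOR", reskey))
                    else:
                        found.add(("HBOND_LIG_ACCEPTOR", reskey))
        # hydrophobic: ligand C (only C/H neighbors, non-ring) vs template C
        apolar_names = ia.APOLAR_CARBONS.get(resname, frozenset())
        for la in lig:
            if la.element != "C":
                continue
            nbrs = [
                b
                for b in lig
                if b is not la and np.linalg.norm(b.position - la.position) < 1.9
            ]
            if any(b.element not in ("C", "H") for b in nbrs):
                continue
            if _in_ring(la, lig):
                continue
            for pa in res_atoms:
                if pa.name in apolar_names and pa.element == "C":
                    if np.linalg.norm(la.position - pa.position) <= rules.hydrophobic_dist_max:
                        found.add(("HYDROPHOBIC", reskey))
        # ionic
        for table, sign in ((ia.NEGATIVE_CENTERS, -1), (ia.POSITIVE_CENTERS, +1)):
            names = table.get(resname)
            if not names:
                continue
            pts = [a.position for a in res_atoms if a.name in names]
            if not pts:
                continue
            center = np.mean(pts, axis=0)
            for la in lig:
                if la.formal_charge * sign < 0:
                    if np.linalg.norm(la.position - center) <= rules.ionic_dist_max:
                        found.add(("IONIC", reskey))
        # aromatic
        ring_names = ia.AROMATIC_RING_ATOMS.get(resname)
        if ring_names:
            pts = [a.position for n in ring_names for a in res_atoms if a.name == n]
            if len(pts) == len(ring_names):
                pc, pn = _plane(np.array(pts))
                for ring in _ligand_rings(lig):
                    lc, ln = _plane(np.array([a.position for a in ring]))
                    d = np.linalg.norm(lc - pc)
                    ang = math.degrees(
                        math.acos(min(1.0, abs(float(np.dot(ln, pn)))))
                    )
                    if d <= rules.aromatic_centroid_dist_max and (
                        ang <= rules.aromatic_plane_angle_max
                        or ang >= rules.aromatic_tshape_angle_min
                    ):
                        found.add(("AROMATIC_PI", reskey))
    return found


def _angle(a, b, c):
    v1, v2 = a - b, c - b
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _plane(points):
    centroid = points.mean(axis=0)
    _, _, Vt = np.linalg.svd(points - centroid)
    return centroid, Vt[2]


def _in_ring(atom, lig):
    return any(atom in ring for ring in _ligand_rings(lig))


def _ligand_rings(lig):
    import networkx as nx

    g = nx.Graph()
    for i, a in enumerate(lig):
        g.add_node(i)
    for i, a in enumerate(lig):
        for j in range(i + 1, len(lig)):
            b = lig[j]
            if a.element == "H" or b.element == "H":
                continue
            if np.linalg.norm(a.position - b.position) < 1.9:
                g.add_edge(i, j)
    rings = []
    for cyc in nx.cycle_basis(g):
        if len(cyc) in (5, 6):
            pts = np.array([lig[i].position for i in cyc])
            c, n = _plane(pts)
            if np.abs((pts - c) @ n).max() <= 0.15:
                rings.append([lig[i] for i in cyc])
    return rings
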