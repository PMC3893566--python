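"""Independent naive reference implementations used as test oracles.

These deliberately avoid the package's traversal code: plain dictionaries,
recursion and brute-force numerics.  They mirror the documented feature
conventions but share no implementation with l1census.morphology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import ConvexHull, QhullError


def ols_slope_intercept(xs, ys):
    """Closed-form least squares: slope and intercept from raw sums."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    n = len(xs)
    sx, sy = xs.sum(), ys.sum()
    sxx = (xs * xs).sum()
    sxy = (xs * ys).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def biexp_crossings(tau_rise, tau_decay, lo=0.2, hi=0.8):
    """20/80 crossing times of a normalized difference of exponentials.

    f(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / f(t_peak); returns
    (t_lo, t_hi) on the rising flank by root bracketing.
    """
    t_peak = (tau_rise * tau_decay / (tau_decay - tau_rise)
              * math.log(tau_decay / tau_rise))
    fmax = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)

    def f(t):
        return (math.exp(-t / tau_decay) - math.exp(-t / tau_rise)) / fmax

    t_lo = brentq(lambda t: f(t) - lo, 1e-9, t_peak)
    t_hi = brentq(lambda t: f(t) - hi, 1e-9, t_peak)
    return t_lo, t_hi


# ---------------------------------------------------------------------------
# Naive morphometry
# ---------------------------------------------------------------------------

def _nodes_of(morph):
    """morph -> dict id -> (parent_id, structure, xyz, radius)."""
    out = {}
    for k in range(morph.n_nodes):
        out[int(morph.ids[k])] = (
            int(morph.parent_ids[k]), int(morph.structure[k]),
            np.array(morph.xyz[k]), float(morph.radius[k]),
        )
    return out


def naive_segments(morph, structure):
    """Segments as ordered id lists, first id = anchor branch point."""
    nodes = _nodes_of(morph)
    kids: dict[int, list[int]] = {}
    for nid, (pid, st, _, _) in nodes.items():
        if pid != -1:
            kids.setdefault(pid, []).append(nid)

    def in_f(nid):
        return nodes[nid][1] == structure

    trunk_heads = [
        nid for nid in nodes
        if in_f(nid) and (nodes[nid][0] == -1 or not in_f(nodes[nid][0]))
    ]
    segments = []

    def walk(head, anchor, order):
        chain = ([anchor] if anchor != head else []) + [head]
        node = head
        while True:
            ch = [c for c in kids.get(node, []) if in_f(c)]
            if len(ch) == 1:
                node = ch[0]
                chain.append(node)
            else:
                break
        segments.append((chain, order))
        for c in ch:
            walk(c, node, order + 1)

    for h in trunk_heads:
        walk(h, h, 1)
    return segments, nodes


def _chain_path(chain, nodes):
    return sum(
        float(np.linalg.norm(nodes[a][2] - nodes[b][2]))
        for a, b in zip(chain, chain[1:])
    )


def naive_feature_family(morph, structure):
    """Naive recomputation of the per-neurite-type feature family."""
    segments, nodes = naive_segments(morph, structure)
    kids: dict[int, list[int]] = {}
    for nid, (pid, st, _, _) in nodes.items():
        if pid != -1:
            kids.setdefault(pid, []).append(nid)

    def in_f(nid):
        return nodes[nid][1] == structure

    mask_ids = [nid for nid in nodes if in_f(nid)]
    soma_pts = [nodes[n][2] for n in nodes if nodes[n][1] == 1]
    soma = (np.mean(soma_pts, axis=0) if soma_pts
            else nodes[min(nodes)][2])

    trunks = [s for s, o in segments if o == 1]
    out = {}
    out["n_trunks"] = len(trunks)
    out["mean_trunk_diameter"] = float(np.mean([2 * nodes[c[0]][3] for c in trunks]))
    out["n_segments"] = len(segments)
    out["max_branch_order"] = max(o for _, o in segments)

    # path length from entry, accumulated naively per node
    plens = {}

    def fill_plen(nid, acc):
        pid = nodes[nid][0]
        step = float(np.linalg.norm(nodes[nid][2] - nodes[pid][2])) if pid != -1 else 0.0
        plens[nid] = acc + step
        for c in kids.get(nid, []):
            if in_f(c):
                fill_plen(c, plens[nid])

    for c in trunks:
        fill_plen(c[0], 0.0)
    out["max_path_length"] = max(plens.values())
    out["max_radial_distance"] = max(
        float(np.linalg.norm(nodes[n][2] - soma)) for n in mask_ids
    )

    def count_tips(nid):
        ch = [c for c in kids.get(nid, []) if in_f(c)]
        if not ch:
            return 1
        return sum(count_tips(c) for c in ch)

    out["max_degree"] = max(count_tips(c[0]) for c in trunks)

    total_len = total_area = total_vol = 0.0
    for nid in mask_ids:
        pid = nodes[nid][0]
        if pid == -1 or not in_f(pid):
            continue
        h = float(np.linalg.norm(nodes[nid][2] - nodes[pid][2]))
        if h == 0:
            continue
        r1, r2 = nodes[pid][3], nodes[nid][3]
        total_len += h
        total_area += math.pi * (r1 + r2) * math.sqrt(h * h + (r1 - r2) ** 2)
        total_vol += math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
    out["total_length"] = total_len
    out["total_surface_area"] = total_area
    out["total_volume"] = total_vol
    out["bif_mean_branch_length"] = float(
        np.mean([_chain_path(c, nodes) for c, _ in segments])
    )

    pts = np.array([nodes[n][2] for n in mask_ids])
    out["horizontal_range"] = float(pts[:, 0].max() - pts[:, 0].min())
    out["vertical_range"] = float(pts[:, 1].max() - pts[:, 1].min())
    vr = out["vertical_range"]
    out["hv_ratio"] = out["horizontal_range"] / vr if vr > 0 else math.inf

    torts = []
    for chain, _ in segments:
        p = _chain_path(chain, nodes)
        chord = float(np.linalg.norm(nodes[chain[-1]][2] - nodes[chain[0]][2]))
        if chord > 0 and p > 0:
            torts.append(p / chord)
    out["tortuosity"] = float(np.mean(torts)) if torts else math.nan

    # length-weighted line-integral moments over in-structure edges,
    # computed by dense resampling of every edge (brute force)
    samples, ws = [], []
    for nid in mask_ids:
        pid = nodes[nid][0]
        if pid == -1 or not in_f(pid):
            continue
        a, b = nodes[pid][2], nodes[nid][2]
        w = float(np.linalg.norm(b - a))
        if w > 0:
            k = max(2, int(w / 0.01))
            frac = (np.arange(k) + 0.5) / k
            samples.append(a + frac[:, None] * (b - a) - soma)
            ws.append(np.full(k, w / k))
    cloud = np.vstack(samples)
    wts = np.concatenate(ws)
    m1 = (cloud * wts[:, None]).sum(axis=0) / wts.sum()
    m2 = np.sqrt(((cloud - m1) ** 2 * wts[:, None]).sum(axis=0) / wts.sum())
    out["moment1"] = m1
    out["moment2"] = m2
    try:
        out["density"] = total_len / ConvexHull(pts).volume
    except QhullError:
        out["density"] = math.nan
    return out


def naive_soma_csa(morph):
    soma_idx = [k for k in range(morph.n_nodes) if morph.structure[k] == 1]
    if len(soma_idx) < 3:
        return math.pi * float(morph.radius[soma_idx[0]]) ** 2
    pts = morph.xyz[soma_idx][:, :2]
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return math.pi * float(np.mean(morph.radius[soma_idx])) ** 2


def random_tree(seed, structure_codes=(2, 3), n_extra=40):
    """A small random two-neurite tree for oracle-equivalence checks."""
    from l1census.morphology import Morphology

    rng = np.random.default_rng(seed)
    ids = [1]
    parents = [-1]
    structs = [1]
    xyz = [np.zeros(3)]
    radius = [6.0]

    def add(parent, struct, pos, r):
        ids.append(len(ids) + 1)
        parents.append(parent)
        structs.append(struct)
        xyz.append(pos)
        radius.append(r)
        return ids[-1]

    attachable = {code: [] for code in structure_codes}
    for code in structure_codes:
        for _ in range(rng.integers(1, 4)):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            nid = add(1, code, direction * rng.uniform(5, 15), 0.5 + rng.random())
            attachable[code].append(nid)
    for _ in range(n_extra):
        code = structure_codes[rng.integers(len(structure_codes))]
        parent = int(rng.choice(attachable[code]))
        base = xyz[parent - 1]
        step = rng.standard_normal(3)
        step /= np.linalg.norm(step)
        nid = add(parent, code, base + step * rng.uniform(3, 20),
                  0.3 + rng.random())
        attachable[code].append(nid)
    return Morphology(
        np.array(ids), np.array(parents), np.array(structs),
        np.array(xyz), np.array(radius),
    )
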