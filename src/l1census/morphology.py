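"""SWC neuron reconstructions and the morphometric feature battery.

A reconstruction is a rooted tree of typed points (soma / axon / basal
dendrite) with micrometre coordinates and radii.  Coordinate convention:
y increases from white matter toward the pia, x is horizontal within the
layer, z is slice depth.  The feature battery yields 44 named morphometric
features (soma cross-section; dendritic and axonal trunk / segment / order /
extent / moment / density / tortuosity families; horizontal-to-vertical
extent ratios) plus bifurcation-angle statistics and, when bouton markers
are supplied, a bouton density.

Definitions used for quantities whose original (proprietary) definitions are
unpublished are documented on each function; they are conventions of this
package, not claims of bit-compatibility with any other tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "Morphology",
    "Segment",
    "SwcError",
    "SOMA",
    "AXON",
    "DENDRITE",
    "read_swc",
    "write_swc",
    "shrinkage_correct",
    "extract_segments",
    "compute_extents",
    "compute_tortuosity",
    "compute_branch_angles",
    "compute_moments_density",
    "compute_feature_vector",
    "FEATURE_NAMES",
]

SOMA, AXON, DENDRITE = 1, 2, 3
_STRUCTURES = {SOMA: "soma", AXON: "axon", DENDRITE: "dendrite"}


class SwcError(ValueError):
    """Structural problem in an SWC file (orphan, cycle, multiple roots...)."""


@dataclass
class Morphology:
    """A rooted neurite tree in SWC node form.

    Arrays are aligned by position; ``parent_id`` of the root is -1 and every
    other parent appears earlier in the arrays (topological order).
    """

    ids: np.ndarray
    parent_ids: np.ndarray
    structure: np.ndarray   # SWC codes: 1 soma, 2 axon, 3 basal dendrite
    xyz: np.ndarray         # (n, 3) in um
    radius: np.ndarray      # um
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.parent_ids = np.asarray(self.parent_ids, dtype=int)
        self.structure = np.asarray(self.structure, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self._validate()

    def _validate(self) -> None:
        if np.any(self.radius <= 0):
            bad = self.ids[self.radius <= 0][0]
            raise SwcError(f"non-positive radius at node {bad}")
        roots = np.nonzero(self.parent_ids == -1)[0]
        if len(roots) != 1:
            raise SwcError(f"expected exactly one root, found {len(roots)}")
        for k, pid in enumerate(self.parent_ids):
            if pid == -1:
                continue
            if pid not in self._index:
                raise SwcError(f"orphan node {self.ids[k]}: parent {pid} missing")
            if self._index[pid] >= k:
                raise SwcError(
                    f"node {self.ids[k]}: parent {pid} does not precede it"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_index(self) -> int:
        return int(np.nonzero(self.parent_ids == -1)[0][0])

    @property
    def soma_position(self) -> np.ndarray:
        soma = self.xyz[self.structure == SOMA]
        return soma.mean(axis=0) if len(soma) else self.xyz[self.root_index]

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def children_map(self) -> dict[int, list[int]]:
        """Map from array index to list of child array indices."""
        children: dict[int, list[int]] = {k: [] for k in range(self.n_nodes)}
        for k, pid in enumerate(self.parent_ids):
            if pid != -1:
                children[self._index[pid]].append(k)
        return children


@dataclass
class Segment:
    """An unbranched point chain between consecutive branch points (or a
    branch point / trunk origin and a terminal tip)."""

    node_indices: np.ndarray   # ordered, first point = parent branch point
    structure: int
    order: int                 # centrifugal, trunk = 1
    path_length: float         # um
    euclidean_length: float    # um (end-to-end chord)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Read a standard 7-column SWC file (``#`` comments allowed)."""
    ids, parents, structs, coords, radii = [], [], [], [], []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcError(f"{path}: line {lineno}: expected 7 fields")
        ids.append(int(parts[0]))
        structs.append(int(parts[1]))
        coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
        radii.append(float(parts[5]))
        parents.append(int(parts[6]))
    if not ids:
        raise SwcError(f"{path}: empty file")
    return Morphology(
        np.array(ids), np.array(parents), np.array(structs),
        np.array(coords), np.array(radii),
    )


def write_swc(morph: Morphology, path) -> None:
    lines = ["# SWC export (l1census)"]
    for k in range(morph.n_nodes):
        x, y, z = morph.xyz[k]
        lines.append(
            f"{morph.ids[k]} {morph.structure[k]} {x:.6f} {y:.6f} {z:.6f} "
            f"{morph.radius[k]:.6f} {morph.parent_ids[k]}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def shrinkage_correct(
    morph: Morphology,
    measured_thickness: float,
    original_thickness: float = 300.0,
) -> Morphology:
    """Undo slice shrinkage along the z (slice depth) axis.

    Histological processing shrinks the slice along its depth; z coordinates
    are rescaled by ``original/measured``.  In-plane (x, y) shrinkage is
    small and left uncorrected.
    """
    if not (0 < measured_thickness <= original_thickness):
        raise ValueError(
            f"measured thickness {measured_thickness} must be in "
            f"(0, {original_thickness}]"
        )
    factor = original_thickness / measured_thickness
    xyz = morph.xyz.copy()
    xyz[:, 2] *= factor
    return Morphology(
        morph.ids.copy(), morph.parent_ids.copy(), morph.structure.copy(),
        xyz, morph.radius.copy(), dict(morph.metadata),
    )


# ---------------------------------------------------------------------------
# Tree traversal
# ---------------------------------------------------------------------------

def _neurite_mask(morph: Morphology, neurite_filter) -> np.ndarray:
    if neurite_filter is None:
        return morph.structure != SOMA
    if isinstance(neurite_filter, int):
        return morph.structure == neurite_filter
    if isinstance(neurite_filter, str):
        code = {v: k for k, v in _STRUCTURES.items()}[neurite_filter]
        return morph.structure == code
    return np.asarray(neurite_filter, dtype=bool)


def _path_length(morph: Morphology, indices) -> float:
    pts = morph.xyz[np.asarray(indices)]
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def extract_segments(morph: Morphology, neurite_filter=None) -> list[Segment]:
    """Partition the filtered neurites into inter-branch-point segments.

    A segment runs from a branch point (or from the soma, for a trunk) to
    the next branch point or tip.  Orders are assigned centrifugally with
    the trunk at order 1; a bifurcation increments the order of both
    daughters.
    """
    mask = _neurite_mask(morph, neurite_filter)
    children = morph.children_map()

    def in_filter(k: int) -> bool:
        return bool(mask[k])

    segments: list[Segment] = []
    # trunk starts: filtered nodes whose parent is soma/root/outside filter
    starts = []
    for k in range(morph.n_nodes):
        if not in_filter(k):
            continue
        pid = morph.parent_ids[k]
        if pid == -1 or not in_filter(morph.index_of(pid)):
            starts.append(k)

    for trunk in starts:
        # trunk anchor is the trunk node itself: the soma-to-trunk edge is
        # not part of the neurite, so segment lengths sum to neurite length
        stack = [(trunk, trunk, 1)]
        while stack:
            head, anchor, order = stack.pop()
            chain = [anchor] if anchor != head else []
            node = head
            while True:
                chain.append(node)
                kids = [c for c in children[node] if in_filter(c)]
                if len(kids) == 1:
                    node = kids[0]
                    continue
                break
            pts = chain if len(chain) >= 2 else [chain[0], chain[0]]
            idx = np.array(pts)
            plen = _path_length(morph, idx)
            chord = float(np.linalg.norm(morph.xyz[idx[-1]] - morph.xyz[idx[0]]))
            segments.append(Segment(idx, int(morph.structure[head]), order, plen, chord))
            for c in kids:
                stack.append((c, node, order + 1))
    return segments


# ---------------------------------------------------------------------------
# Elementary morphometrics
# ---------------------------------------------------------------------------

def compute_extents(morph: Morphology, neurite_filter=None) -> dict:
    """Horizontal (x) and vertical (y) extents and their ratio.

    ``h_extent`` = max - min of x over the filtered nodes, ``v_extent``
    likewise over y.  A zero vertical extent yields an infinite ratio with
    ``flagged=True`` rather than being dropped.
    """
    mask = _neurite_mask(morph, neurite_filter)
    if not mask.any():
        raise ValueError("neurite filter selects no nodes")
    pts = morph.xyz[mask]
    h = float(pts[:, 0].max() - pts[:, 0].min())
    v = float(pts[:, 1].max() - pts[:, 1].min())
    flagged = v == 0.0
    ratio = math.inf if flagged else h / v
    return {"h_extent": h, "v_extent": v, "hv_ratio": ratio, "flagged": flagged}


def compute_tortuosity(segment: Segment) -> float:
    """Path length over end-to-end chord; >= 1, NaN for coincident endpoints."""
    if segment.path_length <= 0:
        raise ValueError("segment has zero path length")
    if segment.euclidean_length == 0:
        return math.nan
    return segment.path_length / segment.euclidean_length


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    ua, ub = _unit(a), _unit(b)
    c = float(np.clip(np.dot(ua, ub), -1.0, 1.0))
    return math.degrees(math.acos(c))


def compute_branch_angles(morph: Morphology, neurite_filter=None) -> dict:
    """Mean bifurcation angles (degrees) over the filtered neurites.

    Per bifurcation:

    * local - angle between the vectors from the branch point to the first
      point of each daughter;
    * maximum - angle between the daughter chords (branch point to the next
      branch point or tip);
    * planar - angle between the daughter chords after projection onto the
      plane normal to the incoming parent direction;
    * local_spline - local angle computed on 5-point moving-average smoothed
      daughter paths.

    Trifurcations use the pairwise maximum; the cell value is the mean over
    bifurcations.  Raises when the filtered tree has no bifurcation.
    """
    mask = _neurite_mask(morph, neurite_filter)
    children = morph.children_map()

    def chain_from(k: int) -> list[int]:
        """Follow single-child path from k to next branch point / tip."""
        chain = [k]
        node = k
        while True:
            kids = [c for c in children[node] if mask[c]]
            if len(kids) == 1:
                node = kids[0]
                chain.append(node)
            else:
                break
        return chain

    locals_, maxes, planars, splines = [], [], [], []
    for k in range(morph.n_nodes):
        if not mask[k]:
            continue
        kids = [c for c in children[k] if mask[c]]
        if len(kids) < 2:
            continue
        p = morph.xyz[k]
        pid = morph.parent_ids[k]
        parent_dir = (
            _unit(p - morph.xyz[morph.index_of(pid)]) if pid != -1 else np.zeros(3)
        )
        pair_vals = {"local": [], "max": [], "planar": [], "spline": []}
        chains = [chain_from(c) for c in kids]
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                a1 = morph.xyz[kids[i]] - p
                a2 = morph.xyz[kids[j]] - p
                pair_vals["local"].append(_angle_deg(a1, a2))
                c1 = morph.xyz[chains[i][-1]] - p
                c2 = morph.xyz[chains[j][-1]] - p
                pair_vals["max"].append(_angle_deg(c1, c2))
                if np.linalg.norm(parent_dir) > 0:
                    q1 = c1 - np.dot(c1, parent_dir) * parent_dir
                    q2 = c2 - np.dot(c2, parent_dir) * parent_dir
                    if np.linalg.norm(q1) > 0 and np.linalg.norm(q2) > 0:
                        pair_vals["planar"].append(_angle_deg(q1, q2))
                s1 = _smoothed_dir(morph, p, chains[i])
                s2 = _smoothed_dir(morph, p, chains[j])
                pair_vals["spline"].append(_angle_deg(s1, s2))
        locals_.append(max(pair_vals["local"]))
        maxes.append(max(pair_vals["max"]))
        if pair_vals["planar"]:
            planars.append(max(pair_vals["planar"]))
        splines.append(max(pair_vals["spline"]))

    if not locals_:
        raise ValueError("no bifurcation in the filtered tree")
    return {
        "local": float(np.mean(locals_)),
        "maximum": float(np.mean(maxes)),
        "planar": float(np.mean(planars)) if planars else math.nan,
        "local_spline": float(np.mean(splines)),
        "n_bifurcations": len(locals_),
    }


def _smoothed_dir(morph: Morphology, origin: np.ndarray, chain: list[int],
                  n_points: int = 5) -> np.ndarray:
    pts = morph.xyz[np.asarray(chain[:n_points])]
    if len(pts) >= 3:
        kernel = np.ones(min(3, len(pts))) / min(3, len(pts))
        sm = np.vstack([np.convolve(pts[:, d], kernel, mode="valid") for d in range(3)]).T
        target = sm[-1]
    else:
        target = pts[-1]
    return target - origin


def compute_moments_density(morph: Morphology, neurite_filter=None) -> dict:
    """Length-weighted spatial moments and arbor density.

    ``moment1`` is the length-weighted centroid offset from the soma per
    axis; ``moment2`` the length-weighted SD per axis (edges contribute their
    midpoint weighted by their length).  ``density`` is total neurite length
    divided by the convex-hull volume of the filtered points (um/um^3); for
    degenerate (coplanar) point sets a planar hull is used and the result is
    an area-based density with ``flagged=True``.
    """
    mask = _neurite_mask(morph, neurite_filter)
    if mask.sum() < 2:
        raise ValueError("need >= 2 nodes for moments")
    soma = morph.soma_position
    mids, spans, weights = [], [], []
    for k in range(morph.n_nodes):
        pid = morph.parent_ids[k]
        if pid == -1 or not mask[k]:
            continue
        pk = morph.index_of(pid)
        if not mask[pk]:
            continue
        a, b = morph.xyz[pk], morph.xyz[k]
        w = float(np.linalg.norm(b - a))
        if w == 0:
            continue
        mids.append((a + b) / 2.0 - soma)
        spans.append(b - a)
        weights.append(w)
    mids_arr = np.asarray(mids)
    spans_arr = np.asarray(spans)
    w_arr = np.asarray(weights)
    total_length = float(w_arr.sum())
    if total_length == 0:
        raise ValueError("zero total length in filter")
    m1 = (mids_arr * w_arr[:, None]).sum(axis=0) / total_length
    # exact line integral: each edge contributes its midpoint offset plus
    # the within-edge variance of a uniform segment (span^2 / 12)
    var = (
        ((mids_arr - m1) ** 2 + spans_arr**2 / 12.0) * w_arr[:, None]
    ).sum(axis=0) / total_length
    m2 = np.sqrt(var)

    pts = morph.xyz[mask]
    flagged = False
    try:
        hull = ConvexHull(pts)
        density = total_length / hull.volume
    except QhullError:
        flagged = True
        try:
            hull2 = ConvexHull(pts[:, :2])
            density = total_length / hull2.volume  # 2D "volume" is the area
        except QhullError:
            density = math.nan
    return {
        "moment1": m1,
        "moment2": m2,
        "density": float(density),
        "total_length": total_length,
        "flagged": flagged,
    }


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

FEATURE_NAMES = [
    "soma_cross_sectional_area",
    "basal_n_trunks",
    "basal_mean_trunk_diameter",
    "basal_n_segments",
    "basal_max_branch_order",
    "basal_max_path_length",
    "basal_max_radial_distance",
    "basal_max_degree",
    "basal_total_length",
    "basal_total_surface_area",
    "basal_total_volume",
    "basal_bif_mean_branch_length",
    "basal_horizontal_range",
    "basal_vertical_range",
    "dend_moment1_x",
    "dend_moment1_y",
    "dend_moment1_z",
    "dend_moment2_x",
    "dend_moment2_y",
    "dend_moment2_z",
    "dend_density",
    "dend_tortuosity",
    "hv_ratio_dend",
    "axon_mean_trunk_diameter",
    "axon_n_segments",
    "axon_max_branch_order",
    "axon_max_path_length",
    "axon_max_radial_distance",
    "axon_max_degree",
    "axon_total_length",
    "axon_total_surface_area",
    "axon_total_volume",
    "axon_bif_mean_branch_length",
    "axon_horizontal_range",
    "axon_vertical_range",
    "axon_moment1_x",
    "axon_moment1_y",
    "axon_moment1_z",
    "axon_moment2_x",
    "axon_moment2_y",
    "axon_moment2_z",
    "axon_density",
    "axon_tortuosity",
    "hv_ratio_axon",
]


def _soma_csa(morph: Morphology) -> float:
    # 2D (x, y) contour projection of the soma nodes; a single-point soma
    # uses the equivalent circle of its radius
    idx = np.nonzero(morph.structure == SOMA)[0]
    if len(idx) == 0:
        return math.nan
    if len(idx) < 3:
        return math.pi * float(morph.radius[idx[0]]) ** 2
    pts = morph.xyz[idx][:, :2]
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return math.pi * float(morph.radius[idx].mean()) ** 2


def _frustum_area_volume(r1: float, r2: float, h: float) -> tuple[float, float]:
    slant = math.sqrt(h * h + (r1 - r2) ** 2)
    area = math.pi * (r1 + r2) * slant
    vol = math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
    return area, vol


def _neurite_family(morph: Morphology, structure: int) -> dict:
    """All per-neurite-type scalar features for one structure code."""
    mask = morph.structure == structure
    out: dict[str, float] = {}
    if not mask.any():
        return {k: math.nan for k in (
            "n_trunks", "mean_trunk_diameter", "n_segments", "max_branch_order",
            "max_path_length", "max_radial_distance", "max_degree",
            "total_length", "total_surface_area", "total_volume",
            "bif_mean_branch_length", "horizontal_range", "vertical_range",
            "tortuosity",
        )}
    segments = extract_segments(morph, structure)
    trunk_segs = [s for s in segments if s.order == 1]
    trunk_first = [s.node_indices[0] for s in trunk_segs]
    out["n_trunks"] = float(len(trunk_segs))
    out["mean_trunk_diameter"] = float(
        np.mean([2.0 * morph.radius[i] for i in trunk_first])
    )
    out["n_segments"] = float(len(segments))
    out["max_branch_order"] = float(max(s.order for s in segments))

    # path length from trunk origin to every node, by propagation
    soma = morph.soma_position
    children = morph.children_map()
    plen = np.zeros(morph.n_nodes)
    order_nodes = range(morph.n_nodes)
    for k in order_nodes:
        pid = morph.parent_ids[k]
        if pid == -1 or not mask[k]:
            continue
        pk = morph.index_of(pid)
        step = float(np.linalg.norm(morph.xyz[k] - morph.xyz[pk]))
        plen[k] = (plen[pk] if mask[pk] else 0.0) + step
    out["max_path_length"] = float(plen[mask].max())
    out["max_radial_distance"] = float(
        np.max(np.linalg.norm(morph.xyz[mask] - soma, axis=1))
    )

    # degree = number of terminal tips downstream of a trunk; max over trunks
    tips = [
        k for k in range(morph.n_nodes)
        if mask[k] and not any(mask[c] for c in children[k])
    ]
    # count tips per trunk subtree
    trunk_of = {}
    for s in trunk_segs:
        head = s.node_indices[0]
        stack = [int(head)]
        while stack:
            node = stack.pop()
            trunk_of[node] = int(head)
            stack.extend(c for c in children[node] if mask[c])
    tip_counts: dict[int, int] = {}
    for tp in tips:
        root = trunk_of.get(tp)
        if root is not None:
            tip_counts[root] = tip_counts.get(root, 0) + 1
    out["max_degree"] = float(max(tip_counts.values())) if tip_counts else 1.0

    total_len = total_area = total_vol = 0.0
    for k in range(morph.n_nodes):
        pid = morph.parent_ids[k]
        if pid == -1 or not mask[k]:
            continue
        pk = morph.index_of(pid)
        if not mask[pk]:
            continue
        h = float(np.linalg.norm(morph.xyz[k] - morph.xyz[pk]))
        if h == 0:
            continue
        a, v = _frustum_area_volume(float(morph.radius[pk]), float(morph.radius[k]), h)
        total_len += h
        total_area += a
        total_vol += v
    out["total_length"] = total_len
    out["total_surface_area"] = total_area
    out["total_volume"] = total_vol
    out["bif_mean_branch_length"] = float(np.mean([s.path_length for s in segments]))

    ext = compute_extents(morph, structure)
    out["horizontal_range"] = ext["h_extent"]
    out["vertical_range"] = ext["v_extent"]
    torts = [compute_tortuosity(s) for s in segments if s.euclidean_length > 0]
    out["tortuosity"] = float(np.nanmean(torts)) if torts else math.nan
    return out


def compute_feature_vector(morph: Morphology, markers=None):
    """The 44-feature morphometric vector of one reconstruction.

    Returns a pandas Series indexed by :data:`FEATURE_NAMES` (canonical
    order), with bifurcation-angle means appended under ``*_angle`` names and
    ``bouton_density`` (markers per um of axon) when ``markers`` is given.
    Features that cannot be computed are NaN rather than fabricated.
    """
    import pandas as pd

    dend = _neurite_family(morph, DENDRITE)
    axon = _neurite_family(morph, AXON)

    def moments(structure):
        try:
            return compute_moments_density(morph, structure)
        except ValueError:
            nan3 = np.array([math.nan] * 3)
            return {"moment1": nan3, "moment2": nan3, "density": math.nan}

    dm = moments(DENDRITE)
    am = moments(AXON)

    def hv(structure):
        try:
            e = compute_extents(morph, structure)
            return e["hv_ratio"]
        except ValueError:
            return math.nan

    values = {
        "soma_cross_sectional_area": _soma_csa(morph),
        "basal_n_trunks": dend["n_trunks"],
        "basal_mean_trunk_diameter": dend["mean_trunk_diameter"],
        "basal_n_segments": dend["n_segments"],
        "basal_max_branch_order": dend["max_branch_order"],
        "basal_max_path_length": dend["max_path_length"],
        "basal_max_radial_distance": dend["max_radial_distance"],
        "basal_max_degree": dend["max_degree"],
        "basal_total_length": dend["total_length"],
        "basal_total_surface_area": dend["total_surface_area"],
        "basal_total_volume": dend["total_volume"],
        "basal_bif_mean_branch_length": dend["bif_mean_branch_length"],
        "basal_horizontal_range": dend["horizontal_range"],
        "basal_vertical_range": dend["vertical_range"],
        "dend_moment1_x": dm["moment1"][0],
        "dend_moment1_y": dm["moment1"][1],
        "dend_moment1_z": dm["moment1"][2],
        "dend_moment2_x": dm["moment2"][0],
        "dend_moment2_y": dm["moment2"][1],
        "dend_moment2_z": dm["moment2"][2],
        "dend_density": dm["density"],
        "dend_tortuosity": dend["tortuosity"],
        "hv_ratio_dend": hv(DENDRITE),
        "axon_mean_trunk_diameter": axon["mean_trunk_diameter"],
        "axon_n_segments": axon["n_segments"],
        "axon_max_branch_order": axon["max_branch_order"],
        "axon_max_path_length": axon["max_path_length"],
        "axon_max_radial_distance": axon["max_radial_distance"],
        "axon_max_degree": axon["max_degree"],
        "axon_total_length": axon["total_length"],
        "axon_total_surface_area": axon["total_surface_area"],
        "axon_total_volume": axon["total_volume"],
        "axon_bif_mean_branch_length": axon["bif_mean_branch_length"],
        "axon_horizontal_range": axon["horizontal_range"],
        "axon_vertical_range": axon["vertical_range"],
        "axon_moment1_x": am["moment1"][0],
        "axon_moment1_y": am["moment1"][1],
        "axon_moment1_z": am["moment1"][2],
        "axon_moment2_x": am["moment2"][0],
        "axon_moment2_y": am["moment2"][1],
        "axon_moment2_z": am["moment2"][2],
        "axon_density": am["density"],
        "axon_tortuosity": axon["tortuosity"],
        "hv_ratio_axon": hv(AXON),
    }
    series = pd.Series([values[n] for n in FEATURE_NAMES], index=FEATURE_NAMES,
                       dtype=float)

    extras = {}
    for prefix, struct in (("dend", DENDRITE), ("axon", AXON)):
        try:
            ang = compute_branch_angles(morph, struct)
            for key in ("maximum", "planar", "local", "local_spline"):
                extras[f"{prefix}_{key}_angle"] = ang[key]
        except ValueError:
            for key in ("maximum", "planar", "local", "local_spline"):
                extras[f"{prefix}_{key}_angle"] = math.nan
    if markers is not None:
        pts = np.asarray(markers, dtype=float)
        axon_len = axon["total_length"]
        extras["bouton_density"] = (
            len(pts) / axon_len if axon_len and axon_len > 0 else math.nan
        )
    if extras:
        series = pd.concat([series, pd.Series(extras, dtype=float)])
    return series
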