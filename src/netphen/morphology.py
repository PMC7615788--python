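"""Morphometry of reconstructed neurons from SWC files: summary
parameters (soma size, primary dendrites, nodes, ends, dendritic length,
covered area) and Sholl profiles in concentric shells around the soma.

Axon-typed nodes (SWC type 2) are excluded from all dendritic metrics;
the source reconstructions excluded axons by morphology.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

__all__ = [
    "NeuronTree",
    "ShollProfile",
    "load_swc",
    "parse_swc",
    "write_swc",
    "morphometrics",
    "sholl",
]

SOMA, AXON = 1, 2


@dataclass
class NeuronTree:
    """Validated SWC reconstruction (single root, connected, acyclic)."""

    nodes: pd.DataFrame   # columns: id, type, x, y, z, radius, parent (id-indexed)
    root: int
    children: dict = field(repr=False, default_factory=dict)

    @property
    def soma_center(self) -> np.ndarray:
        soma = self.nodes[self.nodes["type"] == SOMA]
        if soma.empty:
            soma = self.nodes.loc[[self.root]]
        return soma[["x", "y", "z"]].mean().to_numpy()

    def dendrite_edges(self) -> list[tuple[int, int]]:
        """(parent, child) pairs where the child is a non-axon, non-soma
        node — the segments that carry dendritic length."""
        out = []
        for nid, row in self.nodes.iterrows():
            p = row["parent"]
            if p == -1 or row["type"] in (SOMA, AXON):
                continue
            out.append((int(p), int(nid)))
        return out

    def xyz(self, nid: int) -> np.ndarray:
        return self.nodes.loc[nid, ["x", "y", "z"]].to_numpy(dtype=float)


@dataclass
class ShollProfile:
    """Per-shell dendritic statistics at a fixed radial interval."""

    interval: float
    radii: np.ndarray          # outer edge of each shell, µm
    length: np.ndarray         # clipped dendritic length per shell, µm
    intersections: np.ndarray  # crossings of each shell boundary
    nodes: np.ndarray          # branch points per shell

    def as_frame(self, neuron: str = "neuron") -> pd.DataFrame:
        return pd.DataFrame({
            "neuron": neuron,
            "radius_um": self.radii,
            "length_um": self.length,
            "intersections": self.intersections,
            "nodes": self.nodes,
        })


def parse_swc(text: str) -> NeuronTree:
    """Parse SWC text, rejecting orphans, cycles and multiple roots with
    the offending node ids."""
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) != 7:
            raise ValueError(f"line {lineno}: expected 7 SWC columns, got {len(parts)}")
        rows.append((int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                     float(parts[4]), float(parts[5]), int(parts[6])))
    if not rows:
        raise ValueError("empty SWC file")
    df = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate node ids: {dup}")
    df = df.set_index("id", drop=False)

    roots = df.index[df["parent"] == -1].tolist()
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root (parent -1), found {roots}")
    ids = set(df.index)
    orphans = [int(n) for n, p in zip(df.index, df["parent"])
               if p != -1 and p not in ids]
    if orphans:
        raise ValueError(f"orphan nodes (parent missing): {orphans}")

    children: dict[int, list[int]] = {int(n): [] for n in df.index}
    for nid, p in zip(df.index, df["parent"]):
        if p != -1:
            children[int(p)].append(int(nid))
    # cycle / reachability check from the root
    seen = set()
    stack = [int(roots[0])]
    while stack:
        n = stack.pop()
        if n in seen:
            raise ValueError(f"cycle detected at node {n}")
        seen.add(n)
        stack.extend(children[n])
    unreachable = sorted(set(map(int, df.index)) - seen)
    if unreachable:
        raise ValueError(f"nodes unreachable from root: {unreachable}")
    return NeuronTree(nodes=df, root=int(roots[0]), children=children)


def load_swc(path) -> NeuronTree:
    with open(path) as fh:
        return parse_swc(fh.read())


def write_swc(tree: NeuronTree, path=None) -> str:
    buf = io.StringIO()
    for _, r in tree.nodes.iterrows():
        buf.write(f"{int(r['id'])} {int(r['type'])} {r['x']:.4f} {r['y']:.4f} "
                  f"{r['z']:.4f} {r['radius']:.4f} {int(r['parent'])}\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _dendritic_node_ids(tree: NeuronTree) -> set:
    return {
        int(n) for n, row in tree.nodes.iterrows()
        if row["type"] not in (SOMA, AXON)
    }


def morphometrics(tree: NeuronTree) -> dict:
    """Summary morphometry: soma area (equivalent circle from the root
    radius), primary dendrite count, branch nodes, ends, total and mean
    dendritic length, and covered area (2-D convex hull of dendritic
    sample points, x-y plane)."""
    soma_radius = float(tree.nodes.loc[tree.root, "radius"])
    dend = _dendritic_node_ids(tree)
    edges = tree.dendrite_edges()

    lengths = [float(np.linalg.norm(tree.xyz(c) - tree.xyz(p))) for p, c in edges]
    total_length = float(sum(lengths))

    primary = [c for c in tree.children[tree.root] if c in dend]
    n_nodes = sum(
        1 for n in dend if len([c for c in tree.children[n] if c in dend]) >= 2
    )
    n_ends = sum(
        1 for n in dend if len([c for c in tree.children[n] if c in dend]) == 0
    )
    if not dend:
        return {
            "soma_area_um2": math.pi * soma_radius ** 2, "n_primary_dendrites": 0,
            "n_nodes": 0, "n_ends": 0, "total_length_um": 0.0,
            "mean_length_um": 0.0, "covered_area_um2": 0.0,
        }

    pts = tree.nodes.loc[sorted(dend), ["x", "y"]].to_numpy(dtype=float)
    pts = np.vstack([pts, tree.soma_center[:2]])
    if pts.shape[0] >= 3 and np.ptp(pts, axis=0).min() > 0:
        try:
            hull_area = float(ConvexHull(pts).volume)  # 2-D hull: volume == area
        except Exception:
            hull_area = 0.0
    else:
        hull_area = 0.0
    n_primary = len(primary)
    return {
        "soma_area_um2": math.pi * soma_radius ** 2,
        "n_primary_dendrites": n_primary,
        "n_nodes": n_nodes,
        "n_ends": n_ends,
        "total_length_um": total_length,
        "mean_length_um": total_length / n_primary if n_primary else 0.0,
        "covered_area_um2": hull_area,
    }


_S_TOL = 1e-9  # crossings this close to a segment endpoint are handled as
               # node-on-boundary cases, not interior crossings


def _boundary_roots(
    a: np.ndarray, d: np.ndarray, interval: float
) -> list[tuple[float, float]]:
    """Parameters s in (0, 1) where |a + s d| equals a shell radius,
    as (s, radius) pairs. Radius along a straight segment is convex, so
    its maximum sits at an endpoint."""
    dd = float(d @ d)
    if dd == 0.0:
        return []
    r_max = max(float(np.linalg.norm(a)), float(np.linalg.norm(a + d)))
    roots = []
    k = 1
    while k * interval < r_max:
        r = k * interval
        # |a + s d|^2 = r^2  ->  dd s^2 + 2 (a.d) s + (a.a - r^2) = 0
        b = float(a @ d)
        c = float(a @ a) - r * r
        disc = b * b - dd * c
        if disc > 0:
            sq = math.sqrt(disc)
            for s in ((-b - sq) / dd, (-b + sq) / dd):
                if _S_TOL < s < 1.0 - _S_TOL:
                    roots.append((s, r))
        k += 1
    return roots


def _segment_shell_pieces(
    p0: np.ndarray, p1: np.ndarray, center: np.ndarray, interval: float,
    planar: bool,
) -> tuple[list[tuple[float, float]], list[float]]:
    """Split segment p0->p1 at every shell-boundary crossing.

    Returns ((mid_radius, piece_length) pairs, crossing radii). Radii are
    3-D spherical distances unless ``planar`` (2-D circles in x-y);
    lengths are always true 3-D path lengths."""
    dims = 2 if planar else 3
    a = p0[:dims] - center[:dims]
    d = p1[:dims] - p0[:dims]
    seg_len3 = float(np.linalg.norm(p1 - p0))
    if seg_len3 == 0.0:
        return [], []
    if float(d @ d) == 0.0:  # no radial extent in the measured plane
        return [(float(np.linalg.norm(a)), seg_len3)], []

    roots = _boundary_roots(a, d, interval)
    ss = sorted({0.0, 1.0} | {s for s, _ in roots})
    pieces = []
    for s_lo, s_hi in zip(ss[:-1], ss[1:]):
        s_mid = 0.5 * (s_lo + s_hi)
        r_mid = float(np.linalg.norm(a + s_mid * d))
        pieces.append((r_mid, (s_hi - s_lo) * seg_len3))
    return pieces, [r for _, r in roots]


def sholl(
    tree: NeuronTree, interval_um: float = 20.0, mode: str = "3d"
) -> ShollProfile:
    """Sholl profile: dendritic segments are split exactly at shell
    boundaries (spheres by default, ``mode='2d'`` for circles in x-y)
    centered on the soma centroid; per shell the clipped length, boundary
    crossings and branch nodes are accumulated."""
    if interval_um <= 0:
        raise ValueError("interval_um must be > 0")
    if mode not in ("3d", "2d"):
        raise ValueError("mode must be '3d' or '2d'")
    planar = mode == "2d"
    center = tree.soma_center
    dims = 2 if planar else 3
    edges = tree.dendrite_edges()
    dend = _dendritic_node_ids(tree)

    def radius_of(nid: int) -> float:
        return float(np.linalg.norm(tree.xyz(nid)[:dims] - center[:dims]))

    pieces: list[tuple[float, float]] = []
    crossing_radii: list[float] = []
    for p, c in edges:
        p0, p1 = tree.xyz(p), tree.xyz(c)
        seg_pieces, seg_cross = _segment_shell_pieces(p0, p1, center, interval_um, planar)
        pieces.extend(seg_pieces)
        crossing_radii.extend(seg_cross)

    # a node lying exactly on a shell boundary carries the crossing itself:
    # one per child on the opposite side of the boundary from the parent
    # (a terminal tip touching a boundary is therefore no crossing)
    tol = 1e-6
    for n in dend:
        d_n = radius_of(n)
        k = round(d_n / interval_um)
        if k < 1 or abs(d_n - k * interval_um) > tol:
            continue
        r = k * interval_um
        parent = int(tree.nodes.loc[n, "parent"])
        d_p = radius_of(parent)
        for ch in tree.children[n]:
            if ch not in dend:
                continue
            d_c = radius_of(ch)
            if (d_p - r) * (d_c - r) < 0:
                crossing_radii.append(r)

    max_r = 0.0
    if pieces:
        max_r = max(r for r, _ in pieces)
    for n in dend:
        max_r = max(max_r, radius_of(n))
    n_shells = max(int(math.ceil(max_r / interval_um)), 1)
    length = np.zeros(n_shells)
    for r_mid, plen in pieces:
        shell = min(int(r_mid // interval_um), n_shells - 1)
        length[shell] += plen

    inter = np.zeros(n_shells, dtype=int)
    for r in crossing_radii:
        inter[int(round(r / interval_um)) - 1] += 1

    node_counts = np.zeros(n_shells, dtype=int)
    for n in dend:
        if len([c for c in tree.children[n] if c in dend]) >= 2:
            shell = min(int(radius_of(n) // interval_um), n_shells - 1)
            node_counts[shell] += 1

    radii = interval_um * np.arange(1, n_shells + 1)
    return ShollProfile(interval_um, radii, length, inter, node_counts)
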