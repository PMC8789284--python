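"""Column-map construction and pale/yellow/DRA identity assignment.

The medulla column lattice is anchored on Mi1 cells (one per column): a
column center is the center-of-mass of the Mi1 dendrite in layer M5. Points
(synapses, arbor nodes) are assigned to their nearest column center in the
lattice plane. Pale columns are those occupied by an aMe12 vertical process;
remaining non-DRA columns are yellow. Dorsal-rim (DRA) columns are those
whose R7 and R8 both terminate in the M6 band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import ColumnRecord, Point3, Skeleton
from .layers import LayerFrame, PlanarDepthAxis

__all__ = [
    "fit_lattice_plane",
    "column_centers_from_mi1",
    "assign_points_to_columns",
    "pale_from_ame12",
    "detect_dra_columns",
    "DraDetection",
]


def fit_lattice_plane(
    points_nm: np.ndarray, thickness_um: float
) -> PlanarDepthAxis:
    """Total-least-squares plane through a point cloud as a depth axis.

    The lattice plane is the best-fit plane (smallest singular vector of the
    centered cloud) through the supplied points (nm); the returned axis
    treats it as the distal surface of a slab of the given thickness. The
    normal is oriented toward +z where possible, for a deterministic sign.
    """
    p = np.asarray(points_nm, dtype=float)
    centroid = p.mean(axis=0)
    _, _, vt = np.linalg.svd(p - centroid)
    normal = vt[2]
    if normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or normal[1] < 0)):
        normal = -normal
    return PlanarDepthAxis(origin_nm=centroid, normal=normal, thickness_um=thickness_um)


def column_centers_from_mi1(
    mi1_skeletons: Sequence[Skeleton],
    layer_frame: LayerFrame,
    depth_axis: PlanarDepthAxis,
    band_label: str = "M5",
) -> list[ColumnRecord]:
    """Column centers as per-cell centers of mass of Mi1 nodes in layer M5.

    One center per skeleton: the unweighted mean of the node positions whose
    depth fraction lies in the M5 band, projected onto the lattice plane.
    Column ids are assigned in skeleton order. A cell with no node in the
    band is an error (it cannot anchor a column).
    """
    lo, hi = layer_frame.band(band_label)
    records: list[ColumnRecord] = []
    for i, skel in enumerate(mi1_skeletons):
        pos = skel.positions()[["x", "y", "z"]].to_numpy()
        frac = depth_axis.depth_fraction(pos)
        in_band = (frac >= lo) & (frac < hi)
        if not np.any(in_band):
            raise ValueError(
                f"cell {skel.cell_id}: no nodes in the {band_label} band"
            )
        com = pos[in_band].mean(axis=0)
        # Project onto the distal plane (drop the axis-parallel component).
        proj = com - ((com - depth_axis.origin_nm) @ depth_axis.normal) * depth_axis.normal
        records.append(
            ColumnRecord(column_id=i, center=Point3(*proj), subtype=None)
        )
    return records


def assign_points_to_columns(
    points_nm: np.ndarray,
    columns: Sequence[ColumnRecord],
    depth_axis: PlanarDepthAxis,
) -> np.ndarray:
    """Assign each point to the nearest column center in the lattice plane.

    Distances are Euclidean in the plane perpendicular to the depth axis.
    Ties (equal distance within 1e-9 relative) are broken toward the
    smallest ``column_id``. Returns an array of column ids; idempotent and
    independent of point order.
    """
    if len(columns) == 0:
        raise ValueError("empty column list")
    pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
    centers = np.array([c.center.as_tuple() for c in columns])
    ids = np.array([c.column_id for c in columns])
    p2 = depth_axis.to_plane_um(pts)
    c2 = depth_axis.to_plane_um(centers)
    tree = cKDTree(c2)
    k = min(4, len(columns))
    dist, idx = tree.query(p2, k=k)
    if k == 1:
        return ids[idx]
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    out = np.empty(len(p2), dtype=ids.dtype)
    tol = 1e-9
    for i in range(len(p2)):
        d0 = dist[i, 0]
        tied = idx[i, dist[i] <= d0 + tol * max(d0, 1.0)]
        out[i] = ids[tied].min()
    return out


def _default_vertical_process_detector(
    skeleton: Skeleton,
    columns: Sequence[ColumnRecord],
    layer_frame: LayerFrame,
    depth_axis: PlanarDepthAxis,
) -> set[int]:
    """Columns containing an aMe12-style vertical process of this skeleton.

    A vertical process is an ascending run of nodes within one column whose
    depth extent reaches from the M6 band up into (or above) the M3 band.
    Both the short (M6 to M3) and the long (M6 to M1) processes qualify: the
    criterion is at least one node with depth in the M6 band and at least
    one node at or above the top of M3, within the same column.
    """
    m6_lo, m6_hi = layer_frame.band("M6")
    _, m3_hi = layer_frame.band("M3")
    pos = skeleton.positions()[["x", "y", "z"]].to_numpy()
    frac = np.asarray(depth_axis.depth_fraction(pos))
    col_of = assign_points_to_columns(pos, columns, depth_axis)
    occupied: set[int] = set()
    for cid in np.unique(col_of):
        f = frac[col_of == cid]
        reaches_m6 = np.any((f >= m6_lo) & (f < m6_hi))
        reaches_m3 = np.any(f < m3_hi)
        if reaches_m6 and reaches_m3:
            occupied.add(int(cid))
    return occupied


def pale_from_ame12(
    ame12_skeletons: Sequence[Skeleton],
    columns: Sequence[ColumnRecord],
    layer_frame: LayerFrame,
    depth_axis: PlanarDepthAxis,
    vertical_process_detector: Callable[..., set[int]] | None = None,
    dra_ids: Iterable[int] = (),
) -> tuple[list[ColumnRecord], dict[int, list[str]]]:
    """Set pale/yellow subtypes from aMe12 occupancy; DRA flags override.

    A column is pale iff at least one aMe12 vertical process is assigned to
    it; every remaining non-DRA column is yellow. Returns the relabelled
    columns plus a provenance map (column id -> claiming aMe12 cell ids).
    Occupancy by several aMe12 cells is resolved by set union.
    """
    detector = vertical_process_detector or _default_vertical_process_detector
    provenance: dict[int, list[str]] = {}
    for skel in ame12_skeletons:
        for cid in sorted(detector(skel, columns, layer_frame, depth_axis)):
            provenance.setdefault(cid, []).append(skel.cell_id)
    dra = set(dra_ids)
    out = []
    for c in columns:
        if c.column_id in dra:
            subtype = "DRA"
        elif c.column_id in provenance:
            subtype = "pale"
        else:
            subtype = "yellow"
        out.append(ColumnRecord(c.column_id, c.center, subtype))
    return out, provenance


@dataclass
class DraDetection:
    """Result of dorsal-rim column detection."""

    dra_ids: set[int] = field(default_factory=set)
    non_dra_ids: set[int] = field(default_factory=set)
    indeterminate_ids: set[int] = field(default_factory=set)


def detect_dra_columns(
    photoreceptor_terminals: pd.DataFrame,
    columns: Sequence[ColumnRecord],
    layer_frame: LayerFrame,
) -> DraDetection:
    """Flag DRA columns: both R7 and R8 terminals in the M6 depth band.

    ``photoreceptor_terminals`` needs columns ``column_id``, ``kind``
    ("R7"/"R8") and ``terminal_fraction`` (percent depth). In central
    columns R8 terminates in M3, far from M6, so co-termination in M6 is
    diagnostic of the dorsal rim. Columns missing either terminal are
    flagged indeterminate and excluded from both sets.
    """
    m6_lo, m6_hi = layer_frame.band("M6")
    det = DraDetection()
    terms = photoreceptor_terminals
    by_col = {cid: g for cid, g in terms.groupby("column_id")}
    for c in columns:
        g = by_col.get(c.column_id)
        fracs = {}
        if g is not None:
            for kind in ("R7", "R8"):
                sel = g[g["kind"] == kind]
                if len(sel):
                    fracs[kind] = float(sel["terminal_fraction"].iloc[0])
        if "R7" not in fracs or "R8" not in fracs:
            det.indeterminate_ids.add(c.column_id)
            continue
        in_m6 = all(m6_lo <= fracs[k] < m6_hi for k in ("R7", "R8"))
        (det.dra_ids if in_m6 else det.non_dra_ids).add(c.column_id)
    return det
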