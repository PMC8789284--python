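"""Seeded generator of ground-truthed synthetic medullas.

The generator emulates the statistical structure the analysis assumes: a
hexagonal column lattice with a stochastic pale/yellow mosaic (pale
probability 0.38) and a contiguous dorsal-rim arc of DRA columns; per-column
R7/R8 axons entering from the optic chiasm (depth < 0) and terminating in
their characteristic layers (central R7 in M6, R8 in M3; both in M6 in the
DRA, R8 shallower than R7); multicolumnar target cells with per-type layer
profiles and R7/R8 and pale/yellow selectivities; and synapses placed both
inside the medulla and distally in the chiasm.

The medulla is modelled as a planar slab (default thickness 40 um) with the
depth axis along +z; all downstream analysis consumes depth fractions, so
the curvature of the real neuropil is deliberately out of scope. Synapse
counts per (column, cell) pair are Poisson; every draw comes from a single
seeded NumPy generator, so identical seeds give byte-identical output files.
By construction each synapse is jittered by less than half the column pitch
around its source column center, so the ground-truth column is always the
nearest lattice center — enabling exact recovery tests downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    NM_PER_UM,
    CellRecord,
    ColumnRecord,
    Point3,
    Skeleton,
    SkeletonNode,
    SynapseRecord,
    write_cell_table,
    write_column_table,
    write_skeleton,
    write_synapse_table,
)
from .layers import MEDULLA_FRAME, LayerFrame, PlanarDepthAxis, layer_of

__all__ = [
    "LatticeSpec",
    "CellTemplate",
    "ConnectivityRule",
    "GroundTruth",
    "SyntheticDataset",
    "generate_lattice",
    "generate_photoreceptors",
    "generate_target_cells",
    "sample_synapses",
    "generate_dataset",
    "write_dataset",
    "default_templates",
    "default_rules",
    "expected_synapse_total",
]


@dataclass
class LatticeSpec:
    """Study-scale defaults: a ~780-column medulla, 38% pale mosaic, 42 DRA
    columns along the dorsal rim, 5 um column pitch, 40 um slab thickness."""

    n_rows: int = 30
    n_cols: int = 26
    pitch: float = 5.0            # um, center-to-center
    pale_prob: float = 0.38
    n_dra: int = 42
    medulla_thickness: float = 40.0  # um
    chiasm_depth: float = 5.0     # um of axon distal to the M1 surface
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pale_prob <= 1.0:
            raise ValueError("pale_prob must be in [0, 1]")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.n_dra > len(perimeter_indices(self.n_rows, self.n_cols)):
            raise ValueError("n_dra exceeds the number of rim columns")

    @property
    def depth_axis(self) -> PlanarDepthAxis:
        return PlanarDepthAxis(
            origin_nm=np.zeros(3),
            normal=np.array([0.0, 0.0, 1.0]),
            thickness_um=self.medulla_thickness,
        )


@dataclass
class CellTemplate:
    """Statistical template for one target cell type.

    ``layer_profile`` weights (summing to 1) govern both where arbor nodes
    sit and which layer each medulla synapse is drawn in. ``r7_weight`` /
    ``r8_weight`` and ``pale_weight`` / ``yellow_weight`` multiply the
    per-rule Poisson mean; ``home_column_boost`` additionally multiplies it
    in the cell's home column (Dm8-style enrichment). ``chiasm_fraction`` is
    the probability that a synapse is placed distal to M1, in the chiasm.
    """

    type_label: str
    class_label: str = ""
    arbor_span: int = 0          # radius in column units
    layer_profile: tuple[tuple[str, float], ...] = (("M6", 1.0),)
    home_column_boost: float = 1.0
    r7_weight: float = 1.0
    r8_weight: float = 1.0
    pale_weight: float = 1.0
    yellow_weight: float = 1.0
    chiasm_fraction: float = 0.0
    pale_columns_only: bool = False
    placement: str = "tile"      # "tile" | "per_column" | "single"

    def __post_init__(self) -> None:
        for w in (
            self.home_column_boost,
            self.r7_weight,
            self.r8_weight,
            self.pale_weight,
            self.yellow_weight,
        ):
            if w < 0:
                raise ValueError("weights must be nonnegative")
        if not 0.0 <= self.chiasm_fraction <= 1.0:
            raise ValueError("chiasm_fraction must be in [0, 1]")
        total = sum(w for _, w in self.layer_profile)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("layer_profile weights must sum to 1")


@dataclass
class ConnectivityRule:
    """Poisson rate from one photoreceptor subtype onto one target type.

    ``mean`` is the expected synapse count per (source column, overlapping
    target cell) pair before the template's weight factors. ``target`` may
    name a template or be "R7"/"R8" for inter-photoreceptor synapses within
    a column; for those, ``chiasm_fraction`` on the rule applies.
    """

    source: str
    target: str
    mean: float
    chiasm_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("mean must be nonnegative")


@dataclass
class GroundTruth:
    """Generator-side truth used as the oracle in recovery tests."""

    columns: pd.DataFrame = field(default_factory=pd.DataFrame)   # column_id, subtype, is_rim
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)     # cell_id, type_label, home_column
    synapses: pd.DataFrame = field(default_factory=pd.DataFrame)  # synapse_id, column_id, compartment, layer


@dataclass
class SyntheticDataset:
    spec: LatticeSpec
    columns: list[ColumnRecord]
    photoreceptor_skeletons: dict[str, Skeleton]
    target_skeletons: dict[str, Skeleton]
    cells: list[CellRecord]
    synapses: list[SynapseRecord]
    terminals: pd.DataFrame   # cell_id, column_id, kind, subtype_tag, terminal_fraction
    arbors: pd.DataFrame      # cell_id, type_label, column_id, is_home
    truth: GroundTruth

    @property
    def depth_axis(self) -> PlanarDepthAxis:
        return self.spec.depth_axis

    @property
    def skeletons(self) -> dict[str, Skeleton]:
        return {**self.photoreceptor_skeletons, **self.target_skeletons}

    @property
    def seed_photoreceptor_ids(self) -> set[str]:
        return set(self.terminals["cell_id"])


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------

def hex_positions_um(n_rows: int, n_cols: int, pitch: float) -> np.ndarray:
    """Centers of an offset hexagonal lattice, row-major, in um (z = 0)."""
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    x = (cols + 0.5 * (rows % 2)) * pitch
    y = rows * pitch * math.sqrt(3.0) / 2.0
    return np.column_stack([x, y, np.zeros_like(x, dtype=float)])


def perimeter_indices(n_rows: int, n_cols: int) -> list[int]:
    """Boundary column indices in contiguous order around the lattice rim
    (dorsal row left-to-right, then down the far edge, ventral row, near
    edge)."""
    def idx(r: int, c: int) -> int:
        return r * n_cols + c

    if n_rows == 1:
        return [idx(0, c) for c in range(n_cols)]
    if n_cols == 1:
        return [idx(r, 0) for r in range(n_rows)]
    order = [idx(0, c) for c in range(n_cols)]
    order += [idx(r, n_cols - 1) for r in range(1, n_rows)]
    order += [idx(n_rows - 1, c) for c in range(n_cols - 2, -1, -1)]
    order += [idx(r, 0) for r in range(n_rows - 2, 0, -1)]
    return order


def generate_lattice(
    spec: LatticeSpec, rng: np.random.Generator
) -> tuple[list[ColumnRecord], pd.DataFrame]:
    """Hexagonal lattice with DRA rim arc and stochastic pale/yellow mosaic.

    The first ``n_dra`` columns along the rim perimeter are DRA; every other
    column is pale with probability ``pale_prob`` independently, else
    yellow. Returns the columns plus the ground-truth subtype table.
    """
    pos = hex_positions_um(spec.n_rows, spec.n_cols, spec.pitch) * NM_PER_UM
    n = len(pos)
    rim = perimeter_indices(spec.n_rows, spec.n_cols)
    dra = set(rim[: spec.n_dra])
    pale_draw = rng.random(n) < spec.pale_prob
    columns: list[ColumnRecord] = []
    rows = []
    for i in range(n):
        if i in dra:
            subtype = "DRA"
        elif pale_draw[i]:
            subtype = "pale"
        else:
            subtype = "yellow"
        columns.append(ColumnRecord(column_id=i, center=Point3(*pos[i]), subtype=subtype))
        rows.append({"column_id": i, "subtype": subtype, "is_rim": i in set(rim)})
    return columns, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Photoreceptors
# ---------------------------------------------------------------------------

_M3_BAND = MEDULLA_FRAME.band("M3")
_M6_BAND = MEDULLA_FRAME.band("M6")


def _subtype_tag(column_subtype: str, kind: str) -> str:
    if column_subtype == "DRA":
        return f"{kind}-DRA"
    return ("p" if column_subtype == "pale" else "y") + kind


def _axon_skeleton(
    cell_id: str, x_nm: float, y_nm: float, spec: LatticeSpec, terminal_fraction: float
) -> Skeleton:
    """Unbranched axon entering at the chiasm (depth < 0) and descending to
    its terminal depth; nodes every ~2 um along the columnar axis."""
    z0 = -spec.chiasm_depth * NM_PER_UM
    z1 = terminal_fraction / 100.0 * spec.medulla_thickness * NM_PER_UM
    n_steps = max(2, int(math.ceil((z1 - z0) / (2.0 * NM_PER_UM))) + 1)
    zs = np.linspace(z0, z1, n_steps)
    nodes = [
        SkeletonNode(
            node_id=i + 1,
            parent_id=None if i == 0 else i,
            position=Point3(x_nm, y_nm, float(z)),
            radius=200.0,
        )
        for i, z in enumerate(zs)
    ]
    return Skeleton(cell_id=cell_id, nodes=nodes)


def generate_photoreceptors(
    columns: Sequence[ColumnRecord], spec: LatticeSpec, rng: np.random.Generator
) -> tuple[dict[str, Skeleton], pd.DataFrame, list[CellRecord]]:
    """Per-column R7/R8 axons with layer-appropriate terminal depths.

    Central columns: R7 terminates uniformly within the M6 band, R8 within
    the M3 band. DRA columns: both terminate within M6, with R8-DRA drawn
    from the shallower half of the band so it always ends before R7-DRA.
    Every root node lies distal to the neuropil (depth < 0).
    """
    skeletons: dict[str, Skeleton] = {}
    cells: list[CellRecord] = []
    rows = []
    m6_mid = 0.5 * (_M6_BAND[0] + _M6_BAND[1])
    for col in columns:
        assert col.subtype is not None
        for kind in ("R7", "R8"):
            if col.subtype == "DRA":
                lo, hi = (m6_mid, _M6_BAND[1]) if kind == "R7" else (_M6_BAND[0], m6_mid)
            else:
                lo, hi = _M6_BAND if kind == "R7" else _M3_BAND
            frac = float(rng.uniform(lo, hi))
            cell_id = f"{kind}_c{col.column_id:04d}"
            skeletons[cell_id] = _axon_skeleton(
                cell_id, col.center.x, col.center.y, spec, frac
            )
            tag = _subtype_tag(col.subtype, kind)
            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    type_label=kind,
                    class_label="R",
                    status="identified_type",
                    subtype_tag=tag,
                )
            )
            rows.append(
                {
                    "cell_id": cell_id,
                    "column_id": col.column_id,
                    "kind": kind,
                    "subtype_tag": tag,
                    "terminal_fraction": frac,
                }
            )
    return skeletons, pd.DataFrame(rows), cells


# ---------------------------------------------------------------------------
# Target cells
# ---------------------------------------------------------------------------

def _disc_jitter(rng: np.random.Generator, radius_um: float) -> tuple[float, float]:
    r = radius_um * math.sqrt(rng.random())
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return r * math.cos(phi), r * math.sin(phi)


def _sample_layer(
    template: CellTemplate, rng: np.random.Generator, frame: LayerFrame
) -> tuple[str, float]:
    labels = [l for l, _ in template.layer_profile]
    weights = np.array([w for _, w in template.layer_profile])
    label = labels[int(rng.choice(len(labels), p=weights / weights.sum()))]
    lo, hi = frame.band(label)
    return label, float(rng.uniform(lo, hi))


def generate_target_cells(
    templates: Sequence[CellTemplate],
    columns: Sequence[ColumnRecord],
    spec: LatticeSpec,
    rng: np.random.Generator,
    frame: LayerFrame = MEDULLA_FRAME,
) -> tuple[dict[str, Skeleton], list[CellRecord], pd.DataFrame]:
    """Place target cells on the lattice per template and build their arbors.

    ``tile`` placement puts home columns on a stride-(span+1) sublattice so
    arbors tile with overlap; ``per_column`` puts one cell in every column
    (Mi1-style); pale-restricted templates (aMe12-style) emit one cell whose
    vertical processes occupy exactly the pale column set. Arbor nodes are
    scattered within the template's layers around each arbor column center.
    """
    centers = {c.column_id: np.array(c.center.as_tuple()) for c in columns}
    subtype = {c.column_id: c.subtype for c in columns}
    pitch_nm = spec.pitch * NM_PER_UM
    skeletons: dict[str, Skeleton] = {}
    cells: list[CellRecord] = []
    arbor_rows = []

    max_span_nm = (max(spec.n_rows, spec.n_cols) - 1) * pitch_nm

    for template in templates:
        if template.arbor_span * pitch_nm > max_span_nm:
            raise ValueError(
                f"{template.type_label}: arbor span exceeds the lattice"
            )
        if template.pale_columns_only:
            homes = [min(cid for cid, s in subtype.items() if s == "pale")] if any(
                s == "pale" for s in subtype.values()
            ) else []
            arbor_sets = [sorted(cid for cid, s in subtype.items() if s == "pale")]
        elif template.placement == "per_column" or template.arbor_span == 0:
            homes = sorted(centers.keys())
            arbor_sets = [[h] for h in homes]
        else:
            stride = template.arbor_span + 1
            homes = []
            for r in range(0, spec.n_rows, stride):
                for c in range(0, spec.n_cols, stride):
                    homes.append(r * spec.n_cols + c)
            cutoff = template.arbor_span * pitch_nm * 1.001
            all_ids = sorted(centers.keys())
            all_xy = np.array([centers[i][:2] for i in all_ids])
            arbor_sets = []
            for h in homes:
                d = np.linalg.norm(all_xy - centers[h][:2], axis=1)
                arbor_sets.append([all_ids[i] for i in np.where(d <= cutoff)[0]])

        for k, (home, arbor) in enumerate(zip(homes, arbor_sets)):
            if not arbor:
                continue
            cell_id = f"{template.type_label}_{k:04d}"
            nodes: list[SkeletonNode] = []
            nid = 0
            for cid in arbor:
                cx, cy = centers[cid][0], centers[cid][1]
                if template.pale_columns_only:
                    # Vertical process: an ascending run spanning M6 up to M1.
                    fracs = np.linspace(58.0, 4.0, 6)
                    jx, jy = _disc_jitter(rng, 0.1 * spec.pitch)
                    for f in fracs:
                        nid += 1
                        nodes.append(
                            SkeletonNode(
                                nid,
                                None if nid == 1 else nid - 1,
                                Point3(
                                    cx + jx * NM_PER_UM,
                                    cy + jy * NM_PER_UM,
                                    f / 100.0 * spec.medulla_thickness * NM_PER_UM,
                                ),
                            )
                        )
                else:
                    # One node minimum in every layer the template occupies,
                    # remaining nodes allocated by weight (4 per column).
                    labels = [l for l, w in template.layer_profile if w > 0]
                    weights = np.array(
                        [w for _, w in template.layer_profile if w > 0], dtype=float
                    )
                    extra = max(0, 4 - len(labels))
                    alloc = {l: 1 for l in labels}
                    if extra:
                        shares = np.floor(extra * weights / weights.sum()).astype(int)
                        for j in np.argsort(-weights)[: extra - shares.sum()]:
                            shares[j] += 1
                        for l, s in zip(labels, shares):
                            alloc[l] += int(s)
                    node_layers = [l for l in labels for _ in range(alloc[l])]
                    for label in node_layers:
                        lo_f, hi_f = frame.band(label)
                        frac = float(rng.uniform(lo_f, hi_f))
                        jx, jy = _disc_jitter(rng, 0.25 * spec.pitch)
                        nid += 1
                        nodes.append(
                            SkeletonNode(
                                nid,
                                None if nid == 1 else nid - 1,
                                Point3(
                                    cx + jx * NM_PER_UM,
                                    cy + jy * NM_PER_UM,
                                    frac / 100.0 * spec.medulla_thickness * NM_PER_UM,
                                ),
                            )
                        )
            skeletons[cell_id] = Skeleton(cell_id=cell_id, nodes=nodes)
            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    type_label=template.type_label,
                    class_label=template.class_label or template.type_label,
                    status="identified_type",
                )
            )
            for cid in arbor:
                arbor_rows.append(
                    {
                        "cell_id": cell_id,
                        "type_label": template.type_label,
                        "column_id": cid,
                        "is_home": cid == home,
                    }
                )
    return skeletons, cells, pd.DataFrame(arbor_rows)


# ---------------------------------------------------------------------------
# Synapses
# ---------------------------------------------------------------------------

def _rule_rate(
    rule: ConnectivityRule,
    template: CellTemplate,
    column_subtype: str,
    kind: str,
    is_home: bool,
) -> float:
    lam = rule.mean
    lam *= template.r7_weight if kind == "R7" else template.r8_weight
    if column_subtype == "pale":
        lam *= template.pale_weight
    elif column_subtype == "yellow":
        lam *= template.yellow_weight
    if is_home:
        lam *= template.home_column_boost
    return lam


def expected_synapse_total(
    rules: Sequence[ConnectivityRule],
    templates: Mapping[str, CellTemplate],
    arbors: pd.DataFrame,
    truth_columns: pd.DataFrame,
) -> float:
    """Sum of Poisson means over all (rule, column, cell) triples."""
    subtype = dict(zip(truth_columns["column_id"], truth_columns["subtype"]))
    total = 0.0
    for rule in rules:
        kind = "R7" if "R7" in rule.source else "R8"
        src_sub = _source_column_subtype(rule.source)
        if rule.target in ("R7", "R8"):
            total += rule.mean * sum(1 for s in subtype.values() if s == src_sub)
            continue
        template = templates[rule.target]
        sel = arbors[arbors["type_label"] == rule.target]
        for row in sel.itertuples(index=False):
            if subtype.get(row.column_id) != src_sub:
                continue
            total += _rule_rate(rule, template, src_sub, kind, row.is_home)
    return total


def _source_column_subtype(source_tag: str) -> str:
    if source_tag.endswith("-DRA"):
        return "DRA"
    return "pale" if source_tag.startswith("p") else "yellow"


def sample_synapses(
    rules: Sequence[ConnectivityRule],
    templates: Mapping[str, CellTemplate],
    terminals: pd.DataFrame,
    arbors: pd.DataFrame,
    columns: Sequence[ColumnRecord],
    spec: LatticeSpec,
    rng: np.random.Generator,
    frame: LayerFrame = MEDULLA_FRAME,
) -> tuple[list[SynapseRecord], pd.DataFrame]:
    """Draw Poisson synapse counts per rule and place each synapse.

    A synapse sits in the lateral footprint of its source column (jitter
    under half the pitch, so the nearest center is always the true column),
    at a depth drawn from the target template's layer profile, or distal to
    M1 (uniform within the chiasm segment) with the template's or rule's
    ``chiasm_fraction``. The ground-truth table records the source column,
    compartment and layer of every synapse.
    """
    by_col_kind = {
        (row.column_id, row.kind): row
        for row in terminals.itertuples(index=False)
    }
    centers = {c.column_id: c.center for c in columns}
    subtype = {c.column_id: c.subtype for c in columns}
    synapses: list[SynapseRecord] = []
    truth_rows = []
    counter = 0

    def place(
        pre: str,
        post: str,
        column_id: int,
        chiasm_fraction: float,
        layer_sampler,
    ) -> None:
        nonlocal counter
        counter += 1
        sid = f"syn{counter:06d}"
        cx, cy = centers[column_id].x, centers[column_id].y
        jx, jy = _disc_jitter(rng, 0.3 * spec.pitch)
        if rng.random() < chiasm_fraction:
            z = rng.uniform(-spec.chiasm_depth, 0.0) * NM_PER_UM
            compartment, layer = "chiasm", ""
        else:
            layer, frac = layer_sampler()
            z = frac / 100.0 * spec.medulla_thickness * NM_PER_UM
            compartment = "medulla"
        synapses.append(
            SynapseRecord(
                synapse_id=sid,
                pre_cell=pre,
                post_cell=post,
                location=Point3(cx + jx * NM_PER_UM, cy + jy * NM_PER_UM, z),
                compartment=compartment,
            )
        )
        truth_rows.append(
            {
                "synapse_id": sid,
                "column_id": column_id,
                "compartment": compartment,
                "layer": layer,
            }
        )

    arbors_by_type = {t: g for t, g in arbors.groupby("type_label")} if len(arbors) else {}

    for rule in rules:
        kind = "R7" if "R7" in rule.source else "R8"
        src_sub = _source_column_subtype(rule.source)
        src_columns = sorted(cid for cid, s in subtype.items() if s == src_sub)
        if rule.target in ("R7", "R8"):
            other = rule.target
            cf = rule.chiasm_fraction or 0.0
            for cid in src_columns:
                pre = by_col_kind[(cid, kind)].cell_id
                post_row = by_col_kind[(cid, other)]
                n = int(rng.poisson(rule.mean))
                cap = min(
                    by_col_kind[(cid, kind)].terminal_fraction,
                    post_row.terminal_fraction,
                )

                def pr_layer(cap=cap):
                    frac = float(rng.uniform(0.0, cap))
                    return layer_of(frac, frame), frac

                for _ in range(n):
                    place(pre, post_row.cell_id, cid, cf, pr_layer)
            continue

        if rule.target not in templates:
            raise KeyError(f"rule references unknown template {rule.target!r}")
        template = templates[rule.target]
        cf = rule.chiasm_fraction if rule.chiasm_fraction is not None else template.chiasm_fraction
        sel = arbors_by_type.get(rule.target)
        if sel is None:
            continue
        by_col = {c: g for c, g in sel.groupby("column_id")}
        for cid in src_columns:
            g = by_col.get(cid)
            if g is None:
                continue
            pre = by_col_kind[(cid, kind)].cell_id
            for row in g.itertuples(index=False):
                lam = _rule_rate(rule, template, src_sub, kind, row.is_home)
                n = int(rng.poisson(lam)) if lam > 0 else 0

                def tmpl_layer():
                    return _sample_layer(template, rng, frame)

                for _ in range(n):
                    place(pre, row.cell_id, cid, cf, tmpl_layer)

    truth = pd.DataFrame(
        truth_rows, columns=["synapse_id", "column_id", "compartment", "layer"]
    )
    return synapses, truth


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_templates() -> list[CellTemplate]:
    """Templates emulating the strongest seed-column photoreceptor targets:
    R7-selective Dm8 (home-column enriched) and MeTu, mixed Dm9 feedback,
    R8-selective yellow-biased Tm5c, chiasm-heavy Mi15, per-column Mi1
    (anchor cells), and pale-restricted aMe12."""
    return [
        CellTemplate(
            "Mi1", class_label="Mi", arbor_span=0, placement="per_column",
            layer_profile=(("M1", 0.5), ("M5", 0.5)), r7_weight=0.0, r8_weight=1.0,
        ),
        CellTemplate(
            "Dm9", class_label="Dm", arbor_span=1,
            layer_profile=(("M1", 0.35), ("M3", 0.25), ("M6", 0.4)),
            chiasm_fraction=0.08,
        ),
        CellTemplate(
            "Dm8", class_label="Dm", arbor_span=2, layer_profile=(("M6", 1.0),),
            r7_weight=1.0, r8_weight=0.0, home_column_boost=3.0,
        ),
        CellTemplate(
            "Tm5c", class_label="Tm", arbor_span=1,
            layer_profile=(("M3", 0.3), ("M6", 0.7)),
            r7_weight=0.12, r8_weight=0.88, pale_weight=1.0, yellow_weight=4.0,
        ),
        CellTemplate(
            "Mi15", class_label="Mi", arbor_span=1,
            layer_profile=(("M2", 0.3), ("M5", 0.7)), r7_weight=0.1, r8_weight=0.9,
            chiasm_fraction=0.47,
        ),
        CellTemplate(
            "MeTu", class_label="MeTu", arbor_span=1, layer_profile=(("M6", 1.0),),
            r7_weight=1.0, r8_weight=0.0,
        ),
        CellTemplate(
            "aMe12", class_label="aMe", layer_profile=(("M1", 0.5), ("M6", 0.5)),
            r7_weight=0.13, r8_weight=0.87, pale_weight=1.0, yellow_weight=0.0,
            pale_columns_only=True,
        ),
        CellTemplate(
            "Dm-DRA1", class_label="Dm", arbor_span=2, layer_profile=(("M6", 1.0),),
            r7_weight=1.0, r8_weight=0.0, home_column_boost=2.0,
        ),
    ]


def default_rules() -> list[ConnectivityRule]:
    """Per-column Poisson rates loosely matched to the seed-column tables
    (a few synapses per column-cell pair for the strong partners), plus the
    chiasm-dominated inter-photoreceptor synapses (~80% outside the
    medulla)."""
    rules: list[ConnectivityRule] = []
    central = ("pR7", "yR7", "pR8", "yR8")
    for tag in central:
        rules.append(ConnectivityRule(tag, "Dm9", 3.0))
        rules.append(ConnectivityRule(tag, "Tm5c", 1.0))
        rules.append(ConnectivityRule(tag, "Mi15", 1.2))
        rules.append(ConnectivityRule(tag, "aMe12", 1.0))
    for tag in ("pR7", "yR7"):
        rules.append(ConnectivityRule(tag, "Dm8", 3.0))
        rules.append(ConnectivityRule(tag, "MeTu", 1.5))
        rules.append(ConnectivityRule(tag, "R8", 2.5, chiasm_fraction=0.8))
    for tag in ("pR8", "yR8"):
        rules.append(ConnectivityRule(tag, "Mi1", 2.0))
        rules.append(ConnectivityRule(tag, "R7", 2.5, chiasm_fraction=0.8))
    rules.append(ConnectivityRule("R7-DRA", "Dm-DRA1", 4.0))
    rules.append(ConnectivityRule("R7-DRA", "Dm9", 2.0))
    rules.append(ConnectivityRule("R8-DRA", "Dm9", 3.0))
    rules.append(ConnectivityRule("R7-DRA", "R8", 2.0, chiasm_fraction=0.5))
    rules.append(ConnectivityRule("R8-DRA", "R7", 4.0, chiasm_fraction=0.15))
    return rules


# ---------------------------------------------------------------------------
# End-to-end generation and export
# ---------------------------------------------------------------------------

def generate_dataset(
    spec: LatticeSpec,
    templates: Sequence[CellTemplate] | None = None,
    rules: Sequence[ConnectivityRule] | None = None,
) -> SyntheticDataset:
    """Generate a complete synthetic medulla from one seeded RNG stream."""
    rng = np.random.default_rng(spec.seed)
    templates = list(templates if templates is not None else default_templates())
    rules = list(rules if rules is not None else default_rules())
    columns, truth_columns = generate_lattice(spec, rng)
    pr_skels, terminals, pr_cells = generate_photoreceptors(columns, spec, rng)
    tgt_skels, tgt_cells, arbors = generate_target_cells(templates, columns, spec, rng)
    template_map = {t.type_label: t for t in templates}
    synapses, truth_synapses = sample_synapses(
        rules, template_map, terminals, arbors, columns, spec, rng
    )
    home = (
        arbors[arbors["is_home"]].set_index("cell_id")["column_id"]
        if len(arbors)
        else pd.Series(dtype=int)
    )
    cells = pr_cells + tgt_cells
    truth_cells = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "type_label": [c.type_label for c in cells],
            "home_column": [home.get(c.cell_id, -1) for c in cells],
        }
    )
    return SyntheticDataset(
        spec=spec,
        columns=columns,
        photoreceptor_skeletons=pr_skels,
        target_skeletons=tgt_skels,
        cells=cells,
        synapses=synapses,
        terminals=terminals,
        arbors=arbors,
        truth=GroundTruth(columns=truth_columns, cells=truth_cells, synapses=truth_synapses),
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Export a dataset to SWC + CSV files (deterministic byte content)."""
    outdir = Path(outdir)
    (outdir / "skeletons").mkdir(parents=True, exist_ok=True)
    write_column_table(dataset.columns, outdir / "columns.csv")
    write_synapse_table(dataset.synapses, outdir / "synapses.csv")
    write_cell_table(dataset.cells, outdir / "cells.csv")
    dataset.terminals.to_csv(outdir / "terminals.csv", index=False, float_format="%.6f")
    dataset.arbors.to_csv(outdir / "arbors.csv", index=False)
    dataset.truth.columns.to_csv(outdir / "ground_truth_columns.csv", index=False)
    dataset.truth.cells.to_csv(outdir / "ground_truth_cells.csv", index=False)
    dataset.truth.synapses.to_csv(outdir / "ground_truth_synapses.csv", index=False)
    for cell_id in sorted(dataset.skeletons):
        write_skeleton(dataset.skeletons[cell_id], outdir / "skeletons" / f"{cell_id}.swc")
    spec_dict = asdict(dataset.spec)
    with (outdir / "lattice_spec.yaml").open("w", encoding="utf-8") as fh:
        for key in sorted(spec_dict):
            fh.write(f"{key}: {spec_dict[key]}\n")
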