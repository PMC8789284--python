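"""Domain records and file I/O for skeletons, synapses, cells and columns.

Conventions
-----------
* All coordinates are stored internally in **nanometres** (the native unit of
  large serial-section EM volumes). Analysis parameters expressed in
  micrometres (smoothing bandwidths, lattice pitch) are converted once at
  module boundaries; see :data:`NM_PER_UM`.
* Skeletons use the SWC dialect: seven whitespace-separated columns
  ``node_id type x y z radius parent_id``, ``#`` comments, parent ``-1``
  for the root. Node ids are arbitrary positive integers, not necessarily
  contiguous.
* Tabular interchange is plain comma-separated UTF-8 with a mandatory header
  and ``.`` decimal separator, so round trips are bit-exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

NM_PER_UM = 1000.0

#: Recognised synapse compartments.
COMPARTMENTS = ("medulla", "chiasm", "other")

#: Recognised cell identification statuses.
CELL_STATUSES = ("identified_type", "identified_class", "unidentified")

#: Photoreceptor subtype tags (pale/yellow central R7 and R8, dorsal-rim R7/R8).
SUBTYPE_TAGS = ("pR7", "yR7", "pR8", "yR8", "R7-DRA", "R8-DRA")

#: Column subtypes.
COLUMN_SUBTYPES = ("pale", "yellow", "DRA")


class SkeletonError(ValueError):
    """Malformed skeleton file or inconsistent tree structure."""


@dataclass(frozen=True)
class Point3:
    """A 3-D location in nanometres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError(f"non-finite coordinate in {self!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class SkeletonNode:
    node_id: int
    parent_id: int | None  # None for the root
    position: Point3
    radius: float = 1.0


@dataclass
class Skeleton:
    """A rooted tree of 3-D nodes representing one reconstructed cell.

    Invariants (checked on construction): exactly one root, every parent
    reference resolves, and the graph is a tree (no cycles, so the number of
    edges equals ``n_nodes - 1``).
    """

    cell_id: str
    nodes: list[SkeletonNode]

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        id_set = set(ids)
        if len(id_set) != len(ids):
            raise SkeletonError(f"{self.cell_id}: duplicate node ids")
        roots = [n.node_id for n in self.nodes if n.parent_id is None]
        if len(roots) == 0:
            raise SkeletonError(f"{self.cell_id}: no root node")
        if len(roots) > 1:
            raise SkeletonError(f"{self.cell_id}: multiple roots {roots}")
        parent = {}
        for n in self.nodes:
            if n.parent_id is not None:
                if n.parent_id not in id_set:
                    raise SkeletonError(
                        f"{self.cell_id}: node {n.node_id} references "
                        f"unknown parent {n.parent_id}"
                    )
                parent[n.node_id] = n.parent_id
        # Cycle check: walk each node to the root, memoising visited chains.
        ok: set[int] = {roots[0]}
        for nid in ids:
            chain = []
            cur = nid
            seen = set()
            while cur not in ok:
                if cur in seen:
                    raise SkeletonError(f"{self.cell_id}: cycle at node {cur}")
                seen.add(cur)
                chain.append(cur)
                cur = parent[cur]
            ok.update(chain)

    @property
    def root(self) -> int:
        return next(n.node_id for n in self.nodes if n.parent_id is None)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def positions(self) -> "pd.DataFrame":
        """Node positions as a DataFrame (node_id, x, y, z) in nm."""
        return pd.DataFrame(
            {
                "node_id": [n.node_id for n in self.nodes],
                "x": [n.position.x for n in self.nodes],
                "y": [n.position.y for n in self.nodes],
                "z": [n.position.z for n in self.nodes],
            }
        )


@dataclass(frozen=True)
class SynapseRecord:
    """One presynaptic-to-postsynaptic contact at a T-bar.

    ``compartment`` is ``"medulla"``, ``"chiasm"``, ``"other"`` or ``None``
    (unset). One record corresponds to one (pre, post) pairing of a T-bar.
    """

    synapse_id: str
    pre_cell: str
    post_cell: str
    location: Point3
    compartment: str | None = None

    def __post_init__(self) -> None:
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class CellRecord:
    """Annotation for one cell: identity, class and identification status."""

    cell_id: str
    type_label: str | None = None
    class_label: str | None = None
    status: str = "unidentified"
    subtype_tag: str | None = None

    def __post_init__(self) -> None:
        if self.status not in CELL_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "identified_type" and not self.type_label:
            raise ValueError(f"{self.cell_id}: identified_type requires type_label")
        if self.status == "identified_class" and not self.class_label:
            raise ValueError(f"{self.cell_id}: identified_class requires class_label")
        if self.subtype_tag is not None and self.subtype_tag not in SUBTYPE_TAGS:
            raise ValueError(f"unknown subtype tag {self.subtype_tag!r}")

    @property
    def identified(self) -> bool:
        return self.status in ("identified_type", "identified_class")


@dataclass(frozen=True)
class ColumnRecord:
    """A medulla column center with (optional) pale/yellow/DRA subtype."""

    column_id: int
    center: Point3
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.subtype is not None and self.subtype not in COLUMN_SUBTYPES:
            raise ValueError(f"unknown column subtype {self.subtype!r}")


# ---------------------------------------------------------------------------
# SWC skeletons
# ---------------------------------------------------------------------------

def read_skeleton(path: str | Path, cell_id: str | None = None) -> Skeleton:
    """Parse one SWC file into a validated :class:`Skeleton`.

    Units are taken as nm. ``cell_id`` defaults to the file stem. Errors
    (malformed line, dangling parent, multiple roots, cycles) are raised
    with the offending line number where applicable.
    """
    path = Path(path)
    nodes: list[SkeletonNode] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SkeletonError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                x, y, z, radius = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SkeletonError(f"{path.name}:{lineno}: {exc}") from None
            nodes.append(
                SkeletonNode(
                    node_id=nid,
                    parent_id=None if parent == -1 else parent,
                    position=Point3(x, y, z),
                    radius=radius,
                )
            )
    if not nodes:
        raise SkeletonError(f"{path.name}: no nodes")
    return Skeleton(cell_id=cell_id or path.stem, nodes=nodes)


def write_skeleton(skeleton: Skeleton, path: str | Path) -> None:
    """Write a skeleton in the 7-column SWC dialect (structure type 0)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# cell_id {skeleton.cell_id}\n")
        for n in skeleton.nodes:
            parent = -1 if n.parent_id is None else n.parent_id
            fh.write(
                f"{n.node_id} 0 {n.position.x:.3f} {n.position.y:.3f} "
                f"{n.position.z:.3f} {n.radius:.3f} {parent}\n"
            )


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_SYNAPSE_COLUMNS = ("synapse_id", "pre_cell", "post_cell", "x", "y", "z")


def read_synapse_table(
    path: str | Path, allow_autapses: bool = False
) -> list[SynapseRecord]:
    """Read a synapse CSV (``synapse_id,pre_cell,post_cell,x,y,z[,compartment]``).

    The compartment field is left unset when the column is absent or empty.
    Autapses (pre == post) are rejected unless ``allow_autapses``.
    """
    df = pd.read_csv(path, dtype={"synapse_id": str, "pre_cell": str, "post_cell": str})
    missing = [c for c in _SYNAPSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    for c in ("x", "y", "z"):
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().any() and len(df):
            bad = df.index[coerced.isna()][0]
            raise ValueError(f"{path}: non-numeric coordinate {c!r} at data row {bad}")
        df[c] = coerced
    has_comp = "compartment" in df.columns
    records = []
    for row in df.itertuples(index=False):
        comp = getattr(row, "compartment", None) if has_comp else None
        if comp is not None and (pd.isna(comp) or comp == ""):
            comp = None
        if row.pre_cell == row.post_cell and not allow_autapses:
            raise ValueError(
                f"{path}: autapse on cell {row.pre_cell} (synapse {row.synapse_id})"
            )
        records.append(
            SynapseRecord(
                synapse_id=str(row.synapse_id),
                pre_cell=str(row.pre_cell),
                post_cell=str(row.post_cell),
                location=Point3(float(row.x), float(row.y), float(row.z)),
                compartment=comp,
            )
        )
    return records


def write_synapse_table(synapses: Sequence[SynapseRecord], path: str | Path) -> None:
    synapse_frame(synapses).to_csv(path, index=False, float_format="%.3f")


def synapse_frame(synapses: Sequence[SynapseRecord]) -> pd.DataFrame:
    """Synapse records as a DataFrame (coordinates in nm)."""
    return pd.DataFrame(
        {
            "synapse_id": [s.synapse_id for s in synapses],
            "pre_cell": [s.pre_cell for s in synapses],
            "post_cell": [s.post_cell for s in synapses],
            "x": [s.location.x for s in synapses],
            "y": [s.location.y for s in synapses],
            "z": [s.location.z for s in synapses],
            "compartment": [s.compartment or "" for s in synapses],
        }
    )


def read_cell_table(path: str | Path) -> list[CellRecord]:
    """Read a cell annotation CSV (``cell_id,type_label,class_label,status,subtype_tag``)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = ("cell_id", "status")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CellRecord(
                cell_id=row.cell_id,
                type_label=getattr(row, "type_label", "") or None,
                class_label=getattr(row, "class_label", "") or None,
                status=row.status,
                subtype_tag=getattr(row, "subtype_tag", "") or None,
            )
        )
    return records


def write_cell_table(cells: Sequence[CellRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "type_label": [c.type_label or "" for c in cells],
            "class_label": [c.class_label or "" for c in cells],
            "status": [c.status for c in cells],
            "subtype_tag": [c.subtype_tag or "" for c in cells],
        }
    ).to_csv(path, index=False)


def read_column_table(path: str | Path) -> list[ColumnRecord]:
    """Read a column CSV (``column_id,x,y,z,subtype``; coordinates in nm)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        subtype = getattr(row, "subtype", "")
        if pd.isna(subtype) or subtype == "":
            subtype = None
        records.append(
            ColumnRecord(
                column_id=int(row.column_id),
                center=Point3(float(row.x), float(row.y), float(row.z)),
                subtype=subtype,
            )
        )
    ids = [c.column_id for c in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate column ids")
    return records


def write_column_table(columns: Sequence[ColumnRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "column_id": [c.column_id for c in columns],
            "x": [c.center.x for c in columns],
            "y": [c.center.y for c in columns],
            "z": [c.center.z for c in columns],
            "subtype": [c.subtype or "" for c in columns],
        }
    ).to_csv(path, index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# Referential-integrity validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def count(self, kind: str) -> int:
        return sum(1 for i in self.issues if i.kind == kind)

    def to_json(self) -> str:
        return json.dumps(
            [{"kind": i.kind, "message": i.message} for i in self.issues], indent=2
        )


def validate_dataset(
    skeletons: Mapping[str, Skeleton] | Iterable[Skeleton],
    synapses: Sequence[SynapseRecord],
    cells: Sequence[CellRecord],
) -> ValidationReport:
    """Cross-check skeletons, synapses and cell annotations.

    Report-only (never raises). Issue kinds: ``duplicate_id`` (cells or
    synapses), ``unknown_cell`` (a synapse endpoint with no cell record),
    ``missing_skeleton`` (a cell record with no skeleton),
    ``skeleton_without_cell`` and ``autapse``. The report is empty iff the
    dataset is consistent.
    """
    if isinstance(skeletons, Mapping):
        skel_ids = set(skeletons.keys())
    else:
        skel_ids = {s.cell_id for s in skeletons}
    report = ValidationReport()
    cell_ids: set[str] = set()
    for c in cells:
        if c.cell_id in cell_ids:
            report.issues.append(
                ValidationIssue("duplicate_id", f"duplicate cell id {c.cell_id}")
            )
        cell_ids.add(c.cell_id)
    seen_syn: set[str] = set()
    for s in synapses:
        if s.synapse_id in seen_syn:
            report.issues.append(
                ValidationIssue("duplicate_id", f"duplicate synapse id {s.synapse_id}")
            )
        seen_syn.add(s.synapse_id)
        for end, cid in (("pre", s.pre_cell), ("post", s.post_cell)):
            if cid not in cell_ids:
                report.issues.append(
                    ValidationIssue(
                        "unknown_cell",
                        f"synapse {s.synapse_id}: {end} cell {cid} has no record",
                    )
                )
        if s.pre_cell == s.post_cell:
            report.issues.append(
                ValidationIssue("autapse", f"synapse {s.synapse_id} on {s.pre_cell}")
            )
    for cid in sorted(cell_ids - skel_ids):
        report.issues.append(
            ValidationIssue("missing_skeleton", f"cell {cid} has no skeleton")
        )
    for cid in sorted(skel_ids - cell_ids):
        report.issues.append(
            ValidationIssue("skeleton_without_cell", f"skeleton {cid} has no cell record")
        )
    return report
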