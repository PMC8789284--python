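"""Per-cell-type connectivity summaries, selectivity calls, coverage and
compartment statistics for seed-column photoreceptor partners.

The summary schema mirrors the published seed-column tables: one row per
partner cell type with synapse counts per photoreceptor subtype (pale/yellow
R7 and R8 centrally; DRA R7 and R8 in the dorsal rim), the row sum, derived
percentages (%R7/%R8, %p/%y, %Total and the per-source %Total_R7/%Total_R8),
pooled rows for sub-threshold and unidentified cells, and a grand-total row.

All internal arithmetic is exact (integer counts and rationals); rounding
happens once, at presentation. The default rounding is round-half-to-even,
which reproduces the published tables' tie cells exactly; half-up is
available as a config option. Reliability threshold: a partner counts as
reliable with more than two synapses (>=3) from/to the seed photoreceptor
set. Selectivity: an input is called selective when at least 65% of it comes
from one source class, evaluated on unrounded fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CellRecord, SynapseRecord

__all__ = [
    "AnalysisConfig",
    "EdgeCount",
    "FROM_SEED",
    "TO_SEED",
    "edge_counts",
    "partner_subtype_counts",
    "threshold_partition",
    "summarize_counts",
    "type_summary",
    "selectivity_call",
    "selectivity_table",
    "coverage_stats",
    "coverage_from_summary",
    "compartment_breakdown",
    "pale_fraction_percent",
    "CENTRAL_SUBTYPES",
    "DRA_SUBTYPES",
    "POOLED_LABELS",
]

FROM_SEED = "from_seed_photoreceptors"
TO_SEED = "to_seed_photoreceptors"

CENTRAL_SUBTYPES = ("pR7", "yR7", "pR8", "yR8")
DRA_SUBTYPES = ("R7-DRA", "R8-DRA")

#: Column headers used for the DRA subtypes in the printed-table schema.
DRA_HEADER = {"R7-DRA": "DRAR7", "R8-DRA": "DRAR8"}

POOLED_LABELS = ("Identified_<3", "Unidentified_>=3", "Unidentified_<3")


@dataclass
class AnalysisConfig:
    min_synapses: int = 3            # ">2 synapses" reliability threshold
    selectivity_threshold: float = 0.65
    percent_decimals: int = 1
    rounding: str = "half-even"      # "half-even" | "half-up"

    def __post_init__(self) -> None:
        if self.min_synapses < 1:
            raise ValueError("min_synapses must be >= 1")
        if not 0.5 < self.selectivity_threshold <= 1.0:
            raise ValueError("selectivity_threshold must be in (0.5, 1]")
        if self.rounding not in ("half-even", "half-up"):
            raise ValueError(f"unknown rounding {self.rounding!r}")


@dataclass(frozen=True)
class EdgeCount:
    """Synapse count for one ordered (pre, post) cell pair."""

    pre_cell: str
    post_cell: str
    n: int
    n_chiasm: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or not 0 <= self.n_chiasm <= self.n:
            raise ValueError("require n >= 1 and 0 <= n_chiasm <= n")


def round_percent(
    numerator: int, denominator: int, config: AnalysisConfig
) -> float:
    """Exact rational percent, rounded once at ``percent_decimals``.

    A zero denominator reports 0.0 (matches the published all-zero rows).
    """
    if denominator == 0:
        return 0.0
    frac = Fraction(100 * numerator, denominator) * 10 ** config.percent_decimals
    if config.rounding == "half-even":
        scaled = round(frac)  # Fraction rounding is exact and half-to-even
    else:  # half-up
        floor = frac.numerator // frac.denominator
        rem = frac - floor
        scaled = floor + (1 if rem >= Fraction(1, 2) else 0)
    return float(scaled) / 10 ** config.percent_decimals


# ---------------------------------------------------------------------------
# Edges
# ---------------------------------------------------------------------------

def edge_counts(
    synapses: Sequence[SynapseRecord],
    direction: str,
    seed_cells: Iterable[str],
) -> list[EdgeCount]:
    """Aggregate synapses into per-(pre, post) edge counts.

    ``direction`` restricts to synapses whose presynaptic (``FROM_SEED``) or
    postsynaptic (``TO_SEED``) cell is in the seed photoreceptor set.
    ``n_chiasm`` counts the synapses tagged as sitting in the optic chiasm.
    """
    seed = set(seed_cells)
    if not seed:
        raise ValueError("empty seed cell set")
    if direction not in (FROM_SEED, TO_SEED):
        raise ValueError(f"unknown direction {direction!r}")
    counts: dict[tuple[str, str], list[int]] = {}
    for s in synapses:
        anchor = s.pre_cell if direction == FROM_SEED else s.post_cell
        if anchor not in seed:
            continue
        key = (s.pre_cell, s.post_cell)
        entry = counts.setdefault(key, [0, 0])
        entry[0] += 1
        if s.compartment == "chiasm":
            entry[1] += 1
    return [
        EdgeCount(pre, post, n, n_chiasm)
        for (pre, post), (n, n_chiasm) in sorted(counts.items())
    ]


def partner_subtype_counts(
    edges: Sequence[EdgeCount],
    cells: Mapping[str, CellRecord],
    direction: str,
) -> pd.DataFrame:
    """Per-partner-cell synapse counts split by seed photoreceptor subtype.

    Returns a DataFrame indexed by partner cell id with one column per
    subtype tag present. Raises if a seed photoreceptor lacks its tag.
    """
    rows: dict[str, dict[str, int]] = {}
    for e in edges:
        seed_id, partner = (
            (e.pre_cell, e.post_cell) if direction == FROM_SEED else (e.post_cell, e.pre_cell)
        )
        seed_rec = cells.get(seed_id)
        if seed_rec is None or seed_rec.subtype_tag is None:
            raise ValueError(f"seed photoreceptor {seed_id} has no subtype tag")
        rows.setdefault(partner, {})
        rows[partner][seed_rec.subtype_tag] = (
            rows[partner].get(seed_rec.subtype_tag, 0) + e.n
        )
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df.index.name = "cell_id"
    return df.sort_index()


def threshold_partition(
    totals: Mapping[str, int], config: AnalysisConfig
) -> tuple[set[str], set[str]]:
    """Split partner cells into reliable (>= min_synapses) and sub-threshold."""
    reliable = {c for c, n in totals.items() if n >= config.min_synapses}
    return reliable, set(totals) - reliable


# ---------------------------------------------------------------------------
# Type summaries
# ---------------------------------------------------------------------------

def _row_label(record: CellRecord | None, reliable: bool) -> str:
    identified = record is not None and record.identified
    if reliable:
        if identified:
            assert record is not None
            if record.status == "identified_type":
                return record.type_label  # type: ignore[return-value]
            return record.class_label  # type: ignore[return-value]
        return "Unidentified_>=3"
    return "Identified_<3" if identified else "Unidentified_<3"


def summarize_counts(
    counts: pd.DataFrame,
    config: AnalysisConfig | None = None,
    region: str = "central",
) -> pd.DataFrame:
    """Derive the percent columns and total row from per-type subtype counts.

    ``counts`` needs columns ``Type``, ``No.`` and the subtype count columns
    (``pR7,yR7,pR8,yR8`` centrally; ``DRAR7,DRAR8`` for the dorsal rim).
    Percentages: %R7 and %R8 of the row sum; %p and %y (central only) of the
    row sum; %Total of the grand total; %Total_R7 / %Total_R8 of the total
    output of each source class (denominators include the pooled rows).
    """
    config = config or AnalysisConfig()
    if region not in ("central", "dra"):
        raise ValueError(f"unknown region {region!r}")
    sub_cols = list(CENTRAL_SUBTYPES) if region == "central" else ["DRAR7", "DRAR8"]
    missing = [c for c in ["Type", "No.", *sub_cols] if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns {missing}")
    body = counts[counts["Type"] != "Total"].copy()
    body["Sum"] = body[sub_cols].sum(axis=1)
    if region == "central":
        r7_cols, r8_cols = ["pR7", "yR7"], ["pR8", "yR8"]
        p_cols, y_cols = ["pR7", "pR8"], ["yR7", "yR8"]
    else:
        r7_cols, r8_cols = ["DRAR7"], ["DRAR8"]
        p_cols = y_cols = []
    grand = int(body["Sum"].sum())
    total_r7 = int(body[r7_cols].to_numpy().sum())
    total_r8 = int(body[r8_cols].to_numpy().sum())

    def pct(num, den):
        return round_percent(int(num), int(den), config)

    out_rows = []
    for row in body.itertuples(index=False):
        d = dict(zip(body.columns, row))
        s = int(d["Sum"])
        r7 = sum(int(d[c]) for c in r7_cols)
        r8 = sum(int(d[c]) for c in r8_cols)
        rec = {k: d[k] for k in ["Type", "No.", *sub_cols, "Sum"]}
        rec["%R7"] = pct(r7, s)
        rec["%R8"] = pct(r8, s)
        if region == "central":
            rec["%p"] = pct(sum(int(d[c]) for c in p_cols), s)
            rec["%y"] = pct(sum(int(d[c]) for c in y_cols), s)
        rec["%Total"] = pct(s, grand)
        rec["%Total_R7"] = pct(r7, total_r7)
        rec["%Total_R8"] = pct(r8, total_r8)
        out_rows.append(rec)
    total_rec = {
        "Type": "Total",
        "No.": int(body["No."].sum()),
        **{c: int(body[c].sum()) for c in sub_cols},
        "Sum": grand,
        "%R7": pct(total_r7, grand),
        "%R8": pct(total_r8, grand),
        "%Total": pct(grand, grand),
        "%Total_R7": pct(total_r7, total_r7),
        "%Total_R8": pct(total_r8, total_r8),
    }
    if region == "central":
        total_rec["%p"] = pct(int(body[p_cols].to_numpy().sum()), grand)
        total_rec["%y"] = pct(int(body[y_cols].to_numpy().sum()), grand)
    out_rows.append(total_rec)
    cols = ["Type", "No.", *sub_cols, "Sum", "%R7", "%R8"]
    if region == "central":
        cols += ["%p", "%y"]
    cols += ["%Total", "%Total_R7", "%Total_R8"]
    return pd.DataFrame(out_rows, columns=cols)


def type_summary(
    edges: Sequence[EdgeCount],
    cells: Mapping[str, CellRecord],
    config: AnalysisConfig | None = None,
    direction: str = FROM_SEED,
    region: str = "central",
) -> pd.DataFrame:
    """Full per-type summary table from edge counts and cell annotations.

    Reliable cells (>= min_synapses across the seed set) are grouped by
    type label (or class label for class-only identifications); cells below
    threshold pool into "Identified_<3" / "Unidentified_<3", reliable
    unidentified cells into "Unidentified_>=3". Named rows sort by Sum
    descending (ties by name); pooled rows and the Total row close the
    table.
    """
    config = config or AnalysisConfig()
    per_cell = partner_subtype_counts(edges, cells, direction)
    sub_tags = list(CENTRAL_SUBTYPES) if region == "central" else list(DRA_SUBTYPES)
    for tag in sub_tags:
        if tag not in per_cell.columns:
            per_cell[tag] = 0
    per_cell = per_cell[sub_tags]
    totals = per_cell.sum(axis=1)
    reliable, _ = threshold_partition(totals.to_dict(), config)
    groups: dict[str, dict[str, int]] = {}
    ncells: dict[str, int] = {}
    for cell_id, row in per_cell.iterrows():
        label = _row_label(cells.get(cell_id), cell_id in reliable)
        g = groups.setdefault(label, {t: 0 for t in sub_tags})
        for t in sub_tags:
            g[t] += int(row[t])
        ncells[label] = ncells.get(label, 0) + 1
    header = (
        {t: t for t in CENTRAL_SUBTYPES} if region == "central" else DRA_HEADER
    )
    rows = []
    for label, g in groups.items():
        rows.append(
            {"Type": label, "No.": ncells[label], **{header[t]: g[t] for t in sub_tags}}
        )
    df = pd.DataFrame(rows)
    named = df[~df["Type"].isin(POOLED_LABELS)].copy()
    named["__sum"] = named[[header[t] for t in sub_tags]].sum(axis=1)
    named = named.sort_values(["__sum", "Type"], ascending=[False, True]).drop(
        columns="__sum"
    )
    pooled = [
        df[df["Type"] == lbl] for lbl in POOLED_LABELS if (df["Type"] == lbl).any()
    ]
    counts = pd.concat([named, *pooled], ignore_index=True)
    return summarize_counts(counts, config, region)


# ---------------------------------------------------------------------------
# Selectivity
# ---------------------------------------------------------------------------

def selectivity_call(
    counts_row: Mapping[str, int],
    config: AnalysisConfig | None = None,
    region: str = "central",
) -> tuple[str, str | None]:
    """Classify one summary row on the source and (central) mosaic axes.

    Evaluated on unrounded fractions; the threshold is inclusive. Returns
    ``(source_axis, mosaic_axis)`` with values "R7-selective" /
    "R8-selective" / "pale-selective" / "yellow-selective" / "mixed";
    ``mosaic_axis`` is None for the dorsal rim (no pale/yellow mosaic).
    """
    config = config or AnalysisConfig()
    thr = Fraction(config.selectivity_threshold).limit_denominator(10**6)
    if region == "central":
        r7 = counts_row["pR7"] + counts_row["yR7"]
        r8 = counts_row["pR8"] + counts_row["yR8"]
        p = counts_row["pR7"] + counts_row["pR8"]
        y = counts_row["yR7"] + counts_row["yR8"]
    else:
        r7, r8 = counts_row["DRAR7"], counts_row["DRAR8"]
        p = y = 0
    s = r7 + r8

    def axis(a: int, b: int, name_a: str, name_b: str) -> str:
        if s == 0:
            return "mixed"
        if Fraction(a, s) >= thr:
            return f"{name_a}-selective"
        if Fraction(b, s) >= thr:
            return f"{name_b}-selective"
        return "mixed"

    source = axis(r7, r8, "R7", "R8")
    mosaic = axis(p, y, "pale", "yellow") if region == "central" else None
    return source, mosaic


def selectivity_table(
    summary: pd.DataFrame,
    config: AnalysisConfig | None = None,
    region: str = "central",
) -> pd.DataFrame:
    """Selectivity calls for every named type row of a summary table."""
    rows = []
    for row in summary[~summary["Type"].isin(POOLED_LABELS + ("Total",))].to_dict(
        "records"
    ):
        source, mosaic = selectivity_call(row, config, region)
        rec = {"Type": row["Type"], "source_axis": source}
        if region == "central":
            rec["mosaic_axis"] = mosaic
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Coverage and compartments
# ---------------------------------------------------------------------------

def coverage_stats(
    edges: Sequence[EdgeCount],
    cells: Mapping[str, CellRecord],
    config: AnalysisConfig | None = None,
    direction: str = FROM_SEED,
) -> dict:
    """Identification coverage of the seed photoreceptors' synapses.

    Reports, as percentages rounded to ``percent_decimals``: the fraction of
    all synapses on partners whose cell type or class is identified; the
    same restricted to reliable (>= min_synapses) partners; and the fraction
    of reliable partner cells that are identified.
    """
    config = config or AnalysisConfig()
    totals: dict[str, int] = {}
    for e in edges:
        partner = e.post_cell if direction == FROM_SEED else e.pre_cell
        totals[partner] = totals.get(partner, 0) + e.n
    reliable, _ = threshold_partition(totals, config)
    total = sum(totals.values())
    identified = {c for c in totals if (rec := cells.get(c)) and rec.identified}
    ident_syn = sum(n for c, n in totals.items() if c in identified)
    rel_total = sum(totals[c] for c in reliable)
    rel_ident = sum(totals[c] for c in reliable & identified)
    return {
        "n_synapses": total,
        "n_identified_synapses": ident_syn,
        "identified_pct": round_percent(ident_syn, total, config),
        "n_reliable_synapses": rel_total,
        "n_reliable_identified_synapses": rel_ident,
        "reliable_identified_pct": round_percent(rel_ident, rel_total, config),
        "n_reliable_cells": len(reliable),
        "n_reliable_identified_cells": len(reliable & identified),
        "reliable_cells_identified_pct": round_percent(
            len(reliable & identified), len(reliable), config
        ),
    }


def coverage_from_summary(
    counts: pd.DataFrame | Sequence[pd.DataFrame],
    config: AnalysisConfig | None = None,
) -> dict:
    """Coverage statistics from summary-table counts (pooled rows included).

    Accepts one or several counts tables (e.g. the central and dorsal-rim
    output tables together); unidentified synapses are those in the
    "Unidentified_>=3" and "Unidentified_<3" rows, and sub-threshold
    synapses those in the "_<3" rows.
    """
    config = config or AnalysisConfig()
    if isinstance(counts, pd.DataFrame):
        counts = [counts]
    total = ident = rel_total = rel_ident = 0
    for df in counts:
        body = df[df["Type"] != "Total"].copy()
        sub_cols = [
            c for c in body.columns if c in CENTRAL_SUBTYPES or c in ("DRAR7", "DRAR8")
        ]
        sums = body[sub_cols].sum(axis=1).astype(int)
        for label, s in zip(body["Type"], sums):
            total += s
            is_unident = label.startswith("Unidentified")
            is_sub = label.endswith("_<3")
            if not is_unident:
                ident += s
            if not is_sub:
                rel_total += s
                if not is_unident:
                    rel_ident += s
    return {
        "n_synapses": total,
        "n_identified_synapses": ident,
        "identified_pct": round_percent(ident, total, config),
        "n_reliable_synapses": rel_total,
        "n_reliable_identified_synapses": rel_ident,
        "reliable_identified_pct": round_percent(rel_ident, rel_total, config),
    }


def compartment_breakdown(
    edges: Sequence[EdgeCount],
    cells: Mapping[str, CellRecord],
    direction: str = FROM_SEED,
) -> pd.DataFrame:
    """Chiasm synapse fraction per photoreceptor subtype and partner type.

    Requires every edge to carry its chiasm count (compartments must have
    been set on the underlying synapses, by tag or by negative depth).
    Returns rows (subtype_tag, partner_type, n, n_chiasm, chiasm_fraction);
    invariant to edge order.
    """
    rows: dict[tuple[str, str], list[int]] = {}
    for e in edges:
        seed_id, partner = (
            (e.pre_cell, e.post_cell) if direction == FROM_SEED else (e.post_cell, e.pre_cell)
        )
        seed_rec = cells.get(seed_id)
        if seed_rec is None or seed_rec.subtype_tag is None:
            raise ValueError(f"seed photoreceptor {seed_id} has no subtype tag")
        partner_rec = cells.get(partner)
        ptype = _row_label(partner_rec, reliable=True) if partner_rec else "Unidentified_>=3"
        key = (seed_rec.subtype_tag, ptype)
        entry = rows.setdefault(key, [0, 0])
        entry[0] += e.n
        entry[1] += e.n_chiasm
    out = [
        {
            "subtype_tag": tag,
            "partner_type": ptype,
            "n": n,
            "n_chiasm": nc,
            "chiasm_fraction": nc / n,
        }
        for (tag, ptype), (n, nc) in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["subtype_tag", "partner_type", "n", "n_chiasm", "chiasm_fraction"])


def require_compartments(synapses: Sequence[SynapseRecord]) -> None:
    """Raise, listing offenders, if any synapse lacks a compartment tag."""
    missing = [s.synapse_id for s in synapses if s.compartment is None]
    if missing:
        shown = ", ".join(missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(f"compartment unset on synapses: {shown}{more}")


def pale_fraction_percent(n_pale: int, n_total: int) -> int:
    """Pale-column share as an integer percent (exact half-even rounding)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(round(Fraction(100 * n_pale, n_total)))
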