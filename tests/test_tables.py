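"""Edge aggregation, per-type summaries, selectivity, coverage, compartments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medconn.io import CellRecord, Point3, SynapseRecord, synapse_frame
from medconn.reference import load_reference_table, reference_counts, table_region
from medconn.tables import (
    FROM_SEED,
    TO_SEED,
    AnalysisConfig,
    EdgeCount,
    compartment_breakdown,
    coverage_stats,
    edge_counts,
    pale_fraction_percent,
    require_compartments,
    round_percent,
    selectivity_call,
    summarize_counts,
    threshold_partition,
    type_summary,
)


def syn(sid, pre, post, compartment="medulla"):
    return SynapseRecord(sid, pre, post, Point3(0, 0, 0), compartment)


@pytest.fixture(scope="module")
def seed_context(small_dataset):
    cells = {c.cell_id: c for c in small_dataset.cells}
    tags = small_dataset.terminals.set_index("cell_id")["subtype_tag"]
    central = set(tags.index[~tags.str.endswith("-DRA")])
    dra = set(tags.index[tags.str.endswith("-DRA")])
    return small_dataset, cells, central, dra


class TestEdgeCounts:
    def test_three_synapses_collapse_to_one_edge(self):
        edges = edge_counts(
            [syn(f"s{i}", "A", "B") for i in range(3)], FROM_SEED, {"A"}
        )
        assert edges == [EdgeCount("A", "B", 3, 0)]

    def test_direction_filter_excludes_non_seed_edges(self):
        synapses = [syn("s1", "A", "B"), syn("s2", "X", "B"), syn("s3", "B", "A")]
        out_edges = edge_counts(synapses, FROM_SEED, {"A"})
        in_edges = edge_counts(synapses, TO_SEED, {"A"})
        assert [(e.pre_cell, e.post_cell) for e in out_edges] == [("A", "B")]
        assert [(e.pre_cell, e.post_cell) for e in in_edges] == [("B", "A")]

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            edge_counts([], FROM_SEED, set())

    def test_edge_total_equals_generated_synapse_count(self, seed_context):
        ds, _, central, dra = seed_context
        edges = edge_counts(ds.synapses, FROM_SEED, central | dra)
        assert sum(e.n for e in edges) == len(ds.synapses)


class TestThreshold:
    def test_boundary_at_three_synapses(self):
        reliable, sub = threshold_partition({"a": 3, "b": 2}, AnalysisConfig())
        assert reliable == {"a"} and sub == {"b"}

    def test_raising_threshold_never_grows_reliable_set(self):
        totals = {f"c{i}": i for i in range(1, 12)}
        sets = [
            threshold_partition(totals, AnalysisConfig(min_synapses=k))[0]
            for k in range(1, 8)
        ]
        assert all(b <= a for a, b in zip(sets, sets[1:]))


class TestRounding:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (160, 445, 36.0),
            (78, 96, 81.2),   # exact tie 81.25 rounds to even
            (18, 96, 18.8),   # exact tie 18.75 rounds to even
            (285, 1520, 18.8),
            (1187, 2707, 43.8),
            (0, 0, 0.0),
        ],
    )
    def test_half_even_percent(self, num, den, expected):
        assert round_percent(num, den, AnalysisConfig()) == expected

    def test_half_up_option(self):
        cfg = AnalysisConfig(rounding="half-up")
        assert round_percent(78, 96, cfg) == 81.3
        assert round_percent(18, 96, cfg) == 18.8


class TestSummaryRows:
    def test_strong_mixed_feedback_row_reproduced(self):
        # Dm9: 94/66/142/143 against grand totals 2707 (R7 1187, R8 1520)
        out = summarize_counts(reference_counts("central_outputs")).set_index("Type")
        row = out.loc["Dm9"]
        assert (
            row["Sum"],
            row["%R7"],
            row["%R8"],
            row["%p"],
            row["%y"],
            row["%Total"],
            row["%Total_R7"],
            row["%Total_R8"],
        ) == (445, 36.0, 64.0, 53.0, 47.0, 16.4, 13.5, 18.8)

    def test_pure_r7_dorsal_rim_row_reproduced(self):
        out = summarize_counts(
            reference_counts("dra_outputs"), region="dra"
        ).set_index("Type")
        row = out.loc["Dm-DRA1"]
        assert (
            row["Sum"],
            row["%R7"],
            row["%R8"],
            row["%Total"],
            row["%Total_R7"],
            row["%Total_R8"],
        ) == (212, 100.0, 0.0, 15.9, 25.3, 0.0)

    def test_single_type_gets_all_of_total(self):
        counts = pd.DataFrame(
            [{"Type": "Dm8", "No.": 1, "pR7": 10, "yR7": 5, "pR8": 0, "yR8": 0}]
        )
        out = summarize_counts(counts)
        assert out.set_index("Type").loc["Dm8", "%Total"] == 100.0

    def test_row_identities_on_generated_data(self, seed_context):
        ds, cells, central, _ = seed_context
        edges = edge_counts(ds.synapses, FROM_SEED, central)
        summary = type_summary(edges, cells, region="central")
        body = summary[summary["Type"] != "Total"]
        total = summary[summary["Type"] == "Total"].iloc[0]
        assert body["Sum"].sum() == total["Sum"]
        assert (body[["pR7", "yR7", "pR8", "yR8"]].sum(axis=1) == body["Sum"]).all()
        nonzero = body[body["Sum"] > 0]
        assert ((nonzero["%R7"] + nonzero["%R8"] - 100).abs() <= 0.1).all()
        assert ((nonzero["%p"] + nonzero["%y"] - 100).abs() <= 0.1).all()
        assert abs(body["%Total"].sum() - 100) <= 0.2
        # grand total equals the generated central-seed synapse count exactly
        n_central = sum(
            1 for s in ds.synapses if s.pre_cell in central
        )
        assert total["Sum"] == n_central

    def test_summary_deterministic_bytes(self, seed_context, tmp_path):
        ds, cells, central, _ = seed_context
        edges = edge_counts(ds.synapses, FROM_SEED, central)
        paths = []
        for name in ("a.csv", "b.csv"):
            p = tmp_path / name
            type_summary(edges, cells, region="central").to_csv(p, index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestSelectivity:
    def test_r8_and_yellow_selective_type(self):
        row = {"pR7": 8, "yR7": 9, "pR8": 20, "yR8": 103}
        assert selectivity_call(row) == ("R8-selective", "yellow-selective")

    def test_balanced_type_is_mixed(self):
        row = {"pR7": 94, "yR7": 66, "pR8": 142, "yR8": 143}  # %R8 = 64.0
        source, mosaic = selectivity_call(row)
        assert source == "mixed"

    def test_threshold_is_inclusive_at_exactly_65_percent(self):
        row = {"pR7": 13, "yR7": 0, "pR8": 7, "yR8": 0}
        source, mosaic = selectivity_call(row)
        assert source == "R7-selective"
        assert mosaic == "pale-selective"

    def test_dra_rows_have_no_mosaic_axis(self):
        source, mosaic = selectivity_call(
            {"DRAR7": 212, "DRAR8": 0}, region="dra"
        )
        assert source == "R7-selective" and mosaic is None

    def test_r8_free_generator_type_called_r7_selective(self, seed_context):
        ds, cells, central, _ = seed_context
        edges = edge_counts(ds.synapses, FROM_SEED, central)
        summary = type_summary(edges, cells, region="central")
        dm8 = summary.set_index("Type").loc["Dm8"]
        assert dm8["%R7"] == 100.0
        counts = {k: int(dm8[k]) for k in ("pR7", "yR7", "pR8", "yR8")}
        assert selectivity_call(counts)[0] == "R7-selective"


class TestCoverage:
    def test_all_unidentified_gives_zero(self):
        edges = [EdgeCount("A", "B", 5)]
        cells = {"B": CellRecord("B", status="unidentified")}
        cov = coverage_stats(edges, cells)
        assert cov["identified_pct"] == 0.0

    def test_hiding_labels_reduces_coverage_exactly(self, seed_context):
        ds, cells, central, dra = seed_context
        edges = edge_counts(ds.synapses, FROM_SEED, central | dra)
        totals: dict[str, int] = {}
        for e in edges:
            totals[e.post_cell] = totals.get(e.post_cell, 0) + e.n
        hidden = sorted(totals)[:5]
        masked = {
            cid: (
                CellRecord(cid, status="unidentified")
                if cid in hidden
                else rec
            )
            for cid, rec in cells.items()
        }
        cov = coverage_stats(edges, masked)
        hidden_share = sum(totals[c] for c in hidden)
        expected = round_percent(
            cov["n_synapses"] - hidden_share, cov["n_synapses"], AnalysisConfig()
        )
        assert cov["identified_pct"] == expected


class TestCompartments:
    def test_all_medulla_synapses_give_zero_fractions(self):
        edges = [EdgeCount("A", "B", 4, 0)]
        cells = {
            "A": CellRecord("A", type_label="R7", status="identified_type", subtype_tag="pR7"),
            "B": CellRecord("B", type_label="Dm8", status="identified_type"),
        }
        out = compartment_breakdown(edges, cells)
        assert (out["chiasm_fraction"] == 0.0).all()

    def test_fractions_invariant_to_edge_order(self, seed_context):
        ds, cells, central, dra = seed_context
        edges = edge_counts(ds.synapses, FROM_SEED, central | dra)
        a = compartment_breakdown(edges, cells)
        b = compartment_breakdown(list(reversed(edges)), cells)
        pd.testing.assert_frame_equal(a, b)

    def test_chiasm_heavy_rule_recovered_within_binomial_interval(self, seed_context):
        ds, cells, central, _ = seed_context
        edges = edge_counts(ds.synapses, FROM_SEED, central)
        out = compartment_breakdown(edges, cells).set_index(
            ["subtype_tag", "partner_type"]
        )
        # R7 -> R8 generated with chiasm probability 0.8
        row = out.loc[("pR7", "R8")]
        n, k = int(row["n"]), int(row["n_chiasm"])
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.8)
        assert lo <= k <= hi

    def test_unset_compartment_raises_with_offenders(self):
        bad = [syn("s9", "A", "B", compartment=None)]
        with pytest.raises(ValueError, match="s9"):
            require_compartments(bad)


class TestPaleFraction:
    def test_integer_percent_of_generated_mosaic(self, small_dataset):
        truth = small_dataset.truth.columns
        n_pale = int((truth["subtype"] == "pale").sum())
        n_total = int((truth["subtype"] != "DRA").sum())
        got = pale_fraction_percent(n_pale, n_total)
        assert got == int(round(100 * n_pale / n_total))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            pale_fraction_percent(1, 0)
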