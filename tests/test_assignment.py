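"""Hit screening, threshold calibration and the assignment cascade."""

import numpy as np
import pytest

from ednakit.assignment import (
    Assignment,
    AssignmentError,
    ThresholdSet,
    assign_query,
    calibrate_thresholds,
    collapse_taxa,
    merge_across_barcodes,
    merge_count_tables,
    screen_hits,
)
from ednakit.io import AuditLog, BlastHit, Checklist, Lineage

from conftest import make_table


def hit(q="q1", acc="A1", ident=100.0, cov=95.0, bits=300.0, length=170):
    return BlastHit(q, acc, ident, cov, length, 1e-40, bits)


LINEAGES = {
    "X1": Lineage("X1", "Genus1 alpha", "Genus1", "Fam1", "Ord1", "Actinopterygii"),
    "X2": Lineage("X2", "Genus1 beta", "Genus1", "Fam1", "Ord1", "Actinopterygii"),
    "Y1": Lineage("Y1", "Genus2 gamma", "Genus2", "Fam1", "Ord1", "Actinopterygii"),
    "Z1": Lineage("Z1", "Genus3 delta", "Genus3", "Fam2", "Ord1", "Actinopterygii"),
}
CHECKLIST = Checklist({"Genus1 alpha": "Genus1", "Genus2 gamma": "Genus2"})


class TestScreenHits:
    def test_coverage_just_below_threshold_removed(self):
        kept = screen_hits([hit(cov=89.9), hit(acc="A2", cov=90.0)])
        assert [h.subject_accession for h in kept] == ["A2"]

    def test_zero_thresholds_keep_everything(self):
        hits = [hit(acc=f"A{i}", ident=80 + i, cov=50 + i) for i in range(10)]
        assert set(screen_hits(hits, 0, 0, 40)) == set(hits)

    def test_top_40_by_bitscore(self):
        hits = [hit(acc=f"A{i:02d}", bits=float(i)) for i in range(50)]
        kept = screen_hits(hits)
        assert len(kept) == 40
        expected = sorted(hits, key=lambda h: -h.bitscore)[:40]
        assert set(kept) == set(expected)


class TestCalibrate:
    def _toy_hits(self, values, level="same_genus"):
        """One query per value: a 100% self hit anchors the query, one hit at
        the value realises the requested relationship level."""
        other_acc = {"same_genus": "X2", "same_family": "Y1", "same_order": "Z1"}[level]
        hits = []
        for i, v in enumerate(values):
            q = f"q{i}"
            hits.append(hit(q=q, acc="X1", ident=100.0, bits=300.0))
            hits.append(hit(q=q, acc=other_acc, ident=float(v), bits=200.0))
        return hits

    def test_pinned_percentile_interpolation(self):
        # pooled congeneric means [95..100]; the 95th percentile interpolates
        # to 99.75 at position 1 + 0.95 * 5
        hits = self._toy_hits([95, 96, 97, 98, 99, 100])
        with pytest.warns(UserWarning):
            ts = calibrate_thresholds(hits, LINEAGES, mapping="direct")
        assert ts.diagnostics["percentiles"]["same_genus"] == pytest.approx(99.75, abs=1e-12)

    def test_direct_mapping_sets_genus_min_from_congeneric_level(self):
        hits = self._toy_hits([93, 94, 95, 96, 97, 98])
        with pytest.warns(UserWarning):  # family level falls back
            ts = calibrate_thresholds(hits, LINEAGES, mapping="direct")
        assert ts.genus_min == pytest.approx(97.75, abs=1e-12)

    def test_adjacent_mapping_reads_genus_min_from_family_level(self):
        hits = self._toy_hits([91, 92, 93, 94, 95, 96], level="same_family")
        with pytest.warns(UserWarning):
            ts = calibrate_thresholds(hits, LINEAGES, mapping="adjacent")
        assert ts.genus_min == pytest.approx(95.75, abs=1e-12)

    def test_degenerate_all_same_species_falls_back_with_warning(self):
        hits = [hit(q="q0", acc="X1"), hit(q="q0", acc="X1", ident=99.5)]
        with pytest.warns(UserWarning, match="falling back"):
            ts = calibrate_thresholds(hits, LINEAGES)
        assert ts.genus_min == 93.0 and ts.family_min == 89.0

    def test_invariant_to_hit_order_and_query_relabeling(self):
        hits = self._toy_hits([93, 94, 95, 96, 97, 98])
        with pytest.warns(UserWarning):
            a = calibrate_thresholds(hits, LINEAGES, mapping="direct")
        relabeled = [
            BlastHit("renamed_" + h.query_id, h.subject_accession,
                     h.percent_identity, h.query_coverage, h.alignment_length,
                     h.evalue, h.bitscore)
            for h in reversed(hits)
        ]
        with pytest.warns(UserWarning):
            b = calibrate_thresholds(relabeled, LINEAGES, mapping="direct")
        assert a.genus_min == b.genus_min and a.family_min == b.family_min

    def test_missing_lineage_is_an_error(self):
        with pytest.raises(AssignmentError, match="UNKNOWN"):
            calibrate_thresholds([hit(acc="UNKNOWN")], LINEAGES)


class TestAssignQuery:
    TS = ThresholdSet(genus_min=93.0, family_min=89.0)

    def test_single_perfect_hit_gives_species(self):
        a = assign_query([hit(acc="X1", ident=100.0)], self.TS, CHECKLIST, LINEAGES)
        assert (a.assigned_rank, a.assigned_taxon) == ("species", "Genus1 alpha")
        assert not a.tie_broken_by_checklist

    def test_checklist_breaks_species_tie(self):
        hits = [hit(acc="X1", ident=100.0), hit(acc="Z1", ident=100.0)]
        a = assign_query(hits, self.TS, CHECKLIST, LINEAGES)
        assert a.assigned_taxon == "Genus1 alpha"
        assert a.tie_broken_by_checklist

    def test_below_species_band_unique_genus(self):
        hits = [hit(acc="X1", ident=97.0), hit(acc="X2", ident=97.0)]
        a = assign_query(hits, self.TS, CHECKLIST, LINEAGES)
        assert (a.assigned_rank, a.assigned_taxon) == ("genus", "Genus1")

    def test_family_level_fallback(self):
        hits = [hit(acc="X1", ident=91.0), hit(acc="Y1", ident=91.0)]
        a = assign_query(hits, self.TS, CHECKLIST, LINEAGES)
        assert (a.assigned_rank, a.assigned_taxon) == ("family", "Fam1")

    def test_below_family_min_unassigned(self):
        a = assign_query([hit(acc="X1", ident=85.0)], self.TS, CHECKLIST, LINEAGES)
        assert a.assigned_rank == "unassigned" and a.assigned_taxon == ""

    def test_species_tie_off_checklist_drops_to_genus_rule(self):
        # both tied species on the checklist -> unresolved at species, and the
        # tied genera differ too -> family
        hits = [hit(acc="X1", ident=100.0), hit(acc="Y1", ident=100.0)]
        a = assign_query(hits, self.TS, CHECKLIST, LINEAGES)
        assert a.assigned_rank == "family" and a.assigned_taxon == "Fam1"

    def test_missing_lineage_names_accession(self):
        with pytest.raises(AssignmentError, match="NOPE"):
            assign_query([hit(acc="NOPE")], self.TS, CHECKLIST, LINEAGES)

    def test_raising_genus_min_only_coarsens(self):
        rng = np.random.default_rng(0)
        accs = list(LINEAGES)
        loose = ThresholdSet(genus_min=93.0, family_min=89.0)
        strict = ThresholdSet(genus_min=96.0, family_min=89.0)
        from ednakit.assignment import RANK_ORDER

        for _ in range(50):
            hits = [
                hit(acc=rng.choice(accs), ident=float(rng.uniform(85, 100)))
                for _ in range(rng.integers(1, 5))
            ]
            a = assign_query(hits, loose, CHECKLIST, LINEAGES)
            b = assign_query(hits, strict, CHECKLIST, LINEAGES)
            assert RANK_ORDER[b.assigned_rank] >= RANK_ORDER[a.assigned_rank]


class TestMergeAcrossBarcodes:
    def test_species_by_either_barcode_wins(self):
        per = {
            "mifish": {"m1": Assignment("m1", "species", "Genus1 alpha", 100.0)},
            "riaz": {"r1": Assignment("r1", "genus", "Genus1", 97.0)},
        }
        groups = {"m1": "g", "r1": "g"}
        out = merge_across_barcodes(per, groups)
        assert out["g"].assigned_rank == "species"
        assert out["g"].assigned_taxon == "Genus1 alpha"
        assert out["g"].supporting_barcodes == frozenset({"mifish"})

    def test_conflicting_species_resolve_to_common_genus_and_log(self):
        per = {
            "mifish": {"m1": Assignment("m1", "species", "Genus1 alpha", 100.0)},
            "riaz": {"r1": Assignment("r1", "species", "Genus1 beta", 100.0)},
        }
        by_name = {
            "Genus1 alpha": LINEAGES["X1"],
            "Genus1 beta": LINEAGES["X2"],
        }
        audit = AuditLog()
        out = merge_across_barcodes(per, {"m1": "g", "r1": "g"}, by_name, audit)
        assert out["g"].assigned_rank == "genus"
        assert out["g"].assigned_taxon == "Genus1"
        assert len(audit) == 1 and audit.records[0].reason == "conflicting_assignments"

    def test_counts_sum_across_barcodes(self):
        a = make_table({"Genus1 alpha": [3, 1]}, ["r1", "r2"])
        b = make_table({"Genus1 alpha": [4, 0], "Genus2 gamma": [1, 1]}, ["r1", "r2"])
        merged = merge_count_tables([a, b])
        assert merged.counts.loc["Genus1 alpha"].tolist() == [7, 1]
        assert merged.counts.loc["Genus2 gamma"].tolist() == [1, 1]


class TestCollapse:
    def test_same_species_rows_sum(self):
        table = make_table({"asv1": [5, 0], "asv2": [2, 3]}, ["r1", "r2"])
        assignments = {
            "asv1": Assignment("asv1", "species", "Genus1 alpha", 100.0),
            "asv2": Assignment("asv2", "species", "Genus1 alpha", 99.5),
        }
        out = collapse_taxa(table, assignments)
        assert out.counts.loc["Genus1 alpha"].tolist() == [7, 3]
        assert out.row_meta.loc["Genus1 alpha", "rank"] == "species"

    def test_unassigned_rows_dropped_and_logged(self):
        table = make_table({"asv1": [5, 0], "asv2": [2, 3]}, ["r1", "r2"])
        assignments = {
            "asv1": Assignment("asv1", "species", "Genus1 alpha", 100.0),
            "asv2": Assignment("asv2", "unassigned", "", 82.0),
        }
        audit = AuditLog()
        out = collapse_taxa(table, assignments, audit=audit)
        assert out.taxa == ["Genus1 alpha"]
        assert len(audit) == 1 and audit.records[0].reason == "unassigned"

    def test_total_reads_of_retained_rows_conserved(self):
        rng = np.random.default_rng(2)
        n = 12
        counts = {f"asv{i}": rng.integers(0, 50, 3).tolist() for i in range(n)}
        table = make_table(counts, ["r1", "r2", "r3"])
        taxa = ["Genus1 alpha", "Genus1", "Fam1"]
        ranks = ["species", "genus", "family"]
        assignments = {
            f"asv{i}": Assignment(f"asv{i}", ranks[i % 3], taxa[i % 3], 95.0)
            for i in range(n)
        }
        out = collapse_taxa(table, assignments)
        assert out.counts.to_numpy().sum() == table.counts.to_numpy().sum()

    def test_missing_assignment_is_an_error(self):
        table = make_table({"asv1": [1]}, ["r1"])
        with pytest.raises(AssignmentError):
            collapse_taxa(table, {})
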