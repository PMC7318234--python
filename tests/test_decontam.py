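"""Blacklist, control-frequency and replicate-support filters."""

import pandas as pd
import pytest

from ednakit.decontam import (
    blacklist_filter,
    control_frequency_filter,
    replicate_support_filter,
)
from ednakit.io import AuditLog, Lineage

from conftest import make_table


def ctrl_table(counts, cols=("s1", "s2", "c1")):
    return make_table(dict(counts), list(cols), roles={"c1": "field_control"})


class TestControlFrequency:
    def test_control_dominant_taxon_removed(self):
        # rel abundance 0.02 in the control vs at most 0.01 in samples
        table = ctrl_table({
            "bad": [10, 5, 2],
            "filler": [990, 995, 98],
        })
        audit = AuditLog()
        out = control_frequency_filter(table, audit=audit)
        assert "bad" not in out.taxa
        assert len(audit) == 1 and audit.records[0].reason == "control_frequency"
        assert "max_control" in audit.records[0].details

    def test_taxon_absent_from_controls_retained(self):
        table = ctrl_table({"good": [10, 5, 0], "filler": [90, 95, 100]})
        out = control_frequency_filter(table)
        assert "good" in out.taxa

    def test_low_level_control_presence_retained(self):
        # 0.001 in the extraction control but 0.05 in a sample
        table = make_table(
            {"retained": [50, 40, 1], "filler": [950, 960, 999]},
            ["s1", "s2", "e1"], roles={"e1": "extraction_control"},
        )
        out = control_frequency_filter(table)
        assert "retained" in out.taxa

    def test_no_controls_is_a_warned_no_op(self):
        table = make_table({"t": [1, 2]}, ["s1", "s2"])
        with pytest.warns(UserWarning, match="no control columns"):
            out = control_frequency_filter(table)
        assert out.taxa == table.taxa

    def test_raw_mode_compares_counts(self):
        # raw counts: 2 in control < 5 in sample -> retained even though the
        # control column is shallow
        table = ctrl_table({"t": [5, 0, 2], "filler": [995, 1000, 8]})
        assert "t" not in control_frequency_filter(table).taxa
        assert "t" in control_frequency_filter(table, mode="raw").taxa

    def test_idempotent(self):
        table = ctrl_table({
            "bad": [10, 5, 2], "edge": [1, 1, 1], "filler": [989, 994, 97],
        })
        once = control_frequency_filter(table)
        twice = control_frequency_filter(once)
        assert once.taxa == twice.taxa
        pd.testing.assert_frame_equal(once.counts, twice.counts)


BY_NAME = {
    "Bos": Lineage("", genus="Bos", family="Bovidae", order="Artiodactyla",
                   class_="Mammalia"),
    "Bos taurus": Lineage("", species="Bos taurus", genus="Bos", family="Bovidae",
                          order="Artiodactyla", class_="Mammalia"),
    "Capra hircus": Lineage("", species="Capra hircus", genus="Capra",
                            family="Bovidae", order="Artiodactyla", class_="Mammalia"),
    "Fish x": Lineage("", species="Fish x", genus="Fish", family="Fishidae",
                      order="Fishiformes", class_="Actinopterygii"),
}


class TestBlacklist:
    def test_open_nomenclature_genus_match(self):
        table = make_table({"Bos sp.": [1, 2], "Fish x": [3, 4]}, ["r1", "r2"])
        audit = AuditLog()
        out = blacklist_filter(table, {"Bos"}, BY_NAME, audit=audit)
        assert out.taxa == ["Fish x"]
        assert audit.records[0].reason == "blacklisted"

    def test_empty_blacklist_is_identity(self):
        table = make_table({"Bos taurus": [1, 2]}, ["r1", "r2"])
        out = blacklist_filter(table, set(), BY_NAME)
        assert out.taxa == table.taxa

    def test_family_entry_removes_member_genera(self):
        table = make_table(
            {"Bos taurus": [1, 0], "Capra hircus": [2, 0], "Fish x": [3, 4]},
            ["r1", "r2"],
        )
        out = blacklist_filter(table, {"Bovidae"}, BY_NAME)
        assert out.taxa == ["Fish x"]

    def test_idempotent(self):
        table = make_table({"Bos taurus": [1, 2], "Fish x": [3, 4]}, ["r1", "r2"])
        once = blacklist_filter(table, {"Bos"}, BY_NAME)
        twice = blacklist_filter(once, {"Bos"}, BY_NAME)
        assert once.taxa == twice.taxa


class TestReplicateSupport:
    def test_single_replicate_taxon_removed(self):
        table = make_table({"one": [5, 0, 0], "two": [1, 1, 0]}, ["r1", "r2", "r3"])
        audit = AuditLog()
        out = replicate_support_filter(table, audit=audit)
        assert out.taxa == ["two"]
        assert audit.records[0].reason == "single_replicate"

    def test_min_reps_one_is_identity(self):
        table = make_table({"one": [5, 0, 0]}, ["r1", "r2", "r3"])
        assert replicate_support_filter(table, min_reps=1).taxa == ["one"]

    def test_controls_do_not_count_as_support(self):
        table = make_table(
            {"t": [5, 0, 9]}, ["r1", "r2", "c1"], roles={"c1": "pcr_control"}
        )
        assert replicate_support_filter(table).taxa == []

    def test_within_sample_three_of_four(self):
        cols = [f"r{i}" for i in range(1, 5)]
        water = {c: "ws1" for c in cols}
        sites = {c: "siteA" for c in cols}
        table = make_table(
            {"weak": [1, 1, 0, 0], "strong": [1, 1, 1, 0]},
            cols, water=water, sites=sites,
        )
        out = replicate_support_filter(table, min_reps=3, scope="within_sample")
        assert out.taxa == ["strong"]

    def test_within_sample_min_reps_exceeding_replicates_errors(self):
        table = make_table({"t": [1, 1]}, ["r1", "r2"])
        with pytest.raises(ValueError, match="exceeds"):
            replicate_support_filter(table, min_reps=3, scope="within_sample")

    def test_idempotent_both_scopes(self):
        cols = [f"r{i}" for i in range(1, 5)]
        water = {c: "ws1" for c in cols}
        sites = {c: "siteA" for c in cols}
        table = make_table(
            {"a": [1, 0, 0, 0], "b": [2, 3, 0, 0], "c": [1, 1, 1, 1]},
            cols, water=water, sites=sites,
        )
        for kwargs in (dict(), dict(min_reps=3, scope="within_sample")):
            once = replicate_support_filter(table, **kwargs)
            twice = replicate_support_filter(once, **kwargs)
            pd.testing.assert_frame_equal(once.counts, twice.counts)


def test_control_filter_recall_is_one_when_contamination_only_in_controls():
    from ednakit.synthetic_data import (
        SimulationConfig,
        simulate_read_counts,
        simulate_reference_and_hits,
    )

    cfg = SimulationConfig(
        n_species_pool=30, n_habitats=3, n_sites_per_habitat=2, seed=7,
        sample_contamination_rate=0.0,
    )
    _, _, truth = simulate_reference_and_hits(cfg)
    table = simulate_read_counts(cfg, truth)
    # taxon-level view: map ASVs to species names
    mapping = truth.asv_species["mifish"]
    renamed = table.with_counts(table.counts.rename(index=mapping))
    out = control_frequency_filter(renamed)
    injected = [c for c in truth.contaminants if c in renamed.taxa]
    assert injected, "no contaminants injected"
    assert all(c not in out.taxa for c in injected)
    # real species leaking into controls at trace level survive
    assert all(l in out.taxa for l in truth.leak_species if l in renamed.taxa)
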