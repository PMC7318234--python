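#!/usr/bin/env python
"""Decontaminate the merged taxon tables: blacklist, control-frequency and
replicate-support filters, with a machine-readable audit ledger.

Writes filtered_counts.tsv and audit.tsv under results/pipeline/<season>/.
"""

from pathlib import Path

from ednakit import decontam
from ednakit.io import AuditLog, read_counts, read_taxonomy, taxon_lineages

ROOT = Path(__file__).resolve().parents[1] / "results"
SEASONS = ("2016", "2017")


def main() -> None:
    for season in SEASONS:
        src = ROOT / "synthetic" / season
        pipe = ROOT / "pipeline" / season
        table = read_counts(pipe / "merged_counts.tsv", pipe / "samplesheet.tsv")
        by_name = taxon_lineages(read_taxonomy(src / "taxonomy.tsv"))
        blacklist = {
            line.strip()
            for line in (src / "blacklist.txt").read_text().splitlines()
            if line.strip()
        }
        audit = AuditLog()
        n0 = len(table.taxa)
        table = decontam.blacklist_filter(table, blacklist, by_name, audit=audit)
        table = decontam.control_frequency_filter(table, audit=audit)
        table = decontam.replicate_support_filter(table, audit=audit)
        table.write(pipe / "filtered_counts.tsv")
        audit.write(pipe / "audit.tsv")
        reasons = audit.to_frame().query("action == 'removed'")["reason"].value_counts()
        summary = ", ".join(f"{k}={v}" for k, v in reasons.items()) or "none"
        print(
            f"[{season}] {n0} -> {len(table.taxa)} taxa; removals by reason: {summary}"
        )


if __name__ == "__main__":
    main()
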