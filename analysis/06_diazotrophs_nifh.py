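#!/usr/bin/env python
"""Screen communities for putative nitrogen fixers and tally nifH OTUs.

Sums the relative abundance of taxa whose lineages match the curated
diazotroph list for every community, compares against the generator's truth,
and totals the packaged nitrogenase OTU count table per OTU and per order.
Writes results/diazotroph_abundance.tsv and results/nifh_totals.tsv.
"""

import importlib.util
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from hypolith.qc import (load_diazotroph_patterns, load_nifh_table,  # noqa: E402
                         screen_diazotrophs, shared_otu_counts,
                         tally_nifh_otus)

spec = importlib.util.spec_from_file_location(
    "simulate_step", Path(__file__).with_name("01_simulate_study.py"))
simulate_step = importlib.util.module_from_spec(spec)
spec.loader.exec_module(simulate_step)


def main() -> None:
    bundle = simulate_step.load_bundle(with_reads=False)
    patterns = load_diazotroph_patterns()
    lineages = {r.id: ";".join(r.lineage) for r in bundle.references}
    truth_flags = {r.id: r.diazotroph for r in bundle.references}

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    max_dev = 0.0
    with open(results / "diazotroph_abundance.tsv", "w", encoding="utf-8") as fh:
        fh.write("site_id\tdiazotroph_abundance\ttrue_diazotroph_abundance\n")
        for sid, abundances in bundle.truth.site_abundances.items():
            by_lineage = {lineages[t]: a for t, a in abundances.items()}
            screened = screen_diazotrophs(by_lineage, patterns)
            true = sum(a for t, a in abundances.items() if truth_flags[t])
            max_dev = max(max_dev, abs(screened - true))
            fh.write(f"{sid}\t{screened:.4f}\t{true:.4f}\n")
    print(f"diazotroph screen: {len(bundle.truth.site_abundances)} sites, "
          f"max |screen - truth| = {max_dev:.2e}")

    # OTU sharing between locations (taxa present above 0.5% per location)
    sets = {}
    for sid, ab in bundle.truth.site_abundances.items():
        loc = bundle.metadata[sid].location
        sets.setdefault(loc, set()).update(t for t, a in ab.items() if a > 0.005)
    four = {k: sets[k] for k in list(sets)[:4]}
    regions = shared_otu_counts(four)
    shared_all = regions[tuple(sorted(four))]
    print(f"OTUs shared by all of {', '.join(sorted(four))}: {shared_all}")

    tally = tally_nifh_otus(load_nifh_table())
    with open(results / "nifh_totals.tsv", "w", encoding="utf-8") as fh:
        fh.write("otu\ttotal\n")
        for otu, total in sorted(tally.per_otu_total.items(),
                                 key=lambda kv: -kv[1]):
            fh.write(f"{otu}\t{total}\n")
        fh.write("#order_totals\n")
        for order, total in sorted(tally.per_order_total.items(),
                                   key=lambda kv: -kv[1]):
            fh.write(f"#{order}\t{total}\n")
    top = max(tally.per_otu_total, key=tally.per_otu_total.get)
    print(f"nifH: top OTU {top} totals {tally.per_otu_total[top]} reads; "
          f"grand total {tally.grand_total}; "
          f"dominant order {max(tally.per_order_total, key=tally.per_order_total.get)}")


if __name__ == "__main__":
    main()
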