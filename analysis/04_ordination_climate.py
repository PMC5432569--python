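#!/usr/bin/env python
"""Compare communities and test the P/C-versus-climate relationships.

Builds the Bray-Curtis dissimilarity matrix over aligned fingerprint
profiles, cuts UPGMA groups at 40% dissimilarity, embeds the communities by
NMDS (Kruskal stress-1), screens P/C outliers with the order-of-magnitude
rule, and fits P/C against growing season, precipitation and temperature.
Writes results/groups.tsv, results/nmds_coords.tsv and results/regressions.tsv.
"""

import importlib.util
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from hypolith.digest import virtual_digest  # noqa: E402
from hypolith.stats import (PREDICTORS, cluster_groups,  # noqa: E402
                            dissimilarity_matrix, fit_pc_vs_climate, nmds,
                            remove_pc_outliers)
from hypolith.trflp import process_peak_table  # noqa: E402

spec = importlib.util.spec_from_file_location(
    "simulate_step", Path(__file__).with_name("01_simulate_study.py"))
simulate_step = importlib.util.module_from_spec(spec)
spec.loader.exec_module(simulate_step)


def main() -> None:
    bundle = simulate_step.load_bundle(with_reads=False)
    table = virtual_digest(bundle.references, bundle.config.primers,
                           bundle.config.enzyme)
    profiles, pcs = [], {}
    for sid, pt in bundle.peak_tables.items():
        profile, _, pc = process_peak_table(pt, table)
        profiles.append(profile)
        pcs[sid] = pc.ratio

    dm = dissimilarity_matrix(profiles)
    groups = cluster_groups(dm, cutoff=0.40)
    ordination = nmds(dm, n_starts=10, seed=simulate_step.STUDY_SEED)

    labels = {sid: bundle.metadata[sid].location for sid in pcs}
    retained, excluded = remove_pc_outliers(pcs, labels)
    fits = [fit_pc_vs_climate(retained, bundle.metadata, p, excluded=excluded)
            for p in PREDICTORS]

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "groups.tsv", "w", encoding="utf-8") as fh:
        fh.write("site_id\tgroup\tlocation\n")
        for sid in dm.ids:
            fh.write(f"{sid}\t{groups[sid]}\t{labels[sid]}\n")
    with open(results / "nmds_coords.tsv", "w", encoding="utf-8") as fh:
        fh.write("site_id\taxis1\taxis2\tgroup\n")
        for sid, row in zip(dm.ids, ordination.coordinates):
            fh.write(f"{sid}\t{row[0]:.5f}\t{row[1]:.5f}\t{groups[sid]}\n")
    with open(results / "regressions.tsv", "w", encoding="utf-8") as fh:
        fh.write("predictor\tslope\tintercept\tr\tr_squared\t"
                 "signed_r_squared\tp_value\tn\texcluded\n")
        for fit in fits:
            fh.write(f"{fit.predictor}\t{fit.slope:.6g}\t{fit.intercept:.6g}\t"
                     f"{fit.r:.4f}\t{fit.r_squared:.4f}\t"
                     f"{fit.signed_r_squared:.4f}\t{fit.p_value:.3g}\t"
                     f"{fit.n}\t{','.join(fit.excluded)}\n")

    print(f"ordination: {len(set(groups.values()))} groups at 40% cutoff, "
          f"NMDS stress-1 = {ordination.stress:.3f}")
    print(f"outliers excluded: {excluded or 'none'}")
    gfit = fits[0]
    print(f"P/C ~ growing season: slope = {gfit.slope:.4f}, "
          f"r^2 = {gfit.r_squared:.3f}, p = {gfit.p_value:.2g} (n = {gfit.n})")


if __name__ == "__main__":
    main()
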