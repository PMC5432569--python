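"""End-to-end orchestration: digest -> fingerprint processing -> community
statistics, with optional read QC, behind a single validated configuration.

The report is a schema-versioned JSON document fully determined by
``(inputs, config, seed)``; every parameter, exclusion and excluded-outlier
id is echoed into it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as hio
from . import qc as hqc
from . import stats as hstats
from . import trflp as htrflp
from .digest import ENZYMES, PrimerPair, virtual_digest
from .errors import ConfigError

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Paths and parameters for one full analysis run.

    Parameter defaults are the study conventions: MspI, the 341F/907R primer
    pair, 1 bp bin/assignment tolerance, a 3-SD noise filter, a 40%
    clustering cutoff and the 300 bp / Q25 / 6-homopolymer read filters.
    """

    refs_fasta: str
    taxonomy_tsv: str
    metadata_tsv: str
    peaks_csv: str
    noise_tsv: str
    out_dir: str
    fastq: str | None = None
    barcodes_tsv: str | None = None
    enzyme: str = "MspI"
    forward_primer: str = "CCTACGGGAGGCAGCAG"
    reverse_primer: str = "CCGTCAATTCMTTTGAGTTT"
    tol_bp: float = 1.0
    noise_k: float = 3.0
    cluster_cutoff: float = 0.40
    predictors: tuple[str, ...] = hstats.PREDICTORS
    min_len: int = 300
    min_avg_q: float = 25.0
    max_hp: int = 6
    nmds_starts: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "predictors" in raw:
            raw["predictors"] = tuple(raw["predictors"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config: {exc}") from exc

    def validate(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ConfigError(f"unknown enzyme {self.enzyme!r}")
        required = {
            "refs_fasta": self.refs_fasta, "taxonomy_tsv": self.taxonomy_tsv,
            "metadata_tsv": self.metadata_tsv, "peaks_csv": self.peaks_csv,
            "noise_tsv": self.noise_tsv,
        }
        if self.fastq:
            required["fastq"] = self.fastq
            required["barcodes_tsv"] = self.barcodes_tsv or ""
        for name, p in required.items():
            if not p or not Path(p).exists():
                raise ConfigError(f"input {name} missing: {p!r}")


def _read_barcodes(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ConfigError(f"{Path(path).name}: expected sample_id/barcode header")
        for line in fh:
            if line.strip() and not line.startswith("#"):
                sid, bc = line.split("\t")[:2]
                out[sid.strip()] = bc.strip()
    return out


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write the report bundle to ``out_dir``.

    Stages: virtual digest; per-sample noise filter, binning, normalisation,
    taxon assignment and P/C; cross-sample alignment, Bray-Curtis matrix,
    UPGMA groups and NMDS; outlier screening and a regression block per
    predictor; read QC and per-sample rarefaction when reads are supplied.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    refs = hio.load_reference_library(config.refs_fasta, config.taxonomy_tsv)
    primers = PrimerPair(forward=config.forward_primer,
                         reverse=config.reverse_primer)
    digest_table = virtual_digest(refs, primers, ENZYMES[config.enzyme])

    metadata = hio.read_metadata(config.metadata_tsv)
    peak_tables = htrflp.read_peak_tables(config.peaks_csv, config.noise_tsv)

    profiles, pc_values, rates = [], {}, {}
    assignments = {}
    for sid, table in peak_tables.items():
        profile, assignment, pc = htrflp.process_peak_table(
            table, digest_table, k=config.noise_k, tol_bp=config.tol_bp)
        profiles.append(profile)
        assignments[sid] = assignment
        pc_values[sid] = pc.ratio
        rates[sid] = htrflp.assignment_rate(assignment)

    dm = hstats.dissimilarity_matrix(profiles, tol_bp=config.tol_bp)
    groups = hstats.cluster_groups(dm, cutoff=config.cluster_cutoff)
    ordination = hstats.nmds(dm, n_starts=config.nmds_starts, seed=config.seed)

    site_labels = {sid: metadata[sid].location if sid in metadata else ""
                   for sid in pc_values}
    retained, excluded = hstats.remove_pc_outliers(pc_values, site_labels)
    regressions = {}
    for predictor in config.predictors:
        fit = hstats.fit_pc_vs_climate(retained, metadata, predictor,
                                       excluded=excluded)
        regressions[predictor] = asdict(fit)

    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "digest": {
            "n_references": len(refs),
            "n_with_amplicon": len(digest_table.entries),
            "excluded_references": list(digest_table.excluded),
        },
        "samples": {
            sid: {
                "pc_ratio": (None if not math.isfinite(pc_values[sid])
                             else pc_values[sid]),
                "pc_infinite": not math.isfinite(pc_values[sid]),
                "assignment_rate": rates[sid],
            }
            for sid in peak_tables
        },
        "dissimilarity": {"ids": dm.ids, "matrix": dm.matrix.tolist()},
        "groups": groups,
        "nmds": {
            "stress": ordination.stress,
            "converged": ordination.converged,
            "n_starts": ordination.n_starts,
            "seed": ordination.seed,
        },
        "pc_outliers_excluded": list(excluded),
        "regressions": regressions,
    }

    if config.fastq:
        reads = hio.read_fastq(config.fastq)
        barcode_map = _read_barcodes(config.barcodes_tsv)
        routed, unmatched = hqc.demultiplex(reads, barcode_map)
        qc_block = {"n_reads": len(reads), "n_unmatched": len(unmatched),
                    "per_sample": {}}
        for sid, sample_reads in routed.items():
            verdicts = [
                hqc.qc_filter(r, min_len=config.min_len,
                              min_avg_q=config.min_avg_q, max_hp=config.max_hp,
                              primer=config.forward_primer,
                              barcode_map=barcode_map)
                for r in sample_reads
            ]
            n_pass = sum(v.passed for v in verdicts)
            qc_block["per_sample"][sid] = {
                "n_reads": len(sample_reads),
                "n_passed": n_pass,
                "pass_rate": n_pass / len(sample_reads) if sample_reads else 0.0,
            }
        report["qc"] = qc_block

    # TSV side outputs
    with open(out_dir / "profiles.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tbin_bp\trelative_abundance\n")
        for p in profiles:
            for rep, ab in sorted(p.abundances.items()):
                fh.write(f"{p.sample_id}\t{rep:.3f}\t{ab:.6g}\n")
    with open(out_dir / "assignments.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tbin_bp\tassigned\ttaxa\trole\tambiguous\n")
        for sid, assignment in assignments.items():
            for rep, e in sorted(assignment.entries.items()):
                fh.write(f"{sid}\t{rep:.3f}\t{e.assigned}\t"
                         f"{','.join(e.taxa)}\t{e.role or ''}\t{e.ambiguous}\n")
    with open(out_dir / "nmds_coords.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\taxis1\taxis2\n")
        for sid, row in zip(dm.ids, ordination.coordinates):
            fh.write(f"{sid}\t{row[0]:.6g}\t{row[1]:.6g}\n")
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
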