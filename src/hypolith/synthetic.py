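"""Synthetic study generator with full ground truth.

Emulates the statistical structure of a multi-desert hypolith fingerprinting
study so every pipeline stage can be exercised against known truth:

* a primer-flanked reference library whose terminal restriction fragments
  (TRFs) are unique and well separated;
* per-site communities whose log producer/consumer ratio declines linearly
  with growing season plus Gaussian noise, masses split within each trophic
  class by a symmetric Dirichlet;
* electropherograms with Gaussian size-calling error, lognormal area noise
  and spurious sub-threshold baseline peaks;
* pyrosequencing-style reads with per-base errors, quality scores and
  planted quality-control defects.

Every stochastic draw is reproducible from ``(config, seed)`` and recorded
in :class:`GroundTruth`.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as hio
from .digest import (DEFAULT_PRIMERS, ENZYMES, IUPAC, Enzyme, PrimerPair,
                     extract_amplicon, reverse_complement, terminal_fragment)
from .errors import ConfigError
from .trflp import Peak, PeakTable

# (location, Koppen class, growing season days) — a hot/cold/tundra/polar
# spread from ~0 to ~92 days per year.
DEFAULT_LOCATIONS: tuple[tuple[str, str, float], ...] = (
    ("mcmurdo", "EF", 0.0),
    ("libyan", "BWh", 8.0),
    ("taklimakan", "BWk", 12.0),
    ("devon_island", "ET", 22.0),
    ("baja", "BWh", 30.0),
    ("atacama", "BWk", 38.0),
    ("simpson", "BWh", 48.0),
    ("mojave", "BWh", 55.0),
    ("death_valley", "BWh", 62.0),
    ("colorado", "BWk", 75.0),
    ("tibetan", "ET", 92.0),
)

_PRODUCER_LINEAGES = (
    ("Cyanobacteria", "Cyanophyceae", "Oscillatoriales", "Oscillatoriaceae",
     "Phormidium", False),
    ("Cyanobacteria", "Cyanophyceae", "Chroococcidiopsidales",
     "Chroococcidiopsidaceae", "Chroococcidiopsis", False),
    ("Cyanobacteria", "Cyanophyceae", "Nostocales", "Nostocaceae", "Nostoc",
     True),
    ("Cyanobacteria", "Cyanophyceae", "Synechococcales", "Synechococcaceae",
     "Synechococcus", False),
)

_CONSUMER_LINEAGES = (
    ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Rhizobiaceae",
     "Rhizobium", True),
    ("Actinobacteria", "Actinomycetia", "Actinomycetales",
     "Micrococcaceae", "Arthrobacter", False),
    ("Bacteroidetes", "Cytophagia", "Cytophagales", "Hymenobacteraceae",
     "Hymenobacter", False),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales",
     "Comamonadaceae", "Polaromonas", True),
    ("Acidobacteria", "Blastocatellia", "Blastocatellales",
     "Blastocatellaceae", "Blastocatella", False),
    ("Proteobacteria", "Alphaproteobacteria", "Rhodospirillales",
     "Acetobacteraceae", "Roseomonas", True),
    ("Deinococcus-Thermus", "Deinococci", "Deinococcales", "Deinococcaceae",
     "Deinococcus", False),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    The producer/consumer model is log-linear in growing season g:
    log(P/C) = beta0 + beta1 * g + eps, eps ~ Normal(0, pc_sigma).  Defaults
    put the noise-free P/C at 2.5 for g = 0 declining to 0.5 at g = 92.
    """

    seed: int
    n_taxa: int = 30
    producer_fraction: float = 0.5
    n_sites: int = 64
    locations: tuple[tuple[str, str, float], ...] = DEFAULT_LOCATIONS
    pc_beta0: float = math.log(2.5)
    pc_beta1: float = -math.log(5.0) / 92.0
    pc_sigma: float = 0.3
    dirichlet_alpha: float = 1.0
    # electropherogram
    size_call_sd: float = 0.15
    area_scale: float = 60000.0
    area_lognorm_sigma: float = 0.15
    spurious_peak_rate: float = 5.0
    noise_mean: float = 50.0
    noise_sd: float = 10.0
    # reference construction
    enzyme_name: str = "MspI"
    primers: PrimerPair = DEFAULT_PRIMERS
    trf_min: int = 60
    trf_max: int = 430
    trf_spacing: int = 3
    # reads
    with_reads: bool = True
    reads_per_sample: int = 1000
    n_sequenced_samples: int = 4
    read_defect_rate: float = 0.1
    read_error_rate: float = 0.005
    barcode_length: int = 8

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ConfigError("need at least two taxa")
        if not 0.0 < self.producer_fraction < 1.0:
            raise ConfigError("producer_fraction must be in (0, 1)")
        for name in ("pc_sigma", "size_call_sd", "area_lognorm_sigma",
                     "spurious_peak_rate", "noise_mean", "noise_sd",
                     "read_defect_rate", "read_error_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.enzyme_name not in ENZYMES:
            raise ConfigError(f"unknown enzyme {self.enzyme_name!r}")
        n_slots = (self.trf_max - self.trf_min) // self.trf_spacing + 1
        if self.n_taxa > n_slots:
            raise ConfigError(
                f"cannot place {self.n_taxa} TRFs >= {self.trf_spacing} bp "
                f"apart in [{self.trf_min}, {self.trf_max}]"
            )

    @property
    def enzyme(self) -> Enzyme:
        return ENZYMES[self.enzyme_name]


def zero_noise_config(seed: int, **overrides) -> SimulationConfig:
    """A configuration with every observation-noise term set to zero: exact
    peak sizes, exact areas, no spurious peaks, no baseline, clean reads."""
    params = dict(
        seed=seed, pc_sigma=0.0, size_call_sd=0.0, area_lognorm_sigma=0.0,
        spurious_peak_rate=0.0, noise_mean=0.0, noise_sd=0.0,
        read_defect_rate=0.0, read_error_rate=0.0,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    trf: dict[str, int] = field(default_factory=dict)           # taxon -> TRF
    roles: dict[str, str] = field(default_factory=dict)         # taxon -> role
    site_abundances: dict[str, dict[str, float]] = field(default_factory=dict)
    true_pc: dict[str, float] = field(default_factory=dict)     # site -> P/C
    read_origin: dict[str, tuple[str, str, str | None]] = field(
        default_factory=dict)  # read id -> (sample, taxon, defect)


# ---------------------------------------------------------------------------
# Reference library

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length)) if length > 0 else ""


def _cap_homopolymers(seq: str, rng: np.random.Generator, max_run: int = 5) -> str:
    """Break runs longer than ``max_run`` so clean reads never trip the
    homopolymer filter by chance."""
    out = list(seq)
    run = 1
    for i in range(1, len(out)):
        if out[i] == out[i - 1]:
            run += 1
            if run > max_run:
                choices = [b for b in "ACGT" if b != out[i]]
                out[i] = choices[rng.integers(len(choices))]
                run = 1
        else:
            run = 1
    return "".join(out)


def _concrete(pattern: str, rng: np.random.Generator) -> str:
    """Replace IUPAC degeneracy with random concrete bases."""
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(len(IUPAC[c]))]
        for c in pattern
    )


def make_reference_library(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[hio.ReferenceRecord], GroundTruth]:
    """Build ``n_taxa`` primer-flanked references with engineered TRFs.

    Each sequence is flank + forward primer + insert + revcomp(reverse
    primer) + flank, with the first restriction cut placed so the labeled
    fragment has exactly the intended length.  TRFs are unique and at least
    ``trf_spacing`` bp apart; every record is verified by running the actual
    digest before it is accepted.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    enzyme = config.enzyme
    primers = config.primers
    fwd = primers.forward

    slots = np.arange(config.trf_min, config.trf_max + 1, config.trf_spacing)
    trfs = np.sort(rng.choice(slots, size=config.n_taxa, replace=False))

    n_producers = round(config.n_taxa * config.producer_fraction)
    producer_idx = set(rng.choice(config.n_taxa, size=n_producers, replace=False))

    records: list[hio.ReferenceRecord] = []
    truth = GroundTruth()
    for i, trf in enumerate(trfs):
        trf = int(trf)
        taxon = f"tax_{i + 1:04d}"
        role = "producer" if i in producer_idx else "consumer"
        pool = _PRODUCER_LINEAGES if role == "producer" else _CONSUMER_LINEAGES
        phylum, cls, order, fam, genus, diazo = pool[i % len(pool)]
        lineage = (phylum, cls, order, fam, genus + f" sp{i + 1}")

        for _attempt in range(100):
            rev_concrete = _concrete(primers.reverse, rng)
            rc_rev = reverse_complement(rev_concrete)
            site = _concrete(enzyme.recognition, rng)
            amp_len = int(rng.integers(500, 541))
            amp_len = max(amp_len, trf + len(site) + len(rc_rev) + 10)
            insert_before = _cap_homopolymers(
                _random_seq(rng, trf - enzyme.cut_offset - len(fwd)), rng)
            tail_len = amp_len - trf + enzyme.cut_offset - len(site) - len(rc_rev)
            tail = _cap_homopolymers(_random_seq(rng, tail_len), rng)
            amplicon = fwd + insert_before + site + tail + rc_rev
            left = _cap_homopolymers(_random_seq(rng, int(rng.integers(10, 41))), rng)
            right = _cap_homopolymers(_random_seq(rng, int(rng.integers(10, 41))), rng)
            seq = left + amplicon + right
            got = extract_amplicon(seq, primers)
            if got != amplicon:
                continue
            got_trf, no_site = terminal_fragment(got, enzyme)
            if no_site or got_trf != trf:
                continue
            break
        else:
            raise ConfigError(f"could not engineer TRF {trf} for {taxon}")

        records.append(hio.ReferenceRecord(
            id=taxon, sequence=seq, lineage=lineage, role=role, diazotroph=diazo))
        truth.trf[taxon] = trf
        truth.roles[taxon] = role
    return records, truth


# ---------------------------------------------------------------------------
# Communities and electropherograms

def simulate_site_community(
    g: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    producers: Sequence[str],
    consumers: Sequence[str],
) -> tuple[dict[str, float], float]:
    """Draw one community: target P/C from the log-linear model, producer
    mass P = PC/(1+PC) split by symmetric Dirichlet, likewise consumers."""
    eps = rng.normal(0.0, config.pc_sigma) if config.pc_sigma > 0 else 0.0
    pc = math.exp(config.pc_beta0 + config.pc_beta1 * g + eps)
    p_mass = pc / (1.0 + pc)
    alpha = config.dirichlet_alpha
    prod_split = rng.dirichlet(np.full(len(producers), alpha))
    cons_split = rng.dirichlet(np.full(len(consumers), alpha))
    abundances = {t: p_mass * w for t, w in zip(producers, prod_split)}
    abundances.update(
        {t: (1.0 - p_mass) * w for t, w in zip(consumers, cons_split)})
    return abundances, pc


def simulate_electropherogram(
    abundances: Mapping[str, float],
    trf_truth: Mapping[str, int],
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "",
) -> PeakTable:
    """One sized peak per present taxon (size-called with Gaussian error,
    area lognormally perturbed, height = area/2) plus Poisson-many spurious
    peaks drawn below the 3-SD noise threshold."""
    peaks = []
    for taxon, ab in abundances.items():
        if ab <= 0:
            continue
        size = trf_truth[taxon] + (
            rng.normal(0.0, config.size_call_sd) if config.size_call_sd > 0 else 0.0)
        noise = (math.exp(rng.normal(0.0, config.area_lognorm_sigma))
                 if config.area_lognorm_sigma > 0 else 1.0)
        area = ab * config.area_scale * noise
        peaks.append(Peak(size_bp=max(size, 1e-6), height=area / 2.0, area=area))
    threshold = config.noise_mean + 3.0 * config.noise_sd
    n_spurious = rng.poisson(config.spurious_peak_rate)
    for _ in range(n_spurious):
        h = float(rng.uniform(0.0, threshold)) if threshold > 0 else 0.0
        peaks.append(Peak(size_bp=float(rng.uniform(50.0, 500.0)),
                          height=h, area=2.0 * h + 1e-6))
    return PeakTable(sample_id=sample_id, peaks=tuple(peaks),
                     noise_mean=config.noise_mean, noise_sd=config.noise_sd)


# ---------------------------------------------------------------------------
# Reads

_DEFECTS = ("too_short", "low_quality", "ambiguous", "homopolymer",
            "no_primer", "no_barcode")


def make_barcodes(
    n: int, rng: np.random.Generator, length: int = 8
) -> list[str]:
    """Distinct equal-length barcodes (hence prefix-free) with short runs."""
    out: list[str] = []
    while len(out) < n:
        bc = _cap_homopolymers(_random_seq(rng, length), rng, max_run=2)
        if bc not in out:
            out.append(bc)
    return out


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), rate)
    for pos in rng.choice(len(arr), size=n_err, replace=False):
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_reads(
    abundances: Mapping[str, float],
    refs: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    barcode: str,
    all_barcodes: Sequence[str] = (),
) -> tuple[list[hio.Read], dict[str, tuple[str, str, str | None]]]:
    """Amplicon reads for one sample: barcode + amplicon prefix, multinomial
    by abundance, with a configured fraction given one planted QC defect.

    ``refs`` maps taxon id to its amplicon sequence.  The defect type per
    read is returned so filter verdicts can be checked against truth.
    """
    taxa = list(abundances)
    probs = np.array([abundances[t] for t in taxa], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(config.reads_per_sample, probs)
    reads: list[hio.Read] = []
    origin: dict[str, tuple[str, str, str | None]] = {}
    idx = 0
    for taxon, count in zip(taxa, counts):
        template = refs[taxon]
        for _ in range(count):
            idx += 1
            rid = f"{sample_id}_read{idx:05d}"
            read_len = int(np.clip(rng.normal(360, 20), 320, len(template)))
            # the barcode+primer head is synthesised, not sequenced: error-free
            n_head = len(config.primers.forward)
            seq = barcode + template[:n_head] + _apply_errors(
                template[n_head:read_len], config.read_error_rate, rng)
            quals = np.clip(rng.normal(33, 4, size=len(seq)).round(), 20, 40
                            ).astype(int)
            defect: str | None = None
            if config.read_defect_rate > 0 and rng.random() < config.read_defect_rate:
                defect = _DEFECTS[rng.integers(len(_DEFECTS))]
                seq, quals = _plant_defect(seq, quals, defect, barcode,
                                           all_barcodes, rng)
            reads.append(hio.Read(id=rid, sequence=seq,
                                  qualities=tuple(int(q) for q in quals)))
            origin[rid] = (sample_id, taxon, defect)
    return reads, origin


def _plant_defect(seq, quals, defect, barcode, all_barcodes, rng):
    if defect == "too_short":
        n = int(rng.integers(100, 291))
        return seq[:n], quals[:n]
    if defect == "low_quality":
        return seq, np.clip(rng.normal(18, 3, size=len(seq)).round(), 2, 24
                            ).astype(int)
    if defect == "ambiguous":
        pos = int(rng.integers(len(barcode), len(seq)))
        return seq[:pos] + "N" + seq[pos + 1:], quals
    if defect == "homopolymer":
        base = "ACGT"[rng.integers(4)]
        pos = int(rng.integers(len(barcode) + 30, len(seq) - 10))
        run = base * 8
        out = seq[:pos] + run + seq[pos + len(run):]
        return out, quals
    if defect == "no_primer":
        # scramble the primer region just after the barcode
        start = len(barcode)
        scrambled = _cap_homopolymers(_random_seq(rng, 17), rng)
        return seq[:start] + scrambled + seq[start + 17:], quals
    if defect == "no_barcode":
        while True:
            bc = _cap_homopolymers(_random_seq(rng, len(barcode)), rng, max_run=2)
            if bc not in all_barcodes and bc != barcode:
                break
        return bc + seq[len(barcode):], quals
    raise ConfigError(f"unknown defect {defect!r}")


# ---------------------------------------------------------------------------
# Whole study

@dataclass
class StudyBundle:
    """Everything one synthetic study produces, in memory."""

    config: SimulationConfig
    references: list[hio.ReferenceRecord]
    metadata: dict[str, hio.SiteMetadata]
    peak_tables: dict[str, PeakTable]
    reads: dict[str, list[hio.Read]]
    barcode_map: dict[str, str]
    truth: GroundTruth


def simulate_study(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> StudyBundle:
    """Generate a full multi-site study; optionally write it to ``out_dir``
    with a checksum manifest.

    Sites are spread round-robin over the configured locations; growing
    seasons therefore span the configured ~0-92 day range.  Reads are
    generated for ``n_sequenced_samples`` representative sites drawn from
    distinct locations, mirroring a study that sequences a few communities
    deeply and fingerprints the rest.
    """
    rng = np.random.default_rng(config.seed)
    references, truth = make_reference_library(config, rng)
    producers = [t for t, r in truth.roles.items() if r == "producer"]
    consumers = [t for t, r in truth.roles.items() if r == "consumer"]

    amplicons = {
        rec.id: extract_amplicon(rec.sequence, config.primers)
        for rec in references
    }

    metadata: dict[str, hio.SiteMetadata] = {}
    peak_tables: dict[str, PeakTable] = {}
    locs = config.locations
    for i in range(config.n_sites):
        loc, koppen, g = locs[i % len(locs)]
        sid = f"{loc}_{i // len(locs) + 1:02d}"
        map_mm = max(0.0, 15.0 + 4.0 * g + rng.normal(0, 10))
        tmin = -35.0 + 0.35 * g + rng.normal(0, 2)
        tmax = tmin + 30.0 + abs(rng.normal(0, 3))
        metadata[sid] = hio.SiteMetadata(
            site_id=sid, koppen=koppen, map_mm=map_mm, tmin_c=tmin,
            tmax_c=tmax, growing_season_d=g, location=loc)
        abundances, pc = simulate_site_community(g, config, rng, producers,
                                                 consumers)
        truth.site_abundances[sid] = abundances
        truth.true_pc[sid] = pc
        peak_tables[sid] = simulate_electropherogram(
            abundances, truth.trf, config, rng, sample_id=sid)

    reads: dict[str, list[hio.Read]] = {}
    barcode_map: dict[str, str] = {}
    if config.with_reads and config.n_sequenced_samples > 0:
        seen_locs: list[str] = []
        sequenced: list[str] = []
        for sid, meta in metadata.items():
            if meta.location not in seen_locs:
                seen_locs.append(meta.location)
                sequenced.append(sid)
            if len(sequenced) == config.n_sequenced_samples:
                break
        barcodes = make_barcodes(len(sequenced), rng, config.barcode_length)
        barcode_map = dict(zip(sequenced, barcodes))
        for sid in sequenced:
            sample_reads, origin = simulate_reads(
                truth.site_abundances[sid], amplicons, config, rng,
                sample_id=sid, barcode=barcode_map[sid],
                all_barcodes=barcodes)
            reads[sid] = sample_reads
            truth.read_origin.update(origin)

    bundle = StudyBundle(config=config, references=references,
                         metadata=metadata, peak_tables=peak_tables,
                         reads=reads, barcode_map=barcode_map, truth=truth)
    if out_dir is not None:
        write_study(bundle, out_dir)
    return bundle


def write_study(bundle: StudyBundle, out_dir: str | Path) -> Path:
    """Write every artifact of a study plus a sha256 manifest; returns the
    manifest path."""
    from .trflp import write_peak_tables

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_fasta(out / "references.fasta",
                    [(r.id, r.sequence) for r in bundle.references])
    hio.write_taxonomy(out / "taxonomy.tsv", bundle.references)
    hio.write_metadata(out / "metadata.tsv", bundle.metadata.values())
    write_peak_tables(out / "peaks.csv", out / "noise.tsv",
                      list(bundle.peak_tables.values()))
    with open(out / "true_pc.tsv", "w", encoding="utf-8") as fh:
        fh.write("site_id\ttrue_pc\n")
        for sid, pc in bundle.truth.true_pc.items():
            fh.write(f"{sid}\t{pc:.10g}\n")
    with open(out / "trf_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("taxon\ttrf_bp\trole\n")
        for taxon, trf in bundle.truth.trf.items():
            fh.write(f"{taxon}\t{trf}\t{bundle.truth.roles[taxon]}\n")
    if bundle.reads:
        all_reads = [r for sid in bundle.reads for r in bundle.reads[sid]]
        hio.write_fastq(out / "reads.fastq", all_reads)
        with open(out / "barcodes.tsv", "w", encoding="utf-8") as fh:
            fh.write("sample_id\tbarcode\n")
            for sid, bc in bundle.barcode_map.items():
                fh.write(f"{sid}\t{bc}\n")
        with open(out / "read_origins.tsv", "w", encoding="utf-8") as fh:
            fh.write("read_id\tsample_id\ttaxon\tdefect\n")
            for rid, (sid, taxon, defect) in bundle.truth.read_origin.items():
                fh.write(f"{rid}\t{sid}\t{taxon}\t{defect or ''}\n")
    manifest = out / "manifest.tsv"
    entries = sorted(p for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.tsv")
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write("file\tsha256\n")
        for p in entries:
            digest = hashlib.sha256(p.read_bytes()).hexdigest()
            fh.write(f"{p.name}\t{digest}\n")
    return manifest
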