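"""Readers, writers and the shared data model.

The pipeline touches four plain-text formats: FASTA reference sequences, a
taxonomy TSV mapping reference ids to a lineage and a trophic role, a
site-metadata TSV with the macroclimate variables, and phred+33 FASTQ reads.
All TSV readers require a header row, are UTF-8, and ignore ``#`` comment
lines.  Parsing is order-preserving; writing then reading any record set
reproduces it exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ParseError, ValidationError

ROLES = ("producer", "consumer")
KOPPEN_CLASSES = ("EF", "ET", "BWk", "BWh", "Af")

_REFERENCE_ALPHABET = set("ACGTN")
_CONCRETE_BASES = set("ACGT")


@dataclass(frozen=True)
class ReferenceRecord:
    """One 16S reference sequence with taxonomy and trophic role.

    The role partitions the community into producers (Cyanobacteria and
    chemoautotrophs) and consumers (all other bacteria); ``diazotroph``
    flags taxa known to fix nitrogen.
    """

    id: str
    sequence: str
    lineage: tuple[str, ...]
    role: str
    diazotroph: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reference record has empty id")
        if not self.sequence:
            raise ValidationError(f"reference {self.id!r} has empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValidationError(f"reference {self.id!r} is not uppercase")
        bad = set(self.sequence) - _REFERENCE_ALPHABET
        if bad:
            raise ValidationError(
                f"reference {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        if self.role not in ROLES:
            raise ValidationError(
                f"reference {self.id!r} has unknown role {self.role!r}; "
                f"expected one of {ROLES}"
            )
        if len(self.lineage) < 1:
            raise ValidationError(f"reference {self.id!r} has empty lineage")


@dataclass(frozen=True)
class SiteMetadata:
    """Macroclimate descriptors for one sampled community.

    ``growing_season_d`` is the number of days per year when temperature,
    moisture and light jointly permit photosynthesis; it is consumed as
    metadata, never derived here.  ``location`` is an optional sampling-
    location label used for location-relative outlier screening.
    """

    site_id: str
    koppen: str
    map_mm: float
    tmin_c: float
    tmax_c: float
    growing_season_d: float
    location: str = ""

    def __post_init__(self) -> None:
        if self.koppen not in KOPPEN_CLASSES:
            raise ValidationError(
                f"site {self.site_id!r}: unknown Koppen class {self.koppen!r}"
            )
        if self.map_mm < 0:
            raise ValidationError(f"site {self.site_id!r}: negative precipitation")
        if self.tmax_c < self.tmin_c:
            raise ValidationError(f"site {self.site_id!r}: tmax < tmin")
        if not 0.0 <= self.growing_season_d <= 366.0:
            raise ValidationError(
                f"site {self.site_id!r}: growing season outside [0, 366]"
            )


@dataclass(frozen=True)
class Read:
    """A single sequencing read with per-base phred qualities.

    ``barcode`` is filled in by demultiplexing; the sequence itself retains
    the barcode prefix.  Ambiguity codes are preserved (the QC filter
    inspects them).
    """

    id: str
    sequence: str
    qualities: tuple[int, ...]
    barcode: str = ""

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValidationError(
                f"read {self.id!r}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )
        if self.qualities and not all(0 <= q <= 60 for q in self.qualities):
            raise ValidationError(f"read {self.id!r}: phred value outside [0, 60]")

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs in file order.

    Sequences are uppercased with gaps and whitespace stripped.  A file whose
    first non-blank line is not a header, or a record with an empty sequence,
    raises :class:`ParseError`.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path.name}:{lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
        else:
            return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        seq = "".join(seq.split())
        if not seq:
            raise ParseError(f"{path.name}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Taxonomy TSV

def _parse_bool(token: str, context: str) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValidationError(f"{context}: cannot parse boolean {token!r}")


def read_taxonomy(path: str | Path) -> dict[str, tuple[tuple[str, ...], str, bool]]:
    """Read a taxonomy TSV (columns id, lineage, role, diazotroph).

    Lineage ranks are ``;``-joined, ordered phylum -> genus; missing ranks may
    be empty strings.  Roles are parsed strictly against the
    producer/consumer vocabulary.  Duplicate ids raise.
    """
    path = Path(path)
    out: dict[str, tuple[tuple[str, ...], str, bool]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        rows = csv.reader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        try:
            header = next(rows)
        except StopIteration:
            raise ParseError(f"{path.name}: empty taxonomy file (header required)")
        required = ["id", "lineage", "role", "diazotroph"]
        if [h.strip() for h in header[:4]] != required:
            raise ParseError(
                f"{path.name}: header must start with {required}, got {header}"
            )
        for row in rows:
            if not row or not "".join(row).strip():
                continue
            if len(row) < 4:
                raise ParseError(f"{path.name}: short row {row}")
            rid, lineage_s, role, diazo = (c.strip() for c in row[:4])
            if rid in out:
                raise ValidationError(f"{path.name}: duplicate id {rid!r}")
            if role not in ROLES:
                raise ValidationError(
                    f"{path.name}: id {rid!r} has role {role!r}; expected one of {ROLES}"
                )
            lineage = tuple(r.strip() for r in lineage_s.split(";"))
            out[rid] = (lineage, role, _parse_bool(diazo, f"id {rid!r}"))
    return out


def write_taxonomy(
    path: str | Path, records: Iterable[ReferenceRecord]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tlineage\trole\tdiazotroph\n")
        for rec in records:
            fh.write(
                f"{rec.id}\t{';'.join(rec.lineage)}\t{rec.role}\t"
                f"{'true' if rec.diazotroph else 'false'}\n"
            )


def load_reference_library(
    fasta_path: str | Path, taxonomy_path: str | Path
) -> list[ReferenceRecord]:
    """Join a FASTA file and a taxonomy TSV into reference records.

    Every FASTA id must have a taxonomy row; reference sequences may contain
    N but no other ambiguity code.
    """
    taxonomy = read_taxonomy(taxonomy_path)
    records = []
    for rid, seq in read_fasta(fasta_path):
        if rid not in taxonomy:
            raise ValidationError(f"reference {rid!r} missing from taxonomy table")
        lineage, role, diazo = taxonomy[rid]
        records.append(
            ReferenceRecord(id=rid, sequence=seq, lineage=lineage, role=role,
                            diazotroph=diazo)
        )
    return records


# ---------------------------------------------------------------------------
# FASTQ (phred+33)

def read_fastq(path: str | Path) -> list[Read]:
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                Read(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:  # biopython names the offending record
        raise ParseError(f"{path.name}: {exc}") from exc
    return reads


def write_fastq(path: str | Path, reads: Iterable[Read]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Site metadata TSV

_METADATA_COLUMNS = ["site_id", "koppen", "map_mm", "tmin_c", "tmax_c",
                     "growing_season_d"]


def read_metadata(path: str | Path) -> dict[str, SiteMetadata]:
    """Read the site-metadata TSV into an ordered ``site_id -> SiteMetadata``
    mapping.  An optional trailing ``location`` column is honoured."""
    path = Path(path)
    out: dict[str, SiteMetadata] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        rows = csv.reader((ln for ln in fh if not ln.startswith("#")), delimiter="\t")
        try:
            header = [h.strip() for h in next(rows)]
        except StopIteration:
            raise ParseError(f"{path.name}: empty metadata file (header required)")
        if header[: len(_METADATA_COLUMNS)] != _METADATA_COLUMNS:
            raise ParseError(
                f"{path.name}: header must start with {_METADATA_COLUMNS}, got {header}"
            )
        has_location = len(header) > 6 and header[6] == "location"
        for row in rows:
            if not row or not "".join(row).strip():
                continue
            sid = row[0].strip()
            if sid in out:
                raise ValidationError(f"{path.name}: duplicate site_id {sid!r}")
            out[sid] = SiteMetadata(
                site_id=sid,
                koppen=row[1].strip(),
                map_mm=float(row[2]),
                tmin_c=float(row[3]),
                tmax_c=float(row[4]),
                growing_season_d=float(row[5]),
                location=row[6].strip() if has_location and len(row) > 6 else "",
            )
    return out


def write_metadata(path: str | Path, sites: Iterable[SiteMetadata]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_METADATA_COLUMNS + ["location"]) + "\n")
        for s in sites:
            fh.write(
                f"{s.site_id}\t{s.koppen}\t{s.map_mm:g}\t{s.tmin_c:g}\t"
                f"{s.tmax_c:g}\t{s.growing_season_d:g}\t{s.location}\n"
            )
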