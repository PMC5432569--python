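"""Electropherogram peak processing: noise filter, binning, taxon assignment.

The fingerprint of one community is a table of sized peaks (fragment size in
bp from the internal size standard, plus height and area).  Processing
follows the fingerprinting conventions of the field:

1. peaks within ``k`` (default 3) standard deviations of the baseline noise
   are excluded — retention is strict: ``height > noise_mean + k * noise_sd``;
2. surviving peaks within 1 bp of another are merged (greedy single linkage
   over sorted sizes) since size-calling error blurs a single taxon's
   fragment across adjacent size calls;
3. relative abundance of a fragment is its peak-area share of total area;
4. bins are assigned to taxa by nearest predicted TRF within the same 1 bp
   tolerance, which also defines the producer/consumer split.

Height is used for the noise filter (the baseline statistics are signal
heights) and area for abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .digest import DigestTable
from .errors import ValidationError

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class Peak:
    size_bp: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValidationError("peak size must be positive")
        if self.height < 0:
            raise ValidationError("peak height must be non-negative")
        if self.area <= 0:
            raise ValidationError("peak area must be positive")


@dataclass(frozen=True)
class PeakTable:
    """Per-sample peaks plus the baseline-noise statistics needed to filter."""

    sample_id: str
    peaks: tuple[Peak, ...]
    noise_mean: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative noise standard deviation"
            )


@dataclass(frozen=True)
class FragmentBin:
    """A group of same-taxon peaks; representative is the area-weighted mean."""

    representative_bp: float
    members: tuple[Peak, ...]
    total_area: float


@dataclass(frozen=True)
class CommunityProfile:
    """Relative abundance per fragment bin; sums to 1 when non-empty."""

    sample_id: str
    abundances: dict[float, float]  # representative_bp -> relative abundance

    def total(self) -> float:
        return sum(self.abundances.values())


@dataclass(frozen=True)
class BinAssignmentEntry:
    assigned: bool
    taxa: tuple[str, ...] = ()
    role: str | None = None
    ambiguous: bool = False
    distance: float = math.inf


@dataclass(frozen=True)
class BinAssignment:
    entries: dict[float, BinAssignmentEntry]  # representative_bp -> entry


def filter_noise(table: PeakTable, k: float = 3.0) -> PeakTable:
    """Drop peaks within ``k`` standard deviations of the baseline noise.

    Retains exactly the peaks with ``height > noise_mean + k * noise_sd``
    (a peak sitting exactly on the threshold is excluded).  Idempotent.
    """
    if k <= 0:
        raise ValidationError("noise threshold multiplier k must be positive")
    threshold = table.noise_mean + k * table.noise_sd
    kept = tuple(p for p in table.peaks if p.height > threshold)
    return replace(table, peaks=kept)


def chain_bins(values: Sequence[float], tol: float) -> list[list[int]]:
    """Greedy single-linkage chaining of sorted scalar values.

    Indices into ``values`` are grouped so that consecutive members (in
    ascending value order) differ by at most ``tol``; a chain's total width
    may exceed ``tol``.
    """
    order = sorted(range(len(values)), key=lambda i: values[i])
    groups: list[list[int]] = []
    for idx in order:
        if groups and values[idx] - values[groups[-1][-1]] <= tol:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    return groups


def bin_peaks(table: PeakTable, tol_bp: float = 1.0) -> list[FragmentBin]:
    """Merge peaks within ``tol_bp`` of another into fragment bins.

    Adjacent peaks (sizes sorted ascending) with gap <= ``tol_bp`` join one
    bin; the representative size is the area-weighted mean of members.
    """
    peaks = table.peaks
    bins = []
    for group in chain_bins([p.size_bp for p in peaks], tol_bp):
        members = tuple(peaks[i] for i in group)
        total_area = sum(p.area for p in members)
        rep = sum(p.size_bp * p.area for p in members) / total_area
        bins.append(FragmentBin(representative_bp=rep, members=members,
                                total_area=total_area))
    return bins


def relative_abundance(
    bins: Sequence[FragmentBin], sample_id: str = ""
) -> CommunityProfile:
    """Peak-area share per bin: ``area_i / sum(area)``; sums to 1."""
    if not bins:
        raise ValidationError("cannot compute relative abundance of zero bins")
    total = sum(b.total_area for b in bins)
    if total <= 0:
        raise ValidationError("total peak area is zero")
    return CommunityProfile(
        sample_id=sample_id,
        abundances={b.representative_bp: b.total_area / total for b in bins},
    )


def assign_bins(
    profile: CommunityProfile, digest_table: DigestTable, tol_bp: float = 1.0
) -> BinAssignment:
    """Match each bin to the nearest predicted TRF within ``tol_bp``.

    Ties — equal distance to several TRFs, or several taxa sharing one TRF —
    keep the full tied taxon set with ``ambiguous`` set; the trophic role is
    kept only if all tied taxa agree.  A bin with no TRF within tolerance is
    unassigned.
    """
    if not digest_table.entries:
        raise ValidationError("digest table is empty")
    entries: dict[float, BinAssignmentEntry] = {}
    table = list(digest_table.entries.items())
    for rep in profile.abundances:
        dists = [(abs(rep - e.trf_bp), rid, e) for rid, e in table]
        best = min(d for d, _, _ in dists)
        if best > tol_bp:
            entries[rep] = BinAssignmentEntry(assigned=False)
            continue
        tied = [(rid, e) for d, rid, e in dists if d - best <= _TIE_EPS]
        roles = {e.role for _, e in tied}
        entries[rep] = BinAssignmentEntry(
            assigned=True,
            taxa=tuple(rid for rid, _ in tied),
            role=roles.pop() if len(roles) == 1 else None,
            ambiguous=len(tied) > 1,
            distance=best,
        )
    return BinAssignment(entries=entries)


@dataclass(frozen=True)
class PCResult:
    """Producer/consumer statistic for one community.

    ``ratio`` is producer abundance mass over consumer mass; when no consumer
    mass is present the ratio is flagged infinite.  ``excluded_mass`` is the
    abundance carried by unassigned or role-ambiguous bins.
    """

    producer_mass: float
    consumer_mass: float
    ratio: float
    infinite: bool
    excluded_mass: float

    @property
    def producer_fraction(self) -> float:
        return self.producer_mass / (self.producer_mass + self.consumer_mass)


def producer_consumer_ratio(
    profile: CommunityProfile, assignment: BinAssignment
) -> PCResult:
    """P/C over relative-abundance mass of role-assigned bins."""
    p = c = excluded = 0.0
    for rep, abundance in profile.abundances.items():
        entry = assignment.entries.get(rep)
        role = entry.role if entry is not None and entry.assigned else None
        if role == "producer":
            p += abundance
        elif role == "consumer":
            c += abundance
        else:
            excluded += abundance
    if p + c == 0:
        raise ValidationError("no role-assigned bins; P/C undefined")
    if c == 0:
        return PCResult(p, c, math.inf, True, excluded)
    return PCResult(p, c, p / c, False, excluded)


def assignment_rate(assignment: BinAssignment) -> float:
    """Fraction of bins matched to a predicted TRF (ambiguous included)."""
    if not assignment.entries:
        raise ValidationError("no bins to rate")
    n = len(assignment.entries)
    return sum(1 for e in assignment.entries.values() if e.assigned) / n


def read_peak_tables(peaks_csv, noise_tsv) -> dict[str, PeakTable]:
    """Load per-sample peak tables from a peak CSV plus a noise sidecar TSV.

    Peak CSV columns: sample_id, size_bp, height, area (PeakScanner-export
    style).  Noise TSV columns: sample_id, noise_mean, noise_sd.  Every
    sample in the peak CSV must have noise statistics.
    """
    import csv as _csv
    from pathlib import Path

    noise: dict[str, tuple[float, float]] = {}
    with open(noise_tsv, encoding="utf-8", newline="") as fh:
        rows = _csv.reader((ln for ln in fh if not ln.startswith("#")),
                           delimiter="\t")
        header = next(rows, None)
        if header is None or [h.strip() for h in header[:3]] != [
            "sample_id", "noise_mean", "noise_sd"
        ]:
            raise ValidationError(
                f"{Path(noise_tsv).name}: expected header sample_id/noise_mean/noise_sd"
            )
        for row in rows:
            if row and "".join(row).strip():
                noise[row[0].strip()] = (float(row[1]), float(row[2]))

    grouped: dict[str, list[Peak]] = {}
    with open(peaks_csv, encoding="utf-8", newline="") as fh:
        rows = _csv.reader(ln for ln in fh if not ln.startswith("#"))
        header = next(rows, None)
        if header is None or [h.strip() for h in header[:4]] != [
            "sample_id", "size_bp", "height", "area"
        ]:
            raise ValidationError(
                f"{Path(peaks_csv).name}: expected header sample_id/size_bp/height/area"
            )
        for row in rows:
            if not row or not "".join(row).strip():
                continue
            sid = row[0].strip()
            grouped.setdefault(sid, []).append(
                Peak(size_bp=float(row[1]), height=float(row[2]),
                     area=float(row[3]))
            )
    tables = {}
    for sid, peaks in grouped.items():
        if sid not in noise:
            raise ValidationError(f"sample {sid!r} has no noise statistics")
        mean, sd = noise[sid]
        tables[sid] = PeakTable(sample_id=sid, peaks=tuple(peaks),
                                noise_mean=mean, noise_sd=sd)
    return tables


def write_peak_tables(peaks_csv, noise_tsv, tables: Sequence[PeakTable]) -> None:
    with open(peaks_csv, "w", encoding="utf-8") as fh:
        fh.write("sample_id,size_bp,height,area\n")
        for t in tables:
            for p in t.peaks:
                fh.write(f"{t.sample_id},{p.size_bp:.4f},{p.height:.4f},{p.area:.4f}\n")
    with open(noise_tsv, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tnoise_mean\tnoise_sd\n")
        for t in tables:
            fh.write(f"{t.sample_id}\t{t.noise_mean:g}\t{t.noise_sd:g}\n")


def process_peak_table(
    table: PeakTable,
    digest_table: DigestTable,
    k: float = 3.0,
    tol_bp: float = 1.0,
) -> tuple[CommunityProfile, BinAssignment, PCResult]:
    """Noise filter -> bin -> normalize -> assign -> P/C, in one call."""
    filtered = filter_noise(table, k=k)
    bins = bin_peaks(filtered, tol_bp=tol_bp)
    profile = relative_abundance(bins, sample_id=table.sample_id)
    assignment = assign_bins(profile, digest_table, tol_bp=tol_bp)
    return profile, assignment, producer_consumer_ratio(profile, assignment)
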