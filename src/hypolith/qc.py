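"""Amplicon read de-noising, demultiplexing, rarefaction and OTU tallies.

The read filter applies the de-noising rules standard for 454-era amplicon
data: discard a read if it is shorter than 300 bp, its mean phred quality is
below 25, it contains an ambiguous base or a homopolymer run longer than
6 nt, or the primer or barcode cannot be found.  All criteria are evaluated
for every read (no short-circuiting) so the verdict lists every reason.

Rarefaction uses the analytic hypergeometric expectation of richness in a
random subsample, E[S(m)] = sum_i (1 - C(N-N_i, m)/C(N, m)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations, groupby
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .digest import find_primer
from .errors import ConfigError, ValidationError
from .io import Read

FILTER_REASONS = ("too_short", "low_quality", "ambiguous", "homopolymer",
                  "no_primer", "no_barcode")


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-character run; 0 for an empty string."""
    return max((sum(1 for _ in g) for _, g in groupby(seq)), default=0)


@dataclass(frozen=True)
class FilterVerdict:
    read_id: str
    passed: bool
    reasons: frozenset[str]

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValidationError("verdict passed flag inconsistent with reasons")


def _match_barcode(seq: str, barcode_map: Mapping[str, str]) -> str | None:
    for bc in barcode_map.values():
        if seq.startswith(bc):
            return bc
    return None


def qc_filter(
    read: Read,
    min_len: int = 300,
    min_avg_q: float = 25.0,
    max_hp: int = 6,
    primer: str = "CCTACGGGAGGCAGCAG",
    barcode_map: Mapping[str, str] | None = None,
    max_mismatch: int = 0,
) -> FilterVerdict:
    """De-noising verdict for one read.

    Length is the untrimmed read length (barcode and primer in place).
    ``ambiguous`` means any non-ACGT base outside a recognised barcode
    prefix.  ``homopolymer`` fails iff the longest run exceeds ``max_hp``.
    The barcode check is skipped when no barcode map is supplied.
    """
    reasons = set()
    seq = read.sequence
    matched_bc = _match_barcode(seq, barcode_map) if barcode_map else None
    if barcode_map and matched_bc is None:
        reasons.add("no_barcode")
    if len(seq) < min_len:
        reasons.add("too_short")
    if read.mean_quality < min_avg_q:
        reasons.add("low_quality")
    body = seq[len(matched_bc):] if matched_bc else seq
    if any(b not in "ACGT" for b in body):
        reasons.add("ambiguous")
    if max_homopolymer_run(seq) > max_hp:
        reasons.add("homopolymer")
    if find_primer(seq, primer, max_mismatch) is None:
        reasons.add("no_primer")
    return FilterVerdict(read_id=read.id, passed=not reasons,
                         reasons=frozenset(reasons))


def demultiplex(
    reads: Iterable[Read], barcode_map: Mapping[str, str]
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Route reads to samples by exact 5' barcode prefix.

    The barcode table must be prefix-free (no barcode a prefix of another);
    otherwise assignment would be ambiguous and a :class:`ConfigError` is
    raised.  Unmatched reads are returned separately.
    """
    if not barcode_map:
        raise ConfigError("empty barcode map")
    barcodes = list(barcode_map.items())
    for (s1, b1), (s2, b2) in combinations(barcodes, 2):
        if b1.startswith(b2) or b2.startswith(b1):
            raise ConfigError(
                f"ambiguous barcode table: {b1!r} ({s1}) and {b2!r} ({s2})"
            )
    by_barcode = {bc: sample for sample, bc in barcodes}
    routed: dict[str, list[Read]] = {sample: [] for sample in barcode_map}
    unmatched: list[Read] = []
    for read in reads:
        bc = _match_barcode(read.sequence, barcode_map)
        if bc is None:
            unmatched.append(read)
        else:
            routed[by_barcode[bc]].append(replace(read, barcode=bc))
    return routed, unmatched


# ---------------------------------------------------------------------------
# Rarefaction

def rarefaction_expected_richness(counts: Sequence[int], depth: int) -> float:
    """Expected OTU richness of a without-replacement subsample of ``depth``.

    E[S(depth)] = sum_i [1 - C(N-N_i, depth) / C(N, depth)], the probability
    that OTU i appears at least once in the subsample, summed over OTUs.
    """
    counts = np.asarray([c for c in counts if c > 0], dtype=int)
    if (np.asarray(counts) < 0).any():
        raise ValidationError("negative OTU counts")
    n_total = int(counts.sum())
    if depth < 0 or depth > n_total:
        raise ValidationError(f"depth {depth} outside [0, {n_total}]")
    if depth == 0 or counts.size == 0:
        return 0.0
    # P(absent) = hypergeometric pmf of drawing 0 of the N_i marked items
    p_absent = hypergeom.pmf(0, n_total, counts, depth)
    return float(np.sum(1.0 - p_absent))


def coverage_at_depth(counts: Sequence[int], depth: int) -> float:
    """Fraction of observed richness expected at ``depth``: E[S(depth)]/S."""
    s_obs = sum(1 for c in counts if c > 0)
    if s_obs == 0:
        raise ValidationError("no OTUs observed; coverage undefined")
    return rarefaction_expected_richness(counts, depth) / s_obs


# ---------------------------------------------------------------------------
# OTU sharing and diazotroph screening

def shared_otu_counts(
    otu_sets: Mapping[str, set]
) -> dict[tuple[str, ...], int]:
    """Venn-region OTU counts for every non-empty sample combination.

    Keys are sorted tuples of sample names; the count is the number of OTUs
    found in exactly that set of samples.  Regions partition the union.
    """
    if len(otu_sets) < 2:
        raise ValidationError("need at least two OTU sets")
    names = sorted(otu_sets)
    regions = {
        tuple(combo): 0
        for r in range(1, len(names) + 1)
        for combo in combinations(names, r)
    }
    universe = set().union(*otu_sets.values())
    for otu in universe:
        members = tuple(n for n in names if otu in otu_sets[n])
        regions[members] += 1
    return regions


def screen_diazotrophs(
    taxon_abundances: Mapping[str, float], diazotroph_patterns: Sequence[str]
) -> float:
    """Summed relative abundance of taxa matching known-diazotroph lineages.

    A taxon matches when any pattern equals (case-insensitively) one of its
    ``;``-separated lineage ranks or its full name.  The pattern list must be
    supplied explicitly — screening against nothing is a configuration error.
    """
    if not diazotroph_patterns:
        raise ValidationError("diazotroph pattern list is empty")
    patterns = {p.strip().lower() for p in diazotroph_patterns}
    total = 0.0
    for taxon, abundance in taxon_abundances.items():
        ranks = {r.strip().lower() for r in taxon.split(";")}
        ranks.add(taxon.strip().lower())
        if ranks & patterns:
            total += abundance
    return total


# ---------------------------------------------------------------------------
# nifH tallies

@dataclass
class NifhTally:
    per_otu_total: dict[str, int]
    per_order_total: dict[str, int]
    per_site_total: dict[str, int]
    grand_total: int


def tally_nifh_otus(table: pd.DataFrame) -> NifhTally:
    """Row, order and grand totals of a nifH OTU count table.

    Expects a column ``otu``, a column ``order``, and one integer count
    column per site in between.
    """
    if "otu" not in table.columns or "order" not in table.columns:
        raise ValidationError("nifH table needs 'otu' and 'order' columns")
    site_cols = [c for c in table.columns if c not in ("otu", "order", "total")]
    counts = table[site_cols].to_numpy()
    if (counts < 0).any():
        raise ValidationError("negative nifH counts")
    per_otu = dict(zip(table["otu"].astype(str), counts.sum(axis=1).astype(int)))
    per_order = {
        str(order): int(sub[site_cols].to_numpy().sum())
        for order, sub in table.groupby("order", sort=False)
    }
    per_site = {c: int(table[c].sum()) for c in site_cols}
    return NifhTally(
        per_otu_total=per_otu,
        per_order_total=per_order,
        per_site_total=per_site,
        grand_total=int(counts.sum()),
    )


def load_nifh_table() -> pd.DataFrame:
    """The packaged nitrogenase (nifH) OTU count table used as the worked
    example input."""
    from importlib.resources import files

    path = files("hypolith.data").joinpath("nifh_counts.tsv")
    return pd.read_csv(path, sep="\t", comment="#")


def load_diazotroph_patterns() -> list[str]:
    """The packaged, editable list of lineage patterns treated as putative
    diazotrophs (curated, not canonical)."""
    from importlib.resources import files

    import yaml

    path = files("hypolith.data").joinpath("diazotrophs.yml")
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    return list(data["patterns"])
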