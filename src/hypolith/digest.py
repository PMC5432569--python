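"""In-silico PCR and restriction digest: predicted terminal fragment sizes.

A t-RFLP fingerprint is read out as the sizes of fluorescently labeled
terminal restriction fragments (TRFs): the label sits on the 5' end of the
forward primer, so each amplicon contributes one fragment running from the
forward-primer start to the first restriction cut.  Predicting those sizes
for a curated reference library (a "virtual digest") is what lets observed
peak sizes be assigned to taxa.

Conventions (declared, since capillary practice varies):

* TRF length is measured in nucleotides from the 5' labeled primer start to
  the cut, primer included — this is the length of the labeled molecule that
  runs on the capillary.
* An amplicon with no recognition site yields an uncut labeled fragment of
  full amplicon length, flagged ``no_site``.
* Primer matching allows IUPAC degeneracy in the primer (907R carries an M)
  and zero mismatches by default; only the leftmost forward match is used.
* The reverse primer is given 5'->3' and matched as its reverse complement;
  the leftmost downstream site is taken (the shortest product dominates PCR).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .io import ReferenceRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC degeneracy codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(code: str, base: str) -> bool:
    """True iff concrete ``base`` is in the expansion set of IUPAC ``code``."""
    try:
        expansion = IUPAC[code]
    except KeyError:
        raise ValidationError(f"invalid IUPAC code {code!r}") from None
    if base not in "ACGT":
        return False
    return base in expansion


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site and cut offset.

    The cut occurs before position ``cut_offset`` within the site (0-based),
    e.g. MspI C^CGG has recognition ``CCGG`` and offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition or any(c not in IUPAC for c in self.recognition):
            raise ValidationError(f"{self.name}: invalid recognition site")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValidationError(f"{self.name}: cut offset outside recognition site")


MSPI = Enzyme("MspI", "CCGG", 1)
HAEIII = Enzyme("HaeIII", "GGCC", 2)
HINFI = Enzyme("HinfI", "GANTC", 1)
ENZYMES: dict[str, Enzyme] = {e.name: e for e in (MSPI, HAEIII, HINFI)}


@dataclass(frozen=True)
class PrimerPair:
    """A labeled forward / unlabeled reverse primer pair, both given 5'->3'.

    Defaults are the bacterial 16S V3–V5 pair 341F / 907R.
    """

    forward: str = "CCTACGGGAGGCAGCAG"
    reverse: str = "CCGTCAATTCMTTTGAGTTT"

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p or any(c not in IUPAC for c in p):
                raise ValidationError(f"{name} primer is empty or non-IUPAC")


DEFAULT_PRIMERS = PrimerPair()


def _iupac_regex(primer: str) -> re.Pattern[str]:
    return re.compile("".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in primer
    ))


def find_primer(seq: str, primer: str, max_mismatch: int = 0) -> int | None:
    """Leftmost 0-based start of ``primer`` in ``seq``, or None.

    Degenerate primer positions match any base in their IUPAC expansion;
    ambiguous bases in ``seq`` (anything outside ACGT) never match.  Up to
    ``max_mismatch`` mismatching positions are tolerated.
    """
    if any(c not in IUPAC for c in primer):
        raise ValidationError(f"primer contains invalid IUPAC code: {primer!r}")
    if max_mismatch == 0:
        m = _iupac_regex(primer).search(seq)
        return m.start() if m else None
    n, k = len(seq), len(primer)
    for start in range(n - k + 1):
        mism = 0
        for i in range(k):
            if not iupac_match(primer[i], seq[start + i]):
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return start
    return None


def extract_amplicon(
    seq: str, primers: PrimerPair = DEFAULT_PRIMERS, max_mismatch: int = 0
) -> str | None:
    """The PCR product predicted from ``seq``, primer annealing sites included.

    Returns None when either primer is absent or the reverse site is not
    downstream of the forward site.
    """
    f = find_primer(seq, primers.forward, max_mismatch)
    if f is None:
        return None
    rc = reverse_complement(primers.reverse)
    downstream = seq[f + len(primers.forward):]
    r = find_primer(downstream, rc, max_mismatch)
    if r is None:
        return None
    end = f + len(primers.forward) + r + len(rc)
    return seq[f:end]


def find_cut_positions(seq: str, enzyme: Enzyme) -> list[int]:
    """Ascending between-base cut coordinates of ``enzyme`` in ``seq``.

    Overlapping recognition sites are all reported.  N in the sequence never
    matches a recognition position.
    """
    site = enzyme.recognition
    k = len(site)
    cuts = []
    for start in range(len(seq) - k + 1):
        if all(iupac_match(site[i], seq[start + i]) for i in range(k)):
            cuts.append(start + enzyme.cut_offset)
    return cuts


def terminal_fragment(amplicon: str, enzyme: Enzyme) -> tuple[int, bool]:
    """(TRF length, no_site flag) for a labeled amplicon.

    The TRF runs from the 5' labeled end to the first cut; with no cut the
    uncut amplicon is the fragment.  A cut coordinate of 0 would yield a
    zero-length labeled fragment and is skipped as undetectable.
    """
    if not amplicon:
        raise ValidationError("empty amplicon")
    cuts = [c for c in find_cut_positions(amplicon, enzyme) if c > 0]
    if cuts:
        return cuts[0], False
    return len(amplicon), True


@dataclass(frozen=True)
class DigestEntry:
    trf_bp: int
    no_site: bool
    role: str | None = None
    lineage: tuple[str, ...] = ()
    diazotroph: bool = False


@dataclass
class DigestTable:
    """Predicted TRF length per reference id, plus ids with no amplicon."""

    enzyme: Enzyme
    primers: PrimerPair
    entries: dict[str, DigestEntry] = field(default_factory=dict)
    excluded: tuple[str, ...] = ()


def virtual_digest(
    refs: Sequence[ReferenceRecord],
    primers: PrimerPair = DEFAULT_PRIMERS,
    enzyme: Enzyme = MSPI,
    max_mismatch: int = 0,
) -> DigestTable:
    """Predict one TRF length per reference; references that yield no
    amplicon are excluded and reported."""
    entries: dict[str, DigestEntry] = {}
    excluded: list[str] = []
    for rec in refs:
        amplicon = extract_amplicon(rec.sequence, primers, max_mismatch)
        if amplicon is None:
            excluded.append(rec.id)
            continue
        trf, no_site = terminal_fragment(amplicon, enzyme)
        entries[rec.id] = DigestEntry(
            trf_bp=trf, no_site=no_site, role=rec.role,
            lineage=rec.lineage, diazotroph=rec.diazotroph,
        )
    if not entries:
        raise ValidationError("no reference yielded an amplicon")
    return DigestTable(enzyme=enzyme, primers=primers, entries=entries,
                       excluded=tuple(excluded))
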