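"""Reference ORF model and SpCas9 protospacer/PAM site location.

The unit of analysis is a PCR amplicon spanning the portion of an open
reading frame targeted by a single sgRNA.  The reference carries the ORF
annotation (0-based, half-open coordinates); the guide is located on
either strand by exact 20-nt match adjacent to an NGG PAM, and the
expected blunt Cas9 cut is placed 3 bp 5' of the PAM, i.e. between
protospacer bases 17 and 18.  Minus-strand hits are reported in
plus-strand coordinates.  An analysis window around the cut site defines
which edits are attributed to the targeted region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

PROTOSPACER_LEN = 20
#: blunt cut between protospacer positions 17 and 18 (3 bp 5' of the PAM)
CUT_OFFSET = 17
DEFAULT_WINDOW_HALFWIDTH = 30

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class CrisprEError(ValueError):
    """Base class for input/analysis errors raised by this package."""


class TargetError(CrisprEError):
    """The guide cannot be located unambiguously on the reference."""


class GuideNotFoundError(TargetError):
    pass


class AmbiguousTargetError(TargetError):
    pass


class MissingPAMError(TargetError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceTarget:
    """Amplified reference sequence with its ORF annotation.

    ``orf_start`` is the 0-based offset of the first codon base within
    ``sequence``; ``orf_end`` is the exclusive end of the ORF region
    covered by the amplicon.  The sequence is uppercase-normalized and
    must contain only A/C/G/T (ambiguity codes are rejected).
    """

    name: str
    sequence: str
    orf_start: int
    orf_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if re.search(r"[^ACGT]", self.sequence):
            raise CrisprEError(
                f"{self.name}: reference may contain only A/C/G/T "
                "(ambiguity codes are rejected)"
            )
        if not (0 <= self.orf_start < self.orf_end <= len(self.sequence)):
            raise CrisprEError(
                f"{self.name}: frame annotation error: require "
                f"0 <= orf_start < orf_end <= {len(self.sequence)}, "
                f"got [{self.orf_start}, {self.orf_end})"
            )

    @property
    def orf_codon_end(self) -> int:
        """Last codon-complete position of the annotated ORF region."""
        return self.orf_start + 3 * ((self.orf_end - self.orf_start) // 3)


@dataclass(frozen=True)
class TargetSite:
    """A located protospacer with its PAM, cut site and analysis window.

    ``cut_index`` is the plus-strand position such that the blunt cut
    lies between ``cut_index - 1`` and ``cut_index``.  ``window_start``
    and ``window_end`` delimit (half-open) the reference interval whose
    edits are attributed to this site.
    """

    protospacer: str
    pam: str
    strand: str  # "+" or "-"
    cut_index: int
    window_start: int
    window_end: int


def _pam_regex(pattern: str) -> re.Pattern:
    return re.compile("".join("[ACGT]" if c == "N" else c for c in pattern.upper()))


def find_target_site(
    ref: ReferenceTarget,
    guide: str,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
    pam_pattern: str = "NGG",
) -> TargetSite:
    """Locate a 20-nt guide on either strand of the reference.

    The protospacer must occur exactly once (over both strands)
    immediately 5' of a PAM matching ``pam_pattern``.  Raises
    :class:`GuideNotFoundError`, :class:`MissingPAMError` or
    :class:`AmbiguousTargetError` otherwise.
    """
    guide = guide.upper()
    if len(guide) != PROTOSPACER_LEN or re.search(r"[^ACGT]", guide):
        raise CrisprEError(
            f"guide must be {PROTOSPACER_LEN} nt of A/C/G/T, got {guide!r}"
        )
    if window_halfwidth <= 0:
        raise CrisprEError("window_halfwidth must be positive")
    pam_re = _pam_regex(pam_pattern)
    plen = len(pam_pattern)
    seq = ref.sequence
    n = len(seq)

    hits: list[tuple[str, int, str]] = []
    protospacer_seen = False
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        start = s.find(guide)
        while start != -1:
            protospacer_seen = True
            pam = s[start + PROTOSPACER_LEN : start + PROTOSPACER_LEN + plen]
            if len(pam) == plen and pam_re.fullmatch(pam):
                if strand == "+":
                    cut = start + CUT_OFFSET
                else:
                    # bond between minus-strand positions maps to the
                    # plus-strand bond at n - start - CUT_OFFSET
                    cut = n - start - CUT_OFFSET
                hits.append((strand, cut, pam))
            start = s.find(guide, start + 1)

    if not hits:
        if protospacer_seen:
            raise MissingPAMError(
                f"missing PAM: protospacer found but no adjacent {pam_pattern}"
            )
        raise GuideNotFoundError("guide not found on either strand of the reference")
    if len(hits) > 1:
        raise AmbiguousTargetError(
            f"ambiguous target: guide matches {len(hits)} PAM-adjacent sites"
        )

    strand, cut, pam = hits[0]
    return TargetSite(
        protospacer=guide,
        pam=pam,
        strand=strand,
        cut_index=cut,
        window_start=max(0, cut - window_halfwidth),
        window_end=min(n, cut + window_halfwidth),
    )
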