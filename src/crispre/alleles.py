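"""Allele calling from clonal amplicon sequences.

Each surviving clone contributes one Sanger-sequenced amplicon.  The
pipeline aligns the clone to the reference (global alignment, affine
gaps), extracts left-normalized edits (insertions, deletions,
substitutions), classifies the allele by the residue of its net indel
length mod 3 (3n in-frame, 3n+1 / 3n+2 frameshift), translates the
mutant ORF segment, and collapses byte-identical edit signatures into
independent gene-editing events (identical clones are taken to be
progeny of a single cut-and-repair outcome).

Only edits intersecting the target site's analysis window count toward
frame classification; clones whose edits all lie outside the window are
classified WT at the target and flagged.  Substitutions never change
the reading frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .target import CrisprEError, ReferenceTarget, TargetSite

STATUS_OK = "ok"
STATUS_FAILED = "failed_sequencing"

FRAME_WT = "WT"
FRAME_IN = "in_frame"
FRAME_P1 = "frameshift_plus1"
FRAME_P2 = "frameshift_plus2"
#: edited frame classes, in reporting order
FRAME_CLASSES = (FRAME_IN, FRAME_P1, FRAME_P2)
FRAMESHIFT_CLASSES = (FRAME_P1, FRAME_P2)

EDIT_KINDS = ("insertion", "deletion", "substitution")

#: default alignment scoring: chosen so the largest deletions seen in
#: practice (>20 nt) are recovered as one gap rather than mismatch runs
DEFAULT_SCORING = {"match": 2, "mismatch": -3, "gap_open": -6, "gap_extend": -1}
DEFAULT_MIN_IDENTITY = 0.60


class UnalignableCloneError(CrisprEError):
    """Clone sequence cannot be credibly aligned to the reference."""


@dataclass(frozen=True)
class CloneObservation:
    """One picked clone: an amplicon sequence or a sequencing failure."""

    clone_id: str
    sequence: str | None = None
    status: str = STATUS_OK

    def __post_init__(self) -> None:
        if self.sequence is not None:
            object.__setattr__(self, "sequence", self.sequence.upper())
        # invariant: failed_sequencing <=> sequence absent
        if self.sequence is None:
            object.__setattr__(self, "status", STATUS_FAILED)
        elif self.status == STATUS_FAILED:
            object.__setattr__(self, "sequence", None)


@dataclass(frozen=True)
class Edit:
    """A normalized edit in reference coordinates (VCF-style).

    ``position`` is the 0-based, left-normalized reference coordinate:
    for deletions/substitutions the first affected base, for insertions
    the base before which the new sequence is inserted.
    """

    kind: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise CrisprEError(f"unknown edit kind {self.kind!r}")
        if self.position < 0:
            raise CrisprEError("edit position must be >= 0")
        if self.kind == "insertion" and not (
            self.ref_allele == "" and self.alt_allele
        ):
            raise CrisprEError("insertion requires empty ref_allele, non-empty alt")
        if self.kind == "deletion" and not (
            self.alt_allele == "" and self.ref_allele
        ):
            raise CrisprEError("deletion requires empty alt_allele, non-empty ref")
        if self.kind == "substitution" and (
            len(self.ref_allele) != len(self.alt_allele) or not self.ref_allele
        ):
            raise CrisprEError("substitution requires equal non-zero allele lengths")

    @property
    def end(self) -> int:
        """Exclusive end of the affected reference interval."""
        return self.position + len(self.ref_allele)

    @property
    def length_change(self) -> int:
        if self.kind == "insertion":
            return len(self.alt_allele)
        if self.kind == "deletion":
            return -len(self.ref_allele)
        return 0

    def as_tuple(self) -> tuple[str, int, str, str]:
        return (self.kind, self.position, self.ref_allele, self.alt_allele)

    def __str__(self) -> str:
        if self.kind == "insertion":
            return f"ins:{self.position}:+{self.alt_allele}"
        if self.kind == "deletion":
            return f"del:{self.position}:-{self.ref_allele}"
        return f"sub:{self.position}:{self.ref_allele}>{self.alt_allele}"


def _edit_sort_key(e: Edit) -> tuple:
    return (e.position, e.kind, e.ref_allele, e.alt_allele)


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    ref_gapped: str
    clone_gapped: str
    score: float
    identity: float


@dataclass(frozen=True)
class AlleleCall:
    """One clone's normalized edits and frame classification."""

    clone_id: str
    status: str = STATUS_OK
    edits: tuple[Edit, ...] = ()
    in_window: tuple[bool, ...] = ()
    net_indel: int = 0
    n_substitutions: int = 0
    frame_class: str | None = None  # None for failed clones
    stop_gain: bool = False
    protein_consequence: str = ""
    identity: float | None = None

    @property
    def edits_in_window(self) -> tuple[Edit, ...]:
        return tuple(e for e, f in zip(self.edits, self.in_window) if f)

    @property
    def edited(self) -> bool:
        """True when the clone carries edits at the targeted region."""
        return self.status == STATUS_OK and any(self.in_window)

    def signature(self) -> tuple:
        """Canonical identity of this allele's in-window edits."""
        return tuple(e.as_tuple() for e in self.edits_in_window)


@dataclass(frozen=True)
class EditingEvent:
    """One independent gene-editing outcome (possibly several sibling clones)."""

    event_id: str
    clone_ids: tuple[str, ...]
    edits: tuple[Edit, ...]
    net_indel: int
    frame_class: str
    stop_gain: bool
    protein_consequence: str


@dataclass
class EditingSummary:
    """Per-experiment tallies over clones and independent events."""

    n_clones: int
    n_failed: int
    n_sequenced: int
    n_wt: int
    n_edited: int
    n_events: int
    clone_class_counts: dict[str, int]
    event_class_counts: dict[str, int]
    n_outside_window: int = 0
    n_stop_gain_events: int = 0

    def __post_init__(self) -> None:
        assert self.n_clones == self.n_failed + self.n_sequenced
        assert self.n_sequenced == self.n_wt + self.n_edited
        assert self.n_events <= self.n_edited
        assert sum(self.event_class_counts.values()) == self.n_events
        assert sum(self.clone_class_counts.values()) == self.n_edited

    @property
    def n_frameshift_clones(self) -> int:
        return sum(self.clone_class_counts.get(c, 0) for c in FRAMESHIFT_CLASSES)

    @property
    def n_frameshift_events(self) -> int:
        return sum(self.event_class_counts.get(c, 0) for c in FRAMESHIFT_CLASSES)

    def to_dict(self) -> dict:
        return {
            "n_clones": self.n_clones,
            "n_failed": self.n_failed,
            "n_sequenced": self.n_sequenced,
            "n_wt": self.n_wt,
            "n_edited": self.n_edited,
            "n_events": self.n_events,
            "clone_class_counts": dict(self.clone_class_counts),
            "event_class_counts": dict(self.event_class_counts),
            "n_outside_window": self.n_outside_window,
            "n_stop_gain_events": self.n_stop_gain_events,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EditingSummary":
        return cls(
            n_clones=d["n_clones"],
            n_failed=d["n_failed"],
            n_sequenced=d["n_sequenced"],
            n_wt=d["n_wt"],
            n_edited=d["n_edited"],
            n_events=d["n_events"],
            clone_class_counts=dict(d["clone_class_counts"]),
            event_class_counts=dict(d["event_class_counts"]),
            n_outside_window=d.get("n_outside_window", 0),
            n_stop_gain_events=d.get("n_stop_gain_events", 0),
        )


# ---------------------------------------------------------------------------
# alignment


def build_aligner(
    match: float = DEFAULT_SCORING["match"],
    mismatch: float = DEFAULT_SCORING["mismatch"],
    gap_open: float = DEFAULT_SCORING["gap_open"],
    gap_extend: float = DEFAULT_SCORING["gap_extend"],
) -> Align.PairwiseAligner:
    """Global affine-gap aligner.  A gap of length L scores
    ``gap_open + (L - 1) * gap_extend``; end gaps are penalized like
    internal ones (the clone is a full-length amplicon)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_clone(
    ref: ReferenceTarget,
    clone: CloneObservation,
    aligner: Align.PairwiseAligner | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_length_ratio: float = 1.5,
) -> PairwiseAlignmentResult:
    """Globally align one clone amplicon to the reference.

    Raises :class:`UnalignableCloneError` when the clone's length or
    alignment identity falls below the configured floor; callers degrade
    such clones to ``failed_sequencing``.
    """
    if clone.status != STATUS_OK or clone.sequence is None:
        raise CrisprEError(f"{clone.clone_id}: cannot align a failed clone")
    ratio = len(clone.sequence) / len(ref.sequence)
    if not (1.0 / max_length_ratio <= ratio <= max_length_ratio):
        raise UnalignableCloneError(
            f"unalignable clone {clone.clone_id}: length ratio {ratio:.2f}"
        )
    if aligner is None:
        aligner = build_aligner()
    aln = aligner.align(ref.sequence, clone.sequence)[0]
    ref_g, clone_g = str(aln[0]), str(aln[1])
    matches = sum(1 for a, b in zip(ref_g, clone_g) if a == b and a != "-")
    identity = matches / len(ref_g)
    if identity < min_identity:
        raise UnalignableCloneError(
            f"unalignable clone {clone.clone_id}: identity {identity:.2f} "
            f"< {min_identity:.2f}"
        )
    return PairwiseAlignmentResult(ref_g, clone_g, float(aln.score), identity)


def extract_edits(
    alignment: PairwiseAlignmentResult, ref_seq: str
) -> list[Edit]:
    """Turn alignment columns into normalized edits.

    Contiguous gap runs become single insertion/deletion edits; each
    mismatch column becomes a single-base substitution.  Indels are then
    left-normalized (shifted to their 5'-most equivalent placement).
    """
    edits: list[Edit] = []
    rpos = 0
    i = 0
    ref_g, clone_g = alignment.ref_gapped, alignment.clone_gapped
    ncol = len(ref_g)
    while i < ncol:
        if ref_g[i] == "-":
            j = i
            while j < ncol and ref_g[j] == "-":
                j += 1
            edits.append(Edit("insertion", rpos, "", clone_g[i:j]))
            i = j
        elif clone_g[i] == "-":
            j = i
            n = 0
            while j < ncol and clone_g[j] == "-" and ref_g[j] != "-":
                n += 1
                j += 1
            edits.append(Edit("deletion", rpos, ref_seq[rpos : rpos + n], ""))
            rpos += n
            i = j
        else:
            if ref_g[i] != clone_g[i]:
                edits.append(Edit("substitution", rpos, ref_g[i], clone_g[i]))
            rpos += 1
            i += 1
    return normalize_edits(edits, ref_seq)


def normalize_edits(edits: Iterable[Edit], ref_seq: str) -> list[Edit]:
    """Left-normalize indels against the reference (VCF-style).

    Shifting is bounded by the preceding edit so the result stays a
    valid non-overlapping edit list; the canonical form makes duplicate
    clone detection byte-exact.
    """
    out: list[Edit] = []
    bound = 0
    for e in sorted(edits, key=_edit_sort_key):
        if e.position < bound:
            raise CrisprEError(f"overlapping edits at position {e.position}")
        if e.kind == "deletion":
            p, L = e.position, len(e.ref_allele)
            while p > bound and ref_seq[p - 1] == ref_seq[p + L - 1]:
                p -= 1
            e = Edit("deletion", p, ref_seq[p : p + L], "")
        elif e.kind == "insertion":
            p, a = e.position, e.alt_allele
            while p > bound and ref_seq[p - 1] == a[-1]:
                a = ref_seq[p - 1] + a[:-1]
                p -= 1
            e = Edit("insertion", p, "", a)
        out.append(e)
        bound = e.position + 1 if e.kind == "insertion" else e.end
    return sorted(out, key=_edit_sort_key)


def apply_edits(ref_seq: str, edits: Iterable[Edit]) -> str:
    """Apply non-overlapping edits to the reference, reconstructing the
    clone sequence."""
    parts: list[str] = []
    prev = 0
    for e in sorted(edits, key=_edit_sort_key):
        if e.position < prev:
            raise CrisprEError(f"overlapping edits at position {e.position}")
        if e.ref_allele and ref_seq[e.position : e.end] != e.ref_allele:
            raise CrisprEError(
                f"ref allele mismatch at {e.position}: expected "
                f"{ref_seq[e.position:e.end]!r}, edit says {e.ref_allele!r}"
            )
        parts.append(ref_seq[prev : e.position])
        parts.append(e.alt_allele)
        prev = e.end
    parts.append(ref_seq[prev:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# classification and translation


def edit_in_window(edit: Edit, site: TargetSite) -> bool:
    """Edits overlapping the window count in full, including those
    spanning its boundary (a cut-site deletion may extend past it)."""
    if edit.kind == "insertion":
        return site.window_start <= edit.position <= site.window_end
    return edit.position < site.window_end and edit.end > site.window_start


def net_frame_shift(edits: Iterable[Edit]) -> int:
    """Net indel length in nt: insertions positive, deletions negative,
    substitutions zero."""
    return sum(e.length_change for e in edits)


def classify_allele(edits_in_window: Sequence[Edit]) -> str:
    """Frame class from the non-negative residue of the net indel mod 3.

    No in-window edits -> WT.  Substitution-only alleles are edited and
    in-frame (net 0).
    """
    if not edits_in_window:
        return FRAME_WT
    residue = net_frame_shift(edits_in_window) % 3
    return {0: FRAME_IN, 1: FRAME_P1, 2: FRAME_P2}[residue]


def _translate(seq: str) -> str:
    seq = seq[: 3 * (len(seq) // 3)]
    return str(Seq(seq).translate())


def _map_to_mutant(pos: int, edits: Sequence[Edit]) -> int:
    """Map a reference coordinate through an edit list to mutant
    coordinates (positions inside a deletion map to its start)."""
    off = 0
    for e in sorted(edits, key=_edit_sort_key):
        if e.end <= pos and not (e.kind == "insertion" and e.position == pos):
            off += e.length_change
        elif e.kind == "deletion" and e.position < pos < e.end:
            off -= pos - e.position
    return pos + off


def translate_allele(
    ref: ReferenceTarget, edits_in_window: Sequence[Edit], site: TargetSite
) -> tuple[str, bool]:
    """Translate the mutant ORF segment; detect in-frame stop gains.

    Returns ``(protein_consequence, stop_gain)``.  For in-frame alleles
    the segment runs from the ORF start to one codon past the window (or
    past the furthest edit); a stop codon appearing there that is absent
    from the reference translation is flagged as a stop gain.  For
    frameshift alleles translation continues to the first downstream
    stop (shown as ``*``) or the end of the covered ORF.
    """
    seq = ref.sequence
    landmark = max(
        site.window_end, max((e.end for e in edits_in_window), default=0)
    ) + 3
    ncod = math.ceil(max(0, landmark - ref.orf_start) / 3)
    lm = min(ref.orf_start + 3 * ncod, ref.orf_codon_end)
    ref_prot = _translate(seq[ref.orf_start : lm])
    if not edits_in_window:
        return ref_prot, False
    mutant = apply_edits(seq, edits_in_window)
    mut_start = _map_to_mutant(ref.orf_start, edits_in_window)
    if net_frame_shift(edits_in_window) % 3 == 0:
        mut_end = _map_to_mutant(lm, edits_in_window)
        prot = _translate(mutant[mut_start:mut_end])
        stop_gain = "*" in prot and "*" not in ref_prot
        return prot, stop_gain
    # frameshift: divergent peptide until the first downstream stop
    mut_orf_end = _map_to_mutant(ref.orf_end, edits_in_window)
    prot = _translate(mutant[mut_start:mut_orf_end])
    if "*" in prot:
        prot = prot[: prot.index("*") + 1]
    return prot, False


# ---------------------------------------------------------------------------
# per-clone calling


def _finalize_call(
    ref: ReferenceTarget,
    site: TargetSite,
    clone_id: str,
    edits: Sequence[Edit],
    identity: float | None = None,
) -> AlleleCall:
    edits = tuple(sorted(edits, key=_edit_sort_key))
    flags = tuple(edit_in_window(e, site) for e in edits)
    in_win = [e for e, f in zip(edits, flags) if f]
    frame_class = classify_allele(in_win)
    protein, stop_gain = translate_allele(ref, in_win, site)
    return AlleleCall(
        clone_id=clone_id,
        status=STATUS_OK,
        edits=edits,
        in_window=flags,
        net_indel=net_frame_shift(in_win),
        n_substitutions=sum(1 for e in in_win if e.kind == "substitution"),
        frame_class=frame_class,
        stop_gain=stop_gain,
        protein_consequence=protein,
        identity=identity,
    )


def call_clone(
    ref: ReferenceTarget,
    site: TargetSite,
    clone: CloneObservation,
    aligner: Align.PairwiseAligner | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> AlleleCall:
    """Full per-clone pipeline: align, extract edits, classify, translate.

    Unalignable clones are degraded to ``failed_sequencing`` rather than
    aborting the experiment.
    """
    if clone.status != STATUS_OK:
        return AlleleCall(clone_id=clone.clone_id, status=STATUS_FAILED)
    try:
        aln = align_clone(ref, clone, aligner=aligner, min_identity=min_identity)
    except UnalignableCloneError:
        return AlleleCall(clone_id=clone.clone_id, status=STATUS_FAILED)
    edits = extract_edits(aln, ref.sequence)
    return _finalize_call(ref, site, clone.clone_id, edits, identity=aln.identity)


def call_experiment(
    ref: ReferenceTarget,
    site: TargetSite,
    clones: Iterable[CloneObservation],
    aligner: Align.PairwiseAligner | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[AlleleCall]:
    if aligner is None:
        aligner = build_aligner()
    return [
        call_clone(ref, site, c, aligner=aligner, min_identity=min_identity)
        for c in clones
    ]


# ---------------------------------------------------------------------------
# event collapsing and summary


def collapse_identical_clones(
    calls: Sequence[AlleleCall],
) -> tuple[list[EditingEvent], EditingSummary]:
    """Merge clones with byte-identical in-window edit signatures into
    independent editing events and tally the experiment.

    WT clones are never merged with edited ones; only edited clones form
    events.  Clones whose edits all lie outside the window count as WT
    at the target (tracked in ``n_outside_window``).
    """
    ok = [c for c in calls if c.status == STATUS_OK]
    failed = [c for c in calls if c.status != STATUS_OK]
    edited = [c for c in ok if c.edited]
    wt = [c for c in ok if not c.edited]
    n_outside = sum(1 for c in wt if c.edits)

    events: list[EditingEvent] = []
    by_sig: dict[tuple, int] = {}
    for call in edited:
        sig = call.signature()
        if sig in by_sig:
            ev = events[by_sig[sig]]
            events[by_sig[sig]] = EditingEvent(
                event_id=ev.event_id,
                clone_ids=ev.clone_ids + (call.clone_id,),
                edits=ev.edits,
                net_indel=ev.net_indel,
                frame_class=ev.frame_class,
                stop_gain=ev.stop_gain,
                protein_consequence=ev.protein_consequence,
            )
        else:
            by_sig[sig] = len(events)
            events.append(
                EditingEvent(
                    event_id=f"event_{len(events) + 1}",
                    clone_ids=(call.clone_id,),
                    edits=call.edits_in_window,
                    net_indel=call.net_indel,
                    frame_class=call.frame_class,  # type: ignore[arg-type]
                    stop_gain=call.stop_gain,
                    protein_consequence=call.protein_consequence,
                )
            )

    clone_counts = {c: 0 for c in FRAME_CLASSES}
    for call in edited:
        clone_counts[call.frame_class] += 1  # type: ignore[index]
    event_counts = {c: 0 for c in FRAME_CLASSES}
    for ev in events:
        event_counts[ev.frame_class] += 1

    summary = EditingSummary(
        n_clones=len(calls),
        n_failed=len(failed),
        n_sequenced=len(ok),
        n_wt=len(wt),
        n_edited=len(edited),
        n_events=len(events),
        clone_class_counts=clone_counts,
        event_class_counts=event_counts,
        n_outside_window=n_outside,
        n_stop_gain_events=sum(1 for ev in events if ev.stop_gain),
    )
    return events, summary


# ---------------------------------------------------------------------------
# tabular I/O

VARIANT_COLUMNS = ["clone_id", "kind", "position", "ref_allele", "alt_allele"]


def calls_from_variant_table(
    table: pd.DataFrame, ref: ReferenceTarget, site: TargetSite
) -> list[AlleleCall]:
    """Build allele calls from a pre-called variant table, bypassing
    alignment.

    One row per edit with columns ``clone_id, kind, position,
    ref_allele, alt_allele``; ``kind`` may also be ``wt`` (unedited
    clone, other columns empty) or ``failed`` (sequencing failure).
    Edits are validated against the reference and left-normalized.
    """
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise CrisprEError(f"variant table missing columns: {missing}")
    calls: list[AlleleCall] = []
    for clone_id, group in table.groupby("clone_id", sort=False):
        kinds = set(group["kind"])
        if kinds == {"failed"}:
            calls.append(AlleleCall(clone_id=str(clone_id), status=STATUS_FAILED))
            continue
        if kinds == {"wt"}:
            calls.append(_finalize_call(ref, site, str(clone_id), []))
            continue
        bad = kinds - set(EDIT_KINDS)
        if bad:
            raise CrisprEError(f"{clone_id}: unknown variant kinds {sorted(bad)}")
        edits = [
            Edit(row.kind, int(row.position), str(row.ref_allele), str(row.alt_allele))
            for row in group.itertuples(index=False)
        ]
        edits = normalize_edits(edits, ref.sequence)
        calls.append(_finalize_call(ref, site, str(clone_id), edits))
    return calls


def read_variant_table(path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    if "position" in table.columns:
        table["position"] = table["position"].replace("", "0")
    return table


def calls_to_table(calls: Sequence[AlleleCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "clone_id": c.clone_id,
                "status": c.status,
                "edits": ";".join(str(e) for e in c.edits),
                "in_window": ";".join("1" if f else "0" for f in c.in_window),
                "net_indel": c.net_indel,
                "n_substitutions": c.n_substitutions,
                "frame_class": c.frame_class if c.frame_class else "",
                "stop_gain": c.stop_gain,
                "protein_consequence": c.protein_consequence,
            }
        )
    return pd.DataFrame(rows)


def events_to_table(events: Sequence[EditingEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "clone_ids": ",".join(ev.clone_ids),
                "n_clones": len(ev.clone_ids),
                "edits": ";".join(str(e) for e in ev.edits),
                "net_indel": ev.net_indel,
                "frame_class": ev.frame_class,
                "stop_gain": ev.stop_gain,
                "protein_consequence": ev.protein_consequence,
            }
        )
    return pd.DataFrame(rows)
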