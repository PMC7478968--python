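"""File-format front doors: FASTA references and clone sets, status
side files."""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO

from .alleles import STATUS_FAILED, STATUS_OK, CloneObservation
from .target import CrisprEError, ReferenceTarget


def read_reference_fasta(path, orf_start: int, orf_end: int) -> ReferenceTarget:
    """Single-record FASTA plus the ORF annotation (0-based half-open)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise CrisprEError(
            f"{path}: reference FASTA must contain exactly one record, "
            f"found {len(records)}"
        )
    rec = records[0]
    return ReferenceTarget(
        name=rec.id, sequence=str(rec.seq), orf_start=orf_start, orf_end=orf_end
    )


def read_status_table(path) -> dict[str, str]:
    statuses: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {
            "clone_id",
            "status",
        } <= set(reader.fieldnames):
            raise CrisprEError(f"{path}: status table needs clone_id and status")
        for row in reader:
            statuses[row["clone_id"]] = row["status"]
    return statuses


def read_clones_fasta(path, status_path=None) -> list[CloneObservation]:
    """Multi-FASTA of clone amplicons; record IDs are clone IDs.

    An optional status TSV (clone_id, status) marks failed clones;
    clones listed there but absent from the FASTA are failed
    sequencing reactions.
    """
    statuses = read_status_table(status_path) if status_path else {}
    clones: list[CloneObservation] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seen.add(rec.id)
        if statuses.get(rec.id) == STATUS_FAILED:
            clones.append(CloneObservation(rec.id, None, STATUS_FAILED))
        else:
            clones.append(CloneObservation(rec.id, str(rec.seq), STATUS_OK))
    for clone_id, status in statuses.items():
        if clone_id not in seen:
            if status != STATUS_FAILED:
                raise CrisprEError(
                    f"{clone_id}: listed '{status}' in the status table but "
                    "missing from the FASTA"
                )
            clones.append(CloneObservation(clone_id, None, STATUS_FAILED))
    if not clones:
        raise CrisprEError(f"{path}: no clones")
    return clones


def ensure_outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out
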