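"""Built-in clone-set fixtures on synthetic reference sequences.

Five worked single-gene experiments from *Dictyostelium discoideum*
CRISPR/Cas9 clone genotyping are packaged here: grlB and grlC (method
demonstrations), KIF1A and fAR1 (non-essential genes with clear null
phenotypes) and Dync1li1 (an essential dynein light intermediate
chain, whose surviving clones carry exclusively in-frame alleles).
The clone compositions — net indel per clone, substitution counts,
sequencing failures and sibling-clone pairs — follow the published
tallies; the reference sequences themselves are synthetic (no
accessions exist for the original amplicons), generated
deterministically with an embedded guide + NGG PAM and a stop-free
ORF.  Where an individual indel's exact size or position was not
printed (fAR1, the combined Dync1li1 set), synthetic values consistent
with the published class tallies are used.

Each experiment is available both as ready clone sequences (built by
applying the edits to the reference) and as a pre-called variant
table, the lossless encoding of the printed per-clone edits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alleles import (
    CloneObservation,
    Edit,
    VARIANT_COLUMNS,
    apply_edits,
    normalize_edits,
)
from .target import ReferenceTarget, TargetSite, TargetError, find_target_site

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


def _random_guide(rng: np.random.Generator) -> str:
    """20-mer whose codon-aligned placement creates no in-frame stop."""
    while True:
        guide = "".join(rng.choice(list(_BASES), size=20))
        codons = [guide[i : i + 3] for i in range(0, 18, 3)]
        if any(c in _STOPS for c in codons):
            continue
        if guide[18:20] in {"TA", "TG"}:  # would form TAA/TGA with the PAM's A
            continue
        return guide


def make_synthetic_target(
    name: str, seed: int, window_halfwidth: int = 30
) -> tuple[ReferenceTarget, str, TargetSite]:
    """Deterministic synthetic amplicon: 12-nt flanks around an ORF of
    ATG + 5 codons + guide(20) + AGG PAM + 1-nt pad + 38 codons + TAA.

    The guide lands on a codon boundary, the ORF contains no premature
    stop, and the guide occurs exactly once (checked; the seed is
    advanced until the construction is unambiguous).
    """
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        guide = _random_guide(rng)
        flank5 = "".join(rng.choice(list(_BASES), size=12))
        flank3 = "".join(rng.choice(list(_BASES), size=12))
        pre = "".join(rng.choice(_SENSE_CODONS, size=5))
        pad = str(rng.choice(list(_BASES)))
        post = "".join(rng.choice(_SENSE_CODONS, size=38))
        orf = "ATG" + pre + guide + "AGG" + pad + post + "TAA"
        sequence = flank5 + orf + flank3
        ref = ReferenceTarget(
            name=name,
            sequence=sequence,
            orf_start=len(flank5),
            orf_end=len(flank5) + len(orf),
        )
        try:
            site = find_target_site(ref, guide, window_halfwidth=window_halfwidth)
        except TargetError:
            continue
        return ref, guide, site
    raise RuntimeError(f"could not construct a unique synthetic target for {name}")


@dataclass
class Experiment:
    """A packaged clone-set experiment ready for the calling pipeline."""

    name: str
    ref: ReferenceTarget
    guide: str
    site: TargetSite
    clones: list[CloneObservation]
    variants: pd.DataFrame


# recipe spec atoms: ("del", start_offset_from_cut, length),
# ("ins", offset, bases), ("sub", offset); None marks a failed clone.


def _build_edits(ref: ReferenceTarget, site: TargetSite, specs) -> list[Edit]:
    seq, cut = ref.sequence, site.cut_index
    edits = []
    for spec in specs:
        if spec[0] == "del":
            _, off, L = spec
            start = cut + off
            edits.append(Edit("deletion", start, seq[start : start + L], ""))
        elif spec[0] == "ins":
            _, off, bases = spec
            edits.append(Edit("insertion", cut + off, "", bases))
        elif spec[0] == "sub":
            _, off = spec
            pos = cut + off
            old = seq[pos]
            alt = _BASES[(_BASES.index(old) + 1) % 4]
            edits.append(Edit("substitution", pos, old, alt))
        else:  # pragma: no cover
            raise ValueError(f"unknown spec {spec!r}")
    return edits


def _build_experiment(name: str, seed: int, recipes) -> Experiment:
    ref, guide, site = make_synthetic_target(name, seed)
    clones: list[CloneObservation] = []
    rows: list[dict] = []
    for clone_id, specs in recipes:
        if specs is None:
            clones.append(CloneObservation(clone_id, None))
            rows.append(
                {
                    "clone_id": clone_id,
                    "kind": "failed",
                    "position": 0,
                    "ref_allele": "",
                    "alt_allele": "",
                }
            )
            continue
        edits = _build_edits(ref, site, specs)
        if edits:
            edits = normalize_edits(edits, ref.sequence)
            sequence = apply_edits(ref.sequence, edits)
        else:
            sequence = ref.sequence
        clones.append(CloneObservation(clone_id, sequence))
        if not edits:
            rows.append(
                {
                    "clone_id": clone_id,
                    "kind": "wt",
                    "position": 0,
                    "ref_allele": "",
                    "alt_allele": "",
                }
            )
        for e in edits:
            rows.append(
                {
                    "clone_id": clone_id,
                    "kind": e.kind,
                    "position": e.position,
                    "ref_allele": e.ref_allele,
                    "alt_allele": e.alt_allele,
                }
            )
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return Experiment(
        name=name, ref=ref, guide=guide, site=site, clones=clones, variants=variants
    )


def grlb() -> Experiment:
    """grlB, sgRNA1: 12 clones, 6 failed sequencing; edited nets
    +12, +4, -4, -22, +3 and +7 (the last with one substitution) —
    class fractions 2/2/2 over six events."""
    recipes = [
        ("grlB_B1", [("ins", 0, "GATCCAGTTGCA")]),  # +12, in-frame
        ("grlB_B2", [("ins", 0, "ACCA")]),  # +4, 3n+1
        ("grlB_B3", None),
        ("grlB_B4", [("del", -2, 4)]),  # -4, 3n+2
        ("grlB_B5", None),
        ("grlB_B6", None),
        ("grlB_B7", None),
        ("grlB_B8", None),
        ("grlB_B9", [("del", -11, 22)]),  # -22, 3n+2
        ("grlB_B10", [("ins", 0, "GAT")]),  # +3, in-frame
        ("grlB_B11", None),
        ("grlB_B12", [("ins", 0, "ACCGGTA"), ("sub", 4)]),  # +7 bp, 1 s
    ]
    return _build_experiment("grlB", 11, recipes)


def grlc() -> Experiment:
    """grlC, sgRNA1: 12 edited clones with two identical sibling pairs
    (C1/C2 and C6/C11) -> 10 independent events with nets
    -6, +3, -3, +2, -1, -1, -17, +4, +2, +2 (fractions 30/20/50)."""
    c1 = [("ins", 0, "AC"), ("sub", 3)]  # +2 bp, 1 s
    c6 = [("del", -4, 1)]  # -1 bp
    recipes = [
        ("grlC_C1", c1),
        ("grlC_C2", c1),  # sibling of C1
        ("grlC_C3", [("del", 0, 1)]),  # -1, 3n+2
        ("grlC_C4", [("del", -3, 6)]),  # -6, in-frame
        ("grlC_C5", [("ins", 0, "GTT"), ("sub", 4)]),  # +3 bp, 1 s
        ("grlC_C6", c6),
        ("grlC_C7", [("del", -8, 17)]),  # -17, 3n+1
        ("grlC_C8", [("ins", 0, "TTCG"), ("sub", 2), ("sub", 3), ("sub", 4)]),
        ("grlC_C9", [("ins", 0, "GT"), ("sub", 5), ("sub", 6)]),  # +2 bp, 2 s
        ("grlC_C10", [("del", 2, 3)]),  # -3, in-frame
        ("grlC_C11", c6),  # sibling of C6
        ("grlC_C12", [("ins", 0, "CA")]),  # +2, 3n+2
    ]
    return _build_experiment("grlC", 22, recipes)


def kif1a() -> Experiment:
    """KIF1A: 19 sequenced clones — 2 WT, seven 5-bp deletions at
    different positions, one 6-bp deletion, five 3-bp deletions, one
    5-bp insertion with a 1-bp substitution, three point-mutation-only
    clones.  Editing 17/19, inactivation (frameshift) 8/19."""
    recipes = [
        ("KIF1A_WT1", []),
        ("KIF1A_WT2", []),
        ("KIF1A_N1", [("del", -15, 5)]),
        ("KIF1A_N2", [("del", -10, 5)]),
        ("KIF1A_N3", [("del", -5, 5)]),
        ("KIF1A_N4", [("del", 0, 5)]),
        ("KIF1A_N5", [("del", 3, 5)]),
        ("KIF1A_N6", [("del", 6, 5)]),
        ("KIF1A_N7", [("del", 9, 5)]),
        ("KIF1A_N8", [("del", -3, 6)]),
        ("KIF1A_N9", [("del", -9, 3)]),
        ("KIF1A_N10", [("del", -6, 3)]),
        ("KIF1A_N11", [("del", -2, 3)]),
        ("KIF1A_N12", [("del", 1, 3)]),
        ("KIF1A_N13", [("del", 4, 3)]),
        ("KIF1A_N14", [("ins", 0, "GTACC"), ("sub", 3)]),  # +5 bp, 1 s
        ("KIF1A_N15", [("sub", -1)]),
        ("KIF1A_N16", [("sub", 1)]),
        ("KIF1A_N17", [("sub", 2)]),
    ]
    return _build_experiment("KIF1A", 33, recipes)


def far1() -> Experiment:
    """fAR1: five sequenced clones, one in-frame and four frameshift
    (editing 100%, inactivation 80%).  Individual sizes are synthetic;
    only the class tallies are published."""
    recipes = [
        ("fAR1_N1", [("del", 0, 3)]),  # in-frame
        ("fAR1_N2", [("del", 0, 1)]),
        ("fAR1_N3", [("del", -1, 2)]),
        ("fAR1_N4", [("ins", 0, "T")]),
        ("fAR1_N5", [("del", -2, 5)]),
    ]
    return _build_experiment("fAR1", 44, recipes)


def dync1li1_sgrna1() -> Experiment:
    """Dync1li1, sgRNA1: eight clones — four WT, two point-mutation
    alleles, one +3 insertion, one 21-bp deletion.  Editing 50%, all
    edits in-frame (k = 4)."""
    recipes = [
        ("Dync1li1_WT1", []),
        ("Dync1li1_WT2", []),
        ("Dync1li1_WT3", []),
        ("Dync1li1_WT4", []),
        ("Dync1li1_N1", [("sub", -1)]),
        ("Dync1li1_N2", [("sub", 1)]),
        ("Dync1li1_N3", [("ins", 0, "GCT")]),
        ("Dync1li1_N4", [("del", -10, 21)]),
    ]
    return _build_experiment("Dync1li1_sg1", 55, recipes)


def dync1li1_sgrna2() -> Experiment:
    """Dync1li1, sgRNA2: ten clones — three WT, two point-mutation
    alleles, one -6, one -9 and three -3 deletions.  Editing 70%, all
    edits in-frame (k = 7)."""
    recipes = [
        ("Dync1li1_WT1", []),
        ("Dync1li1_WT2", []),
        ("Dync1li1_WT3", []),
        ("Dync1li1_N1", [("sub", -2)]),
        ("Dync1li1_N2", [("sub", 2)]),
        ("Dync1li1_N3", [("del", -3, 6)]),
        ("Dync1li1_N4", [("del", -4, 9)]),
        ("Dync1li1_N5", [("del", -1, 3)]),
        ("Dync1li1_N6", [("del", 1, 3)]),
        ("Dync1li1_N7", [("del", 4, 3)]),
    ]
    return _build_experiment("Dync1li1_sg2", 66, recipes)


def dync1li1_combined() -> Experiment:
    """Dync1li1, sgRNA1 + sgRNA2 co-transformed: 21 clones, 3 WT and 18
    edited — every single one in-frame (k = 18, x = 0: the essential-
    gene signature).  Individual edits are synthetic, consistent with
    the published all-in-frame composition."""
    recipes = [
        ("Dync1li1_WT1", []),
        ("Dync1li1_WT2", []),
        ("Dync1li1_WT3", []),
        ("Dync1li1_N1", [("sub", -5)]),
        ("Dync1li1_N2", [("sub", -1)]),
        ("Dync1li1_N3", [("sub", 1)]),
        ("Dync1li1_N4", [("sub", 2)]),
        ("Dync1li1_N5", [("ins", 0, "GCT")]),
        ("Dync1li1_N6", [("ins", 0, "AGT")]),
        ("Dync1li1_N7", [("ins", 0, "GCTAGT")]),
        ("Dync1li1_N8", [("del", -9, 3)]),
        ("Dync1li1_N9", [("del", -6, 3)]),
        ("Dync1li1_N10", [("del", -3, 3)]),
        ("Dync1li1_N11", [("del", 0, 3)]),
        ("Dync1li1_N12", [("del", 3, 3)]),
        ("Dync1li1_N13", [("del", 6, 3)]),
        ("Dync1li1_N14", [("del", -2, 6)]),
        ("Dync1li1_N15", [("del", -8, 6)]),
        ("Dync1li1_N16", [("del", -5, 9)]),
        ("Dync1li1_N17", [("del", -6, 12)]),
        ("Dync1li1_N18", [("del", -10, 21)]),
    ]
    return _build_experiment("Dync1li1_combined", 77, recipes)


ALL_EXPERIMENTS = {
    "grlB": grlb,
    "grlC": grlc,
    "KIF1A": kif1a,
    "fAR1": far1,
    "Dync1li1_sg1": dync1li1_sgrna1,
    "Dync1li1_sg2": dync1li1_sgrna2,
    "Dync1li1_combined": dync1li1_combined,
}


def write_experiment(exp: Experiment, outdir) -> dict:
    """Write an experiment's reference FASTA, clone FASTA, status TSV
    and variant table to ``outdir``; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "clones": outdir / "clones.fasta",
        "status": outdir / "status.tsv",
        "variants": outdir / "variants.tsv",
    }
    with open(paths["reference"], "w") as fh:
        fh.write(f">{exp.ref.name}\n{exp.ref.sequence}\n")
    with open(paths["clones"], "w") as fh:
        for clone in exp.clones:
            if clone.sequence is not None:
                fh.write(f">{clone.clone_id}\n{clone.sequence}\n")
    with open(paths["status"], "w") as fh:
        fh.write("clone_id\tstatus\n")
        for clone in exp.clones:
            fh.write(f"{clone.clone_id}\t{clone.status}\n")
    exp.variants.to_csv(paths["variants"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
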