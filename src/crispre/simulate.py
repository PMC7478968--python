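"""Synthetic clonal NHEJ outcome generator.

Emulates the data-generating process the essentiality test assumes: a
transformed cell population in which each picked clone either failed
sequencing, is an unedited (WT) survivor, is a sibling of an earlier
editing event, or carries one NHEJ repair outcome drawn from a
configurable mixture of deletions, insertions and substitution-only
(point-mutation) alleles centered at the Cas9 cut site.  Viability
selection against frameshift alleles is modeled at the clone level: a
frameshift outcome survives with probability ``frameshift_survival``
(0 for an essential gene, 1 for a neutral one); rejected outcomes are
resampled as surviving lineages so the number of picked clones stays
fixed, matching a picked-N-clones experimental design.

Indel sizes default to capped geometric distributions spanning the
range observed in real clone sets (deletions up to ~30 nt, insertions
up to ~12 nt); explicit size weights can be supplied instead, e.g. a
uniform spectrum over {1..6} whose frameshift mass is exactly 2/3.
Everything is reproducible from the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alleles import (
    AlleleCall,
    CloneObservation,
    Edit,
    EditingSummary,
    FRAME_WT,
    STATUS_FAILED,
    STATUS_OK,
    apply_edits,
    call_experiment,
    classify_allele,
    collapse_identical_clones,
    net_frame_shift,
)
from .stats import DEFAULT_F_EXP, EssentialityResult, essentiality_score
from .target import CrisprEError, ReferenceTarget, TargetSite

BASES = np.array(list("ACGT"))

TRUTH_COLUMNS = [
    "clone_id",
    "status",
    "edited",
    "kind",
    "net_indel",
    "frame_class",
    "duplicate_of",
]


@dataclass
class SimulationConfig:
    """Study-condition knobs for one simulated experiment.

    Defaults mirror a typical single-gene clone set: a dozen picked
    clones, editing efficiency ~70%, occasional sibling clones from one
    editing event and occasional sequencing failures.
    """

    n_clones: int = 12
    p_edit: float = 0.7
    p_fail: float = 0.1
    p_duplicate: float = 0.15
    deletion_weight: float = 0.55
    insertion_weight: float = 0.30
    substitution_weight: float = 0.15
    deletion_geom_p: float = 0.20
    deletion_cap: int = 30
    insertion_geom_p: float = 0.30
    insertion_cap: int = 12
    #: explicit {size: weight} maps overriding the geometric defaults
    deletion_sizes: dict[int, float] | None = None
    insertion_sizes: dict[int, float] | None = None
    frameshift_survival: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_edit", "p_fail", "p_duplicate", "frameshift_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CrisprEError(f"{name} must lie in [0, 1], got {v}")
        w = self.deletion_weight + self.insertion_weight + self.substitution_weight
        if w <= 0 or min(
            self.deletion_weight, self.insertion_weight, self.substitution_weight
        ) < 0:
            raise CrisprEError("mixture weights must be non-negative, sum > 0")
        self.deletion_weight /= w
        self.insertion_weight /= w
        self.substitution_weight /= w
        if self.n_clones <= 0:
            raise CrisprEError("n_clones must be positive")
        for sizes in (self.deletion_sizes, self.insertion_sizes):
            if sizes is not None and (not sizes or min(sizes) < 1):
                raise CrisprEError("explicit indel sizes must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("deletion_sizes", "insertion_sizes"):
            if d[key] is not None:
                d[key] = {str(k): v for k, v in d[key].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("deletion_sizes", "insertion_sizes"):
            if d.get(key) is not None:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass
class SimulationResult:
    clones: list[CloneObservation]
    truth: pd.DataFrame
    config: SimulationConfig


def _size_distribution(
    geom_p: float, cap: int, explicit: dict[int, float] | None
) -> tuple[np.ndarray, np.ndarray]:
    if explicit is not None:
        sizes = np.array(sorted(explicit), dtype=int)
        probs = np.array([explicit[int(s)] for s in sizes], dtype=float)
    else:
        sizes = np.arange(1, cap + 1)
        probs = (1.0 - geom_p) ** (sizes - 1) * geom_p
    return sizes, probs / probs.sum()


def _spectrum_tables(cfg: SimulationConfig):
    dsz = _size_distribution(cfg.deletion_geom_p, cfg.deletion_cap, cfg.deletion_sizes)
    isz = _size_distribution(
        cfg.insertion_geom_p, cfg.insertion_cap, cfg.insertion_sizes
    )
    return dsz, isz


def expected_frameshift_fraction(cfg: SimulationConfig) -> float:
    """Frameshift probability of one edit drawn from the configured
    mixture, before any selection (substitution-only alleles are
    in-frame)."""
    (dsizes, dprobs), (isizes, iprobs) = _spectrum_tables(cfg)
    p_del = float(dprobs[dsizes % 3 != 0].sum())
    p_ins = float(iprobs[isizes % 3 != 0].sum())
    return cfg.deletion_weight * p_del + cfg.insertion_weight * p_ins


def expected_E(cfg: SimulationConfig, f_exp: float = DEFAULT_F_EXP) -> float:
    """Analytic E score implied by the configured spectrum and
    frameshift survival s: surviving edited clones carry frameshift
    alleles with frequency p_fs*s / (p_fs*s + (1 - p_fs))."""
    p_fs = expected_frameshift_fraction(cfg)
    s = cfg.frameshift_survival
    denom = p_fs * s + (1.0 - p_fs)
    if denom == 0.0:
        return 0.0
    return (p_fs * s / denom) / f_exp


def _draw_edits(
    rng: np.random.Generator,
    ref: ReferenceTarget,
    site: TargetSite,
    cfg: SimulationConfig,
) -> list[Edit]:
    """One NHEJ repair outcome centered at the cut site."""
    seq = ref.sequence
    cut = site.cut_index
    (dsizes, dprobs), (isizes, iprobs) = _spectrum_tables(cfg)
    kind = rng.choice(
        ["deletion", "insertion", "substitution"],
        p=[cfg.deletion_weight, cfg.insertion_weight, cfg.substitution_weight],
    )
    if kind == "deletion":
        L = int(rng.choice(dsizes, p=dprobs))
        L = min(L, len(seq) - 2)
        jitter = int(rng.integers(-2, 3))
        start = cut - (L + 1) // 2 + jitter
        start = max(1, min(start, len(seq) - L - 1))
        return [Edit("deletion", start, seq[start : start + L], "")]
    if kind == "insertion":
        L = int(rng.choice(isizes, p=iprobs))
        bases = "".join(rng.choice(BASES, size=L))
        return [Edit("insertion", cut, "", bases)]
    # substitution-only allele: 1-3 substituted bases adjacent to the cut
    m = int(rng.integers(1, 4))
    offsets = rng.choice(np.arange(-2, 3), size=m, replace=False)
    edits = []
    for off in sorted(int(o) for o in offsets):
        pos = max(1, min(cut + off, len(seq) - 2))
        old = seq[pos]
        alt = rng.choice(BASES[BASES != old])
        edits.append(Edit("substitution", pos, old, str(alt)))
    # clipping may collide offsets at the boundary; drop duplicates
    seen: set[int] = set()
    uniq = [e for e in edits if not (e.position in seen or seen.add(e.position))]
    return uniq


def simulate_experiment(
    ref: ReferenceTarget, site: TargetSite, cfg: SimulationConfig
) -> SimulationResult:
    """Generate one clone set plus its truth table.

    Per clone: decide sequencing failure, sibling duplication, then
    editing; frameshift outcomes survive with probability
    ``frameshift_survival``, otherwise the clone is resampled as a
    surviving lineage.  Byte-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.frameshift_survival
    clones: list[CloneObservation] = []
    rows: list[dict] = []
    survivors: list[tuple[str, tuple[Edit, ...]]] = []  # edited, surviving events

    for i in range(cfg.n_clones):
        clone_id = f"sim_{i + 1:04d}"
        if rng.random() < cfg.p_fail:
            clones.append(CloneObservation(clone_id, None, STATUS_FAILED))
            rows.append(
                {
                    "clone_id": clone_id,
                    "status": STATUS_FAILED,
                    "edited": False,
                    "kind": "",
                    "net_indel": 0,
                    "frame_class": "",
                    "duplicate_of": "",
                }
            )
            continue

        edits: tuple[Edit, ...] = ()
        duplicate_of = ""
        for _attempt in range(10_000):
            if survivors and rng.random() < cfg.p_duplicate:
                parent_id, parent_edits = survivors[
                    int(rng.integers(len(survivors)))
                ]
                edits, duplicate_of = parent_edits, parent_id
                break  # sibling of an already-surviving event
            duplicate_of = ""
            if rng.random() >= cfg.p_edit:
                edits = ()
                break  # unedited survivor
            candidate = tuple(_draw_edits(rng, ref, site, cfg))
            fs = net_frame_shift(candidate) % 3 != 0
            if not fs or rng.random() < s:
                edits = candidate
                break
        else:  # pragma: no cover - only reachable with pathological configs
            edits = ()

        sequence = apply_edits(ref.sequence, edits) if edits else ref.sequence
        clones.append(CloneObservation(clone_id, sequence, STATUS_OK))
        if edits and not duplicate_of:
            survivors.append((clone_id, edits))
        net = net_frame_shift(edits)
        rows.append(
            {
                "clone_id": clone_id,
                "status": STATUS_OK,
                "edited": bool(edits),
                "kind": edits[0].kind if edits else "",
                "net_indel": net,
                "frame_class": classify_allele(edits) if edits else FRAME_WT,
                "duplicate_of": duplicate_of,
            }
        )

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return SimulationResult(clones=clones, truth=truth, config=cfg)


def write_simulation(result: SimulationResult, outdir) -> None:
    """Write clones.fasta (failed clones omitted), truth.tsv and the
    echoed config (with seed) as JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "clones.fasta", "w") as fh:
        for clone in result.clones:
            if clone.sequence is not None:
                fh.write(f">{clone.clone_id}\n{clone.sequence}\n")
    with open(outdir / "status.tsv", "w") as fh:
        fh.write("clone_id\tstatus\n")
        for clone in result.clones:
            fh.write(f"{clone.clone_id}\t{clone.status}\n")
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(result.config.to_dict(), fh, indent=2)
        fh.write("\n")


@dataclass
class RecoveryReport:
    """Estimated vs analytic E for one simulated experiment."""

    k: int
    x: int
    result: EssentialityResult | None
    E_true: float

    @property
    def E_hat(self) -> float | None:
        return self.result.E if self.result else None

    @property
    def ci_covers_truth(self) -> bool:
        if self.result is None:
            return False
        lo, hi = self.result.E_ci
        return lo <= self.E_true <= hi


def recover_parameters(
    ref: ReferenceTarget,
    site: TargetSite,
    cfg: SimulationConfig,
    f_exp: float = DEFAULT_F_EXP,
    confidence: float = 0.95,
    collapse: bool = True,
) -> RecoveryReport:
    """Simulate, analyze the FASTA with the full calling pipeline, and
    compare the estimated E against the analytic expectation.

    With ``collapse=False`` every edited clone counts as one event;
    appropriate when ``p_duplicate = 0``, where signature collapsing
    would wrongly merge coincidentally identical independent outcomes.
    """
    sim = simulate_experiment(ref, site, cfg)
    calls = call_experiment(ref, site, sim.clones)
    events, summary = collapse_identical_clones(calls)
    if collapse:
        k, x = summary.n_events, summary.n_frameshift_events
    else:
        k, x = summary.n_edited, summary.n_frameshift_clones
    result = (
        essentiality_score(k, x, f_exp=f_exp, confidence=confidence) if k else None
    )
    return RecoveryReport(k=k, x=x, result=result, E_true=expected_E(cfg, f_exp))
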