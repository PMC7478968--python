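"""Essentiality statistics from clone-editing tallies.

The test logic: error-prone NHEJ repair of a Cas9 cut produces net
indel lengths whose residues mod 3 are, under the default assumption,
uniform over {0, 1, 2} — so a fraction ``f_exp = 2/3`` of independent
editing events should be frameshifts.  If the targeted gene is
essential, frameshift alleles are purged by selection during clonal
growth and only in-frame (3n) alleles survive.  The probability of
observing k independent edited events that are all in-frame under the
neutral null is ``(1 - f_exp)^k = (1/3)^k``, and more generally the
one-sided evidence for a frameshift deficit is the exact binomial tail
``P(X <= x)`` with ``X ~ Binom(k, f_exp)``.

The essentiality score is ``E = f_obs / f_exp`` where ``f_obs = x/k``
is the observed frameshift frequency among edited events: E = 0 flags
an essential gene, E = 1 a neutral knockout, 0 < E < 1 a deleterious
one and E > 1 a knockout that benefits growth.  Confidence intervals
are exact (Clopper–Pearson) on ``x/k``, scaled by ``1/f_exp``; clone
counts per gene are small (order 10–20), so no asymptotic intervals
are used.

``f_exp`` is configurable because real sgRNA-specific indel spectra can
be biased away from frame-uniformity; it may be estimated from a
non-essential control gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint

from .alleles import EditingSummary
from .target import CrisprEError

DEFAULT_F_EXP = 2.0 / 3.0

VERDICT_BENEFICIAL = "beneficial_to_lose"
VERDICT_NEUTRAL = "neutral"
VERDICT_DELETERIOUS = "deleterious"
VERDICT_ESSENTIAL = "essential"


class Efficiency(NamedTuple):
    """A fraction reported with its numerator and denominator."""

    numerator: int
    denominator: int
    value: float

    def __str__(self) -> str:
        return f"{100 * self.value:.1f}% ({self.numerator} out of {self.denominator})"


@dataclass(frozen=True)
class EssentialityResult:
    k: int
    x_frameshift: int
    f_exp: float
    f_obs: float
    p_all_in_frame: float
    p_deficit: float
    E: float
    E_ci: tuple[float, float]
    confidence: float
    verdict: str

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "x_frameshift": self.x_frameshift,
            "f_exp": self.f_exp,
            "f_obs": self.f_obs,
            "p_all_in_frame": self.p_all_in_frame,
            "p_deficit": self.p_deficit,
            "E": self.E,
            "E_ci": list(self.E_ci),
            "confidence": self.confidence,
            "verdict": self.verdict,
        }


def _check_f_exp(f_exp: float) -> None:
    if not 0.0 < f_exp < 1.0:
        raise CrisprEError(f"f_exp must lie in (0, 1), got {f_exp}")


def editing_efficiency(summary: EditingSummary) -> Efficiency:
    """Fraction of successfully sequenced clones carrying any edit at
    the target (on-target cutting/editing efficiency)."""
    if summary.n_sequenced == 0:
        raise CrisprEError("no data: zero successfully sequenced clones")
    return Efficiency(
        summary.n_edited, summary.n_sequenced, summary.n_edited / summary.n_sequenced
    )


def inactivation_efficiency(summary: EditingSummary) -> Efficiency:
    """Fraction of sequenced clones carrying a frameshift allele (the
    expected loss-of-function rate)."""
    if summary.n_sequenced == 0:
        raise CrisprEError("no data: zero successfully sequenced clones")
    x = summary.n_frameshift_clones
    return Efficiency(x, summary.n_sequenced, x / summary.n_sequenced)


def class_fractions(summary: EditingSummary) -> tuple[float, float, float]:
    """(in-frame, 3n+1, 3n+2) fractions over independent edited events."""
    k = summary.n_events
    if k == 0:
        raise CrisprEError("no editing observed: zero independent events")
    c = summary.event_class_counts
    return (
        c.get("in_frame", 0) / k,
        c.get("frameshift_plus1", 0) / k,
        c.get("frameshift_plus2", 0) / k,
    )


def all_in_frame_pvalue(k: int, f_exp: float = DEFAULT_F_EXP) -> float:
    """Null probability that all k independent edited events are
    in-frame: ``(1 - f_exp)^k`` (``(1/3)^k`` by default)."""
    if k < 0:
        raise CrisprEError(f"invalid count: k must be >= 0, got {k}")
    _check_f_exp(f_exp)
    return (1.0 - f_exp) ** k

def frameshift_deficit_test(
    k: int,
    x: int,
    f_exp: float = DEFAULT_F_EXP,
    alternative: str = "less",
) -> float:
    """Exact binomial tail probability of seeing <= x frameshift events
    among k under the neutral null (one-sided by default; pass
    ``alternative='two-sided'`` for the two-sided exact test)."""
    if not 0 <= x <= k:
        raise CrisprEError(f"invalid counts: require 0 <= x <= k, got x={x}, k={k}")
    _check_f_exp(f_exp)
    if k == 0:
        return 1.0
    return float(binomtest(x, k, f_exp, alternative=alternative).pvalue)


def essentiality_score(
    k: int,
    x: int,
    f_exp: float = DEFAULT_F_EXP,
    confidence: float = 0.95,
) -> EssentialityResult:
    """Essentiality score E = (x/k) / f_exp with an exact CI.

    ``k`` is the number of independent edited events and ``x`` the
    number of frameshift events among them.  The Clopper–Pearson
    interval on x/k is scaled by 1/f_exp.
    """
    if k <= 0:
        raise CrisprEError("no edited events; E undefined (k must be > 0)")
    if not 0 <= x <= k:
        raise CrisprEError(f"invalid counts: require 0 <= x <= k, got x={x}, k={k}")
    _check_f_exp(f_exp)
    if not 0.0 < confidence < 1.0:
        raise CrisprEError("confidence must lie in (0, 1)")
    f_obs = x / k
    E = f_obs / f_exp
    lo, hi = proportion_confint(x, k, alpha=1.0 - confidence, method="beta")
    ci = (float(lo) / f_exp, float(hi) / f_exp)
    if x == 0:
        verdict = VERDICT_ESSENTIAL
    elif math.isclose(E, 1.0, rel_tol=1e-12):
        verdict = VERDICT_NEUTRAL
    elif E > 1.0:
        verdict = VERDICT_BENEFICIAL
    else:
        verdict = VERDICT_DELETERIOUS
    return EssentialityResult(
        k=k,
        x_frameshift=x,
        f_exp=f_exp,
        f_obs=f_obs,
        p_all_in_frame=all_in_frame_pvalue(k, f_exp),
        p_deficit=frameshift_deficit_test(k, x, f_exp),
        E=E,
        E_ci=ci,
        confidence=confidence,
        verdict=verdict,
    )


def essentiality_from_summary(
    summary: EditingSummary,
    f_exp: float = DEFAULT_F_EXP,
    confidence: float = 0.95,
) -> EssentialityResult:
    """E score over independent edited events of an experiment summary."""
    return essentiality_score(
        summary.n_events, summary.n_frameshift_events, f_exp=f_exp,
        confidence=confidence,
    )


def min_edited_clones(alpha: float, f_exp: float = DEFAULT_F_EXP) -> int:
    """Smallest number k of independent edited events for which an
    all-in-frame outcome is significant at level alpha (planning aid)."""
    if not 0.0 < alpha < 1.0:
        raise CrisprEError(f"alpha must lie in (0, 1), got {alpha}")
    _check_f_exp(f_exp)
    k = math.ceil(math.log(alpha) / math.log(1.0 - f_exp))
    # guard against floating-point edge at the boundary
    while k > 1 and (1.0 - f_exp) ** (k - 1) <= alpha:
        k -= 1
    while (1.0 - f_exp) ** k > alpha:
        k += 1
    return max(k, 1)
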