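"""Credibility assessment of significant associations: power, FPRP, BFDP.

False positive report probability (FPRP) is the posterior probability of
no true association given a significant finding,

    FPRP = alpha (1 - pi) / (alpha (1 - pi) + power * pi),

where ``alpha`` is the observed p-value, ``power`` the probability of
detecting a design odds ratio at that significance level, and ``pi`` the
prior probability of a true association.  Findings with FPRP < 0.2 are
conventionally called noteworthy.

Bayesian false discovery probability (BFDP) replaces the power argument
with an approximate Bayes factor on the log-OR scale: with V the squared
standard error of the log odds ratio and W the prior variance of a
normal effect whose 97.5% point sits at a chosen odds ratio bound,

    ABF  = sqrt((V + W) / V) * exp(-theta^2 W / (2 V (V + W))),
    BFDP = ABF * PO / (1 + ABF * PO),      PO = (1 - pi) / pi.

The 0.8 noteworthiness cutoff encodes a false non-discovery being four
times as costly as a false discovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .assoc import Z975

__all__ = [
    "CredibilityResult",
    "log_or_se",
    "power_at_or",
    "fprp",
    "bfdp",
    "credibility_table",
]


@dataclass(frozen=True)
class CredibilityResult:
    """Power, FPRP and BFDP across a prior grid for one association."""

    label: str
    or_point: float
    ci_low: float
    ci_high: float
    p_obs: float
    power: float
    design_or: float
    se: float
    se_mode: str  # "counts" | "ci"
    priors: tuple
    fprp: tuple
    bfdp: tuple
    noteworthy_fprp: tuple  # fprp < 0.2 per prior
    noteworthy_bfdp: tuple  # bfdp < 0.8 per prior


def log_or_se(
    counts: Optional[Sequence[float]] = None,
    ci: Optional[Sequence[float]] = None,
) -> float:
    """Standard error of the log odds ratio.

    Either from 2x2 ``counts`` (a, b, c, d) via Woolf's formula, or from a
    printed ``(or, ci_low, ci_high)`` triple by inverting the Wald
    interval: SE = (ln high - ln low) / (2 z).
    """
    if (counts is None) == (ci is None):
        raise ValueError("provide exactly one of counts or ci")
    if counts is not None:
        a, b, c, d = (float(x) for x in counts)
        if min(a, b, c, d) <= 0.0:
            raise ValueError(
                "zero cell: use ci mode or a continuity-corrected table"
            )
        return math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    or_point, low, high = (float(x) for x in ci)
    if not 0.0 < low < high:
        raise ValueError("need 0 < ci_low < ci_high")
    return (math.log(high) - math.log(low)) / (2.0 * Z975)


def power_at_or(p_obs: float, se: float, design_or: float) -> float:
    """Power to detect ``design_or`` at significance level ``p_obs``.

    With z_c the two-sided critical value at level ``p_obs`` and
    delta = |ln design_or| / se, power = 1 - Phi(z_c - delta) +
    Phi(-z_c - delta).
    """
    if not 0.0 < p_obs < 1.0:
        raise ValueError("p_obs must lie in (0, 1)")
    if se <= 0.0 or design_or <= 0.0:
        raise ValueError("se and design_or must be positive")
    z_crit = stats.norm.isf(p_obs / 2.0)
    delta = abs(math.log(design_or)) / se
    return float(stats.norm.sf(z_crit - delta) + stats.norm.cdf(-z_crit - delta))


def fprp(p_obs: float, power: float, prior: float) -> float:
    """False positive report probability for one observed association."""
    if not 0.0 < p_obs < 1.0 or not 0.0 < prior < 1.0:
        raise ValueError("p_obs and prior must lie in (0, 1)")
    if power < 0.0 or power > 1.0:
        raise ValueError("power must lie in [0, 1]")
    if power == 0.0:
        return 1.0  # continuity limit: no detectable effect
    numerator = p_obs * (1.0 - prior)
    return numerator / (numerator + power * prior)


def bfdp(theta_hat: float, se: float, prior: float, w_or: float = 1.5) -> float:
    """Bayesian false discovery probability for a log odds ratio estimate.

    ``w_or`` anchors the 97.5% point of the normal prior on the effect
    size; protective effects may pass w_or < 1, only |ln w_or| matters.
    """
    if se <= 0.0:
        raise ValueError("se must be positive")
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must lie in (0, 1)")
    if w_or <= 0.0 or w_or == 1.0:
        raise ValueError("w_or must be a positive odds ratio different from 1")
    v = se * se
    w = (abs(math.log(w_or)) / Z975) ** 2
    log_abf = 0.5 * math.log((v + w) / v) - theta_hat**2 * w / (2.0 * v * (v + w))
    abf = math.exp(log_abf)
    prior_odds = (1.0 - prior) / prior
    return abf * prior_odds / (1.0 + abf * prior_odds)


def credibility_table(
    rows: Sequence,
    priors: Sequence[float] = (0.25, 0.1, 0.01),
    design_or_risk: float = 1.5,
    design_or_protective: float = 0.67,
    w_or: float = 1.5,
    alpha: float = 0.05,
    se_mode: str = "auto",
    include_nonsignificant: bool = False,
    fprp_threshold: float = 0.2,
    bfdp_threshold: float = 0.8,
) -> list:
    """Evaluate power, FPRP and BFDP for a list of association rows.

    Each row needs ``label``/``or_point``/``ci_low``/``ci_high``/``p_value``
    attributes and optionally 2x2 ``counts``; both
    :class:`~endoassoc.assoc.AssocResult` (using ``contrast`` as label) and
    :class:`~endoassoc.fixtures.SignificantRow` satisfy this.  The design
    odds ratio is picked per row: ``design_or_risk`` when the observed OR
    exceeds 1, ``design_or_protective`` otherwise.  ``se_mode`` chooses the
    SE source: ``"counts"`` when a 2x2 is available, ``"ci"`` from the
    interval, or ``"auto"`` (counts when available).  Rows that are not
    significant at ``alpha`` are rejected unless
    ``include_nonsignificant`` is set.
    """
    if se_mode not in ("auto", "counts", "ci"):
        raise ValueError("se_mode must be auto, counts or ci")
    results = []
    for row in rows:
        label = getattr(row, "label", None) or getattr(row, "contrast", "")
        p_obs = getattr(row, "p_value")
        or_point = getattr(row, "or_point")
        if p_obs is None or or_point is None:
            raise ValueError(f"{label}: undefined association cannot be assessed")
        if p_obs >= alpha and not include_nonsignificant:
            raise ValueError(
                f"{label}: p = {p_obs} is not significant at alpha = {alpha}; "
                "pass include_nonsignificant=True to force inclusion"
            )
        counts = getattr(row, "counts", None)
        use_counts = counts is not None and se_mode in ("auto", "counts")
        if se_mode == "counts" and counts is None:
            raise ValueError(f"{label}: counts requested but unavailable")
        se = log_or_se(counts=counts) if use_counts else log_or_se(
            ci=(or_point, row.ci_low, row.ci_high)
        )
        design = design_or_risk if or_point > 1.0 else design_or_protective
        power = power_at_or(p_obs, se, design)
        theta = math.log(or_point)
        fprp_vals = tuple(fprp(p_obs, power, pi) for pi in priors)
        bfdp_vals = tuple(bfdp(theta, se, pi, w_or=w_or) for pi in priors)
        results.append(
            CredibilityResult(
                label=label,
                or_point=or_point,
                ci_low=row.ci_low,
                ci_high=row.ci_high,
                p_obs=p_obs,
                power=power,
                design_or=design,
                se=se,
                se_mode="counts" if use_counts else "ci",
                priors=tuple(priors),
                fprp=fprp_vals,
                bfdp=bfdp_vals,
                noteworthy_fprp=tuple(v < fprp_threshold for v in fprp_vals),
                noteworthy_bfdp=tuple(v < bfdp_threshold for v in bfdp_vals),
            )
        )
    return results
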