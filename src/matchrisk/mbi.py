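"""Magnitude-based inference (MBI) for hazard-ratio effects.

An effect's uncertainty is modelled as Normal on the log-HR scale, with the
standard error back-calculated from the confidence interval:
``se = (ln ci_high − ln ci_low) / (2 z)``.  The probabilities that the true
hazard ratio lies below the benefit threshold (default HR 0.90), above the
harm threshold (default HR 1.11) or between them are reported as
percentages.  An effect is *unclear* when both the beneficial and the
harmful probabilities exceed 5%; otherwise it takes the category with the
largest probability, qualified by the probabilistic term of that
probability:

    <0.5% most unlikely · 0.5–5% very unlikely · 5–25% unlikely ·
    25–75% possibly · 75–95% likely · 95–99.5% very likely ·
    >99.5% most likely

Unrounded percentages drive both the >5% rule and the term lookup; rounding
(half away from zero) is for display only.  The harm threshold ships as
1.11; an alternative 1.10 convention circulates for the same scale, and the
threshold is a parameter everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

BENEFIT_HR = 0.90
HARM_HR = 1.11

# (upper bound of percentage band, qualifier)
_SCALE = [
    (0.5, "most unlikely"),
    (5.0, "very unlikely"),
    (25.0, "unlikely"),
    (75.0, "possibly"),
    (95.0, "likely"),
    (99.5, "very likely"),
    (float("inf"), "most likely"),
]

CATEGORIES = ("beneficial", "trivial", "harmful")


@dataclass
class MBIResult:
    """Beneficial/trivial/harmful likelihoods and label for one effect."""

    p_beneficial: float  # percent, unrounded
    p_trivial: float
    p_harmful: float
    label: str
    benefit_hr: float = BENEFIT_HR
    harm_hr: float = HARM_HR
    conf: float = 0.90

    @property
    def rounded(self) -> tuple[int, int, int]:
        return tuple(_round_half_away(p) for p in (self.p_beneficial, self.p_trivial, self.p_harmful))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def _probs_from_normal(mu: float, se: float, benefit: float, harm: float):
    """Region probabilities (percent) for log-HR ~ Normal(mu, se^2)."""
    lb, lh = math.log(benefit), math.log(harm)
    if se < 0:
        raise ValueError("negative standard error")
    if se == 0.0:
        p_ben = 100.0 if mu < lb else 0.0
        p_harm = 100.0 if mu > lh else 0.0
    else:
        p_ben = float(norm.cdf((lb - mu) / se)) * 100.0
        p_harm = float(norm.sf((lh - mu) / se)) * 100.0
    p_triv = 100.0 - p_ben - p_harm
    return p_ben, p_triv, p_harm


def mbi_probs(
    hr: float,
    ci_low: float,
    ci_high: float,
    conf: float = 0.90,
    benefit: float = BENEFIT_HR,
    harm: float = HARM_HR,
) -> tuple[float, float, float]:
    """(p_beneficial, p_trivial, p_harmful) percentages from an HR and CI.

    The CI must bracket the point estimate and the confidence level of the
    interval must be supplied (0.90 for the conventional 90% CI).
    """
    if not (0 < ci_low <= hr <= ci_high):
        raise ValueError("mbi_probs: require 0 < ci_low <= hr <= ci_high")
    if not (0 < benefit < harm):
        raise ValueError("mbi_probs: require 0 < benefit < harm thresholds")
    z = norm.ppf(0.5 + conf / 2.0)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    return _probs_from_normal(math.log(hr), se, benefit, harm)


def mbi_label(probs: tuple[float, float, float]) -> str:
    """Qualitative label from unrounded (beneficial, trivial, harmful) %.

    Unclear when both directional probabilities exceed 5%; otherwise the
    largest category, prefixed with its probabilistic qualifier.
    """
    p_ben, p_triv, p_harm = probs
    if p_ben > 5.0 and p_harm > 5.0:
        return "unclear"
    best = max(range(3), key=lambda i: probs[i])
    p = probs[best]
    for hi, term in _SCALE:
        if p <= hi:
            return f"{term} {CATEGORIES[best]}"
    raise AssertionError("unreachable")


def mbi_from_ci(
    hr: float,
    ci_low: float,
    ci_high: float,
    conf: float = 0.90,
    benefit: float = BENEFIT_HR,
    harm: float = HARM_HR,
) -> MBIResult:
    probs = mbi_probs(hr, ci_low, ci_high, conf, benefit, harm)
    return MBIResult(*probs, label=mbi_label(probs), benefit_hr=benefit, harm_hr=harm, conf=conf)


def mbi_from_fit(
    model,
    term: str,
    benefit: float = BENEFIT_HR,
    harm: float = HARM_HR,
) -> MBIResult:
    """MBI for a fitted-model term, using (beta, se) directly.

    Identical formulas to :func:`mbi_probs` without round-tripping through
    a printed confidence interval.
    """
    if term not in model.names:
        raise KeyError(f"term {term!r} not in model: {model.names}")
    i = model.names.index(term)
    probs = _probs_from_normal(float(model.beta[i]), float(model.se_beta[i]), benefit, harm)
    return MBIResult(*probs, label=mbi_label(probs), benefit_hr=benefit, harm_hr=harm)


def mbi_table(
    effects: pd.DataFrame,
    conf: float = 0.90,
    benefit: float = BENEFIT_HR,
    harm: float = HARM_HR,
) -> pd.DataFrame:
    """Batch MBI over an effects table with columns term, hr, ci_low, ci_high.

    Returns the input plus p_beneficial/p_trivial/p_harmful (rounded display
    integers), their unrounded values, and the inference label.
    """
    rows = []
    for _, r in effects.iterrows():
        res = mbi_from_ci(r["hr"], r["ci_low"], r["ci_high"], conf, benefit, harm)
        b, t, h = res.rounded
        rows.append(
            {
                "term": r["term"],
                "hr": r["hr"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "p_beneficial": b,
                "p_trivial": t,
                "p_harmful": h,
                "p_beneficial_raw": res.p_beneficial,
                "p_trivial_raw": res.p_trivial,
                "p_harmful_raw": res.p_harmful,
                "inference": res.label,
            }
        )
    return pd.DataFrame(rows)
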