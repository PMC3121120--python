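"""Rule-based confirmation of predicted links against expression experiments.

Each experiment supplies a ternary call (expressed / not expressed / absent)
for the link's TF and TG.  The rule table classifies every experiment as
Confirming, Contradictory, Neutral, or ignored:

====== =========== =========== ==============
sign   TF call     TG call     outcome
====== =========== =========== ==============
  \\+    expressed   expressed   Confirming
  \\+    expressed   not expr.   Contradictory
  \\+    not expr.   expressed   Neutral
  \\+    not expr.   not expr.   ignored
  \\-    expressed   expressed   Contradictory
  \\-    expressed   not expr.   Confirming
  \\-    not expr.   expressed   Confirming
  \\-    not expr.   not expr.   Contradictory
====== =========== =========== ==============

An experiment with either call absent is always ignored — nothing can be
inferred without both calls.  Per link the Confirming count ``c`` is compared
(i) against a weighted sum of the Contradictory and Neutral counts (the
"verified" test, default weights 2 and 1, strict ``>``) and (ii) against
multiples of the Contradictory count, yielding the four ratio tiers reported
in the summary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import ExpressionCall, ExpressionMatrix, Sign

__all__ = [
    "Outcome",
    "RatioTier",
    "ConfirmationCounts",
    "TierConfig",
    "TierAssignment",
    "classify_experiment",
    "count_link",
    "assign_tier",
    "confirm_links",
    "ConfirmationReport",
]


class Outcome(enum.Enum):
    CONFIRMING = "Confirming"
    CONTRADICTORY = "Contradictory"
    NEUTRAL = "Neutral"
    IGNORED = "Ignored"


class RatioTier(str, enum.Enum):
    STRONG_3X = "strong_3x"      # c >= ratio_high * contradictory
    STRONG_2X = "strong_2x"      # ratio_mid * contradictory <= c < ratio_high * ...
    WEAK = "weak"                # contradictory <= c < ratio_mid * contradictory
    UNSUPPORTED = "unsupported"  # c < contradictory
    NO_DATA = "no_data"          # no informative experiment at all


_POSITIVE_RULES = {
    (ExpressionCall.EXPRESSED, ExpressionCall.EXPRESSED): Outcome.CONFIRMING,
    (ExpressionCall.EXPRESSED, ExpressionCall.NOT_EXPRESSED): Outcome.CONTRADICTORY,
    (ExpressionCall.NOT_EXPRESSED, ExpressionCall.EXPRESSED): Outcome.NEUTRAL,
    (ExpressionCall.NOT_EXPRESSED, ExpressionCall.NOT_EXPRESSED): Outcome.IGNORED,
}

_NEGATIVE_RULES = {
    (ExpressionCall.EXPRESSED, ExpressionCall.EXPRESSED): Outcome.CONTRADICTORY,
    (ExpressionCall.EXPRESSED, ExpressionCall.NOT_EXPRESSED): Outcome.CONFIRMING,
    (ExpressionCall.NOT_EXPRESSED, ExpressionCall.EXPRESSED): Outcome.CONFIRMING,
    (ExpressionCall.NOT_EXPRESSED, ExpressionCall.NOT_EXPRESSED): Outcome.CONTRADICTORY,
}


def classify_experiment(
    sign: Sign, tf_call: ExpressionCall, tg_call: ExpressionCall
) -> Outcome:
    """Classify one experiment for one link (total over the enums)."""
    if ExpressionCall.ABSENT in (tf_call, tg_call):
        return Outcome.IGNORED
    rules = _POSITIVE_RULES if sign is Sign.POSITIVE else _NEGATIVE_RULES
    return rules[(tf_call, tg_call)]


@dataclass(frozen=True)
class ConfirmationCounts:
    """Per-link tallies over all experiments; the four counts always sum to
    the experiment count."""

    c: int
    contradictory: int
    neutral: int
    ignored: int

    @property
    def n_experiments(self) -> int:
        return self.c + self.contradictory + self.neutral + self.ignored

    @property
    def informative(self) -> int:
        return self.c + self.contradictory + self.neutral


def count_link(link, expr: ExpressionMatrix, id_map: Mapping | None = None) -> ConfirmationCounts:
    """Tally rule outcomes for one predicted link over all experiments.

    ``id_map`` translates the link's target TF/TG ids into expression-matrix
    gene ids; unresolved or unknown genes behave as absent everywhere.
    """
    id_map = id_map or {}
    tf_gene = id_map.get(link.target_tf_id, link.target_tf_id)
    tg_gene = id_map.get(link.target_tg_id, link.target_tg_id)
    tf_calls = expr.calls_for(tf_gene)
    tg_calls = expr.calls_for(tg_gene)
    tally = {o: 0 for o in Outcome}
    for tf_call, tg_call in zip(tf_calls, tg_calls):
        tally[classify_experiment(link.sign, tf_call, tg_call)] += 1
    return ConfirmationCounts(
        c=tally[Outcome.CONFIRMING],
        contradictory=tally[Outcome.CONTRADICTORY],
        neutral=tally[Outcome.NEUTRAL],
        ignored=tally[Outcome.IGNORED],
    )


@dataclass(frozen=True)
class TierConfig:
    """Weights and ratio multiples used to grade links.

    Defaults: Contradictory weighs 2 and Neutral 1 in the verified test, and
    the ratio tiers compare ``c`` with 3x and 2x the Contradictory count.
    """

    contradictory_weight: int = 2
    neutral_weight: int = 1
    ratio_high: int = 3
    ratio_mid: int = 2

    def __post_init__(self) -> None:
        if self.contradictory_weight < 0 or self.neutral_weight < 0:
            raise ValueError("weights must be >= 0")
        if not self.ratio_high > self.ratio_mid >= 1:
            raise ValueError("need ratio_high > ratio_mid >= 1")


@dataclass(frozen=True)
class TierAssignment:
    verified: bool
    ratio_tier: RatioTier


def assign_tier(counts: ConfirmationCounts, config: TierConfig = TierConfig()) -> TierAssignment:
    """Grade one link from its outcome counts.

    ``verified`` is strict: ``c`` must exceed the weighted sum.  The ratio
    tiers partition every informative count pattern; a link with no
    informative experiment is ``no_data``.
    """
    threshold = (
        config.contradictory_weight * counts.contradictory
        + config.neutral_weight * counts.neutral
    )
    verified = counts.c > threshold
    if counts.informative == 0:
        tier = RatioTier.NO_DATA
    elif counts.c >= config.ratio_high * counts.contradictory:
        tier = RatioTier.STRONG_3X
    elif counts.c >= config.ratio_mid * counts.contradictory:
        tier = RatioTier.STRONG_2X
    elif counts.c >= counts.contradictory:
        tier = RatioTier.WEAK
    else:
        tier = RatioTier.UNSUPPORTED
    return TierAssignment(verified=verified, ratio_tier=tier)


@dataclass
class ConfirmationReport:
    """Per-link confirmation table plus tier totals.

    ``n_analyzed`` counts links with at least one informative experiment;
    the four ratio-tier totals partition exactly those links.
    """

    per_link: pd.DataFrame
    n_links: int
    n_analyzed: int
    n_verified: int
    tier_totals: dict

    def summary(self) -> dict:
        return {
            "links": self.n_links,
            "links_analyzed": self.n_analyzed,
            "links_verified": self.n_verified,
            **{tier.value: n for tier, n in self.tier_totals.items()},
        }


_REPORT_COLUMNS = [
    "source_tf_id", "source_tg_id", "target_tf_id", "target_tg_id", "sign",
    "provenance", "c", "contradictory", "neutral", "ignored", "verified",
    "ratio_tier",
]


def confirm_links(
    links: Iterable,
    expr: ExpressionMatrix,
    config: TierConfig = TierConfig(),
    id_map: Mapping | None = None,
) -> ConfirmationReport:
    """Count and grade every predicted link against the expression matrix."""
    rows = []
    tier_totals = {t: 0 for t in RatioTier if t is not RatioTier.NO_DATA}
    n_analyzed = n_verified = n_links = 0
    for link in links:
        n_links += 1
        counts = count_link(link, expr, id_map)
        grade = assign_tier(counts, config)
        if grade.ratio_tier is not RatioTier.NO_DATA:
            n_analyzed += 1
            tier_totals[grade.ratio_tier] += 1
        if grade.verified:
            n_verified += 1
        rows.append(
            [
                link.source_tf_id, link.source_tg_id,
                link.target_tf_id, link.target_tg_id, link.sign.symbol,
                link.provenance, counts.c, counts.contradictory,
                counts.neutral, counts.ignored, grade.verified,
                grade.ratio_tier.value,
            ]
        )
    frame = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    return ConfirmationReport(
        per_link=frame,
        n_links=n_links,
        n_analyzed=n_analyzed,
        n_verified=n_verified,
        tier_totals=tier_totals,
    )
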