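"""Stratified sensitivity/specificity evaluation of a linkage run.

The gold standard is registry-derived: a record counts toward
sensitivity if the registry itself recorded the death (within the death
window), and toward specificity if the person was provably alive at an
index date (hospital encounters on both sides of it).  Because the
mortality file keeps accumulating deaths after the index date, a living
person may legitimately be linked to a *later* death; only links to
deaths before the index date are false positives.

Overall estimates use the stratified sampling proportion method: strata
are sex × country of birth, sexes weighted one half each and the
born-outside-the-home-country fraction taken from census data.  The
point estimate is Σ wₛ pₛ with variance Σ wₛ² pₛ(1−pₛ)/nₛ (Wald 95% CI,
clipped to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .matching import MatchResult
from .records import ConfigurationError

Z95 = 1.959963984540054

#: canonical stratum labels: sex × birth-country group
STRATA = ("m_france", "m_other", "f_france", "f_other")


@dataclass
class EvaluationConfig:
    index_date: str = "2016-01-01"
    death_window: tuple[str, str] = ("2001-01-01", "2020-12-31")
    #: percentage of the population born outside the home country
    born_outside_pct: float = 4.5

    def stratum_weights(self) -> dict[str, float]:
        p_out = self.born_outside_pct / 100.0
        return {
            "m_france": 0.5 * (1 - p_out),
            "m_other": 0.5 * p_out,
            "f_france": 0.5 * (1 - p_out),
            "f_other": 0.5 * p_out,
        }


def _selected_links(results: Iterable[MatchResult]) -> dict[str, list[str]]:
    """local_id → death dates of its selected links (ISO strings)."""
    links: dict[str, list[str]] = {}
    for m in results:
        if m.selected and m.death_date:
            links.setdefault(m.local_id, []).append(m.death_date)
    return links


def classify_for_sensitivity(gold_deceased: Sequence[str],
                             results: Iterable[MatchResult],
                             config: EvaluationConfig | None = None
                             ) -> dict[str, bool]:
    """True iff the deceased record is linked to ≥1 in-window death."""
    config = config or EvaluationConfig()
    lo, hi = config.death_window
    links = _selected_links(results)
    return {rid: any(lo <= d <= hi for d in links.get(rid, []))
            for rid in gold_deceased}


def classify_for_specificity(gold_living: Sequence[str],
                             results: Iterable[MatchResult],
                             config: EvaluationConfig | None = None
                             ) -> dict[str, bool]:
    """True (true negative) iff no selected link to a pre-index death."""
    config = config or EvaluationConfig()
    links = _selected_links(results)
    return {rid: not any(d < config.index_date for d in links.get(rid, []))
            for rid in gold_living}


def census_weight(born_outside: int, total: int) -> float:
    """Percentage of a census population born outside the home country."""
    if total <= 0:
        raise ConfigurationError("census total must be positive")
    if not 0 < born_outside <= total:
        raise ConfigurationError("born_outside must be in (0, total]")
    return 100.0 * born_outside / total


@dataclass(frozen=True)
class Estimate:
    value: float
    ci_low: float
    ci_high: float
    n: int

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.value, self.ci_low, self.ci_high)


def proportion_estimate(successes: int, n: int) -> Estimate:
    """Simple binomial proportion with a clipped Wald 95% CI."""
    if n < 1:
        raise ConfigurationError("stratum size must be ≥ 1")
    p = successes / n
    half = Z95 * np.sqrt(p * (1 - p) / n)
    return Estimate(p, max(0.0, p - half), min(1.0, p + half), n)


def weighted_performance(per_stratum: Mapping[str, tuple[float, int]],
                         weights: Mapping[str, float]) -> Estimate:
    """Stratified sampling proportion estimate with Wald 95% CI.

    ``per_stratum`` maps stratum → (proportion, n).  Weights must sum to 1.
    """
    if abs(sum(weights[s] for s in per_stratum) - 1.0) > 1e-9:
        raise ConfigurationError("stratum weights must sum to 1")
    point = 0.0
    var = 0.0
    n_total = 0
    for s, (p, n) in per_stratum.items():
        if n < 1:
            raise ConfigurationError(f"stratum {s!r} has n < 1")
        w = weights[s]
        point += w * p
        var += w * w * p * (1 - p) / n
        n_total += n
    half = Z95 * np.sqrt(var)
    return Estimate(point, max(0.0, point - half), min(1.0, point + half),
                    n_total)


@dataclass(frozen=True)
class McNemarResult:
    statistic: float  # continuity-corrected chi-square
    p_value: float
    b: int  # strategy A correct, strategy B wrong
    c: int  # strategy A wrong, strategy B correct
    exact: bool  # exact binomial p used (discordant total < 25)
    degenerate: bool = False  # no discordant pairs at all


def compare_strategies(outcomes_a: Mapping[str, bool],
                       outcomes_b: Mapping[str, bool]) -> McNemarResult:
    """McNemar test on paired per-record outcomes of two strategies.

    Continuity-corrected chi-square statistic (|b−c|−1)²/(b+c); the
    p-value switches to the exact binomial when b+c < 25.
    """
    ids = sorted(outcomes_a)
    if sorted(outcomes_b) != ids:
        raise ConfigurationError("strategies were scored on different records")
    b = sum(1 for i in ids if outcomes_a[i] and not outcomes_b[i])
    c = sum(1 for i in ids if not outcomes_a[i] and outcomes_b[i])
    if b + c == 0:
        return McNemarResult(0.0, 1.0, 0, 0, exact=True, degenerate=True)
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    exact = (b + c) < 25
    n11 = sum(1 for i in ids if outcomes_a[i] and outcomes_b[i])
    n00 = len(ids) - n11 - b - c
    table = [[n11, b], [c, n00]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return McNemarResult(statistic, float(res.pvalue), b, c, exact=exact)


@dataclass
class EvaluationReport:
    """Per-stratum and overall sensitivity/specificity for one strategy."""

    sensitivity_by_stratum: dict[str, Estimate] = field(default_factory=dict)
    specificity_by_stratum: dict[str, Estimate] = field(default_factory=dict)
    sensitivity: Estimate | None = None
    specificity: Estimate | None = None

    def to_text(self) -> str:
        lines = ["stratum        sensitivity (95% CI)      specificity (95% CI)"]
        for s in STRATA:
            se = self.sensitivity_by_stratum.get(s)
            sp = self.specificity_by_stratum.get(s)
            fmt = (lambda e: f"{100*e.value:5.1f} ({100*e.ci_low:.1f}-{100*e.ci_high:.1f})"
                   if e else "     n/a")
            lines.append(f"{s:<14} {fmt(se):<25} {fmt(sp)}")
        if self.sensitivity and self.specificity:
            se, sp = self.sensitivity, self.specificity
            lines.append(
                f"{'overall':<14} {100*se.value:5.1f} "
                f"({100*se.ci_low:.1f}-{100*se.ci_high:.1f})"
                f"{'':<10}{100*sp.value:5.1f} "
                f"({100*sp.ci_low:.1f}-{100*sp.ci_high:.1f})")
        return "\n".join(lines)


def evaluate(gold: Mapping[str, tuple[str, str]],
             results: Iterable[MatchResult],
             config: EvaluationConfig | None = None) -> EvaluationReport:
    """Score one strategy's results against a gold standard.

    ``gold`` maps record_id → (truth, stratum) with truth in
    {"deceased", "living"} and stratum one of :data:`STRATA`.
    """
    config = config or EvaluationConfig()
    results = list(results)
    weights = config.stratum_weights()
    report = EvaluationReport()

    deceased = {rid: s for rid, (truth, s) in gold.items() if truth == "deceased"}
    living = {rid: s for rid, (truth, s) in gold.items() if truth == "living"}
    sens = classify_for_sensitivity(sorted(deceased), results, config)
    spec = classify_for_specificity(sorted(living), results, config)

    for kind, outcomes, members, out in (
        ("sensitivity", sens, deceased, report.sensitivity_by_stratum),
        ("specificity", spec, living, report.specificity_by_stratum),
    ):
        per_stratum: dict[str, tuple[float, int]] = {}
        for s in STRATA:
            ids = [rid for rid, st in members.items() if st == s]
            if not ids:
                continue
            hits = sum(outcomes[rid] for rid in ids)
            est = proportion_estimate(hits, len(ids))
            out[s] = est
            per_stratum[s] = (est.value, est.n)
        if per_stratum:
            w = {s: weights[s] for s in per_stratum}
            total_w = sum(w.values())
            w = {s: v / total_w for s, v in w.items()}  # renormalise to observed strata
            overall = weighted_performance(per_stratum, w)
            if kind == "sensitivity":
                report.sensitivity = overall
            else:
                report.specificity = overall
    return report
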