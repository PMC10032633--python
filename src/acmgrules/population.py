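"""Frequency-based criteria BA1, BS1, PM2 and BS2.

The comparison statistic is either the point allele frequency or the
one-sided exact binomial (Clopper-Pearson) lower confidence bound,
depending on gene configuration. Founder populations (bottlenecked, e.g.
Ashkenazi Jewish or Finnish) can be excluded from the BA1/BS1 maximum
because drift there may mask natural negative selection of pathogenic
alleles. Only populations whose site coverage passed quality control
(mean >= 20x) ever argue for presence or absence of the variant.
"""
from __future__ import annotations

from typing import Optional

from scipy.stats import beta as beta_dist

from .models import (
    CriterionCall,
    EvidenceBundle,
    FrequencySummary,
    GeneConfig,
    PopulationRecord,
    State,
    Strength,
)


def af_ci_lower(allele_count: int, allele_number: int, confidence: float = 0.95) -> float:
    """One-sided Clopper-Pearson lower confidence bound on an allele frequency.

    For ``k`` successes in ``n`` trials the bound is the ``1 - confidence``
    quantile of Beta(k, n - k + 1); it is 0 when ``k == 0``.
    """
    if allele_number <= 0:
        raise ValueError("allele_number must be positive")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly between 0 and 1")
    if allele_count < 0 or allele_count > allele_number:
        raise ValueError("allele_count must lie in [0, allele_number]")
    if allele_count == 0:
        return 0.0
    return float(
        beta_dist.ppf(1.0 - confidence, allele_count, allele_number - allele_count + 1)
    )


class NoEvaluablePopulation(ValueError):
    """All population records were excluded (founder or failed coverage)."""


def filtered_popmax(
    records: list[PopulationRecord], cfg: GeneConfig
) -> FrequencySummary:
    """The population maximizing the configured comparison statistic.

    Founder populations are excluded when ``cfg.exclude_founder``;
    populations failing coverage are always excluded. The maximum is taken
    over the CI lower bound when ``cfg.use_ci_lower``, else the point AF.
    """
    excluded: list[str] = []
    candidates: list[PopulationRecord] = []
    for rec in records:
        if not rec.coverage_ok:
            excluded.append(f"{rec.population_label} (coverage)")
        elif cfg.exclude_founder and rec.founder:
            excluded.append(f"{rec.population_label} (founder)")
        else:
            candidates.append(rec)
    if not candidates:
        raise NoEvaluablePopulation(
            "no evaluable population after founder/coverage exclusion"
        )

    def stat(rec: PopulationRecord) -> float:
        if cfg.use_ci_lower:
            return af_ci_lower(rec.allele_count, rec.allele_number, cfg.ci_confidence)
        return rec.af

    best = max(candidates, key=stat)
    return FrequencySummary(
        popmax_label=best.population_label,
        af_point=best.af,
        af_ci_lower=af_ci_lower(best.allele_count, best.allele_number, cfg.ci_confidence),
        used_ci=cfg.use_ci_lower,
        excluded_populations=excluded,
    )


def _not_automated(codes: list[str], why: str) -> list[CriterionCall]:
    return [CriterionCall(c, State.NOT_AUTOMATED, explanation=why) for c in codes]


def evaluate_frequency_criteria(
    summary: Optional[FrequencySummary],
    records: list[PopulationRecord],
    cfg: GeneConfig,
) -> list[CriterionCall]:
    """BA1 / BS1 / PM2 from the filtered population maximum.

    BA1 (standalone) fires at statistic >= ba1_af; otherwise BS1 at
    >= bs1_af. PM2 fires when the variant is absent from every
    coverage-passing population, or when the global statistic is
    <= pm2_af; it is never combined with BA1/BS1. Thresshold comparisons
    are inclusive.
    """
    covered = [r for r in records if r.coverage_ok]
    if summary is None or not covered:
        return _not_automated(
            ["BA1", "BS1", "PM2"], "no evaluable population data"
        )

    stat = summary.statistic
    stat_name = "CI lower bound" if summary.used_ci else "point AF"
    where = (
        f"{stat_name} {stat:.3g} in {summary.popmax_label} "
        f"(AF {summary.af_point:.3g})"
    )
    if summary.excluded_populations:
        where += "; excluded: " + ", ".join(summary.excluded_populations)

    calls: list[CriterionCall] = []
    if stat >= cfg.ba1_af:
        calls.append(CriterionCall(
            "BA1", State.ASSIGNED, Strength.STANDALONE,
            f"{where} >= BA1 threshold {cfg.ba1_af:.3g}",
        ))
        calls.append(CriterionCall(
            "BS1", State.DENIED,
            explanation="BA1 is standalone and incompatible with BS1",
        ))
        calls.append(CriterionCall(
            "PM2", State.DENIED,
            explanation="variant frequency is common (BA1); PM2 cannot apply",
        ))
        return calls

    if stat >= cfg.bs1_af:
        calls.append(CriterionCall("BA1", State.DENIED,
                                   explanation=f"{where} < BA1 threshold {cfg.ba1_af:.3g}"))
        calls.append(CriterionCall(
            "BS1", State.ASSIGNED, Strength.STRONG,
            f"{where} >= BS1 threshold {cfg.bs1_af:.3g}",
        ))
        calls.append(CriterionCall(
            "PM2", State.DENIED,
            explanation="variant frequency exceeds the BS1 threshold; PM2 cannot apply",
        ))
        return calls

    calls.append(CriterionCall("BA1", State.DENIED,
                               explanation=f"{where} < BA1 threshold {cfg.ba1_af:.3g}"))
    calls.append(CriterionCall("BS1", State.DENIED,
                               explanation=f"{where} < BS1 threshold {cfg.bs1_af:.3g}"))

    absent_everywhere = all(r.allele_count == 0 for r in covered)
    # global statistic: pooled across coverage-passing populations
    total_ac = sum(r.allele_count for r in covered)
    total_an = sum(r.allele_number for r in covered)
    if cfg.use_ci_lower:
        global_stat = af_ci_lower(total_ac, total_an, cfg.ci_confidence)
    else:
        global_stat = total_ac / total_an

    if absent_everywhere:
        calls.append(CriterionCall(
            "PM2", State.ASSIGNED, cfg.pm2_strength,
            f"variant absent from all {len(covered)} coverage-passing populations "
            f"(AN {total_an})",
        ))
    elif global_stat <= cfg.pm2_af:
        calls.append(CriterionCall(
            "PM2", State.ASSIGNED, cfg.pm2_strength,
            f"global {stat_name} {global_stat:.3g} <= PM2 threshold {cfg.pm2_af:.3g} "
            f"(AC {total_ac}/AN {total_an})",
        ))
    else:
        calls.append(CriterionCall(
            "PM2", State.DENIED,
            explanation=(
                f"global {stat_name} {global_stat:.3g} > PM2 threshold {cfg.pm2_af:.3g}"
            ),
        ))
    return calls


def evaluate_population(
    bundle: EvidenceBundle, cfg: GeneConfig
) -> list[CriterionCall]:
    """BA1/BS1/PM2 for a bundle (popmax computation plus band logic)."""
    try:
        summary = filtered_popmax(bundle.population, cfg) if bundle.population else None
    except NoEvaluablePopulation:
        summary = None
    return evaluate_frequency_criteria(summary, bundle.population, cfg)


def evaluate_bs2(bundle: EvidenceBundle, cfg: GeneConfig) -> CriterionCall:
    """BS2 from FLOSSIES observations and non-cancer homozygote counts.

    The gene mode decides whether the criterion is inapplicable (ATM,
    CHEK2), beyond automation (CDH1, mismatch-repair genes) or evaluated
    from the two counts.
    """
    if cfg.bs2_mode == "off":
        return CriterionCall(
            "BS2", State.NOT_APPLICABLE,
            explanation=f"BS2 does not apply to {cfg.gene_symbol} guidelines",
        )
    if cfg.bs2_mode == "not_automated":
        return CriterionCall(
            "BS2", State.NOT_AUTOMATED,
            explanation=f"BS2 is not automated for {cfg.gene_symbol}",
        )

    fl = bundle.flossies_count
    hom = bundle.homozygote_count_noncancer
    if fl is None and hom is None:
        return CriterionCall(
            "BS2", State.NOT_AUTOMATED,
            explanation="no FLOSSIES or homozygote evidence available",
        )
    if (fl or 0) >= cfg.bs2_flossies_min:
        return CriterionCall(
            "BS2", State.ASSIGNED, Strength.STRONG,
            f"{fl} FLOSSIES observations >= threshold {cfg.bs2_flossies_min}",
        )
    if (hom or 0) >= cfg.bs2_homozygote_min:
        return CriterionCall(
            "BS2", State.ASSIGNED, Strength.STRONG,
            f"{hom} non-cancer homozygotes >= threshold {cfg.bs2_homozygote_min}",
        )
    return CriterionCall(
        "BS2", State.DENIED,
        explanation=(
            f"FLOSSIES count {fl or 0} < {cfg.bs2_flossies_min} and "
            f"homozygote count {hom or 0} < {cfg.bs2_homozygote_min}"
        ),
    )
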