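"""Pattern search over SNP-environment pairs.

For one pair, every enumerated pattern is fitted and the best is
selected by smallest BIC (default — parsimony) or smallest interaction
p-value.  Batch mode runs the search across SNPs against one
environmental factor, combines it with allele summaries and SNP
main-effect tests, and applies a Bonferroni correction across pairs.

The selected pattern's interaction p-value is reported unadjusted for
the within-pair search over 27 (or 18) patterns; the Bonferroni
correction applies only across pairs.  The within-pair selection
effect (the minimum of 27 p-values is stochastically smaller than
uniform) is a known property of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptives import maf_info, recode_minor_count, snp_main
from .fitstats import PatternFit, fit_pattern
from .patterns import enumerate_patterns

__all__ = ["PairResult", "BatchResult", "snpxe_pair", "snpxe_batch", "bonferroni_threshold"]

_BIC_TIE = 1e-9

_MODE_SHORT = {"additive": "Add", "dominant": "Dom", "recessive": "Rec"}


@dataclass
class PairResult:
    """All pattern fits for one SNP-environment pair plus the selected best."""

    snp_name: str
    env_name: str
    all_fits: list[PatternFit]
    best: PatternFit | None
    selection_rule: str
    n_used: int
    failure: str | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long table of every pattern's p-value and BIC (Table-1-like)."""
        rows = []
        for f in self.all_fits:
            rows.append({
                "snp": self.snp_name,
                "env": self.env_name,
                "pattern": f.label,
                "structure": f.spec.structure.value,
                "mode": f.spec.mode.value,
                "p_int": f.p_interaction,
                "bic": f.bic,
                "estimable": f.estimable,
                "selected": self.best is not None and f.label == self.best.label,
            })
        return pd.DataFrame(rows)


@dataclass
class BatchResult:
    """One summary row per SNP-environment pair plus the corrected threshold."""

    table: pd.DataFrame
    alpha: float
    alpha_corrected: float
    m_tests: int
    pairs: dict[str, PairResult] = field(default_factory=dict)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected significance level alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def _select_best(fits: list[PatternFit], selection: str) -> PatternFit | None:
    estimable = [(i, f) for i, f in enumerate(fits) if f.estimable]
    if not estimable:
        return None
    if selection == "bic":
        # smallest BIC; ties (within 1e-9) broken by smaller p, then order
        best_bic = min(f.bic for _, f in estimable)
        tied = [(i, f) for i, f in estimable if f.bic - best_bic <= _BIC_TIE]
        return min(tied, key=lambda t: (t[1].p_interaction, t[0]))[1]
    if selection == "pvalue":
        best_p = min(f.p_interaction for _, f in estimable)
        tied = [(i, f) for i, f in estimable if f.p_interaction == best_p]
        return min(tied, key=lambda t: (t[1].bic, t[0]))[1]
    raise ValueError(f"selection must be 'bic' or 'pvalue', got {selection!r}")


def snpxe_pair(
    data: pd.DataFrame,
    snp_name: str,
    env_name: str,
    outcome_name: str,
    env_type: str = "ordinal",
    family: str = "logistic",
    covariates: list[str] | None = None,
    selection: str = "bic",
    test: str = "lrt",
) -> PairResult:
    """Fit every interaction pattern for one SNP-environment pair.

    The SNP column must already hold 0/1/2 minor-allele counts (use
    :func:`snpxe.descriptives.recode_minor_count` for allele strings).
    Non-estimable patterns are kept in ``all_fits`` with missing
    p/BIC.  If fewer than two patterns are estimable the pair is
    returned as a failure record rather than raising.
    """
    specs = enumerate_patterns(env_type)
    cache: dict = {}
    fits = [
        fit_pattern(
            data, spec, snp=snp_name, env=env_name, outcome=outcome_name,
            env_type=env_type, family=family, covariates=covariates,
            test=test, _reduced_cache=cache,
        )
        for spec in specs
    ]
    n_used = max((f.n_used for f in fits), default=0)
    best = _select_best(fits, selection)
    n_estimable = sum(f.estimable for f in fits)
    failure = None
    if n_estimable < 2:
        best = None
        reasons = {f.reason for f in fits if f.reason}
        failure = f"only {n_estimable} estimable pattern(s); reasons: {sorted(reasons)}"
    return PairResult(
        snp_name=snp_name, env_name=env_name, all_fits=fits, best=best,
        selection_rule=selection, n_used=n_used, failure=failure,
    )


def snpxe_batch(
    data: pd.DataFrame,
    snp_names: list[str],
    env_name: str,
    outcome_name: str,
    env_type: str = "ordinal",
    family: str = "logistic",
    covariates: list[str] | None = None,
    selection: str = "bic",
    alpha: float = 0.05,
    test: str = "lrt",
) -> BatchResult:
    """Run the pattern search for each SNP against one environmental factor.

    Each output row combines the allele summary (major/minor, MAF),
    the SNP main-effect test (best inheritance mode and its p-value),
    and the pair's selected interaction pattern with its p-value.
    ``alpha_corrected = alpha / len(snp_names)`` (Bonferroni across
    pairs); rows are flagged significant when p_int falls below it.
    Per-SNP failures are recorded in their row; the batch continues.
    """
    if not snp_names:
        raise ValueError("need at least one SNP column")
    alpha_c = bonferroni_threshold(alpha, len(snp_names))
    rows = []
    pairs: dict[str, PairResult] = {}
    for snp in snp_names:
        row = {"SNP": snp, "Environment": env_name, "maj/min": None, "MAF": None,
               "SNP Mode": None, "p_SNPiv": None, "Interaction Pattern": None,
               "p_int": None, "significant": False, "note": None}
        try:
            info = maf_info(data[snp], snp_name=snp)
            row["maj/min"] = (
                f"{info.major_allele}/{info.minor_allele}"
                if info.major_allele else "-/-"
            )
            row["MAF"] = info.maf
            work = data
            if info.allele_coded:
                work = data.copy()
                work[snp] = recode_minor_count(data[snp], info)
            if info.monomorphic:
                row["note"] = "monomorphic SNP"
                rows.append(row)
                continue
            main = snp_main(work, snp, outcome_name, family=family, covariates=covariates)
            if main.best_mode is not None:
                row["SNP Mode"] = _MODE_SHORT[main.best_mode.value]
                row["p_SNPiv"] = main.p_snpiv
            pair = snpxe_pair(
                work, snp, env_name, outcome_name, env_type=env_type,
                family=family, covariates=covariates, selection=selection, test=test,
            )
            pairs[snp] = pair
            if pair.best is not None:
                row["Interaction Pattern"] = pair.best.label
                row["p_int"] = pair.best.p_interaction
                row["significant"] = bool(pair.best.p_interaction < alpha_c)
            else:
                row["note"] = pair.failure
        except (ValueError, KeyError) as exc:
            row["note"] = str(exc)
        rows.append(row)
    return BatchResult(
        table=pd.DataFrame(rows), alpha=alpha, alpha_corrected=alpha_c,
        m_tests=len(snp_names), pairs=pairs,
    )
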