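"""Model/Results interface tying the pipeline together.

:class:`ACCE` is constructed from a cohort and a nested-model
specification; :meth:`ACCE.fit` runs the four steps — fit both linear
propensity scores, estimate both stratified treatment effects, estimate the
Introduced-Variable outcome coefficients and balances, and evaluate the
summary equation — and returns an :class:`ACCEResults` carrying every named
intermediate, the qualitative probe reading, warnings and a ``summary()``
table.  Bootstrap confidence intervals hang off the results object.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from . import core
from .core import (
    AcceInputs,
    AcceResult,
    AmplificationPair,
    BrossTerm,
    ProbeThresholds,
)
from .propensity import (
    Cohort,
    IVBalance,
    NestedModelSpec,
    PsFit,
    estimate_tee_stratified,
    fit_linear_ps,
    iv_balance,
    iv_outcome_coefficient,
)

logger = logging.getLogger(__name__)

__all__ = ["ACCE", "ACCEResults"]


@dataclass(frozen=True)
class _IVTerm:
    name: str
    rr_outcome: float
    balance_m1: IVBalance
    balance_m2: IVBalance
    conf_m1: float
    conf_m2: float


class ACCE:
    """Amplified-confounding estimation of total residual confounding.

    Parameters
    ----------
    cohort
        A validated :class:`~acce.propensity.Cohort`.
    spec
        The nested-model specification: Model 1 covariates, Introduced
        Variable(s), stratum count and options.
    thresholds
        Cutoffs for the qualitative probe (defaults in
        :class:`~acce.core.ProbeThresholds`).
    """

    def __init__(self, cohort: Cohort, spec: NestedModelSpec,
                 thresholds: ProbeThresholds | None = None,
                 min_increment: float = 0.01) -> None:
        missing = [c for c in (*spec.model1_covariates, *spec.introduced_variables)
                   if c not in cohort.data.columns]
        if missing:
            from .exceptions import CohortValidationError
            raise CohortValidationError(f"spec names columns absent from cohort: {missing}")
        self.cohort = cohort
        self.spec = spec
        self.thresholds = thresholds
        # OLS nesting makes R²_M2 >= R²_M1 mechanically, so the fitted
        # increment is positive even when the Introduced Variable predicts
        # nothing; dividing the TEE change by sampling noise is meaningless.
        # Below this floor the back-extrapolation is refused.
        self.min_increment = float(min_increment)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, treatment: str, outcome: str,
                       model1_covariates: list[str],
                       introduced_variables: list[str],
                       n_strata: int = 10,
                       withheld_marker: str | None = None,
                       iv_balance_m1: str = "stratified",
                       thresholds: ProbeThresholds | None = None,
                       min_per_arm: int = 1) -> "ACCE":
        """Build the model straight from a subject-level table."""
        covariates = [*model1_covariates, *introduced_variables]
        if withheld_marker is not None:
            covariates.append(withheld_marker)
        cohort = Cohort.from_dataframe(
            data, treatment=treatment, outcome=outcome,
            covariates=covariates, iv_columns=tuple(introduced_variables),
            min_per_arm=min_per_arm)
        spec = NestedModelSpec(
            model1_covariates=tuple(model1_covariates),
            introduced_variables=tuple(introduced_variables),
            n_strata=n_strata, withheld_marker=withheld_marker,
            iv_balance_m1=iv_balance_m1)
        return cls(cohort, spec, thresholds=thresholds)

    def fit(self) -> "ACCEResults":
        """Run the full pipeline and evaluate the summary equation."""
        cohort, spec = self.cohort, self.spec
        logger.info("Step 1: fitting nested propensity models "
                    "(Model 1: %d covariates; Model 2: +%d introduced)",
                    len(spec.model1_covariates), len(spec.introduced_variables))
        fit1 = fit_linear_ps(cohort, spec.model1_covariates)
        fit2 = fit_linear_ps(cohort, spec.model2_covariates)
        logger.info("Step 2: stratified treatment effects (n_strata=%d); "
                    "R² %.4f -> %.4f", spec.n_strata, fit1.r2, fit2.r2)
        amp = AmplificationPair(fit1.r2, fit2.r2)
        if amp.increment < self.min_increment:
            from .exceptions import ExtrapolationInvalidError
            raise ExtrapolationInvalidError(
                f"between-model amplification increment {amp.increment:.2e} "
                f"is below the floor {self.min_increment:g}; the Introduced "
                "Variable(s) add too little exposure prediction to "
                "back-extrapolate from")
        tee1 = estimate_tee_stratified(cohort, fit1, spec.n_strata)
        tee2 = estimate_tee_stratified(cohort, fit2, spec.n_strata)
        logger.info("Step 3: Introduced-Variable outcome coefficients and "
                    "balances for %s", list(spec.introduced_variables))
        iv_terms: list[_IVTerm] = []
        warnings: list[str] = []
        for name in spec.introduced_variables:
            others = [c for c in spec.model2_covariates if c != name]
            coef = iv_outcome_coefficient(cohort, name, others)
            warnings.extend(coef.info.get("warnings", ()))
            rr = math.exp(coef.beta)
            if spec.iv_balance_m1 == "raw":
                bal1 = iv_balance(cohort, name, fit=None)
            else:
                bal1 = iv_balance(cohort, name, fit=fit1, n_strata=spec.n_strata)
            bal2 = iv_balance(cohort, name, fit=fit2, n_strata=spec.n_strata)
            term1 = BrossTerm(bal1.prev_treated, bal1.prev_comparison, rr)
            term2 = BrossTerm(bal2.prev_treated, bal2.prev_comparison, rr)
            iv_terms.append(_IVTerm(
                name=name, rr_outcome=rr, balance_m1=bal1, balance_m2=bal2,
                conf_m1=core.bross_log_confounding(term1),
                conf_m2=core.bross_log_confounding(term2)))
        if len(iv_terms) > 1:
            warnings.append(
                "multiple Introduced Variables: Bross terms computed per "
                "variable from marginal balances and summed (additive "
                "approximation)")
        conf_delta, conf_m1 = core.combine_iv_terms(
            [t.conf_m2 - t.conf_m1 for t in iv_terms],
            [t.conf_m1 for t in iv_terms])
        inputs = AcceInputs(
            tee_m1=tee1, tee_m2=tee2, amp=amp,
            conf_iv_delta=conf_delta, conf_iv_m1=conf_m1)
        logger.info("Step 4: summary equation")
        result = core.unconfounded_tee(inputs, self.thresholds)
        warnings.extend(result.warnings)
        return ACCEResults(model=self, result=result, ps_fit_m1=fit1,
                           ps_fit_m2=fit2, iv_terms=tuple(iv_terms),
                           warnings=tuple(warnings))

    def bootstrap_ci(self, B: int = 500, level: float = 0.95,
                     seed: int | None = None, stratify_by_arm: bool = False):
        """Case-resampling bootstrap CI for the unconfounded effect; see
        :func:`acce.inference.bootstrap_ci`."""
        from .inference import bootstrap_ci
        return bootstrap_ci(self.cohort, self.spec, B=B, level=level,
                            seed=seed, stratify_by_arm=stratify_by_arm,
                            thresholds=self.thresholds)


@dataclass(frozen=True)
class ACCEResults:
    """Fitted ACCE pipeline: estimates, intermediates and diagnostics."""

    model: ACCE
    result: AcceResult
    ps_fit_m1: PsFit
    ps_fit_m2: PsFit
    iv_terms: tuple[_IVTerm, ...]
    warnings: tuple[str, ...] = field(default=())

    # -- convenience accessors -------------------------------------------
    @property
    def unconfounded_tee(self) -> float:
        """Unconfounded treatment effect (log-RR scale), ``k``."""
        return self.result.unconfounded_tee

    @property
    def unconfounded_rr(self) -> float:
        return self.result.unconfounded_rr

    @property
    def total_residual_confounding(self) -> float:
        return self.result.total_residual_confounding

    @property
    def amplifiable_confounding(self) -> float:
        return self.result.amplifiable_confounding

    @property
    def qualitative(self):
        return self.result.qualitative

    @property
    def params(self) -> pd.Series:
        """Named terms of the summary equation at full precision."""
        return pd.Series(core.summary_equation_terms(self.result))

    def bootstrap_ci(self, B: int = 500, level: float = 0.95,
                     seed: int | None = None, stratify_by_arm: bool = False):
        return self.model.bootstrap_ci(B=B, level=level, seed=seed,
                                       stratify_by_arm=stratify_by_arm)

    def to_report(self) -> dict:
        """JSON-serializable report with every named intermediate."""
        r = self.result
        q = r.qualitative
        return {
            "terms": core.summary_equation_terms(r),
            "worked_chain_4dp": core.worked_chain(r.inputs),
            "introduced_variables": [
                {
                    "name": t.name,
                    "rr_outcome": t.rr_outcome,
                    "balance_m1": {"prev_treated": t.balance_m1.prev_treated,
                                   "prev_comparison": t.balance_m1.prev_comparison,
                                   "stratified": t.balance_m1.stratified},
                    "balance_m2": {"prev_treated": t.balance_m2.prev_treated,
                                   "prev_comparison": t.balance_m2.prev_comparison,
                                   "stratified": t.balance_m2.stratified},
                    "conf_m1": t.conf_m1,
                    "conf_m2": t.conf_m2,
                } for t in self.iv_terms
            ],
            "qualitative": {"direction": q.direction, "magnitude": q.magnitude,
                            "delta_beta": q.delta_beta},
            "tee_info": {"m1": self.result.inputs.tee_m1.info,
                         "m2": self.result.inputs.tee_m2.info},
            "warnings": list(self.warnings),
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        t = core.summary_equation_terms(self.result)
        q = self.result.qualitative
        lines = [
            "ACCE: amplified-confounding estimate of residual confounding",
            "=" * 62,
            f"{'Model 1 TEE (beta / RR)':38s} {t['TEE_M1']:+.4f} / {math.exp(t['TEE_M1']):.4f}",
            f"{'Model 2 TEE (beta / RR)':38s} {t['TEE_M2']:+.4f} / {math.exp(t['TEE_M2']):.4f}",
            f"{'Exposure R² (Model 1, Model 2)':38s} {t['R2_M1']:.4f}, {t['R2_M2']:.4f}",
            f"{'Amplification ratio / increment':38s} {t['amplification_ratio']:.4f} / "
            f"{t['amplification_increment']:.4f}",
            f"{'Conf_IntV Δ(M2-M1)':38s} {t['Conf_IntV_delta']:+.4f}",
            f"{'Conf_IntV M1':38s} {t['Conf_IntV_M1']:+.4f}",
            f"{'Adjusted ΔTEE':38s} {t['Adj_delta_TEE']:+.4f}",
            "-" * 62,
            f"{'Amplifiable-fraction confounding (x)':38s} {t['x']:+.4f}",
            f"{'Total residual confounding':38s} {t['total_residual_confounding']:+.4f}",
            f"{'Unconfounded TEE (k, beta / RR)':38s} {t['unconfounded_TEE']:+.4f} / "
            f"{t['unconfounded_RR']:.4f}",
            f"{'Qualitative probe':38s} {q.magnitude}, {q.direction} "
            f"(Δbeta {q.delta_beta:+.4f})",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)
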