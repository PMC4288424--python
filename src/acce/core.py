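"""Arithmetic core of the ACCE method.

ACCE (Amplified Confounding-based Confounding Estimation) deliberately
*amplifies* the residual confounding of a treatment-effect estimate and then
extrapolates backwards to the unamplified amount.  Two nested propensity-score
models are compared: Model 2 adds one or more "Introduced Variables" that
strongly predict treatment.  Conditioning on more of the exposure variance
amplifies the confounding contributed by every confounder absent from both
models, and — for linear-probability propensity models with stratified
risk-ratio estimation — the amplification is proportional to ``1/(1 - R²)``
of each model's exposure fit.

Everything here is closed-form algebra on the natural-log risk-ratio scale
(``beta = ln RR``).  Writing the Model 1 estimate as ``beta_M1 = x + y + k``
with

* ``x`` — confounding from the *amplifiable fraction* (confounders in
  neither model),
* ``y`` — confounding from the Introduced Variable's Model 1 imbalance
  (it joins Model 2's score, so it does not amplify), and
* ``k`` — the genuine treatment effect,

the Model 2 estimate is ``beta_M2 = A·x + y' + k`` where
``A = (1/(1-R²_M2)) / (1/(1-R²_M1))`` and ``y'`` is the (Bross-estimated)
Introduced-Variable confounding that remains after it is balanced by
Model 2.  Solving for ``x``:

    x = [ (beta_M2 - beta_M1) - (y' - y) ] / (A - 1)

and the unconfounded effect is ``k = beta_M1 - x - y``.  The Introduced
Variable terms ``y`` and ``y'`` come from the Bross bias factor for a binary
confounder, ``B = (1 + p_t (RR-1)) / (1 + p_c (RR-1))``, combining its
arm-specific prevalences with its outcome risk ratio.

Estimation of the inputs (propensity fits, stratified treatment effects,
Introduced-Variable coefficients and balances) lives in
:mod:`acce.propensity`; this module never touches subject-level data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .exceptions import DomainError, ExtrapolationInvalidError

__all__ = [
    "EffectEstimate",
    "AmplificationPair",
    "BrossTerm",
    "AcceInputs",
    "AcceResult",
    "ProbeClassification",
    "ProbeThresholds",
    "model_amplification",
    "amplification_increment",
    "bross_log_confounding",
    "delta_iv_confounding",
    "adjusted_delta_tee",
    "amplifiable_confounding",
    "unconfounded_tee",
    "qualitative_probe",
    "worked_chain",
    "R2_VALIDATED_RANGE",
]

#: Range of exposure-model R² over which the 1/(1-R²) amplification law has
#: simulation support for stratified/matched linear propensity scores.
#: Outside it a non-fatal warning is attached to results.
R2_VALIDATED_RANGE = (0.04, 0.56)


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class EffectEstimate:
    """A treatment-effect estimate on the natural-log risk-ratio scale.

    Parameters
    ----------
    beta
        ``ln(RR)``; the package does all arithmetic on this scale.
    info
        Optional diagnostics attached by the estimator (dropped strata,
        stratum counts, ...); never consulted by the algebra.
    """

    beta: float
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        _check_finite("beta", self.beta)

    @classmethod
    def from_rr(cls, rr: float) -> "EffectEstimate":
        rr = float(rr)
        if not (rr > 0 and math.isfinite(rr)):
            raise DomainError(f"risk ratio must be a positive finite number, got {rr!r}")
        return cls(beta=math.log(rr))

    @property
    def rr(self) -> float:
        """The estimate as a risk ratio, ``exp(beta)``."""
        return math.exp(self.beta)


@dataclass(frozen=True)
class AmplificationPair:
    """Exposure-model R² for the nested pair (Model 1, Model 2)."""

    r2_m1: float
    r2_m2: float

    def __post_init__(self) -> None:
        for name, r2 in (("r2_m1", self.r2_m1), ("r2_m2", self.r2_m2)):
            r2 = _check_finite(name, r2)
            if not (0.0 <= r2 < 1.0):
                raise DomainError(f"{name} must lie in [0, 1), got {r2}")

    @property
    def ratio(self) -> float:
        """Proportional confounding amplification of Model 2 relative to
        Model 1, ``(1/(1-R²_M2)) / (1/(1-R²_M1))``."""
        return model_amplification(self.r2_m2) / model_amplification(self.r2_m1)

    @property
    def increment(self) -> float:
        """``ratio - 1``; see :func:`amplification_increment`."""
        return amplification_increment(self)

    def outside_validated_range(self) -> bool:
        lo, hi = R2_VALIDATED_RANGE
        return not (lo <= self.r2_m1 <= hi and lo <= self.r2_m2 <= hi)


@dataclass(frozen=True)
class BrossTerm:
    """Inputs to the Bross bias factor for one binary confounder.

    ``prev_treated`` / ``prev_comparison`` are the confounder's prevalences
    in the treated and comparison arms (raw, or weighted within propensity
    strata); ``rr_iv_outcome`` is its risk ratio for the outcome from a
    multivariate regression.
    """

    prev_treated: float
    prev_comparison: float
    rr_iv_outcome: float

    def __post_init__(self) -> None:
        for name, p in (("prev_treated", self.prev_treated),
                        ("prev_comparison", self.prev_comparison)):
            p = _check_finite(name, p)
            if not (0.0 <= p <= 1.0):
                raise DomainError(f"{name} must lie in [0, 1], got {p}")
        rr = _check_finite("rr_iv_outcome", self.rr_iv_outcome)
        if rr <= 0:
            raise DomainError(f"rr_iv_outcome must be > 0, got {rr}")


@dataclass(frozen=True)
class AcceInputs:
    """Every term of the summary equation, ready for :func:`unconfounded_tee`.

    ``conf_iv_delta`` is the change in Introduced-Variable confounding from
    Model 1 to Model 2 (Model 2 term minus Model 1 term; negative when
    balance improves for an RR>1, treated-excess variable) and
    ``conf_iv_m1`` its Model 1 confounding relative to perfect balance.
    """

    tee_m1: EffectEstimate
    tee_m2: EffectEstimate
    amp: AmplificationPair
    conf_iv_delta: float = 0.0
    conf_iv_m1: float = 0.0
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        _check_finite("conf_iv_delta", self.conf_iv_delta)
        _check_finite("conf_iv_m1", self.conf_iv_m1)


@dataclass(frozen=True)
class ProbeThresholds:
    """Cutoffs on ``|Δbeta|`` for the qualitative probe.

    Defaults: a change below 0.01 is negligible ("no change"), below 0.05
    small, at or above 0.05 sizeable.  There are no canonical values; these
    bracket the published probe readings (a "small" change of ≈0.024 and a
    "sizeable" one of ≈0.097) and are configurable.
    """

    negligible: float = 0.01
    small: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.negligible <= self.small):
            raise DomainError(
                f"thresholds must satisfy 0 <= negligible <= small, "
                f"got {self.negligible}, {self.small}"
            )


Direction = Literal["toward_null", "away_from_null", "no_change"]
Magnitude = Literal["negligible", "small", "sizeable"]


@dataclass(frozen=True)
class ProbeClassification:
    """Qualitative reading of the Model 1 → Model 2 change.

    Because amplification pushes the estimate *further in the direction of
    its residual confounding*, a change away from the null flags residual
    confounding in that direction; its size tracks the amount.
    """

    direction: Direction
    magnitude: Magnitude
    delta_beta: float
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class AcceResult:
    """Output of the summary equation (all on the log-RR scale)."""

    amplifiable_confounding: float      # x
    conf_iv_m1: float                   # y
    total_residual_confounding: float   # x + y
    unconfounded_tee: float             # k = beta_M1 - (x + y)
    qualitative: ProbeClassification
    inputs: AcceInputs
    warnings: tuple[str, ...] = ()

    @property
    def unconfounded_rr(self) -> float:
        return math.exp(self.unconfounded_tee)


# ---------------------------------------------------------------------------
# elementary operations

def model_amplification(r2: float) -> float:
    """Confounding-amplification multiplier ``1/(1-R²)`` of a single model.

    Relative to a hypothetical model with no exposure prediction, a linear
    propensity score explaining a fraction ``r2`` of exposure variance is
    expected to amplify residual confounding ``1/(1-r2)``-fold.

    >>> model_amplification(0.5)
    2.0
    """
    r2 = _check_finite("r2", r2)
    if not (0.0 <= r2 < 1.0):
        raise DomainError(f"amplification undefined for r2={r2}; need 0 <= r2 < 1")
    return 1.0 / (1.0 - r2)


def amplification_increment(amp: AmplificationPair) -> float:
    """Between-model amplification expressed as an increment.

    ``(1/(1-R²_M2))/(1/(1-R²_M1)) - 1``, algebraically
    ``(R²_M2 - R²_M1)/(1 - R²_M2)``.  The adjusted change in the treatment
    effect estimate equals this increment times the amplifiable confounding
    ``x``, so dividing by it back-extrapolates to ``x``.  Zero when the two
    models predict exposure equally (no amplification, nothing to divide by).
    """
    return model_amplification(amp.r2_m2) / model_amplification(amp.r2_m1) - 1.0


def _require_positive_increment(amp: AmplificationPair) -> float:
    inc = amplification_increment(amp)
    if inc <= 0.0:
        raise ExtrapolationInvalidError(
            f"between-model amplification increment is {inc:.6g} "
            f"(R² {amp.r2_m1:.4g} -> {amp.r2_m2:.4g}); back-extrapolation "
            "requires Model 2 to predict exposure strictly better than Model 1"
        )
    return inc


def bross_log_confounding(term: BrossTerm) -> float:
    """Confounding attributable to one binary confounder, as ``ln B``.

    Bross bias factor ``B = (1 + p_t(RR-1)) / (1 + p_c(RR-1))``: the ratio
    by which a confounder with outcome risk ratio ``RR`` and arm prevalences
    ``p_t``/``p_c`` distorts the crude treatment-outcome risk ratio.  Zero
    when the arms are balanced or the confounder is outcome-neutral;
    swapping the prevalences flips the sign.
    """
    excess = term.rr_iv_outcome - 1.0
    num = 1.0 + term.prev_treated * excess
    den = 1.0 + term.prev_comparison * excess
    if num <= 0.0 or den <= 0.0:
        raise DomainError(
            f"Bross bias factor undefined: 1 + p(RR-1) must stay positive, "
            f"got numerator {num:.6g}, denominator {den:.6g}"
        )
    return math.log(num) - math.log(den)


def delta_iv_confounding(balance_m1: BrossTerm, balance_m2: BrossTerm) -> float:
    """Change in Introduced-Variable confounding, Model 2 minus Model 1.

    Both terms must share the same outcome risk ratio (the coefficient is a
    property of the variable, the balances of the models).  Negative when
    Model 2 improves the balance of an RR>1, treated-excess variable — the
    balancing alone would *decrease* the effect estimate, which must be
    netted out before attributing the remaining change to amplification.
    """
    if not math.isclose(balance_m1.rr_iv_outcome, balance_m2.rr_iv_outcome,
                        rel_tol=0.0, abs_tol=1e-12):
        raise DomainError(
            "balance_m1 and balance_m2 must share the same rr_iv_outcome; got "
            f"{balance_m1.rr_iv_outcome!r} and {balance_m2.rr_iv_outcome!r}"
        )
    return bross_log_confounding(balance_m2) - bross_log_confounding(balance_m1)


def adjusted_delta_tee(tee_m1: EffectEstimate, tee_m2: EffectEstimate,
                       conf_iv_delta: float = 0.0) -> float:
    """Between-model change attributable to amplification alone:
    ``(beta_M2 - beta_M1) - Conf_IntV_Δ(M2-M1)``."""
    return tee_m2.beta - tee_m1.beta - _check_finite("conf_iv_delta", conf_iv_delta)


def amplifiable_confounding(adj_delta: float, amp: AmplificationPair) -> float:
    """Back-extrapolated Model 1 confounding of the amplifiable fraction:
    ``x = AdjΔTEE / (A - 1)`` with ``A`` the between-model amplification
    ratio.  Raises :class:`ExtrapolationInvalidError` when the increment
    ``A - 1`` is not positive."""
    inc = _require_positive_increment(amp)
    return _check_finite("adj_delta", adj_delta) / inc


def unconfounded_tee(inputs: AcceInputs,
                     thresholds: ProbeThresholds | None = None) -> AcceResult:
    """Evaluate the full summary equation.

    ``k = beta_M1 - x - Conf_IntV_M1`` with
    ``x = [(beta_M2 - beta_M1) - Conf_IntV_Δ] / (A - 1)``.

    Returns the amplifiable confounding ``x``, the total residual
    confounding ``x + Conf_IntV_M1``, the unconfounded effect ``k``, the
    qualitative probe classification of the raw Model 1 → Model 2 change,
    and non-fatal warnings (currently: either R² outside the
    simulation-validated range ``[0.04, 0.56]``).
    """
    adj = adjusted_delta_tee(inputs.tee_m1, inputs.tee_m2, inputs.conf_iv_delta)
    x = amplifiable_confounding(adj, inputs.amp)
    total = x + inputs.conf_iv_m1
    k = inputs.tee_m1.beta - total
    warnings: list[str] = []
    if inputs.amp.outside_validated_range():
        lo, hi = R2_VALIDATED_RANGE
        warnings.append(
            f"R² pair ({inputs.amp.r2_m1:.4g}, {inputs.amp.r2_m2:.4g}) falls "
            f"outside [{lo}, {hi}], the range over which the 1/(1-R²) "
            "amplification law has simulation support; the quantitative "
            "extrapolation is unvalidated there"
        )
    qual = qualitative_probe(inputs.tee_m1, inputs.tee_m2, thresholds)
    return AcceResult(
        amplifiable_confounding=x,
        conf_iv_m1=inputs.conf_iv_m1,
        total_residual_confounding=total,
        unconfounded_tee=k,
        qualitative=qual,
        inputs=inputs,
        warnings=tuple(warnings),
    )


def qualitative_probe(tee_m1: EffectEstimate, tee_m2: EffectEstimate,
                      thresholds: ProbeThresholds | None = None) -> ProbeClassification:
    """Classify the Model 1 → Model 2 change in size and direction.

    The probe needs no R² values: amplification moves the estimate further
    in the direction of its residual confounding, so a change *away from the
    null* (same sign as the Model 1 beta) indicates confounding biasing the
    estimate away from the null, and vice versa.  Magnitude is binned by
    ``|Δbeta|`` against the configured cutoffs.
    """
    t = thresholds or ProbeThresholds()
    delta = tee_m2.beta - tee_m1.beta
    warnings: tuple[str, ...] = ()
    if abs(delta) < t.negligible:
        direction: Direction = "no_change"
    elif tee_m1.beta == 0.0:
        direction = "away_from_null"
        warnings = ("Model 1 estimate is exactly null; any change is "
                    "classified as away from the null",)
    elif math.copysign(1.0, delta) == math.copysign(1.0, tee_m1.beta):
        direction = "away_from_null"
    else:
        direction = "toward_null"
    if abs(delta) < t.negligible:
        magnitude: Magnitude = "negligible"
    elif abs(delta) < t.small:
        magnitude = "small"
    else:
        magnitude = "sizeable"
    return ProbeClassification(direction=direction, magnitude=magnitude,
                               delta_beta=delta, warnings=warnings)


# ---------------------------------------------------------------------------
# audit display

def worked_chain(inputs: AcceInputs, decimals: int = 4) -> dict[str, float]:
    """The summary equation as a desk-calculation audit trail.

    Recomputes every intermediate with each step rounded to ``decimals``
    places before the next, the way the method's worked examples are
    carried out by hand.  Full-precision results come from
    :func:`unconfounded_tee`; this chain exists so a report can be checked
    line-by-line against a hand calculation at the printed precision.
    """
    rnd = lambda v: round(v, decimals)  # noqa: E731
    delta_tee = rnd(inputs.tee_m2.beta - inputs.tee_m1.beta)
    conf_delta = rnd(inputs.conf_iv_delta)
    adj = rnd(delta_tee - conf_delta)
    inc = rnd(_require_positive_increment(inputs.amp))
    x = rnd(adj / inc)
    y = rnd(inputs.conf_iv_m1)
    total = rnd(x + y)
    k = rnd(rnd(inputs.tee_m1.beta) - total)
    return {
        "TEE_M1": rnd(inputs.tee_m1.beta),
        "TEE_M2": rnd(inputs.tee_m2.beta),
        "delta_TEE": delta_tee,
        "Conf_IntV_delta": conf_delta,
        "Adj_delta_TEE": adj,
        "amplification_increment": inc,
        "x": x,
        "Conf_IntV_M1": y,
        "total_residual_confounding": total,
        "unconfounded_TEE": k,
    }


def summary_equation_terms(result: AcceResult) -> dict[str, float]:
    """Full-precision named terms of the summary equation, for reports."""
    i = result.inputs
    return {
        "TEE_M1": i.tee_m1.beta,
        "TEE_M2": i.tee_m2.beta,
        "R2_M1": i.amp.r2_m1,
        "R2_M2": i.amp.r2_m2,
        "amplification_ratio": i.amp.ratio,
        "amplification_increment": i.amp.increment,
        "Conf_IntV_delta": i.conf_iv_delta,
        "Conf_IntV_M1": i.conf_iv_m1,
        "Adj_delta_TEE": adjusted_delta_tee(i.tee_m1, i.tee_m2, i.conf_iv_delta),
        "x": result.amplifiable_confounding,
        "total_residual_confounding": result.total_residual_confounding,
        "unconfounded_TEE": result.unconfounded_tee,
        "unconfounded_RR": result.unconfounded_rr,
    }


def combine_iv_terms(deltas: Sequence[float], m1_terms: Sequence[float]) -> tuple[float, float]:
    """Additive combination of per-Introduced-Variable Bross terms.

    With several Introduced Variables the confounding contributions are
    computed per variable from its marginal balance and summed; a joint
    treatment would need the variables' joint distribution, which the
    marginal balances do not determine.
    """
    return float(sum(deltas)), float(sum(m1_terms))
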