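"""ϕ-value, Brønsted and double-mutant-cycle thermodynamics.

A ϕ-value compares the effect of a point mutation on the association
transition state with its effect on the bound complex:

    ΔΔG_TS = RT·ln(kon_wt / kon_mt)
    ΔΔG_EQ = RT·ln(Kd_mt / Kd_wt),   Kd = koff/kon
    ϕ       = ΔΔG_TS / ΔΔG_EQ

With this sign convention a destabilizing mutation gives positive
ΔΔG values, which is the natural orientation for Brønsted plots
(ΔΔG_TS against ΔΔG_EQ, slope = average ϕ). ϕ ≈ 0 means the residue's
native contacts form after the rate-limiting barrier; ϕ ≈ 1 means they
are fully formed in the transition state.

Kd is always recomputed from the (unrounded) koff/kon of a record,
never read from a rounded Kd column — this is what reproduces the
published ϕ-values from the published rate constants.

Standard errors are propagated to first order treating the four rate
constants (kon, koff of mutant and wild type) as independent; the
correlation between Kd and kon induced by sharing kon is handled
analytically through the log-ratio derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import Constants, DEFAULT_CONSTANTS

__all__ = [
    "RateRecord",
    "PhiResult",
    "BronstedFit",
    "CouplingCycle",
    "ddG_ts",
    "ddG_eq",
    "phi",
    "classify_phi",
    "bronsted",
    "coupling_energy",
    "DEFAULT_RELIABILITY_THRESHOLD",
]

#: |ΔΔG_EQ| below which a ϕ-value is flagged unreliable (kcal/mol, ≈0.25·RT).
DEFAULT_RELIABILITY_THRESHOLD = 0.14

STATUS_VALUES = ("ok", "too_unstable", "too_fast")
KOFF_SOURCES = ("binding_fit", "displacement")


@dataclass
class RateRecord:
    """Fitted rate constants for one mutant complex.

    kon in µM⁻¹s⁻¹, koff in s⁻¹, each with a standard error.
    ``koff_source`` records whether koff came from the global binding
    fit or from a separate displacement experiment.
    """

    complex_id: str
    ncbd_variant: str = ""
    cid_variant: str = ""
    probe: str = ""
    condition: str = ""
    kon: float | None = None
    kon_se: float | None = None
    koff: float | None = None
    koff_se: float | None = None
    koff_source: str = "binding_fit"
    status: str = "ok"
    group: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUS_VALUES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "ok":
            if self.kon is None or self.koff is None:
                raise ValueError(f"{self.complex_id}: status ok requires kon and koff")
            if self.kon <= 0 or self.koff <= 0:
                raise ValueError(f"{self.complex_id}: rate constants must be positive")
            if self.koff_source not in KOFF_SOURCES:
                raise ValueError(f"unknown koff_source {self.koff_source!r}")

    @property
    def Kd(self) -> float:
        """Dissociation constant koff/kon in µM, from unrounded rates."""
        if self.status != "ok":
            raise ValueError(f"{self.complex_id}: no rates (status {self.status})")
        return self.koff / self.kon

    @property
    def Kd_se(self) -> float | None:
        if self.kon_se is None or self.koff_se is None:
            return None
        return self.Kd * np.hypot(self.kon_se / self.kon, self.koff_se / self.koff)


@dataclass
class PhiResult:
    ddG_TS: float
    ddG_TS_se: float | None
    ddG_EQ: float
    ddG_EQ_se: float | None
    phi: float | None
    phi_se: float | None
    reliable: bool
    category: str  # negative | low | intermediate | high | undefined
    mutant_id: str = ""
    wt_id: str = ""


@dataclass
class BronstedFit:
    """Linear free-energy relationship over a set of mutants."""

    points: list[tuple[float, float]]  # (ddG_EQ, ddG_TS)
    point_errors: list[tuple[float | None, float | None]]
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    group: str = ""
    labels: list[str] = field(default_factory=list)
    degenerate: bool = False


@dataclass
class CouplingCycle:
    """Double-mutant thermodynamic cycle (all Kd in µM)."""

    Kd_wt: float
    Kd_mutA: float
    Kd_mutB: float
    Kd_double: float
    Kd_wt_se: float | None = None
    Kd_mutA_se: float | None = None
    Kd_mutB_se: float | None = None
    Kd_double_se: float | None = None

    def __post_init__(self) -> None:
        for name in ("Kd_wt", "Kd_mutA", "Kd_mutB", "Kd_double"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValueError(f"{name} must be a positive Kd, got {v}")


def _check_comparable(mut: RateRecord, wt: RateRecord, allow_mismatch: bool) -> None:
    for rec in (mut, wt):
        if rec.status != "ok":
            raise ValueError(f"{rec.complex_id}: status {rec.status!r}, no rates")
    if not allow_mismatch:
        if mut.probe != wt.probe:
            raise ValueError(
                f"probe mismatch: {mut.probe!r} vs {wt.probe!r} "
                "(pass allow_mismatch=True to override)"
            )
        if mut.condition != wt.condition:
            raise ValueError(
                f"condition mismatch: {mut.condition!r} vs {wt.condition!r} "
                "(pass allow_mismatch=True to override)"
            )


def ddG_ts(
    mut: RateRecord,
    wt: RateRecord,
    constants: Constants = DEFAULT_CONSTANTS,
    allow_mismatch: bool = False,
) -> tuple[float, float | None]:
    """Change in activation free energy of association, kcal/mol.

    RT·ln(kon_wt/kon_mt); positive when the mutation slows association.
    """
    _check_comparable(mut, wt, allow_mismatch)
    value = constants.RT * np.log(wt.kon / mut.kon)
    se = None
    if mut.kon_se is not None and wt.kon_se is not None:
        se = constants.RT * np.hypot(mut.kon_se / mut.kon, wt.kon_se / wt.kon)
    return float(value), se


def ddG_eq(
    mut: RateRecord,
    wt: RateRecord,
    constants: Constants = DEFAULT_CONSTANTS,
    allow_mismatch: bool = False,
) -> tuple[float, float | None]:
    """Change in overall binding free energy, kcal/mol.

    RT·ln(Kd_mt/Kd_wt) with Kd = koff/kon from unrounded record values;
    positive when the mutation destabilizes the complex.
    """
    _check_comparable(mut, wt, allow_mismatch)
    value = constants.RT * np.log((mut.koff / mut.kon) / (wt.koff / wt.kon))
    se = None
    ses = (mut.kon_se, mut.koff_se, wt.kon_se, wt.koff_se)
    if all(s is not None for s in ses):
        rel = [
            mut.kon_se / mut.kon,
            mut.koff_se / mut.koff,
            wt.kon_se / wt.kon,
            wt.koff_se / wt.koff,
        ]
        se = constants.RT * float(np.sqrt(np.sum(np.square(rel))))
    return float(value), se


def classify_phi(value: float) -> str:
    """Category boundaries: <0 negative, [0,0.3) low, [0.3,0.9] intermediate, >0.9 high."""
    if value < 0:
        return "negative"
    if value < 0.3:
        return "low"
    if value <= 0.9:
        return "intermediate"
    return "high"


def phi(
    mut: RateRecord,
    wt: RateRecord,
    constants: Constants = DEFAULT_CONSTANTS,
    reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
    allow_mismatch: bool = False,
    error_model: str = "independent",
) -> PhiResult:
    """Compute the ϕ-value for one mutant against its reference complex.

    ϕ = ΔΔG_TS/ΔΔG_EQ reduces to a ratio of log rate ratios, so it is
    independent of RT. When |ΔΔG_EQ| falls below the reliability
    threshold the ratio is numerically unstable and the result is
    flagged; an exactly zero ΔΔG_EQ leaves ϕ undefined.

    Error models: ``independent`` (default) propagates ΔΔG_TS and
    ΔΔG_EQ as if uncorrelated — the convention behind the published
    ϕ errors, which it reproduces; ``correlated`` applies the full
    delta method in log-rate space, accounting for the shared kon
    terms (it gives markedly smaller errors near ϕ = 1, where the
    kon contributions to numerator and denominator cancel).
    """
    gts, gts_se = ddG_ts(mut, wt, constants, allow_mismatch)
    geq, geq_se = ddG_eq(mut, wt, constants, allow_mismatch)

    if geq == 0.0:
        return PhiResult(gts, gts_se, geq, geq_se, None, None, False, "undefined",
                         mut.complex_id, wt.complex_id)

    L_ts = gts / constants.RT
    L_eq = geq / constants.RT
    value = L_ts / L_eq

    phi_se = None
    ses = (mut.kon_se, mut.koff_se, wt.kon_se, wt.koff_se)
    if all(s is not None for s in ses):
        if error_model == "independent":
            phi_se = float(
                abs(value) * np.hypot(gts_se / gts if gts != 0 else 0.0,
                                      geq_se / geq)
            ) if gts != 0 else float(gts_se / abs(geq))
        elif error_model == "correlated":
            d_lnkon_mt = (L_ts - L_eq) / L_eq**2
            d_lnkon_wt = (L_eq - L_ts) / L_eq**2
            d_lnkoff_mt = -L_ts / L_eq**2
            d_lnkoff_wt = L_ts / L_eq**2
            rel = np.array(
                [mut.kon_se / mut.kon, mut.koff_se / mut.koff,
                 wt.kon_se / wt.kon, wt.koff_se / wt.koff]
            )
            grads = np.array([d_lnkon_mt, d_lnkoff_mt, d_lnkon_wt, d_lnkoff_wt])
            phi_se = float(np.sqrt(np.sum((grads * rel) ** 2)))
        else:
            raise ValueError(f"unknown error model {error_model!r}")

    reliable = abs(geq) >= reliability_threshold
    return PhiResult(
        ddG_TS=gts,
        ddG_TS_se=gts_se,
        ddG_EQ=geq,
        ddG_EQ_se=geq_se,
        phi=float(value),
        phi_se=phi_se,
        reliable=reliable,
        category=classify_phi(value),
        mutant_id=mut.complex_id,
        wt_id=wt.complex_id,
    )


def bronsted(
    records: list[RateRecord],
    wt: RateRecord,
    constants: Constants = DEFAULT_CONSTANTS,
    group: str = "",
    weighted: bool = False,
    through_origin: bool = False,
    allow_mismatch: bool = False,
) -> BronstedFit:
    """Fit ΔΔG_TS against ΔΔG_EQ by linear regression.

    The default is ordinary (unweighted) least squares with a free
    intercept; the slope is interpretable as the group-average ϕ.
    Weighted and through-origin variants are exposed as options. A fit
    over an x-range narrower than 0.1 kcal/mol is flagged degenerate.
    """
    if len(records) < 3:
        raise ValueError(f"Brønsted fit requires >= 3 records, got {len(records)}")
    xs, ys, errs, labels = [], [], [], []
    for rec in records:
        gts, gts_se = ddG_ts(rec, wt, constants, allow_mismatch)
        geq, geq_se = ddG_eq(rec, wt, constants, allow_mismatch)
        xs.append(geq)
        ys.append(gts)
        errs.append((geq_se, gts_se))
        labels.append(rec.complex_id)
    x = np.array(xs)
    y = np.array(ys)
    degenerate = float(np.ptp(x)) < 0.1

    if through_origin:
        w = np.ones_like(y)
        if weighted:
            w = np.array([1.0 / (e[1] or 1.0) ** 2 for e in errs])
        slope = float(np.sum(w * x * y) / np.sum(w * x * x))
        resid = y - slope * x
        dof = max(len(x) - 1, 1)
        slope_se = float(
            np.sqrt(np.sum(w * resid**2) / dof / np.sum(w * x * x))
        )
        intercept, intercept_se = 0.0, 0.0
    elif weighted:
        w = np.array([1.0 / (e[1] or 1.0) ** 2 for e in errs])
        W = np.diag(w)
        X = np.column_stack([x, np.ones_like(x)])
        cov = np.linalg.inv(X.T @ W @ X)
        beta = cov @ X.T @ W @ y
        resid = y - X @ beta
        s2 = float(resid @ (w * resid)) / max(len(x) - 2, 1)
        slope, intercept = float(beta[0]), float(beta[1])
        slope_se = float(np.sqrt(cov[0, 0] * s2))
        intercept_se = float(np.sqrt(cov[1, 1] * s2))
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        slope_se, intercept_se = float(res.stderr), float(res.intercept_stderr)

    return BronstedFit(
        points=list(zip(xs, ys)),
        point_errors=errs,
        slope=slope,
        slope_se=slope_se,
        intercept=intercept,
        intercept_se=intercept_se,
        group=group,
        labels=labels,
        degenerate=degenerate,
    )


def coupling_energy(
    cycle: CouplingCycle, constants: Constants = DEFAULT_CONSTANTS
) -> tuple[float, float | None]:
    """Double-mutant-cycle interaction free energy, kcal/mol.

    ΔΔG_coupling = RT·ln[(Kd_wt·Kd_double)/(Kd_mutA·Kd_mutB)];
    zero for thermodynamically additive mutations, symmetric under
    exchange of the two single mutants.
    """
    value = constants.RT * np.log(
        (cycle.Kd_wt * cycle.Kd_double) / (cycle.Kd_mutA * cycle.Kd_mutB)
    )
    se = None
    ses = (cycle.Kd_wt_se, cycle.Kd_mutA_se, cycle.Kd_mutB_se, cycle.Kd_double_se)
    kds = (cycle.Kd_wt, cycle.Kd_mutA, cycle.Kd_mutB, cycle.Kd_double)
    if all(s is not None for s in ses):
        rel = [s / k for s, k in zip(ses, kds)]
        se = constants.RT * float(np.sqrt(np.sum(np.square(rel))))
    return float(value), se
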