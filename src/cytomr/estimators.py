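"""Wald-ratio, inverse-variance-weighted and MR-Egger causal estimators.

Notation: for instrument j, β̂_xj is the SNP-exposure effect (SD units),
β̂_yj the SNP-outcome effect (log-odds), σ_yj its standard error, and
w_j = 1/σ_yj² the outcome-precision weight.

* Wald ratio: β̂ = β̂_y / β̂_x with first-order delta-method SE σ_y/|β̂_x|.
* IVW: the fixed-effect precision-weighted combination of Wald ratios,
  algebraically the origin-constrained weighted regression of β̂_y on β̂_x,
  β̂ = Σ w_j β̂_xj β̂_yj / Σ w_j β̂_xj², SE = (Σ w_j β̂_xj²)^{-1/2}.
* MR-Egger: weighted least squares of β̂_y on β̂_x with a free intercept;
  the slope estimates the causal effect and the intercept the average
  directional pleiotropy, consistent when instrument strength is
  independent of direct effects (the InSIDE assumption). Exposure effects
  are oriented non-negative before fitting (the conventional Egger
  orientation; it fixes the intercept's sign, not its magnitude).
  Inference uses the t distribution with m − 2 degrees of freedom and the
  residual-scaled WLS covariance. Egger is only defined here for three or
  more instruments.

Causal effects are reported per SD of the exposure on the log-odds scale,
with exp-transformed odds ratios alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from cytomr.exceptions import InsufficientInstrumentsError, UndefinedRatioError
from cytomr.harmonize import HarmonizedSet

MIN_EGGER_SNPS = 3


@dataclass
class MREstimate:
    """One causal estimate with normal/t CI, two-tailed p and OR scale."""

    method: str  # "wald" | "ivw" | "egger_slope" | "egger_intercept"
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    ci_level: float = 0.95
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.or_ is None:
            self.or_ = math.exp(self.beta)
            self.or_ci_low = math.exp(self.ci_low)
            self.or_ci_high = math.exp(self.ci_high)


@dataclass
class MRResult:
    """All estimates for one biomarker, with the Egger eligibility decision."""

    biomarker: str
    estimates: list[MREstimate] = field(default_factory=list)
    egger_performed: bool = False
    egger_reason: str = ""

    def get(self, method: str) -> MREstimate | None:
        for e in self.estimates:
            if e.method == method:
                return e
        return None


def _finish(method: str, beta: float, se: float, n_snps: int, ci_level: float,
            df: float | None = None) -> MREstimate:
    """CI and two-tailed p from a point estimate and SE.

    ``df=None`` uses the normal reference distribution, otherwise t(df).
    """
    dist = stats.norm if df is None else stats.t(df)
    crit = dist.ppf(0.5 + ci_level / 2.0)
    z = beta / se if se > 0.0 else math.copysign(math.inf, beta) if beta else 0.0
    p = float(min(1.0, 2.0 * dist.sf(abs(z))))
    p = max(p, 5e-324)  # keep within (0, 1] under extreme z
    return MREstimate(method, beta, se, beta - crit * se, beta + crit * se, p, n_snps, ci_level)


def wald_ratio(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
    ci_level: float = 0.95,
) -> MREstimate:
    """Single-SNP causal estimate β̂_y/β̂_x with first-order delta SE.

    The first-order SE σ_y/|β̂_x| ignores the exposure-side uncertainty,
    the standard two-sample convention (the second-order term adds
    β̂_y²σ_x²/β̂_x⁴ under the radical and is negligible for strong
    instruments).
    """
    if beta_exposure == 0.0:
        raise UndefinedRatioError("Wald ratio undefined: SNP-exposure effect is zero")
    beta = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    return _finish("wald", beta, se, 1, ci_level)


def ivw_arrays(
    beta_exposure: np.ndarray,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
    ci_level: float = 0.95,
    random_effects: bool = False,
) -> MREstimate:
    """IVW on raw effect arrays (fast path used by simulations).

    ``random_effects=True`` applies multiplicative overdispersion scaling:
    the SE is inflated by max(1, √(RSS/(m−1))) where RSS is the weighted
    residual sum of squares of the origin-constrained fit.
    """
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    if bx.size == 0:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    if bx.size == 1:
        # Degenerate case: exactly the Wald ratio (computed in ratio form so
        # the equivalence holds to the last bit).
        if bx[0] == 0.0:
            raise UndefinedRatioError("IVW with one instrument of zero exposure effect")
        e = _finish("ivw", float(by[0] / bx[0]), float(sy[0] / abs(bx[0])), 1, ci_level)
        return e
    w = 1.0 / (sy * sy)
    denom = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / denom
    se = 1.0 / math.sqrt(denom)
    if random_effects and bx.size > 1:
        rss = float(np.sum(w * (by - beta * bx) ** 2))
        phi = max(1.0, rss / (bx.size - 1))
        se *= math.sqrt(phi)
    return _finish("ivw", beta, se, int(bx.size), ci_level)


def ivw(h: HarmonizedSet, ci_level: float = 0.95, random_effects: bool = False) -> MREstimate:
    """Fixed-effect IVW estimate from a harmonized set.

    With a single instrument this reduces exactly to the Wald ratio.
    """
    bx, _, by, sy = h.arrays()
    return ivw_arrays(bx, by, sy, ci_level, random_effects)


def egger_arrays(
    beta_exposure: np.ndarray,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
    ci_level: float = 0.95,
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger WLS on raw arrays; returns (slope, intercept) estimates."""
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    m = bx.size
    if m < MIN_EGGER_SNPS:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires at least {MIN_EGGER_SNPS} instruments; got {m} "
            "(the regression loses two degrees of freedom to slope and intercept)"
        )
    # Orient all exposure effects non-negative, flipping the paired outcome
    # effect; the intercept then measures pleiotropy in the direction of
    # exposure-increasing alleles.
    sign = np.where(bx < 0.0, -1.0, 1.0)
    bx, by = sign * bx, sign * by
    w = 1.0 / (sy * sy)
    # Weighted normal equations for y = a + b x.
    sw = float(np.sum(w))
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx * swx
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    sigma2 = float(np.sum(w * resid * resid)) / (m - 2)
    se_slope = math.sqrt(sigma2 * sw / det)
    se_intercept = math.sqrt(sigma2 * swxx / det)
    df = m - 2
    return (
        _finish("egger_slope", slope, se_slope, m, ci_level, df=df),
        _finish("egger_intercept", intercept, se_intercept, m, ci_level, df=df),
    )


def mr_egger(h: HarmonizedSet, ci_level: float = 0.95) -> tuple[MREstimate, MREstimate]:
    """MR-Egger (slope, intercept) from a harmonized set; needs ≥ 3 SNPs."""
    bx, _, by, sy = h.arrays()
    return egger_arrays(bx, by, sy, ci_level)


def to_or_scale(e: MREstimate) -> MREstimate:
    """Populate the odds-ratio fields as exp of the log-odds fields."""
    return replace(
        e,
        or_=math.exp(e.beta),
        or_ci_low=math.exp(e.ci_low),
        or_ci_high=math.exp(e.ci_high),
    )


def estimate_all(
    h: HarmonizedSet,
    methods: tuple[str, ...] = ("ivw", "egger"),
    ci_level: float = 0.95,
    min_egger_snps: int = MIN_EGGER_SNPS,
) -> MRResult:
    """Run the requested estimators, skipping Egger below the SNP minimum."""
    result = MRResult(h.biomarker)
    if "ivw" in methods:
        result.estimates.append(to_or_scale(ivw(h, ci_level)))
    if "egger" in methods:
        if len(h) >= min_egger_snps:
            slope, intercept = mr_egger(h, ci_level)
            result.estimates.extend([to_or_scale(slope), to_or_scale(intercept)])
            result.egger_performed = True
            result.egger_reason = f"{len(h)} instruments available"
        else:
            result.egger_performed = False
            result.egger_reason = (
                f"skipped: {len(h)} instrument(s) < required {min_egger_snps}"
            )
    return result
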