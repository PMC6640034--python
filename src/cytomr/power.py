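"""Power and minimum sample size for two-sample MR with a binary outcome.

Under the standard noncentrality approximation (the one behind the mRnd
web calculator), the Wald statistic of the IVW estimate is approximately
N(√λ, 1) with

    λ = n · R²_xz · (log OR)² · K(1 − K)

where n is the outcome-study sample size, R²_xz the fraction of exposure
variance explained by the instruments, OR the hypothesized causal odds
ratio per SD of exposure, and K the case fraction. Two-sided power at
level α is then Φ(−z_{1−α/2} + √λ) + Φ(−z_{1−α/2} − √λ), which equals α
at the null OR = 1 and increases monotonically in n, R²_xz and |log OR|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from cytomr.exceptions import InputError

#: Case/control totals of the stage-1 Alzheimer's GWAS meta-analysis used
#: as the outcome study (17 008 cases, 37 154 controls).
IGAP_CASES = 17008
IGAP_CONTROLS = 37154
DEFAULT_CASE_FRACTION = IGAP_CASES / (IGAP_CASES + IGAP_CONTROLS)


@dataclass
class PowerQuery:
    r2_xz: float
    or_per_sd: float
    n_outcome: int
    case_fraction: float = DEFAULT_CASE_FRACTION
    alpha: float = 0.05

    def validate(self) -> None:
        if not (0.0 < self.r2_xz < 1.0):
            raise InputError(f"r2_xz {self.r2_xz} outside (0, 1)")
        if not (self.or_per_sd > 0.0):
            raise InputError(f"or_per_sd {self.or_per_sd} must be > 0")
        if not (0.0 < self.case_fraction < 1.0):
            raise InputError(f"case_fraction {self.case_fraction} outside (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise InputError(f"alpha {self.alpha} outside (0, 1)")
        if self.n_outcome < 1:
            raise InputError(f"n_outcome {self.n_outcome} must be >= 1")


@dataclass
class PowerResult:
    power: float
    min_n_for_target: int | None = None
    target_power: float = 0.8


def _power(n: float, r2: float, log_or: float, k: float, alpha: float) -> float:
    lam = n * r2 * log_or * log_or * k * (1.0 - k)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    s = math.sqrt(lam)
    return float(stats.norm.cdf(-z + s) + stats.norm.cdf(-z - s))


def mr_power(q: PowerQuery, target_power: float | None = None) -> PowerResult:
    """Two-sided power of the MR Wald test at the query's parameters.

    If ``target_power`` is given (and the effect is non-null) the minimum
    outcome sample size reaching it is computed as well.
    """
    q.validate()
    power = _power(q.n_outcome, q.r2_xz, math.log(q.or_per_sd), q.case_fraction, q.alpha)
    result = PowerResult(power)
    if target_power is not None:
        result.target_power = target_power
        result.min_n_for_target = min_sample_size(q, target_power)
    return result


def min_sample_size(q: PowerQuery, target_power: float = 0.8) -> int:
    """Smallest outcome-study n with power ≥ ``target_power``.

    Undefined (raises) at the null OR = 1, where power never exceeds α.
    Any n suffices when the target does not exceed α (power ≥ α always).
    """
    q.validate()
    if not (0.0 < target_power < 1.0):
        raise InputError(f"target_power {target_power} outside (0, 1)")
    if q.or_per_sd == 1.0:
        raise InputError("minimum sample size undefined at the null (OR = 1)")
    log_or = math.log(q.or_per_sd)
    if target_power <= q.alpha:
        return 1
    # Invert power(√λ) for the required noncentrality, then convert to n.
    from scipy.optimize import brentq

    z = stats.norm.ppf(1.0 - q.alpha / 2.0)

    def gap(s: float) -> float:
        return float(stats.norm.cdf(-z + s) + stats.norm.cdf(-z - s)) - target_power

    s_star = brentq(gap, 0.0, 100.0)
    unit = q.r2_xz * log_or * log_or * q.case_fraction * (1.0 - q.case_fraction)
    n = max(1, math.ceil(s_star * s_star / unit))
    # Integer rounding can land one off; settle exactly.
    while n > 1 and _power(n - 1, q.r2_xz, log_or, q.case_fraction, q.alpha) >= target_power:
        n -= 1
    while _power(n, q.r2_xz, log_or, q.case_fraction, q.alpha) < target_power:
        n += 1
    return n
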