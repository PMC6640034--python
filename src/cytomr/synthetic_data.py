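"""Synthetic paired GWAS summary statistics with known ground truth.

The generator emulates the two-sample design the estimators consume: m
independent biallelic SNPs instrument a standardized continuous exposure
measured in one study, and a binary outcome (log-odds scale) measured in
another. Per SNP j with effect-allele frequency f_j ~ U(0.1, 0.9):

    true exposure effect   γ_j   (drawn, then rescaled so Σ 2γ_j²f_j(1−f_j)
                                  equals the target variance explained)
    pleiotropic effect     α_j ~ N(μ_α, σ_α²), with a configurable
                                  correlation to |γ_j| (0 ⇒ InSIDE holds)
    true outcome effect    Γ_j = θ·γ_j + α_j            (exactly)
    observed effects       β̂_xj ~ N(γ_j, se_xj²),  β̂_yj ~ N(Γ_j, se_yj²)
    se_xj = 1/√(2 n_x f_j(1−f_j)),  se_yj = 1/√(2 n_y K(1−K) f_j(1−f_j))

Outcome statistics are generated directly on the log-odds scale from this
linear approximation rather than by simulating individual-level
case-control data: the estimators only ever see summary statistics, so
the approximation error is irrelevant to testing their algebra.

After observation, optional corruptions emulate real-world allele-coding
hazards — allele-order swaps, strand flips (non-palindromic SNPs only),
variants missing from the outcome — and LD satellites can be injected for
clumping/proxy tests. Every corruption is recorded in the returned
:class:`SimulationTruth` so round-trip tests can assert exact recovery.

Default sample sizes mirror the motivating study design: ~12 000
exposure-study participants and an outcome case-control study of 54 162
with case fraction 0.314.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cytomr.exceptions import ConfigurationError
from cytomr.summary_io import (
    COMPLEMENT,
    LDTable,
    SummaryStatRecord,
    SummaryStatSet,
)

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and COMPLEMENT[a] != b
]


@dataclass
class CorruptionConfig:
    """Post-observation corruptions applied to the outcome dataset.

    Fractions are per-SNP Bernoulli probabilities, drawn in a fixed order
    (swap, flip, missing) from the simulation's single RNG stream. Strand
    flips are only applied to non-palindromic SNPs (on a palindromic SNP a
    strand flip is indistinguishable from an allele swap).
    """

    allele_swap_fraction: float = 0.0
    strand_flip_fraction: float = 0.0
    missing_fraction: float = 0.0


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic two-sample MR dataset.

    ``n_ld_partners`` injects that many satellite SNPs per index SNP, in
    LD r² ~ U(0.3, 0.95) with it (recorded in the LD table), present in
    both datasets with proportionally attenuated effects — fodder for
    clumping and proxy-substitution tests.
    """

    m: int = 10
    theta: float = 0.0
    r2_target: float = 0.03
    n_exposure: int = 12_000
    n_outcome: int = 54_162
    case_fraction: float = 0.314
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: float = 0.0
    palindromic_fraction: float = 0.2
    n_ld_partners: int = 0
    corruption: CorruptionConfig = field(default_factory=CorruptionConfig)
    seed: int = 0
    noise_scale: float = 1.0  # 0 ⇒ noiseless limit (observed == true effects)

    def validate(self) -> None:
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if not (0.0 < self.r2_target < 1.0):
            raise ConfigurationError(f"r2_target {self.r2_target} outside (0, 1)")
        for name in ("case_fraction",):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} {v} outside (0, 1)")
        for name in ("palindromic_fraction",):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} {v} outside [0, 1]")
        if not (-1.0 <= self.inside_violation <= 1.0):
            raise ConfigurationError("inside_violation outside [-1, 1]")


@dataclass
class SimulationTruth:
    """Ground truth attached to a synthetic dataset for recovery tests."""

    variant_ids: list[str]
    gamma: np.ndarray  # true SNP-exposure effects
    alpha: np.ndarray  # true pleiotropic (direct) effects
    theta: float
    eaf: np.ndarray
    allele_coding: dict[str, tuple[str, str]]  # pre-corruption (ea, oa)
    corruptions: dict[str, list[str]]  # variant_id -> applied corruption names
    satellites: dict[str, list[str]] = field(default_factory=dict)  # index -> satellite ids

    @property
    def gamma_outcome(self) -> np.ndarray:
        """True SNP-outcome effects Γ = θγ + α (exact by construction)."""
        return self.theta * self.gamma + self.alpha


@dataclass
class SimulatedStudy:
    exposure: SummaryStatSet
    outcome: SummaryStatSet
    ld: LDTable
    truth: SimulationTruth


def _pvalue(beta: float, se: float) -> float:
    from scipy import stats

    p = 2.0 * stats.norm.sf(abs(beta / se))
    return float(min(1.0, max(p, 5e-324)))


def simulate(config: SimulationConfig) -> SimulatedStudy:
    """Generate one synthetic exposure/outcome pair with known truth.

    Fully deterministic given ``config`` (single RNG stream seeded from
    ``config.seed``; draws are consumed in a fixed documented order:
    frequencies, alleles, γ, pleiotropy, observation noise, satellites,
    corruptions).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m
    k = config.case_fraction

    eaf = rng.uniform(0.1, 0.9, size=m)
    palindromic = rng.uniform(size=m) < config.palindromic_fraction
    pair_choice = rng.integers(0, 12, size=m)  # max of the two pool sizes
    alleles: list[tuple[str, str]] = []
    for j in range(m):
        pool = _PALINDROMIC_PAIRS if palindromic[j] else _NONPALINDROMIC_PAIRS
        alleles.append(pool[pair_choice[j] % len(pool)])

    # Effects are coded for the exposure-increasing allele (γ ≥ 0), the
    # frame in which directional pleiotropy (mean α ≠ 0) is well defined;
    # allele-coding corruptions below exercise the sign handling instead.
    # Relative strengths are uniform on [0.5, 1.5] before rescaling:
    # instruments model SNPs that passed genome-wide significance, whose
    # effects are bounded away from zero by selection.
    gamma = rng.uniform(0.5, 1.5, size=m)
    scale = np.sqrt(config.r2_target / np.sum(2.0 * gamma**2 * eaf * (1.0 - eaf)))
    gamma = gamma * scale

    z = rng.normal(size=m)
    if config.pleiotropy_sd > 0.0:
        rho = config.inside_violation
        g = np.abs(gamma)
        sd = g.std()
        u = (g - g.mean()) / sd if sd > 0 else np.zeros(m)
        alpha = config.pleiotropy_mean + config.pleiotropy_sd * (
            rho * u + np.sqrt(1.0 - rho * rho) * z
        )
    else:
        alpha = np.full(m, config.pleiotropy_mean)
    big_gamma = config.theta * gamma + alpha

    se_x = 1.0 / np.sqrt(2.0 * config.n_exposure * eaf * (1.0 - eaf))
    se_y = 1.0 / np.sqrt(2.0 * config.n_outcome * k * (1.0 - k) * eaf * (1.0 - eaf))
    noise_x = rng.normal(size=m)
    noise_y = rng.normal(size=m)
    beta_x = gamma + config.noise_scale * se_x * noise_x
    beta_y = big_gamma + config.noise_scale * se_y * noise_y

    variant_ids = [f"rs{1_000_000 + j}" for j in range(m)]
    exposure = SummaryStatSet("synthetic_exposure", "continuous")
    outcome = SummaryStatSet("synthetic_outcome", "binary")
    ld = LDTable()
    coding: dict[str, tuple[str, str]] = {}
    for j, vid in enumerate(variant_ids):
        ea, oa = alleles[j]
        coding[vid] = (ea, oa)
        common = dict(chromosome=str(j % 22 + 1), position=1_000_000 + 10_000 * j,
                      effect_allele=ea, other_allele=oa, eaf=float(eaf[j]))
        exposure.add(SummaryStatRecord(
            variant_id=vid, beta=float(beta_x[j]), se=float(se_x[j]),
            pvalue=_pvalue(beta_x[j], se_x[j]), n=float(config.n_exposure), **common))
        outcome.add(SummaryStatRecord(
            variant_id=vid, beta=float(beta_y[j]), se=float(se_y[j]),
            pvalue=_pvalue(beta_y[j], se_y[j]), n=float(config.n_outcome), **common))

    # LD satellites: weaker copies of each index SNP, linked in the LD table.
    satellites: dict[str, list[str]] = {}
    if config.n_ld_partners > 0:
        for j, vid in enumerate(variant_ids):
            sats = []
            for s in range(config.n_ld_partners):
                r2 = float(rng.uniform(0.3, 0.95))
                svid = f"{vid}_sat{s}"
                r = np.sqrt(r2)
                g_sat = r * gamma[j]
                gy_sat = config.theta * g_sat + alpha[j] * r
                bx = float(g_sat + config.noise_scale * se_x[j] * rng.normal())
                by = float(gy_sat + config.noise_scale * se_y[j] * rng.normal())
                ea, oa = alleles[j]
                common = dict(chromosome=str(j % 22 + 1),
                              position=1_000_000 + 10_000 * j + s + 1,
                              effect_allele=ea, other_allele=oa, eaf=float(eaf[j]))
                exposure.add(SummaryStatRecord(
                    variant_id=svid, beta=bx, se=float(se_x[j]),
                    pvalue=_pvalue(bx, se_x[j]), n=float(config.n_exposure), **common))
                outcome.add(SummaryStatRecord(
                    variant_id=svid, beta=by, se=float(se_y[j]),
                    pvalue=_pvalue(by, se_y[j]), n=float(config.n_outcome), **common))
                ld.add(vid, svid, r2)
                coding[svid] = (ea, oa)
                sats.append(svid)
            satellites[vid] = sats

    # Corruptions, in fixed order: allele swap, strand flip, missing.
    corr = config.corruption
    corruptions: dict[str, list[str]] = {}
    all_outcome_ids = list(outcome.records)
    swap_draw = rng.uniform(size=len(all_outcome_ids))
    flip_draw = rng.uniform(size=len(all_outcome_ids))
    miss_draw = rng.uniform(size=len(all_outcome_ids))
    for idx, vid in enumerate(all_outcome_ids):
        rec = outcome.records[vid]
        applied: list[str] = []
        if swap_draw[idx] < corr.allele_swap_fraction:
            outcome.records[vid] = replace(
                rec,
                effect_allele=rec.other_allele,
                other_allele=rec.effect_allele,
                beta=-rec.beta,
                eaf=1.0 - rec.eaf,
            )
            rec = outcome.records[vid]
            applied.append("allele_swap")
        if flip_draw[idx] < corr.strand_flip_fraction and not rec.is_palindromic:
            outcome.records[vid] = replace(
                rec,
                effect_allele=COMPLEMENT[rec.effect_allele],
                other_allele=COMPLEMENT[rec.other_allele],
            )
            applied.append("strand_flip")
        if miss_draw[idx] < corr.missing_fraction:
            del outcome.records[vid]
            applied.append("missing")
        if applied:
            corruptions[vid] = applied

    truth = SimulationTruth(
        variant_ids=variant_ids,
        gamma=gamma,
        alpha=alpha,
        theta=config.theta,
        eaf=eaf,
        allele_coding=coding,
        corruptions=corruptions,
        satellites=satellites,
    )
    return SimulatedStudy(exposure, outcome, ld, truth)
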