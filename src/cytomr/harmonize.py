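"""Harmonization of exposure and outcome summary statistics.

Two-sample MR combines SNP-exposure and SNP-outcome effects estimated in
different studies, which may report the same variant with respect to
different effect alleles or on opposite DNA strands. This module aligns
each exposure index SNP and its outcome record onto a common effect allele:

* same allele pair, swapped effect allele → flip the outcome beta's sign
  and replace its frequency by 1−eaf;
* reverse-complementary allele pair (strand difference, non-palindromic)
  → complement the outcome alleles, then align as above;
* palindromic variant (A/T or C/G; strand unresolvable from alleles alone)
  → orient by comparing which side of 0.5 the effect-allele frequency lies
  on in each study, unless either folded frequency is within an ambiguity
  window of 0.5, in which case the variant is dropped;
* variant absent from the outcome study → substitute the highest-r²
  available proxy with r² above a threshold (default > 0.8), else drop.

Every decision is recorded per variant and exposed as an audit table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cytomr.exceptions import InputError
from cytomr.instruments import InstrumentSet
from cytomr.summary_io import COMPLEMENT, LDTable, SummaryStatRecord, SummaryStatSet

logger = logging.getLogger(__name__)

DEFAULT_PROXY_R2 = 0.8
DEFAULT_PALINDROME_WINDOW = 0.08

#: Terminal actions a variant can end a harmonization pass with.
TERMINAL_ACTIONS = frozenset(
    {"kept", "flipped", "strand_swapped", "palindromic_aligned",
     "palindromic_dropped", "proxied", "dropped_unmatched"}
)


@dataclass
class Decision:
    action: str
    detail: str


@dataclass
class HarmonizedInstrument:
    """An exposure/outcome effect pair expressed on one common effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float
    eaf_outcome: float
    proxy_of: str | None = None
    decisions: list[Decision] = field(default_factory=list)

    @property
    def terminal_decision(self) -> str:
        return self.decisions[-1].action if self.decisions else "kept"


@dataclass
class HarmonizedSet:
    biomarker: str
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (variant_id, reason)

    def __len__(self) -> int:
        return len(self.instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) as arrays."""
        bx = np.array([h.beta_exposure for h in self.instruments])
        sx = np.array([h.se_exposure for h in self.instruments])
        by = np.array([h.beta_outcome for h in self.instruments])
        sy = np.array([h.se_outcome for h in self.instruments])
        return bx, sx, by, sy


def _is_palindromic_pair(ea: str, oa: str) -> bool:
    return COMPLEMENT[ea] == oa


def _align_pair(
    exp: SummaryStatRecord,
    out: SummaryStatRecord,
    palindrome_eaf_window: float,
) -> tuple[HarmonizedInstrument | None, str | None, list[Decision]]:
    """Align one exposure/outcome record pair onto the exposure's alleles.

    Returns (instrument, drop_reason, decisions); exactly one of instrument
    and drop_reason is non-None.
    """
    decisions: list[Decision] = []
    ea_x, oa_x = exp.effect_allele, exp.other_allele
    if oa_x is None:
        raise InputError(f"exposure SNP {exp.variant_id} is missing its other allele")
    if out.other_allele is None:
        return None, "outcome other allele unknown; strand unresolvable", decisions
    ea_y, oa_y = out.effect_allele, out.other_allele
    by, eaf_y = out.beta, out.eaf
    pair_x = {ea_x, oa_x}

    if _is_palindromic_pair(ea_x, oa_x):
        if {ea_y, oa_y} != pair_x:
            return None, f"allele mismatch ({ea_y}/{oa_y} vs {ea_x}/{oa_x})", decisions
        # Within the ambiguity window the frequency comparison cannot tell
        # the two strand interpretations apart: drop.
        if (
            abs(exp.eaf - 0.5) < palindrome_eaf_window
            or abs(eaf_y - 0.5) < palindrome_eaf_window
        ):
            decisions.append(
                Decision(
                    "palindromic_dropped",
                    f"folded eaf within {palindrome_eaf_window:g} of 0.5 "
                    f"(exposure {exp.eaf:.3f}, outcome {eaf_y:.3f})",
                )
            )
            return None, "palindromic, ambiguous allele frequency", decisions
        # Bring the outcome onto the exposure's effect-allele letter, then
        # require the frequencies to fall on the same side of 0.5; if they
        # do not, the studies reported opposite strands: flip.
        if ea_y != ea_x:
            by, eaf_y = -by, 1.0 - eaf_y
        if (exp.eaf - 0.5) * (eaf_y - 0.5) < 0.0:
            by, eaf_y = -by, 1.0 - eaf_y
            decisions.append(
                Decision("palindromic_aligned", "frequencies discordant; strand interpretation flipped")
            )
        else:
            decisions.append(
                Decision("palindromic_aligned", "frequencies concordant across studies")
            )
        inst = HarmonizedInstrument(
            exp.variant_id, ea_x, oa_x, exp.beta, exp.se, by, out.se,
            exp.eaf, eaf_y, decisions=decisions,
        )
        return inst, None, decisions

    # Non-palindromic: resolve strand first if needed.
    if {ea_y, oa_y} == pair_x:
        strand_swapped = False
    elif {COMPLEMENT[ea_y], COMPLEMENT[oa_y]} == pair_x:
        ea_y, oa_y = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
        strand_swapped = True
    else:
        return None, f"allele mismatch ({ea_y}/{oa_y} vs {ea_x}/{oa_x})", decisions
    if ea_y == oa_x:  # effect allele reported for the opposite allele
        by, eaf_y = -by, 1.0 - eaf_y
        action = "strand_swapped" if strand_swapped else "flipped"
        detail = "outcome effect allele was the exposure's other allele"
        if strand_swapped:
            detail = "opposite strand; " + detail
    else:
        action = "strand_swapped" if strand_swapped else "kept"
        detail = "opposite strand, same orientation" if strand_swapped else "same alleles, same orientation"
    decisions.append(Decision(action, detail))
    inst = HarmonizedInstrument(
        exp.variant_id, ea_x, oa_x, exp.beta, exp.se, by, out.se,
        exp.eaf, eaf_y, decisions=decisions,
    )
    return inst, None, decisions


def harmonize(
    exposure: InstrumentSet,
    outcome: SummaryStatSet,
    ld: LDTable | None = None,
    proxy_r2: float = DEFAULT_PROXY_R2,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW,
    exposure_full: SummaryStatSet | None = None,
) -> HarmonizedSet:
    """Harmonize an exposure instrument set against outcome summary stats.

    When an index SNP is absent from the outcome study, the LD table is
    searched for the highest-r² partner with r² strictly above ``proxy_r2``
    that is present in the outcome *and* (when ``exposure_full`` is given)
    in the exposure candidate set; the proxy's own statistics then stand in
    for the missing variant, recorded with ``proxy_of``. With no suitable
    proxy the variant is dropped as unmatched.

    ``palindrome_eaf_window = 0`` disables the ambiguity window, so every
    palindromic SNP is oriented purely by frequency comparison.
    """
    if not (0.0 < proxy_r2 <= 1.0):
        raise ValueError(f"proxy_r2 {proxy_r2} outside (0, 1]")
    if not (0.0 <= palindrome_eaf_window < 0.5):
        raise ValueError(f"palindrome_eaf_window {palindrome_eaf_window} outside [0, 0.5)")
    hset = HarmonizedSet(exposure.biomarker)
    for exp in exposure.index_snps:
        out = outcome.get(exp.variant_id)
        if out is not None:
            inst, reason, decisions = _align_pair(exp, out, palindrome_eaf_window)
            if inst is not None:
                hset.instruments.append(inst)
            else:
                hset.dropped.append((exp.variant_id, reason))
                logger.info("harmonize: %s dropped (%s)", exp.variant_id, reason)
            continue
        # Proxy search.
        proxy = _find_proxy(exp.variant_id, outcome, ld, proxy_r2, exposure_full)
        if proxy is None:
            hset.dropped.append((exp.variant_id, "dropped_unmatched"))
            logger.info(
                "harmonize: %s absent from outcome and no proxy with r² > %g",
                exp.variant_id, proxy_r2,
            )
            continue
        proxy_id, r2 = proxy
        exp_proxy = exposure_full.get(proxy_id)  # non-None by construction
        inst, reason, decisions = _align_pair(exp_proxy, outcome.get(proxy_id), palindrome_eaf_window)
        if inst is None:
            hset.dropped.append((exp.variant_id, f"proxy {proxy_id}: {reason}"))
            continue
        inst.proxy_of = exp.variant_id
        inst.decisions.append(Decision("proxied", f"proxy {proxy_id} for {exp.variant_id}, r²={r2:g}"))
        hset.instruments.append(inst)
    return hset


def _find_proxy(
    variant_id: str,
    outcome: SummaryStatSet,
    ld: LDTable | None,
    proxy_r2: float,
    exposure_full: SummaryStatSet | None,
) -> tuple[str, float] | None:
    if ld is None or exposure_full is None:
        return None
    candidates = [
        (pid, r2)
        for pid, r2 in ld.partners(variant_id).items()
        if r2 > proxy_r2 and pid in outcome and pid in exposure_full
        and exposure_full.get(pid).other_allele is not None
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda t: (t[1], t[0]))


def audit_report(h: HarmonizedSet) -> pd.DataFrame:
    """One row per input SNP, lossless with respect to harmonization decisions."""
    rows = []
    for inst in h.instruments:
        rows.append(
            {
                "variant_id": inst.proxy_of or inst.variant_id,
                "harmonized_as": inst.variant_id,
                "kept": True,
                "decision": inst.terminal_decision,
                "detail": "; ".join(f"{d.action}: {d.detail}" for d in inst.decisions),
            }
        )
    for vid, reason in h.dropped:
        rows.append(
            {
                "variant_id": vid,
                "harmonized_as": "",
                "kept": False,
                "decision": "dropped",
                "detail": reason,
            }
        )
    return pd.DataFrame(rows, columns=["variant_id", "harmonized_as", "kept", "decision", "detail"])


def format_audit(df: pd.DataFrame) -> str:
    """Human-readable rendering of an audit table."""
    if df.empty:
        return "no variants processed"
    return df.to_string(index=False)


# ---------------------------------------------------------------------------
# Persistence of harmonized sets (TSV), so the estimation stage can be
# re-run from the harmonization stage's saved output.
# ---------------------------------------------------------------------------

_HARMONIZED_COLUMNS = [
    "variant_id", "proxy_of", "effect_allele", "other_allele",
    "beta_exposure", "se_exposure", "beta_outcome", "se_outcome",
    "eaf_exposure", "eaf_outcome", "decision",
]


def write_harmonized(h: HarmonizedSet, path) -> None:
    rows = [
        {
            "variant_id": i.variant_id,
            "proxy_of": i.proxy_of or "",
            "effect_allele": i.effect_allele,
            "other_allele": i.other_allele,
            "beta_exposure": i.beta_exposure,
            "se_exposure": i.se_exposure,
            "beta_outcome": i.beta_outcome,
            "se_outcome": i.se_outcome,
            "eaf_exposure": i.eaf_exposure,
            "eaf_outcome": i.eaf_outcome,
            "decision": i.terminal_decision,
        }
        for i in h.instruments
    ]
    pd.DataFrame(rows, columns=_HARMONIZED_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_harmonized(path, biomarker: str | None = None) -> HarmonizedSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    h = HarmonizedSet(biomarker or "harmonized")
    for row in df.itertuples(index=False):
        h.instruments.append(
            HarmonizedInstrument(
                variant_id=str(row.variant_id),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                beta_exposure=float(row.beta_exposure),
                se_exposure=float(row.se_exposure),
                beta_outcome=float(row.beta_outcome),
                se_outcome=float(row.se_outcome),
                eaf_exposure=float(row.eaf_exposure),
                eaf_outcome=float(row.eaf_outcome),
                proxy_of=(str(row.proxy_of) if isinstance(row.proxy_of, str) and row.proxy_of else None),
                decisions=[Decision(str(row.decision), "loaded from file")],
            )
        )
    return h
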