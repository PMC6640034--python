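"""Instrument selection and instrument-strength accounting.

Candidates pass a genome-wide significance filter (default p ≤ 5e-8,
Bonferroni-style) and a minor-allele-frequency filter (default folded
MAF > 0.3), then are LD-clumped: variants connected by known r² above a
threshold (default 0.2) form a cluster and the variant with the greatest
|beta| represents it as the index SNP. Instrument strength is the variance
in the exposure explained by each index SNP, R² = 2·β²·f·(1−f) for a
biallelic variant with folded MAF f and a standardized (unit-variance)
exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from cytomr.summary_io import (
    LDTable,
    SummaryStatRecord,
    SummaryStatSet,
    Table1Fixture,
)

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_MAF_THRESHOLD = 0.3
DEFAULT_CLUMP_R2 = 0.2


@dataclass
class SelectionEntry:
    variant_id: str
    action: str  # "retained" | "excluded" | "index" | "clumped_out"
    reason: str


@dataclass
class InstrumentSet:
    """Post-filter, post-clump index SNPs for one biomarker.

    ``per_snp_variance`` maps each index SNP to the fraction of exposure
    variance it explains; ``total_variance`` is their exact sum.
    """

    biomarker: str
    index_snps: list[SummaryStatRecord] = field(default_factory=list)
    per_snp_variance: dict[str, float] = field(default_factory=dict)
    selection_log: list[SelectionEntry] = field(default_factory=list)

    @property
    def total_variance(self) -> float:
        return sum(self.per_snp_variance[r.variant_id] for r in self.index_snps)

    def __len__(self) -> int:
        return len(self.index_snps)

    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.index_snps]


def variance_explained(beta: float, eaf: float) -> float:
    """Exposure variance explained by one biallelic SNP: 2·β²·f·(1−f).

    ``beta`` is the per-allele effect in exposure SD units and ``f`` the
    folded minor-allele frequency min(eaf, 1−eaf); the result lies in
    [0, β²/2], maximal at eaf = 0.5 and symmetric under eaf ↔ 1−eaf.
    """
    if not (0.0 <= eaf <= 1.0):
        raise ValueError(f"eaf {eaf} outside [0, 1]")
    f = min(eaf, 1.0 - eaf)
    return 2.0 * beta * beta * f * (1.0 - f)


def filter_candidates(
    candidates: SummaryStatSet,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    maf_on: str = "folded",
    log: list[SelectionEntry] | None = None,
) -> SummaryStatSet:
    """Keep genome-wide-significant, common variants.

    Retains records with ``pvalue <= p_threshold`` and MAF strictly above
    ``maf_threshold``. ``maf_on`` selects whether the frequency filter acts
    on the folded MAF ``min(eaf, 1-eaf)`` (default) or on the reported
    ``eaf`` column as-is; published instrument tables are not always
    consistent about which the filter was applied to, so both are
    reachable. Every exclusion is logged with its reason.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold {p_threshold} outside (0, 1)")
    if maf_on == "folded" and not (0.0 <= maf_threshold <= 0.5):
        raise ValueError(f"maf_threshold {maf_threshold} outside [0, 0.5]")
    if maf_on not in ("folded", "eaf"):
        raise ValueError(f"maf_on must be 'folded' or 'eaf', got {maf_on!r}")
    out = SummaryStatSet(candidates.trait_name, candidates.trait_type)
    for rec in candidates:
        freq = rec.folded_maf if maf_on == "folded" else rec.eaf
        if rec.pvalue > p_threshold:
            entry = SelectionEntry(rec.variant_id, "excluded", f"p={rec.pvalue:.3g} > {p_threshold:g}")
        elif freq <= maf_threshold:
            entry = SelectionEntry(rec.variant_id, "excluded", f"MAF {freq:.4g} <= {maf_threshold:g}")
        else:
            entry = SelectionEntry(rec.variant_id, "retained", "passed p and MAF filters")
            out.add(rec)
        if log is not None:
            log.append(entry)
        if entry.action == "excluded":
            logger.info("filter: %s excluded (%s)", rec.variant_id, entry.reason)
    return out


def _clusters(
    variant_ids: list[str], ld: LDTable, r2_threshold: float
) -> list[list[str]]:
    """Connected components under 'known r² strictly above threshold'.

    Union-find over the candidate variants; pairs with unknown r² are
    treated as independent (the clumping rule acts only on measured
    linkage).
    """
    parent = {v: v for v in variant_ids}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    ids = sorted(variant_ids)
    for i, a in enumerate(ids):
        known = ld.partners(a)
        for b in ids[i + 1 :]:
            r2 = known.get(b)
            if r2 is None:
                logger.debug("clump: r²(%s, %s) unknown; treated as independent", a, b)
                continue
            if r2 > r2_threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[str, list[str]] = {}
    for v in ids:
        groups.setdefault(find(v), []).append(v)
    return sorted(groups.values())


def clump(
    candidates: SummaryStatSet,
    ld: LDTable,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    biomarker: str | None = None,
) -> InstrumentSet:
    """LD-clump candidates into independent index SNPs.

    Variants linked (transitively) by known r² > ``r2_threshold`` form one
    cluster; the cluster's index SNP is the record with the greatest |beta|
    (ties broken by smaller p-value, then lexicographic variant ID, for
    determinism). The result is independent of candidate input order.
    """
    inst = InstrumentSet(biomarker or candidates.trait_name)
    by_id = {r.variant_id: r for r in candidates}
    for cluster in _clusters(list(by_id), ld, r2_threshold):
        records = [by_id[v] for v in cluster]
        index = min(records, key=lambda r: (-abs(r.beta), r.pvalue, r.variant_id))
        inst.index_snps.append(index)
        inst.per_snp_variance[index.variant_id] = variance_explained(index.beta, index.eaf)
        inst.selection_log.append(
            SelectionEntry(index.variant_id, "index", f"greatest |beta| in cluster of {len(cluster)}")
        )
        for rec in records:
            if rec.variant_id != index.variant_id:
                inst.selection_log.append(
                    SelectionEntry(rec.variant_id, "clumped_out", f"in LD cluster of index {index.variant_id}")
                )
    inst.index_snps.sort(key=lambda r: r.variant_id)
    return inst


def select_instruments(
    candidates: SummaryStatSet,
    ld: LDTable,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    maf_on: str = "folded",
    biomarker: str | None = None,
) -> InstrumentSet:
    """Filter then clump: the full instrument-selection stage."""
    log: list[SelectionEntry] = []
    filtered = filter_candidates(candidates, p_threshold, maf_threshold, maf_on, log)
    inst = clump(filtered, ld, r2_threshold, biomarker)
    inst.selection_log = log + inst.selection_log
    return inst


@dataclass
class StrengthSummary:
    biomarker: str
    total_variance: float  # fraction
    per_snp: list[tuple[str, float]]  # (variant_id, fraction), descending

    @property
    def total_pct(self) -> float:
        return 100.0 * self.total_variance

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_snp, columns=["variant_id", "variance_explained"])
        df["variance_explained_pct"] = 100.0 * df["variance_explained"]
        return df


def summarize_strength(instruments: InstrumentSet) -> StrengthSummary:
    """Total and per-SNP exposure variance explained, strongest first."""
    per_snp = sorted(
        ((r.variant_id, instruments.per_snp_variance[r.variant_id]) for r in instruments.index_snps),
        key=lambda t: (-t[1], t[0]),
    )
    return StrengthSummary(instruments.biomarker, instruments.total_variance, per_snp)


def instrument_sets_from_table1(fixture: Table1Fixture) -> dict[str, InstrumentSet]:
    """Build one InstrumentSet per biomarker from the packaged 12-SNP table.

    Per-SNP variance explained is taken verbatim from the published column
    (as fractions), not recomputed, so strength summaries reproduce the
    published totals exactly.
    """
    out: dict[str, InstrumentSet] = {}
    for biomarker, variant_ids in fixture.groups.items():
        inst = InstrumentSet(biomarker)
        for vid in variant_ids:
            rec = fixture.exposure.get(vid)
            assert rec is not None
            inst.index_snps.append(rec)
            inst.per_snp_variance[vid] = fixture.variance_pct[vid] / 100.0
            inst.selection_log.append(SelectionEntry(vid, "index", "published index SNP"))
        out[biomarker] = inst
    return out
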