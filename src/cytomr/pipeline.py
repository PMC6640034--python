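"""End-to-end orchestration: select → harmonize → estimate → report.

A :class:`RunConfig` names the inputs (summary-statistic files or a
simulation block) and all thresholds; :func:`run` executes the stages in
order, persists each stage's output when an output directory is given, and
writes a manifest (config hash, package version, seed) so a run is
reproducible byte-for-byte from its config.

:func:`run_table1_fixture` runs the instrument-strength stage on the
packaged 12-SNP instrument table, reproducing the published per-biomarker
variance-explained totals and index-SNP counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from cytomr import estimators, power
from cytomr.exceptions import ConfigurationError
from cytomr.harmonize import audit_report, harmonize, write_harmonized
from cytomr.instruments import (
    InstrumentSet,
    StrengthSummary,
    instrument_sets_from_table1,
    select_instruments,
    summarize_strength,
)
from cytomr.summary_io import (
    LDTable,
    load_table1_fixture,
    read_ld_table,
    read_summary_stats,
    write_summary_stats,
)
from cytomr.synthetic_data import CorruptionConfig, SimulationConfig, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Either the three input paths or a ``simulate`` block must be given.
    Thresholds default to the published workflow: genome-wide significance
    5e-8, folded MAF > 0.3, clump r² 0.2, proxy r² 0.8, palindrome
    ambiguity window 0.08, 95% CIs, α 0.05.
    """

    biomarker: str = "exposure"
    exposure_path: str | None = None
    outcome_path: str | None = None
    ld_path: str | None = None
    simulate: SimulationConfig | None = None
    p_threshold: float = 5e-8
    maf_threshold: float = 0.3
    maf_on: str = "folded"
    clump_r2: float = 0.2
    proxy_r2: float = 0.8
    palindrome_window: float = 0.08
    ci_level: float = 0.95
    alpha: float = 0.05
    methods: tuple[str, ...] = ("ivw", "egger")
    power_or_per_sd: float | None = None
    power_target: float = 0.8
    case_fraction: float = power.DEFAULT_CASE_FRACTION
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None and (self.exposure_path is None or self.outcome_path is None):
            raise ConfigurationError("either exposure/outcome paths or a simulate block is required")
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigurationError("p_threshold outside (0, 1)")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ConfigurationError("clump_r2 outside [0, 1]")
        if not (0.0 < self.proxy_r2 <= 1.0):
            raise ConfigurationError("proxy_r2 outside (0, 1]")
        if not (0.0 <= self.palindrome_window < 0.5):
            raise ConfigurationError("palindrome_window outside [0, 0.5)")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigurationError("ci_level outside (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            corr = sim.pop("corruption", None)
            sim = SimulationConfig(
                **sim, corruption=CorruptionConfig(**corr) if corr else CorruptionConfig()
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown run-config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(simulate=sim, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    instruments: InstrumentSet
    harmonized: "object"
    result: estimators.MRResult
    strength: StrengthSummary
    power_result: power.PowerResult | None
    audit: pd.DataFrame
    manifest: dict


def estimates_table(result: estimators.MRResult) -> pd.DataFrame:
    """Report table: method, n SNPs, OR with 95% CI and p, plus log-odds columns."""
    rows = []
    for e in result.estimates:
        rows.append(
            {
                "biomarker": result.biomarker,
                "method": e.method,
                "n_snps": e.n_snps,
                "or": e.or_,
                "or_ci_low": e.or_ci_low,
                "or_ci_high": e.or_ci_high,
                "p": e.pvalue,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["biomarker", "method", "n_snps", "or", "or_ci_low", "or_ci_high",
                 "p", "beta", "se", "ci_low", "ci_high"],
    )


def run(config: RunConfig) -> RunResult:
    """Execute select → harmonize → estimate (→ power) as one run."""
    config.validate()
    stage = "load"
    try:
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            study = simulate(sim_cfg)
            exposure, outcome, ld = study.exposure, study.outcome, study.ld
        else:
            exposure = read_summary_stats(config.exposure_path, trait_name=config.biomarker)
            outcome = read_summary_stats(config.outcome_path, trait_type="binary")
            ld = read_ld_table(config.ld_path) if config.ld_path else LDTable()

        stage = "select"
        inst = select_instruments(
            exposure, ld, config.p_threshold, config.maf_threshold,
            config.clump_r2, config.maf_on, biomarker=config.biomarker,
        )
        strength = summarize_strength(inst)

        stage = "harmonize"
        hset = harmonize(
            inst, outcome, ld, config.proxy_r2, config.palindrome_window,
            exposure_full=exposure,
        )
        audit = audit_report(hset)

        stage = "estimate"
        result = estimators.estimate_all(hset, config.methods, config.ci_level)
        if not result.egger_performed and "egger" in config.methods:
            logger.info("%s: MR-Egger %s", config.biomarker, result.egger_reason)

        stage = "power"
        power_result = None
        if config.power_or_per_sd is not None and strength.total_variance > 0:
            q = power.PowerQuery(
                r2_xz=strength.total_variance,
                or_per_sd=config.power_or_per_sd,
                n_outcome=int(outcome.get(next(iter(outcome.records))).n or 0) or 54162,
                case_fraction=config.case_fraction,
                alpha=config.alpha,
            )
            target = None if config.power_or_per_sd == 1.0 else config.power_target
            power_result = power.mr_power(q, target_power=target)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "package": "cytomr",
        "version": _version(),
        "seed": config.seed,
        "n_instruments": len(inst),
        "n_harmonized": len(hset),
    }
    run_result = RunResult(config, inst, hset, result, strength, power_result, audit, manifest)
    if config.out_dir:
        _persist(run_result, exposure, outcome)
    return run_result


def _version() -> str:
    import cytomr

    return cytomr.__version__


def _persist(rr: RunResult, exposure, outcome) -> None:
    out = Path(rr.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if rr.config.simulate is not None:
        write_summary_stats(exposure, out / "exposure.tsv")
        write_summary_stats(outcome, out / "outcome.tsv")
    inst_set = rr.instruments
    pd.DataFrame(
        [
            {
                "variant_id": r.variant_id, "chr": r.chromosome, "pos": r.position,
                "ea": r.effect_allele, "oa": r.other_allele or "", "eaf": r.eaf,
                "beta": r.beta, "se": r.se, "p": r.pvalue,
                "variance_explained": inst_set.per_snp_variance[r.variant_id],
            }
            for r in inst_set.index_snps
        ]
    ).to_csv(out / "instruments.tsv", sep="\t", index=False)
    write_harmonized(rr.harmonized, out / "harmonized.tsv")
    estimates_table(rr.result).to_csv(out / "estimates.tsv", sep="\t", index=False)
    rr.audit.to_csv(out / "audit.tsv", sep="\t", index=False)
    with open(out / "audit.jsonl", "w") as fh:
        for rec in rr.audit.to_dict(orient="records"):
            fh.write(json.dumps(rec) + "\n")
    rr.strength.to_dataframe().to_csv(out / "strength.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(rr.manifest, fh, indent=2, sort_keys=True)


def run_table1_fixture() -> pd.DataFrame:
    """Instrument-strength summary of the packaged 12-SNP table.

    Returns one row per biomarker with the index-SNP count and the total
    variance explained (%), computed by summing the per-SNP values through
    the strength-summary operation.
    """
    fixture = load_table1_fixture()
    rows = []
    for biomarker, inst in instrument_sets_from_table1(fixture).items():
        s = summarize_strength(inst)
        rows.append(
            {
                "biomarker": biomarker,
                "n_index_snps": len(inst),
                "total_variance_pct": s.total_pct,
            }
        )
    return pd.DataFrame(rows, columns=["biomarker", "n_index_snps", "total_variance_pct"])
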