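"""Reading, validating and writing GWAS summary statistics and LD tables.

The central containers are :class:`SummaryStatRecord` (one variant's
association with one trait, fully allele-oriented) and
:class:`SummaryStatSet` (one trait's records keyed by variant ID).
Pairwise linkage disequilibrium is consumed as a plain ``r²`` lookup table
(:class:`LDTable`); this package never computes LD from genotypes.

A packaged fixture (:func:`load_table1_fixture`) carries the twelve index
SNPs for serum IL-18, IL-1ra, IL-6 and erythrocyte sedimentation rate,
with their published chromosome, position, effect alleles in the exposure
and outcome datasets, effect-allele frequency and per-SNP variance
explained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from cytomr.exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Default column names expected in summary-statistic files. Keys are the
#: canonical field names; values the file header names. Override any subset
#: via the ``column_map`` argument of :func:`read_summary_stats`.
DEFAULT_COLUMNS: dict[str, str] = {
    "variant_id": "variant_id",
    "chromosome": "chr",
    "position": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "p",
    "n": "n",
}

_OPTIONAL_FIELDS = {"other_allele", "n"}


@dataclass
class SummaryStatRecord:
    """One variant's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``, in trait SD
    units for a continuous exposure or log-odds for a binary outcome.
    ``other_allele`` may be ``None`` when the source study did not report
    it; strand resolution is then impossible downstream and harmonization
    will drop the variant with an explicit reason.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str | None
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float | None = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        if self.other_allele is not None:
            oa = str(self.other_allele).upper()
            self.other_allele = oa if oa in VALID_ALLELES else None
        self.chromosome = str(self.chromosome)

    def validation_errors(self) -> list[str]:
        """Return human-readable contract violations (empty when valid)."""
        errs: list[str] = []
        if not self.variant_id:
            errs.append("variant_id is empty")
        if self.effect_allele not in VALID_ALLELES:
            errs.append(f"effect_allele {self.effect_allele!r} not one of A/C/G/T")
        if self.other_allele is not None and self.other_allele == self.effect_allele:
            errs.append("effect_allele equals other_allele")
        if not (0.0 <= self.eaf <= 1.0) or math.isnan(self.eaf):
            errs.append(f"eaf {self.eaf} outside [0, 1]")
        if not (self.se > 0.0):
            errs.append(f"se {self.se} is not > 0")
        if not (0.0 < self.pvalue <= 1.0):
            errs.append(f"pvalue {self.pvalue} outside (0, 1]")
        if math.isnan(self.beta):
            errs.append("beta is NaN")
        return errs

    @property
    def folded_maf(self) -> float:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants (alleles identical on both strands)."""
        return (
            self.other_allele is not None
            and self.other_allele == COMPLEMENT[self.effect_allele]
        )


COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStatSet:
    """A trait's summary statistics, keyed by variant ID (unique)."""

    trait_name: str
    trait_type: str = "continuous"  # "continuous" | "binary"
    records: dict[str, SummaryStatRecord] = field(default_factory=dict)

    def add(self, record: SummaryStatRecord) -> None:
        if record.variant_id in self.records:
            raise InputError(
                f"duplicate variant_id {record.variant_id!r} in set "
                f"{self.trait_name!r}"
            )
        self.records[record.variant_id] = record

    def get(self, variant_id: str) -> SummaryStatRecord | None:
        return self.records.get(variant_id)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryStatRecord]:
        return iter(self.records.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id,
                "chr": r.chromosome,
                "pos": r.position,
                "ea": r.effect_allele,
                "oa": r.other_allele if r.other_allele is not None else "",
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "p": r.pvalue,
                "n": r.n if r.n is not None else "",
            }
            for r in self
        ]
        return pd.DataFrame(
            rows, columns=["variant_id", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]
        )


def _resolve_columns(
    header: Iterable[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ConfigurationError(f"unknown column-map keys: {sorted(unknown)}")
        cols.update(column_map)
    header = set(header)
    missing = [
        f"{field} (column {name!r})"
        for field, name in cols.items()
        if field not in _OPTIONAL_FIELDS and name not in header
    ]
    if missing:
        raise ConfigurationError(
            "summary-statistic file is missing mandatory columns: "
            + ", ".join(missing)
        )
    return cols


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-delimited table with a header row.

    Floats are parsed with the round-trip parser so that write → read is
    lossless to the last bit.
    """
    with open(path) as fh:
        sep = "\t" if "\t" in fh.readline() else ","
    return pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_name: str | None = None,
) -> SummaryStatSet:
    """Read a summary-statistic file into a validated :class:`SummaryStatSet`.

    Rows violating the record contract (``se <= 0``, frequency outside
    ``[0, 1]``, invalid alleles, ...) are rejected individually with a
    row-numbered warning; a missing mandatory column raises
    :class:`~cytomr.exceptions.ConfigurationError` and a duplicate variant
    ID raises :class:`~cytomr.exceptions.InputError`.
    """
    if trait_type not in ("continuous", "binary"):
        raise ConfigurationError(f"trait_type must be continuous or binary, got {trait_type!r}")
    df = _read_table(path)
    cols = _resolve_columns(df.columns, column_map)
    sset = SummaryStatSet(trait_name or Path(path).stem, trait_type)
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row_d = dict(zip(df.columns, row))

        def _opt(fld: str):
            name = cols[fld]
            if name not in row_d or pd.isna(row_d[name]) or row_d[name] == "":
                return None
            return row_d[name]

        try:
            rec = SummaryStatRecord(
                variant_id=str(row_d[cols["variant_id"]]),
                chromosome=str(row_d[cols["chromosome"]]),
                position=int(row_d[cols["position"]]),
                effect_allele=str(row_d[cols["effect_allele"]]),
                other_allele=_opt("other_allele"),
                eaf=float(row_d[cols["eaf"]]),
                beta=float(row_d[cols["beta"]]),
                se=float(row_d[cols["se"]]),
                pvalue=float(row_d[cols["pvalue"]]),
                n=(float(_opt("n")) if _opt("n") is not None else None),
            )
        except (TypeError, ValueError) as exc:
            logger.warning("%s row %d rejected: unparseable field (%s)", path, i, exc)
            continue
        errs = rec.validation_errors()
        if errs:
            logger.warning("%s row %d (%s) rejected: %s", path, i, rec.variant_id, "; ".join(errs))
            continue
        sset.add(rec)  # raises InputError on duplicates
    return sset


def write_summary_stats(sset: SummaryStatSet, path: str | Path) -> None:
    """Write a set as TSV (or CSV if the path ends in ``.csv``), full precision."""
    df = sset.to_dataframe()
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False)


class LDTable:
    """Symmetric pairwise ``r²`` lookup.

    ``get(a, b)`` returns ``None`` for an unknown pair — never 0, because
    absence of evidence of linkage is not evidence of independence (callers
    decide how to treat unknowns). ``r²(x, x)`` is 1 by definition.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], float] = {}
        self._adjacency: dict[str, dict[str, float]] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float, warn_on_overwrite: bool = True) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise InputError(f"r² for pair ({a}, {b}) is {r2}, outside [0, 1]")
        key = self._key(a, b)
        if key in self._entries and warn_on_overwrite:
            logger.warning(
                "LD pair (%s, %s): overwriting r²=%s with %s", a, b, self._entries[key], r2
            )
        self._entries[key] = r2
        self._adjacency.setdefault(a, {})[b] = r2
        self._adjacency.setdefault(b, {})[a] = r2

    def get(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        return self._entries.get(self._key(a, b))

    def partners(self, variant_id: str) -> dict[str, float]:
        """All variants with a known r² to ``variant_id`` (excluding itself)."""
        return dict(self._adjacency.get(variant_id, {}))

    def __len__(self) -> int:
        return len(self._entries)

    def items(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), r2 in self._entries.items():
            yield a, b, r2


def read_ld_table(path: str | Path) -> LDTable:
    """Read a three-column (variant_a, variant_b, r2) LD table.

    Later duplicates of the same unordered pair overwrite earlier entries
    with a logged warning; an r² outside [0, 1] is an input error.
    """
    df = _read_table(path)
    required = {"variant_a", "variant_b", "r2"}
    if not required <= set(df.columns):
        raise ConfigurationError(
            f"LD table must have columns {sorted(required)}, found {list(df.columns)}"
        )
    table = LDTable()
    for row in df.itertuples(index=False):
        table.add(str(row.variant_a), str(row.variant_b), float(row.r2))
    return table


def write_ld_table(table: LDTable, path: str | Path) -> None:
    df = pd.DataFrame(list(table.items()), columns=["variant_a", "variant_b", "r2"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged instrument-table fixture
# ---------------------------------------------------------------------------

#: GWAS sample sizes for the four biomarker exposure studies.
BIOMARKER_SAMPLE_SIZES = {"IL-18": 12736, "IL-1ra": 12381, "IL-6": 14501, "ESR": 6145}


@dataclass
class Table1Fixture:
    """The published 12-SNP instrument table plus stub summary-stat sets.

    ``table`` holds the printed columns verbatim. ``exposure`` and
    ``outcome`` are *stub* :class:`SummaryStatSet` objects: effect alleles,
    frequencies, chromosomes and positions are as published; exposure betas
    are back-calculated from the printed per-SNP variance explained
    (β = sqrt(R² / (2·f·(1−f))) with f the folded MAF), and standard
    errors/p-values/outcome betas are synthetic placeholders, since the
    source publications' effect sizes are not reproduced here. The
    ``variance_pct`` mapping is authoritative for instrument strength.
    """

    table: pd.DataFrame
    exposure: SummaryStatSet
    outcome: SummaryStatSet
    groups: dict[str, list[str]]
    variance_pct: dict[str, float]

    @property
    def biomarkers(self) -> list[str]:
        return list(self.groups)


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged 12-SNP instrument table for the four biomarkers.

    The frequency column is stored as *effect-allele* frequency: the
    published table labels it "minor allele frequency" but contains values
    above 0.5 (e.g. 0.934), which only make sense as frequencies of the
    reported effect allele.
    """
    ref = resources.files("cytomr") / "data" / "table1.tsv"
    with resources.as_file(ref) as p:
        table = pd.read_csv(p, sep="\t")
    exposure = SummaryStatSet("inflammatory_biomarkers", "continuous")
    outcome = SummaryStatSet("alzheimers_disease", "binary")
    groups: dict[str, list[str]] = {}
    variance_pct: dict[str, float] = {}
    for row in table.itertuples(index=False):
        f = min(row.eaf, 1.0 - row.eaf)
        r2 = row.variance_explained_pct / 100.0
        beta = math.sqrt(r2 / (2.0 * f * (1.0 - f)))
        n_exp = BIOMARKER_SAMPLE_SIZES[row.biomarker]
        exposure.add(
            SummaryStatRecord(
                variant_id=row.variant_id,
                chromosome=str(row.chromosome),
                position=int(row.position),
                effect_allele=row.biomarker_effect_allele,
                other_allele=None,
                eaf=float(row.eaf),
                beta=beta,
                se=beta / 6.0,  # stub: genome-wide significant by construction
                pvalue=1e-9,  # stub
                n=float(n_exp),
            )
        )
        outcome.add(
            SummaryStatRecord(
                variant_id=row.variant_id,
                chromosome=str(row.chromosome),
                position=int(row.position),
                effect_allele=row.igap_effect_allele,
                other_allele=None,
                eaf=float(row.eaf),  # stub: outcome-study frequency not published
                beta=0.0,  # stub
                se=0.05,  # stub
                pvalue=1.0,
                n=54162.0,
            )
        )
        groups.setdefault(row.biomarker, []).append(row.variant_id)
        variance_pct[row.variant_id] = float(row.variance_explained_pct)
    return Table1Fixture(table, exposure, outcome, groups, variance_pct)
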