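"""Read, validate and join GWAS summary-statistic tables and instrument lists.

The canonical on-disk format is header-bearing tab-delimited text with columns
``SNP CHR POS EA OA EAF BETA SE P N``.  Public downloads name these columns
differently (consortium dialects), so every reader accepts a ``column_map``
translating file headers to the canonical names.  Positions are 1-based and
chromosome labels are compared as strings after stripping any ``chr`` prefix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyJoinError, FormatError, IntegrityError, ParseError, ValidationError

__all__ = [
    "SumStatRecord",
    "InstrumentSet",
    "CANONICAL_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "read_instruments",
    "join_instruments",
]

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait, in the
    trait's units (often SD units); ``eaf`` is the effect-allele frequency and
    may be ``None`` (palindromic harmonization then fails loudly downstream
    rather than guessing strand).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None = None

    def __post_init__(self) -> None:
        for name in ("eaf", "beta", "se", "pval"):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, float(value))
        if self.n is not None:
            object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "pos", int(self.pos))
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if not (0.0 < self.pval <= 1.0):
            raise ValidationError(f"{self.snp_id}: p-value {self.pval} outside (0, 1]")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"{self.snp_id}: sample size must be positive, got {self.n}")

    def flipped(self) -> "SumStatRecord":
        """Return the same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass(frozen=True)
class InstrumentSet:
    """A named list of instrument SNPs with their adult-trait effect sizes.

    Records carry the adult-adiposity-raising allele as effect allele, so the
    downstream pooled birth-weight effect is expressed per raising allele.
    """

    name: str
    records: tuple[SumStatRecord, ...]
    trait_units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.snp_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise IntegrityError(f"instrument set '{self.name}': duplicate snp_ids {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]


def _norm_chrom(label: str) -> str:
    label = str(label).strip()
    return label[3:] if label.lower().startswith("chr") else label


def _parse_float(raw: object, field: str, line: int) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"line {line}: non-numeric {field} value {raw!r}") from None
    if math.isnan(value):
        raise ParseError(f"line {line}: {field} is NaN")
    return value


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SumStatRecord]:
    """Read a tab-delimited summary-statistics file into validated records.

    Parameters
    ----------
    path
        Header-bearing TSV file.
    column_map
        Mapping of file headers to canonical names (``{"rsid": "SNP", ...}``).
        Omitted for files already using canonical headers.  ``EAF`` and ``N``
        are optional; empty/NA cells in them become ``None``.

    Row order is preserved; the first failing row raises with its line number
    (line 1 is the header).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"summary-statistics file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        unknown = set(column_map) - set(table.columns)
        if unknown:
            raise FormatError(f"{path}: column_map refers to absent columns {sorted(unknown)}")
        table = table.rename(columns=dict(column_map))
    required = [c for c in CANONICAL_COLUMNS if c not in ("EAF", "N")]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    records: list[SumStatRecord] = []
    for idx, row in enumerate(table.itertuples(index=False)):
        line = idx + 2  # header is line 1
        row_d = dict(zip(table.columns, row))
        eaf_raw = row_d.get("EAF")
        n_raw = row_d.get("N")
        try:
            record = SumStatRecord(
                snp_id=str(row_d["SNP"]).strip(),
                chrom=str(row_d["CHR"]),
                pos=int(_parse_float(row_d["POS"], "POS", line)),
                effect_allele=str(row_d["EA"]).strip(),
                other_allele=str(row_d["OA"]).strip(),
                eaf=None if _is_na(eaf_raw) else _parse_float(eaf_raw, "EAF", line),
                beta=_parse_float(row_d["BETA"], "BETA", line),
                se=_parse_float(row_d["SE"], "SE", line),
                pval=_parse_float(row_d["P"], "P", line),
                n=None if _is_na(n_raw) else int(_parse_float(n_raw, "N", line)),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {line} (data row {idx + 1}): {exc}") from exc
        records.append(record)
    return records


def _is_na(raw: object) -> bool:
    return raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() in ("", "NA", "nan", ".")


def write_sumstats(records: Iterable[SumStatRecord], path: str | Path) -> None:
    """Write records to canonical tab-delimited text (``NA`` for absent fields)."""
    rows = [
        {
            "SNP": r.snp_id,
            "CHR": r.chrom,
            "POS": r.pos,
            "EA": r.effect_allele,
            "OA": r.other_allele,
            "EAF": "NA" if r.eaf is None else repr(r.eaf),
            "BETA": repr(r.beta),
            "SE": repr(r.se),
            "P": repr(r.pval),
            "N": "NA" if r.n is None else r.n,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_instruments(
    path: str | Path,
    name: str | None = None,
    trait_units: str = "",
    column_map: Mapping[str, str] | None = None,
) -> InstrumentSet:
    """Read an instrument list stored in the canonical summary-stat format."""
    records = read_sumstats(path, column_map=column_map)
    return InstrumentSet(name=name or Path(path).stem, records=tuple(records), trait_units=trait_units)


def join_instruments(
    instruments: InstrumentSet,
    outcome: Sequence[SumStatRecord],
) -> tuple[list[tuple[SumStatRecord, SumStatRecord]], list[str]]:
    """Pair each instrument SNP with its outcome-trait record by ``snp_id``.

    Returns ``(pairs, missing_ids)`` where ``missing_ids`` lists instrument
    SNPs absent from the outcome table (reported, never silently dropped).
    Duplicate ids in the outcome table raise; zero overlap raises.
    """
    outcome_ids = [r.snp_id for r in outcome]
    dupes = {i for i in outcome_ids if outcome_ids.count(i) > 1}
    if dupes:
        raise IntegrityError(f"outcome table: duplicate snp_ids {sorted(dupes)}")
    by_id = {r.snp_id: r for r in outcome}

    pairs: list[tuple[SumStatRecord, SumStatRecord]] = []
    missing: list[str] = []
    for rec in instruments.records:
        if rec.snp_id in by_id:
            pairs.append((rec, by_id[rec.snp_id]))
        else:
            missing.append(rec.snp_id)
    if not pairs:
        raise EmptyJoinError(
            f"no overlap between instrument set '{instruments.name}' ({len(instruments)} SNPs) "
            f"and outcome table ({len(outcome)} SNPs)"
        )
    return pairs, missing
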