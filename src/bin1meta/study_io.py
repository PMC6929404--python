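"""Reading, validating and writing case-control study rosters.

A *study roster* is one row per case-control study: a label, an ancestry
group, case/control sample sizes, the frequency of the rs744373 C allele
(MAF), and the study's reported allelic odds ratio.  A roster may optionally
carry per-arm genotype counts (CC/CT/TT), which enable dominant and
recessive contrasts in addition to the allelic one.

The package ships a transcribed 37-study roster (11 East Asian, 26
Caucasian; 22,395 cases and 48,773 controls) available via
:func:`load_bundled_roster`.  Each row's ``or_allele`` column records which
allele the reported OR refers to: the East Asian studies report the OR for
the C allele, while the Caucasian studies (predominantly GWAS reports)
tabulate the OR for the opposite allele, so their values are inverted when
effects are harmonised to the C-vs-T direction (see ``effect_models``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .errors import PipelineError, SchemaError, ValidationError

GROUPS = ("east_asian", "caucasian")

_REQUIRED = ("label", "group", "n_case", "n_control", "maf", "or")
_GENOTYPE_COLS = ("cc_case", "ct_case", "tt_case", "cc_control", "ct_control", "tt_control")


@dataclass(frozen=True)
class StudyRecord:
    """One study's roster row.

    ``maf`` is the frequency of allele C; ``or_reported`` is the odds ratio
    as published, referring to allele ``or_allele`` (C or T).  Genotype
    counts, when present, are (CC, CT, TT) tuples per arm.
    """

    label: str
    group: str
    n_case: int
    n_control: int
    maf: float
    or_reported: float
    or_allele: str = "C"
    genotype_case: tuple[int, int, int] | None = None
    genotype_control: tuple[int, int, int] | None = None
    platform: str | None = None

    def __post_init__(self):
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValidationError("sample sizes must be positive", label=self.label)
        if not 0.0 < self.maf < 1.0:
            raise ValidationError(f"maf must lie in (0,1), got {self.maf}", label=self.label)
        if self.or_reported <= 0:
            raise ValidationError(f"or must be positive, got {self.or_reported}", label=self.label)
        if self.or_allele not in ("C", "T"):
            raise ValidationError(f"or_allele must be C or T, got {self.or_allele!r}", label=self.label)
        for counts, n, arm in (
            (self.genotype_case, self.n_case, "case"),
            (self.genotype_control, self.n_control, "control"),
        ):
            if counts is None:
                continue
            if len(counts) != 3 or any(c < 0 for c in counts):
                raise ValidationError(f"{arm} genotype counts must be 3 non-negative integers", label=self.label)
            if sum(counts) > n:
                raise ValidationError(
                    f"{arm} genotype counts sum to {sum(counts)} > declared N {n}", label=self.label
                )

    @property
    def or_c_vs_t(self) -> float:
        """The reported OR expressed in the C-vs-T direction."""
        return self.or_reported if self.or_allele == "C" else 1.0 / self.or_reported

    @property
    def has_genotypes(self) -> bool:
        return self.genotype_case is not None and self.genotype_control is not None


@dataclass
class StudyTable:
    """An ordered collection of :class:`StudyRecord`, order exactly as read.

    Labels need not be unique (multi-cohort articles contribute one row per
    cohort under the same citation label).
    """

    records: list[StudyRecord]
    source: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def subset(self, group: str) -> "StudyTable":
        return StudyTable([r for r in self.records if r.group == group], source=f"{self.source}[{group}]")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "label": r.label,
                "group": r.group,
                "n_case": r.n_case,
                "n_control": r.n_control,
                "maf": r.maf,
                "or": r.or_reported,
                "or_allele": r.or_allele,
            }
            if r.has_genotypes:
                row.update(zip(("cc_case", "ct_case", "tt_case"), r.genotype_case))
                row.update(zip(("cc_control", "ct_control", "tt_control"), r.genotype_control))
            if r.platform is not None:
                row["platform"] = r.platform
            rows.append(row)
        return pd.DataFrame(rows)


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def _record_from_row(i: int, row: pd.Series, need_genotypes: bool) -> StudyRecord:
    for col in _REQUIRED:
        if _is_missing(row.get(col)):
            raise ValidationError(f"missing value in column {col!r}", row=i)
    try:
        n_case = int(row["n_case"])
        n_control = int(row["n_control"])
        maf = float(row["maf"])
        or_ = float(row["or"])
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell: {exc}", row=i) from None
    group = str(row["group"]).strip()
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r} (expected one of {GROUPS})", row=i)

    genotype_case = genotype_control = None
    have = [c for c in _GENOTYPE_COLS if not _is_missing(row.get(c))]
    if need_genotypes and len(have) < 6:
        raise ValidationError(f"genotype columns incomplete: missing {sorted(set(_GENOTYPE_COLS) - set(have))}", row=i)
    if len(have) == 6:
        try:
            gc = tuple(int(row[c]) for c in ("cc_case", "ct_case", "tt_case"))
            gn = tuple(int(row[c]) for c in ("cc_control", "ct_control", "tt_control"))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric genotype count: {exc}", row=i) from None
        genotype_case, genotype_control = gc, gn

    platform = None if _is_missing(row.get("platform")) else str(row["platform"])
    or_allele = "C" if _is_missing(row.get("or_allele")) else str(row["or_allele"]).strip().upper()
    try:
        return StudyRecord(
            label=str(row["label"]),
            group=group,
            n_case=n_case,
            n_control=n_control,
            maf=maf,
            or_reported=or_,
            or_allele=or_allele,
            genotype_case=genotype_case,
            genotype_control=genotype_control,
            platform=platform,
        )
    except ValidationError as exc:
        raise ValidationError(str(exc), row=i) from None


def read_study_table(path: str | Path, sep: str = ",") -> StudyTable:
    """Read a delimited study roster into a :class:`StudyTable`.

    The file must have a header naming at least
    ``label,group,n_case,n_control,maf,or``; optional columns are
    ``or_allele``, ``platform`` and the six genotype-count columns.  Rows
    are kept in file order.  A missing required column raises
    :class:`SchemaError`; a bad cell raises :class:`ValidationError` naming
    the offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=True)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    records = [_record_from_row(i, row, need_genotypes=False) for i, row in frame.iterrows()]
    return StudyTable(records, source=str(path))


def read_genotype_table(path: str | Path, sep: str = ",") -> StudyTable:
    """Read a roster whose every row carries per-arm CC/CT/TT counts."""
    path = Path(path)
    frame = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=True)
    missing = [c for c in (*_REQUIRED, *_GENOTYPE_COLS) if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    records = [_record_from_row(i, row, need_genotypes=True) for i, row in frame.iterrows()]
    return StudyTable(records, source=str(path))


def write_study_table(table: StudyTable, path: str | Path, sep: str = ",") -> None:
    """Write a roster so that ``read_study_table`` round-trips it exactly."""
    if not table.records:
        raise PipelineError("refusing to write an empty study table")
    table.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_results_table(results: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a results table at full precision (round-trippable to 15+ digits)."""
    if results is None or len(results) == 0:
        raise PipelineError("refusing to write an empty results table")
    results.to_csv(path, sep=sep, index=False, float_format="%.17g")


def load_bundled_roster() -> StudyTable:
    """The packaged 37-study rs744373 roster (11 East Asian, 26 Caucasian)."""
    with resources.as_file(resources.files("bin1meta.data") / "rs744373_study_roster.csv") as p:
        table = read_study_table(p)
    table.source = "bundled:rs744373_study_roster"
    return table
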