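"""Domain records, TSV readers/writers and packaged reference tables.

The canonical on-disk format for gene tables is TSV with a header row;
comma and semicolon dialects are accepted through :class:`TableDialect`.
Unicode minus (U+2212), used by many typesetters, is normalized to ASCII
``-`` before numeric parsing.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DEGRecord",
    "DatasetMeta",
    "TableDialect",
    "TableParseError",
    "read_deg_table",
    "write_deg_table",
    "load_fixture",
    "fixture_checksum",
    "FIXTURE_NAMES",
]

_MINUS_VARIANTS = str.maketrans({"−": "-", "–": "-", "—": "-"})


def _clean_number(raw: str) -> float:
    return float(raw.strip().translate(_MINUS_VARIANTS))


class TableParseError(ValueError):
    """Structured parse failure naming the offending row and column."""

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        super().__init__(message)


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential expression in one study.

    ``log2fc`` is the log2-transformed ratio of the expression level in the
    ``group_high_label`` group (numerator; domestic/tame) to that in the
    ``group_low_label`` group (denominator; wild/aggressive).
    """

    symbol: str
    log2fc: float
    species: str = ""
    tissue: str = ""
    group_high_label: str = ""
    group_low_label: str = ""
    p_value: float | None = None
    p_adj: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ValueError("DEGRecord symbol must be non-empty")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc must be finite, got {self.log2fc!r}")
        for name, p in (("p_value", self.p_value), ("p_adj", self.p_adj)):
            if p is not None and not (0.0 < p <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {p!r}")


@dataclass(frozen=True)
class DatasetMeta:
    """One comparison dataset: a domestic/wild contrast in one tissue."""

    source_id: str
    wild_species: str
    domestic_species: str
    tissue: str
    n_deg: int

    def __post_init__(self) -> None:
        if self.n_deg < 0:
            raise ValueError("n_deg must be >= 0")


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping plus the field separator for a DEG table."""

    symbol: str = "symbol"
    log2fc: str = "log2fc"
    species: str | None = "species"
    tissue: str | None = "tissue"
    group_high_label: str | None = "group_high_label"
    group_low_label: str | None = "group_low_label"
    p_value: str | None = "p_value"
    p_adj: str | None = "p_adj"
    source_id: str | None = "source_id"
    separator: str = "\t"

    def required_columns(self) -> tuple[str, ...]:
        return (self.symbol, self.log2fc)


DEFAULT_DIALECT = TableDialect()


def read_deg_table(path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> list[DEGRecord]:
    """Read a delimited DEG table into :class:`DEGRecord` rows.

    Raises :class:`TableParseError` on a missing required column or an
    unparseable numeric cell; the error carries the 1-based data-row index
    and the column name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="") as fh:
        return _read_deg_stream(fh, dialect)


def _read_deg_stream(fh: Iterable[str], dialect: TableDialect) -> list[DEGRecord]:
    reader = csv.DictReader(fh, delimiter=dialect.separator)
    header = reader.fieldnames or []
    for col in dialect.required_columns():
        if col not in header:
            raise TableParseError(f"missing required column {col!r}", column=col)

    def optional(row: dict, col: str | None) -> str:
        return (row.get(col) or "").strip() if col else ""

    records: list[DEGRecord] = []
    for i, row in enumerate(reader, start=1):
        raw_fc = (row.get(dialect.log2fc) or "").strip()
        try:
            log2fc = _clean_number(raw_fc)
        except ValueError:
            raise TableParseError(
                f"row {i}: cannot parse {dialect.log2fc!r} value {raw_fc!r}",
                row=i,
                column=dialect.log2fc,
            ) from None
        p_value = _parse_optional_p(row, dialect.p_value, i)
        p_adj = _parse_optional_p(row, dialect.p_adj, i)
        records.append(
            DEGRecord(
                symbol=(row.get(dialect.symbol) or "").strip(),
                log2fc=log2fc,
                species=optional(row, dialect.species),
                tissue=optional(row, dialect.tissue),
                group_high_label=optional(row, dialect.group_high_label),
                group_low_label=optional(row, dialect.group_low_label),
                p_value=p_value,
                p_adj=p_adj,
                source_id=optional(row, dialect.source_id),
            )
        )
    return records


def _parse_optional_p(row: dict, col: str | None, i: int) -> float | None:
    if not col:
        return None
    raw = (row.get(col) or "").strip()
    if not raw or raw.upper() in {"NA", "ND", "NAN"}:
        return None
    try:
        return _clean_number(raw)
    except ValueError:
        raise TableParseError(
            f"row {i}: cannot parse {col!r} value {raw!r}", row=i, column=col
        ) from None


def write_deg_table(records: Sequence[DEGRecord], path: str | Path,
                    dialect: TableDialect = DEFAULT_DIALECT) -> None:
    """Write records back to disk; numeric fields round-trip bit-exactly."""
    cols = [
        (dialect.symbol, "symbol"),
        (dialect.log2fc, "log2fc"),
        (dialect.species, "species"),
        (dialect.tissue, "tissue"),
        (dialect.group_high_label, "group_high_label"),
        (dialect.group_low_label, "group_low_label"),
        (dialect.p_value, "p_value"),
        (dialect.p_adj, "p_adj"),
        (dialect.source_id, "source_id"),
    ]
    cols = [(c, attr) for c, attr in cols if c]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.separator)
        writer.writerow([c for c, _ in cols])
        for rec in records:
            row = []
            for _, attr in cols:
                v = getattr(rec, attr)
                row.append("" if v is None else repr(v) if isinstance(v, float) else v)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Packaged fixtures (transcribed reference tables)
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table2", "table4", "table5", "table6", "table8")

_FIXTURE_FILES = {
    "table2": ("table2.tsv", "table2_meta.json"),
    "table4": ("table4.tsv",),
    "table5": ("table5.tsv", "table5_totals.tsv"),
    "table6": ("table6.tsv",),
    "table8": ("table8_human.tsv", "table8_animal.tsv"),
    "homology_maps": ("homology_maps.json",),
}

# sha256 of the packaged transcriptions; load_fixture verifies these so a
# silently edited data file fails loudly rather than shifting statistics.
_CHECKSUMS = {
    "table2.tsv": "62e0459787ad89d11cee032bf64e1f61bc3f81a49971cedf86dc7d6b85343557",
    "table2_meta.json": "475e2878e2d691b424e5171948241afd5754cbc66c67e9beb60ae23def0eafdc",
    "table4.tsv": "d08cbcf4c51d2aa6990bac6ee744d61387649eccdc06cb0b2dba96e9225ec556",
    "table5.tsv": "b35d6901c7fc411c07805239a9f58fd71caf908ea4589ec06b43a6cacd31011e",
    "table5_totals.tsv": "f1d6d23b39f848bdf0d28abb550d11211d68d0caa9f8a06baaf99bdcdcd49fba",
    "table6.tsv": "32a1c2d3f6c81adbfc03c3b0fe4d5ab3c7229afde063a9cff085e4c58a724578",
    "table8_human.tsv": "2fa863db2a4e2b03bcacafd02e64976e672e0c5a3c53637c90c33340b5587fcd",
    "table8_animal.tsv": "de708036796a668d953e15eaa8595a1905565be466bc3adc4413a07d7343fcd5",
    "homology_maps.json": "ebe8c466a06385f188ec4c165e19b87a667f08cda77f7aff584907abff20d344",
}


def _fixture_text(filename: str, verify: bool = True) -> str:
    data = resources.files("degcord.fixtures").joinpath(filename).read_bytes()
    if verify:
        digest = hashlib.sha256(data).hexdigest()
        expected = _CHECKSUMS.get(filename)
        if expected is not None and digest != expected:
            raise RuntimeError(
                f"fixture {filename} checksum mismatch: {digest} != {expected}"
            )
    return data.decode("utf-8")


def fixture_checksum(filename: str) -> str:
    data = resources.files("degcord.fixtures").joinpath(filename).read_bytes()
    return hashlib.sha256(data).hexdigest()


@dataclass(frozen=True)
class Table2Fixture:
    rows: tuple[DatasetMeta, ...]
    printed_total_n_deg: int

    @property
    def column_sum(self) -> int:
        return sum(r.n_deg for r in self.rows)


@dataclass(frozen=True)
class QPCRRow:
    gene: str
    group: str
    animal_id: int
    glove_score: int
    rel_expr: float | None  # None when below detection ("ND")
    tech_sem: float | None
    nd_flag: bool


@dataclass(frozen=True)
class Table5Fixture:
    rows: tuple[QPCRRow, ...]
    printed_totals: tuple[dict, ...]  # gene/group/m0/sem as printed


@dataclass(frozen=True)
class HomologPairRow:
    row: int
    focal_symbol: str
    focal_log2fc: float
    focal_p_adj: float
    domestic_group: str
    wild_group: str
    tissue: str
    comp_symbol: str
    comp_log2fc: float
    comp_p_adj: float
    source_id: str


@dataclass(frozen=True)
class Table8Fixture:
    annotations: tuple[dict, ...]  # human_gene, effect_of_deficit, effect_of_excess, evidence_refs
    animal_rows: tuple[dict, ...]  # human_gene, animal_deg, log2fc, deficit_group, excess_group, source_id


def _tsv_rows(filename: str) -> list[dict]:
    return list(csv.DictReader(io.StringIO(_fixture_text(filename)), delimiter="\t"))


def load_fixture(name: str):
    """Return one of the packaged transcribed tables.

    ``name`` must be one of ``table2``, ``table4``, ``table5``, ``table6``
    or ``table8``. Content is checksummed and stable across runs.
    """
    if name == "table2":
        rows = tuple(
            DatasetMeta(
                source_id=r["source_id"],
                wild_species=r["wild_species"],
                domestic_species=r["domestic_species"],
                tissue=r["tissue"],
                n_deg=int(r["n_deg"]),
            )
            for r in _tsv_rows("table2.tsv")
        )
        meta = json.loads(_fixture_text("table2_meta.json"))
        return Table2Fixture(rows=rows, printed_total_n_deg=meta["printed_total_n_deg"])
    if name == "table4":
        return [
            DEGRecord(
                symbol=r["symbol"],
                log2fc=_clean_number(r["log2fc"]),
                species="rats",
                tissue="hypothalamus",
                group_high_label="tame",
                group_low_label="aggressive",
                p_value=_clean_number(r["p_value"]),
                p_adj=_clean_number(r["p_adj"]),
                source_id="this_work",
            )
            for r in _tsv_rows("table4.tsv")
        ]
    if name == "table5":
        rows = []
        for r in _tsv_rows("table5.tsv"):
            nd = r["rel_expr"].strip().upper() == "ND"
            rows.append(
                QPCRRow(
                    gene=r["gene"],
                    group=r["group"],
                    animal_id=int(r["animal_id"]),
                    glove_score=int(r["glove_score"]),
                    rel_expr=None if nd else _clean_number(r["rel_expr"]),
                    tech_sem=_clean_number(r["tech_sem"]) if r["tech_sem"].strip() else None,
                    nd_flag=nd,
                )
            )
        totals = tuple(
            {
                "gene": r["gene"],
                "group": r["group"],
                "m0": _clean_number(r["m0"]),
                "sem": _clean_number(r["sem"]),
            }
            for r in _tsv_rows("table5_totals.tsv")
        )
        return Table5Fixture(rows=tuple(rows), printed_totals=totals)
    if name == "table6":
        return [
            HomologPairRow(
                row=int(r["row"]),
                focal_symbol=r["focal_symbol"],
                focal_log2fc=_clean_number(r["focal_log2fc"]),
                focal_p_adj=_clean_number(r["focal_p_adj"]),
                domestic_group=r["domestic_group"],
                wild_group=r["wild_group"],
                tissue=r["tissue"],
                comp_symbol=r["comp_symbol"],
                comp_log2fc=_clean_number(r["comp_log2fc"]),
                comp_p_adj=_clean_number(r["comp_p_adj"]),
                source_id=r["source_id"],
            )
            for r in _tsv_rows("table6.tsv")
        ]
    if name == "table8":
        return Table8Fixture(
            annotations=tuple(_tsv_rows("table8_human.tsv")),
            animal_rows=tuple(
                {
                    "human_gene": r["human_gene"],
                    "animal_deg": r["animal_deg"],
                    "log2fc": _clean_number(r["log2fc"]),
                    "deficit_group": r["deficit_group"],
                    "excess_group": r["excess_group"],
                    "source_id": r["source_id"],
                }
                for r in _tsv_rows("table8_animal.tsv")
            ),
        )
    raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")


def known_discrepancies() -> dict:
    """Recompute-and-report quirks of the transcribed source tables.

    These are documented, not reproduced: the exact upper-tail binomial
    probability for 7 of 7 same-sign pairs is 1/128 (the source prints a
    smaller bound), and the dataset-inventory column sums to a different
    value than its printed grand total.
    """
    from .stats import binomial_sign_test

    t2 = load_fixture("table2")
    return {
        "binomial_7_of_7": {
            "printed_bound": 1e-3,
            "exact_value": binomial_sign_test(7, 7).p_value,
            "reproduced": False,
        },
        "dataset_inventory_total": {
            "printed_total": t2.printed_total_n_deg,
            "column_sum": t2.column_sum,
            "reproduced": t2.printed_total_n_deg == t2.column_sum,
        },
    }


def table6_comparison_records(rows=None) -> list[DEGRecord]:
    """Comparison-side DEG records (columns v-xi of the 54-pair table)."""
    rows = load_fixture("table6") if rows is None else rows
    return [
        DEGRecord(
            symbol=r.comp_symbol,
            log2fc=r.comp_log2fc,
            species=r.domestic_group,
            tissue=r.tissue,
            group_high_label=r.domestic_group,
            group_low_label=r.wild_group,
            p_adj=r.comp_p_adj,
            source_id=r.source_id,
        )
        for r in rows
    ]
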