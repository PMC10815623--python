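"""Reading and writing sizing tables and reference genotypes.

Genotyping software exports a "sizing table": one row per detected peak
with marker, allele, size (bp), height (RFU), area and data point (scan
index).  Two dialects are supported:

* ``long`` — a single tab-delimited table with a ``Dye`` column;
* ``blocks`` — one section per dye, each introduced by a ``Dye: X`` line
  followed by a header and rows without the dye column (the per-dye export
  layout of some software versions).

The in-memory model is always long: a :class:`SizingTable` wrapping a
pandas DataFrame with canonical columns plus run metadata.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .kits import KitConfig

#: canonical column order of the record frame
RECORD_COLUMNS = (
    "sample_id",
    "dye",
    "marker",
    "allele",
    "size_bp",
    "height_rfu",
    "area",
    "data_point",
)

_HEADER_ALIASES = {
    "sample file": "sample_id",
    "sample id": "sample_id",
    "sample": "sample_id",
    "dye": "dye",
    "marker": "marker",
    "allele": "allele",
    "size": "size_bp",
    "size (bp)": "size_bp",
    "size_bp": "size_bp",
    "height": "height_rfu",
    "height_rfu": "height_rfu",
    "area": "area",
    "data point": "data_point",
    "data_point": "data_point",
    "datapoint": "data_point",
}

_WRITE_HEADERS = {
    "sample_id": "Sample File",
    "dye": "Dye",
    "marker": "Marker",
    "allele": "Allele",
    "size_bp": "Size",
    "height_rfu": "Height",
    "area": "Area",
    "data_point": "Data Point",
}

#: columns that must be present in a sizing-table file (sample/marker/allele
#: default to empty strings when absent)
_MANDATORY = ("size_bp", "height_rfu", "area", "data_point")


class SignalRecord(NamedTuple):
    """One above-threshold peak from a sizing table."""

    sample_id: str
    dye: str
    marker: str
    allele: str
    size_bp: float
    height_rfu: float
    area: float
    data_point: int


def empty_records() -> pd.DataFrame:
    """An empty record frame with canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "sample_id": pd.Series(dtype=str),
            "dye": pd.Series(dtype=str),
            "marker": pd.Series(dtype=str),
            "allele": pd.Series(dtype=str),
            "size_bp": pd.Series(dtype=float),
            "height_rfu": pd.Series(dtype=float),
            "area": pd.Series(dtype=float),
            "data_point": pd.Series(dtype=np.int64),
        }
    )


@dataclass
class SizingTable:
    """An ordered collection of peak records plus run metadata.

    ``sample_role`` is one of ``negative``, ``positive`` or ``ladder``;
    ``template_pg`` records the DNA input of a positive low-template run.
    """

    records: pd.DataFrame = field(default_factory=empty_records)
    lab_id: str = ""
    kit_id: str = ""
    run_date: _dt.date | None = None
    pcr_cycles: int | None = None
    sample_role: str = "negative"
    template_pg: float | None = None

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"record frame missing columns: {missing}")
        self.records = df.loc[:, list(RECORD_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def with_records(self, records: pd.DataFrame) -> "SizingTable":
        """A copy of this table carrying the same metadata but new records."""
        return replace(self, records=records.reset_index(drop=True))

    def iter_records(self) -> Iterator[SignalRecord]:
        for row in self.records.itertuples(index=False):
            yield SignalRecord(
                sample_id=row.sample_id,
                dye=row.dye,
                marker=row.marker,
                allele=row.allele,
                size_bp=float(row.size_bp),
                height_rfu=float(row.height_rfu),
                area=float(row.area),
                data_point=int(row.data_point),
            )

    def heights(self, dye: str | None = None) -> np.ndarray:
        """Peak heights (RFU), optionally restricted to one dye."""
        df = self.records
        if dye is not None:
            df = df[df["dye"] == dye]
        return df["height_rfu"].to_numpy(dtype=float)

    def dye_counts(self) -> dict[str, int]:
        return self.records["dye"].value_counts().to_dict()


def _read_text(source: str | Path) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    if isinstance(source, Path):
        return source.read_text()
    text = str(source)
    if "\t" in text or "\n" in text or "," in text:
        return text
    path = Path(text)
    if path.exists():
        return path.read_text()
    raise FormatError(f"input file not found: {source}")


def _normalize_header(cells: list[str]) -> list[str]:
    out = []
    for cell in cells:
        key = cell.strip().lower().replace("-", " ")
        out.append(_HEADER_ALIASES.get(key, key))
    return out


def _parse_block(
    header: list[str],
    rows: list[tuple[int, list[str]]],
    fixed_dye: str | None,
    bad_rows: list[tuple[int, str]],
    out: list[dict],
) -> None:
    col_idx = {name: i for i, name in enumerate(header)}
    for lineno, cells in rows:
        rec: dict = {}
        try:
            rec["size_bp"] = float(cells[col_idx["size_bp"]])
            rec["height_rfu"] = float(cells[col_idx["height_rfu"]])
            rec["area"] = float(cells[col_idx["area"]])
            rec["data_point"] = int(float(cells[col_idx["data_point"]]))
        except (ValueError, IndexError) as exc:
            bad_rows.append((lineno, str(exc)))
            continue
        rec["dye"] = fixed_dye if fixed_dye is not None else cells[col_idx["dye"]].strip()
        for opt in ("sample_id", "marker", "allele"):
            if opt in col_idx and col_idx[opt] < len(cells):
                rec[opt] = cells[col_idx[opt]].strip()
            else:
                rec[opt] = ""
        if rec["size_bp"] <= 0 or rec["height_rfu"] < 0:
            bad_rows.append((lineno, "size must be > 0 and height >= 0"))
            continue
        out.append(rec)


def parse_sizing_table(
    source,
    kit: KitConfig,
    dialect: str = "long",
    **metadata,
) -> SizingTable:
    """Parse a tab-delimited sizing-table export.

    ``dialect`` is ``"long"`` (single table with a Dye column) or
    ``"blocks"`` (per-dye sections, each opened by a ``Dye: X`` line).
    Extra keyword arguments become :class:`SizingTable` metadata.

    Rows with unparseable size/height/area/data-point values are rejected
    explicitly: a :class:`FormatError` names every offending line.  Dye
    labels not declared by the kit raise :class:`ValidationError`.
    """
    text = _read_text(source)
    lines = text.splitlines()
    bad_rows: list[tuple[int, str]] = []
    out: list[dict] = []

    if dialect == "long":
        content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
        if not content:
            return SizingTable(empty_records(), **metadata)
        header = _normalize_header(content[0][1].split("\t"))
        missing = [c for c in _MANDATORY + ("dye",) if c not in header]
        if missing:
            raise FormatError(f"sizing table missing mandatory column(s): {missing}")
        rows = [(n, ln.split("\t")) for n, ln in content[1:]]
        _parse_block(header, rows, None, bad_rows, out)
    elif dialect == "blocks":
        header: list[str] | None = None
        fixed_dye: str | None = None
        rows: list[tuple[int, list[str]]] = []

        def flush():
            if fixed_dye is not None and header is not None:
                _parse_block(header, rows, fixed_dye, bad_rows, out)

        for i, ln in enumerate(lines):
            if not ln.strip():
                continue
            if ln.startswith("Dye:"):
                flush()
                fixed_dye = ln.split(":", 1)[1].strip()
                header = None
                rows = []
            elif fixed_dye is not None and header is None:
                header = _normalize_header(ln.split("\t"))
                missing = [c for c in _MANDATORY if c not in header]
                if missing:
                    raise FormatError(
                        f"block for dye {fixed_dye}: missing mandatory column(s): {missing}"
                    )
            elif fixed_dye is not None:
                rows.append((i + 1, ln.split("\t")))
            else:
                raise FormatError(f"line {i + 1}: data before any 'Dye:' block header")
        flush()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if bad_rows:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad_rows[:10])
        raise FormatError(f"{len(bad_rows)} unparseable data row(s) rejected: {detail}")

    if out:
        df = pd.DataFrame(out, columns=list(RECORD_COLUMNS))
        df["data_point"] = df["data_point"].astype(np.int64)
    else:
        df = empty_records()

    unknown = sorted(set(df["dye"]) - set(kit.dyes))
    if unknown:
        raise ValidationError(
            f"dye label(s) not declared by kit {kit.kit_name!r}: {unknown}"
        )
    return SizingTable(df, **metadata)


def _format_row(row) -> list[str]:
    return [
        str(row.sample_id),
        str(row.marker),
        str(row.allele),
        repr(float(row.size_bp)),
        repr(float(row.height_rfu)),
        repr(float(row.area)),
        str(int(row.data_point)),
    ]


def write_sizing_table(table: SizingTable, dest: str | Path, dialect: str = "long") -> None:
    """Write a sizing table in a dialect :func:`parse_sizing_table` reads back.

    Floats are written with full precision so a write/parse round trip
    reproduces every record field exactly.
    """
    lines: list[str] = []
    if dialect == "long":
        cols = ["sample_id", "dye", "marker", "allele", "size_bp", "height_rfu", "area", "data_point"]
        lines.append("\t".join(_WRITE_HEADERS[c] for c in cols))
        for row in table.records.itertuples(index=False):
            cells = _format_row(row)
            cells.insert(1, str(row.dye))
            lines.append("\t".join(cells))
    elif dialect == "blocks":
        cols = ["sample_id", "marker", "allele", "size_bp", "height_rfu", "area", "data_point"]
        # preserve order of first appearance of each dye
        for dye in dict.fromkeys(table.records["dye"]):
            lines.append(f"Dye: {dye}")
            lines.append("\t".join(_WRITE_HEADERS[c] for c in cols))
            sub = table.records[table.records["dye"] == dye]
            for row in sub.itertuples(index=False):
                lines.append("\t".join(_format_row(row)))
            lines.append("")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    Path(dest).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reference genotypes
# ---------------------------------------------------------------------------

ReferenceGenotype = dict[str, frozenset[str]]
"""Per-marker expected allele labels: 1 label for homozygotes, 2 for heterozygotes."""


def parse_genotype(source, kit: KitConfig) -> ReferenceGenotype:
    """Parse a two-column reference genotype file.

    Each non-comment line reads ``marker,alleles`` with allele labels
    separated by ``/`` (e.g. ``M1,10/12``; homozygote ``M1,10``).  Markers
    must exist in the kit; more than two alleles at a marker is an error.
    """
    text = _read_text(source)
    genotype: ReferenceGenotype = {}
    known = set(kit.marker_names)
    for i, ln in enumerate(text.splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split(",")
        if len(parts) != 2:
            raise FormatError(f"line {i}: expected 'marker,alleles', got {ln!r}")
        marker, alleles_field = parts[0].strip(), parts[1].strip()
        alleles = frozenset(a.strip() for a in alleles_field.split("/") if a.strip())
        if marker not in known:
            raise ValidationError(f"line {i}: marker {marker!r} not defined by kit")
        if not 1 <= len(alleles) <= 2:
            raise ValidationError(
                f"line {i}: marker {marker} has {len(alleles)} alleles; expected 1 or 2"
            )
        genotype[marker] = alleles
    return genotype


def write_genotype(genotype: ReferenceGenotype, path: str | Path) -> None:
    lines = [f"{m},{'/'.join(sorted(a))}" for m, a in sorted(genotype.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def concat_tables(tables: Iterable[SizingTable]) -> pd.DataFrame:
    """Concatenate the record frames of several tables (order preserved)."""
    frames = [t.records for t in tables if len(t)]
    if not frames:
        return empty_records()
    return pd.concat(frames, ignore_index=True)
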