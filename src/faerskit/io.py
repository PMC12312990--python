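"""Reading and writing the FAERS quarterly ASCII dialect.

The FDA Adverse Event Reporting System publishes each quarter as a set of
``$``-delimited text files with a single header row.  Three of them carry
everything a disproportionality analysis needs:

* ``DEMOyyQq.txt`` — one row per report version: identifiers, patient sex,
  age (with a unit code), and the reporter's occupation;
* ``DRUGyyQq.txt`` — one row per drug mention: role code (PS/SS/C/I) and
  the product's active ingredient;
* ``REACyyQq.txt`` — one row per reported reaction, as a MedDRA
  preferred term (PT).

Parsing is header-driven (column order is read from the first line, never
assumed), fields are ``$``-separated with no quoting, and empty fields map
to ``None`` — never to sentinel numbers.  Files are read as UTF-8 with a
latin-1 fallback because older quarters contain non-UTF-8 bytes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

DELIMITER = "$"

QUARTER_RE = re.compile(r"^\d{4}Q[1-4]$")

#: occupation codes the FDA assigns to health-care professionals
PROFESSIONAL_OCCUPATIONS = frozenset({"HP", "MD", "OT", "PH"})


class FaersFormatError(ValueError):
    """A file does not conform to the FAERS ASCII dialect."""


@dataclass(frozen=True)
class RawDemoRecord:
    """One row of a DEMO file: report/case identifiers plus demographics."""

    primaryid: str
    caseid: str
    caseversion: Optional[int] = None
    age: Optional[float] = None
    age_cod: Optional[str] = None
    sex: Optional[str] = None
    occp_cod: Optional[str] = None
    quarter: Optional[str] = None


@dataclass(frozen=True)
class RawDrugRecord:
    """One row of a DRUG file: a drug mention with its reported role."""

    primaryid: str
    drug_seq: Optional[int] = None
    role_cod: Optional[str] = None
    prod_ai: Optional[str] = None
    drugname: Optional[str] = None


@dataclass(frozen=True)
class RawReacRecord:
    """One row of a REAC file: a MedDRA preferred term for one report."""

    primaryid: str
    pt: Optional[str] = None


_KIND_SPEC = {
    # kind -> (record class, required columns, optional columns)
    "demo": (
        RawDemoRecord,
        ("primaryid", "caseid", "caseversion", "age", "age_cod", "sex", "occp_cod"),
        (),
    ),
    "drug": (
        RawDrugRecord,
        ("primaryid", "drug_seq", "role_cod", "prod_ai"),
        ("drugname",),
    ),
    "reac": (RawReacRecord, ("primaryid", "pt"), ()),
}

_INT_FIELDS = {"caseversion", "drug_seq"}
_FLOAT_FIELDS = {"age"}


@dataclass
class ParseDiagnostics:
    """Per-file parse accounting."""

    path: str = ""
    n_rows: int = 0
    n_skipped: int = 0
    skipped_lines: list = None  # line numbers (1-based), capped

    def __post_init__(self):
        if self.skipped_lines is None:
            self.skipped_lines = []


class ParsedFile(Sequence):
    """Sequence of raw records plus :class:`ParseDiagnostics`.

    Behaves like the list of records it wraps, so callers that only care
    about the rows can iterate it directly.
    """

    def __init__(self, records: list, diagnostics: ParseDiagnostics):
        self.records = records
        self.diagnostics = diagnostics

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __eq__(self, other):
        if isinstance(other, ParsedFile):
            return self.records == other.records
        return self.records == other


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def _coerce(field_name: str, raw: str):
    raw = raw.strip()
    if raw == "":
        return None
    if field_name in _INT_FIELDS:
        try:
            value = int(float(raw))
        except ValueError:
            return None
        return value if value >= 0 else None
    if field_name in _FLOAT_FIELDS:
        try:
            value = float(raw)
        except ValueError:
            return None
        return value if value >= 0 else None
    return raw


def infer_quarter(path: Union[str, Path]) -> Optional[str]:
    """Derive a ``YYYYQq`` label from a FAERS file name like ``DEMO20Q3.txt``."""
    m = re.match(r"^(?:demo|drug|reac)(\d{2})q([1-4])", Path(path).name, re.IGNORECASE)
    if not m:
        return None
    return f"20{m.group(1)}Q{m.group(2)}"


def detect_kind(path: Union[str, Path]) -> Optional[str]:
    """Guess demo/drug/reac from a FAERS-style file name, or ``None``."""
    name = Path(path).name.lower()
    for kind in _KIND_SPEC:
        if name.startswith(kind):
            return kind
    return None


def parse_faers_file(
    path: Union[str, Path],
    file_kind: str,
    quarter: Optional[str] = None,
) -> ParsedFile:
    """Parse one FAERS ASCII file into typed raw records.

    Parameters
    ----------
    path
        The ``$``-delimited file; first line must be a header naming at
        least the required columns for *file_kind* (case-insensitive).
    file_kind
        One of ``"demo"``, ``"drug"``, ``"reac"`` — never sniffed.
    quarter
        ``YYYYQq`` label stamped on demo records; inferred from the file
        name when omitted.

    Raises
    ------
    FaersFormatError
        If a required column is missing from the header.
    """
    if file_kind not in _KIND_SPEC:
        raise ValueError(f"file_kind must be demo, drug or reac, got {file_kind!r}")
    path = Path(path)
    cls, required, optional = _KIND_SPEC[file_kind]
    if quarter is None:
        quarter = infer_quarter(path)
    if quarter is not None and not QUARTER_RE.match(quarter):
        raise ValueError(f"quarter label {quarter!r} does not match YYYYQ[1-4]")

    text = _read_text(path)
    lines = text.splitlines()
    if not lines:
        raise FaersFormatError(f"{path}: empty file, no header row")

    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    col_index = {}
    for i, name in enumerate(header):
        col_index.setdefault(name, i)
    for col in required:
        if col not in col_index:
            raise FaersFormatError(f"{path}: required column {col!r} missing from header")

    wanted = list(required) + [c for c in optional if c in col_index]
    positions = {c: col_index[c] for c in wanted}
    min_fields = max(positions[c] for c in required) + 1

    diagnostics = ParseDiagnostics(path=str(path))
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line.strip() == "":
            continue
        parts = line.split(DELIMITER)
        if len(parts) < min_fields:
            diagnostics.n_skipped += 1
            if len(diagnostics.skipped_lines) < 100:
                diagnostics.skipped_lines.append(lineno)
            continue
        values = {}
        for col, pos in positions.items():
            values[col] = _coerce(col, parts[pos]) if pos < len(parts) else None
        if not values.get("primaryid"):
            diagnostics.n_skipped += 1
            if len(diagnostics.skipped_lines) < 100:
                diagnostics.skipped_lines.append(lineno)
            continue
        if file_kind == "demo":
            values["quarter"] = quarter
        records.append(cls(**values))
        diagnostics.n_rows += 1
    return ParsedFile(records, diagnostics)


def _field_to_text(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(int(value)) if value == int(value) else repr(value)
    return str(value)


def write_faers_file(records: Sequence, path: Union[str, Path]) -> Path:
    """Write homogeneous raw records back out in the FAERS dialect.

    Round-trips with :func:`parse_faers_file`: parsing the written file
    reproduces the records field-for-field (the demo ``quarter`` label is
    provenance, carried by the file name or the ``quarter`` argument, not
    by a column).
    """
    path = Path(path)
    records = list(records)
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError(f"records must be homogeneous in kind, got {sorted(k.__name__ for k in kinds)}")
    if records:
        cls = type(records[0])
    else:
        cls = {"demo": RawDemoRecord, "drug": RawDrugRecord, "reac": RawReacRecord}.get(
            detect_kind(path) or "", None
        )
        if cls is None:
            raise ValueError("cannot determine file kind for an empty record list; name the file DEMO*/DRUG*/REAC*")
    columns = [f.name for f in dc_fields(cls) if f.name != "quarter"]
    lines = [DELIMITER.join(columns)]
    for rec in records:
        lines.append(DELIMITER.join(_field_to_text(getattr(rec, c)) for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_quarter_dir(directory: Union[str, Path]):
    """Read every DEMO/DRUG/REAC file under *directory* (non-recursive).

    Returns three lists of raw records (demo, drug, reac), concatenated
    across quarters, plus a list of :class:`ParseDiagnostics`.
    """
    directory = Path(directory)
    demo, drug, reac = [], [], []
    diags = []
    buckets = {"demo": demo, "drug": drug, "reac": reac}
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        kind = detect_kind(path)
        if kind is None or path.suffix.lower() not in {".txt", ".tsv", ""}:
            continue
        parsed = parse_faers_file(path, kind)
        buckets[kind].extend(parsed.records)
        diags.append(parsed.diagnostics)
    return demo, drug, reac, diags
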