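"""Clinical-record data model, punctuation segmentation, and corpus I/O.

A record is one patient visit: up to seven free-text diagnostic fields plus
an optional syndrome label.  Field texts are segmented into symptom tokens
by splitting on a configurable punctuation set; tokens are compared by exact
string equality after whitespace trimming (no synonym normalisation).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FieldType",
    "DIAGNOSTIC_FIELDS",
    "EMRecord",
    "SymptomToken",
    "DEFAULT_PUNCTUATION",
    "CorpusFormatError",
    "segment_field",
    "read_corpus",
    "write_corpus",
]


class FieldType(str, Enum):
    """The eight entity categories of the record schema."""

    TONGUE_INSPECTION = "tongue inspection"
    PULSE_TAKING = "pulse taking"
    LISTENING_AND_SMELLING = "listening and smelling"
    INSPECTION = "inspection"
    BODY_SURFACE_EXAMINATION = "body surface examination"
    NURSING_PRECAUTIONS = "nursing precautions"
    DIAGNOSIS_OF_TCM = "diagnosis of TCM"
    SYNDROME = "syndrome"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The seven free-text diagnostic fields (everything except the label).
DIAGNOSTIC_FIELDS: tuple[FieldType, ...] = tuple(
    ft for ft in FieldType if ft is not FieldType.SYNDROME
)

#: ASCII and full-width separators; configurable everywhere it is used.
DEFAULT_PUNCTUATION = ",;。，、；　"

_FORBIDDEN = ("\t", "\n", "\r")


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files or invalid record contents."""


def _check_text(value: str, what: str) -> None:
    if any(ch in value for ch in _FORBIDDEN):
        raise CorpusFormatError(
            f"{what} contains a reserved delimiter character (tab/newline): {value!r}"
        )


@dataclass
class EMRecord:
    """One clinical visit: typed free-text fields plus an optional label.

    ``fields`` maps each diagnostic :class:`FieldType` to its raw text;
    missing fields are empty strings.  A training record must carry a
    non-empty ``syndrome``; a prediction record may leave it ``None``.
    """

    record_id: str
    fields: dict[FieldType, str] = field(default_factory=dict)
    syndrome: str | None = None

    def __post_init__(self) -> None:
        _check_text(self.record_id, "record_id")
        clean: dict[FieldType, str] = {}
        for ft, text in self.fields.items():
            ft = FieldType(ft)
            if ft is FieldType.SYNDROME:
                raise CorpusFormatError(
                    "the syndrome label belongs in EMRecord.syndrome, not fields"
                )
            _check_text(text, f"field {ft.value!r}")
            clean[ft] = text
        for ft in DIAGNOSTIC_FIELDS:
            clean.setdefault(ft, "")
        self.fields = clean
        if self.syndrome is not None:
            _check_text(self.syndrome, "syndrome")
            if not self.syndrome.strip():
                self.syndrome = None

    @property
    def is_labelled(self) -> bool:
        return bool(self.syndrome and self.syndrome.strip())


@dataclass(frozen=True)
class SymptomToken:
    """A normalised token together with the field it was segmented from."""

    text: str
    field_type: FieldType

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("SymptomToken.text must be non-empty after trimming")
        _check_text(self.text, "token")


def segment_field(text: str, punctuation: str = DEFAULT_PUNCTUATION) -> list[str]:
    """Split ``text`` on any character of ``punctuation``.

    Returns the maximal substrings between punctuation characters, each
    trimmed of surrounding whitespace, with empty fragments dropped and
    original order preserved.  Duplicates are retained; deduplication is a
    vocabulary-level concern.
    """
    if not punctuation:
        raise ValueError("punctuation set must be non-empty")
    marks = set(punctuation)
    tokens: list[str] = []
    current: list[str] = []
    for ch in text:
        if ch in marks:
            frag = "".join(current).strip()
            if frag:
                tokens.append(frag)
            current = []
        else:
            current.append(ch)
    frag = "".join(current).strip()
    if frag:
        tokens.append(frag)
    return tokens


def tokenize_record(
    record: EMRecord,
    punctuation: str = DEFAULT_PUNCTUATION,
    *,
    include_nursing: bool = True,
) -> list[SymptomToken]:
    """Segment every diagnostic field of ``record`` into typed tokens."""
    out: list[SymptomToken] = []
    for ft in DIAGNOSTIC_FIELDS:
        if not include_nursing and ft is FieldType.NURSING_PRECAUTIONS:
            continue
        for tok in segment_field(record.fields.get(ft, ""), punctuation):
            out.append(SymptomToken(tok, ft))
    return out


# --------------------------------------------------------------------------
# Corpus I/O.  Two dialects:
#   * "tsv"   - one record per line, columns: record_id, 7 field texts,
#               syndrome (UTF-8, header row, tab-separated)
#   * "jsonl" - one JSON object per line with keys record_id / fields /
#               syndrome
# --------------------------------------------------------------------------

_TSV_HEADER = ["record_id", *(ft.value for ft in DIAGNOSTIC_FIELDS), "syndrome"]

DIALECTS = ("tsv", "jsonl")


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in DIALECTS:
            raise ValueError(f"unknown corpus dialect {dialect!r}; expected one of {DIALECTS}")
        return dialect
    return "jsonl" if path.suffix == ".jsonl" else "tsv"


def read_corpus(
    path: str | Path,
    dialect: str | None = None,
    *,
    require_labels: bool = False,
) -> list[EMRecord]:
    """Read a corpus file into records.

    ``dialect`` is inferred from the file suffix when omitted.  With
    ``require_labels`` every record must carry a non-empty syndrome label
    (strict-training mode).  Duplicate record ids and malformed rows raise
    :class:`CorpusFormatError` naming the offending line.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    records: list[EMRecord] = []
    seen_ids: set[str] = set()
    with path.open("r", encoding="utf-8", newline="") as fh:
        if dialect == "tsv":
            reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
            try:
                header = next(reader)
            except StopIteration:
                raise CorpusFormatError(f"{path}: empty file (missing header)") from None
            if header != _TSV_HEADER:
                raise CorpusFormatError(
                    f"{path}: unexpected header {header!r}; expected {_TSV_HEADER!r}"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != len(_TSV_HEADER):
                    raise CorpusFormatError(
                        f"{path}:{lineno}: expected {len(_TSV_HEADER)} columns, got {len(row)}"
                    )
                rid = row[0]
                fields = dict(zip(DIAGNOSTIC_FIELDS, row[1:-1]))
                syndrome = row[-1] or None
                records.append(_make_record(rid, fields, syndrome, seen_ids, path, lineno))
        else:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                if not isinstance(obj, dict):
                    raise CorpusFormatError(f"{path}:{lineno}: expected a JSON object")
                rid = obj.get("record_id", "")
                raw_fields = obj.get("fields", {})
                try:
                    fields = {FieldType(k): str(v) for k, v in raw_fields.items()}
                except ValueError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
                syndrome = obj.get("syndrome")
                records.append(_make_record(rid, fields, syndrome, seen_ids, path, lineno))
    if require_labels:
        for i, rec in enumerate(records):
            if not rec.is_labelled:
                raise CorpusFormatError(
                    f"{path}: record {rec.record_id!r} (#{i}) lacks a syndrome label "
                    "(required in strict-training mode)"
                )
    return records


def _make_record(
    rid: str,
    fields: dict[FieldType, str],
    syndrome: str | None,
    seen_ids: set[str],
    path: Path,
    lineno: int,
) -> EMRecord:
    if not rid:
        rid = f"r{len(seen_ids)}"
    if rid in seen_ids:
        raise CorpusFormatError(f"{path}:{lineno}: duplicate record_id {rid!r}")
    seen_ids.add(rid)
    try:
        return EMRecord(record_id=rid, fields=fields, syndrome=syndrome)
    except ValueError as exc:
        raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc


def write_corpus(
    records: Sequence[EMRecord] | Iterable[EMRecord],
    path: str | Path,
    dialect: str | None = None,
) -> Path:
    """Write records so that :func:`read_corpus` reproduces them exactly."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    records = list(records)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if dialect == "tsv":
            fh.write("\t".join(_TSV_HEADER) + "\n")
            for rec in records:
                cells = [rec.record_id]
                cells += [rec.fields.get(ft, "") for ft in DIAGNOSTIC_FIELDS]
                cells.append(rec.syndrome or "")
                for c in cells:
                    _check_text(c, "corpus cell")
                fh.write("\t".join(cells) + "\n")
        else:
            for rec in records:
                obj = {
                    "record_id": rec.record_id,
                    "fields": {ft.value: txt for ft, txt in rec.fields.items() if txt},
                    "syndrome": rec.syndrome,
                }
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    return path
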