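"""Transcript and cohort-metadata input/output.

A *transcript* is the ordered word-token sequence a subject produced (the
study design concatenates three free-speech memory reports per subject —
dream, day, image — into one text). Tokenization is deliberately
non-semantic: no lemmatization, no stop-word removal, no part-of-speech
information; every surface word form is its own symbol.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Group",
    "Sex",
    "Transcript",
    "EmptyTranscriptError",
    "tokenize",
    "read_cohort",
    "write_cohort",
    "read_metadata",
    "REPORT_ORDER",
]

#: fixed concatenation order when a subject's text is split across report files
REPORT_ORDER = ("dream", "day", "image")


class Group(str, Enum):
    CONTROL = "control"
    PSYCHOSIS = "psychosis"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class EmptyTranscriptError(ValueError):
    """Raised when a text yields no tokens (empty or all punctuation)."""


# Maximal runs of Unicode letters/digits, optionally joined by a single
# internal apostrophe or hyphen ("dog's", "well-being"). Underscore is not a
# word character here. Leading/trailing apostrophes and hyphens separate.
_WORD = r"[^\W_]+"
_TOKEN_RE = re.compile(rf"{_WORD}(?:['’-]{_WORD})*")
_TOKEN_RE_SPLIT_APOS = re.compile(rf"{_WORD}(?:-{_WORD})*")
_TOKEN_RE_SPLIT_BOTH = re.compile(_WORD)
_TOKEN_RE_SPLIT_HYPHEN = re.compile(rf"{_WORD}(?:['’]{_WORD})*")


def tokenize(
    raw_text: str,
    *,
    split_apostrophes: bool = False,
    split_hyphens: bool = False,
    subject_id: str | None = None,
) -> list[str]:
    """Split text into lower-cased word tokens, preserving order.

    Tokens are maximal runs of letters/digits; a single apostrophe or hyphen
    *inside* a run is kept as part of the token unless the corresponding
    ``split_*`` flag is set (the original graph software's convention on
    these characters is unknown, so both behaviours are available).
    Punctuation and whitespace are discarded. No lemmatization.

    Raises
    ------
    EmptyTranscriptError
        If no token survives, e.g. for ``"..."``.
    """
    if split_apostrophes and split_hyphens:
        pat = _TOKEN_RE_SPLIT_BOTH
    elif split_apostrophes:
        pat = _TOKEN_RE_SPLIT_APOS
    elif split_hyphens:
        pat = _TOKEN_RE_SPLIT_HYPHEN
    else:
        pat = _TOKEN_RE
    # fold before extraction: folding can introduce combining marks that are
    # not word characters, and tokens must re-tokenize to themselves
    tokens = pat.findall(raw_text.casefold())
    if not tokens:
        who = f" for subject {subject_id!r}" if subject_id else ""
        raise EmptyTranscriptError(f"empty transcript{who}")
    return tokens


@dataclass
class Transcript:
    """One subject's token sequence plus cohort metadata.

    ``age_years`` / ``education_years`` are the candidate time variables t of
    the maturation model. Optional clinical covariates are carried through
    untouched for confound analyses.
    """

    subject_id: str
    tokens: list[str]
    group: Group
    age_years: float
    education_years: float
    sex: Sex = Sex.UNKNOWN
    income: float | None = None
    panss_negative: float | None = None
    cpz_dose: float | None = None
    dropout: bool | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tokens:
            raise EmptyTranscriptError(
                f"empty transcript for subject {self.subject_id!r}"
            )
        if any(not t for t in self.tokens):
            raise ValueError(f"blank token in transcript {self.subject_id!r}")
        if self.age_years < 0 or self.education_years < 0:
            raise ValueError(f"negative age/education for {self.subject_id!r}")
        if self.education_years > self.age_years:
            # real cohorts can violate naive rules (rounding, grade skipping);
            # warn but keep the record
            warnings.warn(
                f"subject {self.subject_id!r}: education_years "
                f"({self.education_years}) exceeds age_years ({self.age_years})",
                stacklevel=2,
            )

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


_METADATA_COLUMNS = [
    "subject_id",
    "group",
    "age_years",
    "education_years",
    "sex",
    "income",
    "panss_negative",
    "cpz_dose",
    "dropout",
]

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "": None, "nan": None,
}


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a cohort metadata table (CSV or TSV, delimiter auto-detected)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    # round_trip: the default float parser can be one ULP off
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str},
                     float_precision="round_trip")
    missing = {"subject_id", "group", "age_years", "education_years"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id in metadata: {dups}")
    return df


def _parse_group(value: str) -> Group:
    try:
        return Group(str(value).strip().casefold())
    except ValueError:
        raise ValueError(f"unknown group label: {value!r}") from None


def _parse_sex(value) -> Sex:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return Sex.UNKNOWN
    try:
        return Sex(str(value).strip().casefold())
    except ValueError:
        return Sex.UNKNOWN


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    v = float(value)
    return None if pd.isna(v) else v


def _parse_optional_bool(value) -> bool | None:
    if value is None or isinstance(value, bool):
        return value
    if isinstance(value, float):
        return None if pd.isna(value) else bool(value)
    if isinstance(value, int):
        return bool(value)
    return _BOOL_MAP.get(str(value).strip().casefold())


def _find_text(directory: Path, subject_id: str) -> str | None:
    """Locate a subject's text: one file, or three report files concatenated."""
    single = directory / f"{subject_id}.txt"
    if single.exists():
        return single.read_text(encoding="utf-8")
    parts = [directory / f"{subject_id}_{r}.txt" for r in REPORT_ORDER]
    if all(p.exists() for p in parts):
        return "\n".join(p.read_text(encoding="utf-8") for p in parts)
    return None


def read_cohort(
    transcript_source: str | Path | Mapping[str, str],
    metadata_table: str | Path | pd.DataFrame,
    **tokenize_kwargs,
) -> list[Transcript]:
    """Assemble Transcripts from raw texts plus a metadata table.

    ``transcript_source`` is either a directory of ``<subject_id>.txt`` files
    (or ``<subject_id>_{dream,day,image}.txt`` triplets, concatenated in that
    fixed order), or an in-memory mapping ``subject_id -> raw text``.
    Metadata rows whose text cannot be found are skipped with a warning.
    """
    if isinstance(metadata_table, pd.DataFrame):
        meta = metadata_table
        if meta["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in metadata")
    else:
        meta = read_metadata(metadata_table)

    def lookup(sid: str) -> str | None:
        if isinstance(transcript_source, Mapping):
            return transcript_source.get(sid)
        return _find_text(Path(transcript_source), sid)

    cohort: list[Transcript] = []
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        text = lookup(sid)
        if text is None:
            warnings.warn(f"no transcript found for subject {sid!r}; skipped",
                          stacklevel=2)
            continue
        cohort.append(
            Transcript(
                subject_id=sid,
                tokens=tokenize(text, subject_id=sid, **tokenize_kwargs),
                group=_parse_group(row.group),
                age_years=float(row.age_years),
                education_years=float(row.education_years),
                sex=_parse_sex(getattr(row, "sex", None)),
                income=_parse_optional_float(getattr(row, "income", None)),
                panss_negative=_parse_optional_float(
                    getattr(row, "panss_negative", None)),
                cpz_dose=_parse_optional_float(getattr(row, "cpz_dose", None)),
                dropout=_parse_optional_bool(getattr(row, "dropout", None)),
            )
        )
    return cohort


def write_cohort(
    cohort: Iterable[Transcript],
    out_dir: str | Path,
    *,
    metadata_name: str = "metadata.csv",
) -> Path:
    """Write one ``<subject_id>.txt`` per transcript plus a metadata CSV.

    Produces exactly the dialect :func:`read_cohort` consumes, so a cohort
    round-trips losslessly (tokens are stored space-joined, which tokenize
    maps back to itself).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in cohort:
        (out / f"{t.subject_id}.txt").write_text(" ".join(t.tokens),
                                                 encoding="utf-8")
        rows.append({
            "subject_id": t.subject_id,
            "group": t.group.value,
            "age_years": t.age_years,
            "education_years": t.education_years,
            "sex": t.sex.value,
            "income": t.income,
            "panss_negative": t.panss_negative,
            "cpz_dose": t.cpz_dose,
            "dropout": t.dropout,
        })
    meta_path = out / metadata_name
    # repr gives shortest round-tripping float strings; pandas' default
    # formatter can drop the last significant digit
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(
        meta_path, index=False, float_format=lambda v: repr(float(v)))
    return meta_path


def save_json(obj, path: str | Path) -> None:
    """Serialize a results mapping (fit / test output) to JSON."""
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable),
                          encoding="utf-8")


def _jsonable(o):
    if hasattr(o, "_asdict"):
        return o._asdict()
    if hasattr(o, "__dict__"):
        return o.__dict__
    if hasattr(o, "tolist"):
        return o.tolist()
    return str(o)
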