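"""Rearrangement tables in AIRR and Change-O dialects.

A repertoire is held as a :class:`pandas.DataFrame` with AIRR
Rearrangement column names (``sequence_id``, ``sequence_alignment``,
``v_call``, ``j_call``, ``junction``, ``junction_length``,
``productive``).  The legacy Change-O dialect (``SEQUENCE_ID``,
``SEQUENCE_IMGT``, ...) is mapped onto the same columns at read time.
Corrected allele assignments are written to an added
``v_call_genotyped`` column; the original ``v_call`` is never touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .germline import GermlineDatabase, V_REGION_END, parse_allele_name

logger = logging.getLogger(__name__)

AIRR_COLUMNS = (
    "sequence_id",
    "sequence_alignment",
    "v_call",
    "j_call",
    "junction",
    "junction_length",
    "productive",
)

#: Change-O column dialect -> AIRR column names.
CHANGEO_TO_AIRR = {
    "SEQUENCE_ID": "sequence_id",
    "SEQUENCE_IMGT": "sequence_alignment",
    "V_CALL": "v_call",
    "J_CALL": "j_call",
    "JUNCTION": "junction",
    "JUNCTION_LENGTH": "junction_length",
    "FUNCTIONAL": "productive",
}

MANDATORY = ("sequence_id", "sequence_alignment", "v_call")

_TRUE = {"T", "TRUE", "true", "True", "1", "t"}
_FALSE = {"F", "FALSE", "false", "False", "0", "f", ""}


class RepertoireError(ValueError):
    pass


@dataclass(frozen=True)
class RearrangementRecord:
    """One unique observed BCR sequence in IMGT coordinates."""

    sequence_id: str
    gapped_observed: str
    v_call: tuple[str, ...]
    j_call: str = ""
    junction: str = ""
    junction_length: int | None = None
    productive: bool = True


@dataclass
class Repertoire:
    """Ordered collection of rearrangement records plus provenance."""

    data: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in MANDATORY:
            if col not in self.data.columns:
                raise RepertoireError(f"missing mandatory column {col!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def grouping_call(self) -> pd.Series:
        """First allele of the current call (genotyped if present)."""
        col = (
            "v_call_genotyped"
            if "v_call_genotyped" in self.data.columns
            else "v_call"
        )
        return self.data[col].str.split(",").str[0].str.strip()

    def records(self) -> Iterator[RearrangementRecord]:
        for row in self.data.itertuples(index=False):
            jl = getattr(row, "junction_length", None)
            yield RearrangementRecord(
                sequence_id=row.sequence_id,
                gapped_observed=row.sequence_alignment,
                v_call=tuple(s.strip() for s in row.v_call.split(",") if s.strip()),
                j_call=str(getattr(row, "j_call", "") or ""),
                junction=str(getattr(row, "junction", "") or ""),
                junction_length=int(jl) if jl not in (None, "") else None,
                productive=bool(getattr(row, "productive", True)),
            )

    def copy(self) -> "Repertoire":
        return Repertoire(self.data.copy(), list(self.provenance))


def _parse_productive(series: pd.Series) -> pd.Series:
    def one(v: object) -> bool:
        if isinstance(v, bool):
            return v
        s = str(v).strip()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        return False

    return series.map(one)


def detect_dialect(columns: Sequence[str]) -> str:
    if "sequence_alignment" in columns:
        return "airr"
    if "SEQUENCE_IMGT" in columns:
        return "changeo"
    raise RepertoireError(
        "cannot detect dialect: neither 'sequence_alignment' (AIRR) nor "
        "'SEQUENCE_IMGT' (Change-O) present"
    )


def read_rearrangements(path: str | Path, dialect: str = "auto") -> Repertoire:
    """Read an AIRR or Change-O rearrangement TSV.

    ``dialect='auto'`` inspects the header.  Missing mandatory columns
    raise :class:`RepertoireError` naming the column and the detected
    dialect.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    if dialect == "auto":
        dialect = detect_dialect(df.columns)
    if dialect == "changeo":
        df = df.rename(columns=CHANGEO_TO_AIRR)
    elif dialect != "airr":
        raise RepertoireError(f"unknown dialect {dialect!r}")
    for col in MANDATORY:
        if col not in df.columns:
            raise RepertoireError(
                f"missing mandatory column {col!r} (dialect={dialect})"
            )
    if "productive" in df.columns:
        df["productive"] = _parse_productive(df["productive"])
    else:
        logger.warning("%s: no productive/functional column; assuming all productive", path)
        df["productive"] = True
    for col in ("j_call", "junction"):
        if col not in df.columns:
            df[col] = ""
    if "junction_length" not in df.columns:
        df["junction_length"] = df["junction"].str.len().astype(str)
    df["sequence_alignment"] = df["sequence_alignment"].str.upper()
    rep = Repertoire(df.reset_index(drop=True))
    rep.provenance.append(f"read_rearrangements(path={path}, dialect={dialect})")
    return rep


def filter_input(
    rep: Repertoire,
    db: GermlineDatabase | None = None,
    unique_on: str = "v_junction",
) -> Repertoire:
    """Retain productive records with a junction, unique by sequence.

    Uniqueness is keyed on the gapped observed sequence over IMGT
    positions 1-312 plus the junction (``unique_on='v_junction'``,
    default) or the full observed sequence (``unique_on='full'``); the
    first occurrence is kept.  If a germline database is given, records
    whose first V call names a gene absent from it are dropped.  The
    operation is idempotent.
    """
    df = rep.data
    n0 = len(df)
    df = df[df["productive"] & (df["junction"].str.len() > 0)]
    n_functional = len(df)
    if unique_on == "v_junction":
        key = df["sequence_alignment"].str[:V_REGION_END] + "|" + df["junction"]
    elif unique_on == "full":
        key = df["sequence_alignment"]
    else:
        raise ValueError(f"unknown unique_on {unique_on!r}")
    df = df[~key.duplicated(keep="first")]
    n_unique = len(df)
    n_in_db = n_unique
    if db is not None:
        genes = db.genes()

        def known(call: str) -> bool:
            first = call.split(",")[0].strip()
            try:
                return parse_allele_name(first).gene in genes
            except Exception:
                return False

        df = df[df["v_call"].map(known)]
        n_in_db = len(df)
    logger.info(
        "filter_input: %d -> %d productive+junction -> %d unique -> %d in database",
        n0,
        n_functional,
        n_unique,
        n_in_db,
    )
    if len(df) == 0:
        logger.warning("filter_input: no records retained")
    out = Repertoire(df.reset_index(drop=True), list(rep.provenance))
    out.provenance.append(
        f"filter_input(unique_on={unique_on}, kept={len(df)}/{n0})"
    )
    return out


def write_rearrangements(
    rep: Repertoire,
    path: str | Path,
    extra_columns: dict[str, Sequence] | None = None,
    header_comments: Sequence[str] = (),
) -> None:
    """Write the repertoire as an AIRR TSV.

    ``extra_columns`` are appended (e.g. ``v_call_genotyped``).
    ``header_comments`` are emitted as leading ``#`` lines (skipped by
    :func:`read_rearrangements`).
    """
    df = rep.data.copy()
    if extra_columns:
        for name, values in extra_columns.items():
            df[name] = list(values)
    df["productive"] = df["productive"].map({True: "T", False: "F"})
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
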