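"""Corpus, metadata and embedding I/O.

A study corpus lives in a directory of plain-text retelling transcripts,
one file per participant per text condition, named ``<participant_id>_<condition>.txt``
with condition ``AT`` (action text) or ``nAT`` (non-action text), plus a CSV
metadata table with one row per participant (group label, MoCA, IFS,
UPDRS-III and optional demographics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("AT", "nAT")
GROUPS = ("HC", "PD-nMCI", "PD-MCI")

#: required columns of the metadata CSV
METADATA_COLUMNS = ("participant_id", "group", "moca", "ifs", "updrs3")


class CorpusError(ValueError):
    """Raised for malformed corpora, metadata or embedding files."""


@dataclass(frozen=True)
class Transcript:
    """One retelling: a participant's free recall of one reference story."""

    participant_id: str
    condition: str  # "AT" or "nAT"
    raw_text: str

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise CorpusError("participant_id must be non-empty")
        if self.condition not in CONDITIONS:
            raise CorpusError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not self.raw_text.strip():
            raise CorpusError(
                f"empty transcript for {self.participant_id}/{self.condition}"
            )


@dataclass(frozen=True)
class ParticipantRecord:
    """Clinical/demographic metadata for one participant.

    ``moca`` (Montreal Cognitive Assessment) and ``ifs`` (INECO Frontal
    Screening) are the covariates of the group comparisons; ``updrs3``
    (UPDRS part III, motor severity) may be missing (NaN), e.g. for
    healthy controls.
    """

    participant_id: str
    group: str
    moca: float
    ifs: float
    updrs3: float = float("nan")
    sex: str | None = None
    age: float | None = None
    education: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CorpusError(
                f"unknown group {self.group!r} for participant "
                f"{self.participant_id!r}; expected one of {GROUPS}"
            )
        for name in ("moca", "ifs"):
            v = getattr(self, name)
            if not np.isnan(v) and v < 0:
                raise CorpusError(f"{name} must be non-negative, got {v}")


@dataclass
class WordEmbeddingTable:
    """Mapping word -> dense vector, all of one dimensionality ``dim``."""

    vectors: dict[str, np.ndarray]
    dim: int

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def __getitem__(self, word: str) -> np.ndarray:
        """Look up a word's vector; absent words raise ``KeyError`` (OOV),
        which is distinct from a stored zero vector."""
        return self.vectors[word]


def transcript_filename(participant_id: str, condition: str) -> str:
    return f"{participant_id}_{condition}.txt"


def _parse_transcript_name(name: str) -> tuple[str, str] | None:
    stem = name[:-4] if name.endswith(".txt") else None
    if stem is None or "_" not in stem:
        return None
    pid, _, cond = stem.rpartition("_")
    if cond not in CONDITIONS or not pid:
        return None
    return pid, cond


def read_metadata(metadata_path: str | Path) -> list[ParticipantRecord]:
    """Read the participant metadata CSV.

    Required columns: participant_id, group, moca, ifs, updrs3; optional
    sex, age, education. Empty updrs3 fields become NaN.
    """
    df = pd.read_csv(metadata_path, dtype={"participant_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusError(f"metadata {metadata_path} lacks columns {missing}")
    if df["participant_id"].duplicated().any():
        dups = sorted(df.loc[df["participant_id"].duplicated(), "participant_id"])
        raise CorpusError(f"duplicate participant_id rows in metadata: {dups}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ParticipantRecord(
                    participant_id=str(row["participant_id"]),
                    group=str(row["group"]),
                    moca=float(row["moca"]),
                    ifs=float(row["ifs"]),
                    updrs3=float(row["updrs3"]) if pd.notna(row["updrs3"]) else float("nan"),
                    sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row["sex"]) else None,
                    age=float(row["age"]) if "age" in df.columns and pd.notna(row["age"]) else None,
                    education=float(row["education"])
                    if "education" in df.columns and pd.notna(row["education"])
                    else None,
                )
            )
        except CorpusError as exc:
            raise CorpusError(f"metadata row {i}: {exc}") from exc
    return records


def read_corpus(
    directory_path: str | Path, metadata_path: str | Path
) -> tuple[list[Transcript], list[ParticipantRecord]]:
    """Read all transcripts in a directory together with their metadata.

    Every transcript must match exactly one metadata row; transcripts whose
    participant is absent from the metadata are a hard error (never silently
    dropped), as are duplicate (participant, condition) files and empty files.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise CorpusError(f"transcript directory not found: {directory}")
    records = read_metadata(metadata_path)
    known = {r.participant_id for r in records}

    transcripts: list[Transcript] = []
    seen: set[tuple[str, str]] = set()
    unmatched: list[str] = []
    for path in sorted(directory.glob("*.txt")):
        parsed = _parse_transcript_name(path.name)
        if parsed is None:
            logger.warning("skipping unrecognized transcript filename %s", path.name)
            continue
        pid, cond = parsed
        if (pid, cond) in seen:
            raise CorpusError(f"duplicate transcript for ({pid}, {cond})")
        seen.add((pid, cond))
        text = path.read_text(encoding="utf-8")
        if not text.strip():
            raise CorpusError(f"empty transcript file: {path}")
        if pid not in known:
            unmatched.append(pid)
            continue
        transcripts.append(Transcript(pid, cond, text))
    if unmatched:
        raise CorpusError(
            f"transcripts with no metadata row: {sorted(set(unmatched))}"
        )
    return transcripts, records


def write_corpus(
    directory_path: str | Path,
    transcripts: list[Transcript],
    records: list[ParticipantRecord],
    metadata_name: str = "metadata.csv",
) -> Path:
    """Write transcripts + metadata in the layout :func:`read_corpus` expects.

    Returns the metadata path. Transcript text is written verbatim (UTF-8),
    so a write/read round trip is string-exact.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    for t in transcripts:
        (directory / transcript_filename(t.participant_id, t.condition)).write_text(
            t.raw_text, encoding="utf-8"
        )
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "moca": r.moca,
                "ifs": r.ifs,
                "updrs3": "" if np.isnan(r.updrs3) else r.updrs3,
                "sex": r.sex if r.sex is not None else "",
                "age": r.age if r.age is not None else "",
                "education": r.education if r.education is not None else "",
            }
        )
    meta_path = directory / metadata_name
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    return meta_path


def read_word_vectors(path: str | Path) -> WordEmbeddingTable:
    """Read a plain-text word-vector file (word2vec-text or GloVe-text).

    Each line is a token followed by ``d`` whitespace-separated numbers.
    A word2vec-style ``<vocab_size> <d>`` header line is auto-detected.
    Duplicate tokens keep the first occurrence (with a warning); a line with
    the wrong number of components is a hard error naming the line.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:  # word2vec-text header: "<vocab_size> <dim>"
                    int(parts[0]), int(parts[1])
                    continue
                except ValueError:
                    pass
            token, comps = parts[0], parts[1:]
            try:
                vec = np.asarray([float(x) for x in comps], dtype=float)
            except ValueError as exc:
                raise CorpusError(
                    f"{path}:{lineno}: non-numeric vector component"
                ) from exc
            if dim is None:
                if vec.size == 0:
                    raise CorpusError(f"{path}:{lineno}: token with no components")
                dim = vec.size
            elif vec.size != dim:
                raise CorpusError(
                    f"{path}:{lineno}: expected {dim} components, got {vec.size}"
                )
            if token in vectors:
                logger.warning("duplicate embedding token %r (keeping first)", token)
                continue
            vectors[token] = vec
    if dim is None:
        raise CorpusError(f"no vectors found in {path}")
    return WordEmbeddingTable(vectors=vectors, dim=dim)
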