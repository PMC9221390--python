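"""Readers/writers for the formats the pipeline touches, and shared domain records.

The binary reactivity matrix is a TSV with proteins as rows and subjects as
columns; a sidecar metadata TSV maps each subject column to its study, age,
sex, and case/control group.  Missing cells (protein not probed in a study)
are literal ``NA`` (also accepted: empty string, ``NaN``) and are never
coerced to 0 — a non-probed protein carries no information about reactivity.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 20 canonical residues plus X for masked/unknown positions.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Ambiguity/rare codes folded into X on input.
_AMBIGUOUS = {"B", "Z", "U", "J", "O"}

_NA_TOKENS = {"NA", "", "NaN", "nan"}


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    Sequences are uppercase and restricted to the 20 canonical residues plus
    ``X`` for masked or unknown positions.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: characters outside amino-acid alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Subject:
    """One serum donor: identifier, age in years (or None), sex, and group."""

    subject_id: str
    age: float | None = None
    sex: str = "missing"  # {male, female, missing}
    group: str = "control"  # {case, control}


@dataclass
class StudyResponseSet:
    """Per-study binary reactivity with probed-mask and subject metadata.

    ``responses`` is an antibody x subject float matrix holding 0.0
    (non-reactive), 1.0 (reactive) or NaN (protein not probed in this study).
    The probed mask is column-constant: a protein is probed for all of a
    study's subjects or for none of them.
    """

    study_id: str
    antibodies: list[str]
    subjects: list[Subject]
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.shape != (len(self.antibodies), len(self.subjects)):
            raise ValueError(
                f"study {self.study_id!r}: response matrix shape {self.responses.shape} "
                f"does not match {len(self.antibodies)} antibodies x {len(self.subjects)} subjects"
            )
        finite = self.responses[~np.isnan(self.responses)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError(f"study {self.study_id!r}: response values must be 0, 1 or missing")
        probed = ~np.isnan(self.responses)
        row_any = probed.any(axis=1)
        row_all = probed.all(axis=1)
        if not np.array_equal(row_any, row_all):
            # normally a protein is probed for all or none of a study's
            # subjects; tolerate subject-level dropouts but flag them
            n_partial = int((row_any & ~row_all).sum())
            logger.warning(
                "study %r: %d antibodies have a non-constant probed mask (subject-level missingness)",
                self.study_id,
                n_partial,
            )

    @property
    def probed(self) -> np.ndarray:
        """Boolean vector: which antibodies were probed (for any subject)."""
        return ~np.isnan(self.responses).all(axis=1)

    def counts(self, antibody: str) -> tuple[int, int] | None:
        """(reactive count, probed-subject count) for one antibody, over
        non-missing subjects; None if the antibody was not probed at all."""
        i = self.antibodies.index(antibody)
        row = self.responses[i]
        ok = ~np.isnan(row)
        if not ok.any():
            return None
        return int(row[ok].sum()), int(ok.sum())


@dataclass
class AnnotationTable:
    """Per-protein subcellular-localization terms and optional organ x gene TPMs."""

    localization: dict[str, list[str]] = field(default_factory=dict)
    tpm: pd.DataFrame | None = None  # organs as rows, genes as columns

    def __post_init__(self) -> None:
        if self.tpm is not None and (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA into ProteinRecords.

    Order-preserving.  Sequences are uppercased; ``*`` and gap characters are
    stripped with a logged warning; ambiguity codes B/Z/U/J/O map to X with a
    warning.  Duplicate ids raise.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has no sequence")
        cleaned = seq.replace("*", "").replace("-", "").replace(".", "")
        if cleaned != seq:
            logger.warning("%s: stripped %d stop/gap characters from %s", path, len(seq) - len(cleaned), rec.id)
            seq = cleaned
        ambig = set(seq) & _AMBIGUOUS
        if ambig:
            logger.warning("%s: record %s: mapping ambiguous residues %s to X", path, rec.id, sorted(ambig))
            for ch in ambig:
                seq = seq.replace(ch, "X")
        records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (round-trips with :func:`read_fasta`)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Response matrix


def _parse_cell(token: str, row: str, col: str) -> float:
    t = token.strip()
    if t in _NA_TOKENS:
        return math.nan
    if t in {"0", "0.0"}:
        return 0.0
    if t in {"1", "1.0"}:
        return 1.0
    raise ValueError(f"non-binary response value {token!r} at protein {row!r}, subject {col!r}")


def read_response_matrix(path: str | Path, metadata_path: str | Path) -> list[StudyResponseSet]:
    """Read an antibody x subject binary TSV plus its subject-metadata sidecar.

    The matrix has proteins as rows (first column = protein id) and subjects
    as columns.  The metadata TSV must contain columns subject_id, study_id,
    age, sex, group, one row per subject column of the matrix.  Returns one
    StudyResponseSet per study id, partitioning the subject columns; NA cells
    are preserved as missing.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"subject_id", "study_id", "age", "sex", "group"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"{metadata_path}: metadata lacks columns {sorted(missing_cols)}")
    meta = meta.set_index("subject_id")
    unknown = [c for c in mat.columns if c not in meta.index]
    if unknown:
        raise ValueError(f"{path}: subject columns lacking metadata: {unknown}")

    values = np.empty(mat.shape, dtype=float)
    for j, col in enumerate(mat.columns):
        for i, row in enumerate(mat.index):
            values[i, j] = _parse_cell(mat.iat[i, j], str(row), str(col))

    antibodies = [str(a) for a in mat.index]
    studies: list[StudyResponseSet] = []
    for study_id in pd.unique(meta.loc[list(mat.columns), "study_id"]):
        cols = [c for c in mat.columns if meta.at[c, "study_id"] == study_id]
        subjects = []
        for c in cols:
            age_tok = meta.at[c, "age"].strip()
            age = None if age_tok in _NA_TOKENS else float(age_tok)
            sex = meta.at[c, "sex"].strip() or "missing"
            group = meta.at[c, "group"].strip() or "control"
            subjects.append(Subject(str(c), age, sex, group))
        idx = [mat.columns.get_loc(c) for c in cols]
        sub = values[:, idx]
        # drop antibodies entirely unprobed in this study? keep them: the
        # probed mask is per-study and column-constant, NaN rows are allowed.
        studies.append(StudyResponseSet(str(study_id), list(antibodies), subjects, sub))
    return studies


def write_response_matrix(
    studies: Sequence[StudyResponseSet], path: str | Path, metadata_path: str | Path
) -> None:
    """Write StudyResponseSets back to the matrix + sidecar TSV pair."""
    antibodies = studies[0].antibodies
    for s in studies:
        if s.antibodies != antibodies:
            raise ValueError("all studies must share one antibody universe for a joint matrix")
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for s in studies:
        for j, subj in enumerate(s.subjects):
            cols[subj.subject_id] = s.responses[:, j]
            meta_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "study_id": s.study_id,
                    "age": "NA" if subj.age is None else subj.age,
                    "sex": subj.sex,
                    "group": subj.group,
                }
            )
    df = pd.DataFrame(cols, index=antibodies)
    out = df.map(lambda v: "NA" if math.isnan(v) else str(int(v)))
    out.index.name = "protein"
    out.to_csv(path, sep="\t")
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reports


def _format_value(v) -> str:
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return f"{v:.6g}"
    if v is None:
        return "NA"
    return str(v)


def write_report(results: Sequence[Mapping], path: str | Path, format: str = "tsv") -> None:
    """Serialize a list of flat mapping rows as TSV or JSON.

    Deterministic column order (first-seen order across rows); floats at six
    significant digits; missing values as NA (TSV) / null (JSON).  Writing the
    same results twice yields byte-identical files.
    """
    if format not in {"tsv", "json"}:
        raise ValueError(f"unsupported report format {format!r}")
    columns: list[str] = []
    for row in results:
        for k in row:
            if k not in columns:
                columns.append(k)
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(columns)]
        for row in results:
            lines.append("\t".join(_format_value(row.get(c)) for c in columns))
        path.write_text("\n".join(lines) + "\n")
    else:
        def _round(v):
            if isinstance(v, float):
                return None if math.isnan(v) else float(f"{v:.6g}")
            if isinstance(v, (np.floating,)):
                return _round(float(v))
            if isinstance(v, (np.integer,)):
                return int(v)
            return v

        payload = [{c: _round(row.get(c)) for c in columns if c in row} for row in results]
        path.write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n")
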