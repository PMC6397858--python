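"""Sequence and structure records with strict validation, plus standard-format I/O.

Sequences are RNA over the four-letter alphabet {A, C, G, U}. DNA-style input
is accepted (T is mapped to U, case is normalised); IUPAC ambiguity codes are
rejected because the mutual-information feature space is defined over exactly
four symbols and silent imputation would distort the n-gram counts.

Secondary structures use Vienna dot-bracket notation: "(" and ")" mark the 5'
and 3' partners of a base pair, "." an unpaired base. Each structure carries
the folding free energy (MFE, kcal/mol) of the conformation it encodes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"
STRUCT_ALPHABET = "(.)"

#: minimum sequence length; the 3-gram probability denominator is L - 2 and
#: must be at least 2 for the estimates to be meaningful
MIN_LENGTH = 4


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Residues outside the strict {A, C, G, U} alphabet (after T->U)."""


class StructureValidationError(ValueError):
    """Dot-bracket string violating the balance invariant or the alphabet."""


class ViennaParseError(ValueError):
    """Malformed Vienna (RNAfold-style) structure file."""


def normalize_residues(raw: str, record_id: str = "<anonymous>") -> str:
    """Uppercase, map T->U, and reject anything outside {A, C, G, U}."""
    residues = raw.upper().replace("T", "U")
    for ch in residues:
        if ch not in RNA_ALPHABET:
            raise SequenceValidationError(
                f"record {record_id!r}: residue {ch!r} is not one of A/C/G/U/T"
            )
    return residues


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    residues : str
        Residue string over {A, C, G, U}. ``normalize_residues`` is applied
        by :func:`read_fasta`; construct via :meth:`from_raw` to get the same
        normalisation.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        for ch in self.residues:
            if ch not in RNA_ALPHABET:
                raise SequenceValidationError(
                    f"record {self.id!r}: residue {ch!r} is not one of A/C/G/U"
                )
        if len(self.residues) < MIN_LENGTH:
            raise SequenceValidationError(
                f"record {self.id!r}: length {len(self.residues)} < {MIN_LENGTH}"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "RnaSequence":
        return cls(id=id, residues=normalize_residues(raw, id))

    def __len__(self) -> int:
        return len(self.residues)

    def reverse(self) -> "RnaSequence":
        return RnaSequence(id=self.id, residues=self.residues[::-1])


def validate_dotbracket(dotbracket: str) -> None:
    """Check alphabet and parenthesis balance; raise on violation."""
    depth = 0
    for i, ch in enumerate(dotbracket):
        if ch not in STRUCT_ALPHABET:
            raise StructureValidationError(
                f"position {i}: symbol {ch!r} is not one of '(', ')', '.'"
            )
        depth += 1 if ch == "(" else -1 if ch == ")" else 0
        if depth < 0:
            raise StructureValidationError(
                f"position {i}: ')' without a matching '('"
            )
    if depth != 0:
        raise StructureValidationError(
            f"{depth} unmatched '(' at end of structure"
        )


@dataclass(frozen=True)
class SecondaryStructure:
    """A dot-bracket secondary structure with its free energy.

    ``mfe`` is in kcal/mol; 0.0 for a fully unpaired structure, negative for
    folded ones (the Nussinov backend reports a pseudo-energy on the same
    sign convention).
    """

    dotbracket: str
    mfe: float

    def __post_init__(self) -> None:
        validate_dotbracket(self.dotbracket)

    def __len__(self) -> int:
        return len(self.dotbracket)

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")

    def pair_table(self) -> list[tuple[int, int]]:
        """Return (i, j) index pairs of matched parentheses, i < j."""
        stack: list[int] = []
        pairs: list[tuple[int, int]] = []
        for i, ch in enumerate(self.dotbracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                pairs.append((stack.pop(), i))
        return sorted(pairs)


@dataclass
class LabeledRecord:
    """A sequence with optional structure and optional class label."""

    sequence: RnaSequence
    structure: SecondaryStructure | None = None
    label: int | None = None  # 1 positive, 0 negative, None unknown

    def __post_init__(self) -> None:
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise StructureValidationError(
                f"record {self.sequence.id!r}: structure length "
                f"{len(self.structure)} != sequence length {len(self.sequence)}"
            )


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a FASTA file into validated :class:`RnaSequence` records.

    T/t is mapped to U, lowercase is uppercased, record order is preserved.
    Raises :class:`SequenceValidationError` for ambiguity codes and
    :class:`FastaParseError` for files with no parseable records.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    out = []
    n_t = 0
    for rec in records:
        raw = str(rec.seq)
        if "T" in raw.upper():
            n_t += 1
        out.append(RnaSequence.from_raw(rec.id, raw))
    if n_t:
        logger.info("read_fasta(%s): mapped T->U in %d of %d records", path, n_t, len(out))
    return out


def write_fasta(records: Iterable[RnaSequence], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# RNAfold writes e.g. "(((...))) ( -1.20)"; energy is the final parenthesised
# token, tolerant of internal spaces.
_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def _parse_structure_line(line: str, lineno: int) -> tuple[str, float]:
    m = _ENERGY_RE.search(line)
    if not m:
        raise ViennaParseError(
            f"line {lineno}: no parenthesized energy at end of structure line: {line!r}"
        )
    mfe = float(m.group(1))
    dotbracket = line[: m.start()].strip()
    try:
        validate_dotbracket(dotbracket)
    except StructureValidationError as exc:
        raise StructureValidationError(f"line {lineno}: {exc}") from None
    return dotbracket, mfe


def read_vienna(path: str | Path) -> list[tuple[RnaSequence, SecondaryStructure]]:
    """Read RNAfold-style output: header, sequence, structure+energy triplets."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.open(encoding="utf-8") if ln.strip()]
    if len(lines) % 3 != 0:
        raise ViennaParseError(
            f"{path}: expected header/sequence/structure triplets, got {len(lines)} lines"
        )
    out = []
    for i in range(0, len(lines), 3):
        header, seqline, structline = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise ViennaParseError(f"line {i + 1}: expected '>' header, got {header!r}")
        seq = RnaSequence.from_raw(header[1:].split()[0], seqline.strip())
        dotbracket, mfe = _parse_structure_line(structline, i + 3)
        if len(dotbracket) != len(seq):
            raise ViennaParseError(
                f"record {seq.id!r}: structure length {len(dotbracket)} != "
                f"sequence length {len(seq)}"
            )
        out.append((seq, SecondaryStructure(dotbracket, mfe)))
    return out


def write_vienna(
    records: Iterable[tuple[RnaSequence, SecondaryStructure]], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for seq, struct in records:
            fh.write(f">{seq.id}\n{seq.residues}\n{struct.dotbracket} ({struct.mfe:.2f})\n")


def write_features(
    ids: Sequence[str],
    X,
    feature_names: Sequence[str],
    path: str | Path,
    sep: str = "\t",
) -> None:
    """Write a feature matrix as delimited text: id column first, then one
    column per canonical feature name."""
    import pandas as pd

    X = _as_2d(X, len(feature_names))
    if len(ids) != X.shape[0]:
        raise ValueError(f"{len(ids)} ids but {X.shape[0]} feature rows")
    df = pd.DataFrame(X, columns=list(feature_names))
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_features(path: str | Path, sep: str = "\t"):
    """Read a feature table written by :func:`write_features`.

    Returns ``(ids, X, feature_names)``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=sep)
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    return df["id"].tolist(), df.iloc[:, 1:].to_numpy(dtype=float), list(df.columns[1:])


def read_labels(path: str | Path, sep: str = "\t") -> dict[str, int]:
    """Read a two-column id/label table; labels are 'positive'/'negative' or 1/0."""
    import pandas as pd

    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, label)")
    mapping = {"positive": 1, "negative": 0, "1": 1, "0": 0}
    out = {}
    for rec_id, lab in zip(df.iloc[:, 0], df.iloc[:, 1]):
        key = str(lab).strip().lower()
        if key not in mapping:
            raise ValueError(f"{path}: unrecognised label {lab!r} for id {rec_id!r}")
        out[str(rec_id)] = mapping[key]
    return out


def write_labels(records: Iterable[LabeledRecord], path: str | Path, sep: str = "\t") -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"id{sep}label\n")
        for rec in records:
            name = {1: "positive", 0: "negative"}.get(rec.label, "unknown")
            fh.write(f"{rec.sequence.id}{sep}{name}\n")


def _as_2d(X, n_cols: int):
    import numpy as np

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(0, n_cols) if X.size == 0 else X.reshape(1, -1)
    if X.shape[1] != n_cols:
        raise ValueError(f"expected {n_cols} feature columns, got {X.shape[1]}")
    return X
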