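"""Position-specific scoring matrix (PSSM) profiles.

A profile holds one signed log-odds row per window position and one column
per canonical residue.  Profiles for real peptides come from PSI-BLAST
ASCII output (one ``<id>.pssm`` file per peptide); synthetic profiles are
produced by :mod:`epiforest.synthetic`.  Padding mirrors peptide padding:
rows appended for gap positions are all zero, so padded positions are
score-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .seqio import AMINO_ACIDS, AA_SET, DEFAULT_WIDTH, GAP, PaddedPeptide

# Column order PSI-BLAST prints (differs from our alphabetical order).
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

_HEADER_LINE = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


class PssmParseError(ValueError):
    """Raised when a PSSM ASCII file cannot be parsed."""


@dataclass(frozen=True)
class PssmProfile:
    """A rows x 20 log-odds matrix aligned to a peptide.

    ``matrix`` columns follow the package-wide alphabetical residue order
    regardless of the producing program's column order; ``query`` holds the
    residue letters the profile was computed for (gap letters for padded
    rows, which are all zero).
    """

    id: str
    matrix: np.ndarray
    query: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 20:
            raise ValueError(
                f"profile {self.id!r}: matrix must be rows x 20, got {m.shape}"
            )
        object.__setattr__(self, "matrix", m)
        if self.query and len(self.query) != m.shape[0]:
            raise ValueError(
                f"profile {self.id!r}: query length {len(self.query)} != "
                f"{m.shape[0]} rows"
            )

    @property
    def n_rows(self) -> int:
        return int(self.matrix.shape[0])

    def score(self, position: int, residue: str) -> float:
        """Log-odds score of ``residue`` at 1-based window ``position``."""
        return float(self.matrix[position - 1, AMINO_ACIDS.index(residue)])


def pad_profile(profile: PssmProfile, width: int = DEFAULT_WIDTH) -> PssmProfile:
    """Append all-zero rows up to ``width`` (score-neutral padding)."""
    n = profile.n_rows
    if n > width:
        raise ValueError(
            f"profile {profile.id!r} has {n} rows > window width {width}"
        )
    if n == width:
        return profile
    padded = np.vstack([profile.matrix, np.zeros((width - n, 20))])
    query = (profile.query + GAP * (width - n)) if profile.query else ""
    return replace(profile, matrix=padded, query=query)


def parse_pssm_ascii(path: str | Path) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file.

    Only the first 20 numeric columns (the log-odds block) are kept; they
    are remapped from the file's own column order (read from the header
    line of residue letters) to alphabetical order.  The profile id is the
    file's stem.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    col_order: str | None = None
    start = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and all(t in AA_SET and len(t) == 1 for t in tokens[:20]):
            col_order = "".join(tokens[:20])
            start = i + 1
            break
    if col_order is None or start is None:
        raise PssmParseError(f"{path}: no residue-letter column header found")

    rows: list[np.ndarray] = []
    query: list[str] = []
    expected = 1
    for line in lines[start:]:
        tokens = line.split()
        if not tokens:
            break
        if len(tokens) < 22:
            raise PssmParseError(
                f"{path}: truncated row at position {expected}: {line.strip()!r}"
            )
        try:
            idx = int(tokens[0])
            scores = [float(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PssmParseError(f"{path}: malformed row {line.strip()!r}") from exc
        if idx != expected:
            raise PssmParseError(
                f"{path}: row index {idx} where {expected} was expected"
            )
        if tokens[1] not in AA_SET:
            raise PssmParseError(f"{path}: bad query residue {tokens[1]!r}")
        query.append(tokens[1])
        rows.append(np.array(scores))
        expected += 1

    if not rows:
        raise PssmParseError(f"{path}: no score rows found")

    raw = np.vstack(rows)
    order = [col_order.index(aa) for aa in AMINO_ACIDS]
    return PssmProfile(id=path.stem, matrix=raw[:, order], query="".join(query))


def write_pssm_ascii(profile: PssmProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect read back by
    :func:`parse_pssm_ascii`.

    Scores are rounded to integers (PSI-BLAST prints integer log-odds) and
    emitted in PSI-BLAST's native column order; trailing all-zero padding
    rows are not written (padding is re-applied on load).  A flat weighted
    percentage block is appended so real PSI-BLAST output and these files
    share a column layout.
    """
    path = Path(path)
    mat = profile.matrix
    query = profile.query or "X" * mat.shape[0]
    n = mat.shape[0]
    # drop trailing zero (padding) rows
    while n > 1 and not mat[n - 1].any() and query[n - 1] == GAP:
        n -= 1
    order = [AMINO_ACIDS.index(aa) for aa in PSIBLAST_ORDER]
    with open(path, "w") as fh:
        fh.write("\n" + _HEADER_LINE + "\n")
        letters = "  ".join(PSIBLAST_ORDER)
        fh.write("            " + letters + "   " + letters + "\n")
        for i in range(n):
            ints = mat[i, order]
            cells = "".join(f"{int(round(v)):4d}" for v in ints)
            pct = "".join(f"{0:4d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {query[i]} {cells} {pct}  0.00 0.00\n")
        fh.write("\n")


def check_alignment(p: PaddedPeptide, profile: PssmProfile) -> None:
    """Raise unless ``profile`` is padded to and consistent with ``p``."""
    if profile.id != p.id:
        raise ValueError(f"profile id {profile.id!r} != peptide id {p.id!r}")
    if profile.n_rows != p.width:
        raise ValueError(
            f"profile {profile.id!r}: {profile.n_rows} rows != window width {p.width}"
        )
    if profile.query and profile.query[: p.original_length] != p.sequence:
        raise ValueError(
            f"profile {profile.id!r}: query does not match peptide sequence"
        )
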