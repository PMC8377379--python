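"""The four fixed-dimension peptide feature encodings.

For a window of width ``W`` (default 24) over the 20-letter alphabet:

AIP   per-position physicochemical property lookup, one value per
      (position, AAindex entry): dimension ``W x 8`` = 192.  Gap positions
      contribute 0.
AFC   k-spaced amino-acid pair composition (the CKSAAP family): for each
      spacing ``k`` and ordered residue pair, the count of positions ``m``
      with the pair at ``(m, m+k+1)`` (both non-gap) divided by
      ``N_total = W - k - 1``.  Dimension ``400 x |spacings|`` = 800 for
      the default spacings {0, 1}.
PSSM  row-major flattening of the padded W x 20 profile: dimension 480.
PKAF  profile-weighted k-spaced pairs: for each spacing and ordered pair,
      the sum over matching positions of ``max(min(S[m, x_i],
      S[m+k+1, x_j]), 0)`` divided by ``W - 1``, where ``S`` is the
      profile.  The denominator is ``W - 1`` for every spacing (an
      optional switch uses ``W - k - 1`` instead).  Dimension 800.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .aaindex import AAIndexTable
from .profiles import PssmProfile, check_alignment
from .seqio import AA_INDEX, AMINO_ACIDS, GAP, LabeledDataset, PaddedPeptide

ENCODINGS = ("AIP", "AFC", "PSSM", "PKAF")

DEFAULT_SPACINGS: tuple[int, ...] = (0, 1)

#: The 400 ordered residue pairs, in alphabetical order (AA, AC, ..., YY).
PAIRS: tuple[str, ...] = tuple(a + b for a, b in product(AMINO_ACIDS, AMINO_ACIDS))


@dataclass(frozen=True)
class FeatureVector:
    encoding: str
    values: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.columns):
            raise ValueError("values and column names differ in length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FeatureMatrix:
    """n x d feature block for one encoding, rows in dataset order."""

    encoding: str
    values: np.ndarray
    columns: tuple[str, ...]
    ids: tuple[str, ...]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("value matrix shape does not match column names")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    @property
    def d(self) -> int:
        return int(self.values.shape[1])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "id", list(self.ids))
        if self.labels is not None:
            df["label"] = self.labels
        return df


def _check_spacings(spacings: Sequence[int], width: int) -> tuple[int, ...]:
    ks = tuple(sorted(set(int(k) for k in spacings)))
    if not ks:
        raise ValueError("at least one spacing is required")
    for k in ks:
        if k < 0 or k >= width - 1:
            raise ValueError(f"spacing {k} out of range for window width {width}")
    return ks


def afc_n_total(width: int, k: int) -> int:
    """The pair-count normalizer for spacing ``k``: the number of pair
    start positions in a full window, ``W - k - 1``."""
    if k < 0 or k >= width - 1:
        raise ValueError(f"spacing {k} out of range for window width {width}")
    return width - k - 1


def afc_columns(spacings: Sequence[int] = DEFAULT_SPACINGS) -> tuple[str, ...]:
    return tuple(f"k{k}_{pair}" for k in sorted(set(spacings)) for pair in PAIRS)


def pkaf_columns(spacings: Sequence[int] = DEFAULT_SPACINGS) -> tuple[str, ...]:
    return tuple(
        f"pkaf_k{k}_{pair[0]}x{pair[1]}"
        for k in sorted(set(spacings))
        for pair in PAIRS
    )


def aip_columns(width: int = 24, accessions: Sequence[str] = ()) -> tuple[str, ...]:
    from .aaindex import ACCESSIONS

    accs = tuple(accessions) or ACCESSIONS
    return tuple(f"pos{m}_{acc}" for m in range(1, width + 1) for acc in accs)


def pssm_columns(width: int = 24) -> tuple[str, ...]:
    return tuple(
        f"pssm_m{m}_{aa}" for m in range(1, width + 1) for aa in AMINO_ACIDS
    )


def encode_aip(p: PaddedPeptide, table: AAIndexTable) -> FeatureVector:
    """Per-position property lookup; gaps contribute 0.  Dimension W x 8."""
    if not table.normalized:
        raise ValueError("AIP encoding requires a normalized AAIndexTable")
    accs = table.accessions
    lookup = np.stack([table.values[acc] for acc in accs], axis=1)  # 20 x 8
    out = np.zeros((p.width, len(accs)))
    for m, ch in enumerate(p.window):
        if ch != GAP:
            out[m] = lookup[AA_INDEX[ch]]
    return FeatureVector("AIP", out.ravel(), aip_columns(p.width, accs))


def encode_pssm(profile: PssmProfile, width: int = 24) -> FeatureVector:
    """Row-major flattening of a padded profile.  Dimension W x 20."""
    if profile.n_rows != width:
        raise ValueError(
            f"profile {profile.id!r} has {profile.n_rows} rows; pad to {width} first"
        )
    return FeatureVector("PSSM", profile.matrix.ravel().copy(), pssm_columns(width))


def encode_afc(
    p: PaddedPeptide, spacings: Sequence[int] = DEFAULT_SPACINGS
) -> FeatureVector:
    """k-spaced pair composition normalized by ``W - k - 1`` per spacing."""
    ks = _check_spacings(spacings, p.width)
    codes = np.array(
        [AA_INDEX[c] if c != GAP else -1 for c in p.window], dtype=int
    )
    blocks = []
    for k in ks:
        counts = np.zeros(400)
        step = k + 1
        left, right = codes[: p.width - step], codes[step:]
        ok = (left >= 0) & (right >= 0)
        np.add.at(counts, left[ok] * 20 + right[ok], 1.0)
        blocks.append(counts / afc_n_total(p.width, k))
    return FeatureVector("AFC", np.concatenate(blocks), afc_columns(ks))


def encode_pkaf(
    p: PaddedPeptide,
    profile: PssmProfile,
    spacings: Sequence[int] = DEFAULT_SPACINGS,
    per_k_denominator: bool = False,
) -> FeatureVector:
    """Profile-weighted k-spaced pairs with a zero floor.

    Each occurrence of the ordered pair ``(x_i, x_j)`` at positions
    ``(m, m+k+1)`` contributes ``max(min(S[m, x_i], S[m+k+1, x_j]), 0)``;
    sums are divided by ``W - 1`` (or ``W - k - 1`` if
    ``per_k_denominator``).
    """
    check_alignment(p, profile)
    ks = _check_spacings(spacings, p.width)
    codes = np.array(
        [AA_INDEX[c] if c != GAP else -1 for c in p.window], dtype=int
    )
    pos_scores = np.array(
        [profile.matrix[m, codes[m]] if codes[m] >= 0 else 0.0 for m in range(p.width)]
    )
    blocks = []
    for k in ks:
        sums = np.zeros(400)
        step = k + 1
        for m in range(p.width - step):
            i, j = codes[m], codes[m + step]
            if i >= 0 and j >= 0:
                contrib = max(min(pos_scores[m], pos_scores[m + step]), 0.0)
                sums[i * 20 + j] += contrib
        denom = afc_n_total(p.width, k) if per_k_denominator else p.width - 1
        blocks.append(sums / denom)
    return FeatureVector("PKAF", np.concatenate(blocks), pkaf_columns(ks))


def encode_dataset(
    ds: LabeledDataset,
    encoding: str,
    profiles: Mapping[str, PssmProfile] | None = None,
    table: AAIndexTable | None = None,
    spacings: Sequence[int] = DEFAULT_SPACINGS,
    per_k_denominator: bool = False,
) -> FeatureMatrix:
    """Encode every peptide of a dataset with one scheme.

    ``profiles`` (keyed by peptide id) are required for PSSM and PKAF;
    ``table`` is required for AIP (the packaged table is used if omitted).
    """
    encoding = encoding.upper()
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")

    if encoding in ("PSSM", "PKAF"):
        if profiles is None:
            raise ValueError(f"{encoding} encoding requires profiles")
        missing = [p.id for p in ds if p.id not in profiles]
        if missing:
            raise ValueError(
                f"missing profiles for {len(missing)} peptide(s): "
                + ", ".join(missing[:10])
            )
    if encoding == "AIP" and table is None:
        from .aaindex import aaindex_table

        table = aaindex_table()

    rows = []
    columns: tuple[str, ...] | None = None
    for p in ds:
        if encoding == "AIP":
            fv = encode_aip(p, table)  # type: ignore[arg-type]
        elif encoding == "AFC":
            fv = encode_afc(p, spacings)
        elif encoding == "PSSM":
            fv = encode_pssm(profiles[p.id], width=p.width)  # type: ignore[index]
        else:
            fv = encode_pkaf(
                p, profiles[p.id], spacings, per_k_denominator  # type: ignore[index]
            )
        rows.append(fv.values)
        columns = fv.columns
    assert columns is not None
    return FeatureMatrix(
        encoding=encoding,
        values=np.vstack(rows) if rows else np.empty((0, len(columns))),
        columns=columns,
        ids=tuple(ds.ids),
        labels=ds.labels if len(ds) else None,
    )


def write_feature_tsv(fm: FeatureMatrix, path) -> None:
    fm.to_frame().to_csv(path, sep="\t", index=False)


def read_feature_tsv(path, encoding: str) -> FeatureMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    labels = df.pop("label").to_numpy() if "label" in df.columns else None
    ids = tuple(df.pop("id").astype(str))
    return FeatureMatrix(
        encoding=encoding,
        values=df.to_numpy(dtype=float),
        columns=tuple(df.columns),
        ids=ids,
        labels=labels,
    )
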