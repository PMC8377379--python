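"""Synthetic peptides, profiles and fusion scores with known ground truth.

The peptide generator emulates the class structure that drives real
linear-epitope data: positives are enriched for the neutral residues P, N
and Y at a fixed set of window positions (3, 4, 6, 7, 8, 10, 11) while
negatives are enriched for A, H, L, M and V at the same positions; all
other positions are uniform over the 20 residues.  Lengths are drawn
uniformly from 5..24 and peptides are padded downstream to the window
width.  Profile generation produces a signed log-odds-like matrix
consistent with the peptide sequence (the true residue's entry is
elevated by a configurable sharpness), so evolutionary-profile encodings
inherit the sequence-level class signal just as PSI-BLAST profiles would.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .profiles import PssmProfile, pad_profile, write_pssm_ascii
from .seqio import (
    AMINO_ACIDS,
    AA_INDEX,
    DEFAULT_WIDTH,
    GAP,
    LabeledDataset,
    NEGATIVE,
    POSITIVE,
    PaddedPeptide,
    Peptide,
    pad_peptide,
)

#: Window positions (1-based) carrying class-conditional enrichment.
ENRICHED_POSITIONS: tuple[int, ...] = (3, 4, 6, 7, 8, 10, 11)
POSITIVE_RESIDUES: tuple[str, ...] = ("P", "N", "Y")
NEGATIVE_RESIDUES: tuple[str, ...] = ("A", "H", "L", "M", "V")


def _cycle(
    positions: Sequence[int], residues: Sequence[str]
) -> tuple[tuple[int, str], ...]:
    return tuple(
        (pos, residues[i % len(residues)]) for i, pos in enumerate(positions)
    )


@dataclass(frozen=True)
class EnrichmentSpec:
    """Class-conditional positional residue enrichment.

    Each boost is a (1-based position, residue) pair: at that position the
    class's residue distribution moves probability mass ``delta`` onto the
    boosted residue(s), scaling the rest down proportionally so the vector
    stays a valid distribution for any ``delta`` in [0, 1].  The default
    cycles P/N/Y across the enriched positions for positives (so position 3
    favors P) and A/H/L/M/V for negatives; unboosted positions are uniform.
    """

    positive_boosts: tuple[tuple[int, str], ...] = _cycle(
        ENRICHED_POSITIONS, POSITIVE_RESIDUES
    )
    negative_boosts: tuple[tuple[int, str], ...] = _cycle(
        ENRICHED_POSITIONS, NEGATIVE_RESIDUES
    )

    def __post_init__(self) -> None:
        for boosts in (self.positive_boosts, self.negative_boosts):
            for pos, residue in boosts:
                if pos < 1 or residue not in AA_INDEX:
                    raise ValueError(f"invalid boost ({pos}, {residue!r})")

    def distribution(self, position: int, label: str, delta: float) -> np.ndarray:
        """Residue distribution (alphabetical order) at a 1-based position."""
        base = np.full(20, 1.0 / 20.0)
        boosts = self.positive_boosts if label == POSITIVE else self.negative_boosts
        favored = [r for pos, r in boosts if pos == position]
        if delta == 0.0 or not favored:
            return base
        mass = min(max(delta, 0.0), 1.0)
        dist = base * (1.0 - mass)
        for r in favored:
            dist[AA_INDEX[r]] += mass / len(favored)
        assert abs(dist.sum() - 1.0) < 1e-12 and dist.min() >= 0.0
        return dist


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings: sizes, length range, effect size, profile
    sharpness and the master seed."""

    n_pos: int = 200
    n_neg: int = 200
    min_length: int = 5
    max_length: int = DEFAULT_WIDTH
    width: int = DEFAULT_WIDTH
    effect_size: float = 0.3
    profile_sharpness: float = 6.0
    profile_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")
        if not 1 <= self.min_length <= self.max_length <= self.width:
            raise ValueError("need 1 <= min_length <= max_length <= width")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")


def generate_peptides(
    cfg: SimulationConfig, spec: EnrichmentSpec | None = None
) -> LabeledDataset:
    """Draw a labeled, padded peptide dataset from the enrichment model."""
    spec = spec or EnrichmentSpec()
    rng = np.random.default_rng(cfg.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    peptides: list[PaddedPeptide] = []
    for label, count, prefix in (
        (POSITIVE, cfg.n_pos, "pos"),
        (NEGATIVE, cfg.n_neg, "neg"),
    ):
        if count == 0:
            continue
        # per-position residue distributions for this class
        cums = [
            np.cumsum(spec.distribution(m, label, cfg.effect_size))
            for m in range(1, cfg.width + 1)
        ]
        lengths = rng.integers(cfg.min_length, cfg.max_length + 1, size=count)
        u = rng.random((count, cfg.width))
        codes = np.empty((count, cfg.width), dtype=int)
        for m in range(cfg.width):
            codes[:, m] = np.minimum(
                np.searchsorted(cums[m], u[:, m], side="right"), 19
            )
        for i in range(count):
            seq = "".join(alphabet[codes[i, : lengths[i]]])
            p = Peptide(id=f"{prefix}_{i + 1:05d}", sequence=seq, label=label)
            peptides.append(pad_peptide(p, cfg.width))
    return LabeledDataset(peptides, require_both_classes=False)


def generate_profile(
    p: PaddedPeptide,
    sharpness: float = 6.0,
    noise_sd: float = 2.0,
    noise_seed: int = 0,
) -> PssmProfile:
    """A synthetic signed profile consistent with the peptide sequence.

    Non-gap rows have mean ``sharpness`` at the true residue and mean -1
    elsewhere, plus Gaussian noise of sd ``noise_sd``; gap rows are all
    zero.  Writable in the PSI-BLAST ASCII dialect.
    """
    if sharpness < 0:
        raise ValueError("sharpness must be >= 0")
    rng = np.random.default_rng(noise_seed)
    matrix = np.zeros((p.width, 20))
    n = p.original_length
    matrix[:n] = -1.0 + rng.normal(0.0, noise_sd, size=(n, 20))
    for m, ch in enumerate(p.sequence):
        matrix[m, AA_INDEX[ch]] = sharpness + rng.normal(0.0, noise_sd)
    return PssmProfile(id=p.id, matrix=matrix, query=p.window)


def generate_profiles(
    ds: LabeledDataset, cfg: SimulationConfig
) -> dict[str, PssmProfile]:
    """One synthetic profile per dataset peptide, seeded from the config."""
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,))
    seeds = ss.generate_state(len(ds))
    return {
        p.id: generate_profile(
            p,
            sharpness=cfg.profile_sharpness,
            noise_sd=cfg.profile_noise_sd,
            noise_seed=int(seeds[i]),
        )
        for i, p in enumerate(ds)
    }


def simulate_fusion_scores(
    n: int, betas: Sequence[float], alpha: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Scores uniform on [0,1]^4 with labels drawn from the logistic model
    P(label=1) = sigmoid(sum beta_n R_n + alpha)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    betas = np.asarray(betas, dtype=float)
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0.0, 1.0, size=(n, len(betas)))
    logit = scores @ betas + alpha
    p = 1.0 / (1.0 + np.exp(-logit))
    labels = (rng.uniform(size=n) < p).astype(int)
    return scores, labels


def write_fixture_dir(
    outdir: str | Path,
    ds: LabeledDataset,
    profiles: Mapping[str, PssmProfile],
    config: SimulationConfig | None = None,
) -> None:
    """Write FASTA + labels TSV + per-peptide ``.pssm`` files + manifest."""
    outdir = Path(outdir)
    (outdir / "pssm").mkdir(parents=True, exist_ok=True)
    with open(outdir / "peptides.fasta", "w") as fh:
        for p in ds:
            fh.write(f">{p.id}\n{p.sequence}\n")
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("id\tsequence\tlabel\n")
        for p in ds:
            fh.write(f"{p.id}\t{p.sequence}\t{p.label}\n")
    for p in ds:
        write_pssm_ascii(profiles[p.id], outdir / "pssm" / f"{p.id}.pssm")
    manifest = {
        "n_pos": ds.n_pos,
        "n_neg": ds.n_neg,
        "width": ds.width,
        "config": None if config is None else {
            k: getattr(config, k)
            for k in (
                "n_pos", "n_neg", "min_length", "max_length", "width",
                "effect_size", "profile_sharpness", "profile_noise_sd", "seed",
            )
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_fixture_dir(
    fixture_dir: str | Path, width: int | None = None
) -> tuple[LabeledDataset, dict[str, PssmProfile]]:
    """Read back a fixture directory written by :func:`write_fixture_dir`."""
    from .profiles import parse_pssm_ascii
    from .seqio import read_labeled_tsv

    fixture_dir = Path(fixture_dir)
    manifest = json.loads((fixture_dir / "manifest.json").read_text())
    width = width or manifest["width"]
    peptides = [
        pad_peptide(p, width) for p in read_labeled_tsv(fixture_dir / "labels.tsv")
    ]
    ds = LabeledDataset(peptides)
    profiles = {}
    for p in ds:
        prof = parse_pssm_ascii(fixture_dir / "pssm" / f"{p.id}.pssm")
        profiles[p.id] = pad_profile(prof, width)
    return ds, profiles
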