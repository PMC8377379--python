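import numpy as np
import pytest

import epiforest as ef
from epiforest.seqio import AMINO_ACIDS, GAP


@pytest.fixture(scope="session")
def table():
    return ef.aaindex_table()


def random_padded_peptide(rng, width=24, min_len=1, max_len=None, prefix="pep"):
    """A random valid peptide embedded in a width-wide window."""
    max_len = max_len or width
    length = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ef.pad_peptide(
        ef.Peptide(id=f"{prefix}_{rng.integers(1 << 30)}", sequence=seq), width
    )


def random_profile(rng, peptide):
    """A random signed profile aligned to ``peptide`` (zero gap rows)."""
    matrix = np.zeros((peptide.width, 20))
    n = peptide.original_length
    matrix[:n] = rng.integers(-8, 12, size=(n, 20)).astype(float)
    return ef.PssmProfile(id=peptide.id, matrix=matrix, query=peptide.window)


def afc_oracle(p, spacings=(0, 1)):
    """Naive position-loop evaluation of the k-spaced pair composition."""
    out = []
    for k in sorted(set(spacings)):
        block = {}
        for m in range(p.width - k - 1):  # 0-based start positions
            a, b = p.window[m], p.window[m + k + 1]
            if a != GAP and b != GAP:
                block[a + b] = block.get(a + b, 0) + 1
        n_total = p.width - k - 1
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                out.append(block.get(a + b, 0) / n_total)
    return np.array(out)


def pkaf_oracle(p, profile, spacings=(0, 1), per_k_denominator=False):
    """Naive evaluation of the profile-weighted k-spaced pair encoding."""
    out = []
    for k in sorted(set(spacings)):
        block = {}
        for m in range(p.width - k - 1):
            a, b = p.window[m], p.window[m + k + 1]
            if a != GAP and b != GAP:
                sa = profile.matrix[m, AMINO_ACIDS.index(a)]
                sb = profile.matrix[m + k + 1, AMINO_ACIDS.index(b)]
                block[a + b] = block.get(a + b, 0.0) + max(min(sa, sb), 0.0)
        denom = (p.width - k - 1) if per_k_denominator else (p.width - 1)
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                out.append(block.get(a + b, 0.0) / denom)
    return np.array(out)


@pytest.fixture(scope="session")
def small_fixture():
    """A small labeled dataset with matching synthetic profiles."""
    cfg = ef.SimulationConfig(n_pos=40, n_neg=40, seed=11)
    ds = ef.generate_peptides(cfg)
    profiles = ef.generate_profiles(ds, cfg)
    return ds, profiles, cfg
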