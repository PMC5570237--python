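"""Amino-acid alphabet, encoding helpers and the BLOSUM62 substitution prior.

Everything downstream works on the 20 standard residues in alphabetical
one-letter order.  Index 20 is reserved for the insertion gap symbol '-' so
that gapped cores can be scored with a single fancy-index gather against a
21-column matrix whose gap column is all zeros.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 standard residues, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = 20
#: Integer code used for an insertion gap inside an aligned core.
GAP_CODE = 20
GAP_CHAR = "-"

#: Flat background distribution (1/20 per residue).
FLAT_BACKGROUND = np.full(N_AA, 1.0 / N_AA)


def is_valid_sequence(seq: str) -> bool:
    """True if *seq* is non-empty and contains only the 20 standard residues."""
    s = seq.upper()
    return len(s) >= 1 and all(c in AA_INDEX for c in s)


def encode(seq: str) -> np.ndarray:
    """Encode a peptide string as an int array of residue indices (0..19)."""
    try:
        return np.array([AA_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded by filtering upstream
        raise ValueError(f"illegal residue {exc.args[0]!r} in {seq!r}") from exc


def decode(codes: np.ndarray) -> str:
    return "".join(GAP_CHAR if c == GAP_CODE else AMINO_ACIDS[c] for c in codes)


@lru_cache(maxsize=1)
def blosum62_joint() -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct BLOSUM62 target (joint) frequencies and marginals.

    The published BLOSUM62 matrix stores rounded half-bit log-odds
    s_ab = 2*log2(q_ab / (p_a p_b)).  The joint frequencies q and the
    marginals p are recovered jointly by fixed-point iteration:
    q_ab ∝ p_a p_b 2^(s_ab/2) with p required to equal the row marginal
    of q.  Convergence is fast and deterministic; the result is cached.

    Returns (q, p): q is (20, 20) symmetric summing to 1, p its marginal.
    """
    mat = substitution_matrices.load("BLOSUM62")
    order = [mat.alphabet.index(a) for a in AMINO_ACIDS]
    s = np.array(mat)[np.ix_(order, order)]
    odds = np.exp2(s / 2.0)
    p = FLAT_BACKGROUND.copy()
    for _ in range(200):
        q = np.outer(p, p) * odds
        q /= q.sum()
        p_new = q.sum(axis=1)
        if np.max(np.abs(p_new - p)) < 1e-14:
            p = p_new
            break
        p = p_new
    q = np.outer(p, p) * odds
    q /= q.sum()
    return q, q.sum(axis=1)


@lru_cache(maxsize=1)
def blosum62_conditional() -> np.ndarray:
    """Conditional substitution probabilities P(a | b) from BLOSUM62.

    Returns a (20, 20) matrix C with C[b, a] = P(a | b); each row sums to 1.
    Used as the pseudocount prior: g[p] = f[p] @ C.
    """
    q, p = blosum62_joint()
    return q / p[:, None]
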