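"""PSSM estimation and scoring: counts -> frequencies -> log-odds, in bits.

The estimation pipeline for one cluster is

1. aligned core matrix: each member contributes one residue (or a gap) per
   motif position, as dictated by its :class:`~pepgibbs.core.CorePlacement`;
2. Henikoff position-based sequence weighting (redundancy correction),
   weights normalized to sum to the member count;
3. position-wise weighted counts -> relative frequencies;
4. pseudocount correction with a BLOSUM62 substitution prior:
   f' = (alpha*f + beta*g) / (alpha + beta), g[p] = f[p] @ P(a|b),
   alpha = effective_count - 1, beta the configurable prior weight;
5. log-odds PSSM in bits: log2(f' / background).

Insertion-gap motif positions contribute nothing to counts and score zero;
bulged (deleted) peptide residues contribute nothing at all.  There is no
additional gap penalty: indel geometry competes purely on core score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alphabet import (FLAT_BACKGROUND, GAP_CODE, N_AA, blosum62_conditional,
                       encode)
from .core import Assignment, Config, CorePlacement, Peptide

_BIG = 10 ** 9  # effectively-unbounded indel length for geometry-only checks


# ---------------------------------------------------------------------------
# placement enumeration

def enumerate_placements(peptide_length: int, config: Config) -> list[CorePlacement]:
    """All legal core placements for a peptide of the given length.

    Complete and duplicate-free: every ungapped offset, every single
    contiguous insertion (any length 1..max_insertion_length at any motif
    position, terminal gaps included) and every single contiguous deletion
    (any length 1..max_deletion_length, strictly interior to the consumed
    window), each at every compatible offset.  Returned in canonical order
    (offset, kind, indel_pos, indel_len) with none < insertion < deletion.
    """
    L = config.motif_length
    n = peptide_length
    if n < config.min_peptide_length():
        raise ValueError(
            f"peptide length {n} below minimum {config.min_peptide_length()} "
            f"for motif length {L}")
    out: list[CorePlacement] = []
    for off in range(n - L + 1):
        out.append(CorePlacement(off))
    for d in range(1, config.max_insertion_length + 1):
        consumed = L - d
        for off in range(n - consumed + 1):
            for pos in range(L - d + 1):
                out.append(CorePlacement(off, "insertion", pos, d))
    for d in range(1, config.max_deletion_length + 1):
        consumed = L + d
        for off in range(n - consumed + 1):
            for pos in range(1, consumed - d):
                out.append(CorePlacement(off, "deletion", pos, d))
    out.sort(key=CorePlacement.sort_key)
    return out


def core_codes(encoded: np.ndarray, placement: CorePlacement, L: int) -> np.ndarray:
    """Residue code per motif position (GAP_CODE at insertion gaps)."""
    pos = placement.peptide_positions(L)
    codes = np.where(pos < 0, GAP_CODE, encoded[pos])  # gaps masked before use
    return codes.astype(np.int64)


def placement_code_matrix(encoded: np.ndarray, placements: Sequence[CorePlacement],
                          L: int) -> np.ndarray:
    """(n_placements, L) matrix of residue codes, GAP_CODE at gaps."""
    return np.stack([core_codes(encoded, c, L) for c in placements])


# ---------------------------------------------------------------------------
# estimation pipeline

@dataclass
class FrequencyMatrix:
    """Pseudocount-corrected per-position residue frequencies of a cluster."""

    values: np.ndarray          # (L, 20), rows sum to 1
    effective_count: float      # weighted number of sequences behind it
    raw: Optional[np.ndarray] = None   # pre-pseudocount frequencies


@dataclass
class PSSM:
    """Log-odds matrix in bits against a background distribution."""

    values: np.ndarray          # (L, 20)
    background: np.ndarray      # (20,), sums to 1

    @property
    def motif_length(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterModel:
    members: list[Assignment]
    freq: FrequencyMatrix
    pssm: PSSM


def henikoff_weights(code_matrix: np.ndarray) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights.

    Each occupied column distributes weight 1/(r*m) to a member carrying a
    residue seen m times in a column with r distinct residues; gaps earn
    nothing.  Weights are normalized to sum to the number of members, so a
    redundancy-free alignment gets unit weights.
    """
    n, L = code_matrix.shape
    w = np.zeros(n)
    for p in range(L):
        col = code_matrix[:, p]
        occ = col != GAP_CODE
        if not occ.any():
            continue
        counts = np.bincount(col[occ], minlength=N_AA)
        r = int((counts > 0).sum())
        contrib = 1.0 / (r * counts[col[occ]])
        w[occ] += contrib
    total = w.sum()
    if total <= 0:
        return np.ones(n)
    return w * (n / total)


def weighted_counts(code_matrix: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """(L, 20) weighted residue counts; gap cells contribute nothing."""
    n, L = code_matrix.shape
    counts = np.zeros((L, N_AA))
    for i in range(n):
        codes = code_matrix[i]
        occ = codes != GAP_CODE
        counts[np.nonzero(occ)[0], codes[occ]] += weights[i]
    return counts


def frequencies_from_counts(counts: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Row-normalize counts; a fully-gapped position falls back to background."""
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / sums
    empty = (sums[:, 0] <= 0)
    if empty.any():
        freq[empty] = background
    return freq


def effective_sequence_number(counts: np.ndarray) -> float:
    """Effective number of independent sequences behind a count matrix.

    The classic profile heuristic: the mean, over occupied motif positions,
    of the number of distinct residues observed there.  Saturates at 20, so
    large clusters are not rewarded with ever-sharper estimates (which
    would let one cluster absorb everything), and low-diversity fragments
    carved out of a larger cluster are smoothed harder than the cluster
    they came from (which keeps overfit splits from paying off).  A single
    sequence gives exactly 1.
    """
    occupied = counts.sum(axis=1) > 1e-12
    if not occupied.any():
        return 1.0
    distinct = (counts[occupied] > 1e-12).sum(axis=1)
    return float(distinct.mean())


def pseudocount_correct(freq: np.ndarray, effective_count: float, beta: float,
                        background: np.ndarray,
                        prior: str = "background") -> np.ndarray:
    """Blend observed frequencies with a low-count prior.

    f' = (alpha*f + beta*g) / (alpha + beta), alpha = effective_count - 1.

    ``prior="background"`` (default) uses g = background, so beta -> inf
    recovers the background exactly (all-zero PSSM, zero KLD);
    ``prior="blosum62"`` uses the substitution prior g[p] = f[p] @ P(a|b),
    which spreads observed counts onto biochemically similar residues.
    """
    alpha = max(0.0, effective_count - 1.0)
    if alpha + beta <= 0:
        return freq.copy()
    if prior == "blosum62":
        g = freq @ blosum62_conditional()
    else:
        g = np.broadcast_to(background, freq.shape)
    return (alpha * freq + beta * g) / (alpha + beta)


def pssm_from_frequencies(freq: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Entry-wise log2(f/q); -inf only possible when pseudocounts are off."""
    with np.errstate(divide="ignore"):
        return np.log2(freq / background)


def resolve_background(config: Config, peptides: Optional[Sequence[Peptide]] = None
                       ) -> np.ndarray:
    """Flat 1/20 background, or overall residue frequencies of the input."""
    if config.background_model == "flat":
        return FLAT_BACKGROUND.copy()
    if not peptides:
        raise ValueError("data-derived background requires peptides")
    counts = np.zeros(N_AA)
    for p in peptides:
        counts += np.bincount(encode(p.sequence), minlength=N_AA)
    return counts / counts.sum()


def build_cluster_model(cores: Sequence[tuple[Peptide, CorePlacement]],
                        config: Config,
                        background: Optional[np.ndarray] = None) -> ClusterModel:
    """Estimate the full model (counts -> freq -> PSSM) for one cluster."""
    if len(cores) == 0:
        raise ValueError("empty cluster model")
    L = config.motif_length
    q = FLAT_BACKGROUND if background is None else background
    for pep, c in cores:
        if not c.is_legal(len(pep), L, _BIG, _BIG):
            raise ValueError(f"illegal placement {c} for peptide {pep.sequence}")
    codes = np.stack([core_codes(encode(pep.sequence), c, L) for pep, c in cores])
    w = henikoff_weights(codes)
    counts = weighted_counts(codes, w)
    eff = effective_sequence_number(counts)
    raw = frequencies_from_counts(counts, q)
    corrected = pseudocount_correct(raw, eff, config.beta, q,
                                    config.pseudocount_prior)
    pssm_vals = pssm_from_frequencies(corrected, q)
    pssm = PSSM(pssm_vals, np.asarray(q, dtype=float))
    members = [Assignment(pep.index, 0, c) for pep, c in cores]
    members = [
        Assignment(a.peptide_index, a.group, a.placement,
                   score_core(pssm, cores[i][0], cores[i][1]))
        for i, a in enumerate(members)
    ]
    return ClusterModel(members, FrequencyMatrix(corrected, eff, raw), pssm)


# ---------------------------------------------------------------------------
# scoring

def score_core(pssm: PSSM, peptide: Peptide, placement: CorePlacement) -> float:
    """Log-odds score in bits of the placed core: sum over occupied positions.

    Insertion-gap positions contribute 0; bulged residues are ignored.
    """
    L = pssm.motif_length
    if not placement.is_legal(len(peptide), L, _BIG, _BIG):
        raise ValueError(f"illegal placement {placement} for {peptide.sequence}")
    enc = encode(peptide.sequence)
    codes = core_codes(enc, placement, L)
    # sequential accumulation in motif-position order (reproducible scalar sum)
    total = 0.0
    values = pssm.values
    for p in range(L):
        if codes[p] != GAP_CODE:
            total += float(values[p, codes[p]])
    return total


def best_placement(pssm: PSSM, peptide: Peptide, config: Config
                   ) -> tuple[CorePlacement, float]:
    """Highest-scoring legal placement; ties go to canonical order."""
    placements = enumerate_placements(len(peptide), config)
    best_i, best_s = 0, -math.inf
    for i, c in enumerate(placements):
        s = score_core(pssm, peptide, c)
        if s > best_s:   # strict: ties keep the earlier canonical placement
            best_i, best_s = i, s
    return placements[best_i], best_s


def assignment_objective(peptide: Peptide, target_cluster: int, state,
                         config: Config) -> float:
    """Gibbs objective Delta(p, g) for moving *peptide* into *target_cluster*.

    Delta = S(p,g) - lam * max_{g' != g, g' non-empty} S(p,g')
            + sigma * log2(N_g + 1)

    where S is the best-placement score against each cluster's current
    (leave-one-out) PSSM, an empty candidate cluster scores 0 bits (flat
    model) so new clusters can nucleate, and N_g excludes the peptide
    itself.  The peptide must already be removed from every model.
    """
    G = state.n_clusters
    if not (0 <= target_cluster < G):
        raise ValueError(f"unknown cluster id {target_cluster}")
    scores = np.array([
        best_placement(state.cluster_pssm(g), peptide, config)[1]
        for g in range(G)
    ])
    competitors = [scores[g] for g in range(G)
                   if g != target_cluster and state.cluster_size(g) > 0]
    lam_term = config.lam * max(competitors) if competitors else 0.0
    n_g = state.cluster_size(target_cluster)
    return float(scores[target_cluster] - lam_term
                 + config.sigma * math.log2(n_g + 1))


def kld_of_frequencies(freq: np.ndarray, background: np.ndarray) -> float:
    """Information content sum_p sum_a f log2(f/q) of one matrix, in bits."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = freq * np.log2(freq / background)
    return float(np.where(freq > 0, terms, 0.0).sum())


def system_kld(state, config: Config) -> tuple[float, list[float]]:
    """Size-weighted Kullback-Leibler distance of the clustering solution.

    per_cluster[g] = (N_g / N) * KLD(f_g || q) over the pseudocount-
    corrected frequencies, with N the total number of input peptides
    (trash included), so discarding peptides into the trash shrinks the
    total rather than being free.  Trash peptides contribute to no
    cluster's numerator.  Total is the sum over non-empty clusters.
    """
    groups = [g for g in range(state.n_clusters) if state.cluster_size(g) > 0]
    n_assigned = state.n_peptides
    if sum(state.cluster_size(g) for g in groups) == 0:
        raise ValueError("empty state: no peptide assigned to any cluster")
    q = state.background
    per_cluster = []
    for g in range(state.n_clusters):
        n_g = state.cluster_size(g)
        if n_g == 0:
            per_cluster.append(0.0)
            continue
        f = state.corrected_frequencies(g)
        per_cluster.append((n_g / n_assigned) * kld_of_frequencies(f, q))
    return float(sum(per_cluster)), per_cluster
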