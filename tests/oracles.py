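"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over explicit gapped core strings,
deliberately sharing no geometry or linear-algebra code with the package.
"""

from __future__ import annotations

import math
import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_IDX = {a: i for i, a in enumerate(AA)}
GAP = "-"


def brute_core(seq: str, offset: int, kind: str, pos, length, L: int):
    """Materialize the L motif columns as a string, or None if illegal.

    Insertion gaps appear as '-', deleted residues are dropped.  Returns
    None whenever the placement violates the geometry rules.
    """
    n = len(seq)
    if offset < 0:
        return None
    if kind == "none":
        if pos is not None or length is not None:
            return None
        if offset + L > n:
            return None
        return seq[offset:offset + L]
    if pos is None or length is None or length < 1:
        return None
    if kind == "insertion":
        consumed = L - length
        if consumed < 1 or offset + consumed > n:
            return None
        if pos < 0 or pos + length > L:
            return None
        w = seq[offset:offset + consumed]
        return w[:pos] + GAP * length + w[pos:]
    if kind == "deletion":
        consumed = L + length
        if offset + consumed > n:
            return None
        if pos < 1 or pos + length > consumed - 1:
            return None
        w = seq[offset:offset + consumed]
        return w[:pos] + w[pos + length:]
    return None


def brute_enumerate(peptide_len: int, L: int, max_ins: int, max_del: int):
    """Every legal (offset, kind, pos, len) tuple by exhaustive search."""
    seq = "A" * peptide_len
    out = []
    for offset in range(peptide_len + 1):
        if brute_core(seq, offset, "none", None, None, L) is not None:
            out.append((offset, "none", None, None))
        for length in range(1, max_ins + 1):
            for pos in range(L + 1):
                if brute_core(seq, offset, "insertion", pos, length, L) is not None:
                    out.append((offset, "insertion", pos, length))
        for length in range(1, max_del + 1):
            for pos in range(L + length + 1):
                if brute_core(seq, offset, "deletion", pos, length, L) is not None:
                    out.append((offset, "deletion", pos, length))
    return out


def brute_score(pssm_values: np.ndarray, seq: str, offset: int, kind: str,
                pos, length) -> float:
    """Score by explicitly walking the gapped core string."""
    L = pssm_values.shape[0]
    core = brute_core(seq, offset, kind, pos, length, L)
    assert core is not None, "illegal placement passed to oracle"
    total = 0.0
    for p, ch in enumerate(core):
        if ch != GAP:
            total += pssm_values[p][AA_IDX[ch]]
    return total


def brute_henikoff(cores: list[str]) -> list[float]:
    """Position-based sequence weights from explicit core strings."""
    n = len(cores)
    L = len(cores[0])
    w = [0.0] * n
    for p in range(L):
        col = [c[p] for c in cores]
        residues = [ch for ch in col if ch != GAP]
        if not residues:
            continue
        distinct = sorted(set(residues))
        r = len(distinct)
        for i, ch in enumerate(col):
            if ch != GAP:
                w[i] += 1.0 / (r * residues.count(ch))
    total = sum(w)
    if total <= 0:
        return [1.0] * n
    return [x * n / total for x in w]


def brute_model(cores: list[str], beta: float, background: np.ndarray,
                prior: str = "background",
                conditional: np.ndarray | None = None,
                weights: list[float] | None = None):
    """counts -> weights -> frequencies -> pseudocounts -> PSSM, all loops.

    Sequence weights are recomputed from the cores unless given (the
    sampler caches batch weights, so its leave-one-out models keep the
    weights of the surrounding batch).  Returns
    (corrected_freq, pssm, effective_count).
    """
    n = len(cores)
    L = len(cores[0])
    w = brute_henikoff(cores) if weights is None else list(weights)
    counts = [[0.0] * 20 for _ in range(L)]
    for i, core in enumerate(cores):
        for p, ch in enumerate(core):
            if ch != GAP:
                counts[p][AA_IDX[ch]] += w[i]
    # effective count: mean distinct residues over occupied positions
    distinct = []
    for p in range(L):
        if sum(counts[p]) > 1e-12:
            distinct.append(sum(1 for v in counts[p] if v > 1e-12))
    eff = sum(distinct) / len(distinct) if distinct else 1.0
    freq = [[0.0] * 20 for _ in range(L)]
    for p in range(L):
        s = sum(counts[p])
        for a in range(20):
            freq[p][a] = counts[p][a] / s if s > 0 else background[a]
    alpha = max(0.0, eff - 1.0)
    corrected = [[0.0] * 20 for _ in range(L)]
    for p in range(L):
        for a in range(20):
            if alpha + beta <= 0:
                corrected[p][a] = freq[p][a]
            elif prior == "background":
                corrected[p][a] = (alpha * freq[p][a] + beta * background[a]) / (alpha + beta)
            else:
                g = sum(freq[p][b] * conditional[b][a] for b in range(20))
                corrected[p][a] = (alpha * freq[p][a] + beta * g) / (alpha + beta)
    pssm = [[math.log2(corrected[p][a] / background[a]) if corrected[p][a] > 0
             else -math.inf for a in range(20)] for p in range(L)]
    return np.array(corrected), np.array(pssm), eff


def brute_system_kld(cluster_freqs: dict[int, np.ndarray],
                     cluster_sizes: dict[int, int], n_total: int,
                     background: np.ndarray):
    """Size-weighted KLD by explicit double loops over positions/residues."""
    per = {}
    for g, f in cluster_freqs.items():
        kld = 0.0
        for p in range(f.shape[0]):
            for a in range(20):
                if f[p][a] > 0:
                    kld += f[p][a] * math.log2(f[p][a] / background[a])
        per[g] = (cluster_sizes[g] / n_total) * kld
    return sum(per.values()), per


def ari_from_labels(truth: list, pred: list) -> float:
    """Adjusted Rand index straight from the textbook pair-counting formula."""
    n = len(truth)
    t_classes = sorted(set(truth))
    p_classes = sorted(set(pred))
    nij = {(t, p): 0 for t in t_classes for p in p_classes}
    for t, p in zip(truth, pred):
        nij[(t, p)] += 1

    def c2(x):
        return x * (x - 1) // 2

    sum_ij = sum(c2(v) for v in nij.values())
    sum_a = sum(c2(truth.count(t)) for t in t_classes)
    sum_b = sum(c2(pred.count(p)) for p in p_classes)
    expected = sum_a * sum_b / c2(n)
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 0.0
    return (sum_ij - expected) / (maximum - expected)


def random_pssm(rng: np.random.Generator, L: int = 9, scale: float = 2.0) -> np.ndarray:
    return rng.normal(0.0, scale, size=(L, 20))


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(20, size=length))
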