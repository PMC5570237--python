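"""Planted-motif peptide generators and clustering-agreement metrics.

These synthetic sets stand in for mass-spectrometry peptidome data in all
tests: each peptide is drawn from a known per-position residue distribution
(the *motif*), optionally stretched or shortened around the motif (so that
recovering the alignment requires an indel), flanked by background residues
and mixed with uniform-random noise peptides.  The ground truth (source
motif, planted offset, planted indel) is recorded per peptide.

The canonical benchmark mirrors anchor-style binding motifs: a few
high-information anchor positions over a near-background remainder, three
motifs with disjoint anchors, class sizes 150/100/50 and 5% noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA
from .core import TRASH, Peptide
from .sampler import Solution

NOISE_LABEL = "noise"
TRASH_LABEL = "Trash"


@dataclass(frozen=True)
class MotifSpec:
    """A named motif: one residue distribution per position."""

    name: str
    probs: np.ndarray        # (L, 20), rows sum to 1

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != N_AA or p.shape[0] < 1:
            raise ValueError("probs must be (L, 20) with L >= 1")
        if (p < 0).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position must be a probability distribution")
        object.__setattr__(self, "probs", p)

    def information_content(self) -> np.ndarray:
        """Per-position information in bits against a flat background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.probs * np.log2(self.probs * N_AA)
        return np.where(self.probs > 0, t, 0.0).sum(axis=1)


def anchor_motif(name: str, length: int, anchors: dict[int, str],
                 anchor_prob: float = 0.9) -> MotifSpec:
    """Motif with high-probability anchor residues over a flat remainder."""
    probs = np.full((length, N_AA), 1.0 / N_AA)
    for pos, residue in anchors.items():
        row = np.full(N_AA, (1.0 - anchor_prob) / (N_AA - 1))
        row[AA_INDEX[residue]] = anchor_prob
        probs[pos] = row
    return MotifSpec(name, probs)


def mhc_like_motif(name: str, consensus: str, anchors: set[int],
                   anchor_prob: float = 0.9, weak_prob: float = 0.25) -> MotifSpec:
    """Anchor-style motif with weak preferences at non-anchor positions.

    Mirrors class-I binding motifs: strong anchors (default ~3.4 bits) at
    the given positions, a mild consensus preference (default ~0.3 bits,
    near background) everywhere else.
    """
    L = len(consensus)
    probs = np.zeros((L, N_AA))
    for p, residue in enumerate(consensus.upper()):
        dom = anchor_prob if p in anchors else weak_prob
        row = np.full(N_AA, (1.0 - dom) / (N_AA - 1))
        row[AA_INDEX[residue]] = dom
        probs[p] = row
    return MotifSpec(name, probs)


def consensus_motif(name: str, consensus: str, dominant_prob: float) -> MotifSpec:
    """Motif placing *dominant_prob* on a consensus residue at every position."""
    L = len(consensus)
    probs = np.full((L, N_AA), (1.0 - dominant_prob) / (N_AA - 1))
    for p, residue in enumerate(consensus.upper()):
        probs[p, AA_INDEX[residue]] = dominant_prob
    return MotifSpec(name, probs)


def _sample_residues(probs: np.ndarray, rng: np.random.Generator) -> str:
    cum = probs.cumsum(axis=1)
    draws = rng.random(probs.shape[0])
    idx = (draws[:, None] > cum).sum(axis=1)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _random_residues(n: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(N_AA, size=n))


def sample_peptides(spec: MotifSpec, n: int,
                    length_distribution: Optional[dict[int, float]] = None,
                    flank_distribution: Optional[dict[int, float]] = None,
                    rng: Optional[np.random.Generator] = None,
                    start_index: int = 0) -> tuple[list[Peptide], pd.DataFrame]:
    """Draw *n* peptides from a motif with known truth records.

    ``length_distribution`` gives the probability of each motif-region
    length (default: all mass on L).  A region of length L+d carries d
    extra background residues planted at an interior position (the aligner
    must bulge them out with a deletion); a region of length L-d omits d
    consecutive motif residues at an interior position (the aligner must
    realign with an insertion gap).  Background flanks with lengths drawn
    from ``flank_distribution`` (default: none) are added on both sides.

    Returns the peptides and a truth table with columns
    (index, motif, offset, indel_kind, indel_pos, indel_len).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    L = spec.length
    length_distribution = length_distribution or {L: 1.0}
    lengths = sorted(length_distribution)
    lp = np.array([length_distribution[k] for k in lengths], dtype=float)
    if (lp < 0).any() or not np.isclose(lp.sum(), 1.0):
        raise ValueError("invalid length distribution")
    if any(k < 2 for k in lengths):   # interior indel positions must exist
        raise ValueError("invalid length distribution")
    flank_distribution = flank_distribution or {0: 1.0}
    flens = sorted(flank_distribution)
    fp = np.array([flank_distribution[k] for k in flens], dtype=float)
    fp = fp / fp.sum()

    peptides: list[Peptide] = []
    records = []
    for i in range(n):
        core = _sample_residues(spec.probs, rng)
        region_len = lengths[rng.choice(len(lengths), p=lp)]
        kind, pos, ln = "none", None, None
        if region_len > L:
            d = region_len - L
            j = int(rng.integers(1, L))           # insert before core residue j
            core = core[:j] + _random_residues(d, rng) + core[j:]
            kind, pos, ln = "extra", j, d          # needs a deletion at j
        elif region_len < L:
            d = L - region_len
            j = int(rng.integers(1, L - d))        # omit core residues [j, j+d)
            core = core[:j] + core[j + d:]
            kind, pos, ln = "omitted", j, d        # needs an insertion at j
        left = flens[rng.choice(len(flens), p=fp)]
        right = flens[rng.choice(len(flens), p=fp)]
        seq = _random_residues(left, rng) + core + _random_residues(right, rng)
        idx = start_index + i
        peptides.append(Peptide(idx, seq, spec.name))
        records.append({"index": idx, "motif": spec.name, "offset": left,
                        "indel_kind": kind, "indel_pos": pos, "indel_len": ln})
    return peptides, pd.DataFrame.from_records(records)


def make_benchmark(specs: Sequence[MotifSpec], sizes: Sequence[int],
                   noise_fraction: float, rng: np.random.Generator,
                   length_distribution: Optional[dict[int, float]] = None,
                   flank_distribution: Optional[dict[int, float]] = None,
                   ) -> tuple[list[Peptide], pd.DataFrame]:
    """Multi-motif benchmark: per-spec samples plus uniform noise, shuffled.

    The number of noise peptides is binomial with mean
    noise_fraction/(1-noise_fraction) * sum(sizes); noise sequences are
    uniform over residues and over the length range of the signal peptides.
    Peptide labels carry the truth class (motif name or "noise").
    """
    if len(specs) < 1 or len(specs) != len(sizes) or any(s < 1 for s in sizes):
        raise ValueError("need at least one spec with a positive size")
    if not (0 <= noise_fraction < 1):
        raise ValueError("noise_fraction must be in [0, 1)")
    all_peps: list[Peptide] = []
    frames = []
    for spec, n in zip(specs, sizes):
        peps, truth = sample_peptides(spec, n, length_distribution,
                                      flank_distribution, rng,
                                      start_index=len(all_peps))
        all_peps.extend(peps)
        frames.append(truth)
    if noise_fraction > 0:
        total_planned = round(sum(sizes) / (1.0 - noise_fraction))
        n_noise = int(rng.binomial(total_planned, noise_fraction))
        lens = [len(p) for p in all_peps]
        lo, hi = min(lens), max(lens)
        noise_records = []
        for _ in range(n_noise):
            ln = int(rng.integers(lo, hi + 1))
            idx = len(all_peps)
            all_peps.append(Peptide(idx, _random_residues(ln, rng), NOISE_LABEL))
            noise_records.append({"index": idx, "motif": NOISE_LABEL,
                                  "offset": None, "indel_kind": "none",
                                  "indel_pos": None, "indel_len": None})
        if noise_records:
            frames.append(pd.DataFrame.from_records(noise_records))
    truth = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(all_peps))
    shuffled = []
    for new_idx, old_idx in enumerate(order):
        p = all_peps[old_idx]
        shuffled.append(Peptide(new_idx, p.sequence, p.label))
    truth = truth.iloc[order].reset_index(drop=True)
    truth["index"] = np.arange(len(truth))
    return shuffled, truth


def write_benchmark(peptides: Sequence[Peptide], truth: pd.DataFrame,
                    peptide_path, truth_path) -> None:
    """Write the tabular peptide file (sequence + label) and truth TSV."""
    with open(peptide_path, "w") as fh:
        for p in peptides:
            fh.write(f"{p.sequence}\t{p.label}\n" if p.label else f"{p.sequence}\n")
    truth.to_csv(truth_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# canonical fixtures

def canonical_specs() -> list[MotifSpec]:
    """Three 9-mer motifs with disjoint two-position anchors (~3.4 bits each)
    plus weak near-background preferences elsewhere."""
    return [
        mhc_like_motif("motifA", "GLNAVETSY", {1, 8}),
        mhc_like_motif("motifB", "DAEWKSGTC", {0, 4}),
        mhc_like_motif("motifC", "SPQFAMRHE", {3, 6}),
    ]


def canonical_benchmark(seed: int = 42) -> tuple[list[Peptide], pd.DataFrame]:
    """The frozen 3-motif benchmark: sizes 150/100/50, 5% noise, 9-mers."""
    rng = np.random.default_rng(seed)
    return make_benchmark(canonical_specs(), (150, 100, 50), 0.05, rng)


SINGLE_MOTIF_CONSENSUS = "LDKFYEVRW"


def single_motif_fixture(n: int = 300, seed: int = 7,
                         ) -> tuple[list[Peptide], pd.DataFrame]:
    """One planted ungapped 9-mer motif (~1.7 bits/position) with flanks.

    Flank lengths 0-3 on either side give up to 7 candidate offsets per
    peptide; the truth offset is the left-flank length.
    """
    spec = consensus_motif("motif1", SINGLE_MOTIF_CONSENSUS, 0.6)
    rng = np.random.default_rng(seed)
    flanks = {0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25}
    return sample_peptides(spec, n, None, flanks, rng)


def indel_fixture(kind: str, n: int = 200, seed: int = 11,
                  ) -> tuple[list[Peptide], pd.DataFrame]:
    """Strong-consensus 9-mer motif whose peptides all need one indel.

    kind="extra": 10-mers with one planted background residue inside the
    core (a deletion placement must bulge it out).  kind="omitted": 8-mers
    missing one interior core residue (an insertion gap must restore the
    frame).
    """
    spec = consensus_motif("motif1", "WFDKYLEVR", 0.9)
    rng = np.random.default_rng(seed)
    if kind == "extra":
        dist = {10: 1.0}
    elif kind == "omitted":
        dist = {8: 1.0}
    else:
        raise ValueError("kind must be 'extra' or 'omitted'")
    return sample_peptides(spec, n, dist, None, rng)


# ---------------------------------------------------------------------------
# agreement metrics

def _solution_labels(solution: Solution) -> dict[int, str]:
    out = {}
    for a in solution.assignments:
        out[a.peptide_index] = TRASH_LABEL if a.group == TRASH else f"c{a.group}"
    return out


def clustering_agreement(truth: pd.DataFrame, solution: Solution
                         ) -> tuple[float, dict[str, float]]:
    """Adjusted Rand index and per-motif purity of a solution vs truth.

    Trash and noise each count as their own category.  Purity of a truth
    class is the largest fraction of its members captured by any single
    predicted cluster (trash included as a catch-all category).
    """
    truth_map = dict(zip(truth["index"].astype(int), truth["motif"]))
    pred_map = _solution_labels(solution)
    if set(truth_map) != set(pred_map):
        raise ValueError("truth and solution cover different peptide sets")
    keys = sorted(truth_map)
    t = [truth_map[k] for k in keys]
    p = [pred_map[k] for k in keys]
    ari = float(adjusted_rand_score(t, p))
    purity: dict[str, float] = {}
    df = pd.DataFrame({"t": t, "p": p})
    for motif, sub in df.groupby("t"):
        purity[str(motif)] = float(sub["p"].value_counts().iloc[0] / len(sub))
    return ari, purity
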