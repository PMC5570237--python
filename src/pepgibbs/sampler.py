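"""Annealed Gibbs sampler for simultaneous peptide clustering and alignment.

The sampler walks a :class:`SystemState` — a full assignment of every
peptide to (cluster, core placement) or trash — through a geometric cooling
schedule.  Moves:

* **peptide move** — leave-one-out Gibbs resampling of one peptide over the
  joint candidate set of every (cluster, placement) pair, with probability
  proportional to ``exp(Delta / T)``; alignment and clustering are thereby
  sampled simultaneously;
* **indel move** — greedy reset of one peptide's placement to the
  highest-scoring gapped placement within its current cluster, attempted at
  a fixed iteration interval;
* **phase-shift move** — Metropolis-accepted shift of a whole cluster's
  alignment by one position, to escape off-phase local optima;
* **trash resampling** — peptides whose sampled score falls below the trash
  threshold are parked in a trash cluster and periodically offered back.

Cluster models are maintained incrementally (weighted counts per cluster)
with Henikoff sequence weights refreshed once per temperature step; a debug
mode verifies the incremental state against a from-scratch rebuild.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed

from .alphabet import GAP_CODE, N_AA
from .core import TRASH, Assignment, Config, CorePlacement, Peptide, validate_config
from .scoring import (ClusterModel, build_cluster_model,
                      effective_sequence_number, enumerate_placements,
                      frequencies_from_counts, henikoff_weights,
                      placement_code_matrix, pseudocount_correct,
                      pssm_from_frequencies, resolve_background, system_kld,
                      weighted_counts, PSSM)

_EXP_CLIP = 700.0


class SystemState:
    """Mutable sampler state: assignments, incremental counts, cached PSSMs."""

    def __init__(self, peptides: Sequence[Peptide], g: int, config: Config,
                 rng: np.random.Generator,
                 background: Optional[np.ndarray] = None):
        if len(peptides) == 0:
            raise ValueError("no peptides to initialize from")
        if g < 1:
            raise ValueError("need at least one cluster")
        self.peptides = list(peptides)
        self.config = config
        self.n_clusters = g
        self.rng = rng
        self.background = (resolve_background(config, peptides)
                           if background is None else np.asarray(background, float))
        L = config.motif_length
        from .alphabet import encode
        self.enc = [encode(p.sequence) for p in self.peptides]
        self.placements: list[list[CorePlacement]] = [
            enumerate_placements(len(p), config) for p in self.peptides]
        self.codes = [placement_code_matrix(self.enc[i], self.placements[i], L)
                      for i in range(len(self.peptides))]
        self._lookup = [
            {c.sort_key(): k for k, c in enumerate(pl)} for pl in self.placements]
        n = len(self.peptides)
        self.group = np.full(n, TRASH, dtype=np.int64)
        self.placement_i = np.full(n, -1, dtype=np.int64)
        self.weights = np.ones(n)
        self.scores = np.full(n, np.nan)
        self.counts = np.zeros((g, L, N_AA))
        self.sizes = np.zeros(g, dtype=np.int64)
        self.wsums = np.zeros(g)
        self._ext_pssm: list[Optional[np.ndarray]] = [None] * g
        self._freq: list[Optional[np.ndarray]] = [None] * g
        self.T = config.T_initial
        self.iteration = 0
        self.tallies: dict[str, int] = {
            "peptide_moves": 0, "cluster_changes": 0, "to_trash": 0,
            "from_trash": 0, "indel_moves": 0, "indel_changed": 0,
            "indel_noop": 0, "phase_accept": 0, "phase_reject": 0,
            "phase_abort": 0,
        }

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    def cluster_size(self, g: int) -> int:
        return int(self.sizes[g])

    def members_of(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.group == g)

    def trash_members(self) -> np.ndarray:
        return np.flatnonzero(self.group == TRASH)

    def _invalidate(self, g: int) -> None:
        self._ext_pssm[g] = None
        self._freq[g] = None

    def add(self, p: int, g: int, ci: int) -> None:
        codes = self.codes[p][ci]
        occ = np.flatnonzero(codes != GAP_CODE)
        self.counts[g][occ, codes[occ]] += self.weights[p]
        self.sizes[g] += 1
        self.wsums[g] += self.weights[p]
        self.group[p] = g
        self.placement_i[p] = ci
        self._invalidate(g)

    def remove(self, p: int) -> None:
        g = self.group[p]
        if g == TRASH:
            return
        ci = self.placement_i[p]
        codes = self.codes[p][ci]
        occ = np.flatnonzero(codes != GAP_CODE)
        self.counts[g][occ, codes[occ]] -= self.weights[p]
        self.sizes[g] -= 1
        self.wsums[g] -= self.weights[p]
        self.group[p] = TRASH
        self.placement_i[p] = -1
        self._invalidate(g)

    def set_trash(self, p: int) -> None:
        self.group[p] = TRASH
        self.placement_i[p] = -1
        self.scores[p] = np.nan

    # -- models -------------------------------------------------------------

    def corrected_frequencies(self, g: int) -> np.ndarray:
        """Pseudocount-corrected frequency matrix of cluster *g*."""
        if self._freq[g] is None:
            self._compute_model(g)
        return self._freq[g]

    def ext_pssm(self, g: int) -> np.ndarray:
        """(L, 21) log-odds matrix with an all-zero gap column appended."""
        if self._ext_pssm[g] is None:
            self._compute_model(g)
        return self._ext_pssm[g]

    def cluster_pssm(self, g: int) -> PSSM:
        return PSSM(self.ext_pssm(g)[:, :N_AA].copy(), self.background)

    def _compute_model(self, g: int) -> None:
        L = self.config.motif_length
        ext = np.zeros((L, N_AA + 1))
        if self.sizes[g] == 0:
            self._freq[g] = np.tile(self.background, (L, 1))
            self._ext_pssm[g] = ext   # empty cluster: flat model, 0 bits
            return
        counts = np.clip(self.counts[g], 0.0, None)
        raw = frequencies_from_counts(counts, self.background)
        corrected = pseudocount_correct(raw, effective_sequence_number(counts),
                                        self.config.beta, self.background,
                                        self.config.pseudocount_prior)
        ext[:, :N_AA] = pssm_from_frequencies(corrected, self.background)
        self._freq[g] = corrected
        self._ext_pssm[g] = ext

    def score_placements(self, p: int, g: int) -> np.ndarray:
        """Scores of every enumerated placement of peptide p against cluster g."""
        ext = self.ext_pssm(g)
        codes = self.codes[p]
        L = codes.shape[1]
        return ext[np.arange(L)[None, :], codes].sum(axis=1)

    def ext_pssm_at_effective_count(self, g: int, eff: float) -> np.ndarray:
        """PSSM of cluster g with a pinned effective sequence number.

        Used by whole-cluster proposals so that the two configurations are
        compared under the same data:prior balance (a sharper alignment
        lowers the per-column residue diversity and would otherwise be
        smoothed harder than the configuration it competes with).
        """
        L = self.config.motif_length
        ext = np.zeros((L, N_AA + 1))
        if self.sizes[g] == 0:
            return ext
        counts = np.clip(self.counts[g], 0.0, None)
        raw = frequencies_from_counts(counts, self.background)
        corrected = pseudocount_correct(raw, eff, self.config.beta,
                                        self.background,
                                        self.config.pseudocount_prior)
        ext[:, :N_AA] = pssm_from_frequencies(corrected, self.background)
        return ext

    def refresh_weights(self) -> None:
        """Recompute Henikoff weights per cluster and rebuild counts."""
        for g in range(self.n_clusters):
            members = self.members_of(g)
            if len(members) == 0:
                self.counts[g][:] = 0.0
                self.wsums[g] = 0.0
                self._invalidate(g)
                continue
            codes = np.stack([self.codes[p][self.placement_i[p]] for p in members])
            w = henikoff_weights(codes)
            self.weights[members] = w
            self.counts[g] = weighted_counts(codes, w)
            self.wsums[g] = float(w.sum())
            self._invalidate(g)
        tm = self.trash_members()
        if len(tm):
            self.weights[tm] = 1.0

    def rebuilt_counts(self, g: int) -> np.ndarray:
        members = self.members_of(g)
        if len(members) == 0:
            return np.zeros_like(self.counts[g])
        codes = np.stack([self.codes[p][self.placement_i[p]] for p in members])
        return weighted_counts(codes, self.weights[members])

    def check_consistency(self, atol: float = 1e-9) -> None:
        """Assert incremental counts match a from-scratch rebuild; resync."""
        n_in_clusters = int((self.group != TRASH).sum())
        n_trash = int((self.group == TRASH).sum())
        assert n_in_clusters + n_trash == self.n_peptides, "peptides lost"
        assert n_in_clusters == int(self.sizes.sum()), "size ledger broken"
        for g in range(self.n_clusters):
            rebuilt = self.rebuilt_counts(g)
            if not np.allclose(self.counts[g], rebuilt, atol=atol, rtol=0):
                raise AssertionError(
                    f"incremental counts diverged from rebuild for cluster {g}: "
                    f"max |diff| = {np.abs(self.counts[g] - rebuilt).max():.3e}")
            self.counts[g] = rebuilt
            self._invalidate(g)


def initialize_state(peptides: Sequence[Peptide], g: int, config: Config,
                     seed) -> SystemState:
    """Uniform-random initial configuration, fully determined by *seed*.

    Each peptide lands in a uniform-random cluster with a uniform-random
    legal placement; models are built and T set to T_initial.  *seed* may be
    an int, a ``SeedSequence`` or a ``Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = SystemState(peptides, g, config, rng)
    for p in range(state.n_peptides):
        gp = int(rng.integers(g))
        ci = int(rng.integers(len(state.placements[p])))
        state.add(p, gp, ci)
    return state


# ---------------------------------------------------------------------------
# moves

def _competitor_best(best: np.ndarray, nonempty: np.ndarray) -> np.ndarray:
    """For each g, max of best[g'] over non-empty g' != g (0.0 if none)."""
    G = len(best)
    masked = np.where(nonempty, best, -np.inf)
    order = np.argsort(masked)
    top, second = masked[order[-1]], masked[order[-2]] if G > 1 else -np.inf
    out = np.full(G, top)
    out[order[-1]] = second
    out[~np.isfinite(out)] = 0.0
    return out


def peptide_move(state: SystemState, p: int, config: Optional[Config] = None,
                 allow_cluster_change: bool = True) -> None:
    """Gibbs-resample one peptide over the joint (cluster, placement) set.

    The peptide is first removed from its model (leave-one-out).  Candidate
    (g, c) has objective Delta = S(p,g,c) - lam * max_{g' != g} S_best(p,g')
    + sigma*log2(N_g + 1) (competitor max over non-empty clusters only);
    one candidate is drawn with probability prop. to exp(Delta/T).  If the
    trash cluster is active and the drawn candidate's raw score is below the
    threshold, the peptide goes to trash instead.
    """
    cfg = config or state.config
    was = int(state.group[p])
    state.tallies["peptide_moves"] += 1
    if not allow_cluster_change and was == TRASH:
        return
    state.remove(p)
    G = state.n_clusters
    nc = len(state.placements[p])
    score_mat = np.empty((G, nc))
    for g in range(G):
        score_mat[g] = state.score_placements(p, g)
    best = score_mat.max(axis=1)
    nonempty = state.sizes > 0
    comp = _competitor_best(best, nonempty)
    size_term = cfg.sigma * np.log2(state.sizes + 1.0)
    delta = score_mat - cfg.lam * comp[:, None] + size_term[:, None]
    if allow_cluster_change:
        flat = delta.ravel()
        m = flat.max()
        w = np.exp(np.clip((flat - m) / state.T, -_EXP_CLIP, 0.0))
        cum = np.cumsum(w)
        k = int(np.searchsorted(cum, state.rng.random() * cum[-1], side="right"))
        k = min(k, flat.size - 1)
        g_new, ci = divmod(k, nc)
    else:
        row = delta[was]
        m = row.max()
        w = np.exp(np.clip((row - m) / state.T, -_EXP_CLIP, 0.0))
        cum = np.cumsum(w)
        ci = int(np.searchsorted(cum, state.rng.random() * cum[-1], side="right"))
        ci = min(ci, nc - 1)
        g_new = was
    raw = float(score_mat[g_new, ci])
    # The quality gate applies when joining an established cluster; a win
    # for an empty cluster nucleates it regardless, otherwise a fully
    # trashed system could never repopulate (empty models score 0 bits).
    if cfg.use_trash and state.sizes[g_new] > 0 and raw < cfg.trash_threshold:
        state.set_trash(p)
        if was != TRASH:
            state.tallies["to_trash"] += 1
        return
    state.add(p, g_new, ci)
    state.scores[p] = raw
    if was == TRASH:
        state.tallies["from_trash"] += 1
    elif g_new != was:
        state.tallies["cluster_changes"] += 1


def indel_move(state: SystemState, p: int, config: Optional[Config] = None) -> None:
    """Greedily reset peptide p's placement to the best within its cluster.

    Deterministic (argmax over the full gapped enumeration, leave-one-out),
    matching the 'highest peptide score' rule for indel moves.  No-op when
    indels are disabled or the peptide sits in trash.
    """
    cfg = config or state.config
    if not cfg.indels_enabled:
        state.tallies["indel_noop"] += 1
        return
    g = int(state.group[p])
    if g == TRASH:
        return
    state.tallies["indel_moves"] += 1
    old_ci = int(state.placement_i[p])
    state.remove(p)
    scores = state.score_placements(p, g)
    ci = int(np.argmax(scores))
    state.add(p, g, ci)
    state.scores[p] = float(scores[ci])
    if ci != old_ci:
        state.tallies["indel_changed"] += 1


def phase_shift_move(state: SystemState, g: int,
                     config: Optional[Config] = None) -> None:
    """Propose shifting every member of cluster g by one offset position.

    Members whose shifted placement is illegal keep theirs, but if more
    than 10% of members cannot shift the proposal aborts.  Accepted by
    Metropolis on the change in summed member scores at the current T.
    """
    cfg = config or state.config
    members = state.members_of(g)
    if len(members) == 0:
        return
    delta = int(state.rng.choice((-1, 1)))
    new_ci = {}
    illegal = 0
    for p in members:
        c = state.placements[p][state.placement_i[p]]
        key = (c.offset + delta,) + c.sort_key()[1:]
        idx = state._lookup[p].get(key)
        if idx is None:
            illegal += 1
        else:
            new_ci[p] = idx
    if illegal > 0.1 * len(members) or not new_ci:
        state.tallies["phase_abort"] += 1
        return
    eff0 = effective_sequence_number(np.clip(state.counts[g], 0.0, None))

    def _energy() -> float:
        ext = state.ext_pssm_at_effective_count(g, eff0)
        L = cfg.motif_length
        return float(sum(
            ext[np.arange(L), state.codes[p][state.placement_i[p]]].sum()
            for p in members))

    old_energy = _energy()
    old_ci = {p: int(state.placement_i[p]) for p in new_ci}
    for p, ci in new_ci.items():
        state.remove(p)
        state.add(p, g, ci)
    new_energy = _energy()
    dE = new_energy - old_energy
    accept = dE >= 0 or state.rng.random() < math.exp(
        max(-_EXP_CLIP, dE / state.T))
    if accept:
        state.tallies["phase_accept"] += 1
        for p in members:
            state.scores[p] = float(
                state.score_placements(p, g)[state.placement_i[p]])
    else:
        state.tallies["phase_reject"] += 1
        for p, ci in old_ci.items():
            state.remove(p)
            state.add(p, g, ci)


def trash_resample(state: SystemState, config: Optional[Config] = None) -> None:
    """Offer every trash peptide back through a regular peptide move.

    A peptide re-enters a cluster only if its drawn candidate scores at
    least the trash threshold (enforced inside :func:`peptide_move`).
    """
    for p in state.trash_members():
        peptide_move(state, int(p), config, allow_cluster_change=True)


# ---------------------------------------------------------------------------
# annealing and the cluster-number scan

@dataclass
class Solution:
    """A frozen, converged clustering: assignments, models and KLD."""

    peptides: list[Peptide]
    assignments: list[Assignment]
    models: dict[int, ClusterModel]
    kld_total: float
    kld_per_cluster: dict[int, float]
    config: Config
    seed: tuple
    g_configured: int
    tallies: dict[str, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        """De-facto number of non-empty clusters in the solution."""
        return len(self.models)

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {g: 0 for g in self.models}
        for a in self.assignments:
            if not a.in_trash:
                sizes[a.group] += 1
        return sizes


def temperature_ladder(config: Config) -> np.ndarray:
    """Geometric cooling schedule from T_initial down to T_final."""
    n = config.num_T_steps
    if n == 1:
        return np.array([config.T_initial])
    r = (config.T_final / config.T_initial) ** (1.0 / (n - 1))
    return config.T_initial * r ** np.arange(n)


def freeze_solution(state: SystemState, seed: tuple = (0, 0)) -> Solution:
    """Freeze a state into a Solution with renumbered non-empty clusters.

    Models are rebuilt from scratch from the final assignments (fresh
    sequence weights), so every Solution is exactly reproducible from its
    own member list.
    """
    state.refresh_weights()
    cfg = state.config
    nonempty = [g for g in range(state.n_clusters) if state.sizes[g] > 0]
    renumber = {g: i for i, g in enumerate(nonempty)}
    models: dict[int, ClusterModel] = {}
    for g in nonempty:
        members = state.members_of(g)
        cores = [(state.peptides[p],
                  state.placements[p][state.placement_i[p]]) for p in members]
        model = build_cluster_model(cores, cfg, state.background)
        models[renumber[g]] = model
    assignments: list[Assignment] = []
    score_by_index: dict[int, float] = {}
    group_by_index: dict[int, tuple[int, CorePlacement]] = {}
    for g in nonempty:
        for a in models[renumber[g]].members:
            score_by_index[a.peptide_index] = a.score
            group_by_index[a.peptide_index] = (renumber[g], a.placement)
    for p, pep in enumerate(state.peptides):
        if state.group[p] == TRASH:
            assignments.append(Assignment(pep.index, TRASH))
        else:
            grp, plc = group_by_index[pep.index]
            assignments.append(
                Assignment(pep.index, grp, plc, score_by_index[pep.index]))
    if nonempty:
        total, per = system_kld(state, cfg)
        per_map = {renumber[g]: per[g] for g in nonempty}
    else:   # degenerate: everything in trash
        total, per_map = 0.0, {}
    return Solution(list(state.peptides), assignments, models, total, per_map,
                    cfg, seed, state.n_clusters, dict(state.tallies))


def anneal(state: SystemState, config: Optional[Config] = None,
           seed: tuple = (0, 0)) -> Solution:
    """Run the full annealing schedule on *state* and freeze the result.

    Per temperature step: refresh sequence weights; one randomized sweep of
    peptide moves (clustering candidates offered on every sweep or only on
    alternate ones, per config); an indel move on the current peptide every
    ``indel_interval`` iterations; one phase-shift proposal per cluster;
    one trash resampling pass.
    """
    cfg = config or state.config
    n = state.n_peptides
    iters = cfg.resolve_iterations(n)
    if iters == 0:   # no-op schedule: freeze the initial configuration
        return freeze_solution(state, seed)
    for step, T in enumerate(temperature_ladder(cfg)):
        state.T = float(T)
        state.refresh_weights()
        allow = cfg.clustering_move_every_iteration or (step % 2 == 0)
        perm = state.rng.permutation(n)
        for i in range(iters):
            p = int(perm[i % n])
            peptide_move(state, p, cfg, allow_cluster_change=allow)
            state.iteration += 1
            if cfg.indels_enabled and state.iteration % cfg.indel_interval == 0:
                indel_move(state, p, cfg)
        for g in range(state.n_clusters):
            phase_shift_move(state, g, cfg)
        if cfg.use_trash:
            trash_resample(state, cfg)
        if cfg.debug_checks:
            state.check_consistency()
    return freeze_solution(state, seed)


@dataclass
class ScanResult:
    """All solutions of a cluster-number scan plus the KLD-based suggestion."""

    solutions: dict[tuple[int, int], Solution]   # (g, seed index) -> Solution
    best: dict[int, Solution]                    # g -> highest-KLD solution
    suggested_g: int
    config: Config

    def kld_table(self) -> list[tuple[int, float]]:
        return [(g, self.best[g].kld_total) for g in sorted(self.best)]


def _single_run(peptides: Sequence[Peptide], g: int, i: int,
                config: Config) -> tuple[tuple[int, int], Solution]:
    ss = np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(g, i))
    state = initialize_state(peptides, g, config, np.random.default_rng(ss))
    return (g, i), anneal(state, config, seed=(g, i))


def run_scan(peptides: Sequence[Peptide], config: Config,
             n_jobs: int = 1) -> ScanResult:
    """Anneal num_seeds restarts for every cluster count in the range.

    Every (g, seed) run draws from an independent RNG substream derived
    from the base seed, so results are identical whatever the worker count
    or execution order.  Suggests the cluster count whose best restart has
    the highest total KLD (ties to the smaller count).
    """
    config = validate_config(config)
    if len(peptides) == 0:
        raise ValueError("no peptides")
    g_min, g_max = config.cluster_range
    jobs = [(g, i) for g in range(g_min, g_max + 1)
            for i in range(config.num_seeds)]
    if n_jobs == 1:
        results = [_single_run(peptides, g, i, config) for g, i in jobs]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_single_run)(peptides, g, i, config) for g, i in jobs)
    solutions = dict(results)
    best: dict[int, Solution] = {}
    for g in range(g_min, g_max + 1):
        best[g] = max((solutions[(g, i)] for i in range(config.num_seeds)),
                      key=lambda s: s.kld_total)
    top = max(best[g].kld_total for g in best)
    # parsimony under sampling noise: the smallest count whose best KLD is
    # within suggestion_rtol of the maximum (runs that converge to the same
    # de-facto clustering differ only by Monte Carlo noise)
    suggested = min(g for g in best
                    if best[g].kld_total >= top * (1.0 - config.suggestion_rtol))
    return ScanResult(solutions, best, suggested, config)
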