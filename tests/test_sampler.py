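"""Annealed Gibbs sampler: moves, schedules, determinism and recovery."""

from dataclasses import replace

import numpy as np
import pytest

from pepgibbs import (Config, Peptide, anneal,
                      initialize_state, indel_move, peptide_move,
                      phase_shift_move, run_scan, system_kld, trash_resample,
                      validate_config)
from pepgibbs.alphabet import FLAT_BACKGROUND
from pepgibbs.core import TRASH
from pepgibbs.sampler import temperature_ladder
from pepgibbs.synthetic import consensus_motif, sample_peptides

from oracles import brute_model, brute_score, random_peptide


class StubRng:
    """Deterministic stand-in: .random() yields u, .choice() yields fixed."""

    def __init__(self, u=0.5, choice_value=1):
        self.u = u
        self.choice_value = choice_value

    def random(self):
        return self.u

    def choice(self, options):
        return self.choice_value


def strong_cluster_peptides(n=12, seed=0):
    spec = consensus_motif("m", "WFDKYLEVR", 0.95)
    rng = np.random.default_rng(seed)
    peps, truth = sample_peptides(spec, n, None, {1: 0.5, 2: 0.5}, rng)
    return peps, truth


class TestInitializeState:
    def test_single_cluster_takes_everything(self, rng, flat_config):
        peps = [Peptide(i, random_peptide(rng, 9)) for i in range(10)]
        state = initialize_state(peps, 1, flat_config, 0)
        assert (state.group == 0).all()
        assert state.T == flat_config.T_initial

    def test_same_seed_reproduces_the_state(self, rng, flat_config):
        peps = [Peptide(i, random_peptide(rng, 11)) for i in range(20)]
        a = initialize_state(peps, 3, flat_config, 99)
        b = initialize_state(peps, 3, flat_config, 99)
        assert (a.group == b.group).all()
        assert (a.placement_i == b.placement_i).all()

    def test_no_peptides_raises(self, flat_config):
        with pytest.raises(ValueError):
            initialize_state([], 2, flat_config, 0)

    def test_cluster_occupancy_is_uniform(self, rng, flat_config):
        from scipy.stats import binom
        peps = [Peptide(i, random_peptide(rng, 9)) for i in range(100)]
        totals = np.zeros(4)
        n_init = 200
        for s in range(n_init):
            st = initialize_state(peps, 4, flat_config, s)
            totals += np.bincount(st.group, minlength=4)
        n = 100 * n_init
        lo, hi = binom.ppf([0.005, 0.995], n, 0.25)
        assert ((totals >= lo) & (totals <= hi)).all()


class TestPeptideMove:
    def _toy_state(self, lam=0.6, sigma=0.3, T=1.0, seed=4, n=9, g=2):
        cfg = validate_config(Config(cluster_range=(g, g), lam=lam,
                                     sigma=sigma))
        rng = np.random.default_rng(seed)
        peps = [Peptide(i, random_peptide(rng, 10)) for i in range(n)]
        state = initialize_state(peps, g, cfg, seed)
        state.refresh_weights()
        state.T = T
        return state, cfg

    def _oracle_candidate_probs(self, state, cfg, p):
        """Softmax over (cluster, placement) via the brute-force model path."""
        L = cfg.motif_length
        was = int(state.group[p])
        nc = len(state.placements[p])
        score = np.zeros((state.n_clusters, nc))
        best = np.zeros(state.n_clusters)
        for g in range(state.n_clusters):
            members = [i for i in state.members_of(g) if i != p]
            if members:
                # oracle model works on pure motif columns ('-' for gaps),
                # using the state's cached batch weights
                cores = [self._motif_columns(state, i) for i in members]
                _, pssm, _ = brute_model(cores, cfg.beta, FLAT_BACKGROUND,
                                         weights=[state.weights[i]
                                                  for i in members])
            else:
                pssm = np.zeros((L, 20))
            for ci, c in enumerate(state.placements[p]):
                score[g, ci] = brute_score(pssm, state.peptides[p].sequence,
                                           c.offset, c.indel_kind,
                                           c.indel_pos, c.indel_len)
            best[g] = score[g].max()
        sizes = np.bincount(np.delete(state.group, p)[
            np.delete(state.group, p) >= 0], minlength=state.n_clusters)
        delta = np.zeros_like(score)
        for g in range(state.n_clusters):
            comp = [best[h] for h in range(state.n_clusters)
                    if h != g and sizes[h] > 0]
            delta[g] = (score[g] - cfg.lam * (max(comp) if comp else 0.0)
                        + cfg.sigma * np.log2(sizes[g] + 1.0))
        flat = delta.ravel()
        w = np.exp((flat - flat.max()) / state.T)
        return w / w.sum()

    @staticmethod
    def _motif_columns(state, i):
        """The L motif columns of member i as a string ('-' for gaps)."""
        c = state.placements[i][state.placement_i[i]]
        seq = state.peptides[i].sequence
        pos = c.peptide_positions(state.config.motif_length)
        return "".join("-" if q < 0 else seq[q] for q in pos)

    def test_candidate_distribution_matches_hand_softmax(self):
        state, cfg = self._toy_state()
        p = 2
        probs = self._oracle_candidate_probs(state, cfg, p)
        g0, c0 = int(state.group[p]), int(state.placement_i[p])
        nc = len(state.placements[p])
        grid = np.linspace(0.0005, 0.9995, 2001)
        counts = np.zeros(len(probs))
        for u in grid:
            state.rng = StubRng(u)
            peptide_move(state, p)
            g1, c1 = int(state.group[p]), int(state.placement_i[p])
            counts[g1 * nc + c1] += 1
            state.remove(p)
            state.add(p, g0, c0)   # restore
        empirical = counts / counts.sum()
        assert np.abs(empirical - probs).max() < 2e-3

    def test_zero_temperature_limit_selects_argmax(self):
        state, cfg = self._toy_state(T=1e-9)
        for p in range(state.n_peptides):
            probs = self._oracle_candidate_probs(state, cfg, p)
            nc = len(state.placements[p])
            state.rng = StubRng(0.5)
            peptide_move(state, p)
            chosen = int(state.group[p]) * nc + int(state.placement_i[p])
            # the drawn candidate must carry (tied-)maximal probability
            assert probs[chosen] >= probs.max() - 1e-9

    def test_single_cluster_resamples_offset_only(self):
        state, cfg = self._toy_state(g=1, lam=0.0, sigma=0.0)
        groups_before = state.group.copy()
        for p in range(state.n_peptides):
            peptide_move(state, p)
        assert (state.group == groups_before).all()

    def test_peptide_count_is_conserved(self):
        state, cfg = self._toy_state()
        for sweep in range(3):
            for p in range(state.n_peptides):
                peptide_move(state, p)
                n_in = int((state.group >= 0).sum())
                n_trash = int((state.group == TRASH).sum())
                assert n_in + n_trash == state.n_peptides
                assert n_in == int(state.sizes.sum())


class TestIndelMove:
    def _state_with_indels(self, n=30, seed=3):
        cfg = validate_config(Config(cluster_range=(1, 1), lam=0, sigma=0,
                                     max_insertion_length=1,
                                     max_deletion_length=2))
        peps, truth = sample_peptides(
            consensus_motif("m", "WFDKYLEVR", 0.95), n, {10: 1.0}, None,
            np.random.default_rng(seed))
        state = initialize_state(peps, 1, cfg, seed)
        state.refresh_weights()
        return state, cfg, truth

    def test_already_optimal_placement_is_unchanged(self):
        state, cfg, _ = self._state_with_indels()
        indel_move(state, 0)
        before = int(state.placement_i[0])
        indel_move(state, 0)   # greedy move is idempotent
        assert int(state.placement_i[0]) == before

    def test_disabled_indels_are_a_tallied_noop(self, rng, flat_config):
        peps = [Peptide(i, random_peptide(rng, 10)) for i in range(5)]
        state = initialize_state(peps, 1, flat_config, 0)
        before = state.placement_i.copy()
        indel_move(state, 2)
        assert (state.placement_i == before).all()
        assert state.tallies["indel_noop"] == 1

    def test_planted_extra_residue_is_bulged_out_in_one_move(self):
        """Given a converged cluster model, a single greedy indel move puts
        the gap exactly where the extra residue was planted."""
        state, cfg, truth = self._state_with_indels(n=60, seed=8)
        tmap = truth.set_index("index")
        for p in range(state.n_peptides):   # converged: plant true deletions
            row = tmap.loc[state.peptides[p].index]
            want = [i for i, c in enumerate(state.placements[p])
                    if c.indel_kind == "deletion" and c.offset == 0
                    and c.indel_pos == row["indel_pos"]
                    and c.indel_len == row["indel_len"]][0]
            state.remove(p)
            state.add(p, 0, want)
        state.refresh_weights()
        hits = 0
        for p in range(state.n_peptides):
            state.remove(p)
            state.add(p, 0, 0)      # scramble this one to the naive core
            indel_move(state, p)    # one greedy move against the strong model
            c = state.placements[p][state.placement_i[p]]
            row = tmap.loc[state.peptides[p].index]
            seq = state.peptides[p].sequence
            j, d = int(row["indel_pos"]), int(row["indel_len"])
            true_core = seq[:j] + seq[j + d:]
            got_core = TestPeptideMove._motif_columns(state, p)
            # a deletion reproducing the pre-insertion core is a hit, even
            # when the planted residue happens to match the consensus and
            # an equivalent skip position was chosen
            hits += (c.indel_kind == "deletion" and got_core == true_core)
        assert hits >= 0.9 * state.n_peptides


class TestPhaseShift:
    def _phased_state(self, offset_truth, seed=5, n=25):
        """All peptides carry the consensus at offset 1; members placed at
        `offset_truth` so the cluster is aligned (1) or off-phase (0/2)."""
        cfg = validate_config(Config(cluster_range=(1, 1), lam=0, sigma=0))
        rng = np.random.default_rng(seed)
        spec = consensus_motif("m", "WFDKYLEVR", 0.95)
        peps, _ = sample_peptides(spec, n, None, {1: 1.0}, rng)  # flanks of 1
        state = initialize_state(peps, 1, cfg, seed)
        for p in range(n):
            want = [i for i, c in enumerate(state.placements[p])
                    if c.offset == offset_truth][0]
            state.remove(p)
            state.add(p, 0, want)
        state.refresh_weights()
        return state

    def test_offphase_cluster_is_shifted_and_improves(self):
        state = self._phased_state(offset_truth=0)
        state.T = 1e-9
        before = [int(state.placement_i[p]) for p in range(state.n_peptides)]
        state.rng = StubRng(0.99, choice_value=1)   # propose +1 shift
        phase_shift_move(state, 0)
        assert state.tallies["phase_accept"] == 1
        offsets = [state.placements[p][state.placement_i[p]].offset
                   for p in range(state.n_peptides)]
        assert all(o == 1 for o in offsets)

    def test_aligned_cluster_rejects_the_shift_at_low_temperature(self):
        state = self._phased_state(offset_truth=1)
        state.T = 1e-9
        state.rng = StubRng(0.99, choice_value=1)
        phase_shift_move(state, 0)
        assert state.tallies["phase_reject"] == 1
        assert all(state.placements[p][state.placement_i[p]].offset == 1
                   for p in range(state.n_peptides))

    def test_impossible_shift_aborts_without_change(self):
        state = self._phased_state(offset_truth=0)
        state.rng = StubRng(0.5, choice_value=-1)   # nobody can shift to -1
        before = state.placement_i.copy()
        phase_shift_move(state, 0)
        assert state.tallies["phase_abort"] == 1
        assert (state.placement_i == before).all()


class TestTrash:
    def test_matching_trash_peptide_is_reinstated(self):
        cfg = validate_config(Config(cluster_range=(1, 1), lam=0, sigma=0,
                                     use_trash=True, trash_threshold=2.0))
        peps, _ = strong_cluster_peptides(n=20, seed=2)
        probe = Peptide(len(peps), "AWFDKYLEVRA")   # consensus at offset 1
        state = initialize_state(peps + [probe], 1, cfg, 0)
        # converge the model, then banish the probe
        sol = None
        for _ in range(2):
            for p in range(state.n_peptides):
                state.T = 1e-6
                peptide_move(state, p)
        probe_i = state.n_peptides - 1
        state.remove(probe_i)
        state.set_trash(probe_i)
        trash_resample(state, cfg)
        assert state.group[probe_i] == 0
        assert state.scores[probe_i] >= 2.0

    def test_low_scoring_peptide_stays_in_trash(self, rng):
        cfg = validate_config(Config(cluster_range=(1, 1), lam=0, sigma=0,
                                     use_trash=True, trash_threshold=2.0))
        peps, _ = strong_cluster_peptides(n=20, seed=2)
        junk = Peptide(len(peps), random_peptide(rng, 9))
        state = initialize_state(peps + [junk], 1, cfg, 0)
        for _ in range(2):
            state.T = 1e-6
            for p in range(state.n_peptides):
                peptide_move(state, p)
        junk_i = state.n_peptides - 1
        assert state.group[junk_i] == TRASH

    def test_trash_disabled_means_no_peptide_is_ever_trashed(self, rng):
        cfg = validate_config(Config(cluster_range=(2, 2)))
        peps = [Peptide(i, random_peptide(rng, 9)) for i in range(40)]
        sol = anneal(initialize_state(peps, 2, cfg, 1))
        assert all(not a.in_trash for a in sol.assignments)


class TestAnneal:
    def test_temperature_ladder_is_geometric(self):
        cfg = validate_config(Config(T_initial=1.5, num_T_steps=4, T_final=1e-4))
        T = temperature_ladder(cfg)
        assert T[0] == pytest.approx(1.5) and T[-1] == pytest.approx(1e-4)
        ratios = T[1:] / T[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_noop_schedule_preserves_the_initial_state(self, rng, flat_config):
        cfg = replace(flat_config, num_T_steps=1, iterations_per_T=0)
        peps = [Peptide(i, random_peptide(rng, 10)) for i in range(15)]
        state = initialize_state(peps, 2, cfg, 7)
        state.refresh_weights()
        kld0, _ = system_kld(state, cfg)
        sol = anneal(state, cfg)
        assert sol.kld_total == pytest.approx(kld0, abs=1e-12)

    def test_fixed_seed_gives_bit_identical_solutions(self, rng):
        cfg = validate_config(Config(cluster_range=(2, 2), num_T_steps=5))
        peps = [Peptide(i, random_peptide(rng, 10)) for i in range(30)]
        sols = [anneal(initialize_state(peps, 2, cfg, 11)) for _ in range(2)]
        a, b = sols
        assert a.kld_total == b.kld_total
        assert [(x.group, x.placement, x.score) for x in a.assignments] == \
               [(x.group, x.placement, x.score) for x in b.assignments]

    def test_annealing_improves_the_kld(self):
        from pepgibbs.synthetic import canonical_benchmark
        peps, _ = canonical_benchmark(1)
        peps = peps[:120]
        cfg = validate_config(Config(cluster_range=(3, 3)))
        better = 0
        for seed in range(3):
            state = initialize_state(peps, 3, cfg, seed)
            state.refresh_weights()
            kld0, _ = system_kld(state, cfg)
            sol = anneal(state, cfg)
            better += sol.kld_total > kld0
        assert better == 3

    def test_solution_kld_reproduces_from_frozen_members(self):
        peps, _ = strong_cluster_peptides(n=25, seed=6)
        cfg = validate_config(Config(cluster_range=(2, 2)))
        sol = anneal(initialize_state(peps, 2, cfg, 3))
        from pepgibbs import build_cluster_model
        from pepgibbs.scoring import kld_of_frequencies
        by_index = {p.index: p for p in sol.peptides}
        for g, model in sol.models.items():
            cores = [(by_index[a.peptide_index], a.placement)
                     for a in model.members]
            rebuilt = build_cluster_model(cores, cfg)
            expect = (len(cores) / len(sol.peptides)) * kld_of_frequencies(
                rebuilt.freq.values, FLAT_BACKGROUND)
            assert sol.kld_per_cluster[g] == pytest.approx(expect, abs=1e-9)

    def test_debug_mode_consistency_holds_through_an_anneal(self):
        from pepgibbs.synthetic import canonical_benchmark
        peps, _ = canonical_benchmark(5)
        cfg = validate_config(Config(cluster_range=(3, 3), debug_checks=True,
                                     use_trash=True,
                                     max_insertion_length=1,
                                     max_deletion_length=1))
        anneal(initialize_state(peps[:80], 3, cfg, 1))   # raises on divergence


class TestRunScan:
    def test_single_cell_scan_wraps_one_solution(self, rng):
        cfg = Config(cluster_range=(1, 1), num_seeds=1, num_T_steps=3)
        peps = [Peptide(i, random_peptide(rng, 10)) for i in range(12)]
        scan = run_scan(peps, cfg)
        assert set(scan.solutions) == {(1, 0)}
        assert scan.suggested_g == 1

    def test_result_is_independent_of_worker_count(self, rng):
        cfg = Config(cluster_range=(1, 2), num_seeds=2, num_T_steps=4,
                     rng_seed=17)
        peps = [Peptide(i, random_peptide(rng, 9)) for i in range(40)]
        s1 = run_scan(peps, cfg, n_jobs=1)
        s2 = run_scan(peps, cfg, n_jobs=2)
        assert s1.suggested_g == s2.suggested_g
        for k in s1.solutions:
            assert s1.solutions[k].kld_total == s2.solutions[k].kld_total
            assert [(a.group, a.placement) for a in s1.solutions[k].assignments] \
                == [(a.group, a.placement) for a in s2.solutions[k].assignments]

    def test_empty_input_raises(self, flat_config):
        with pytest.raises(ValueError):
            run_scan([], Config())
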