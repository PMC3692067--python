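"""Metropolis kernel, constraints, trajectories and decoy pooling."""
import math

import numpy as np
import pytest

from profdesign._data import AA_ALPHABET, AA_INDEX, BACKGROUND
from profdesign.energy import DesignConfig, EnergyBaseline
from profdesign.features import PropensityPredictor, ScaffoldEchoPredictor
from profdesign.mcsearch import (
    DesignConstraints,
    DesignEngine,
    metropolis_accept,
    pool_decoys,
    random_start,
    run_design,
    trajectory_rng,
)
from profdesign.profile import Profile
from profdesign.structio import ScaffoldFeatures


def make_engine(profile, feats, config, scaffold_seq, predictor=None,
                **kw):
    predictor = predictor or PropensityPredictor(15)
    return DesignEngine(profile, feats, predictor, config, scaffold_seq, **kw)


def toy_profile(log_odds):
    log_odds = np.asarray(log_odds, dtype=float)
    return Profile(log_odds=log_odds, counts=np.exp(log_odds) * BACKGROUND,
                   background=BACKGROUND, n_homologs=1,
                   tm_threshold_used=0.7)


def toy_feats(length):
    rng = np.random.default_rng(0)
    phi = np.full(length, -62.0)
    psi = np.full(length, -41.0)
    phi[0] = np.nan
    psi[-1] = np.nan
    return ScaffoldFeatures(ss="H" * length, phi=phi, psi=psi,
                            rsa=rng.uniform(0.2, 0.8, length))


class TestMetropolisRule:
    def test_zero_delta_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(0.0, 0.03, rng) for _ in range(100))

    def test_acceptance_frequency_matches_boltzmann_factor(self):
        """dZ = T -> empirical acceptance within +-0.01 of exp(-1)."""
        rng = np.random.default_rng(123)
        n = 100_000
        acc = sum(metropolis_accept(0.03, 0.03, rng) for _ in range(n))
        assert abs(acc / n - math.exp(-1.0)) < 0.01


class TestRandomStart:
    def test_all_frozen_returns_scaffold(self):
        c = DesignConstraints(frozen=set(range(10)))
        rng = np.random.default_rng(0)
        assert random_start(10, c, "ACDEFGHIKL", rng) == "ACDEFGHIKL"

    def test_different_seeds_differ(self):
        c = DesignConstraints()
        s1 = random_start(50, c, "A" * 50, np.random.default_rng(1))
        s2 = random_start(50, c, "A" * 50, np.random.default_rng(2))
        assert s1 != s2

    def test_single_allowed_residue_is_forced(self):
        c = DesignConstraints(excluded={3: set(AA_ALPHABET) - {"W"}})
        for seed in range(5):
            s = random_start(8, c, "A" * 8, np.random.default_rng(seed))
            assert s[3] == "W"

    def test_fully_excluded_position_rejected(self):
        c = DesignConstraints(excluded={0: set(AA_ALPHABET)})
        with pytest.raises(ValueError):
            c.validate(5)


@pytest.fixture(scope="module")
def family_engine_parts(request):
    scaffold, members, _ = request.getfixturevalue("family15")
    feats = request.getfixturevalue("helix40_feats")
    prof, _ = request.getfixturevalue("family_profile")
    return scaffold, feats, prof


class TestSweepAndTrajectories:
    def test_flat_landscape_accepts_everything(self):
        length = 12
        prof = toy_profile(np.zeros((length, 20)))
        feats = toy_feats(length)
        echo = ScaffoldEchoPredictor(feats)
        cfg = DesignConfig(n_traj=1, n_sweeps=50, burn_in=10, seed=0)
        base = EnergyBaseline(mean=0.0, std=1.0, n=2, seed=0)
        eng = make_engine(prof, feats, cfg, "A" * length, predictor=echo,
                          baseline=base)
        traj = eng.run_trajectory(np.random.default_rng(0))
        assert traj.acceptance_rate == 1.0

    def test_frozen_positions_constant_in_every_decoy(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        frozen = {0, 5, 17}
        cfg = DesignConfig(n_traj=2, n_sweeps=60, burn_in=10,
                           n_baseline=100, seed=4)
        trajs = run_design(prof, feats, PropensityPredictor(15), cfg,
                           scaffold.sequence,
                           DesignConstraints(frozen=frozen))
        for traj in trajs:
            for p in frozen:
                codes = set(traj.seq_idx[:, p].tolist())
                assert codes == {AA_INDEX[scaffold.sequence[p]]}

    def test_excluded_residues_never_sampled(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        excluded = {3: {"W", "C", "P"}, 11: {"A"}}
        cfg = DesignConfig(n_traj=1, n_sweeps=80, burn_in=10,
                           n_baseline=100, seed=5)
        trajs = run_design(prof, feats, PropensityPredictor(15), cfg,
                           scaffold.sequence,
                           DesignConstraints(excluded=excluded))
        for pos, banned in excluded.items():
            seen = {AA_ALPHABET[i] for i in trajs[0].seq_idx[:, pos]}
            assert not (seen & banned)

    def test_same_seed_reproduces_bit_identical_pools(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        cfg = DesignConfig(n_traj=2, n_sweeps=50, burn_in=5,
                           n_baseline=100, seed=9)
        t1 = run_design(prof, feats, PropensityPredictor(15), cfg,
                        scaffold.sequence)
        t2 = run_design(prof, feats, PropensityPredictor(15), cfg,
                        scaffold.sequence)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.seq_idx, b.seq_idx)
            np.testing.assert_array_equal(a.z, b.z)

    def test_trajectories_independent_of_execution_order(self, family_engine_parts):
        """Running only trajectory 1 reproduces the second trajectory of a
        serial two-trajectory run (parallelizable seeding contract)."""
        scaffold, feats, prof = family_engine_parts
        cfg = DesignConfig(n_traj=2, n_sweeps=40, burn_in=5,
                           n_baseline=100, seed=13)
        both = run_design(prof, feats, PropensityPredictor(15), cfg,
                          scaffold.sequence)
        # a fresh engine auto-calibrates the identical baseline (same seed)
        eng = make_engine(prof, feats, cfg, scaffold.sequence)
        alone = eng.run_trajectory(trajectory_rng(cfg.seed, 1), seed_label=1)
        np.testing.assert_array_equal(alone.seq_idx, both[1].seq_idx)

    def test_z_decreases_on_structured_landscape(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        cfg = DesignConfig(n_traj=2, n_sweeps=100, burn_in=10,
                           n_baseline=100, seed=2)
        trajs = run_design(prof, feats, PropensityPredictor(15), cfg,
                           scaffold.sequence)
        for traj in trajs:
            assert traj.z[-10:].mean() < traj.z[:10].mean()

    def test_hotter_chain_accepts_at_least_as_often(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        rates = {}
        for temp in (0.03, 0.3):
            cfg = DesignConfig(n_traj=1, n_sweeps=100, burn_in=10,
                               n_baseline=100, seed=21, temperature=temp)
            trajs = run_design(prof, feats, PropensityPredictor(15), cfg,
                               scaffold.sequence)
            rates[temp] = trajs[0].acceptance_rate
        assert rates[0.3] >= rates[0.03]

    def test_all_frozen_search_records_scaffold_every_sweep(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        cfg = DesignConfig(n_traj=1, n_sweeps=10, burn_in=1,
                           n_baseline=100, seed=0)
        eng = make_engine(prof, feats, cfg, scaffold.sequence,
                          constraints=DesignConstraints(
                              frozen=set(range(len(scaffold.sequence)))))
        traj = eng.run_trajectory(trajectory_rng(0, 0))
        assert set(traj.sequences()) == {scaffold.sequence}

    def test_compiled_and_generic_paths_agree(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        cfg = DesignConfig(n_traj=1, n_sweeps=60, burn_in=5,
                           n_baseline=100, seed=3)
        eng_fast = make_engine(prof, feats, cfg, scaffold.sequence)
        t_fast = eng_fast.run_trajectory(trajectory_rng(3, 0))
        eng_slow = make_engine(prof, feats, cfg, scaffold.sequence,
                               baseline=eng_fast.baseline)
        eng_slow._compiled = False
        t_slow = eng_slow.run_trajectory(trajectory_rng(3, 0))
        np.testing.assert_array_equal(t_fast.seq_idx, t_slow.seq_idx)
        np.testing.assert_allclose(t_fast.z, t_slow.z, atol=1e-9)

    def test_incremental_state_matches_full_recomputation(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        cfg = DesignConfig(n_traj=1, n_sweeps=100, burn_in=5,
                           n_baseline=100, seed=6)
        eng = make_engine(prof, feats, cfg, scaffold.sequence)
        eng.run_trajectory(trajectory_rng(6, 0))
        inc = eng._current_components()
        full = eng.components_of(eng.seq)
        assert inc.e_profile == pytest.approx(full.e_profile, abs=1e-9)
        assert inc.e_ss == pytest.approx(full.e_ss, abs=1e-9)
        assert inc.e_ta == pytest.approx(full.e_ta, abs=1e-9)
        assert inc.e_sa == pytest.approx(full.e_sa, abs=1e-9)


class TestPooling:
    def test_default_arithmetic_shape(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        cfg = DesignConfig(n_traj=3, n_sweeps=40, burn_in=10,
                           n_baseline=100, seed=1)
        trajs = run_design(prof, feats, PropensityPredictor(15), cfg,
                           scaffold.sequence)
        pool = pool_decoys(trajs, cfg.burn_in)
        assert len(pool) == 3 * (40 - 10)

    def test_zero_burn_in_keeps_everything(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        cfg = DesignConfig(n_traj=1, n_sweeps=10, burn_in=1,
                           n_baseline=100, seed=1)
        trajs = run_design(prof, feats, PropensityPredictor(15), cfg,
                           scaffold.sequence)
        assert len(pool_decoys(trajs, 0)) == 10
        assert len(pool_decoys(trajs, 9)) == 1

    def test_burn_in_beyond_sweeps_rejected(self, family_engine_parts):
        scaffold, feats, prof = family_engine_parts
        cfg = DesignConfig(n_traj=1, n_sweeps=10, burn_in=1,
                           n_baseline=100, seed=1)
        trajs = run_design(prof, feats, PropensityPredictor(15), cfg,
                           scaffold.sequence)
        with pytest.raises(ValueError):
            pool_decoys(trajs, 10)

    def test_archive_roundtrip(self, family_engine_parts, tmp_path):
        from profdesign.mcsearch import read_decoy_archive, write_decoy_archive
        scaffold, feats, prof = family_engine_parts
        cfg = DesignConfig(n_traj=1, n_sweeps=20, burn_in=5,
                           n_baseline=100, seed=1)
        trajs = run_design(prof, feats, PropensityPredictor(15), cfg,
                           scaffold.sequence)
        pool = pool_decoys(trajs, 5)
        p = tmp_path / "decoys.tsv.gz"
        write_decoy_archive(pool, p)
        back = read_decoy_archive(p)
        np.testing.assert_array_equal(back.seq_idx, pool.seq_idx)
        np.testing.assert_allclose(back.z, pool.z, atol=1e-6)


class TestBoltzmannEquilibrium:
    def test_four_state_toy_matches_partition_function(self):
        """2 positions x 2 allowed letters: long-run recorded-state
        frequencies vs brute-force Boltzmann weights exp(-Z/T)/sum."""
        length = 2
        rng_lo = np.random.default_rng(8)
        log_odds = np.zeros((length, 20))
        # give the two allowed letters (A, C) distinct scores per position
        log_odds[0, AA_INDEX["A"]], log_odds[0, AA_INDEX["C"]] = 0.8, 0.1
        log_odds[1, AA_INDEX["A"]], log_odds[1, AA_INDEX["C"]] = -0.3, 0.5
        prof = toy_profile(log_odds)
        feats = toy_feats(length)
        echo = ScaffoldEchoPredictor(feats)
        banned = set(AA_ALPHABET) - {"A", "C"}
        constraints = DesignConstraints(excluded={0: banned, 1: banned})
        cfg = DesignConfig(n_traj=1, n_sweeps=40_000, burn_in=500,
                           n_baseline=200, temperature=0.5, seed=77)
        eng = DesignEngine(prof, feats, echo, cfg, "AA", constraints)
        traj = eng.run_trajectory(trajectory_rng(cfg.seed, 0))
        states = ["".join(p) for p in
                  [("A", "A"), ("A", "C"), ("C", "A"), ("C", "C")]]
        z_of = {}
        for s in states:
            from profdesign._data import encode_sequence
            z_of[s] = eng.z_of(eng.components_of(encode_sequence(s)))
        weights = np.array([math.exp(-z_of[s] / cfg.temperature)
                            for s in states])
        expected = weights / weights.sum()
        recorded = traj.seq_idx[cfg.burn_in:]
        seqs = np.array(["".join(AA_ALPHABET[i] for i in row)
                         for row in recorded])
        for s, p_exp in zip(states, expected):
            ind = (seqs == s).astype(float)
            batches = np.array_split(ind, 20)
            means = np.array([b.mean() for b in batches])
            se = means.std(ddof=1) / math.sqrt(len(batches))
            assert abs(ind.mean() - p_exp) < 3 * se + 0.01
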