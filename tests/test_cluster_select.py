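"""BLOSUM62 distance, threshold-expansion clustering, NRE and reports."""
import numpy as np
import pytest

from profdesign._data import AA_ALPHABET, encode_sequence
from profdesign.cluster_select import (
    ClusterError,
    cluster_decoys,
    compute_nre,
    pairwise_distances,
    render_report_text,
    select_designs,
    seq_distance,
    sequence_identity_pct,
)
from profdesign.mcsearch import DecoyPool


def make_pool(seqs, z=None):
    idx = np.array([encode_sequence(s).astype(np.int8) for s in seqs])
    n = len(seqs)
    return DecoyPool(seq_idx=idx,
                     z=np.zeros(n) if z is None else np.asarray(z, float),
                     traj=np.zeros(n, dtype=int),
                     sweep=np.arange(n))


class TestSeqDistance:
    def test_identity_is_zero(self):
        for s in ("A", "ACDEFGHIKLMNPQRSTVWY", "WWWW"):
            assert seq_distance(s, s) == 0.0

    def test_single_pair_value_from_substitution_scores(self):
        # B(A,A)=4, B(W,W)=11, B(A,W)=-3 -> (4+11+6)/2 = 10.5
        assert seq_distance("A", "W") == pytest.approx(10.5)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = "".join(rng.choice(list(AA_ALPHABET), 15))
            b = "".join(rng.choice(list(AA_ALPHABET), 15))
            assert seq_distance(a, b) == pytest.approx(seq_distance(b, a))
            assert seq_distance(a, b) >= 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClusterError):
            seq_distance("AA", "AAA")

    def test_matrix_matches_scalar_on_random_sequences(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list(AA_ALPHABET), 9)) for _ in range(30)]
        mat = pairwise_distances(
            np.array([encode_sequence(s) for s in seqs]))
        for i in (0, 7, 29):
            for j in (3, 11):
                assert mat[i, j] == pytest.approx(
                    seq_distance(seqs[i], seqs[j]), abs=1e-5)


def brute_force_primary(seqs, threshold):
    """O(n^2) neighbour-count oracle: the primary cluster is the ball of
    the decoy with most neighbours (ties: lowest index)."""
    n = len(seqs)
    counts = []
    for i in range(n):
        counts.append(sum(seq_distance(seqs[i], seqs[j]) <= threshold + 1e-9
                          for j in range(n)))
    center = int(np.argmax(counts))
    return {j for j in range(n)
            if seq_distance(seqs[center], seqs[j]) <= threshold + 1e-9}


class TestClustering:
    def test_identical_pool_is_one_cluster_at_zero(self):
        pool = make_pool(["ACDKW"] * 25)
        clusters, idx = cluster_decoys(pool)
        assert len(clusters) == 1
        assert clusters[0].size == 25
        assert clusters[0].threshold_at_stop == 0.0

    def test_two_family_pool_primary_is_majority(self):
        pool = make_pool(["AAAAA"] * 60 + ["WWWWW"] * 40)
        clusters, _ = cluster_decoys(pool)
        assert clusters[0].size == 60
        assert clusters[1].size == 40
        assert pool.sequence(clusters[0].seed_index) == "AAAAA"

    def test_three_family_membership_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        bases = ["AAAAAAAAAA", "WWWWWWWWWW", "CCCCCCCCCC"]
        seqs = []
        for base, n in zip(bases, (70, 50, 30)):
            for _ in range(n):
                s = list(base)
                for k in range(len(s)):
                    if rng.random() < 0.15:
                        s[k] = AA_ALPHABET[rng.integers(20)]
                seqs.append("".join(s))
        pool = make_pool(seqs)
        clusters, _ = cluster_decoys(pool, cluster_frac=0.4)
        t = clusters[0].threshold_at_stop
        expected = brute_force_primary(seqs, t)
        assert set(clusters[0].members.tolist()) == expected

    def test_primary_reaches_requested_fraction(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list(AA_ALPHABET), 8)) for _ in range(120)]
        pool = make_pool(seqs)
        clusters, idx = cluster_decoys(pool, cluster_frac=0.4)
        assert clusters[0].size >= 0.4 * len(idx)

    def test_clusters_disjoint_and_bounded(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list(AA_ALPHABET), 6)) for _ in range(200)]
        pool = make_pool(seqs)
        clusters, _ = cluster_decoys(pool, cluster_frac=0.3)
        all_members = np.concatenate([c.members for c in clusters])
        assert len(all_members) == len(set(all_members.tolist()))
        assert len(all_members) <= len(pool)
        assert len(clusters) <= 10

    def test_pool_order_does_not_change_cluster_sizes(self):
        rng = np.random.default_rng(8)
        seqs = (["AAAAA"] * 40 + ["WWWWW"] * 30
                + ["".join(rng.choice(list(AA_ALPHABET), 5))
                   for _ in range(30)])
        z = rng.normal(size=len(seqs))
        pool = make_pool(seqs, z)
        perm = rng.permutation(len(seqs))
        pool2 = DecoyPool(seq_idx=pool.seq_idx[perm], z=pool.z[perm],
                          traj=pool.traj[perm], sweep=pool.sweep[perm])
        c1, _ = cluster_decoys(pool)
        c2, _ = cluster_decoys(pool2)
        assert [c.size for c in c1] == [c.size for c in c2]
        # the two well-separated families are uniquely determined, so their
        # (Z, sequence)-stabilized representatives must also agree
        assert [pool.sequence(c.seed_index) for c in c1[:2]] == \
            [pool2.sequence(c.seed_index) for c in c2[:2]]

    def test_empty_pool_rejected(self):
        pool = make_pool(["AA"])
        pool.seq_idx = pool.seq_idx[:0]
        pool.z = pool.z[:0]
        with pytest.raises(ClusterError):
            cluster_decoys(pool)


class TestSelectDesigns:
    def test_single_cluster_single_report(self):
        pool = make_pool(["AAAA"] * 10)
        clusters, _ = cluster_decoys(pool)
        reports = select_designs(clusters, pool, "AAAA")
        assert len(reports) == 1
        assert reports[0].rank == 1
        assert reports[0].identity_pct == 100.0

    def test_at_most_ten_reports(self):
        seqs = []
        for k in range(12):
            seqs.extend([AA_ALPHABET[k] * 4] * (30 - 2 * k))
        pool = make_pool(seqs)
        clusters, _ = cluster_decoys(pool, cluster_frac=0.05)
        assert len(clusters) <= 10
        reports = select_designs(clusters, pool, "AAAA")
        assert len(reports) <= 10

    def test_rank_follows_cluster_size(self):
        pool = make_pool(["AAAA"] * 50 + ["WWWW"] * 30)
        clusters, _ = cluster_decoys(pool)
        reports = select_designs(clusters, pool, "AAAA")
        assert [r.rank for r in reports] == [1, 2]
        assert reports[0].cluster_size >= reports[1].cluster_size

    def test_seed_is_lowest_z_member(self):
        z = np.concatenate([np.linspace(1, 2, 50), np.linspace(-1, 0, 30)])
        pool = make_pool(["AAAA"] * 50 + ["WWWW"] * 30, z)
        clusters, _ = cluster_decoys(pool)
        reports = select_designs(clusters, pool, "AAAA")
        assert reports[0].design_score == pytest.approx(1.0)
        assert reports[1].design_score == pytest.approx(-1.0)


class TestNre:
    def test_design_equal_scaffold_gives_zero(self, helix40, helix40_feats,
                                              propensity):
        nre = compute_nre(helix40.sequence, helix40.sequence,
                          helix40_feats, propensity)
        for v in nre:
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_doubled_error_gives_one(self):
        # direct check of the (EDS - ETS)/ETS identity
        eds, ets = 0.4, 0.2
        assert (eds - ets) / ets == pytest.approx(1.0)

    def test_better_predicting_design_is_negative(self, helix40,
                                                  helix40_feats, propensity):
        """A design made of strong helix formers should match the helical
        scaffold assignment better than the native mixed sequence."""
        design = "".join(
            "A" if c == "H" else s
            for s, c in zip(helix40.sequence, helix40_feats.ss))
        nre = compute_nre(design, helix40.sequence, helix40_feats, propensity)
        assert nre[0] is None or nre[0] <= 0.0

    def test_undefined_when_scaffold_error_zero(self, helix40_feats):
        from profdesign.features import ScaffoldEchoPredictor
        echo = ScaffoldEchoPredictor(helix40_feats)
        nre = compute_nre("A" * 40, "C" * 40, helix40_feats, echo)
        assert nre == (None, None, None, None)

    def test_length_mismatch_rejected(self, helix40_feats, propensity):
        with pytest.raises(ClusterError):
            compute_nre("AAA", "AAAA", helix40_feats, propensity)


class TestRendering:
    def test_report_text_carries_identity_marks(self, helix40, helix40_feats,
                                                propensity):
        pool = make_pool([helix40.sequence] * 5)
        clusters, _ = cluster_decoys(pool)
        reports = select_designs(clusters, pool, helix40.sequence,
                                 helix40_feats, propensity, helix40)
        text = render_report_text(reports[0], helix40.sequence, helix40_feats)
        assert "|" * len(helix40) in text
        assert helix40.sequence in text
        assert helix40_feats.ss in text

    def test_identity_percentage(self):
        assert sequence_identity_pct("AAAA", "AAAW") == pytest.approx(75.0)
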