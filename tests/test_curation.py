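import itertools

import numpy as np
import pytest

from httrace.align import full_identity, global_identity
from httrace.curation import (MultipleAlignment, SEATParams, consensus_call,
                              msa, seat_iterate, split_subfamilies,
                              trim_flanks)
from httrace.synthetic_data import TEFamilySpec, insert_copies, random_dna
from tests.conftest import mutated, rand_dna


def sp_cost(rows: list[str]) -> int:
    """Unit sum-of-pairs cost of an alignment (mismatch 1, gap 1,
    double-gap 0)."""
    cost = 0
    for a, b in itertools.combinations(rows, 2):
        for x, y in zip(a, b):
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-" or x != y:
                cost += 1
    return cost


def optimal_3way_cost(s1: str, s2: str, s3: str) -> int:
    """Exhaustive 3D DP for the minimal unit SP cost of a 3-sequence
    alignment — the oracle the center-star heuristic is checked against."""
    n1, n2, n3 = len(s1), len(s2), len(s3)
    INF = 10 ** 9
    D = np.full((n1 + 1, n2 + 1, n3 + 1), INF, dtype=np.int64)
    D[0, 0, 0] = 0

    def col_cost(a, b, c):
        cost = 0
        for x, y in ((a, b), (a, c), (b, c)):
            if x is None and y is None:
                continue
            if x is None or y is None or x != y:
                cost += 1
        return cost

    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                base = D[i, j, k]
                if base == INF:
                    continue
                c1 = s1[i] if i < n1 else None
                c2 = s2[j] if j < n2 else None
                c3 = s3[k] if k < n3 else None
                for di in (0, 1):
                    for dj in (0, 1):
                        for dk in (0, 1):
                            if di + dj + dk == 0:
                                continue
                            if (di and c1 is None) or (dj and c2 is None) \
                                    or (dk and c3 is None):
                                continue
                            cc = col_cost(c1 if di else None,
                                          c2 if dj else None,
                                          c3 if dk else None)
                            t = base + cc
                            if t < D[i + di, j + dj, k + dk]:
                                D[i + di, j + dj, k + dk] = t
    return int(D[n1, n2, n3])


class TestMSA:
    def test_identical_sequences_gapless(self):
        ali = msa(["ACGTACGT"] * 4)
        assert all("-" not in r for r in ali.rows)

    def test_removing_gaps_recovers_inputs(self, rng):
        core = rand_dna(rng, 120)
        seqs = [rand_dna(rng, rng.randint(0, 20)) + mutated(rng, core, 0.05)
                + rand_dna(rng, rng.randint(0, 20)) for _ in range(6)]
        ali = msa(seqs)
        assert [ali.ungapped(i) for i in range(6)] == seqs

    def test_order_invariant_consensus(self, rng):
        core = rand_dna(rng, 150)
        seqs = [mutated(rng, core, 0.04) for _ in range(8)]
        c1 = consensus_call(msa(seqs))
        perm = list(reversed(seqs))
        c2 = consensus_call(msa(perm))
        assert c1 == c2

    def test_center_star_within_2_approximation(self, rng):
        base = rand_dna(rng, 30)
        s1 = mutated(rng, base, 0.1)
        s2 = mutated(rng, base, 0.1)[:-3]
        s3 = rand_dna(rng, 4) + mutated(rng, base, 0.1)
        opt = optimal_3way_cost(s1, s2, s3)
        cs = sp_cost(msa([s1, s2, s3]).rows)
        assert opt <= cs <= 2 * opt

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            msa(["ACGT"])


class TestTrimFlanks:
    def test_unique_flanks_removed_core_kept(self, rng):
        core = rand_dna(rng, 200)
        rows = [rand_dna(rng, 60) + mutated(rng, core, 0.05)
                + rand_dna(rng, 60) for _ in range(25)]
        ali = trim_flanks(msa(rows), SEATParams())
        cons = consensus_call(ali)
        assert abs(len(cons) - 200) <= 20
        assert global_identity(cons, core) > 95.0

    def test_fully_occupied_conserved_unchanged(self):
        ali = MultipleAlignment(["a", "b", "c"], ["ACGTACGTACGTACGT"] * 3)
        out = trim_flanks(ali, SEATParams())
        assert out.n_cols == ali.n_cols

    def test_occupancy_exactly_at_threshold_retained(self):
        # 2 rows, occupancy 0.5 == default floor (inclusive), agreement 1
        row = "ACGTACGTACGT"
        ali = MultipleAlignment(["a", "b"], [row, "-" * len(row)])
        out = trim_flanks(ali, SEATParams())
        assert out.n_cols == len(row)

    def test_no_homologous_core_raises(self, rng):
        rows = [rand_dna(rng, 80) for _ in range(6)]
        # random rows gapless-aligned: agreement stays low everywhere
        ali = MultipleAlignment([f"r{i}" for i in range(6)], rows)
        with pytest.raises(ValueError, match="no homologous core"):
            trim_flanks(ali, SEATParams())


class TestSplitSubfamilies:
    def _rows(self, rng, centers, sizes, d=0.01):
        rows = []
        for c, n in zip(centers, sizes):
            rows.extend(mutated(rng, c, d) for _ in range(n))
        return msa(rows)

    def test_three_clusters_three_subfamilies(self, rng):
        a = rand_dna(rng, 400)
        b = mutated(rng, a, 0.25)
        c = mutated(rng, a, 0.35)
        ali = self._rows(rng, [a, b, c], [2, 2, 1])
        subs = split_subfamilies(ali)
        assert [s[0] for s in subs] == ["H1", "H2", "H3"]
        assert [s[1].n_rows for s in subs] == [2, 2, 1]

    def test_attach_singletons_option(self, rng):
        a = rand_dna(rng, 400)
        b = mutated(rng, a, 0.25)
        c = mutated(rng, a, 0.35)
        ali = self._rows(rng, [a, b, c], [2, 2, 1])
        subs = split_subfamilies(ali, attach_singletons=True)
        assert len(subs) == 2
        assert sorted(s[1].n_rows for s in subs) == [2, 3]

    def test_homogeneous_rows_single_subfamily(self, rng):
        a = rand_dna(rng, 400)
        ali = self._rows(rng, [a], [6], d=0.002)
        assert len(split_subfamilies(ali)) == 1

    def test_ninety_percent_clusters_split(self, rng):
        a = rand_dna(rng, 500)
        b = mutated(rng, a, 0.11)  # ~90% pairwise identity between groups
        ali = self._rows(rng, [a, b], [3, 3], d=0.005)
        assert len(split_subfamilies(ali, cut_identity=94.0)) == 2


class TestSeatIterate:
    def test_top_25_of_30_hits_used(self, rng):
        np_rng = np.random.default_rng(101)
        fam = random_dna(1200, np_rng)
        spec = TEFamilySpec(name="fam", length=1200, consensus=fam,
                            truncation_p=0.0, divergence_d=0.02,
                            copy_number_per_genome=30,
                            guarantee_full_length=False)
        g, _ = insert_copies(random_dna(80_000, np_rng), spec, 30, np_rng)
        cur = seat_iterate(("fam", fam), {"chr": g},
                           SEATParams(max_iter=2))
        assert cur.n_copies_used == 25

    def test_single_copy_returned_verbatim(self):
        np_rng = np.random.default_rng(102)
        fam = random_dna(1500, np_rng)
        spec = TEFamilySpec(name="fam", length=1500, consensus=fam,
                            truncation_p=0.0, copy_number_per_genome=1)
        g, _ = insert_copies(random_dna(12_000, np_rng), spec, 1, np_rng)
        cur = seat_iterate(("fam", fam), {"chr": g}, SEATParams())
        assert cur.single_copy
        assert cur.seq == fam

    def test_absent_family_raises(self):
        np_rng = np.random.default_rng(103)
        fam = random_dna(1200, np_rng)
        with pytest.raises(ValueError, match="not present"):
            seat_iterate(("fam", fam), {"chr": random_dna(20_000, np_rng)},
                         SEATParams())

    def test_consensus_recovery_from_partial_seed(self):
        """Seeding with a 3' fragment recovers the full ancestral
        sequence to >= 98% identity and within 2% of its length."""
        np_rng = np.random.default_rng(104)
        truth = random_dna(2000, np_rng)
        spec = TEFamilySpec(name="fam", length=2000, consensus=truth,
                            truncation_p=0.4, divergence_d=0.05,
                            copy_number_per_genome=25)
        g, _ = insert_copies(random_dna(140_000, np_rng), spec, 25, np_rng)
        cur = seat_iterate(("fam", truth[800:]), {"chr": g}, SEATParams())
        assert global_identity(cur.seq, truth) >= 98.0
        assert abs(len(cur.seq) - 2000) <= 0.02 * 2000

    def test_identity_trace_non_decreasing(self):
        for seed in (201, 202, 203):
            np_rng = np.random.default_rng(seed)
            truth = random_dna(1200, np_rng)
            spec = TEFamilySpec(name="fam", length=1200, consensus=truth,
                                truncation_p=0.5, divergence_d=0.05,
                                copy_number_per_genome=15)
            g, _ = insert_copies(random_dna(60_000, np_rng), spec, 15,
                                 np_rng)
            cur = seat_iterate(("fam", truth[500:]), {"chr": g},
                               SEATParams(min_hit_len=600))
            trace = cur.per_iteration_identity
            assert trace == sorted(trace), f"seed {seed}: {trace}"
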