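import itertools

import numpy as np
import pytest

from httrace.curation import MultipleAlignment, msa
from httrace.discordance import (block_trim, discordance_stat, filter_intact,
                                 nj_from_matrix, nj_tree, normalized_rf)
from httrace.synthetic_data import mutate_sequence, random_dna
from httrace.te_classify import DomainHit


class TestFilterIntact:
    HITS = [DomainHit("s1", "EN", 0.85), DomainHit("s1", "RT", 0.90),
            DomainHit("s2", "EN", 0.85), DomainHit("s2", "RT", 0.70)]

    def test_both_domains_kept(self):
        kept = filter_intact({"s1": "ACGT", "s2": "ACGT"}, self.HITS)
        assert set(kept) == {"s1"}

    def test_partial_rt_removed(self):
        kept = filter_intact({"s1": "ACGT", "s2": "ACGT"}, self.HITS)
        assert "s2" not in kept

    def test_empty_result_raises(self):
        with pytest.raises(ValueError, match="no intact"):
            filter_intact({"s2": "ACGT"}, self.HITS)


class TestBlockTrim:
    def test_gapless_unchanged(self):
        ali = MultipleAlignment(list("abcd"), ["ACGTACGT"] * 4)
        assert block_trim(ali).n_cols == 8

    def test_isolated_column_dropped(self):
        # kept columns must come in runs of >= 5
        rows = ["AAAAA" + "-" * 6 + "C" + "-" * 6 + "GGGGG"] * 4
        ali = MultipleAlignment(list("abcd"), rows)
        out = block_trim(ali)
        assert out.n_cols == 10  # the lone C column is gone

    def test_center_deleted_block_recovers_flanks(self):
        rng = np.random.default_rng(1)
        left, right = random_dna(40, rng), random_dna(40, rng)
        mid = random_dna(30, rng)
        rows = []
        for i in range(10):
            if i < 6:  # 60% of rows lack the center block
                rows.append(left + "-" * 30 + right)
            else:
                rows.append(left + mid + right)
        ali = MultipleAlignment([f"r{i}" for i in range(10)], rows)
        out = block_trim(ali)
        assert out.n_cols == 80

    def test_needs_four_rows(self):
        with pytest.raises(ValueError):
            block_trim(MultipleAlignment(["a", "b"], ["ACGT", "ACGT"]))


def _five_taxon_matrix(pairs):
    """Additive distances for the unrooted topology with cherries
    ``pairs[0]`` and ``pairs[1]`` plus one outlying tip."""
    taxa = sorted(t for p in pairs for t in p) + []
    all_taxa = set("ABCDE")
    lone = (all_taxa - set(taxa)).pop()
    ids = sorted(all_taxa)
    n = len(ids)
    mat = np.zeros((n, n))

    def d(x, y):
        if x == y:
            return 0.0
        if {x, y} in (set(p) for p in pairs):
            return 2.0
        if lone in (x, y):
            return 6.0
        return 6.0 + 2.0  # across the two cherries

    for i, x in enumerate(ids):
        for j, y in enumerate(ids):
            mat[i, j] = d(x, y)
    return ids, mat, lone


class TestNJ:
    def test_recovers_topology_from_sequences(self):
        rng = np.random.default_rng(2)
        anc = random_dna(800, rng)
        ab = mutate_sequence(anc, 0.12, rng)
        cd = mutate_sequence(anc, 0.12, rng)
        seqs = {"A": mutate_sequence(ab, 0.02, rng),
                "B": mutate_sequence(ab, 0.02, rng),
                "C": mutate_sequence(cd, 0.02, rng),
                "D": mutate_sequence(cd, 0.02, rng),
                "E": mutate_sequence(anc, 0.25, rng)}
        ali = msa(list(seqs.values()), list(seqs))
        nwk = nj_tree(ali)
        assert normalized_rf(nwk, "((A,B),(C,D),E);") == 0.0

    def test_input_order_invariant(self):
        rng = np.random.default_rng(3)
        anc = random_dna(500, rng)
        seqs = {t: mutate_sequence(anc, 0.05 * (i + 1), rng)
                for i, t in enumerate("ABCDE")}
        a1 = msa(list(seqs.values()), list(seqs))
        rev = dict(reversed(list(seqs.items())))
        a2 = msa(list(rev.values()), list(rev))
        assert normalized_rf(nj_tree(a1), nj_tree(a2)) == 0.0

    def test_exhaustive_five_taxon_additive_recovery(self):
        """NJ recovers the generating topology from exact additive
        distances for all 15 labeled 5-taxon topologies."""
        seen = set()
        for pair1 in itertools.combinations("ABCDE", 2):
            rest = [t for t in "ABCDE" if t not in pair1]
            for pair2 in itertools.combinations(rest, 2):
                key = frozenset([frozenset(pair1), frozenset(pair2)])
                if key in seen:
                    continue
                seen.add(key)
                ids, mat, lone = _five_taxon_matrix([pair1, pair2])
                nwk = nj_from_matrix(ids, mat)
                truth = (f"(({pair1[0]},{pair1[1]}),"
                         f"({pair2[0]},{pair2[1]}),{lone});")
                assert normalized_rf(nwk, truth) == 0.0, key
        assert len(seen) == 15

    def test_needs_four_rows(self):
        with pytest.raises(ValueError):
            nj_tree(MultipleAlignment(["a", "b", "c"], ["ACG"] * 3))


class TestDiscordance:
    def test_congruent_trees_rf_zero(self):
        te = "((A_te:1,B_te:1):1,((C_te:1,D_te:1):1,E_te:2):1);"
        sp = "((A,B),((C,D),E));"
        hosts = {f"{t}_te": t for t in "ABCDE"}
        rf, _ = discordance_stat(te, sp, hosts)
        assert rf == 0.0

    def test_four_taxon_nni_maximal_rf(self):
        assert normalized_rf("((A,B),(C,D));", "((A,C),(B,D));") == 1.0

    def test_rf_symmetry(self):
        a = "((A,B),(C,D),E);"
        b = "((A,C),(B,D),E);"
        assert normalized_rf(a, b) == normalized_rf(b, a)

    def test_htt_tip_clusters_with_donor_lineage(self):
        """A snake TE nesting among fish TEs: nearest neighbor is the
        fish element, not the snake's vertical TE, and the induced host
        topology is discordant with the species tree."""
        te = ("((snakeHTT:0.1,fishA_te:0.1):0.5,"
              "((snakeVert:0.1,lizard_te:0.1):0.3,"
              "(bird_te:0.1,fishB_te:0.4):0.3):0.5);")
        hosts = {"snakeHTT": "snake", "snakeVert": "snake",
                 "fishA_te": "fishA", "fishB_te": "fishB",
                 "lizard_te": "lizard", "bird_te": "bird"}
        sp = "(((snake,lizard),bird),(fishA,fishB));"
        rf, nn = discordance_stat(te, sp, hosts,
                                  focal_tips=["snakeHTT"])
        assert nn["snakeHTT"] == "fishA"
        assert rf > 0.0

    def test_unmapped_tip_rejected(self):
        with pytest.raises(ValueError, match="without a host"):
            discordance_stat("((a:1,b:1):1,(c:1,d:1):1);", "((a,b),(c,d));",
                             {"a": "a"})
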