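import math

import numpy as np
import pytest

from httrace.align import global_identity
from httrace.synthetic_data import (HostParams, TEFamilySpec, insert_copies,
                                    make_te_library, mutate_sequence,
                                    random_dna, simulate_panel)


class TestLibrary:
    def test_seeded_determinism(self):
        a = make_te_library(1, seed=7, length=1000)
        b = make_te_library(1, seed=7, length=1000)
        assert a[0].seq == b[0].seq

    def test_pairwise_dissimilarity(self):
        lib = make_te_library(2, seed=1, length=1000)
        assert global_identity(lib[0].seq, lib[1].seq) < 60.0

    def test_short_length_rejected(self):
        with pytest.raises(ValueError, match="800"):
            make_te_library(1, seed=0, length=500)

    def test_domain_markers_present(self):
        lib = make_te_library(1, seed=2, length=1200)
        names = {h.domain_name for h in lib[0].domain_hits}
        assert {"EN", "RT"} <= names


class TestMutate:
    def test_d_zero_identity(self):
        s = "ACGT" * 100
        assert mutate_sequence(s, 0.0, 1) == s

    def test_jc_expected_fraction(self):
        rng = np.random.default_rng(5)
        s = random_dna(100_000, rng)
        d = 0.05
        out = mutate_sequence(s, d, rng)
        p = 0.75 * (1 - math.exp(-4 * d / 3))
        obs = sum(a != b for a, b in zip(s, out)) / len(s)
        sd = math.sqrt(p * (1 - p) / len(s))
        assert abs(obs - p) < 3 * sd

    def test_saturation_limit(self):
        rng = np.random.default_rng(6)
        s = random_dna(50_000, rng)
        out = mutate_sequence(s, 50.0, rng)
        obs = sum(a != b for a, b in zip(s, out)) / len(s)
        assert obs == pytest.approx(0.75, abs=0.01)

    def test_negative_d_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", -0.1, 0)

    def test_composition_is_additive(self):
        """Two JC steps of d/2 give the same expected difference as one
        step of d (Markov composition)."""
        rng = np.random.default_rng(7)
        s = random_dna(100_000, rng)
        two = mutate_sequence(mutate_sequence(s, 0.05, rng), 0.05, rng)
        p = 0.75 * (1 - math.exp(-4 * 0.10 / 3))
        obs = sum(a != b for a, b in zip(s, two)) / len(s)
        assert abs(obs - p) < 4 * math.sqrt(p * (1 - p) / len(s))


def _spec(**kw):
    base = dict(name="fam", length=1000, copy_number_per_genome=5,
                truncation_p=0.5, guarantee_full_length=False)
    base.update(kw)
    return TEFamilySpec(**base)


class TestInsertCopies:
    def test_no_truncation(self):
        rng = np.random.default_rng(1)
        fam = _spec(consensus=random_dna(1000, rng), truncation_p=0.0)
        g, recs = insert_copies(random_dna(20_000, rng), fam, 5, rng)
        assert all(r.truncation_fraction == 1.0 for r in recs)
        assert all(r.end - r.start == 1000 for r in recs)

    def test_truncation_mean_retained_fraction(self):
        # Uniform(0.05, 1) mean = 0.525; 200 copies, seeded MC check
        rng = np.random.default_rng(2)
        fam = _spec(consensus=random_dna(1000, rng), truncation_p=1.0)
        g, recs = insert_copies(random_dna(500_000, rng), fam, 200, rng)
        mean_f = np.mean([r.truncation_fraction for r in recs])
        sd = math.sqrt((1 - 0.05) ** 2 / 12 / 200)
        assert abs(mean_f - 0.525) < 3 * sd

    def test_zero_copies_unchanged(self):
        rng = np.random.default_rng(3)
        g = random_dna(5000, rng)
        g2, recs = insert_copies(g, _spec(consensus="A" * 1000), 0, rng)
        assert g2 == g and recs == []

    def test_insufficient_space(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="space"):
            insert_copies(random_dna(3000, rng),
                          _spec(consensus="A" * 1000), 5, rng)

    def test_truth_records_exact(self):
        rng = np.random.default_rng(5)
        fam = _spec(consensus=random_dna(1000, rng), truncation_p=0.0,
                    divergence_d=0.0)
        g, recs = insert_copies(random_dna(20_000, rng), fam, 4, rng)
        from httrace.align import revcomp

        for r in recs:
            frag = g[r.start:r.end]
            if r.strand == "-":
                frag = revcomp(frag)
            assert frag == fam.consensus


class TestSimulatePanel:
    def test_truth_matrix_equals_event_propagation(self, small_panel):
        panel = small_panel["panel"]
        assert panel.truth.presence == panel.truth.presence_from_events(
            small_panel["tree"], small_panel["specs"])

    def test_htt_confined_to_recipient_clade(self, small_panel):
        row = small_panel["panel"].truth.presence[
            small_panel["library"][1].name]
        assert row == {"A": True, "B": True, "C": False, "D": False}

    def test_vertical_present_everywhere(self, small_panel):
        row = small_panel["panel"].truth.presence[
            small_panel["library"][0].name]
        assert all(row.values())

    def test_seeded_reproducibility(self, four_species_tree):
        from httrace.synthetic_data import make_te_library

        lib = make_te_library(1, seed=9, length=1000)
        spec = TEFamilySpec(name=lib[0].name, consensus=lib[0].seq,
                            length=1000, mode="vertical",
                            copy_number_per_genome=2)
        hp = HostParams(genome_length=10_000)
        p1 = simulate_panel(four_species_tree, [spec], hp, seed=5)
        p2 = simulate_panel(four_species_tree, [spec], hp, seed=5)
        assert {k: v.seq for k, v in p1.genomes.items()} == \
            {k: v.seq for k, v in p2.genomes.items()}

    def test_two_independent_events_counted(self, four_species_tree):
        lib = make_te_library(1, seed=10, length=1000)
        spec = TEFamilySpec(name=lib[0].name, consensus=lib[0].seq,
                            length=1000, mode="htt",
                            origin_branch=["A", "B"],
                            origin_time=[3.0, 2.0],
                            copy_number_per_genome=2)
        hp = HostParams(genome_length=10_000)
        panel = simulate_panel(four_species_tree, [spec], hp, seed=6)
        assert len(panel.truth.events) == 2
        assert panel.truth.presence[lib[0].name] == \
            {"A": True, "B": True, "C": False, "D": False}

    def test_event_age_sets_copy_divergence(self, small_panel):
        # transfer at 10 Ma at 1.25e-9 /site/yr => d = 0.0125 at the tips
        fam = small_panel["library"][1].name
        recs = [r for r in small_panel["panel"].truth.copies["A"]
                if r.family == fam]
        assert recs
        assert np.mean([r.true_divergence for r in recs]) == \
            pytest.approx(0.0125, rel=1e-9)

    def test_event_outside_branch_rejected(self, four_species_tree):
        lib = make_te_library(1, seed=12, length=1000)
        spec = TEFamilySpec(name=lib[0].name, consensus=lib[0].seq,
                            length=1000, mode="htt", origin_branch="A|B",
                            origin_time=25.0, copy_number_per_genome=1)
        with pytest.raises(ValueError, match="outside branch"):
            simulate_panel(four_species_tree, [spec],
                           HostParams(genome_length=8000), seed=0)
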