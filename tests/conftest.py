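"""Shared fixtures: all test data is generated programmatically."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from httrace.io_formats import DatedTree
from httrace.synthetic_data import (HostParams, TEFamilySpec, make_te_library,
                                    simulate_panel)


def rand_dna(rng, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutated(rng, seq: str, d: float) -> str:
    """Per-site substitution at probability d (test-local, independent of
    the package's JC mutator)."""
    out = []
    for c in seq:
        if rng.random() < d:
            out.append(rng.choice([x for x in "ACGT" if x != c]))
        else:
            out.append(c)
    return "".join(out)


def brute_force_min_gains(tree: DatedTree, present: set[str]) -> int:
    """Exhaustive minimal-gain search: smallest set of branches whose
    clades' tip union equals the present set exactly (no losses)."""
    if not present:
        return 0
    nodes = tree.node_ids()
    clades = {n: frozenset(tree.clade_tips(n)) for n in nodes}
    target = frozenset(present)
    usable = [n for n in nodes if clades[n] <= target]
    for k in range(1, len(usable) + 1):
        for combo in itertools.combinations(usable, k):
            union = frozenset().union(*(clades[n] for n in combo))
            if union == target:
                return k
    raise AssertionError("no cover found")  # impossible: tips suffice


@pytest.fixture(scope="session")
def four_species_tree() -> DatedTree:
    return DatedTree.from_newick("((A:5,B:5):13,(C:10,D:10):8):0;")


@pytest.fixture(scope="session")
def small_panel(four_species_tree):
    """One vertical + one horizontally transferred family on a 4-species
    tree (transfer into the A+B clade stem at 10 Ma)."""
    lib = make_te_library(2, seed=3, length=2000)
    specs = [
        TEFamilySpec(name=lib[0].name, consensus=lib[0].seq, length=2000,
                     mode="vertical", copy_number_per_genome=4,
                     divergence_d=0.05, truncation_p=0.5),
        TEFamilySpec(name=lib[1].name, consensus=lib[1].seq, length=2000,
                     mode="htt", origin_branch="A|B", origin_time=10.0,
                     copy_number_per_genome=4, truncation_p=0.5),
    ]
    hp = HostParams(genome_length=30000)
    panel = simulate_panel(four_species_tree, specs, hp, seed=11)
    return {"library": lib, "specs": specs, "panel": panel,
            "tree": four_species_tree}


@pytest.fixture
def rng():
    import random

    return random.Random(20240917)
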