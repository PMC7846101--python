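"""Two clocks for horizontal-transfer events and their reconciliation.

(a) Divergence clock: mean substitutions per site of a family's genomic
copies against its consensus, converted to an age with a per-generation
substitution rate and a generation time,

    T [years] = mean_d / rate_per_site_per_generation * generation_years.

The division is by the per-generation rate directly (no ploidy factor
of 2) — the age is the time a single lineage needs to accumulate
mean_d, because each copy diverges from a consensus that stands for its
own state at insertion, not from a sister lineage.

(b) Branch clock: no-loss gain parsimony on the dated host tree — the
minimal set of branch gains explaining a presence row when losses are
disallowed is exactly one gain per maximal all-present clade, each
dated to the [crown age, stem age] interval of its branch.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DatedTree, logger
from .screening import Evidence, screen_genome
from .similarity_search import PRESET_DEFAULT, SearchParams


@dataclass
class ClockParams:
    rate_per_site_per_generation: float = 1.25e-8
    generation_years: float = 10.0

    def __post_init__(self):
        if self.rate_per_site_per_generation <= 0 or \
                self.generation_years <= 0:
            raise ValueError("clock parameters must be positive")

    @property
    def rate_per_site_per_year(self) -> float:
        return self.rate_per_site_per_generation / self.generation_years


@dataclass
class HTTEvent:
    family: str
    gain_branch: str
    branch_interval: tuple[float, float]  # (crown age, stem age) Ma
    clock_age_mean: float | None = None
    clock_age_sd: float | None = None
    consistent: bool | None = None


def jc_correct(p: float) -> float:
    """Jukes–Cantor distance from an observed proportion of differing
    sites; saturating inputs (p >= 3/4) map to infinity."""
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def per_copy_divergence(hit) -> float:
    """Substitutions per site of one copy: mismatches over aligned
    non-gap columns of its best alignment to the consensus."""
    identities = round(hit.percent_identity / 100.0 * hit.aln_length)
    denom = identities + hit.mismatches  # aligned non-gap columns
    if denom == 0:
        return 0.0
    return hit.mismatches / denom


def copy_divergence(family, genome, preset: SearchParams = PRESET_DEFAULT,
                    min_len: int = 400, jc: bool = False
                    ) -> tuple[float, float, int]:
    """(mean, SD, n) of per-copy substitutions per site for a family's
    copies in one genome.  Copies are the merged loci found by the
    search; divergence per copy comes from its best alignment to the
    consensus.  JC correction optional (corrected >= raw always)."""
    ev: Evidence = screen_genome(family, genome, preset, min_hit_len=min_len)
    if not ev.hits:
        raise ValueError(f"no copies of {ev.family} found")
    ds = []
    for h in ev.hits:
        d = per_copy_divergence(h)
        ds.append(jc_correct(d) if jc else d)
    arr = np.array(ds, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return mean, sd, len(arr)


def insertion_time(mean_d: float, sd_d: float,
                   clock: ClockParams = ClockParams(),
                   n: int | None = None) -> tuple[float, float]:
    """(T_mean, T_sd) in Ma; the SD of copy divergences scales through
    the same linear map.  When n is given, the standard error of the
    mean age (sd / sqrt(n), same units) is logged alongside."""
    years_per_d = clock.generation_years / clock.rate_per_site_per_generation
    t_mean = mean_d * years_per_d / 1e6
    t_sd = sd_d * years_per_d / 1e6
    if n and n > 1:
        logger.info("insertion_time: mean %.3f Ma, sd %.3f Ma, "
                    "se %.3f Ma (n=%d)", t_mean, t_sd,
                    t_sd / math.sqrt(n), n)
    return t_mean, t_sd


def infer_gain_events(presence_row: dict[str, bool], tree: DatedTree,
                      family: str = "") -> list[HTTEvent]:
    """Minimal no-loss gains for one presence row.

    A gain on a branch forces presence in all tips below it, so the
    minimal event set is one gain per maximal clade whose tips are all
    present; the union of event clades equals the present tip set
    exactly.  A family present nowhere yields no events.
    """
    tips = set(tree.tips())
    unknown = set(presence_row) - tips
    if unknown:
        raise ValueError(f"presence row names not in tree: {unknown}")
    present = {t for t in tips if presence_row.get(t, False)}
    if not present:
        return []

    events: list[HTTEvent] = []

    def all_present(node_id: str) -> bool:
        return all(t in present for t in tree.clade_tips(node_id))

    def walk(node_id: str):
        if all_present(node_id):
            crown, stem = tree.branch_span(node_id)
            if node_id == tree.root_id:
                stem = tree.root_age  # no older bound observable
            events.append(HTTEvent(family=family, gain_branch=node_id,
                                   branch_interval=(crown, stem)))
            return
        for c in tree.children(node_id):
            walk(c)

    walk(tree.root_id)
    return events


def count_events(matrix_rows: dict[str, dict[str, bool]],
                 tree: DatedTree) -> int:
    return sum(len(infer_gain_events(row, tree, fam))
               for fam, row in matrix_rows.items())


def consistency(events: list[HTTEvent], clock_age: tuple[float, float]
                ) -> list[HTTEvent]:
    """Annotate events with the overlap test between the divergence
    clock interval (mean +/- sd) and the branch age interval."""
    mean, sd = clock_age
    lo, hi = mean - sd, mean + sd
    for ev in events:
        crown, stem = ev.branch_interval
        ev.clock_age_mean = mean
        ev.clock_age_sd = sd
        ev.consistent = (lo <= stem) and (hi >= crown)
    return events


@dataclass
class EventTable:
    events: list[HTTEvent] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{
            "family": e.family, "branch": e.gain_branch,
            "crown_age": e.branch_interval[0],
            "stem_age": e.branch_interval[1],
            "clock_mean": e.clock_age_mean, "clock_sd": e.clock_age_sd,
            "consistent": e.consistent} for e in self.events])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
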