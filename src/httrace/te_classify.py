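"""Classification of candidate TE consensus sequences and redundancy removal.

Classification is structural: a consensus is assigned a class when the
domain-coverage evidence satisfies a rule (e.g. a LINE must carry >= 80%
of both an endonuclease and a reverse transcriptase domain and be over
800 bp).  Domain hits are consumed from a table (profile searches that
produce them are upstream of this package); the synthetic-data generator
emits truth domain tables in the same shape.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import global_identity
from .io_formats import logger
from .similarity_search import (PRESET_DEFAULT, SimilarityHit, build_index,
                                merge_subject_intervals, search)


@dataclass
class DomainHit:
    consensus_id: str
    domain_name: str
    coverage_fraction: float
    start: int = 0
    end: int = 0

    def __post_init__(self):
        if not (0.0 <= self.coverage_fraction <= 1.0):
            raise ValueError("coverage_fraction must be in [0, 1]")


@dataclass
class TEConsensus:
    """A named repeat consensus with classification and domain evidence."""

    name: str
    seq: str
    class_label: str = "unclassified"
    domain_hits: list[DomainHit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def domain_coverage(self, domain: str) -> float:
        cov = [h.coverage_fraction for h in self.domain_hits
               if h.domain_name == domain]
        return max(cov) if cov else 0.0


@dataclass
class ClassRule:
    class_label: str
    required_domains: list[tuple[str, float]]
    min_length: int = 800


#: shipped rule set.  The LINE rule is the published >=80% EN + RT
#: criterion; the others are documented defaults, editable via YAML.
DEFAULT_RULES = [
    ClassRule("LINE", [("EN", 0.8), ("RT", 0.8)], 800),
    ClassRule("PLE", [("EN-GIY", 0.8), ("RT", 0.8)], 800),
    ClassRule("ERV", [("gag", 0.8), ("pol", 0.8)], 800),
    ClassRule("LTR", [("RT", 0.8), ("RNase-H", 0.8)], 800),
    ClassRule("DNA", [("transposase", 0.8)], 800),
]


def rules_from_config(cfg: list[dict]) -> list[ClassRule]:
    return [ClassRule(c["class_label"],
                      [(d["domain"], float(d["min_coverage"]))
                       for d in c["required_domains"]],
                      int(c.get("min_length", 800)))
            for c in cfg]


def read_domain_table(path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t",
                     names=["consensus_id", "domain", "coverage",
                            "start", "end"],
                     header=None, comment="#")
    return [DomainHit(r.consensus_id, r.domain, float(r.coverage),
                      int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def classify(consensus: TEConsensus, domain_hits: list[DomainHit],
             rules: list[ClassRule] = DEFAULT_RULES) -> str:
    """Assign a class label from domain coverage; first matching rule in
    declared priority order wins.  Deterministic and independent of the
    domain-hit input order (coverage is reduced by max per domain)."""
    if not rules:
        raise ValueError("rules must be non-empty")
    cov: dict[str, float] = {}
    for h in domain_hits:
        if h.consensus_id != consensus.name:
            continue
        cov[h.domain_name] = max(cov.get(h.domain_name, 0.0),
                                 h.coverage_fraction)
    for rule in rules:
        if len(consensus.seq) <= rule.min_length:
            continue
        if all(cov.get(d, 0.0) >= c for d, c in rule.required_domains):
            return rule.class_label
    min_len = min(r.min_length for r in rules)
    if len(consensus.seq) <= min_len:
        return "excluded-short"
    return "unclassified"


def remove_redundant(library: list[TEConsensus],
                     identity_cutoff: float = 94.0,
                     coverage_cutoff: float = 0.5) -> list[TEConsensus]:
    """Collapse redundant consensi: drop any consensus with both >= 94%
    pairwise identity to, and >= 50% of its length covered by, a longer
    consensus (coverage from merged hit intervals against the longer
    one).  Equal-length ties drop the lexicographically later id."""
    # longer first; ties resolved so the lexicographically earlier
    # twin acts as the "longer" reference and survives
    order = sorted(library, key=lambda c: (-len(c.seq), c.name))
    kept: list[TEConsensus] = []
    for cand in order:
        redundant = False
        for ref in kept:
            idx = build_index({ref.name: ref.seq}, PRESET_DEFAULT.word_size)
            hits = search((cand.name, cand.seq), idx, PRESET_DEFAULT)
            strong = [h for h in hits if h.percent_identity >=
                      identity_cutoff]
            if not strong:
                continue
            covered = sum(h.q_end - h.q_start for h in
                          _merge_query_intervals(strong))
            if covered >= coverage_cutoff * len(cand.seq):
                redundant = True
                logger.info("redundant consensus %s collapsed into %s",
                            cand.name, ref.name)
                break
        if not redundant:
            kept.append(cand)
    kept.sort(key=lambda c: [x.name for x in library].index(c.name))
    return kept


def _merge_query_intervals(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    ivs = sorted((h.q_start, h.q_end) for h in hits)
    merged: list[list[int]] = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    class _IV:
        def __init__(self, lo, hi):
            self.q_start, self.q_end = lo, hi

    return [_IV(lo, hi) for lo, hi in merged]


def flag_htt_candidates(library: list[TEConsensus],
                        relative_genomes: dict[str, str | dict],
                        preset=PRESET_DEFAULT) -> list[str]:
    """Horizontal-transfer candidates: consensi absent from EVERY
    designated close-relative genome (presence = screening's call is not
    'absent').  A family found in only some relatives is treated as
    ancestrally shared (not a candidate) and logged as patchy."""
    from .screening import call_presence, screen_genome

    if not relative_genomes:
        raise ValueError("at least one relative genome required")
    candidates = []
    for cons in library:
        calls = {}
        for species, genome in relative_genomes.items():
            ev = screen_genome(cons, genome, preset)
            calls[species] = call_presence(ev)
        n_present = sum(1 for c in calls.values() if c != "absent")
        if n_present == 0:
            candidates.append(cons.name)
        elif n_present < len(calls):
            logger.info("family %s patchy in relatives (%s): treated as "
                        "ancestrally shared", cons.name, calls)
    return candidates


def pairwise_library_identity(a: TEConsensus, b: TEConsensus) -> float:
    return global_identity(a.seq, b.seq)
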