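"""Presence/absence calling of curated families across genome panels.

The three-state call per family x species follows the published shading
rule: present_similar when at least one hit over 1,000 bp reaches 75%
pairwise identity; present_divergent when more than one merged locus
over 1,000 bp exists but none reaches 75%; absent otherwise (a single
sub-75% locus is not enough — one copy in an assembly is treated as a
probable false positive).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import SequenceRecord, logger
from .similarity_search import (PRESET_DEFAULT, PRESET_RELAXED, SearchParams,
                                SimilarityHit, best_hit, build_index, search)
from .te_classify import TEConsensus

MIN_HIT_LEN = 1000
SIMILAR_IDENTITY = 75.0


@dataclass
class Evidence:
    """Per-cell screening evidence for one family in one genome."""

    family: str
    species: str = ""
    hits: list[SimilarityHit] = field(default_factory=list)  # >= 1 kb loci

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def best_identity(self) -> float:
        return max((h.percent_identity for h in self.hits), default=0.0)

    @property
    def best_length(self) -> int:
        return max((h.s_span for h in self.hits), default=0)


def _as_subject_dict(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return {k: (v.seq if isinstance(v, SequenceRecord) else v)
                for k, v in genome.items()}
    if isinstance(genome, SequenceRecord):
        return {genome.id: genome.seq}
    if isinstance(genome, list):
        return {r.id: r.seq for r in genome}
    raise TypeError("genome must be SequenceRecord(s) or id->seq dict")


def _family_query(family) -> tuple[str, str]:
    if isinstance(family, TEConsensus):
        return family.name, family.seq
    if isinstance(family, SequenceRecord):
        return family.id, family.seq
    return family  # (id, seq)


def _merge_loci(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    """Merge overlapping subject hits into loci, keeping the best hit of
    each merged cluster as its representative evidence."""
    out: list[SimilarityHit] = []
    by_sid: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        by_sid.setdefault(h.subject_id, []).append(h)
    for sid, hs in by_sid.items():
        hs.sort(key=lambda h: h.s_start)
        cluster: list[SimilarityHit] = []
        hi = -1
        for h in hs:
            if cluster and h.s_start > hi:
                out.append(best_hit(cluster))
                cluster = []
                hi = -1
            cluster.append(h)
            hi = max(hi, h.s_end)
        if cluster:
            out.append(best_hit(cluster))
    return out


def screen_genome(family, genome, preset: SearchParams = PRESET_RELAXED,
                  min_hit_len: int = MIN_HIT_LEN,
                  species: str = "") -> Evidence:
    """Search one family against one genome and collect qualifying loci
    (merged hits spanning >= ``min_hit_len`` on the subject)."""
    name, seq = _family_query(family)
    subjects = _as_subject_dict(genome)
    idx = build_index(subjects, preset.word_size)
    hits = search((name, seq), idx, preset)
    loci = [h for h in _merge_loci(hits) if h.s_span >= min_hit_len]
    return Evidence(family=name, species=species, hits=loci)


def call_presence(evidence: Evidence,
                  similar_identity: float = SIMILAR_IDENTITY) -> str:
    """Three-state call from qualifying-locus evidence."""
    if any(h.percent_identity >= similar_identity for h in evidence.hits):
        return "present_similar"
    if evidence.n_hits > 1:
        return "present_divergent"
    return "absent"


@dataclass
class PresenceMatrix:
    """families x species grid of three-state calls with evidence."""

    calls: dict[str, dict[str, str]]
    evidence: dict[tuple[str, str], Evidence] = field(default_factory=dict)

    @property
    def families(self) -> list[str]:
        return list(self.calls)

    @property
    def species(self) -> list[str]:
        first = next(iter(self.calls.values()), {})
        return list(first)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls).T

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(calls={fam: dict(row) for fam, row in df.iterrows()})

    def binary_row(self, family: str,
                   divergent_counts: bool = False) -> dict[str, bool]:
        """present_similar (optionally also present_divergent) -> True."""
        ok = {"present_similar"} | (
            {"present_divergent"} if divergent_counts else set())
        return {sp: c in ok for sp, c in self.calls[family].items()}


def screen_panel(families, panel: dict[str, object],
                 preset: SearchParams = PRESET_RELAXED,
                 min_hit_len: int = MIN_HIT_LEN) -> PresenceMatrix:
    """Screen every family against every genome in the panel."""
    calls: dict[str, dict[str, str]] = {}
    evid: dict[tuple[str, str], Evidence] = {}
    for fam in families:
        name, _ = _family_query(fam)
        calls[name] = {}
        for species, genome in panel.items():
            ev = screen_genome(fam, genome, preset, min_hit_len, species)
            evid[(name, species)] = ev
            calls[name][species] = call_presence(ev)
    return PresenceMatrix(calls=calls, evidence=evid)


def transcript_support(family, transcriptome,
                       preset: SearchParams = PRESET_DEFAULT,
                       min_identity: float = 95.0,
                       min_transcript_len: int = 500) -> str:
    """Transcriptome evidence call: 'supported' for a >= 95%-identity hit
    spanning >= ``min_transcript_len``; 'fragment_only' for a shorter
    high-identity hit; 'none' otherwise."""
    name, seq = _family_query(family)
    subjects = _as_subject_dict(transcriptome)
    idx = build_index(subjects, preset.word_size)
    hits = search((name, seq), idx, preset)
    high = [h for h in hits if h.percent_identity >= min_identity]
    if any(h.s_span >= min_transcript_len for h in high):
        return "supported"
    if high:
        return "fragment_only"
    return "none"


def verify_reciprocal(evidence: Evidence, genome,
                      family_library: list[TEConsensus],
                      preset: SearchParams = PRESET_DEFAULT) -> Evidence:
    """Reciprocal confirmation: each candidate region is re-searched
    against the whole family library and kept only when its best library
    match is the probing family."""
    if not family_library:
        raise ValueError("family library must contain at least one family")
    subjects = _as_subject_dict(genome)
    lib_idx = build_index({c.name: c.seq for c in family_library},
                          preset.word_size)
    kept = []
    for h in evidence.hits:
        region = subjects[h.subject_id][h.s_start:h.s_end]
        back = search((f"{h.subject_id}:{h.s_start}-{h.s_end}", region),
                      lib_idx, preset)
        top = best_hit(back)
        if top is not None and top.subject_id == evidence.family:
            kept.append(h)
        else:
            logger.info(
                "reciprocity: dropped %s region %s:%d-%d (best match %s)",
                evidence.family, h.subject_id, h.s_start, h.s_end,
                top.subject_id if top else "none")
    return Evidence(family=evidence.family, species=evidence.species,
                    hits=kept)


def best_hit_identity(query_seq: str, subject_seq: str,
                      preset: SearchParams = PRESET_DEFAULT
                      ) -> tuple[float, int]:
    """(percent identity, hit length) of the best local hit between two
    consensus sequences — the Table-1-style pairwise comparison."""
    idx = build_index({"subject": subject_seq}, preset.word_size)
    hits = search(("query", query_seq), idx, preset)
    top = best_hit(hits)
    if top is None:
        return 0.0, 0
    return top.percent_identity, top.aln_length
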