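"""Seed-and-extend local DNA similarity search.

The engine used by every screening stage: exact-word seeding on an
indexed subject panel, ungapped X-drop extension along the seed
diagonal, then full affine-gap local alignment inside a padded window
around each high-scoring segment.  Within a window the best local
alignment is extracted, its subject span is masked, and the window is
re-aligned until the score threshold is no longer met, so multiple
nearby copies are each reported.

Two presets mirror the two regimes a practitioner runs: ``default``
(megablast-like: long words, cheap gaps) for within- and close-relative
searches, and ``relaxed`` (short words, reward 3 / penalty -4, heavy
gap costs, E-value cutoff 2e-5) for deep cross-phylum screens.
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np

from .align import Alignment, encode, local_align, revcomp, ungapped_xdrop
from .io_formats import SequenceRecord, logger


@dataclass(frozen=True)
class SearchParams:
    word_size: int = 28
    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = 0
    gap_extend: int = 2
    xdrop_ungapped: int = 40
    xdrop_gapped: int = 100
    min_score: int = 50
    max_evalue: float | None = None
    dust: bool = False
    window_pad: int | None = None  # None -> max(64, qlen // 4)
    max_hits_per_window: int = 25

    def __post_init__(self):
        if self.word_size < 7:
            raise ValueError("word_size must be >= 7")
        if not (self.match_reward > 0 > self.mismatch_penalty):
            raise ValueError("need reward > 0 > penalty")


#: megablast-like defaults (the tool's own documented values, not a
#: claim of bit-equivalence with any external program).
PRESET_DEFAULT = SearchParams()

#: the relaxed cross-phylum screening regime.
PRESET_RELAXED = SearchParams(
    word_size=10, match_reward=3, mismatch_penalty=-4,
    gap_open=30, gap_extend=6, xdrop_ungapped=80, xdrop_gapped=150,
    min_score=60, max_evalue=2e-5, dust=True,
)

#: short-word, wide-window settings for desk-scale sequence pairs.
PRESET_SENSITIVE = SearchParams(
    word_size=7, match_reward=1, mismatch_penalty=-2, gap_open=2,
    gap_extend=1, xdrop_ungapped=20, min_score=15, window_pad=10 ** 6,
)

PRESETS = {"default": PRESET_DEFAULT, "relaxed": PRESET_RELAXED,
           "sensitive": PRESET_SENSITIVE}


@dataclass
class SimilarityHit:
    """One local alignment between query and subject.

    Coordinates are 0-based half-open on the plus strand of each
    sequence; for minus-strand hits the query interval refers to the
    plus strand of the query (the aligned segment's reverse complement
    matched the subject).
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    percent_identity: float
    aln_length: int
    mismatches: int = 0
    gap_opens: int = 0
    evalue: float | None = None

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start


class SeedIndex:
    """Exact k-mer -> (subject id, position) index over a subject set."""

    def __init__(self, subjects: dict[str, str], word_size: int):
        self.word_size = word_size
        self.subjects = {k: v.upper() for k, v in subjects.items()}
        self.encoded = {k: encode(v) for k, v in self.subjects.items()}
        self.total_length = sum(len(v) for v in self.subjects.values())
        self.table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for sid, seq in self.subjects.items():
            if len(seq) < word_size:
                logger.warning(
                    "subject %s shorter than word size %d: not indexed",
                    sid, word_size)
                continue
            for i in range(len(seq) - word_size + 1):
                w = seq[i:i + word_size]
                if "N" in w:
                    continue
                self.table[w].append((sid, i))

    def lookup(self, word: str) -> list[tuple[str, int]]:
        return self.table.get(word, [])


def build_index(subject_seqs, word_size: int) -> SeedIndex:
    """Index subject sequences (list of SequenceRecord or id->seq dict)."""
    if isinstance(subject_seqs, dict):
        d = subject_seqs
    else:
        d = {r.id: r.seq for r in subject_seqs}
    return SeedIndex(d, word_size)


def _entropy3(window: str) -> float:
    """Shannon entropy (bits) of overlapping 3-mers in a window."""
    counts: dict[str, int] = defaultdict(int)
    n = 0
    for i in range(len(window) - 2):
        counts[window[i:i + 3]] += 1
        n += 1
    if n == 0:
        return 0.0
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def _dust_mask(seq: str, word_size: int, threshold: float = 1.5,
               window: int = 48) -> np.ndarray:
    """Boolean mask of seed start positions falling in low-complexity
    windows (3-mer entropy below threshold)."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    step = max(8, window // 3)
    for i in range(0, n, step):
        win = seq[i:i + window]
        if len(win) >= 12 and _entropy3(win) < threshold:
            mask[i:i + window] = True
    return mask


def _karlin_lambda(params: SearchParams) -> float:
    """Solve sum p_i p_j exp(lambda s_ij) = 1 for lambda by bisection,
    uniform base frequencies."""
    r, p = params.match_reward, params.mismatch_penalty

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * r) + 0.75 * math.exp(lam * p) - 1.0

    lo, hi = 1e-9, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("lambda solver failed to bracket a root")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    if not math.isfinite(lam) or lam <= 0:
        raise RuntimeError("lambda solver did not converge")
    return lam


def evalue(score: int, m: int, n: int, params: SearchParams,
           K: float = 0.1) -> float:
    """Karlin–Altschul expectation E = K * m * n * exp(-lambda * score).

    K is an uncalibrated constant (gapped calibration is out of scope);
    E-values are comparable within a parameter set, monotone in score
    and linear in the search space, which is all the thresholds need.
    """
    if score <= 0:
        raise ValueError("score must be positive")
    lam = _karlin_lambda(params)
    return K * m * n * math.exp(-lam * score)


def _window_hits(qe: np.ndarray, sub_e: np.ndarray, win_lo: int, win_hi: int,
                 params: SearchParams, min_score: int) -> list[Alignment]:
    """Iterated best local alignments inside one subject window."""
    window = sub_e[win_lo:win_hi].copy()
    out: list[Alignment] = []
    for _ in range(params.max_hits_per_window):
        aln = local_align(qe, window, params.match_reward,
                          params.mismatch_penalty, params.gap_open,
                          params.gap_extend)
        if aln.score < min_score or aln.aln_length == 0:
            break
        aln.s_start += win_lo
        aln.s_end += win_lo
        out.append(aln)
        # mask the claimed subject span so the next-best copy surfaces
        window[aln.s_start - win_lo:aln.s_end - win_lo] = 4
    return out


def search(query, index: SeedIndex, params: SearchParams = PRESET_DEFAULT
           ) -> list[SimilarityHit]:
    """Search a query against an indexed subject panel, both strands.

    Returns hits sorted by descending score; every hit's score is the
    affine-gap score of its reported alignment under ``params``.
    """
    if isinstance(query, SequenceRecord):
        qid, qseq = query.id, query.seq
    else:
        qid, qseq = query
    qseq = qseq.upper()
    qlen = len(qseq)
    if qlen == 0:
        return []
    k = index.word_size
    pad = params.window_pad if params.window_pad is not None else max(
        64, qlen // 4)
    min_ungapped = int(1.5 * k * params.match_reward)
    hits: list[SimilarityHit] = []
    for strand, qs in (("+", qseq), ("-", revcomp(qseq))):
        if qlen < k:
            continue
        qe = encode(qs)
        dust = _dust_mask(qs, k) if params.dust else None
        # seeds grouped per (subject, diagonal)
        diag_seeds: dict[tuple[str, int], list[int]] = defaultdict(list)
        for i in range(qlen - k + 1):
            if dust is not None and dust[i]:
                continue
            for sid, pos in index.lookup(qs[i:i + k]):
                diag_seeds[(sid, pos - i)].append(i)
        # ungapped X-drop extension, one segment per seed cluster
        segments: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for (sid, diag), qpos_list in diag_seeds.items():
            se = index.encoded[sid]
            covered_to = -1
            for i in sorted(qpos_list):
                if i <= covered_to:
                    continue
                q_lo, q_hi, s_lo, s_hi, score = ungapped_xdrop(
                    qe, se, i, i + diag, params.match_reward,
                    params.mismatch_penalty, params.xdrop_ungapped)
                covered_to = q_hi - 1
                if score >= min_ungapped:
                    w_lo = max(0, s_lo - (q_lo + pad))
                    w_hi = min(len(se), s_hi + (qlen - q_hi) + pad)
                    segments[sid].append((w_lo, w_hi))
        # merge overlapping windows, then extract gapped hits per window
        for sid, wins in segments.items():
            se = index.encoded[sid]
            merged: list[list[int]] = []
            for lo, hi in sorted(wins):
                if merged and lo <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi])
            for lo, hi in merged:
                for aln in _window_hits(qe, se, lo, hi, params,
                                        params.min_score):
                    ev = None
                    if params.max_evalue is not None:
                        ev = evalue(aln.score, qlen, index.total_length,
                                    params)
                        if ev > params.max_evalue:
                            continue
                    if strand == "+":
                        q0, q1 = aln.q_start, aln.q_end
                    else:  # map back to plus strand of the query
                        q0, q1 = qlen - aln.q_end, qlen - aln.q_start
                    hits.append(SimilarityHit(
                        query_id=qid, subject_id=sid, q_start=q0, q_end=q1,
                        s_start=aln.s_start, s_end=aln.s_end, strand=strand,
                        score=aln.score,
                        percent_identity=aln.percent_identity,
                        aln_length=aln.aln_length, mismatches=aln.mismatches,
                        gap_opens=aln.gap_opens, evalue=ev))
    hits = _dedupe(hits)
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start))
    return hits


def _dedupe(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    """Drop hits whose subject span is mostly inside a better hit's span
    on the same subject (keeps the best-scoring representative)."""
    kept: list[SimilarityHit] = []
    for h in sorted(hits, key=lambda x: -x.score):
        redundant = False
        for g in kept:
            if g.subject_id != h.subject_id:
                continue
            ov = min(g.s_end, h.s_end) - max(g.s_start, h.s_start)
            if ov > 0 and ov >= 0.5 * h.s_span:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def merge_subject_intervals(hits: list[SimilarityHit], slop: int = 0
                            ) -> list[tuple[str, int, int]]:
    """Merge overlapping subject intervals of a hit list into loci."""
    by_sid: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for h in hits:
        by_sid[h.subject_id].append((h.s_start, h.s_end))
    loci = []
    for sid, ivs in by_sid.items():
        merged: list[list[int]] = []
        for lo, hi in sorted(ivs):
            if merged and lo <= merged[-1][1] + slop:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        loci.extend((sid, lo, hi) for lo, hi in merged)
    return loci


def best_hit(hits: list[SimilarityHit]) -> SimilarityHit | None:
    """Best hit by (score, identity, lexicographic subject id)."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.score, -h.percent_identity,
                                    h.subject_id))


def reciprocal_best_hit(hits_ab: list[SimilarityHit],
                        hits_ba: list[SimilarityHit]
                        ) -> list[tuple[str, str]]:
    """Mutual-best pairing: (a, b) kept iff a's best subject is b and
    b's best subject is a.  Ties break by identity then subject id."""
    def bests(hits):
        per_query: dict[str, list[SimilarityHit]] = defaultdict(list)
        for h in hits:
            per_query[h.query_id].append(h)
        return {q: best_hit(hs).subject_id for q, hs in per_query.items()}

    best_ab = bests(hits_ab)
    best_ba = bests(hits_ba)
    pairs = []
    for a, b in sorted(best_ab.items()):
        if best_ba.get(b) == a:
            pairs.append((a, b))
    return pairs


def with_params(preset: str, **overrides) -> SearchParams:
    return replace(PRESETS[preset], **overrides)
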