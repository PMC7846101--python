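"""Iterative consensus curation: search, extend, align, trim (SEAT).

Each round searches the current consensus against the genome, keeps the
best-scoring hits over a length floor, extends their coordinates into
flanking sequence (to recover consensus ends the previous round
missed), builds a center-star multiple alignment, trims non-homologous
flank columns, and calls a majority consensus.  Iteration stops when
successive consensi converge in identity or the round limit is hit.

The manual alignment editing of the original protocol is replaced by a
deterministic column filter: a column is kept only when enough rows
occupy it AND enough of those rows agree on one base; random flanking
sequence drawn into the alignment by the coordinate extension fails the
agreement test even when every row is full length (in which case the
flanks carry no gaps and an occupancy rule alone would keep them).
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import full_identity, local_align, revcomp
from .io_formats import SequenceRecord, logger
from .similarity_search import PRESET_DEFAULT, build_index, search


@dataclass
class SEATParams:
    top_n: int = 25
    min_hit_len: int = 1000
    extension: int = 1000  # 3000 in cross-species mode
    max_iter: int = 10
    convergence_identity: float = 99.0
    consensus_min_occupancy: float = 0.5
    min_agreement: float = 0.55
    edge_trim_window: int = 10

    def __post_init__(self):
        if self.top_n < 2:
            raise ValueError("top_n must be >= 2 for consensus building")
        if self.extension < 0:
            raise ValueError("extension must be >= 0")


CROSS_SPECIES = SEATParams(extension=3000)


@dataclass
class MultipleAlignment:
    names: list[str]
    rows: list[str]

    def __post_init__(self):
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def take_columns(self, cols) -> "MultipleAlignment":
        rows = ["".join(r[j] for j in cols) for r in self.rows]
        return MultipleAlignment(list(self.names), rows)

    def take_rows(self, idx) -> "MultipleAlignment":
        ali = MultipleAlignment([self.names[i] for i in idx],
                                [self.rows[i] for i in idx])
        keep = [j for j in range(ali.n_cols)
                if any(r[j] != "-" for r in ali.rows)]
        return ali.take_columns(keep)


@dataclass
class CuratedConsensus:
    name: str
    seq: str
    iterations: int = 0
    n_copies_used: int = 0
    per_iteration_identity: list[float] = field(default_factory=list)
    single_copy: bool = False
    lineage: str = ""


def _kmer_profile(seq: str, k: int = 8) -> dict[str, int]:
    d: dict[str, int] = defaultdict(int)
    for i in range(len(seq) - k + 1):
        d[seq[i:i + k]] += 1
    return d


def _choose_center(seqs: list[str]) -> int:
    """Canonical center: the row with the highest summed k-mer-profile
    similarity to all others (a fast, order-invariant stand-in for
    summed pairwise alignment scores); ties break on length then index
    of the lexicographically smallest sequence."""
    profs = [_kmer_profile(s) for s in seqs]
    scores = []
    for i, pi in enumerate(profs):
        tot = 0
        for j, pj in enumerate(profs):
            if i == j:
                continue
            for w, c in pi.items():
                cj = pj.get(w)
                if cj:
                    tot += min(c, cj)
        scores.append(tot)
    ranked = sorted(range(len(seqs)),
                    key=lambda i: (-scores[i], -len(seqs[i]), seqs[i]))
    return ranked[0]


def msa(sequences: list[str] | list[SequenceRecord],
        names: list[str] | None = None) -> MultipleAlignment:
    """Center-star multiple alignment.

    Rows are aligned to the center with affine local alignment and
    merged by gap projection onto center coordinates; the unaligned
    (non-homologous) head and tail of each row are carried as
    single-row insertions, so they occupy sparse columns instead of
    being forced onto homologous ones.  Removing gap columns recovers
    every input exactly.
    """
    if sequences and isinstance(sequences[0], SequenceRecord):
        names = [r.id for r in sequences]
        seqs = [r.seq for r in sequences]
    else:
        seqs = list(sequences)
        names = names or [f"seq{i + 1}" for i in range(len(seqs))]
    if len(seqs) < 2:
        raise ValueError("msa needs at least 2 sequences")
    c = _choose_center(seqs)
    center = seqs[c]
    L = len(center)
    per_row = []  # (ins: boundary->str, at: list of row chars per center pos)
    for i, s in enumerate(seqs):
        if i == c:
            per_row.append(({}, list(center)))
            continue
        aln = local_align(center, s, match=2, mismatch=-3, gap_open=5,
                          gap_extend=2)
        ins: dict[int, str] = defaultdict(str)
        at = ["-"] * L
        ci, ri = aln.q_start, aln.s_start
        ins[ci] += s[:ri]
        for op in aln.ops:
            if op == 0:
                at[ci] = s[ri]
                ci += 1
                ri += 1
            elif op == 1:  # center consumed, row gap
                ci += 1
            else:  # row char inserted relative to center
                ins[ci] += s[ri]
                ri += 1
        ins[ci] += s[ri:]
        per_row.append((ins, at))
    max_ins = [0] * (L + 1)
    for ins, _ in per_row:
        for k, block in ins.items():
            max_ins[k] = max(max_ins[k], len(block))
    rows = []
    for ins, at in per_row:
        parts = []
        for k in range(L + 1):
            block = ins.get(k, "")
            parts.append(block + "-" * (max_ins[k] - len(block)))
            if k < L:
                parts.append(at[k])
        rows.append("".join(parts))
    return MultipleAlignment(names, rows)


def column_stats(alignment: MultipleAlignment
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(occupancy, majority agreement, majority base) per column.

    Agreement = majority-base count / non-gap count; ambiguity codes
    count toward occupancy but never toward a majority.
    """
    n = alignment.n_rows
    occ = np.zeros(alignment.n_cols)
    agree = np.zeros(alignment.n_cols)
    maj: list[str] = []
    for j in range(alignment.n_cols):
        col = alignment.column(j)
        nongap = [ch for ch in col if ch != "-"]
        occ[j] = len(nongap) / n
        counts = {b: 0 for b in "ACGT"}
        for ch in nongap:
            if ch in counts:
                counts[ch] += 1
        best = max("ACGT", key=lambda b: counts[b])  # ties A<C<G<T
        maj.append(best if counts[best] > 0 else "-")
        agree[j] = counts[best] / len(nongap) if nongap else 0.0
    return occ, agree, maj


def trim_flanks(alignment: MultipleAlignment,
                params: SEATParams = SEATParams()) -> MultipleAlignment:
    """Trim non-homologous flank columns and sparse internal columns.

    From each end, columns are dropped until a run of
    ``edge_trim_window`` consecutive columns all qualify (occupancy >=
    consensus_min_occupancy, inclusive, and majority agreement >=
    min_agreement); internal columns with occupancy < 0.2 are dropped.
    """
    if alignment.n_rows == 0:
        raise ValueError("empty alignment")
    occ, agree, _ = column_stats(alignment)
    good = (occ >= params.consensus_min_occupancy) & \
        (agree >= params.min_agreement)
    w = params.edge_trim_window
    start = None
    run = 0
    for j in range(len(good)):
        run = run + 1 if good[j] else 0
        if run == w:
            start = j - w + 1
            break
    if start is None:
        raise ValueError("no homologous core found in alignment")
    run = 0
    end = None
    for j in range(len(good) - 1, -1, -1):
        run = run + 1 if good[j] else 0
        if run == w:
            end = j + w
            break
    cols = [j for j in range(start, end) if occ[j] >= 0.2]
    return alignment.take_columns(cols)


def consensus_call(alignment: MultipleAlignment,
                   params: SEATParams = SEATParams()) -> str:
    """Majority base among non-gap characters per column; ties break
    A<C<G<T; columns below the occupancy floor are not emitted."""
    occ, _, maj = column_stats(alignment)
    return "".join(m for o, m in zip(occ, maj)
                   if o >= params.consensus_min_occupancy and m != "-")


def _row_pairwise_identity(a: str, b: str) -> float:
    """Identity over columns where both rows are non-gap.

    Rows that barely co-occur in the alignment (shared columns under
    20% of the shorter row's residues) are non-homologous by
    construction and score 0 rather than a chance-level identity."""
    shared = match = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            shared += 1
            if x == y and x in "ACGT":
                match += 1
    shortest = min(len(a.replace("-", "")), len(b.replace("-", "")))
    if shared == 0 or (shortest and shared < 0.2 * shortest):
        return 0.0
    return 100.0 * match / shared


def split_subfamilies(alignment: MultipleAlignment,
                      cut_identity: float = 94.0,
                      attach_singletons: bool = False
                      ) -> list[tuple[str, MultipleAlignment]]:
    """Average-linkage clustering of aligned rows, cut at the identity
    threshold; each cut cluster becomes a subfamily (suffixes H1, H2,
    ... by descending size).  A single-copy cluster is a legitimate
    subfamily (represented by its one copy downstream); with
    ``attach_singletons`` singletons are folded into the nearest
    multi-row cluster instead.  Returns [(suffix, sub-alignment)]."""
    n = alignment.n_rows
    if n < 2:
        raise ValueError("need >= 2 rows to split")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 100.0 - _row_pairwise_identity(alignment.rows[i],
                                               alignment.rows[j])
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=100.0 - cut_identity, criterion="distance")
    clusters: dict[int, list[int]] = defaultdict(list)
    for i, lab in enumerate(labels):
        clusters[lab].append(i)
    multi = {lab: idx for lab, idx in clusters.items() if len(idx) >= 2}
    if attach_singletons and multi:
        for lab, idx in clusters.items():
            if len(idx) >= 2:
                continue
            i = idx[0]
            nearest = min(multi, key=lambda m: float(
                np.mean([dist[i, j] for j in multi[m]])))
            multi[nearest] = multi[nearest] + [i]
        final = list(multi.values())
    else:
        final = list(clusters.values())
    final.sort(key=lambda idx: (-len(idx), min(idx)))
    return [(f"H{k + 1}", alignment.take_rows(sorted(idx)))
            for k, idx in enumerate(final)]


def _extract_extended(genome: dict[str, str], hit, extension: int) -> str:
    seq = genome[hit.subject_id]
    lo = max(0, hit.s_start - extension)
    hi = min(len(seq), hit.s_end + extension)
    frag = seq[lo:hi]
    return revcomp(frag) if hit.strand == "-" else frag


def seat_iterate(seed_consensus, genome,
                 params: SEATParams = SEATParams(),
                 preset=PRESET_DEFAULT) -> CuratedConsensus:
    """Run the SEAT loop for one family against one genome.

    Raises when no qualifying hit exists; a single qualifying
    full-length copy is returned verbatim (flagged ``single_copy``).
    """
    if isinstance(seed_consensus, SequenceRecord):
        name, cons = seed_consensus.id, seed_consensus.seq
    elif hasattr(seed_consensus, "name"):
        name, cons = seed_consensus.name, seed_consensus.seq
    else:
        name, cons = seed_consensus
    if len(cons) < 100:
        raise ValueError("seed consensus must be >= 100 bp")
    subjects = (genome if isinstance(genome, dict)
                else {genome.id: genome.seq})
    subjects = {k: (v.seq if isinstance(v, SequenceRecord) else v)
                for k, v in subjects.items()}
    idents: list[float] = []
    n_used = 0
    for it in range(params.max_iter):
        idx = build_index(subjects, preset.word_size)
        hits = search((name, cons), idx, preset)
        qual = [h for h in hits if h.s_span >= params.min_hit_len]
        if not qual:
            raise ValueError(
                f"family {name} not present at curation thresholds")
        qual.sort(key=lambda h: (-h.score, h.subject_id, h.s_start))
        if len(qual) == 1:
            h = qual[0]
            copy = _extract_extended(subjects, h, 0)
            covers = (h.q_end - h.q_start) >= 0.95 * len(cons)
            logger.info("family %s: single qualifying copy (%s full length)",
                        name, "is" if covers else "NOT")
            return CuratedConsensus(name, copy, iterations=it + 1,
                                    n_copies_used=1,
                                    per_iteration_identity=idents,
                                    single_copy=True)
        top = qual[:params.top_n]
        n_used = len(top)
        rows = [_extract_extended(subjects, h, params.extension)
                for h in top]
        ali = msa(rows, [f"{name}_hit{i + 1}" for i in range(len(rows))])
        ali = trim_flanks(ali, params)
        new_cons = consensus_call(ali, params)
        if not new_cons:
            raise ValueError(f"family {name}: empty consensus after trim")
        ident = full_identity(new_cons, cons)
        idents.append(ident)
        cons = new_cons
        if ident >= params.convergence_identity:
            break
    return CuratedConsensus(name, cons, iterations=len(idents),
                            n_copies_used=n_used,
                            per_iteration_identity=idents)
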