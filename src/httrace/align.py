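"""Low-level pairwise DNA alignment kernels (numba-compiled).

Conventions used throughout the package:

* bases are encoded A=0 C=1 G=2 T=3, everything else (N and IUPAC
  ambiguity codes) = 4; code 4 never matches anything, including itself,
  and always scores the mismatch penalty;
* a gap of length L costs ``gap_open + L * gap_extend`` (existence plus
  per-residue, BLAST-style);
* local alignment is Smith–Waterman with affine gaps; "glocal" is
  end-gap-free global alignment (terminal gaps in either sequence are
  free), which tolerates 5'-truncated copies in multiple alignments.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


NEG = np.int32(-(10 ** 8))


@njit(cache=True)
def _fill_affine(q, s, match, mismatch, go, ge, local):
    """Fill H/E/F for SW (local=True) or end-gap-free global (local=False)."""
    m, n = q.shape[0], s.shape[0]
    H = np.empty((m + 1, n + 1), np.int32)
    E = np.empty((m + 1, n + 1), np.int32)
    F = np.empty((m + 1, n + 1), np.int32)
    H[0, 0] = 0
    E[0, 0] = NEG
    F[0, 0] = NEG
    for j in range(1, n + 1):
        H[0, j] = 0
        E[0, j] = NEG
        F[0, j] = NEG
    for i in range(1, m + 1):
        H[i, 0] = 0
        E[i, 0] = NEG
        F[i, 0] = NEG
    gap1 = go + ge
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            e = E[i, j - 1] - ge
            t = H[i, j - 1] - gap1
            if t > e:
                e = t
            E[i, j] = e
            f = F[i - 1, j] - ge
            t = H[i - 1, j] - gap1
            if t > f:
                f = t
            F[i, j] = f
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _traceback(q, s, H, E, F, match, mismatch, go, ge, i, j, local):
    """Walk back from H[i,j]; returns (q0, s0, ops) with ops reversed.

    op codes: 0 = diagonal, 1 = gap in subject (consume q), 2 = gap in
    query (consume s).
    """
    gap1 = go + ge
    ops = []
    state = 0  # 0=H 1=E 2=F
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if local and h == 0:
                break
            qi = q[i - 1]
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            if h == H[i - 1, j - 1] + sub:
                ops.append(0)
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            elif h == F[i, j]:
                state = 2
            else:  # end-gap-free boundary (h == 0 row/col init)
                break
        elif state == 1:
            if E[i, j] == E[i, j - 1] - ge:
                ops.append(2)
                j -= 1
            else:
                ops.append(2)
                j -= 1
                state = 0
        else:
            if F[i, j] == F[i - 1, j] - ge:
                ops.append(1)
                i -= 1
            else:
                ops.append(1)
                i -= 1
                state = 0
    return i, j, ops


@njit(cache=True)
def _best_cell_local(H):
    m, n = H.shape
    bi, bj, best = 0, 0, np.int32(0)
    for i in range(m):
        for j in range(n):
            if H[i, j] > best:
                best = H[i, j]
                bi, bj = i, j
    return bi, bj, best


@njit(cache=True)
def _best_cell_border(H):
    m, n = H.shape[0] - 1, H.shape[1] - 1
    bi, bj = m, n
    best = H[m, n]
    for j in range(n + 1):
        if H[m, j] > best:
            best = H[m, j]
            bi, bj = m, j
    for i in range(m + 1):
        if H[i, n] > best:
            best = H[i, n]
            bi, bj = i, n
    return bi, bj, best


class Alignment:
    """Result of a pairwise alignment of q[q_start:q_end] / s[s_start:s_end]."""

    __slots__ = ("score", "q_start", "q_end", "s_start", "s_end", "ops",
                 "identities", "mismatches", "gap_opens", "gap_columns")

    def __init__(self, score, q_start, q_end, s_start, s_end, ops,
                 identities, mismatches, gap_opens, gap_columns):
        self.score = int(score)
        self.q_start = q_start
        self.q_end = q_end
        self.s_start = s_start
        self.s_end = s_end
        self.ops = ops
        self.identities = identities
        self.mismatches = mismatches
        self.gap_opens = gap_opens
        self.gap_columns = gap_columns

    @property
    def aln_length(self) -> int:
        return len(self.ops)

    @property
    def percent_identity(self) -> float:
        """Identities over all alignment columns, gaps in the denominator."""
        if not self.ops:
            return 0.0
        return 100.0 * self.identities / len(self.ops)

    def aligned_strings(self, q: str, s: str) -> tuple[str, str]:
        qa, sa = [], []
        i, j = self.q_start, self.s_start
        for op in self.ops:
            if op == 0:
                qa.append(q[i])
                sa.append(s[j])
                i += 1
                j += 1
            elif op == 1:
                qa.append(q[i])
                sa.append("-")
                i += 1
            else:
                qa.append("-")
                sa.append(s[j])
                j += 1
        return "".join(qa), "".join(sa)


def _stats(q, s, q0, s0, ops):
    ident = mism = gaps = gap_opens = 0
    i, j = q0, s0
    prev = 0
    for op in ops:
        if op == 0:
            if q[i] == s[j] and q[i] < 4:
                ident += 1
            else:
                mism += 1
            i += 1
            j += 1
        else:
            gaps += 1
            if op != prev:
                gap_opens += 1
            if op == 1:
                i += 1
            else:
                j += 1
        prev = op
    return ident, mism, gap_opens, gaps


def _run(qe, se, match, mismatch, go, ge, local) -> Alignment:
    H, E, F = _fill_affine(qe, se, match, mismatch, go, ge, local)
    if local:
        bi, bj, best = _best_cell_local(H)
    else:
        bi, bj, best = _best_cell_border(H)
    i0, j0, ops = _traceback(qe, se, H, E, F, match, mismatch, go, ge,
                             bi, bj, local)
    ops = ops[::-1]
    ident, mism, gap_opens, gaps = _stats(qe, se, i0, j0, ops)
    return Alignment(best, i0, bi, j0, bj, ops, ident, mism, gap_opens, gaps)


def local_align(q: str | np.ndarray, s: str | np.ndarray, match=1,
                mismatch=-2, gap_open=0, gap_extend=2) -> Alignment:
    """Smith–Waterman local alignment with affine gaps."""
    qe = encode(q) if isinstance(q, str) else q
    se = encode(s) if isinstance(s, str) else s
    if len(qe) == 0 or len(se) == 0:
        return Alignment(0, 0, 0, 0, 0, [], 0, 0, 0, 0)
    return _run(qe, se, match, mismatch, gap_open, gap_extend, True)


def glocal_align(q: str | np.ndarray, s: str | np.ndarray, match=2,
                 mismatch=-3, gap_open=5, gap_extend=2) -> Alignment:
    """End-gap-free global alignment (terminal gaps free both sides)."""
    qe = encode(q) if isinstance(q, str) else q
    se = encode(s) if isinstance(s, str) else s
    if len(qe) == 0 or len(se) == 0:
        return Alignment(0, 0, 0, 0, 0, [], 0, 0, 0, 0)
    return _run(qe, se, match, mismatch, gap_open, gap_extend, False)


def global_identity(a: str, b: str) -> float:
    """Percent identity of the end-gap-free global alignment of a and b
    (identities / aligned columns, terminal overhangs excluded)."""
    aln = glocal_align(a, b)
    if aln.aln_length == 0:
        return 0.0
    return 100.0 * aln.identities / aln.aln_length


def full_identity(a: str, b: str) -> float:
    """Percent identity with terminal overhangs charged to the
    denominator: a sequence strictly contained in a longer one cannot
    score 100%.  Used as the convergence measure in iterative curation."""
    aln = glocal_align(a, b)
    overhang = (aln.q_start + (len(a) - aln.q_end) +
                aln.s_start + (len(b) - aln.s_end))
    denom = aln.aln_length + overhang
    if denom == 0:
        return 0.0
    return 100.0 * aln.identities / denom


@njit(cache=True)
def ungapped_xdrop(q, s, qi, sj, match, mismatch, xdrop):
    """Extend an exact seed at (qi, sj) both ways without gaps.

    Returns (q_lo, q_hi, s_lo, s_hi, score) of the best-scoring ungapped
    segment; extension in each direction stops when the running score
    falls xdrop below the running maximum.
    """
    # right extension (inclusive of seed start position)
    score = 0
    best = 0
    best_r = 0
    i, j = qi, sj
    k = 0
    while i + k < q.shape[0] and j + k < s.shape[0]:
        if q[i + k] == s[j + k] and q[i + k] < 4:
            score += match
        else:
            score += mismatch
        if score > best:
            best = score
            best_r = k + 1
        if best - score > xdrop:
            break
        k += 1
    # left extension
    score = 0
    bestl = 0
    best_l = 0
    k = 1
    while qi - k >= 0 and sj - k >= 0:
        if q[qi - k] == s[sj - k] and q[qi - k] < 4:
            score += match
        else:
            score += mismatch
        if score > bestl:
            bestl = score
            best_l = k
        if bestl - score > xdrop:
            break
        k += 1
    return qi - best_l, qi + best_r, sj - best_l, sj + best_r, best + bestl
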