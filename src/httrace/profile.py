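"""Coverage/divergence profiling of a family's fragments on its consensus.

The classic LINE diagnostic: map every genomic fragment of a family to
the consensus, stack per-position depth and per-fragment divergence,
and summarise 5'-truncation as the ratio of mean depth in the 3'
quartile of consensus positions over the 5' quartile (target-primed
reverse transcription starts at the 3' end, so active LINEs leave a
3'-biased coverage wedge).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import logger
from .screening import _as_subject_dict, _family_query
from .similarity_search import (PRESET_DEFAULT, SearchParams, SimilarityHit,
                                build_index, search)


@dataclass
class Fragment:
    q_start: int  # consensus interval covered
    q_end: int
    divergence: float  # 1 - identity/100
    full_length: bool


@dataclass
class FamilyProfile:
    family: str
    consensus_length: int
    depth: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    fragments: list[Fragment] = field(default_factory=list)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def n_full_length(self) -> int:
        return sum(f.full_length for f in self.fragments)

    @property
    def truncation_ratio(self) -> float:
        """Mean depth over the last quartile of consensus positions
        divided by the mean over the first quartile."""
        L = self.consensus_length
        q = max(1, L // 4)
        five = float(self.depth[:q].mean())
        three = float(self.depth[L - q:].mean())
        if five == 0:
            return np.inf if three > 0 else 1.0
        return three / five


def build_profile(family, genome, preset: SearchParams = PRESET_DEFAULT,
                  min_fragment_len: int = 100,
                  full_length_fraction: float = 0.95,
                  jc_cap: bool = False) -> FamilyProfile:
    """Profile all fragments of a family in a genome.

    Overlapping hits at one locus are merged before depth accumulation
    (the best hit represents the locus) so tandem fragments are not
    double-counted.  A fragment covering >= 95% of the consensus counts
    as full length.  Divergence is 1 - identity/100 per fragment
    (JC-capped to [0, 0.75] when jc_cap is set).
    """
    from .screening import _merge_loci

    name, seq = _family_query(family)
    L = len(seq)
    idx = build_index(_as_subject_dict(genome), preset.word_size)
    hits = search((name, seq), idx, preset)
    loci = [h for h in _merge_loci(hits)
            if h.q_end - h.q_start >= min_fragment_len]
    prof = FamilyProfile(family=name, consensus_length=L,
                         depth=np.zeros(L, dtype=int))
    if not loci:
        logger.warning("no fragments of %s found: empty profile", name)
        return prof
    for h in loci:
        div = 1.0 - h.percent_identity / 100.0
        if jc_cap:
            div = min(div, 0.75)
        prof.depth[h.q_start:h.q_end] += 1
        prof.fragments.append(Fragment(
            h.q_start, h.q_end, div,
            (h.q_end - h.q_start) >= full_length_fraction * L))
    prof.fragments.sort(key=lambda f: (f.q_start, f.q_end))
    return prof


def truncation_call(profile: FamilyProfile, threshold: float = 2.0) -> bool:
    """True when the coverage shape is LINE-typical 5'-truncated
    (truncation ratio >= threshold, inclusive)."""
    if profile.n_fragments == 0:
        raise ValueError("empty profile")
    return profile.truncation_ratio >= threshold


def export_profile_plot(profile: FamilyProfile, path: str | Path,
                        image: bool = False) -> Path:
    """Write the profile TSV (depth section + fragment section); render
    the depth-line / divergence-segment figure alongside when asked.

    The TSV carries one row per consensus position (section 'depth')
    followed by one row per fragment (section 'fragment').
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("section\tpos_or_start\tend\tvalue\tfull_length\n")
        if profile.n_fragments:
            for i, d in enumerate(profile.depth):
                fh.write(f"depth\t{i}\t{i + 1}\t{int(d)}\t\n")
        for f in profile.fragments:
            fh.write(f"fragment\t{f.q_start}\t{f.q_end}\t"
                     f"{f.divergence:.6f}\t{int(f.full_length)}\n")
    if image:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax1 = plt.subplots(figsize=(8, 4))
        ax2 = ax1.twinx()
        for f in profile.fragments:
            ax1.plot([f.q_start, f.q_end], [f.divergence] * 2,
                     color="orange" if f.full_length else "black", lw=1)
        ax2.plot(np.arange(profile.consensus_length), profile.depth,
                 color="tab:blue")
        ax1.set_xlabel("consensus position (bp)")
        ax1.set_ylabel("divergence from consensus")
        ax2.set_ylabel("depth of coverage")
        ax1.set_title(profile.family)
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)
    return path
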