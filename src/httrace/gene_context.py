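"""Gene-context classification and assembly validation of TE insertions.

Each insertion receives exactly one category by priority (coding exon >
5' UTR > 3' UTR > elsewhere in transcript > within 5,000 bp upstream of
the 5' UTR > intergenic; the upstream cutoff is inclusive and
strand-aware), and each is checked for assembly artifacts by locating
its 2-kb flanks in independent comparison assemblies: an insertion
whose flanks land on two different contigs in EVERY comparison assembly
is flagged as a likely mis-join and disregarded from reporting.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel, GenomicInterval, logger
from .similarity_search import (PRESET_DEFAULT, SearchParams, SeedIndex,
                                best_hit, build_index, search)

UPSTREAM_WINDOW = 5000

CATEGORY_PRIORITY = ["coding_exon", "utr5", "utr3", "in_transcript",
                     "upstream_le_5000", "intergenic"]


@dataclass
class InsertionRecord:
    family: str
    interval: GenomicInterval
    category: str
    gene_id: str = ""
    distance_to_5utr: int | None = None
    flank_status: str = "unresolved"
    insertion_size: int = 0

    def __post_init__(self):
        if self.category == "upstream_le_5000":
            if not (self.distance_to_5utr is not None and
                    0 < self.distance_to_5utr <= UPSTREAM_WINDOW):
                raise ValueError("upstream category requires "
                                 f"0 < distance <= {UPSTREAM_WINDOW}")


def _feature_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        for cat, ivs in (("coding_exon", g.cds), ("utr5", g.utr5),
                         ("utr3", g.utr3), ("in_transcript", [g.interval])):
            for iv in ivs:
                trees.setdefault(iv.contig, IntervalTree()).addi(
                    iv.start, iv.end, (cat, g.gene_id))
    return trees


def _upstream_hit(ins: GenomicInterval, gene: GeneModel) -> int | None:
    """Distance from the insertion's nearest edge to the gene's 5' UTR
    start (transcript start when the UTR is unannotated), strand-aware;
    None when the insertion is not on the 5' side or out of range."""
    anchor = gene.utr5_start()
    if anchor is None:
        anchor = gene.tss()
        logger.info("gene %s lacks a 5' UTR: upstream distance measured "
                    "from transcript start", gene.gene_id)
    if ins.contig != gene.interval.contig:
        return None
    if gene.strand != "-":
        dist = anchor - ins.end
    else:
        dist = ins.start - anchor
    if 0 < dist <= UPSTREAM_WINDOW:
        return dist
    return None


def intersect(insertions: list[GenomicInterval],
              genes: list[GeneModel],
              family_of=None) -> list[InsertionRecord]:
    """Assign each insertion its highest-priority gene-context category."""
    trees = _feature_trees(genes)
    records: list[InsertionRecord] = []
    for ins in insertions:
        fam = family_of(ins) if family_of else ins.name
        cat = "intergenic"
        gene_id = ""
        dist: int | None = None
        overlaps = (trees[ins.contig].overlap(ins.start, ins.end)
                    if ins.contig in trees else set())
        found: dict[str, str] = {}
        for ov in overlaps:
            c, gid = ov.data
            if c not in found:
                found[c] = gid
        for c in CATEGORY_PRIORITY[:4]:
            if c in found:
                cat, gene_id = c, found[c]
                break
        if cat == "intergenic":
            best: tuple[int, str] | None = None
            for g in genes:
                d = _upstream_hit(ins, g)
                if d is not None and (best is None or d < best[0]):
                    best = (d, g.gene_id)
            if best is not None:
                cat = "upstream_le_5000"
                dist, gene_id = best
        records.append(InsertionRecord(
            family=fam, interval=ins, category=cat, gene_id=gene_id,
            distance_to_5utr=dist, insertion_size=len(ins)))
    return records


def validate_flanks(insertion: GenomicInterval,
                    self_assembly: dict[str, str],
                    comparison_assemblies: dict[str, dict[str, str]],
                    flank: int = 2000,
                    preset: SearchParams = PRESET_DEFAULT) -> str:
    """Flank-contiguity check against independent assemblies.

    'split' when in every comparison assembly the best hits of the left
    and right flank lie on different contigs; 'contiguous' when in at
    least one comparison both flanks hit a single contig within twice
    the expected span (insertion + both flanks); 'unresolved' otherwise.
    """
    if not comparison_assemblies:
        raise ValueError("need at least one comparison assembly")
    contig_seq = self_assembly[insertion.contig]
    lo = max(0, insertion.start - flank)
    hi = min(len(contig_seq), insertion.end + flank)
    if lo == 0 or hi == len(contig_seq):
        logger.info("flank of %s truncated at contig end", insertion.name)
    left = contig_seq[lo:insertion.start]
    right = contig_seq[insertion.end:hi]
    expected_span = 2 * ((insertion.end - insertion.start) + 2 * flank)
    n_split = 0
    n_contig = 0
    for comp_name, comp in sorted(comparison_assemblies.items()):
        idx = comp if isinstance(comp, SeedIndex) else build_index(
            comp, preset.word_size)
        bl = best_hit(search(("left", left), idx, preset))
        br = best_hit(search(("right", right), idx, preset))
        if bl is None or br is None:
            continue
        if bl.subject_id != br.subject_id:
            n_split += 1
            continue
        span = (max(bl.s_end, br.s_end) - min(bl.s_start, br.s_start))
        if span <= expected_span:
            n_contig += 1
    if n_contig >= 1:
        return "contiguous"
    if n_split == len(comparison_assemblies):
        return "split"
    return "unresolved"


def validate_all(records: list[InsertionRecord],
                 self_assembly: dict[str, str],
                 comparison_assemblies: dict[str, dict[str, str]],
                 flank: int = 2000,
                 preset: SearchParams = PRESET_DEFAULT
                 ) -> list[InsertionRecord]:
    indexed = {name: build_index(comp, preset.word_size)
               for name, comp in comparison_assemblies.items()}
    for r in records:
        r.flank_status = validate_flanks(r.interval, self_assembly,
                                         indexed, flank, preset)
    n_split = sum(r.flank_status == "split" for r in records)
    logger.info("flank validation: %d/%d insertions disregarded as "
                "likely assembly artifacts", n_split, len(records))
    return records


def report(records: list[InsertionRecord], path=None) -> pd.DataFrame:
    """Gene-proximal insertion report (one row per retained record,
    sorted by family then gene); split-status records are excluded and
    counted in the log."""
    kept = [r for r in records if r.flank_status != "split"]
    n_drop = len(records) - len(kept)
    if n_drop:
        logger.info("report: %d split-flank records excluded", n_drop)
    rows = [{
        "gene": r.gene_id, "family": r.family,
        "location": (str(r.distance_to_5utr)
                     if r.category == "upstream_le_5000"
                     else {"coding_exon": "In coding exon",
                           "utr5": "In 5' UTR", "utr3": "In 3' UTR",
                           "in_transcript": "In transcript",
                           "intergenic": "Intergenic"}[r.category]),
        "insertion_size": r.insertion_size,
    } for r in sorted(kept, key=lambda r: (r.family, r.gene_id))]
    df = pd.DataFrame(rows, columns=["gene", "family", "location",
                                     "insertion_size"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
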