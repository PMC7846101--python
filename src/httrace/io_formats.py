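"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open on the plus strand of the
named contig.  GFF3 is read as 1-based inclusive and converted on input;
BED is consumed as-is.  Newick trees used for dating must be rooted and
ultrametric (branch lengths in Ma).
"""
from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("httrace")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[httrace] %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

DNA_ALPHABET = set("ACGTN")

HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "score",
]


@dataclass
class SequenceRecord:
    """A named uppercase DNA sequence."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased).

    Duplicate ids raise; IUPAC ambiguity codes other than N are kept
    verbatim but flagged in the log (alignment scoring treats them as
    never matching).  An empty file returns an empty list with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        extra = set(seq) - DNA_ALPHABET
        if extra:
            logger.warning(
                "record %s contains non-ACGTN codes %s: treated as "
                "mismatch-only in alignment scoring", rec.id, sorted(extra)
            )
        records.append(SequenceRecord(rec.id, seq, rec.description))
    if not records:
        logger.warning("no records read from %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Gene models (GFF3 / BED)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene with its transcripts' merged feature intervals.

    UTRs are taken from explicit five_prime_UTR/three_prime_UTR features
    when present, otherwise derived as exon minus CDS, sided by strand.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.interval.strand

    def tss(self) -> int:
        """Transcript start position (5' end, strand-aware)."""
        return self.interval.start if self.strand != "-" else self.interval.end

    def utr5_start(self) -> int | None:
        """5'-most coordinate of the 5' UTR, or None when unannotated."""
        if not self.utr5:
            return None
        if self.strand != "-":
            return min(i.start for i in self.utr5)
        return max(i.end for i in self.utr5)


def _subtract(intervals: list[tuple[int, int]],
              cut: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set subtraction of sorted interval lists (plain tuples)."""
    out = []
    for s, e in intervals:
        pieces = [(s, e)]
        for cs, ce in cut:
            nxt = []
            for ps, pe in pieces:
                if ce <= ps or cs >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < cs:
                    nxt.append((ps, cs))
                if ce < pe:
                    nxt.append((ce, pe))
            pieces = nxt
        out.extend(pieces)
    return sorted(out)


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels with derived UTRs.

    1-based inclusive GFF coordinates become 0-based half-open. Orphan
    child features (no resolvable gene parent) are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [g.id])[0]
        gene = GeneModel(
            gene_id=gid,
            interval=GenomicInterval(g.seqid, g.start - 1, g.end,
                                     g.strand or ".", gid),
        )
        for ftype, target in (
            ("exon", gene.exons), ("CDS", gene.cds),
            ("five_prime_UTR", gene.utr5), ("three_prime_UTR", gene.utr3),
        ):
            for f in db.children(g, featuretype=ftype):
                target.append(GenomicInterval(
                    f.seqid, f.start - 1, f.end, f.strand or ".", gid))
        if not gene.utr5 and not gene.utr3 and gene.cds and gene.exons:
            ex = sorted((i.start, i.end) for i in gene.exons)
            cd = sorted((i.start, i.end) for i in gene.cds)
            cds_lo = min(s for s, _ in cd)
            cds_hi = max(e for _, e in cd)
            for s, e in _subtract(ex, cd):
                if e <= cds_lo:
                    side = "utr5" if gene.strand != "-" else "utr3"
                elif s >= cds_hi:
                    side = "utr3" if gene.strand != "-" else "utr5"
                else:
                    continue  # internal non-CDS exon chunk (intron retention)
                getattr(gene, side).append(
                    GenomicInterval(g.seqid, s, e, gene.strand, gid))
        genes.append(gene)
    # orphan check: top-level exons/CDS without a gene ancestor
    n_orphan = 0
    for ftype in ("exon", "CDS"):
        for f in db.features_of_type(ftype):
            if not any(True for _ in db.parents(f)):
                n_orphan += 1
    if n_orphan:
        logger.warning("%d orphan child features skipped", n_orphan)
    return genes


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (3-6 columns; already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t"
                     f"{iv.strand}\n")


# ---------------------------------------------------------------------------
# Dated trees
# ---------------------------------------------------------------------------

class DatedTree:
    """Rooted ultrametric host phylogeny with node ages in Ma.

    Node ids: leaf nodes use their taxon label; internal nodes use the
    '|'-joined sorted labels of their descendant tips (stable across
    serialisation).  The tree wraps a dendropy Tree.
    """

    ULTRAMETRIC_TOL = 1e-6

    def __init__(self, tree: dendropy.Tree, require_ultrametric: bool = True):
        self.tree = tree
        if len(tree.seed_node.child_nodes()) > 2:
            raise ValueError("tree is unrooted (basal polytomy); dating "
                             "requires a rooted tree")
        self._ages: dict[str, float] = {}
        self._node_by_id: dict = {}
        self._parent: dict[str, str | None] = {}
        # node depth from root, then age = height above tips
        depths = {}
        for nd in tree.preorder_node_iter():
            d = 0.0 if nd.parent_node is None else (
                depths[nd.parent_node] + (nd.edge.length or 0.0))
            depths[nd] = d
        tip_depths = [depths[lf] for lf in tree.leaf_node_iter()]
        span = max(tip_depths)
        if require_ultrametric and span > 0:
            if max(tip_depths) - min(tip_depths) > self.ULTRAMETRIC_TOL * max(
                    1.0, span):
                raise ValueError(
                    "tree is not ultrametric; cannot be used for dating")
        for nd in tree.postorder_node_iter():
            nid = self._make_id(nd)
            nd._httrace_id = nid
            self._node_by_id[nid] = nd
            self._ages[nid] = max(0.0, span - depths[nd])
        for nd in tree.preorder_node_iter():
            self._parent[nd._httrace_id] = (
                nd.parent_node._httrace_id if nd.parent_node else None)

    @staticmethod
    def _make_id(nd) -> str:
        if nd.is_leaf():
            return nd.taxon.label.replace(" ", "_")
        tips = sorted(
            lf.taxon.label.replace(" ", "_") for lf in nd.leaf_iter())
        return "|".join(tips)

    @classmethod
    def from_newick(cls, newick: str, **kw) -> "DatedTree":
        t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls(t, **kw)

    @property
    def root_id(self) -> str:
        return self.tree.seed_node._httrace_id

    @property
    def root_age(self) -> float:
        return self._ages[self.root_id]

    def tips(self) -> list[str]:
        return [lf.taxon.label.replace(" ", "_")
                for lf in self.tree.leaf_node_iter()]

    def age(self, node_id: str) -> float:
        return self._ages[node_id]

    def parent(self, node_id: str) -> str | None:
        return self._parent[node_id]

    def clade_tips(self, node_id: str) -> list[str]:
        nd = self._node_by_id[node_id]
        if nd.is_leaf():
            return [node_id]
        return sorted(
            lf.taxon.label.replace(" ", "_") for lf in nd.leaf_iter())

    def node_ids(self) -> list[str]:
        return [nd._httrace_id for nd in self.tree.preorder_node_iter()]

    def children(self, node_id: str) -> list[str]:
        return [c._httrace_id
                for c in self._node_by_id[node_id].child_nodes()]

    def branch_span(self, node_id: str) -> tuple[float, float]:
        """(crown age, stem age) of the branch subtending node_id."""
        crown = self._ages[node_id]
        pid = self._parent[node_id]
        stem = self._ages[pid] if pid is not None else crown
        return crown, stem


def read_newick_dated(path: str | Path,
                      require_ultrametric: bool = True) -> DatedTree:
    t = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return DatedTree(t, require_ultrametric=require_ultrametric)


# ---------------------------------------------------------------------------
# 12-column tabular hit dialect
# ---------------------------------------------------------------------------

def hits_to_frame(hits) -> pd.DataFrame:
    """SimilarityHit list -> 12-column table (1-based inclusive coords,
    minus-strand hits encoded as sstart > send, as in the dialect)."""
    rows = []
    for h in hits:
        if h.strand == "+":
            ss, se = h.s_start + 1, h.s_end
        else:
            ss, se = h.s_end, h.s_start + 1
        rows.append((h.query_id, h.subject_id, round(h.percent_identity, 3),
                     h.aln_length, h.mismatches, h.gap_opens,
                     h.q_start + 1, h.q_end, ss, se,
                     h.evalue if h.evalue is not None else 0.0, h.score))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def frame_to_hits(df: pd.DataFrame):
    from .similarity_search import SimilarityHit

    hits = []
    for r in df.itertuples(index=False):
        ss, se = int(r.s_start), int(r.s_end)
        strand = "+" if ss <= se else "-"
        s_lo, s_hi = (ss - 1, se) if strand == "+" else (se - 1, ss)
        hits.append(SimilarityHit(
            query_id=r.query_id, subject_id=r.subject_id,
            q_start=int(r.q_start) - 1, q_end=int(r.q_end),
            s_start=s_lo, s_end=s_hi, strand=strand,
            score=int(r.score), percent_identity=float(r.percent_identity),
            aln_length=int(r.aln_length), mismatches=int(r.mismatches),
            gap_opens=int(r.gap_opens), evalue=float(r.evalue)))
    return hits


def write_hits(hits, path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False, header=False)


def read_hits(path: str | Path):
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, header=None)
    return frame_to_hits(df)


# ---------------------------------------------------------------------------
# Config and run manifest
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


class RunManifest:
    """Plain-text log of stage parameters and record counts."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self.entries: list[str] = []

    def log(self, stage: str, **params) -> None:
        line = f"{stage}\t" + "\t".join(f"{k}={v}" for k, v in params.items())
        self.entries.append(line)
        logger.info("%s", line)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(line + "\n")
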