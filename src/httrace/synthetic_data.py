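"""Synthetic genome panels with vertical and horizontally transferred TEs.

Generates host genomes diverging along a dated tree under Jukes–Cantor
substitution at a stated per-year rate, with TE families either
inserted in the root genome (vertical) or injected on a named branch at
a stated time (horizontal), per-copy 5' truncation (retained 3'
fraction ~ Uniform(0.05, 1)) and post-insertion divergence, plus exact
ground-truth logs: per-copy coordinates, the per-family presence matrix
and the event list.  This is the stand-in for real assemblies in every
recovery test: the generator's defaults define the study conditions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import DatedTree, SequenceRecord, logger
from .te_classify import DomainHit, TEConsensus
from .align import global_identity

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TEFamilySpec:
    """Parameters of one simulated TE family.

    ``mode`` is "vertical" (inserted in the root genome, hence present
    in every descendant) or "htt" (injected on ``origin_branch`` — a
    child-node id of the dated tree — at ``origin_time`` Ma).  Two
    independent transfers of one family are expressed by passing lists
    for origin_branch/origin_time.
    """

    name: str
    length: int = 3000
    domain_layout: list[tuple[str, int, int]] = field(default_factory=list)
    mode: str = "vertical"
    origin_branch: str | list[str] | None = None
    origin_time: float | list[float] | None = None
    copy_number_per_genome: int = 5
    divergence_d: float = 0.0
    truncation_p: float = 0.5
    indel_rate: float = 0.0
    guarantee_full_length: bool = True
    consensus: str = ""

    def __post_init__(self):
        if self.length < 800:
            raise ValueError(
                f"family length {self.length} below the 800-bp admission "
                "rule for classifiable consensi")
        if not (0.0 <= self.divergence_d <= 0.75):
            raise ValueError("divergence_d must be in [0, 0.75]")
        if self.mode not in {"vertical", "htt"}:
            raise ValueError("mode must be 'vertical' or 'htt'")
        if self.mode == "htt" and (self.origin_branch is None or
                                   self.origin_time is None):
            raise ValueError("htt families need origin_branch/origin_time")

    @property
    def events(self) -> list[tuple[str, float]]:
        if self.mode != "htt":
            return []
        branches = (self.origin_branch if isinstance(self.origin_branch, list)
                    else [self.origin_branch])
        times = (self.origin_time if isinstance(self.origin_time, list)
                 else [self.origin_time])
        if len(branches) != len(times):
            raise ValueError("origin_branch/origin_time length mismatch")
        return list(zip(branches, times))


@dataclass
class CopyRecord:
    """Ground truth for one simulated TE copy."""

    family: str
    contig: str
    start: int
    end: int
    strand: str
    truncation_fraction: float  # retained 3' fraction (1.0 = full length)
    true_divergence: float


@dataclass
class GroundTruth:
    copies: dict[str, list[CopyRecord]]  # species -> records
    presence: dict[str, dict[str, bool]]  # family -> species -> present
    events: list[tuple[str, str, float]]  # (family, branch, time Ma)

    def presence_from_events(self, tree: DatedTree,
                             specs: list[TEFamilySpec]
                             ) -> dict[str, dict[str, bool]]:
        """No-loss propagation of the event list down the tree — the
        independent reconstruction the truth matrix must equal."""
        tips = tree.tips()
        out: dict[str, dict[str, bool]] = {}
        for spec in specs:
            row = {t: spec.mode == "vertical" for t in tips}
            for fam, branch, _t in self.events:
                if fam != spec.name:
                    continue
                for t in tree.clade_tips(branch):
                    row[t] = True
            out[spec.name] = row
        return out


def _default_domain_layout(length: int) -> list[tuple[str, int, int]]:
    return [("EN", int(0.05 * length), int(0.35 * length)),
            ("RT", int(0.45 * length), int(0.85 * length))]


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.41) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = BASES[rng.choice(4, size=n, p=p)]
    return arr.tobytes().decode("ascii")


def make_te_library(n_families: int, seed: int, length: int = 3000,
                    max_identity: float = 60.0, max_draws: int = 1000,
                    **spec_kw) -> list[TEConsensus]:
    """Draw TE family consensi pairwise < ``max_identity``% identical
    (rejection sampling) with EN+RT marker intervals."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if length < 800:
        raise ValueError("family length below the 800-bp admission rule")
    rng = np.random.default_rng(seed)
    out: list[TEConsensus] = []
    for i in range(n_families):
        for _draw in range(max_draws):
            seq = random_dna(length, rng)
            if all(global_identity(seq, c.seq) < max_identity for c in out):
                break
        else:
            raise RuntimeError(
                f"could not draw family {i} below {max_identity}% identity "
                f"in {max_draws} attempts")
        name = f"TEfam{i + 1}"
        layout = _default_domain_layout(length)
        hits = [DomainHit(name, dom, 1.0, s, e) for dom, s, e in layout]
        out.append(TEConsensus(name, seq, "LINE", hits))
    return out


def library_specs(library: list[TEConsensus], **kw) -> list[TEFamilySpec]:
    return [TEFamilySpec(name=c.name, length=len(c.seq),
                         domain_layout=[(h.domain_name, h.start, h.end)
                                        for h in c.domain_hits],
                         consensus=c.seq, **kw)
            for c in library]


def domain_truth_table(library: list[TEConsensus]) -> list[DomainHit]:
    return [h for c in library for h in c.domain_hits]


def mutate_sequence(seq: str, d: float, seed_or_rng) -> str:
    """Jukes–Cantor substitution: each site substituted with probability
    p = (3/4)(1 - exp(-4d/3)), uniformly among the other three bases.
    Non-ACGT characters are left untouched."""
    if d < 0:
        raise ValueError("d must be >= 0")
    if d == 0 or not seq:
        return seq
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    code = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    hit = (rng.random(arr.shape[0]) < p) & (code >= 0) & (code < 4)
    shift = rng.integers(1, 4, size=arr.shape[0])
    newcode = (code + shift) % 4
    arr[hit] = BASES[newcode[hit]]
    return arr.tobytes().decode("ascii")


def _truncate(consensus: str, rng: np.random.Generator,
              truncation_p: float) -> tuple[str, float]:
    """LINE-style 5' truncation: with probability truncation_p keep only
    a 3' fraction f ~ Uniform(0.05, 1)."""
    if rng.random() < truncation_p:
        f = rng.uniform(0.05, 1.0)
        n_keep = max(1, int(round(f * len(consensus))))
        return consensus[-n_keep:], n_keep / len(consensus)
    return consensus, 1.0


def insert_copies(genome: str, family: TEFamilySpec, n: int,
                  seed_or_rng, contig: str = "chr1",
                  existing: list[CopyRecord] | None = None
                  ) -> tuple[str, list[CopyRecord]]:
    """Insert n copies of a family into a genome at random non-overlapping
    positions, with truncation, strand choice and per-copy divergence.

    Insertion points avoid intervals in ``existing`` (earlier copies);
    coordinates of ``existing`` records are shifted in place.
    """
    from .align import revcomp

    if n == 0:
        return genome, []
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if len(genome) < 2 * n * family.length:
        raise ValueError("insufficient genome space for requested copies")
    consensus = family.consensus
    if not consensus:
        raise ValueError(f"family {family.name} has no consensus sequence")
    existing = existing if existing is not None else []
    forbidden = sorted((r.start, r.end) for r in existing
                       if r.contig == contig)

    def in_forbidden(p: int) -> bool:
        return any(s < p < e for s, e in forbidden)

    points = []
    attempts = 0
    while len(points) < n:
        p = int(rng.integers(0, len(genome) + 1))
        if in_forbidden(p):
            attempts += 1
            if attempts > 1000 * n:
                raise ValueError("could not place copies outside existing "
                                 "insertions")
            continue
        points.append(p)
    points.sort()

    pieces = []
    records: list[CopyRecord] = []
    prev = 0
    offset = 0
    for i, p in enumerate(points):
        frag, frac = ((consensus, 1.0)
                      if (i == 0 and family.guarantee_full_length)
                      else _truncate(consensus, rng, family.truncation_p))
        frag = mutate_sequence(frag, family.divergence_d, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        pieces.append(genome[prev:p])
        pieces.append(frag)
        start = p + offset
        records.append(CopyRecord(family.name, contig, start,
                                  start + len(frag), strand, frac,
                                  family.divergence_d))
        offset += len(frag)
        prev = p
    pieces.append(genome[prev:])
    # shift pre-existing records past each insertion point
    for r in existing:
        if r.contig != contig:
            continue
        shift = 0
        for p, rec in zip(points, records):
            if p <= r.start:
                shift += rec.end - rec.start
        r.start += shift
        r.end += shift
    return "".join(pieces), records


@dataclass
class HostParams:
    genome_length: int = 40000
    gc: float = 0.41
    rate_per_site_per_year: float = 1.25e-9  # 1.25e-8 / 10-yr generation
    contig: str = "chr1"


@dataclass
class PanelResult:
    genomes: dict[str, SequenceRecord]
    truth: GroundTruth
    tree: DatedTree
    specs: list[TEFamilySpec]


def simulate_panel(tree: DatedTree, family_specs: list[TEFamilySpec],
                   host_params: HostParams | None = None,
                   seed: int = 0) -> PanelResult:
    """Evolve a genome panel along a dated tree with vertical + HTT TEs.

    Host backgrounds (and all resident TE copies) accumulate JC
    substitutions at ``rate_per_site_per_year`` x branch length; HTT
    families are injected on their origin branch at their origin time,
    so copies at the tips carry divergence d = rate x age plus any
    spec-level initial divergence.
    """
    hp = host_params or HostParams()
    rng = np.random.default_rng(seed)
    rate_ma = hp.rate_per_site_per_year * 1e6  # substitutions/site/Ma

    for spec in family_specs:
        for branch, t in spec.events:
            if branch == tree.root_id:
                raise ValueError("htt events must lie on a non-root branch; "
                                 "use mode='vertical' for root presence")
            crown, stem = tree.branch_span(branch)
            if not crown <= t <= stem:
                raise ValueError(
                    f"event time {t} Ma outside branch {branch} span "
                    f"[{crown}, {stem}]")

    root_genome = random_dna(hp.genome_length, rng, hp.gc)
    root_records: list[CopyRecord] = []
    for spec in family_specs:
        if spec.mode == "vertical":
            root_genome, recs = insert_copies(
                root_genome, spec, spec.copy_number_per_genome, rng,
                hp.contig, existing=root_records)
            root_records.extend(recs)

    genomes: dict[str, SequenceRecord] = {}
    copies: dict[str, list[CopyRecord]] = {}
    events = [(spec.name, branch, t)
              for spec in family_specs for branch, t in spec.events]

    def descend(node_id: str, genome: str, records: list[CopyRecord]):
        for child in tree.children(node_id):
            g = genome
            recs = [replace(r) for r in records]
            age_hi = tree.age(node_id)
            age_lo = tree.age(child)
            # branch events, oldest first
            branch_events = sorted(
                [(spec, t) for spec in family_specs
                 for b, t in spec.events if b == child],
                key=lambda x: -x[1])
            cur = age_hi
            for spec, t in branch_events:
                dd = rate_ma * (cur - t)
                if dd > 0:
                    g = mutate_sequence(g, dd, rng)
                    for r in recs:
                        r.true_divergence += dd
                g, new = insert_copies(g, spec,
                                       spec.copy_number_per_genome, rng,
                                       hp.contig, existing=recs)
                recs.extend(new)
                cur = t
            dd = rate_ma * (cur - age_lo)
            if dd > 0:
                g = mutate_sequence(g, dd, rng)
                for r in recs:
                    r.true_divergence += dd
            if not tree.children(child):  # tip
                genomes[child] = SequenceRecord(hp.contig, g,
                                                description=child)
                copies[child] = recs
            else:
                descend(child, g, recs)

    root = tree.root_id
    if not tree.children(root):  # single-tip tree
        genomes[root] = SequenceRecord(hp.contig, root_genome)
        copies[root] = root_records
    else:
        descend(root, root_genome, root_records)

    presence = {
        spec.name: {sp: any(r.family == spec.name for r in recs)
                    for sp, recs in copies.items()}
        for spec in family_specs
    }
    truth = GroundTruth(copies=copies, presence=presence, events=events)
    logger.info("simulated panel: %d species, %d families, seed %d",
                len(genomes), len(family_specs), seed)
    return PanelResult(genomes=genomes, truth=truth, tree=tree,
                       specs=family_specs)


# ---------------------------------------------------------------------------
# Contig-split fixture for flank validation
# ---------------------------------------------------------------------------

@dataclass
class FlankFixture:
    self_assembly: dict[str, str]
    comparisons: dict[str, dict[str, str]]  # species -> contig -> seq
    insertions: list  # GenomicInterval on the self assembly
    split_names: set[str]  # truth: insertions engineered onto breaks


def contig_split_fixture(n_insertions: int = 23, n_split: int = 8,
                         seed: int = 0, flank: int = 2000,
                         insertion_size: int = 300,
                         comparison_divergence: float = 0.02
                         ) -> FlankFixture:
    """Assembly-artifact fixture: gene-proximal insertions whose 2-kb
    flanks are either contiguous in both comparison assemblies or placed
    in the middle of two different contigs in both (engineered breaks).
    """
    from .io_formats import GenomicInterval

    rng = np.random.default_rng(seed)
    split_idx = set(rng.choice(n_insertions, size=n_split, replace=False))
    self_asm: dict[str, str] = {}
    comps: dict[str, dict[str, str]] = {"comparisonA": {}, "comparisonB": {}}
    insertions = []
    split_names = set()
    te = random_dna(insertion_size, rng)
    for i in range(n_insertions):
        name = f"ins{i + 1}"
        fl = random_dna(flank, rng)
        fr = random_dna(flank, rng)
        pad = random_dna(500, rng)
        contig = f"self_ctg{i + 1}"
        self_asm[contig] = pad + fl + te + fr + pad
        start = len(pad) + flank
        insertions.append(GenomicInterval(contig, start,
                                          start + insertion_size,
                                          "+", name))
        for comp in comps.values():
            cl = mutate_sequence(fl, comparison_divergence, rng)
            cr = mutate_sequence(fr, comparison_divergence, rng)
            if i in split_idx:
                comp[f"{contig}_a"] = random_dna(400, rng) + cl + \
                    random_dna(400, rng)
                comp[f"{contig}_b"] = random_dna(400, rng) + cr + \
                    random_dna(400, rng)
            else:
                comp[contig] = random_dna(400, rng) + cl + cr + \
                    random_dna(400, rng)
        if i in split_idx:
            split_names.add(name)
    return FlankFixture(self_asm, comps, insertions, split_names)
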