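"""TE-versus-host phylogeny discordance.

Horizontally transferred elements betray themselves in trees: a TE from
a snake that clusters with fish TEs rather than with the snake's
vertically inherited elements.  This module filters TE sequences to
structurally intact copies (>= 80% of both EN and RT domains), trims a
nucleotide alignment to well-occupied blocks, builds a neighbor-joining
tree from pairwise distances, and quantifies discordance as the
normalized Robinson–Foulds distance between the TE tree's induced host
topology and the host species tree, plus the nearest-neighbor host of
each tip of interest.
"""
from __future__ import annotations

import dendropy
import numpy as np
from dendropy.calculate import treecompare
from skbio import DistanceMatrix
from skbio.tree import nj

from .curation import MultipleAlignment, _row_pairwise_identity
from .dating_events import jc_correct
from .io_formats import logger
from .te_classify import DomainHit


def filter_intact(seqs: dict[str, str], domain_hits: list[DomainHit],
                  min_coverage: float = 0.8,
                  domains: tuple[str, str] = ("EN", "RT")) -> dict[str, str]:
    """Keep only sequences carrying >= ``min_coverage`` of every listed
    domain (default: both endonuclease and reverse transcriptase)."""
    cov: dict[str, dict[str, float]] = {}
    for h in domain_hits:
        cov.setdefault(h.consensus_id, {})
        cov[h.consensus_id][h.domain_name] = max(
            cov[h.consensus_id].get(h.domain_name, 0.0), h.coverage_fraction)
    kept = {}
    for name, seq in seqs.items():
        c = cov.get(name, {})
        if all(c.get(d, 0.0) >= min_coverage for d in domains):
            kept[name] = seq
        else:
            logger.info("filter_intact: removed %s (coverage %s)", name, c)
    if not kept:
        raise ValueError("no intact sequences after domain filtering")
    return kept


def block_trim(alignment: MultipleAlignment, min_occupancy: float = 0.5,
               min_run: int = 5) -> MultipleAlignment:
    """Relaxed block trimming: keep columns with non-gap occupancy >=
    ``min_occupancy``, then keep only runs of >= ``min_run`` consecutive
    kept columns."""
    if alignment.n_rows < 4:
        raise ValueError("block_trim expects >= 4 rows")
    n = alignment.n_rows
    occ_ok = [sum(1 for r in alignment.rows if r[j] != "-") / n >=
              min_occupancy for j in range(alignment.n_cols)]
    cols: list[int] = []
    run: list[int] = []
    for j, ok in enumerate(occ_ok):
        if ok:
            run.append(j)
        else:
            if len(run) >= min_run:
                cols.extend(run)
            run = []
    if len(run) >= min_run:
        cols.extend(run)
    if not cols:
        raise ValueError("block_trim removed every column")
    return alignment.take_columns(cols)


def alignment_distance_matrix(alignment: MultipleAlignment,
                              distance: str = "p") -> DistanceMatrix:
    """Pairwise distances over shared non-gap columns ('p' or 'jc')."""
    n = alignment.n_rows
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = 1.0 - _row_pairwise_identity(alignment.rows[i],
                                             alignment.rows[j]) / 100.0
            d = jc_correct(p) if distance == "jc" else p
            if not np.isfinite(d):
                d = 5.0  # saturated pair: large finite distance
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=list(alignment.names))


def nj_from_matrix(ids: list[str], matrix: np.ndarray) -> str:
    """Neighbor-joining Newick from a precomputed distance matrix
    (negative branch lengths clamped to zero)."""
    order = np.argsort(ids)
    dm = DistanceMatrix(matrix[np.ix_(order, order)],
                        ids=[ids[i] for i in order])
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def nj_tree(alignment: MultipleAlignment, distance: str = "p") -> str:
    """Neighbor-joining tree (Newick) from alignment distances; input
    order cannot matter because rows are sorted by name first, and
    negative branch lengths are clamped to zero."""
    if alignment.n_rows < 4:
        raise ValueError("nj_tree expects >= 4 sequences")
    order = sorted(range(alignment.n_rows),
                   key=lambda i: alignment.names[i])
    ali = MultipleAlignment([alignment.names[i] for i in order],
                            [alignment.rows[i] for i in order])
    dm = alignment_distance_matrix(ali, distance)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def _patristic(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            out[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    return out


def normalized_rf(newick_a: str, newick_b: str) -> float:
    """Robinson–Foulds distance over unrooted bipartitions, normalized
    by the maximum 2(n-3) for the shared taxon set."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", preserve_underscores=True,
                           taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", preserve_underscores=True,
                           taxon_namespace=tns)
    labels_a = {lf.taxon.label for lf in ta.leaf_node_iter()}
    labels_b = {lf.taxon.label for lf in tb.leaf_node_iter()}
    shared = labels_a & labels_b
    if len(shared) < 4:
        raise ValueError("need >= 4 shared taxa for RF")
    ta.retain_taxa_with_labels(shared)
    tb.retain_taxa_with_labels(shared)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    rf = treecompare.symmetric_difference(ta, tb)
    return rf / (2.0 * (len(shared) - 3))


def discordance_stat(te_tree_newick: str, species_tree_newick: str,
                     tip_to_host: dict[str, str],
                     focal_tips: list[str] | None = None
                     ) -> tuple[float, dict[str, str]]:
    """(normalized RF of the induced host topology vs the species tree,
    nearest-neighbor host per focal TE tip).

    Hosts with several TE tips are collapsed to the tip closest to the
    host group's centroid (minimal summed patristic distance to the
    other tips of the same host) before the RF comparison.
    """
    te = dendropy.Tree.get(data=te_tree_newick, schema="newick", preserve_underscores=True)
    missing = [lf.taxon.label for lf in te.leaf_node_iter()
               if lf.taxon.label not in tip_to_host]
    if missing:
        raise ValueError(f"TE tips without a host mapping: {missing}")
    dist = _patristic(te)
    # nearest-neighbor host per focal tip (closest non-self tip)
    tips = [lf.taxon.label for lf in te.leaf_node_iter()]
    nn: dict[str, str] = {}
    for t in (focal_tips or tips):
        others = [o for o in tips if o != t]
        closest = min(others, key=lambda o: (dist[(t, o)], o))
        nn[t] = tip_to_host[closest]
    # collapse duplicate-host tips: keep centroid-most representative
    by_host: dict[str, list[str]] = {}
    for t in tips:
        by_host.setdefault(tip_to_host[t], []).append(t)
    keep: dict[str, str] = {}
    for host, ts in by_host.items():
        if len(ts) == 1:
            keep[ts[0]] = host
        else:
            rep = min(ts, key=lambda t: (sum(dist[(t, o)] for o in ts
                                             if o != t), t))
            keep[rep] = host
    te.retain_taxa_with_labels(list(keep))
    for lf in te.leaf_node_iter():
        lf.taxon.label = keep[lf.taxon.label]
    rf = normalized_rf(str(te), species_tree_newick)
    return rf, nn
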