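# httrace

Discovery and characterisation of **horizontal transposon transfer
(HTT)** from genome assembly panels, built around the sea-snake LINE
invasion analysis: curate LINE consensus sequences, screen genome and
transcriptome panels for presence/absence, profile copy truncation and
divergence, date insertions with a substitution-rate clock, infer the
minimal set of transfer events on a dated host phylogeny, and flag
insertions in or near genes.

## Who this is for

Researchers with (i) one or more genome assemblies of a focal lineage,
(ii) seed repeat consensus sequences from an ab initio annotator, and
(iii) a dated host phylogeny, who want to ask: *which repeat families
arrived horizontally, when, and what might they have landed on?*
Everything runs from Python or the `httrace` command line; a built-in
simulator generates genome panels with known vertical + horizontal TE
histories, so every stage of the pipeline is testable against ground
truth.

## The methods in brief

**Three diagnostics of HTT** drive the pipeline: a patchy taxonomic
distribution among close relatives, excess sequence identity across
distant hosts, and discordance between TE and host phylogenies.

*Presence calls.* A family is called in a genome from local-alignment
evidence (built-in seed-and-extend engine with affine-gap extension;
`default` megablast-like and `relaxed` cross-phylum presets):
`present_similar` if some hit ≥ 1,000 bp reaches 75% identity,
`present_divergent` if more than one ≥ 1 kb locus exists below 75%,
otherwise `absent`.

*Consensus curation (SEAT).* Iterated *search, extend, align, trim*:
take the 25 best hits over 1 kb, extend ±1,000 bp, build a center-star
multiple alignment, trim columns that fail occupancy or majority
agreement, call a majority consensus, repeat to convergence.
Subfamilies are split by average-linkage clustering of aligned copies
at a 94% identity cut.

*Two clocks.* The divergence clock converts mean substitutions per
site d̄ of a family's copies against its consensus into an age

    T = d̄ / r × g        (r = 1.25×10⁻⁸ subst/site/generation,
                           g = 10 yr/generation by default)

The branch clock is no-loss gain parsimony on the dated host tree: the
minimal event set is one gain per maximal all-present clade, dated to
the [crown, stem] interval of its branch. Events are flagged
consistent when the two clocks' intervals overlap.

*Gene context.* Insertions are categorised (coding exon > 5′ UTR > 3′
UTR > in transcript > ≤ 5,000 bp upstream of the 5′ UTR > intergenic,
strand-aware) and validated against independent assemblies: an
insertion whose 2-kb flanks land on two different contigs in every
comparison assembly is disregarded as a likely assembly artifact.

## Worked example

Infer transfer events from the built-in sea-snake survey (seven LINE
subfamilies across seven elapid genomes):

```python
>>> from httrace.datasets import elapid_tree, sea_snake_presence_matrix
>>> from httrace.dating_events import infer_gain_events, count_events
>>> tree = elapid_tree()
>>> matrix = sea_snake_presence_matrix()
>>> count_events(matrix, tree)
9
>>> for e in infer_gain_events(matrix["Rex1-Snek_1H2"], tree, "Rex1-Snek_1H2"):
...     print(e.gain_branch, e.branch_interval)
Hydrophis_melanocephalus (0.0, 8.0)
Aipysurus_laevis (0.0, 5.0)
```

Nine events: one each for the five families whose presence forms a
single clade, and two each for Rex1-Snek_1H2 and Rex1-Snek_1H3, which
occur in *Aipysurus* and *Hydrophis* but not in *Emydocephalus* that
sits between them — two independent invasions of sister sea-snake
lineages, dated by the branch intervals printed above (Ma).

Dating the same kind of event from sequence divergence on a simulated
panel:

```python
>>> from httrace.io_formats import DatedTree
>>> from httrace.synthetic_data import (make_te_library, TEFamilySpec,
...                                     simulate_panel, HostParams)
>>> from httrace.dating_events import copy_divergence, insertion_time
>>> tree = DatedTree.from_newick("(R:12,S:12):0;")
>>> lib = make_te_library(1, seed=21, length=3000)
>>> spec = TEFamilySpec(name=lib[0].name, consensus=lib[0].seq, length=3000,
...                     mode="htt", origin_branch="R", origin_time=10.0,
...                     copy_number_per_genome=50)
>>> panel = simulate_panel(tree, [spec], HostParams(genome_length=350_000),
...                        seed=33)
>>> d_mean, d_sd, n = copy_divergence(lib[0], panel.genomes["R"])
>>> insertion_time(d_mean, d_sd)[0]   # Ma; simulated truth is 10 Ma
10.09...
```

The same steps are available from the shell: `httrace simulate`,
`httrace search`, `httrace classify`, `httrace curate`,
`httrace screen`, `httrace events`, `httrace profile`,
`httrace genes`, `httrace discord`.

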