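# genecontent

Ancestral gene-content reconstruction for comparative genomics: infer which
gene homology groups (HGs) were present in the ancestors on a species tree,
which originated at each ancestor, which were lost — and which novelties
became indispensable across an entire clade.

The package is aimed at evolutionary genomicists asking questions such as
"how much genomic novelty accompanied the origin of animals?". It takes
all-vs-all protein similarity hits (BLAST tabular output), clusters them
into homology groups, projects the HG × species occupancy matrix onto a
user-supplied rooted species tree, and classifies every node's inventory.

## The model

**Homology groups.** All-vs-all BLAST hits with e-value ≤ 10⁻⁵ define a
weighted undirected graph over proteins, with edge weight
w = min(−log₁₀ e, cap) and reciprocal hits combined by maximum. Markov
clustering (MCL) partitions the graph: iterate expansion (M ← M²) and
inflation (entrywise power I = 2.0 followed by column renormalisation),
prune negligible entries, and read clusters off the converged attractor
structure. Each resulting cluster is one HG; singletons count.

**Dollo classification.** An HG arises exactly once and can only be lost
thereafter. Writing S(H) for the possessor species of HG H and L(N) for the
leaves of node N:

* *Ancestral at N* — H is carried by the ancestor at N. Default
  (`two_lineage`) rule: S(H) intersects ≥ 2 child subtrees of N, i.e.
  presence is witnessed independently by two main lineages. The `dollo`
  rule instead places N on the minimal-loss reconstruction
  (S(H) ∩ L(N) ≠ ∅, and S(H) spans ≥ 2 children of N or extends outside N).
* *Novel at N* — H originated at N: S(H) spans ≥ 2 child subtrees and
  S(H) ⊆ L(N). Equivalently, N = MRCA(S(H)); every possessed HG is novel
  at exactly one node.
* *Core* (of the ancestral or novel set at N) — H is absent from at most
  one member of the clade (tolerating one incomplete genome) while every
  child lineage retains a possessor.
* *Lost at N* — S(H) ∩ L(N) = ∅, yet a sibling subtree and a species
  outside N's parent both possess H, so the parent's ancestor carried it.

**Queries.** Any boolean conjunction of clade quantifiers runs directly
against the occupancy matrix, e.g.
`all(Metazoa) & none(!Metazoa)` (animal-specific HGs kept by every animal) or
`any(Homo) & at_least(Hexapoda,2) & none(Lophotrochozoa)`.

**Synthetic ground truth.** A gene birth–death simulator (Poisson origins
per branch, independent per-branch whole-subtree losses, optional
per-genome missingness) and a planted-partition similarity-graph generator
provide data with known histories for every stage.

## Worked example

```bash
cat > tree.nwk <<'NWK'
(((Amphimedon,Sycon)Porifera,((Nematostella,Hydra)Cnidaria,(Drosophila,Homo)Bilateria)Planulozoa)Metazoa,(Monosiga,Salpingoeca)Choanoflagellata)Choanozoa;
NWK
genecontent simulate --tree tree.nwk --origins-per-branch 40 --loss-prob 0.15 \
    --missing-rate 0.05 --seed 11 --out-occupancy occ.tsv --out-truth truth.tsv
genecontent classify --tree tree.nwk --occupancy occ.tsv --out out
```

which prints (trimmed to the first columns):

```
node              n_ancestral  n_novel  n_novel_core  n_lost  novel_fraction_pct
Choanozoa         18           18       4             0       100.0
Metazoa           59           47       20            0       79.7
Porifera          66           27       27            4       40.9
Planulozoa        72           32       28            2       44.4
Cnidaria          87           35       35            14      40.2
Bilateria         79           30       30            9       38.0
Choanoflagellata  37           26       26            0       70.3
```

Each row is one internal node: how many HGs its ancestor carried
(`n_ancestral`), how many originated there (`n_novel`), how many of those
are retained by (almost) every descendant (`n_novel_core`), how many were
lost on the branch leading to it (`n_lost`), and the novel fraction of the
ancestral repertoire. On real data the same table is produced from BLAST
hits via `genecontent run --config pipeline.yaml` (clustering → occupancy →
classification), and specific gene lists come from queries:

```bash
genecontent query --tree tree.nwk --occupancy occ.tsv \
    --expr 'all(Metazoa) & none(!Metazoa)'
```

Alternative rootings (e.g. ctenophores rather than sponges as the sister
group of other animals) are explored simply by supplying a different
Newick tree.

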