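# xdc — exon–domain concordance

Do the boundaries of exons align with the boundaries of protein domains —
and of intrinsically disordered regions — more often than chance would
predict? If exon shuffling contributed to protein evolution, splice
junctions should fall near domain edges more often than a uniform null
allows, and more so in recently evolved proteins. `xdc` is a pipeline for
measuring exactly that, per genome, from standard annotation files, with a
built-in synthetic-genome generator so every stage can be validated
against planted ground truth without any downloads.

## The statistic

For each protein, every domain assignment `(start, end)` defines a
*boundary window*: the union of `{start−1, start, start+1}` and
`{end−1, end, end+1}` clipped to the sequence — six residues for an
interior domain. Each internal splice junction (excluding the start of the
first and end of the last exon) is mapped to a residue position: a
junction after spliced-CDS nucleotide `c` belongs to residue `⌈c/3⌉`, the
residue whose codon it interrupts (phases 1 and 2) or completes (phase 0).

Per genome, over all multi-exon proteins carrying at least one domain:

- **observed** `O` = number of junctions falling in any window,
- **expected** `E = Σ_proteins n_junctions × (window residues / length)`,
  the uniform-placement null,
- the enrichment **ratio** `O/E`, with a two-cell chi-square
  `(O−E)²/E + (O−E)²/(N−E)` (df = 1) for per-genome significance.

The same construction is repeated for disorder-region boundaries, where a
residue is called disordered when at least 75% of the individual
predictors agree. Proteins are split into **new** (domain architecture
found in no other genome of the clade, or labels from an external
ancestral reconstruction) and **old**; the significance of new > old
across genomes is assessed by a bootstrap that repartitions each genome's
proteins into pseudo-new/pseudo-old sets of the original sizes (50 000
trials by default) and counts how often at least as many genomes favour
the pseudo-new set.

## Worked example

Generate a 4-genome synthetic study with planted enrichment (4% of
junctions forced into domain windows, 12% in novel-architecture proteins)
and run the full pipeline:

```sh
xdc generate --seed 7 --n-genomes 4 --n-proteins 300 \
    --theta-domain 0.04 --theta-disorder 0.02 \
    --frac-new 0.1 --theta-new 0.12 --out bundle
xdc run --bundle bundle --seed 7 --n-trials 5000 \
    --min-multiexon 50 --min-new 5 --out results
```

`results/genome_summary.tsv` then contains, per genome and boundary class
(trimmed):

```
genome_id  class     n_boundaries  observed  expected  ratio  p_value      significant
G000       domain    1017          99        26.55     3.73   4.6e-46      1
G000       disorder  790           33        23.72     1.39   0.053        0
G001       domain    927           61        25.44     2.40   8.8e-13      1
G001       disorder  811           42        23.32     1.80   8.7e-05      1
```

Every genome shows domain–exon enrichment (ratio ≫ 1, significant at
P < 0.01), while disorder enrichment is weaker and not uniformly
significant — the expected signature given the planted parameters.
`results/new_old_summary.tsv` splits the domain ratio by protein age
(G000: 8.12 in new proteins vs 3.18 in old), and
`results/bootstrap.json` holds the cross-genome test (here
`actual_count` 4 of 4 genomes above the diagonal, p = 0.056 — four
genomes is near the resolution floor of this test; real studies use
dozens). `results/correlation.json` and the two `scatter_*.csv` files
provide the domain-vs-disorder and new-vs-old ratio scatter data.

The same stages are available separately (`xdc map`, `xdc stats`,
`xdc new-old`, `xdc report`) and compose to identical outputs, or
programmatically through `xdc.pipeline.run_full`.

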