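# Methods

## Model and procedure

The question is whether splice junctions co-locate with the boundaries of
protein domains (and of intrinsically disordered regions) beyond what
uniform placement predicts. The unit of analysis is the protein-coding
transcript; the statistic is a genome-level observed/expected ratio.

**Coordinates.** Genomic coordinates are 1-based inclusive (GTF/GFF
convention); protein residues are 1-based inclusive (domain-table
convention). Only CDS features are read. Exons are ordered 5'→3', i.e. by
descending genomic coordinate on the minus strand, which makes every
downstream computation strand-invariant.

**Stop codon.** When the total CDS length is a multiple of three, the
final codon is taken to be the stop and the protein length is `nt/3 − 1`;
`stop_included=false` disables this for annotation dialects that exclude
the stop from the CDS. Transcripts whose CDS length is not a multiple of
three (annotated frameshifts, partial models) are dropped with a logged
warning — codon-phase bookkeeping is undefined for them. All
protein-coding transcripts are used, not one per gene.

**Junction mapping.** A junction between exons i and i+1 lies after
spliced-CDS nucleotide `c = Σ len(exon_1..i)` and is assigned to residue
`⌈c/3⌉`: for a phase-1/2 junction that is the residue encoded across the
splice; for phase 0 it is the residue completed by the upstream exon.
Junctions that land inside the stop codon are discarded with a warning.
The default counting mode treats each splice event as ONE boundary
(`junction`); mode `both_ends` counts the upstream-exon end and
downstream-exon start separately (2(n−1) events per n-exon transcript),
for sensitivity analysis. `junction` is the default because the expected
count treats boundaries as exchangeable point events and a single splice
should not be counted twice.

**Windows and counts.** Boundary windows are the union over intervals of
the six residues flanking and including each interval edge, clipped to
the sequence; overlapping windows count once. Observed is a multiset
count of junctions in the window union. Expected is
`n_junctions × |windows| / length` per protein — junctions uniform over
residues 1..L, terminal residues not excluded (internal-boundary
filtering already happened upstream). Genome totals sum both quantities
over proteins with ≥1 interval of the class under study; the disorder
class mirrors the domain eligibility rule (proteins with ≥1 disorder
region).

**Filters.** Single-CDS-exon proteins are removed. A genome is excluded
when fewer than `min_multiexon_proteins` (default 200, configurable and
reported) multi-exon domain-containing proteins remain; the source
analyses excluded such genomes without publishing a numeric cutoff, so
the threshold here is explicit.

**Disorder consensus.** In per-predictor mode a residue is disordered iff
`calls / n_predictors ≥ 0.75` (so exactly 6 of 8 qualifies); the binary
consensus track is run-length-encoded into maximal regions. The
comparison is integer-safe so representable thresholds behave exactly.

**Significance.** Per genome, a two-cell goodness-of-fit chi-square with
1 df on pooled counts: aligned vs non-aligned junctions against their
expected split; significance at α = 0.01. Degenerate cases (E = 0 or
E = N) are flagged undefined rather than computed.

**New vs old proteins.** A protein's architecture token is the N→C
comma-joined list of its domain ids after resolving overlapping
assignments (keep the longer; ties: smaller start). Without external
labels, a protein is *new* iff its architecture occurs in exactly one
genome of the clade — a strict presence/absence rule; full ancestral
reconstruction over a species tree is intentionally out of scope, and a
labels file from such a reconstruction can be supplied instead and wins
verbatim. Genomes with fewer than `min_new_proteins` (default 10) new
proteins are excluded from this comparison. The bootstrap repartitions
each genome's labelled proteins into pseudo-new/pseudo-old sets of the
original sizes (default 50 000 trials); the p-value is the plain
proportion of trials in which at least as many genomes show a strictly
larger pseudo-new ratio (ties count as not greater; the add-one
correction is available by flag). All trials flow from one named RNG
seeded from the configuration, so runs are bit-reproducible.

## Synthetic-data generator

The generator emulates the inputs the pipeline consumes, with planted
ground truth:

- protein length ~ log-normal (median 300 residues, σ = 0.6, floor 30);
- exon count = 1 + Poisson(4), junction phases uniform over {0, 1, 2};
- 0–3 domains per protein (probabilities 0.15/0.55/0.20/0.10), lengths
  uniform 40–150 residues, placed non-overlapping uniformly (stars and
  bars over free gaps), ids drawn from a 25-family vocabulary;
- disorder regions carved in inter-domain segments (≥8 residues, one
  region per segment with probability 0.5); `allow_overlap` additionally
  anchors regions flush to domain edges to emulate correlated
  domain/disorder boundaries; 8 per-predictor tracks are derived from the
  consensus by flipping calls at a 2% per-residue error rate;
- each junction residue is drawn, with probability θ (θ_new for
  planted-novel proteins, θ_disorder analogously for disorder windows),
  uniformly over the protein's boundary-window *residue set*, otherwise
  uniformly over the sequence. Drawing over the residue set makes the
  genome ratio follow the closed form `(θ + (1−θ)·w̄)/w̄` exactly, where
  w̄ is the boundary-weighted mean window fraction;
- junction residues are realised as distinct spliced-CDS offsets with a
  random phase each, then laid out as CDS exons on a toy chromosome (one
  per transcript, introns uniform 50–2000 nt, strand uniform), and the
  stop codon appended — so generated GTF exercises the real parser and
  the full coordinate round trip. A residue drawn more than three times
  cannot yield distinct offsets and is redrawn uniformly (vanishingly
  rare; saturation at θ = 1 is therefore near-total, not absolute).

What the generator does **not** emulate: real nucleotide sequence, domain
family frequencies, correlated exon/domain length distributions, genome
duplications, or annotation errors other than predictor noise. Passing
tests demonstrate the statistical machinery is correct and calibrated
under the stated model; they do not certify results on any real genome
annotation.

## Numerical and design choices

- Expected counts and ratios are plain floating sums; genome-level
  expected = 0 flags the ratio undefined instead of dividing.
- The bootstrap draws each trial's pseudo-new set via `argpartition` on
  uniform variates (a uniform random k-subset), chunked to bound memory.
- The consensus threshold comparison subtracts 1e-9 before comparing, so
  exact fractions (6/8 ≥ 0.75) are never lost to rounding.
- Summary TSVs are written with 12 significant digits and round-trip to
  at least 10.
- The null p-value distribution of the bootstrap is uniform only up to
  the granularity of the trial count (an integer in 0..n_genomes): its
  gap against continuous uniform is the maximum point mass of that count.
  The uniformity validation therefore runs at 200 genomes × 40 proteins
  and 2 000 trials × 200 replicates, where the granularity is fine; the
  power check uses 20 genomes × 100 proteins with θ_new = 0.5 vs
  θ_old = 0. Null calibration uses one 5 000-protein genome (ratio
  interval) and 500 genomes of 100 proteins (type-I rate); enrichment
  recovery uses 3 000-protein genomes at θ ∈ {0, 0.3, 0.7}. These sizes
  give Monte-Carlo standard errors comfortably inside the asserted
  3-SE / 99%-interval bounds.

## Known limitations

- The presence/absence novelty rule over-calls "new" for rare multi-domain
  architectures that happen to be observed in a single genome; with real
  data, supply labels from an ancestral reconstruction.
- The chi-square is asymptotic; genomes with very small expected counts
  are conservative rather than exact (no Fisher alternative is provided).
- No multiple-testing correction is applied across genomes, matching the
  per-genome significance colouring the analysis mirrors.
- Selenocysteine recoding, ribosomal frameshifts and trans-splicing are
  out of scope; affected transcripts should be filtered upstream.
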