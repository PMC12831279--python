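# Methods

## Synthetic truth genomes

`syngen.generate_gene_models` draws gene models per class from a
`GenerationConfig`:

* **multi_exon** — 2–8 exons; CDS of 100–400 internal sense codons framed by
  `ATG` and `TAA`; 5'UTR 100–250 bp, 3'UTR 150–400 bp; introns 120–3,000 bp
  emitted as `GT…AG`; exon cuts are uniform over the transcript with a
  40 bp minimum exon length.
* **true_intronless** — a single exon.
* **cds_intronless** — introns only in the UTRs; the CDS sits inside one exon.
* **selenoprotein** — 1–3 internal `TGA` codons whose indices are recorded in
  `sec_positions`; translation recodes those to `U`.
* **readthrough_parent** — generated in adjacent same-strand pairs separated
  by a 300–800 bp gap, cross-linked through `partner_id`.
* **retroelement** — single-exon genes sharing one CDS, used to plant
  dispersed ORF copies.

Genes are placed sequentially on one chromosome with 1–5 kb intergenic
spacers (`emit_genome`). Every generated CDS is verified to translate
cleanly to its recorded protein; minus-strand genes are emitted by
reverse-complementing the gene body and mirroring all intervals.
Coordinates are 0-based half-open internally; GFF3 emission converts to
1-based inclusive.

All randomness comes from `numpy.random.default_rng([seed, stream])` with a
fixed stream code per operator (`_util.RNG_STREAMS`), so adding one
corruption operator never reshuffles the draws of another.

## Error injection

`inject_build_errors` corrupts a copy of the truth genome. Error assignment
is per gene and mutually exclusive, in this order:

1. **merged_locus** — Bernoulli per disjoint adjacent gene pair; the two
   genes are re-annotated as a single feature (`idA--idB`) whose exons are
   the union and whose CDS is the upstream gene's.
2. **premature_stop** (selenoproteins) — the annotated CDS is truncated at
   the first Sec codon, emulating an annotator that treats `TGA` as a stop.
3. **missing_segment** — the gene span is overwritten with random bases and
   the feature dropped. **unannotated** — feature dropped, sequence kept.
   **split_locus** — the gene is cut so each part keeps 35–65% of its exonic
   bases (preferring an exon boundary near the midpoint), the suffix is
   relocated far downstream as `id_b`, and the vacated span is overwritten.
4. **indel** — a homogeneous Poisson process over the concatenated CDS of
   all still-clean genes with mean spacing `indel_spacing_bp`; events are
   1–2 bp, insertion or deletion with equal probability. Events closer than
   4 bp are thinned so sequence edits stay disjoint; the ledger records
   exactly the surviving events.

Under the `truncate` dialect the assembly sequence is edited and every
annotation coordinate is lifted through the edits (insertions at *p* shift
coordinates ≥ *p*; deletions collapse interior coordinates onto the cut).
Under `n_fill` a ±10 bp window around each indel is masked with `N`,
lengths and coordinates unchanged. The `ErrorLedger` stores one record per
truth gene plus build-coordinate indel positions and planted-copy positions.

## Spliced alignment and indel detection

Transcripts are mapped with a seed-and-chain mapper: exact 16-mers of the
genome are encoded into sorted `uint64` codes with 1 Mb guards between
chromosomes; query k-mer hits (capped at 50 per k-mer) are grouped into
co-diagonal runs (≥2 anchors), chained by dynamic programming on matched
bases, and split into loci where the genomic gap exceeds 50 kb. A gap is an
intron when the transcript side is ≤2 bp and the genomic side ≥30 bp
(canonical if `GT…AG` — checked strand-aware with ±3 bp placement slack);
any other unequal-sided gap is an indel event, frameshifting when it lies in
the CDS and its length is not a multiple of 3. Identity is matched bases
over matched+mismatched+unmatched-query bases; loci under 85% identity or
25% coverage are dropped. The reverse orientation is only searched when the
forward best covers <95% of the query.

Pairwise alignment is delegated to `Bio.Align.PairwiseAligner`: local
protein alignment under BLOSUM62 extended with `U` (scored as `C`) and
`X`/`B`/`Z` (gap −11/−1), local nucleotide (match 2, mismatch −3, gap
−5/−2), and global nucleotide identity for UTR comparison (2/−1, −2/−0.5).

## Classification

For each truth gene the mapped loci with coverage ≥0.30 are examined in a
fixed decision order: no locus → `sequence_not_present`; ≥2 loci jointly
covering ≥0.80 with none ≥0.90 → `split_multiple_loci`; the primary locus'
feature hosts ≥2 audited genes → `multiple_genes_one_locus`; no feature →
`not_annotated`; failed protein-length checksum, premature stop,
frameshifting indel, or N-filled CDS → `error_in_locus`; else `correct`.
Translation is Sec-aware, so uncorrupted selenoproteins are never flagged.
A premature stop is additionally flagged as a candidate pseudogene when the
alignment-projected CDS confirms the stop and its codon contains no `N`.

The indel rate is reported as mean bp between events with an exact
(Garwood) 95% Poisson interval:
`[2·L/χ²(0.975, 2n+2), 2·L/χ²(0.025, 2n)]` for `n` events over `L` bp.

## Calibrated end-to-end experiment

`experiments.classification_experiment` generates a 2,000-gene mixed set
(80% multi-exon, 10% true-intronless, 8% CDS-intronless, 2% selenoprotein)
and solves for the indel spacing `s` such that the expected error-free
fraction

`mean_i (1 − p_merged)·(1 − p_cat,i)·exp(−L_i / s)`

equals the requested target (categorical rates fixed at
`p_missing = p_unannotated = p_split = 0.06`, `p_merged = 0.05`,
`p_premature|seleno = 0.4`; `L_i` is the gene's CDS length), using
bisection in log space. The reported percent-correct is then compared with
the realized injected fraction, and per-class recall is scored against the
ledger.

## Statistics and reporting

Over-representation uses the hypergeometric upper tail
`P(X ≥ k) = hypergeom.sf(k−1, N, K, n)` with fold `(k/n)/(K/N)`,
Benjamini–Hochberg correction per collection (statsmodels), and terms
restricted to the supplied background. Reported percentages, folds and
ratios are rounded half-up to one decimal (`decimal.Decimal`); p/q values
are printed in scientific notation. Report rendering is deterministic and
marks absent sections explicitly.

## Scope and limitations

* The generator models compact protein-coding genes on a single chromosome
  per run; no overlapping genes, alternative splicing, or repeat families
  beyond the planted retroelement CDS.
* Indel placement by the mapper is ambiguous within a few bp under local
  sequence repeats; an indel landing in the terminal stop codon can be
  detected as a UTR gap and the gene then passes the length checksum. This
  is a property of alignment itself, not of the implementation, and bounds
  per-class recall slightly below 1.
* The k-mer mapper requires ≥2 exact 16-mer anchors per exon, so exons
  shorter than ~17 bp or extremely diverged sequence will not seed.
* Orthology tiers use full all-vs-all alignment and are intended for
  desk-scale gene sets, not whole proteomes.
* `split_locus` relocation appends the suffix to the same chromosome after a
  60 kb spacer; inter-chromosomal splits are not modelled.
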