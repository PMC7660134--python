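# protloc

Quantitative analysis of subcellular mRNA and protein localization, built
around the transwell protrusion/cell-body fractionation design: migratory
cells extend protrusions through 3 µm filter pores, the two fractions are
profiled separately (3' mRNA-seq, TMT/SILAC proteomics, iCLIP of a
localizing RNA-binding protein, RNA-FISH imaging), and the question is
always the same — *which transcripts, proteins or annotation categories
shift between compartments, and is the shift localization or expression?*

`protloc` provides the full statistical chain as a tested Python library
plus a thin CLI, together with synthetic-data generators that plant known
effects so every stage can be validated end to end without any external
download.

## What it computes

- **Compartment enrichment** — per-sample log2(protrusion/body) ratio
  tables from paired counts (CPM scaling, pseudocount, median centering),
  category shift tests, and a cross-line one-sample t meta-analysis
  volcano with BH-corrected FDR.
- **Category statistics** — an adapted Wilcoxon–Mann–Whitney category
  test reporting the rank-biserial score `s = 2U/(n1·n2) − 1` with an
  exact tie-aware permutation null for small categories; 1D and 2D
  annotation enrichment (the 2D quadrants separate "mislocalization
  candidates" from "expression changes"); Fisher/hypergeometric
  over-representation; Benjamini–Hochberg control throughout.
- **iCLIP** — barcode demultiplexing with 7-nt UMIs, truncation-based
  crosslink assignment (the nucleotide 5' of the cDNA insert), UMI
  deduplication, replicate merging, Paraclu-style density clustering
  (min sum 10, max length 200 nt, stability fold ≥ 2), control-peak
  subtraction, target-gene calls, region/5'TOP distributions and
  library-normalized metaprofiles.
- **Pulsed SILAC** — reciprocal-replicate harmonized log2(open/closed)
  translation-rate ratios, per-label compartment fractions from iBAQ
  triplets, old-versus-nascent nuclear accumulation tests, and spike-in
  referenced knockdown proteome shifts.
- **Imaging** — polarization index
  `PI = ‖r̄_RNA − r̄_cell‖ / Rg_cell`, area-normalized compartment signal
  ratios, greedy spot co-localization, per-frame particle densities.

See `docs/methods.md` for the models, conventions and design decisions.

## Worked example

Plant a ribosomal-protein-sized category shift (80 of 5,000 genes, log2
shift 1.0) in negative-binomial counts and recover it:

```python
from protloc import simulate, compartment

counts, truth = simulate.gen_compartment_counts(
    n_genes=5000, category=80, delta=1.0, seed=101)
ratios, dropped = compartment.log2_ratio_table(counts)
res = compartment.category_shift_test(ratios["s1"], truth.table["feature_id"])
print(f"score_s = {res.score_s:.3f}, q = {res.q:.2e}")
```

prints

```
score_s = 0.666, q = 1.42e-24
```

— the planted category sits far above the rest of the transcriptome
(`score_s` = +1 would mean every member outranks every non-member), with
the shift significant well below the q < 0.01 working threshold.

The same pipeline from the shell, including the iCLIP chain:

```bash
protloc simulate --kind iclip --seed 1 --out sim/
protloc iclip --fastq sim/reads.fastq --alignments sim/alignments.tsv \
    --barcodes GGCTA=s1,TTAGC=s2 --min-sum 10 --max-len 200 --min-fold 2 \
    --out iclip_out/
```

`iclip_out/peaks.bed` then contains the called binding-site clusters, and
`run.log` records every parameter, the seed and input/output checksums;
reruns with the same seed are byte-identical.

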