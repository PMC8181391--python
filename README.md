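# atacatlas

Build a multi-tissue ATAC-seq peak atlas and identify tissue-specific
regulatory elements with a Shannon-entropy specificity index.

`atacatlas` is for epigenomics analysts who have, per tissue and biological
replicate, a set of called peaks (BED) and the mapped fragment intervals
(BED), and want the downstream tissue-comparison analysis as one
reproducible pipeline:

1. **Atlas** — keep peaks present in both biological replicates (≥ 1 bp
   overlap), merge the surviving peaks across all tissues into a
   non-redundant *standard peak set*, and annotate each standard peak with
   its distance to the nearest TSS and a promoter-proximal / distal class.
2. **Quantify** — count fragments over the standard peaks per sample,
   normalize to reads per million (RPM = raw × 10⁶ / library size), and
   compute sample–sample Pearson correlations on log₁₀(RPM + 1) with
   average-linkage clustering.
3. **Specificity** — for each peak, with Eᵢ its RPM in tissue *i*
   (replicate mean) and Rᵢ = Eᵢ / ΣE, score

   H = −Σᵢ Rᵢ log₂ Rᵢ,  H ∈ [0, log₂ N],

   and call peaks with H strictly below a threshold (3 bits for a body-organ
   panel, 2 bits for a brain-region panel at reference scale)
   tissue-specific, assigned to argmaxᵢ Rᵢ. H = 0 means open in exactly one
   tissue; H = log₂ N means uniformly accessible.
4. **QC** — flank-normalized TSS fragment-enrichment profile and score per
   sample, and the region-class composition of the atlas.
5. **Motifs** — scan tissue-specific peak sequences with JASPAR-style PWMs
   (log-odds threshold at 60 % of each motif's maximum score, both strands)
   and test per-(motif, tissue) enrichment against background peaks with a
   one-sided hypergeometric tail. This is a transparent stand-in for a
   HOMER-style analysis, not a HOMER wrapper.

A bundled simulator generates a complete synthetic dataset — genome, TSSs,
replicate peak calls with boundary jitter and replicate-private noise
peaks, per-sample fragments from a multinomial accessibility model, and
planted sequence motifs — with full ground truth, so every stage is
testable without any download.

## Worked example

Simulate 5 tissues × 2 replicates (100 shared TSS-proximal peaks, 40
specific distal peaks per tissue at 8-fold home-tissue accessibility,
100k fragments per sample), then run the whole pipeline:

```sh
atacatlas simulate --outdir demo/data --seed 1 --tissues 5 \
    --shared-peaks 100 --specific-peaks 40 --fragments 100000

cat > demo/config.yaml <<EOF
sample_sheet: data/samples.tsv
genome: data/genome.fa
tss: data/tss.bed
pwms: data/motifs.jaspar
outdir: out
seed: 1
analyses:
  - name: all
    threshold: 2.0
EOF

atacatlas all --config demo/config.yaml
```

The run logs each stage and writes TSVs/BEDs plus a SHA-256 manifest under
`demo/out/`. With seed 1 it prints:

```
[atacatlas:atlas] tissue00: 140 reproducible peaks
...
[atacatlas:specificity] all: 200 specific peaks of 302 at H < 2.0
```

The 302 standard peaks are the 300 planted peaks plus two replicate-noise
survivors; all 200 planted specific peaks (40 per tissue) are recovered at
the 2-bit threshold (entropy ranges 1.52–2.32 bits against
log₂ 5 ≈ 2.32 for shared peaks). Key outputs:

* `region_proportions.tsv` — distal 0.67 vs promoter-proximal 0.33,
  matching the planted design (shared peaks sit on TSSs, specific peaks
  are distal).
* `tss_enrichment_scores.tsv` — scores ≈ 54–62 (flank-normalized; uniform
  coverage would give exactly 1.0).
* `correlations.tsv` — within-tissue replicate r ≈ 0.98 vs between-tissue
  r ≈ 0.15.
* `top_motifs_all.tsv` — each tissue's planted motif ranks first in its own
  column (−log₁₀ P ≈ 15–21).

Every stage is also available as a library function
(`atacatlas.reproducible_peaks`, `build_standard_peaks`,
`build_count_matrix`, `normalize_rpm`, `call_specific_peaks`,
`tss_enrichment`, `motif_enrichment`, ...) operating on plain dataclasses
and pandas objects.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end-to-end: it simulates a 5-tissue dataset with
the given seed, runs every stage on the emitted files (atlas construction,
counting and normalization, entropy-based specificity calling, TSS
enrichment, motif enrichment), and writes the target JSON to `--out`.

## Documentation

`docs/methods.md` describes the statistical model, the simulator's stated
world and its limits, and the numerical conventions (coordinate system,
tie-breaking, thresholds, degenerate-input handling).
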