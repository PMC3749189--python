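# myoscreen

Analysis pipeline for a genome-wide, high-content miRNA loss-of-function
screen of human muscle-cell differentiation, rebuilt as a tested Python
package and exercised end to end on synthetic data.

The pipeline covers five stages:

1. **synthetic_data** — seeded, ground-truthed simulators: two-channel
   field images (nuclear stain + MHC immunofluorescence), plate-level well
   metrics with planted per-reagent effects, two-condition Ct tables with a
   constitutive reference miRNA, and suppressor-rescue (co-knockdown) well
   tables with planted rescuing siRNAs.
2. **hcs_imaging** — intensity-threshold segmentation of nuclei and
   MHC-positive cell/myotube ROIs, nucleus-to-ROI assignment by centroid
   containment, and the four per-well phenotype parameters: percent
   myotubes (MHC+ ROIs with ≥3 nuclei), fusion index, myotube area, cell
   count.
3. **screen_analysis** — normalization to the mock-transfected control,
   primary candidate selection at mean − 2 SD of the pooled negative
   controls, secondary confirmation by exact Mann-Whitney tests (full
   enumeration for n ≤ 12 without ties), and classification into five
   phenotype categories.
4. **stars_rescue** — the suppressor target screen caller: a gene is a
   target hit when ≥2 of its siRNAs significantly rescue the miRNA-inhibition
   phenotype (two-stage 2+2 siRNA design), plus the cross-miRNA
   specificity matrix.
5. **expression_compare** — 2^−ΔΔCt fold changes against the reference
   miRNA, the symmetric ≥2-fold differential-expression rule, knockdown
   efficiency, pulldown enrichment and reporter ratios, and the
   intersection of expression calls with functional hits.

`src/myoscreen/data/table1_hits.tsv` ships the curated final hit table
(63 entries across the five categories) used for bookkeeping and as the
default hit list for expression comparison.

## CLI

```sh
myoscreen simulate-images --out scratch/fields --n-fields 4 --seed 1
myoscreen quantify --images scratch/fields --out scratch/wells.tsv
myoscreen simulate-plate --layout layout.tsv --out metrics.tsv --seed 1
myoscreen call-hits --metrics metrics.tsv --layout layout.tsv --alpha 0.05 --k-sd 2
myoscreen simulate-stars --mirna hsa-mir-365 --genes XPO4,MAPK1 \
    --rescuing 'XPO4:0;XPO4:1' --out stars.tsv
myoscreen stars --wells stars.tsv --alpha 0.05 --min-rescuing 2
myoscreen simulate-expression --n-mirnas 200 --out ct.tsv
myoscreen compare-expression --ct ct.tsv
myoscreen run-all --out-dir scratch/run --seed 1
```

All tables are UTF-8 tab-separated with a header row; images are
per-channel 16-bit grayscale TIFFs named
`{plate}_{well}_{field}_{channel}.tif`. Every stage writes a
machine-readable run log (parameters, seed, versions, input checksums).

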