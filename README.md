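# driverank

Cancer-type-specific prioritization of cancer driver genes from somatic
genomics data — tumor mutation calls and segment-level copy-number
alterations — with no transcriptomics required, in both cohort (batch)
and single-patient (personalized) modes.

Most tumor alterations are passengers; the few drivers are what matter
for diagnosis and therapy selection. driverank scores every altered
gene with a probability of being a driver in a given cancer type by
combining genomics evidence with prior biological knowledge.

## Method

**1. Coding-variant impact metapredictor.** Each coding variant arrives
annotated with 12 impact-predictor scores (SIFT, PolyPhen-2, LRT,
MutationTaster, MutationAssessor, FATHMM, GERP++, PhyloP, CADD, VEST,
SiPhy, DANN). A classifier trained on a labeled benchmark (neutral /
non-neutral variants; rows with missing scores or "uncertain" labels
excluded; 75/25 stratified split; tenfold 3-times-repeated CV
maximizing AUC) turns them into one damaging probability. Six model
families are available behind one interface; the random forest is the
default.

**2. 26 gene-level features.** For every altered gene:
max coding metaprediction score; max non-coding Phred-scaled score;
a copy-number proxy score (gene-level events called when a segment
covers ≥ 25% of the gene, assigned the max-|log2| segment ratio,
|log2| < 0.25 dropped, sex chromosomes excluded, then scored with the
SCNA density of a direction-matched minimal common region);
a hotspot-or-double-hit flag (catalogue occurrence > 5, or a
non-synonymous mutation plus homozygous loss log2 < −1); a
cancer-type-specific prior gene score (phenotype-based gene analyzer
output, consumed as an input table); and 21 binary memberships in
cancer-related pathways.

**3. Sparse multi-task logistic model.** One task per cancer type:

```
min_W  Σᵢ L(Wᵢ | Xᵢ, Yᵢ) + λ₁‖W‖₁ + λ₂‖W‖²_F
```

with L the logistic loss, solved by monotone accelerated proximal
gradient (FISTA with backtracking; soft-threshold prox). λ₂ is chosen
on a validation split, λ₁ by tenfold cross-validation; per-task
probability thresholds maximize validation accuracy. Genes with
probability ≥ threshold are called drivers.

Every input the pipeline consumes can be generated synthetically
(`driverank.synthetic_fixtures`) with a controlled driver/passenger
signal, down to the exchangeable null.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_multitask_model.py` prints:

```
5 tasks, n=500 each, p=26; true support (0, 4, 9, 14, 19)
cross-validated lambda1 = 0.04642
recovered support: [0, 4, 9, 14, 19]
sign agreement on the true support: 100%
```

i.e. on five simulated cancer types sharing five informative features,
the cross-validated L1 penalty zeroes all 21 noise features exactly and
recovers every true coefficient with the correct sign. The end-to-end
script `examples/04_cohort_and_patient_analysis.py` trains the full
pipeline on a synthetic cohort and prints held-out AUC (~0.99 under a
strong signal), per-task driver calls with the percentage of calls that
are true drivers, and the median per-patient AUC of the personalized
rankings.

A thin CLI mirrors the library:

```bash
driverank simulate --preset cohort --out fixtures/ --seed 5
driverank train-metapredictor --table scores.tsv --out meta.joblib
driverank build-features --variants variants.tsv --segments segs.seg \
    --genes genes.bed --mcr mcr.tsv --prior-scores prior.tsv \
    --pathways pathways.gmt --metapredictor meta.joblib --out features.tsv
driverank train --manifest tasks.tsv --out model.json
driverank predict --model model.json --features features.tsv \
    --cancer-type cancer_0 --out predictions.tsv
driverank evaluate --predictions predictions.tsv --truth truth.txt \
    --actionable actionable.txt --out report.json
```

## Layout

- `src/driverank/io_formats.py` — table readers/writers, coordinate conventions
- `src/driverank/metapredictor.py` — variant impact metapredictor
- `src/driverank/feature_builder.py` — the 26 gene-level features
- `src/driverank/mtl_model.py` — sparse multi-task logistic model and solver
- `src/driverank/evaluation.py` — AUC and batch/per-patient scoring
- `src/driverank/synthetic_fixtures.py` — seeded generators for every input
- `src/driverank/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — modeling assumptions, defaults, limitations
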