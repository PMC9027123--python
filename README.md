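# chipshift

Integrative differential ChIP-seq / RNA-seq analysis around a
conditional knockdown, with a planted-truth simulator.

`chipshift` re-creates, as a tested and reusable Python library plus
CLI, the computational workflow used to study how depleting a
chromatin-remodelling subunit (e.g. Smarcb1 of the murine embryonic-stem-cell
BAF complex) reshapes genome-wide occupancy of the complex's ATPase
(Smarca4), a Polycomb writer (Ezh2) and histone marks (H3K27me3,
H3K27ac, H3K4me3), and how those occupancy shifts relate to expression
changes. It is aimed at computational biologists who want the *logic*
of that analysis — peak classification, gene-level integration,
enrichment testing — as composable, unit-tested functions rather than a
chain of external tools.

## What it computes

**Island peak calling.** Tags (1 bp positions) are binned into fixed
windows (200 bp broad mode for histone marks, 50 bp narrow mode for
transcription factors). A window is *eligible* when its count is
improbable under a Poisson null with mean equal to the library-scaled
input expectation λ; eligible windows joined across gaps ≤ 600 bp
(broad) form islands, each island scored by the Poisson upper tail
P(X ≥ n | λ_island) and kept below the island cutoff (10⁻⁵ for
H3K27ac-like marks and narrow factors, 10⁻¹⁰ for other broad marks).

**Differential classification.** Each antibody is called four ways:
control vs input, knockdown vs input, and each condition against the
other. Regions are then classified

* `DECREASE` — control standard peak overlapping a control-over-kd
  differential peak,
* `INCREASE` — knockdown standard peak overlapping a kd-over-control
  differential peak,
* `COMMON` — standard peaks present in both conditions.

Condition-vs-condition calls use the conditional binomial test
(t | t+c ~ Binom(t+c, T/(T+C)), the exact two-sample Poisson
comparison) with a background-normalized depth ratio, since the
"control" there is itself a noisy, signal-bearing sample.

**Annotation and integration.** Peaks are assigned to every gene whose
gene region (1 kb upstream of the TSS through the TES, strand-aware) or
TSS ± 1 kb window they overlap; peaks hitting neither are discarded.
The DESeq2-style expression table is filtered at padj < 0.05 and
|log2FC| > 0.58 and merged per gene with the class memberships.

**Permutation enrichment test.** Downregulated genes carrying a
differential Smarca4 peak form the *basic set*, split into DECREASE and
INCREASE groups. For every other antibody × peak class, the count of
group genes with that concurrent signal is compared with a shuffle null
(k labelled genes redistributed uniformly among N, i.e. a
hypergeometric draw per shuffle), two-sided at 2.5 % per tail,
Bonferroni-corrected over all combinations; an observation outside all
B shuffles is "highly significant".

**Enhancers and profiles.** 1 bp enhancer anchors are extended to
3001 bp centred intervals, overlap-classified, linked to the nearest
gene within 100 kb, and summarised by expression direction per class;
average ±2.5 kb coverage profiles around peak centres are smoothed with
LOESS.

**Synthetic data.** The simulator plants all of the above — occupancy
classes per gene and antibody, expression directions correlated with
Smarca4 shifts (including the "downregulated despite increased
binding" group), enhancer binding tied to target-gene direction — and
exports the truth, so the full pipeline can be scored for exact
recovery.

## Worked example

```python
from chipshift.pipeline import RunConfig, run_pipeline, evaluate_recovery

result = run_pipeline(RunConfig(seed=1), "runs/demo")
print(result.summary["peaks"]["Smarca4"])
print("up", result.summary["de_up"], "down", result.summary["de_down"])
print(result.summary["basic_set"], result.summary["n_significant"], "significant")
rec = evaluate_recovery(result)
print("precision %.3f recall %.3f" % (rec["occupancy_precision"], rec["occupancy_recall"]))
```

prints (seed 1, default settings: 200 genes on two 1.6 Mb chromosomes,
fold-50 occupancy, ±2 log2FC expression effects):

```
{'ctrl': 101, 'kd': 114, 'COMMON': 62, 'INCREASE': 47, 'DECREASE': 38}
up 36 down 51
{'DECREASE': 31, 'INCREASE': 15} 32 significant
precision 1.000 recall 1.000
```

101 control and 114 knockdown Smarca4 islands resolve into 62 regions
bound in both conditions, 47 gained and 38 lost after knockdown; 36/51
genes pass the expression filter up/down; the basic set splits 31/15,
and 32 of 40 permutation tests reach significance — e.g. Ezh2
knockdown-condition binding is over-represented in the DECREASE group
(observed 25 vs null mean 17.5, p ≈ 2×10⁻⁵, positive correlation,
highly significant), matching the planted antagonism between BAF loss
and Polycomb. The recovery line confirms every planted occupancy class
was recovered with neither false nor missed calls.

The same run from a shell:

```bash
chipshift run-all --outdir runs/demo --seed 1
chipshift callpeaks --treatment t.bed --control input.bed --mode broad --pcut 1e-10 --out peaks.bed
chipshift profile --tags t.bed --peaks peaks.bed --halfwidth 2500 --out profile.tsv
```

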