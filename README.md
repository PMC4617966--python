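# pionuc

Analysis toolkit for pioneer-factor-driven nucleosome depletion: how a
pioneer transcription factor opens intrinsically nucleosome-favoring
enhancers and thereby licenses binding of a downstream patterning factor.

The package is aimed at regulatory genomicists working with paired
ChIP-seq / MNase-seq designs across two genotypes (pioneer present vs
absent).  It implements, as a tested pipeline:

- **Track normalization** — MNase: Z-scored log2 coverage; ChIP:
  median-scaled coverage Z-scored against the out-of-peak background.
- **Replicate-consistent peak sets** — pooled-replicate peaks supported by
  both replicates, an input-enrichment filter around summits, a background
  Z >= 1.6445 cutoff for pioneer-bound regions, and the cross-genotype
  union of enriched peak sets as the tested regions.
- **Differential binding** — summit-window counts (±125 bp),
  median-of-ratios size factors, a conditional exact-style
  negative-binomial test with trended, df-shrunk dispersions, BH FDR, and
  the Group I / II / III classification (significantly decreased /
  unchanged / increased in the mutant at FDR < 0.1), plus a model-free
  difference cross-check.
- **ΔMNase** — the accessibility statistic: mutant-minus-wild-type mean
  normalized MNase within 250 bp of a summit, zero-read positions
  excluded.  Positive ΔMNase = occupancy gained when the pioneer is absent.
- **Nucleosome positioning** — Fourier low-pass dyad calling, nearest-dyad
  (≤ 75 bp) summit anchoring, metaprofiles/heatmap matrices, and a
  sequence-intrinsic occupancy model (logistic in windowed GC and A/T-run
  content).
- **Motif machinery** — IUPAC degenerate scanning on both strands
  (CAGGTAG-family heptamers; GGGW-family patterning motifs), density
  enrichment over genome background, central-vs-flanking configuration
  classes, and in-silico motif disruption (C→T, G→A).
- **Rank-and-bin enrichment** — regions ranked by binding strength,
  wild-type openness, or ΔMNase; bins of 500; per-bin enrichment of
  enhancer/HOT/peak annotations; hotness scores; correlation with
  permutation p-values.
- **Synthetic data with ground truth** — a genome/fragment simulator whose
  planted labels (groups, motif placements, depletion depths, hotness)
  make every stage testable end to end without external data.

See `docs/methods.md` for models, estimators, and numerical choices.

## Worked example

From Python, at the full study scale (2 Mb genome, 800 planted regions,
2 × 10⁶ fragments per sample; about a minute on one CPU):

```python
from pionuc.simulate import SyntheticConfig, generate_genome
from pionuc.config import RunConfig
from pionuc.analysis import run_pipeline, group_recovery

dataset = generate_genome(SyntheticConfig(seed=1))
result = run_pipeline(dataset, RunConfig(seed=1))
print(result.group_counts())
print(group_recovery(result))
```

prints

```
{'I': 305, 'II': 145, 'III': 350}
{'group_I_recovery': 1.0, 'group_III_recovery': 1.0, 'delta_vs_log2fc_r': -0.5900433184809541}
```

meaning: of 800 union regions tested for differential patterning-factor
binding, 305 lost binding in the mutant (Group I; 300 enhancers were
planted), 350 gained binding (Group III; the planted open-chromatin
redistribution targets, all recovered), 145 were unchanged — and among
planted Group-I regions the accessibility change (ΔMNase) anticorrelates
with the binding change (log2FC), as the depletion model predicts.

From the shell, on a scaled-down configuration (a full-depth `simulate`
writes multi-gigabyte fragment BEDs; a 400 kb / 3 × 10⁵-fragment config is
enough to see every behavior):

```bash
pionuc simulate --config demo.yaml --out demo_run
pionuc report   --config demo.yaml --out demo_run
# groups I/II/III: 31/14/35 of 80 regions
```

`demo_run/report/` then holds the tables: `group_counts.tsv` (counts and
percentages), `recovery.tsv` (ground-truth recovery rates and the
ΔMNase–log2FC coupling), `bin_enrichment.tsv` (rank-and-bin enrichments
under all three rankings), `correlations.tsv`, and `nucleosomes.tsv`.

Individual stages (`pileup`, `normalize`, `callpeaks`, `diffbind`,
`delta-mnase`, `motifs`, `nucleosomes`, `enrich`) write their artifacts
into the same run directory; every stage writes a JSON manifest and the
config is serialized alongside, so runs are self-describing and
re-runnable.

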