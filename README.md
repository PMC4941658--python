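# msapkit

Analysis of **methylation-sensitive amplified polymorphism (MSAP)** data:
a tested pipeline for scoring CCGG cytosine-methylation states from
dual-enzyme band patterns, profiling relative methylation levels across
tissues, quantifying methylation breadth and tissue specificity, counting
developmental state transitions, and relating methylation states to gene
expression.

MSAP is an AFLP variant that digests genomic DNA in two parallel reactions
with the isoschizomers HpaII and MspI, which recognise the same 5′-CCGG site
but differ in methylation sensitivity: both cut the unmethylated site, HpaII
is blocked when either cytosine is methylated on both strands, and MspI is
blocked when the external cytosine is hemi-methylated. Scoring each locus as
present/absent in the EcoRI/HpaII lane (h) and the EcoRI/MspI lane (m)
therefore resolves four states per locus and sample:

| h | m | state  | interpretation                            |
|---|---|--------|-------------------------------------------|
| 1 | 1 | NON    | non-methylated CCGG                        |
| 1 | 0 | HEMI   | hemi-methylated external cytosine          |
| 0 | 1 | FULL   | fully methylated internal cytosine         |
| 0 | 0 | UNINF  | uninformative (site absent or doubly blocked) |

On top of the state matrix the package computes, for *n* samples:

- **Relative levels** — each class as a percentage of all analysed markers
  (UNINF depresses the informative classes), with Student/Welch t-tests
  between sample groups such as xylem vs. non-xylem tissues.
- **Tau specificity** — with M_j = 1 when sample j is methylated,
  τ = (Σ_j M_j − 1)/(n − 1): 1 = methylated everywhere, 0 = methylated in a
  single sample, NA when methylated nowhere.
- **Set algebra** — sample-specific sites, shared sites over arbitrary
  subsets, Venn-region counts (≤ 5 samples), common-pattern fractions.
- **Transition counting** — loci matching ordered patterns such as
  (F, H) = "fully methylated in the young stage, hemi-methylated in the
  mature stage" over the alphabet N/H/F/M (M = either methylated state;
  UNINF matches nothing).
- **Expression association** — group-mean comparisons of HEMI/FULL/NON gene
  sets per tissue and a Pearson correlation between an ordinal state
  encoding (NON=0, FULL=1, HEMI=2, increasing in expected transcriptional
  suppression) and expression.
- **A synthetic-data generator** that draws biochemical CCGG states per
  locus and tissue, derives band patterns from the enzyme-sensitivity rules,
  and emits methylation-suppressed log-normal expression — ground truth for
  every analysis above.

## Worked example

```python
import msapkit as mk
from msapkit.simulate import SimulationConfig

cfg = SimulationConfig(n_loci=2000, seed=7)      # ten-tissue synthetic study
sim = mk.generate_band_matrix(cfg)
called = mk.call_states(sim.bands)

summary, _ = mk.find_polymorphic(called)
print(f"{summary.polymorphic_loci}/{summary.total_loci} loci polymorphic "
      f"({summary.polymorphic_fraction:.1f}%)")

prof = mk.relative_levels(called)
print(prof[["hemi_pct", "full_pct", "non_pct", "methylated_pct"]].round(2).head(4))

c = mk.compare_groups(prof, mk.xylem_assignment(called.samples), "full_pct")
print(f"xylem vs non-xylem full methylation: t={c.t_statistic:.2f}, p={c.p_value:.3f}")
```

prints

```
1640/2000 loci polymorphic (82.0%)
            hemi_pct  full_pct  non_pct  methylated_pct
sample
shootApex      10.60     13.40    37.45            24.0
youngLeaf       8.50     10.80    32.60            19.3
matureLeaf      7.90     10.80    39.15            18.7
phloem          9.85     12.95    35.05            22.8
xylem vs non-xylem full methylation: t=-0.20, p=0.845
```

82.0% of loci change state between at least two tissues; per-tissue
hemi/full/non percentages land in the configured ranges (the remainder to
100% is uninformative); and, as expected under the default conditions,
genome-wide levels do not separate xylem from non-xylem tissues (p ≫ 0.05 —
in this design it is the methylation *pattern* of specific genes, not the
global level, that distinguishes tissue types).

## Command line

```bash
msap simulate --output-dir fixtures --n-loci 2000 --seed 7
msap call     --input fixtures/bands.tsv --output-dir out
msap levels   --input out/states.tsv --config config.yaml --output-dir out
msap tau      --input out/states.tsv --output-dir out
msap share    --input out/states.tsv --subset "youngLeaf,matureLeaf,root,maleCatkin,femaleCatkin"
msap dynamics --input fixtures/stage_states.tsv --output-dir out
msap assoc    --states out/states.tsv --expression fixtures/expr.tsv
```

Every command writes TSV outputs plus a JSON run summary.

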