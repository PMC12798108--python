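# saltscreen

Salt-tolerance germplasm screening and multi-omics co-regulation analysis.

`saltscreen` implements the quantitative evaluation chain used in salt-stress
screening studies of crop accessions, together with the downstream omics
screening steps, as a tested, reusable pipeline:

- **`saltscreen.tolerance`** — salt-tolerance coefficients (relative plant
  height / fresh weight / dry weight), min–max membership scores, the
  equal-weight composite evaluation value **D** with ranking, the per-trait
  salt tolerance index (STI), and a configurable weighted-grade salt injury
  index.
- **`saltscreen.physiology`** — relative electrolyte leakage
  ((S1/S2) × 100 %), chlorophyll a/b content from ethanol-extract absorbances
  (13.95·A665 − 6.88·A649 etc.), Na⁺/K⁺ ratios, signed percent change, and
  mean ± SD summaries of replicated indicator time courses.
- **`saltscreen.qpcr`** — relative expression by the 2^(−ΔΔCt) method and
  squared-Pearson concordance between qPCR and RNA-seq log2 fold changes.
- **`saltscreen.omics`** — threshold screening of differential genes
  (|log2FC| ≥ 1, adjusted p < 0.05) and metabolites (additionally VIP ≥ 1),
  exact multi-set Venn region counts, hypergeometric enrichment against
  user-supplied annotation sets, and Benjamini–Hochberg FDR adjustment.
- **`saltscreen.conet`** — metabolite–gene co-regulation network: vectorized
  pairwise Pearson correlation with exact t-based p-values, BH-FDR across all
  tested pairs, |R|/FDR edge thresholds, degree ranking, and deterministic
  Gephi-ingestible export (edge-list CSV and GEXF, byte-identical
  round-trip).
- **`saltscreen.simulate`** — synthetic inputs with recorded ground truth
  (planted tolerance gradient, planted differential features, planted
  correlated pairs) so every stage is testable without external data.

## Command line

```bash
# synthetic data (traits, per-feature statistics, abundance matrices)
saltscreen simulate traits   --out sim/ --seed 1
saltscreen simulate stats    --out sim/ --seed 1 --groups P47S_VS_CK47S,P18S_VS_CK18S
saltscreen simulate matrices --out sim/ --seed 1 --n-linked 5

# accession ranking by composite D
saltscreen screen-tolerance --traits sim/traits.csv --weights equal --out scores.csv

# physiology formulas
saltscreen physiology leakage   --in conductivity.csv --out leakage.csv
saltscreen physiology pigments  --in absorbances.csv  --out pigments.csv
saltscreen physiology ions      --in ions.csv         --out ratios.csv
saltscreen physiology summarize --in timecourse.csv   --out summary.csv

# qPCR relative expression
saltscreen qpcr --in ct.csv --out rel.csv

# DEG/DAM screening, Venn regions, enrichment
saltscreen omics-filter degs --stats stats.csv --out degs/
saltscreen omics-filter dams --stats stats.csv --out dams/
saltscreen omics-filter venn --sets g1=degs/up.txt --sets g2=other.txt --out venn.csv
saltscreen omics-filter enrich --selected degs/up.txt --annotation pathways.csv \
    --background background.txt --out enrichment.csv

# co-regulation network
saltscreen network --metab sim/metabolites.csv --genes sim/genes.csv \
    --r-min 0.8 --fdr 0.05 --out net.gexf --ranking degree.csv
```

`simulate` subcommands also accept `--config cfg.yaml` with any
`SimulationConfig` fields (counts, noise, effect sizes, seed).

## File formats

All inputs/outputs are plain UTF-8 CSV with `.` decimals:

- traits: `accession,trait,condition,replicate,value` with trait ∈
  {PHt, FW, DW} and condition ∈ {control, salt};
- tolerance scores: `accession,RPHt,RFW,RDW,mu_RPHt,mu_RFW,mu_RDW,D,rank`
  (4-decimal report precision, full precision internally);
- feature statistics: `feature,kind,group,log2fc,adj_p,vip`;
- Ct tables: `sample,group,gene,ct_target,ct_reference`;
- abundance matrices: features × samples, first column `feature`;
- annotation: two-column `set_id,feature` CSV or GMT
  (`set_id<TAB>description<TAB>members…`);
- networks: `source,target,weight,sign,R,fdr` edge list or GEXF 1.2.
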