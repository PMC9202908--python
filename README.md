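# tadscope

Integrative prioritization of GWAS risk-locus genes from paired RNA-seq and
Hi-C topology — with a fully seeded synthetic-data generator for validating
every step against planted ground truth.

## The problem

For disorders such as keloid disease, genome-wide association studies find
risk SNPs only in non-coding regions, so the susceptibility loci name no
genes. One way forward combines three data types from the same biological
question: (i) paired lesion/normal RNA-seq (mRNA, lncRNA, miRNA) from a
handful of patients, analysed as a self-controlled design; (ii) co-expression
and regulatory-network structure over the differentially expressed RNAs; and
(iii) chromatin topology — the topologically associating domain (TAD)
containing a risk SNP delimits the genes that share its cis-regulatory
context, so differentially expressed RNAs inside that TAD become the
locus's candidate genes.

tadscope implements that workflow end to end:

- **Paired NB differential expression** — median-of-ratios size factors
  s_i; per feature g a negative-binomial log-linear model
  `K_gi ~ NB(mu_gi, alpha)` with
  `log mu_gi = log s_i + mu_g + patient_p(i) + beta_g * 1[lesion]`,
  fit by IRLS with a fixed moment-estimated dispersion; log2FC = beta/ln 2,
  two-sided Wald p, Benjamini–Hochberg q per RNA class, and the class
  filters (mRNA/lncRNA: q < 0.05 and |log2FC| >= 2; miRNA: q < 0.05 and
  |log2FC| >= 0.67).
- **Co-expression** — lncRNA–mRNA pairs with Pearson r > 0.9; WGCNA-style
  unsigned adjacency `a_ij = |r_ij|^beta`, topological overlap
  `t_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)`, average-linkage
  clustering of 1−TOM with a static cut, size-ordered color labels, module
  eigengenes and DE-based module significance.
- **Regulatory network** — typed miRNA→target, lncRNA–mRNA co-expression
  and optional PPI edges; degree ranking (top-20 table); module-restricted
  subnetworks; SIF/GraphML export.
- **Enrichment** — one-sided Fisher/hypergeometric over-representation of
  gene sets (GMT), p < 0.01, BH-adjusted.
- **Hi-C TADs** — square-window insulation score
  `IS(b) = log2(raw(b) / mean raw)` at 40 kb bins (window 5 = 200 kb);
  boundaries at strong local minima; TAD loading from BED for externally
  called domains; locus→TAD lookup.
- **Locus prioritization** — features with TSS inside the risk SNP's TAD,
  screened at raw p < 0.05 and |log2FC| >= 1, reported per locus (empty and
  TAD-less loci reported explicitly).

The synthetic-data generator (`tadscope.simulate`) emulates the study design
— 3 patients × 2 conditions, NB counts with patient effects, planted DE with
class-specific effect sizes, latent-factor co-expression modules,
block-structured Hi-C with planted (sub-)TADs, risk loci planted inside
specific TADs — and emits machine-readable truth tables for all of it.

## Worked example

`examples/05_tads_and_locus_prioritization.py` generates the default study
(seed 7), calls TADs from the synthetic Hi-C, and screens each risk locus:

```
chr1: 14 TADs called (14 planted)
chr2: 11 TADs called (11 planted)
  locus status  n_candidates
locus_A     ok             5
locus_B  empty             0
locus_C     ok             5
  locus         feature_id rna_class    log2fc            p direction
locus_A   candA_lncRNA_up2    lncRNA  2.721560 3.747056e-10        up
locus_A     candA_mRNA_up1      mRNA  2.464429 1.396796e-08        up
locus_A   candA_lncRNA_up3    lncRNA  2.169807 5.535938e-07        up
locus_A   candA_lncRNA_up1    lncRNA  1.716537 1.845824e-04        up
locus_A          mRNA_0505      mRNA -1.086901 2.387247e-02      down
locus_C     candC_mRNA_up2      mRNA  2.505030 1.821366e-08        up
locus_C candC_lncRNA_down2    lncRNA -2.110906 1.074101e-06      down
locus_C   candC_mRNA_down1      mRNA -2.065039 2.068489e-06      down
locus_C     candC_mRNA_up1      mRNA  1.995914 4.529308e-06        up
locus_C     candC_mRNA_up3      mRNA  1.878313 1.511297e-05        up
recovered 9/10 planted candidates; locus_B is the deliberately empty locus
```

Every boundary of the 25 planted TADs is recovered; locus_A and locus_C
return their planted candidates (log2FC is the estimated lesion/normal fold
change, p the paired Wald p-value; `mRNA_0505` is a background feature whose
estimate crossed the TAD-local screen), and locus_B — planted with no
candidate genes, mirroring a risk locus private to another population —
correctly comes back empty. The remaining examples walk through simulation,
differential expression, module detection, network/enrichment and the
one-call pipeline (`tadscope run --seed 7 --outdir out`).

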