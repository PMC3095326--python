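# mycolib

Analysis of clone-library ITS surveys of root-associated fungal
communities: sequence quality control, OTU clustering, hierarchical
diversity statistics and total-species richness extrapolation — with a
ground-truthed synthetic-survey generator for validating every step.

## The problem

Surveys of root-associated fungi (ectomycorrhizal symbionts, dark septate
endophytes) often sequence a fixed number of cloned ITS fragments from each
sampled root system under a nested spatial design: main localities >
sub-localities > individual plants.  Turning those clones into community
conclusions takes a chain of decisions, each with failure modes:

- **Chimera screening.**  PCR template switching produces recombinant
  ITS1/ITS2 fragments.  A clone observed identically in several root
  systems is authentic; a singleton is flagged when its ITS1 and ITS2
  best-match references of *different genera* (split-marker consistency).
- **PCR-error collapse.**  Within a root system, a lone sequence with ≤2
  substitutions relative to a more abundant one is treated as polymerase
  error and merged (two lone near-identical clones merge into their IUPAC
  consensus, e.g. `Y` for C/T); ≥3 unique substitutions count as genuine
  variation.
- **OTU clustering.**  Unique genotypes are grouped at 97% pairwise
  identity (single linkage, the semantics of overlap-based contig
  assembly) and named from the best reference match: ≥97% → species name,
  90–97% → *Genus* sp.N, <90% → family/order label.
- **Richness extrapolation.**  Accumulation curves of such surveys rarely
  level off.  The total-species (T-S) method exploits between-sub-area
  heterogeneity: for every k, the mean terminal richness T_k over
  combinations of k sub-areas (root systems) is computed, T_k is regressed
  on ln(sampling effort), and the fit is read off at a much larger target
  area (e.g. 10⁶ root systems), with uncertainty from bootstrap resampling
  of sub-areas:

  T_k = a + b·ln(n_k),  Ŝ(N) = a + b·ln(N·m),  SD over 100 resamples.

- **Spatial structure.**  Shared-OTU means per spatial stratum, Venn
  counts of sub-locality OTU sets, Sørensen dissimilarities
  (1 − 2|A∩B|/(|A|+|B|)), and ordination by *two methods in parallel* —
  detrended correspondence analysis and global NMDS (Kruskal stress-1,
  100 starts, solutions accepted only when reached from ≥2 starts) — whose
  Kendall-tau concordance indicates the gradients are real.

All of it is exercised end-to-end on a synthetic metacommunity generator
(`mycolib.simulate`) that emulates the survey design (4 main localities ×
3 sub-localities × 2 root systems × 24 clones, 137 true OTUs, lognormal
abundances, hierarchical turnover, 0.8% chimeras, rare PCR errors) and
emits complete ground truth, so QC sensitivity/specificity, clustering
recovery and estimator bias are all measurable.

## Worked example

```python
from mycolib import (SimulationConfig, generate_metacommunity, sample_clone_library,
                     ReferenceDB, run_qc, cluster_otus, TotalSpeciesEstimator,
                     shared_otu_stats)

cfg = SimulationConfig(seed=1)            # the 4 x 3 x 2 x 24 survey design
community = generate_metacommunity(cfg)
records, truth = sample_clone_library(community, cfg)
reference = ReferenceDB.from_metacommunity(community)

qc = run_qc(records, reference)
otus = cluster_otus(qc.genotypes, reference)
est = TotalSpeciesEstimator(random_state=1).fit(
    otus.incidence.T.to_numpy(), groups=list(otus.incidence.columns))
```

prints (via the obvious `print` statements):

```text
581 clones sequenced, 5 chimaeric, 159 unique genotypes
107 OTUs at 97% identity; 76.6% seen in one root system
   otu_id         name  best_identity  n_clones
0  OTU001  species_005       0.993878        18
1  OTU002  species_090       0.993878        18
2  OTU003  species_026       1.000000        18
observed 107 OTUs; T-S estimate at 10^6 root systems 461 (bootstrap 330 +/- 29)
                stratum  mean_shared  n_pairs
     within_sublocality     1.833333       12
  between_sublocalities     1.104167       48
between_main_localities     0.421296      216
```

Reading this: of 581 sequenced clones, 5 (0.86%) were flagged as chimaeric
by the split-marker screen and the rest collapse to 159 unique genotypes
and 107 OTUs, three-quarters of which occur in a single root system —
strong fine-scale patchiness.  The mean number of OTUs shared by two root
systems falls from 1.83 (same sub-locality) to 0.42 (different main
localities): weak but real geographic structure.  The observed richness
(107) is far below the T-S extrapolation (461 at 10⁶ root systems),
the signature of a heavily undersampled community.

The same run from the shell:

```bash
mycolib all --seed 1 --out run/
# 581 clones -> 159 genotypes -> 107 OTUs; summary in run/summary.json
```

`run/` then contains every stage artifact as plain text: `clones.fasta`,
`sample_map.tsv`, `reference.fasta`, `truth.tsv`, `qc_report.tsv`,
`genotypes.fasta`/`.tsv`, `otu_summary.tsv`, `incidence.tsv`,
`accumulation_curves.tsv`, `ts_report.tsv`, `sharing_stats.tsv`,
`venn_counts.tsv`, `ordination_scores.tsv`, `concordance.tsv` and
`summary.json`.  Stages can be run separately (`mycolib simulate`, `qc`,
`cluster`, `richness`, `community`) and compose to the same bytes.

Real data enter the same way: point the configuration at a clones FASTA, a
clone→hierarchy sample map TSV and a labelled reference FASTA (headers
`>id regions=<its1_end>:<5.8s_end> taxonomy=<species>|<genus>|<family>`)
instead of the `simulate` block.

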