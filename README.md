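# gcircuits

Integrated copy-number / expression / mutation analysis for tumor cohorts,
built around the kind of evidence that links urothelial-carcinoma subtypes
to distinct "genomic circuits" — connected sets of co-occurring genomic
alterations such as *FGFR3* mutation + 9q loss + *CDKN2A* deletion +
*CCND1* overexpression on one side, and 6p22 (*E2F3*) amplification +
*RB1* deletion + 5p gain + low *PTEN* expression on the other.

It is aimed at cancer-genomics analysts who have **already-segmented**
array-CGH (or similar) log2-ratio profiles on a shared probe grid, plus
matched expression, mutation, and clinical tables, and who want a tested,
scriptable implementation of the classic integrated workflow:

1. **Copy-number state calling** (`gcircuits.calling`) — per-sample
   sample-adaptive thresholds (SAT) on 250 kb-smoothed data give
   GAIN/LOSS calls; unsmoothed segmented values at log2 ≥ 0.8 / ≤ −0.8
   over runs of more than three consecutive probes give focal
   amplifications (FGA) and homozygous deletions (HD); >50 %-of-arm rules
   give arm-level events; FGAs < 1 Mbp apart merge into one amplicon.
2. **Recurrent-region discovery** (`gcircuits.recurrence`) — per-probe
   support counts; local peak maxima become core regions (minima: FGA 3,
   HD 2, MRD 15 samples); boundaries extend to include cases within 2 of
   the peak (1 for HDs); germline-CNV-heavy regions are masked;
   MRD/HD overlaps resolve to the HD boundaries; arm-scale MRDs are
   suppressed in favour of arm calls.
3. **Genomic complexity** (`gcircuits.complexity`) — nFGA (merged
   amplicon count), fBAC (fraction of altered probes), CIN signature
   score (mean gene-wise z), TP53/MDM2 pathway status, IHC protein scores
   (intensity 0–3 × positive fraction), and the standard group tests.
4. **Expression subtyping** (`gcircuits.subtyping`) — geometric-mean
   batch scaling, negative capping, +30 offset, quantile normalization,
   log2, SD > 0.25 filter; Ward (ward.D2) clustering on 1 − Pearson
   distances into HC groups and the 2-way MS split; rank-based gene
   categorization; Welch-t + Bonferroni differential expression.
5. **Association networks** (`gcircuits.association`) — exact one-sided
   hypergeometric co-occurrence/exclusivity tests in log space, Fisher
   tests against subtype groups, Bonferroni control, Jaccard-distance
   classical MDS of alteration features, and the significant-edge network
   whose connected components are the circuits.
6. **Survival** (`gcircuits.survival`) — Kaplan–Meier estimates and
   log-rank tests with disease-specific survival as the endpoint.

A fully parameterised synthetic-cohort generator
(`gcircuits.simulate`) emulates a 146-sample cohort on a reduced
3000-probe grid with two planted circuits, passenger events, batch-shifted
expression and group-specific exponential survival, so the entire pipeline
is testable end to end with recorded ground truth.

## Worked example

```python
from gcircuits import (SimulationConfig, generate_cohort, call_cohort,
                       deletion_masks, discover_all_regions,
                       recurrent_arm_regions, normalize_expression,
                       hca_clusters, signature_score, complexity_table,
                       define_survival_groups, logrank)

cohort = generate_cohort(SimulationConfig(seed=1))
calls, events, arm_calls = call_cohort(cohort.profiles, cohort.probe_map)
masks = deletion_masks(calls.states, calls.sample_ids)
regions = discover_all_regions(events, masks, cohort.probe_map)
for r in regions:
    start, end = cohort.probe_map.genomic_span(r.ext_start, r.ext_end)
    print(f"{r.kind:3s} {r.chrom}:{start/1e6:.1f}-{end/1e6:.1f} Mb  "
          f"support={r.max_support}")
for a in recurrent_arm_regions(arm_calls):
    print(f"{a.kind} {a.arm}  frequency={a.frequency:.2f}")

norm = normalize_expression(cohort.expression_raw, cohort.batches)
assign = hca_clusters(norm, k=5)
print("MS class sizes:", assign.ms.value_counts().to_dict())

cin = signature_score(norm, cohort.truth.cin_genes)
comp = complexity_table(events, calls, cin_scores=cin)
chi2, p = logrank(cohort.clinical, define_survival_groups(comp, "cin_median"))
print(f"log-rank CIN-high vs CIN-low: chi2={chi2:.2f}, p={p:.4f}")
```

Output:

```
FGA chr1:60.0-61.1 Mb  support=20
FGA chr3:8.0-9.2 Mb  support=35
HD  chr2:12.0-12.9 Mb  support=29
HD  chr4:50.0-50.9 Mb  support=26
MRD chr2:67.7-75.0 Mb  support=52
MRD chr3:52.1-53.9 Mb  support=48
MRD chr4:10.1-11.7 Mb  support=30
ARM_GAIN 1p  frequency=0.31
ARM_LOSS 2q  frequency=0.34
ARM_LOSS 3q  frequency=0.20
ARM_LOSS 4q  frequency=0.29
MS class sizes: {'MS1': 84, 'MS2': 62}
log-rank CIN-high vs CIN-low: chi2=37.83, p=0.0000
```

Every planted event is recovered: the two focal amplifications (a
CCND1-like amplicon carried by 20 samples and a 6p22-like amplicon by
35), the two homozygous deletions (CDKN2A-like, RB1-like), the two
planted minimal deletion regions, plus the arm-level gains/losses that
define the circuits. The extra chr2 MRD sits inside the whole-arm 2q
deletion — a peak produced by overlapping passenger deletions, the
behaviour the arm-scale suppression rule exists to contain (the arm event
itself is reported as `ARM_LOSS 2q`). The expression split recovers the
two molecular subtypes exactly, and a CIN-score median split strongly
stratifies disease-specific survival.

The same workflow is available from a shell:

```sh
gcircuits run-all --outdir out/ --seed 1
```

writes the cohort, call matrix, region tables (TSV + BED), alteration
matrix, subtype assignments, complexity table, association edges, MDS
coordinates, circuit components and survival results into `out/`.

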