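# cksr — convergent kinase–substrate relationship analysis

Protein phosphorylation is organized as a bipartite network: ~500 human
kinases acting on thousands of substrate proteins.  A *convergent*
kinase–substrate relationship (cKSR) is a local motif in which two or more
kinases phosphorylate the same target — either the same substrate protein on
any site (a **general** cKSR) or the very same phosphosite (a **site-specific**
cKSR).  Convergence underlies signal amplification, pathway crosstalk and
feedback loops, and it confounds in-cell assays of individual kinases: the
prototypical example is the CDK4/CDK6 pair, two CMGC-family cyclin-dependent
kinases that both phosphorylate the retinoblastoma protein RB on S780.

`cksr` is a pipeline for quantifying these motifs network-wide from a table of
experimentally validated kinase–substrate relationships (the PhosphoSitePlus
`Kinase_Substrate_Dataset` dialect, or a plain TSV).  It computes, separately
for Ser/Thr and Tyr phosphorylation events:

- **Convergence maps** — each unique target's set of "active kinases",
  identified by string fingerprints `KINASE:SUBSTRATE` /
  `KINASE:SUBSTRATE:SITE` after species filtering, nomenclature
  normalization and deduplication.
- **K:1 topology histograms** — for each target the number of acting kinases
  K (1 ≤ K ≤ 50; larger values go to an overflow bin), the count of targets
  per K, and the fraction of targets with K ≥ 2.
- **Kinase participation** — which kinases act on at least one convergent
  target, with substrate/site degree distributions per kinase.
- **Family-subgroup composition** — counts of acting kinases per target in the
  ten canonical kinome subgroups (AGC, CAMK, CK1, CMGC, RGC, STE, TK, TKL,
  atypical, other; KinHub annotation), and the number of targets hit by
  multiple subgroups versus by ≥ 2 kinases of a single subgroup.
- **Reciprocal phosphorylation loops** — unordered kinase pairs {A, B} with
  both A→B and B→A records (e.g. MEK1/ERK1-style feedback).
- **Co-expression scores** — for each convergent kinase group, the percentage
  of cell lines (CCLE-style log₂(TPM+1) transcriptomes at TPM thresholds
  5/10/20, or median-thresholded MS proteomes) expressing ≥ 2 of the group's
  kinases.

A synthetic-data module generates all of these inputs with *planted* ground
truth — exact K:1 topologies, reciprocal loops, subgroup assignments and
per-kinase Bernoulli expression probabilities — so the entire pipeline is
verifiable without the registration-gated PhosphoSitePlus and CCLE downloads.

## Worked example

```python
from cksr import (KSRDataset, KSRRecord, ResidueClass, build_convergence_map,
                  deduplicate, make_fingerprint, split_residue_classes,
                  topology_histogram)

records = [
    KSRRecord(kinase="CDK4", substrate="RB", site="S780"),
    KSRRecord(kinase="CDK6", substrate="RB", site="S780"),
    KSRRecord(kinase="CDK2", substrate="RB", site="T373"),
    KSRRecord(kinase="ATM",  substrate="CHEK2", site="T68"),
]
print(make_fingerprint(records[0], "general"))        # CDK4:RB
print(make_fingerprint(records[0], "site_specific"))  # CDK4:RB:S780

st = split_residue_classes(KSRDataset(records=records))[ResidueClass.SER_THR]
cm = build_convergence_map(deduplicate(st, "site_specific"),
                           "site_specific", ResidueClass.SER_THR)
hist = topology_histogram(cm)
for target, kinases in sorted(cm.entries.items()):
    print(target, sorted(kinases))
print(f"{hist.convergent_targets}/{hist.total_targets} sites convergent "
      f"({hist.convergent_fraction:.1f}%)")
```

prints

```
CDK4:RB
CDK4:RB:S780
CHEK2:T68 ['ATM']
RB:S780 ['CDK4', 'CDK6']
RB:T373 ['CDK2']
1/3 sites convergent (33.3%)
```

RB:S780 is a 2:1 site-specific cKSR (two kinases, one site); the other two
sites have a single known kinase each, so one of the three Ser/Thr sites
(33.3%) is convergent.

## Command line

```bash
cksr simulate --seed 1 --out bundle/          # synthetic inputs + ground truth
cksr run --config cfg.yaml --out report/      # full pipeline from a config
cksr ingest --input psp.tsv --dialect psp_v6 --species human --out clean.tsv
cksr converge --input clean.tsv --level site --class st --out-prefix st_site
cksr coexpr --matrix expr.csv --mode tpm --threshold 10 \
            --groups st_site_targets.tsv --out scores.tsv
```

`cksr run` emits one TSV per analysis (target lists, K:1 histograms, kinase
tables, family counts, loop table, co-expression tables) plus a
`summary.json` with every headline fraction; reruns on identical inputs are
byte-identical.

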