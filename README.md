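# endrip

Strand-paired DSB cluster calling, seven-category R-loop kinetic
classification, and randomization overlap enrichment for END-seq / DRIP-seq
studies of topoisomerase-I poisoning.

## The problem

Camptothecin-class drugs trap topoisomerase I on DNA (Top1 cleavage
complexes), perturbing DNA-RNA hybrid (R-loop) levels within minutes and
triggering double-strand breaks (DSBs) where transcription and replication
collide.  Mapping this requires two specialized assays and bespoke
downstream logic that generic peak-calling toolchains do not provide:

- **END-seq** maps DSBs strand-specifically: reads pile up on the minus
  strand left of a break (F2R1) and on the plus strand right of it (F1R2).
  A *double-ended* break is a reverse peak paired with a forward peak less
  than 150 bp downstream; the cluster spans reverse start to forward end.
  A *single-ended* break (replication run-off) leaves a solitary one-strand
  peak more than 150 bp from any opposite-strand peak.
- **DRIP-seq** maps hybrids; treated-vs-untreated contrasts at an early (5
  min) and late (60 min) timepoint split peaks into seven kinetic
  categories (stable/transient/late x gain/loss, plus no change), after an
  RNase H1 control filter removes hybrid-independent false positives.

`endrip` implements this pipeline — pairing, replicate consensus, spike-in
normalization, moderated differential testing, kinetic classification,
solitary-peak detection, gene-feature annotation, reference-point
metaprofiles, and shuffle-based overlap enrichment — as a tested library
with a CLI, plus a synthetic-data generator that plants ground truth so
every stage can be validated without external sequencing data.  It is
aimed at genomicists analyzing strand-resolved break maps or hybrid
kinetics, and at method developers who need a transparent, fully seeded
reference implementation.

## Statistics at the core

Spike-in normalization: per library, the raw spike factor
`f = RiP/RQC` (END-seq) or the spike read fraction (DRIP) is rescaled by
the experiment minimum (`s = f / min f`) and combined with a library-size
factor `l = median(N)/N`; counts are corrected as `raw * l / s`.

Differential testing is a moderated t-test on `log2(normalized + 0.5)`:
the per-region pooled variance is shrunk toward the median across regions,
`s~2 = (d0*s0^2 + d*s^2)/(d0 + d)` with `d0 = 4`, and
`t = log2FC / (s~ * sqrt(1/nA + 1/nB))` on `d0 + d` df.  DSB clusters gate
at `|log2FC| > 1, p < 0.05`; hybrid contrasts gate at `p < 0.01`.

Overlap enrichment of a query class in a feature set: the observed overlap
count `k` out of `n` query intervals is compared with the mean count over
100 length- and chromosome-preserving shuffles; `p` is the binomial tail at
`p_hat = expected/n` and the effect is `log2((k+0.5)/(expected+0.5))`.

See `docs/methods.md` for the full model description and design decisions.

## Worked example

Run the full synthetic study (simulate, call DSBs, classify R loops,
enrichment, profile) in one command:

```sh
endrip all --out study --seed 1
```

or step by step with the numbered drivers:

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_call_dsb_clusters.py
python analysis/03_classify_rloop_kinetics.py
python analysis/04_enrichment_and_profiles.py
```

The drivers print, for seed 1:

```
cluster classes: {'persistent': 100, 'transient': 98, 'late': 100, 'unclassified': 2}
recovered 99.3% of 300 planted breaks, class accuracy 100.0%, 0 false clusters from solitary peaks

category counts: {'no_change': 49, 'late_loss': 45, 'stable_gain': 40, 'late_gain': 40,
                  'transient_gain': 38, 'stable_loss': 35, 'transient_loss': 33}
category accuracy 94.3% over 280 planted hybrid peaks; RNase H filter removed 100% of
decoys, retained 100% of true peaks

      features  observed  expected    log2fc            p direction
   stable_gain        39      0.70  5.040746 5.399252e-57  enriched
   stable_loss         0      0.45 -0.925999 6.369809e-01  depleted
   ...
   gene_bodies         6      7.31 -0.264883 3.975273e-01  depleted
```

Reading this: of 300 planted double-ended breaks, 298 are recovered as
strand-paired clusters and every recovered cluster lands in its planted
kinetic class; none of the 30 planted single-ended breaks is mistaken for
a cluster.  On the DRIP side, 94% of hybrid peaks receive their planted
kinetic category (misses are low-power cases near the p < 0.01 gate) and
the RNase H filter separates decoys from true peaks perfectly at the
planted signal levels.  The enrichment table recovers the planted
association — persistent DSB clusters sit inside stable hybrid gains
(observed 39 vs 0.7 expected, log2FC 5.0) and nowhere else.

Class BEDs, differential tables, scale factors, profiles and recovery
summaries are written under `results/` (or `study/` for the CLI run, with
a `run_manifest.json` of checksums per stage).

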