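# tcstalk

Prediction of cognate partners and inter-species cross-talk in bacterial
two-component signalling systems (TCS).

## The problem

Bacteria sense their environment through two-component systems: a sensor
histidine protein kinase (HPK) autophosphorylates on a histidine within
its DHp (dimerisation and histidine-phosphotransfer) domain and passes
the phosphoryl group to the REC (receiver) domain of a cognate response
regulator (RR). Specificity between the two is carried largely by the
DHp and REC domains, so sequence similarity in those domains predicts
shared phosphotransfer partners. Two practical questions follow:

* **Orphans** — which RR does an HPK phosphorylate when it is not encoded
  in an operon with one?
* **Cross-talk** — when a synthetic biologist moves a TCS into a new host
  species, which native host proteins will it unintentionally talk to?

`tcstalk` answers both with a simple genomic-context method:

1. **Extract** DHp and REC domain instances from profile-HMM hit tables,
   keeping hits with per-domain independent E-value strictly below 0.01.
2. **Align** all instances of each class against each other with exact
   Smith–Waterman (BLOSUM62, affine gaps, gap cost `11 + k`), converting
   raw scores `S` to E-values via the Karlin–Altschul form
   `E = K·m·n·e^(−λS)`.
3. **Cluster** each class with the Markov Cluster algorithm on the
   TRIBE-style graph (edge weight = mean of −log₁₀E over both
   directions), at inflation `I = 5`.
4. **Pair** kinases and regulators encoded in the same operon (same
   strand, intergenic gap ≤ 200 bp) with at most two intervening genes —
   these are the probable cognate pairs; HPKs/RRs left unpaired are the
   orphans.
5. **Tabulate** pair counts over (DHp cluster × REC cluster) and
   row-normalise: entry `P(r | h)` is the observed likelihood that a
   kinase in DHp cluster `h` partners a regulator in REC cluster `r`.
6. **Predict**: an orphan or foreign kinase is routed to its DHp cluster
   (directly, or by local alignment for a novel sequence); host kinases
   sharing that cluster are cross-talk competitors, and host regulators
   in the cluster's top partner REC cluster are candidate substrates.

A fully ground-truthed synthetic data generator (multi-species genomes
with sequence families, paired operons, decoy genes, planted orphans and
an introduced foreign TCS) makes every stage testable end to end.

## Worked example

Simulate two species with a cross-talk scenario (family 0's regular
operons removed from host `sp00`, replaced by one lone orphan kinase and
one partner-family orphan regulator), plant a foreign family-0 kinase,
and run the pipeline:

```sh
tcstalk simulate --out demo/data --seed 5 --n-species 2 --members 2 \
    --crosstalk-family 0 --crosstalk-host 0 \
    --plant-foreign 0 --foreign-host sp00
tcstalk run-all --fasta demo/data/proteins.fasta \
    --domtbl demo/data/domains.domtblout \
    --genes demo/data/genes.tsv --out demo/db
```

```
8 DHp clusters, 8 REC clusters, 30 cognate pairs, 5+4 orphans
```

All eight planted kinase families come back as eight DHp clusters; 30
operon-encoded cognate pairs feed the probability table; the planted
orphans (including the scenario pair) are reported. Now ask which host
proteins the foreign kinase (protein `90001102`) will cross-talk with:

```sh
tcstalk predict-crosstalk --db demo/db --query 90001102 --host sp00
```

```
query cluster: DHp 7 (best hit 90001102/DHP/1)
partner REC cluster(s): 7
host kinase candidates: 90000051
host regulator candidates: 90000052
```

The foreign kinase lands in DHp cluster 7 alongside exactly one host
kinase (`90000051`, the planted orphan of the same family) — a
competitor for the same substrates — and the table's top partner REC
cluster contains exactly one `sp00` regulator (`90000052`, the planted
partner-family orphan): the predicted cross-talk pair. Partner lookup
for an orphan kinase works the same way per cluster:

```sh
tcstalk predict-partner --db demo/db --cluster 0 --species sp01
```

```
DHp cluster 0 -> REC cluster 0	p=1.0000	90000059,90000061,90000101
```

i.e. kinases in DHp cluster 0 always paired with REC cluster 0, and
those are the `sp01` proteins carrying REC domains in that cluster.

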