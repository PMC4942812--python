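# metcouple

Joint analysis of matched transcriptomic and metabolomic cohorts on a
genome-scale metabolic network: detect **enzyme–metabolite coupling**
(the association between a metabolic enzyme gene's expression and the
level of a metabolite of its reaction) and exploit it to **predict
per-sample metabolite levels from expression alone**.

The package is aimed at computational biologists working with paired
tumor/normal omics who want to (a) quantify how strongly connected
gene–metabolite pairs co-vary per condition, (b) extend sparse targeted
metabolomics panels by predicting unmeasured metabolites, and (c) screen
predicted metabolites against clinical endpoints.

## The method

Let a gene *g* and metabolite *m* be *connected* when *g* catalyzes a
reaction that consumes or produces *m*, and let an RGM triplet be a
(reaction, gene, metabolite, substrate/product role) tuple.  The
pipeline has two steps:

1. **RGM classifier.**  Connected pairs measured in both omics get a
   Spearman ρ per condition stratum; FDR-significant pairs
   (Benjamini–Hochberg, α = 0.05) label their triplets ±1 by the
   correlation sign.  A class-balanced linear-kernel SVM over 14
   network + expression features (model positions, pathway code, ΔG⁰,
   reversibility, expression mean/var/min/max, reaction composition,
   role flag) is trained on the labeled triplets and emits a calibrated
   confidence in [−1, +1] for *every* triplet in the network —
   including the large majority whose metabolite was never measured.
   An empirical permutation null (classifiers retrained on permuted
   labels) converts confidences into FDR-controlled significance calls.

2. **Level regressor.**  Per metabolite, the most positively (GR⁺) and
   most negatively (GR⁻) confident gene–reaction anchors are selected
   (reported when the best confidence exceeds 0.5); their two 14-feature
   blocks — with the gene-mean slot holding the anchor gene's expression
   in the sample at hand — form 28-feature instances, and one pooled
   ordinary-least-squares model maps instances to z-scored log
   metabolite levels.

Around the two steps: a gene-label permutation test for coupling
enrichment (empirical p = (r+1)/(n+1)), a significant-pair bipartite
gene–metabolite graph with hub pathway enrichment, prediction-based and
raw-data pathway analyses, and a median-split Kaplan–Meier log-rank
screen of (predicted) metabolites against survival and ER status.  A
first-class synthetic-cohort generator plants couplings with exact
Spearman strengths, pathway localization, hazard and ER links, so every
stage is validated against ground truth.  See `docs/methods.md` for the
full model description and design rationale.

## Worked example

Generate a planted cohort, train the classifier and inspect recovery:

```python
import metcouple as mc
from metcouple import association, classifier
from metcouple.network import CYTOSOL, connected_gm_pairs, enumerate_rgm_triplets

net = mc.generate_network(300, 200, 60, n_pathways=10, seed=0)
cohort, truth = mc.generate_omics(
    net, n_samples_per_condition=50,
    coupling_fraction_by_condition={"noncancerous": 0.0, "cancer": 0.4},
    strength_range=(0.7, 0.7), seed=1000)

pairs = connected_gm_pairs(net, CYTOSOL)
cols = cohort.samples[cohort.sample_mask("cancer")]
table = association.spearman_table(
    cohort.expression[cols], cohort.metabolites[cols], pairs, stratum="cancer")

feats, _ = classifier.build_features(net, cohort.expression[cols],
                                     enumerate_rgm_triplets(net))
labels = classifier.build_labels(table, feats)
lab = (labels != 0).to_numpy()
X = classifier.encode_features(feats, net)
cv = classifier.cross_validate(X[lab], labels[lab].to_numpy(), k=5, seed=0)
print(f"{len(pairs)} connected pairs, {int(lab.sum())} labeled triplets, "
      f"mean CV AUC = {cv.mean_auc:.3f}")
```

```
1702 connected pairs, 76 labeled triplets, mean CV AUC = 0.968
```

With 40% of the connected metabolites coupled to a driver-gene module at
Spearman 0.7 in the cancer stratum only, 76 triplets pass the FDR label
filter and the 5-fold cross-validated AUC of 0.968 shows the network
features recover the planted association signs almost perfectly.

The same pipeline runs from the shell:

```bash
metcouple generate --n-reactions 300 --n-genes 200 --n-metabolites 60 \
    --n-pathways 10 --n-samples-per-condition 50 --seed 0 --out demo/
metcouple run-all --config demo_config.yaml --out demo_run/
```

where the YAML config names the network/cohort paths and the thresholds
(α = 0.05, 1000 permutations, 5 folds, confidence threshold 0.5, degree
threshold 4, 10-pair pathway minimum).  Each run directory contains the
per-stratum association tables, permutation statistics, confidence
tables with cross-validation reports, GraphML bipartite graphs, the
predicted metabolite matrix with its evaluation, pathway enrichment
tables and the clinical screens, plus a JSONL log and the config hash.

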