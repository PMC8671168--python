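# distrank

Distance-map-driven quality assessment, ranking and combination of protein
structure models.

When a structure-prediction pipeline produces dozens of candidate tertiary
models for a target, the hard decisions are downstream of modelling: which
model to trust (estimation of model accuracy, EMA), whether to merge the
top models into something better, and where the target's domain boundaries
lie.  `distrank` implements that decision core for single-chain Ca-level
models, for people building or studying CASP-style prediction pipelines:

* **Similarity metrics** — Kabsch superposition, GDT-TS and TM-score with a
  documented seed-and-extend search (exact by subset enumeration on small
  chains):
  GDT-TS = mean over c ∈ {1, 2, 4, 8} Å of max fraction of Ca within c;
  TM-score = max (1/L_ref) Σᵢ 1/(1 + (dᵢ/d₀)²), d₀ = 1.24(L_ref−15)^⅓ − 1.8.
* **2D features** — nine distance-map matching scores (SSIM, PSNR, GIST,
  RMSE, recall, precision, PHASH, Pearson, ORB) comparing a predicted
  distance map with the map realised in a model, plus short/medium/long
  top-L/2 contact matching precision.
* **Ranking** — same-group redundancy filtering (pairwise GDT-TS > 0.95),
  pairwise-consensus scoring, mean-rank fusion, and a two-level stacked
  regressor (`StackedQA`: 10 cross-validated networks whose out-of-fold
  predictions join the input features for a second-level network) that
  predicts per-model GDT-TS.
* **Combination** — selection of neighbours similar to a reference model
  (server rule: GDT-TS > 0.6; human rule: top 60 ranked, GDT-TS > 0.7 or
  RMSD < 3 Å; max 20), Ca-level superpose-and-average consensus with a
  GDT-TS ≥ 0.9 acceptance gate, and TM-score-based region splicing with
  clash/break checking (< 1.9 Å / > 4.5 Å).
* **Domain parsing** — template-hit filtering (E-value ≤ 1, aligned length
  > 40, coverage > 0.5) and FM/TBM segmentation (uncovered regions > 40
  residues are template-free).
* **Evaluation** — ranking loss, CASP-style Z-scores, quality-distribution
  skewness, good-model fraction (TM > 0.5), MSA Neff at 62% identity,
  coverage profiles.
* **Synthetic fixtures** — a deterministic generator of natives, multimodal
  decoy pools, noisy predicted maps/contacts, MSAs and template hit tables,
  so the whole pipeline is testable offline.

See `docs/methods.md` for the models, parameter defaults and the study
design behind the synthetic benchmarks.

## Worked example

Simulate a 60-residue target with a balanced 12-model pool, extract
features, rank by consensus, evaluate the choice, and combine the top
model with its neighbours:

```sh
distrank --seed 7 simulate --length 60 --n-decoys 12 --outdir fixture
distrank features --models-dir fixture/models \
    --map fixture/predicted_map.txt --rr fixture/predicted.rr \
    --out features.csv
distrank rank --features features.csv --out ranking.csv
distrank evaluate --scores scores.csv --out report.json
distrank --seed 7 combine --models-dir fixture/models \
    --ranking ranking.csv --out-pdb combined.pdb --log-json combine.json
```

(`scores.csv` joins `fixture/truth.csv` with `ranking.csv` on model_id.)
This prints:

```
loss 0.0000, sum positive Z 5.240 -> report.json
accepted: candidate written to combined.pdb (7 members, GDT-TS to reference 0.933)
```

Loss 0.0 means the consensus ranking picked the pool's genuinely best
model (ranking loss is the true GDT-TS of the best model minus that of the
selected one).  The combiner found 7 neighbours passing the human-preset
similarity rules, averaged them with the reference, and the candidate
stayed within GDT-TS 0.933 ≥ 0.9 of the start model, so it was accepted.

The same commands on a *skewed* pool (`--skew 1.0`, few good models — the
hard-target regime) show consensus ranking being misled by the dominant
cluster of bad models:

```
loss 0.3125, sum positive Z 4.706 -> report.json
accepted: candidate written to combined.pdb (0 members, GDT-TS to reference 1.000)
```

Here consensus selected a model 0.31 GDT-TS below the pool's best, and no
neighbour passed the similarity rules, so the "combined" model is just the
reference — the
failure mode that motivates stacking single-model features (map matching,
external QA columns) on top of consensus, which `StackedQA` does:

```python
from distrank import pipeline
study = pipeline.ranking_study(n_train=20, n_test=12, L=60, base_seed=1)
print(study["heldout_spearman"])          # 0.928
```

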