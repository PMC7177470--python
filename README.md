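# vsensemble

Consensus-scoring analysis for ensemble docking against oligomeric
targets: enrichment-factor-optimized (EFO) linear combinations of docking
scores, applied progressively over the monomers and MD frames of a
homotetrameric receptor, plus the structural statistics (binding-site
RMSD frame selection, buried contact surface, interaction-energy
profiles) used to pick and interpret those frames.

## Who this is for

Computational chemists running structure-based virtual screening
campaigns against targets with several identical binding sites (e.g. the
TRPM8 tetramer, where each of chains A–D carries a copy of the S1–S4
sensor pocket) across multiple receptor conformations.  Each campaign
yields a ligand × (scoring function, chain, frame) score matrix; this
package turns those matrices into validated consensus ranking models and
quantifies how much the combination of monomers and frames improves
early enrichment.

## The statistic and the model

The objective throughout is the **enrichment factor at 1%**,

    EF₁% = (a / top) / (A / N),    top = ⌈0.01·N⌉,

the active rate among the `top` best-ranked molecules over the library's
active rate (a perfect ranking of a 53-active / 5300-molecule library
scores 100; random scores 1).  Ties are resolved pessimistically —
inactives first — so every reported EF is a lower bound.

A **consensus model** is a linear combination of 1–4 oriented score
columns with the leading coefficient fixed at 1.00,

    C = 1.00·s₁ + w₂·s₂ + … + w₄·s₄,

whose free coefficients are fitted by a seeded, gradient-free coordinate
search maximizing EF 1% (EF is piecewise constant in w, so scans run
over tan-spaced grids with exact breakpoint enumeration on small
libraries).  Models are validated by five stratified 70/30 train/test
repeats.  The **progressive protocol** searches models per monomer
(stage 1), per frame across ≥ 2 monomers (stage 2), and across ≥ 2
frames (stage 3).

## Worked example

Generate a synthetic two-frame campaign (2000 ligands, 1% actives, four
chains of qualities A = 1.0 … B = 0.3), then search cross-monomer
consensus models:

```sh
cat > spec.json <<'EOF'
{"n_ligands": 2000, "n_actives": 20,
 "programs": {"ligen": {"PS": {"signal": 0.6, "direction": "higher_better"},
                        "MLPINS": {"signal": 0.4, "direction": "lower_better"}}},
 "frames": {"990": 0.85, "1049": 1.0}}
EOF
vsensemble simulate --spec spec.json --seed 7 --out campaign/
vsensemble table validate campaign/ligen.csv
vsensemble efo --scores campaign/ligen.csv --max-vars 2 --min-chains 2 \
    --seed 7 --validate --out model.json
```

prints

```
wrote 1 score tables to campaign
2000 ligands, 16 score columns, 20 actives
best model: 1.00 PS__A__990 - 0.257 MLPINS__B__1049  EF 1% = 30.00
```

The best two-variable model combines the Pacman score of chain A (the
highest-quality monomer) with the MLPInS hydrophobic-contact score of
another chain and frame, reaching EF 1% = 30: the top-20 shortlist is 30×
richer in actives than the library (6 of the 20 actives among the top 20
of 2000).  `model.json` records the fitted coefficients and the
validation block:

```json
"ef_train": 30.0,
"validation": {"mean_test_ef": 26.67,
               "test_efs": [16.67, 33.33, 16.67, 33.33, 33.33]}
```

— a held-out mean EF of 26.7, i.e. the model's enrichment survives
train/test splitting rather than being a selection artifact.

The same machinery is available as a library (`vsensemble.efo`,
`vsensemble.protocol`) and the full three-stage protocol runs with
`vsensemble protocol run --config campaign.yaml --stage all`.  Structural
utilities: `vsensemble frames select`, `vsensemble surface`,
`vsensemble energy`.

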