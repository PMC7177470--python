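# Methods

## Problem setting

Structure-based virtual screening against an oligomeric ion channel (a
homotetramer such as TRPM8) produces one docking score per (ligand,
scoring function, monomer chain, MD frame): each of the four chains
carries a copy of the binding site, and several receptor conformations
(frames extracted from an MD trajectory) are screened independently.
`vsensemble` implements the post-docking analysis for such campaigns:

1. **Enrichment-factor (EF) statistics** — the screening objective;
2. **EFO consensus models** — linear combinations of 1–4 score columns
   with coefficients chosen to maximize EF 1%;
3. a **progressive three-stage protocol** that combines scores first per
   monomer, then across monomers of one frame, then across frames;
4. **structural statistics** used to select and interpret the frames
   (binding-site RMSD, buried contact surface, pairwise interaction
   energies);
5. a **synthetic campaign generator** that emulates the statistical
   structure of a real screening dataset, so that every stage is testable
   without proprietary docking data.

## Enrichment factor

For a library of N ligands containing A actives, ranked by a consensus
value, EF at fraction f is

    EF_f = (a_s / top) / (A / N),      top = ceil(f * N),

where a_s counts actives among the `top` best-ranked ligands.  With the
canonical library shape N = 5300, A = 53 and f = 0.01, a perfect ranking
gives EF = 100 and a random one averages EF = 1.

Numerical conventions:

* **Pessimistic ties.**  At equal consensus value, inactives rank before
  actives (then ties break lexicographically by ligand id).  Every
  reported EF is therefore a lower bound over tie resolutions, and
  rankings are fully deterministic.
* **Missing scores.**  A ligand missing any score used by a model gets
  consensus −∞ and ranks last (docking failures happen in practice; a
  model cannot claim enrichment from poses it does not have).
* The EF kernel counts actives above the top-set threshold value instead
  of sorting, which makes scanning hundreds of candidate coefficient
  values a single vectorized pass.  An explicit sort-based path backs the
  `Ranking` objects; tests assert the two agree exactly, including under
  heavy ties and missing values.

## EFO consensus models

A consensus model is `s_1 + w_2 s_2 + … + w_k s_k` over k ≤ 4 *oriented*
columns (every column flipped so larger = better); the leading
coefficient is fixed at +1.0, which is no restriction once each candidate
subset is fitted once per choice of leading variable.

EF is piecewise constant in the coefficients, so the fit is gradient-free:

* **Coordinate scans.**  Each free coefficient is scanned over
  `tan(θ)·(σ_lead/σ_j)` with θ on a 1° grid over (−88°, 88°) (177
  points); the σ ratio makes θ = 45° mean "equal contribution".  Sweeps
  over the free coefficients repeat until EF stops improving (≤ 10
  sweeps), from 5 starts (zeros, equal contribution, 3 seeded random
  draws).  A single free coefficient needs one start and one sweep: its
  scan is already global.
* **Exact scans on small tables.**  For N ≤ 400 the scan additionally
  evaluates every pairwise crossing coefficient
  `w = (b_q − b_p)/(x_p − x_q)` and the mid-points between consecutive
  crossings.  The ranking is constant between crossings, so this makes a
  1-D scan exact — which is what lets the search match a brute-force
  oracle *exactly* on small instances rather than to grid resolution.
* **Plateau resolution.**  Within a scan, ties at the optimal EF are
  resolved to the mid-point of the widest contiguous tied run (the most
  robust plateau).  A final pass over the winning coefficients picks,
  among EF-tied candidates, the value maximizing ROC AUC — a smooth
  internal surrogate that peaks where nuisance noise cancels; this is
  what centers recovered coefficients of a planted complementary pair
  near their generative ratio.  Among multi-start optima, higher mean
  reciprocal rank of actives wins, then smaller coefficient L1 norm.
  Across the leading-variable orderings of one subset — which are
  reparametrizations of the same model class — ties on (EF, MRR) keep
  the canonical first ordering instead of comparing L1, since equal MRR
  means the rankings are equivalent and L1 would systematically prefer
  the smaller-coefficient parametrization.  Everything is deterministic
  given the seed.
* A note on coefficient recovery: maximizing an integer count on a finite
  sample leaves a wide optimal plateau that is not always centered on the
  generative coefficient — dense rescans show the max-EF plateau can
  exclude the true ratio entirely for some seeds.  Recovered ratios are
  therefore calibrated *on average* (mean ≈ 1.0 across seeds, per-seed
  spread ≈ ±0.15 at n = 2000), and the tests assert exactly that.

**Subset search.**  Sizes 1–2 are enumerated exhaustively; sizes 3–4
extend the top-B (beam, default B = 50) smaller models with each
remaining column.  Admissibility constraints — at least two distinct
chains (stage 2) or frames (stage 3) — are hard filters on emitted
models; partial subsets are kept in the beam only if a superset within
`max_vars` could still satisfy the constraint.  Constant or all-missing
columns are dropped from the pool.  Subsets are ranked by training EF
with the tie-break above.

**Validation.**  Stratified 70/30 train/test splits, repeated 5 times
(scikit-learn `StratifiedShuffleSplit`); coefficients are refit on each
training split and EF 1% recorded on the held-out split; the report
carries the per-repeat values and their mean.  Stratification preserves
the ~1% active rate — an unstratified 30% split of a 53-active library
frequently strands too few actives for EF 1% to mean anything.  A test
split with zero actives is re-drawn with the next seed.  Reported
headline coefficients are always refit on the full set; both the full-set
EF and the validation mean are exposed.

## Progressive protocol

* **Stage 1** (per monomer): for every (program, frame, chain) cell, the
  best single column EF and the best EFO model restricted to that cell's
  columns, plus unweighted means per chain, frame, program and global.
  Empty cells are marked absent and excluded from means.
* **Stage 2** (per frame): EFO search over the union of the frame's
  chains, models admissible only if they span ≥ 2 chains — otherwise
  they duplicate stage 1.
* **Stage 3** (all frames): per program, search over all columns with
  ≥ 2 distinct frames required; best model per size (2, 3, 4) reported
  together with the best single column for reference.

Programs are analyzed as separate pools and never mixed inside one model.
Per-cell seeds derive deterministically (CRC32) from the campaign seed
and the cell key, so reports are byte-identical across reruns.

## Synthetic campaigns

Column (j, c, f) scores inactives as N(0, 1) and actives as N(δ, 1) with

    δ = δ_max · s_j · q_c · q_f,

where s_j is the scoring function's signal, q_c / q_f are chain and frame
qualities, and a shared per-ligand latent factor with loading √ρ induces
inter-column correlation.  Defaults reproduce the canonical study shape:

| parameter | default | rationale |
|---|---|---|
| n_ligands / n_actives | 5300 / 53 | the screening library shape (1% actives) |
| chain qualities | A 1.0, B 0.3, C 0.6, D 0.6 | chain A most stable/informative, B worst |
| frame qualities | 562: 0.7, 990: 0.85, 1049: 1.0 | frame 1049 the most productive conformation |
| δ_max | 3.0 | best single column's EF 1% lands in the 10–30 range typical of single-score screening |
| ρ | 0.3 | moderate correlation of scoring functions sharing pose geometry |
| heavy atoms / MW | U[10, 60]; 13.5·HA + N(0, 15) Da | drug-like size range; ~13.5 Da per heavy atom |

The **complementary pair** replaces two columns by (u + v, u − v), u
carrying the activity signal (shift δ_u, unit noise) and v pure nuisance
of scale σ_v: each half is individually weak while the equal-weight sum
reconstructs 2u exactly.  This is the generative mechanism for the
consensus benefit of combining monomers.

Two canonical study conditions are shipped:

* `complementary_pair_campaign` — n = 2000, 1% actives, one function over
  four chains of one frame, pair planted across chains A and C with
  δ_u = 2, σ_v = 3; used for recovery studies.
* `study_campaign` — the canonical protocol study campaign: 5300/53, two
  frames (990, 1049), one program with a primary (s = 0.6) plus a
  rescoring function (s = 0.4, lower-better) so the best single column's
  EF 1% sits in the 10–30 range, and a complementary pair planted across
  chains C/D of each frame with δ_u = 2.5 — the strongest signal in the
  campaign, so multi-monomer combination is the best available model
  while single-monomer cells see only its weak halves.  Stage-1/stage-2
  runs use max_vars = 2 and beam width 8; with 20 seeds this keeps a full
  protocol study under two minutes.

**What the generator does not emulate:** real score distributions are
heavy-tailed and share structured errors (pose-quality artifacts,
size bias beyond the linear MW model); chains and frames of a real
trajectory are correlated rather than independent quality factors; no
3D information exists at all.  Passing tests therefore demonstrate that
the *analysis machinery* is correct and that the protocol recovers
planted structure of the kind the method assumes — not that any
particular real campaign will enrich.

## Structural statistics

* **Superposition** — Kabsch least-squares fit (via
  `scipy.spatial.transform.Rotation.align_vectors`, proper rotation
  guaranteed), atoms paired by (chain, residue number, atom name); the
  fit selection defaults to the binding-site backbone.
* **Binding site and segments** — residues 745, 746, 778, 782, 785, 799,
  802, 838, 841, 844, 1003, 1004, 1012 (as-authored hTRPM8 numbering);
  sensor helices S1–S4 = 736–757, 769–788, 797–816, 824–851; TRP box
  992–1008; backbone = {N, CA, C, O}.  "Heavy" selections take all
  non-hydrogen atoms of the binding-site residues.
* **Frame selection** — per chain × reference × criterion (binding-site
  backbone, binding-site heavy), the frame minimizing RMSD after a
  binding-site-backbone fit; equals an exhaustive per-frame rescan by
  construction (asserted).
* **SASA** — Shrake–Rupley point sampling (`biotite.structure.sasa`),
  Bondi radii by default (overridable per element), probe 1.4 Å, 960
  sphere points.  Isolated-sphere error < 0.5%; totals are rigid-motion
  invariant only to sampling resolution (~0.1% at 960 points).
* **Contact surface** — σ(t) = (S_monomer + S_trimer − S_tetramer)/2 per
  frame for a chosen reference chain; vanishes when groups separate and
  matches the two-sphere spherical-cap closed form within 1%.
* **Interaction energies** — E_elec = Σ 332.0716 q_i q_j/(ε₀ r²)
  (distance-dependent dielectric ε(r) = ε₀·r; the standard form, chosen
  because the analysis convention leaves the prefactor open) and
  CHARMM-form Lennard-Jones ε_ij[(R_min/r)¹² − 2(R_min/r)⁶] with Lorentz
  combination on R_min and geometric on ε; pairs beyond the cutoff
  (default 12 Å) are skipped; overlapping atoms (< 0.1 Å) are an error.
  Parameters (charges, R_min/2, ε) are user-supplied per (residue, atom)
  or atom name — the package never assigns force-field types.
* **PDB conventions** — gemmi I/O; multi-model files are frame
  sequences; residue numbers as-authored; alternate locations beyond 'A'
  skipped; ligand-pose RMSD is computed in a shared frame with no
  symmetry correction (atom-order pairing).

## Design choices made where the design was open

* `top = ceil(f·N)` (53 at 1% of 5300): the standard convention; the
  count-based EF form makes the theoretical maximum (100 for this
  library) attainable.
* Headline EF = full-set fit, with the 5-repeat validation mean always
  attached; published tables rarely state which is printed, so both are.
* Score-table headers use a double-underscore dialect
  `<function>__<chain>__<frame>` (e.g. `Contacts_NORM_HEVATMS__A__990`)
  because single underscores inside function names are ambiguous.
* A direction registry ships for the common scoring functions (ChemPLP,
  PLP95, Xscore, MLPInS, GScore lower-better; GoldScore, ASP, PS, CS,
  Csopt, Contacts higher-better) but is always overridable — directions
  are conventions, not facts, and are never silently trusted for unknown
  functions.
* Whether stage-2 searches are seeded by stage-1 beams or run fresh is
  left open by the protocol description; stage 2 runs fresh here (the
  exhaustive size-1/2 enumeration makes seeding redundant at these pool
  sizes).

## Known limitations

* The EFO optimizer is a coordinate search on a piecewise-constant
  objective: above the exact-scan size (N > 400) it is grid-resolution
  limited and can miss plateaus narrower than ~1° in scaled angle.
* Training EF of searched models is optimistically biased (selection over
  many subsets); the validation report, not ef_train, is the number to
  trust for generalization.
* SASA is point-sampled; tolerances below ~0.1% require more sphere
  points.
* No docking, rescoring descriptor computation, force-field typing or
  trajectory formats beyond multi-model PDB.
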