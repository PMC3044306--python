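# actsite

Template-based prediction of enzyme active sites with **learned**
similarity/deviation measurements.

Enzymes with the same catalytic mechanism share a small, geometrically
conserved constellation of active-site atoms. Template-based prediction
searches a protein structure for *local sites* — small atom sets matching a
curated active-site *template* — and ranks the candidates by how well they
match. The standard measurement, RMSD after optimal superposition, treats
every atom as equally important. In real active sites some atoms are tightly
conserved and others are not, so `actsite` implements two discriminatively
*learned* measurements alongside their unlearned controls:

| measurement | kind | definition |
|---|---|---|
| UMD | deviation | RMSD² = min over rigid motions of (1/m) Σᵢ ‖A sᵢ + b − tᵢ‖² |
| WMD | deviation | min over rigid motions of Σᵢ βᵢ ‖A sᵢ + b − tᵢ‖², β learned |
| MDS | similarity | mean DALI pair score over all m(m−1)/2 atom pairs |
| DSDS | similarity | learned linear combination w·φ of the DALI pair scores |

Here tᵢ are template atom coordinates, sᵢ the corresponding local-site atom
coordinates, and φ the DALI elastic pair score
φ(d_T, d_S) = (0.20 − |d_T − d_S|/d\*)·exp(−(d\*/20)²) with
d\* = (d_T + d_S)/2, computed on intra-set distances so no superposition is
needed.

The WMD weights β (non-negative, summing to 1, capped at 2/m) and a
threshold θ are learned by minimizing a cost-weighted hinge loss — a
bi-level program solved by alternating an exact linear program over (β, θ)
with per-site weighted Procrustes refits (2 iterations, costs 1/n₊ and
1/n₋). The DSDS coefficients are fitted by a cost-weighted soft-margin
linear SVC (unit margin, costs 1000/n₊ and 1000/n₋).

Two analyses are supported end to end:

* **single template analysis** — one template queried against many
  structures: local site search (composition match, distance pre-filter,
  RMSD ≤ 4.0 Å), then ranking by one measurement;
* **multiple template analysis** — one protein queried against a template
  library, with per-template scores made cross-template comparable by
  post-processing: logistic-regression posteriors (LR), a PINTS-style
  significance for √WMD/√UMD (log expected random-match frequency from a
  per-template Gumbel null, size-penalized), or no post-processing
  (Direct control).

Evaluation follows a repeated-split protocol: 50/50 structure-level splits
repaired so every template keeps a positive training example, 30 repeats,
with ROC, ROC5 (area up to the fifth false positive, normalized to [0, 1])
and Sensitivity at 95% specificity.

Because curated enzyme-template datasets are license-bound, the package
ships a first-class synthetic fixture generator (`actsite.synthetic`) that
plants noisy copies of a template in PDB-format decoy structures with a
heterogeneous per-atom noise profile, so the whole stack — search, learning,
post-processing, evaluation — runs and is tested without any downloads.

## Worked example

Train importance weights on synthetic sites of a 5-atom template whose first
two atoms are conserved, then rank candidate sites across six fixture
proteins (two of which contain a planted site):

```python
import numpy as np
from actsite import synthetic, RunConfig, run_single_template
from actsite.learn_wmd import WMDTrainingSet, train_wmd

template = synthetic.make_template(5, seed=11, function_label="model-reaction")
structures = [synthetic.make_protein_fixture(template, planted=(i < 2),
                                             n_decoy_residues=10,
                                             seed=100 + i)[0]
              for i in range(6)]

train = synthetic.make_sites(template, 50, 500, seed=12)
model = train_wmd(WMDTrainingSet(sites=train), template)
print("beta =", np.round(model.weights.beta, 3))

ranked = run_single_template(template, structures,
                             RunConfig(measurement="wmd"), wmd_model=model)
print(ranked.rows.head(5)[["rank", "structure_id", "residues",
                           "score"]].to_string(index=False))
```

prints

```
beta = [0.251 0.4   0.112 0.16  0.077]
 rank structure_id                                    residues    score
    1  fixture0101 SER 1 A, HIS 2 A, ASP 3 A, LYS 4 A, TYR 5 A 0.071658
    2  fixture0100 SER 1 A, HIS 2 A, ASP 3 A, LYS 4 A, TYR 5 A 0.073481
```

The learned weights concentrate on the two conserved atoms (0.251 + 0.400 of
the mass versus 0.2 each under uniform weighting; the cap is 2/5 = 0.4), and
the two planted sites rank first and second with weighted mean deviations
far below any decoy combination. The `score` column is the WMD in Å²; for
similarity measurements (MDS/DSDS) the table is sorted descending instead.

A command-line interface mirrors the library
(`actsite search-single / predict-multi / train-wmd / train-dsds /
fit-post / experiment / make-fixtures`); run `actsite --help`.

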