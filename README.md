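# featlink

Annotation and grouping of **redundant features** in untargeted LC-ESI-MS
metabolomics feature tables.

Most peaks in an untargeted LC-MS experiment are not distinct metabolites:
one compound typically produces a whole family of MS1 features — its
isotopologues, adducts and multimers ([M+Na]⁺, [2M+H]⁺, …), dehydration
products, and in-source fragments (ISFs) formed in the ESI source before
mass analysis. Leaving these degenerate features unannotated inflates
feature counts and causes misidentification; `featlink` links them back to
their parent ion and assigns group indices that downstream analyses can
collapse on.

Who it is for: metabolomics practitioners with an XCMS- or MZmine-style
feature table (feature id, *m/z*, retention time, per-sample intensities),
optionally DDA MS2 data from a pool sample (mzML, mzXML or MGF) and a
target list of metabolite names and molecular formulas.

## What it computes

Seven deterministic passes:

1. **Primary ions** — target formulas are parsed and [M+H]⁺ / [M−H]⁻
   *m/z* values computed from IUPAC monoisotopic element masses.
2. **Target matching** — primary ions matched to features within
   max(0.002 Da, 5 ppm) and 20 s.
3. **Adducts/multimers** — expected adduct *m/z* = (k·M + shift)/|z| from a
   declarative rule table (bundled ESI defaults, user-replaceable), matched
   within max(0.005 Da, 5 ppm) and 2 s of the primary feature.
4. **In-source fragments** — DDA precursor ions aligned to features
   (0.002 Da / 5 ppm, 20 s), then MS2 fragment peaks matched back to
   co-eluting lighter features (0.005 Da / 10 ppm, 3 s).
5. **Isotopes and charge states** — ¹³C isotopologue chains at spacings
   1.0034/*z* for *z* ∈ {1, 2, 3}, up to order 4 (0.002 Da for the first
   isotope, 0.01 Da for higher orders; rt window 3 s).
6. **Neutral losses** — pairwise Δ*m/z* of co-eluting pairs (2 s) compared
   against a neutral-loss table (H₂O, CO₂, anhydrohexose, …) within
   0.002 Da / 5 ppm.
7. **Grouping** — two indices per feature:
   * `group`: connected components over *all* annotated relations;
   * `corgroup`: cliques of features whose pairwise log₁₀-intensity
     correlations (Pearson/Spearman/Kendall, rt window 2 s) all exceed 0.8
     — "annotation by perturbation": all features of one metabolite share
     its fold changes across conditions;

   plus their pairwise **intersection** (conservative, low false discovery
   rate) and **union** (sensitive, high true positive rate).

Grouping quality against a ground truth is scored over unordered feature
pairs: FDR = FP/(FP+TP), TPR = TP/(TP+FN).

## Worked example

Simulate a spike-in style benchmark (50 metabolites with adduct, isotope
and ISF satellites, 6 conditions × 3 replicates, 100 background features),
annotate it, and score the grouping:

```sh
$ featlink simulate --seed 7 --out sim
simulated 423 features (50 metabolites, 41 MS2 spectra) -> sim

$ featlink annotate --features sim/feature_table.csv \
    --targets sim/targets.csv --ms2 sim/spectra.mgf --out run
annotated 423 features: 404 edges, 50 groups, 50 corgroups -> run

$ featlink evaluate --pred run/annotated.csv --pred-column group_intersect \
    --truth sim/truth.csv --out intersect.json
{"fdr": 0.0, "fn": 18, "fp": 0, "tn": 88322, "tp": 913, "tpr": 0.9806659505907627}

$ featlink evaluate --pred run/annotated.csv --pred-column group_union \
    --truth sim/truth.csv --out union.json
{"fdr": 0.0, "fn": 0, "fp": 0, "tn": 88322, "tp": 931, "tpr": 1.0}
```

Of the 88 k feature pairs, the intersect grouping co-groups 913 true pairs
with zero false pairs (FDR 0, TPR 0.98); the union grouping recovers all
931 true pairs. One annotated family from `run/annotated.csv` — a primary
ion with two isotopologues, a potassium adduct, and an in-source fragment
explained by an SO₃ loss, all sharing one `group`/`corgroup` index:

```
feature         mz        rt target         adduct        isotope charge  neutral_loss isf_parent group corgroup
  F0120 352.263342 70.936409   M019                                    1                               1        1
  F0121 353.266452 70.282946                       [M+1] of F0120      1                               1        1
  F0122 354.270721 70.583281                       [M+2] of F0120      1                               1        1
  F0123 390.219444 70.817390        [M+K]+ of M019                                                     1        1
  F0124 272.306728 70.919716                                             SO3 from F0120      F0120     1        1
```

Pairwise correlation statistics for any two features:

```sh
$ featlink corr --features sim/feature_table.csv F0001 F0002
{"coefficient": 0.9962218846630082, "p_value": 2.0626785444279624e-18, "n": 18, "method": "pearson"}
```

The annotation path contains no randomness: re-running `featlink annotate`
on the same inputs reproduces every output byte for byte.

## Library use

```python
from featlink import SimConfig, simulate_dataset, run_annotation, pairwise_confusion, fdr_tpr

res = simulate_dataset(SimConfig(seed=7))
out = run_annotation(res.table, targets=res.targets, spectra=res.spectra)
print(fdr_tpr(pairwise_confusion(out.grouping.combined_intersect, res.truth)))
```

See `docs/methods.md` for the underlying model, parameter semantics and
known limitations.
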