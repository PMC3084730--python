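# smap — stemness meta-analysis of gene-module expression

Single-gene meta-analyses of stem-cell transcriptomes struggle to find
genes up-regulated across *all* stem-cell types: different stem cells often
deploy different, functionally synonymous members of the same gene family.
`smap` implements a module-level meta-analysis for exactly this situation.
It scores **gene modules** — homolog families built from protein-similarity
graphs, plus pathway / complex / interaction gene sets — for recurrent,
specific, cell-type-diverse up- or down-regulation across a compendium of
**stem-cell gene lists** (SGLs: genes up in a stem population) and
**differentiated gene lists** (DGLs: genes up in the matched differentiated
population), classifies each module into an idealized stemness expression
pattern, and scores new experiments with a **stemness index** against the
learned module signature. It is a library for computational biologists
doing gene-list meta-analysis, with a thin `smap` command-line interface
over the same functions.

## The scores

For module *M* over the SGL event matrix *S* (entries: 1 = gene up in that
list, 0 = tested but not up, missing = untested):

- **Recurrence** — a weighted vote count,

  R(M, S) = Σ_{i ∈ M} (G_i / T_i)^q,&nbsp;&nbsp;
  G_i = Σ_j z_j · u_ij · S_ij,&nbsp;&nbsp; T_i = Σ_j z_j · u_ij

  where z_j = −log v_j down-weights large, unspecific lists (v_j = list
  size / tested universe), u_ij gives each group of near-duplicate lists a
  single collective vote per gene, and the exponent q (default 2, chosen by
  simulation) emphasises frequently up-regulated genes. Significance is an
  empirical FDR against 1,000 within-list permutations that preserve
  per-list counts and group correlation, stratified by module size class
  (1, 2, 3, 4, 5–10, >10).
- **Cell-diversity** D_cell(M) — Shannon entropy (bits) of the module's
  pooled up-regulation fractions across stem-cell types; log2(12) ≈ 3.585
  bits is the ceiling for 12 cell types, and ≥ 2.5 bits counts as
  cell-type diverse. **Gene-diversity** is the same entropy across the
  module's genes, normalised to [0, 1].
- **Specificity** — the DGL-side recurrence FDR: high (> 95%), moderate
  (5–95%), or none.
- **Pattern** — six classes from the two diversities and specificity:
  all-for-all (AFA), one-for-all (OFA), constitutive module/gene (CM/CG),
  all-for-one (AFO), one-for-one (OFO). AFA/OFA modules from the SGLs are
  **stemness-on**; from the DGLs, **stemness-off**.
- **Stemness index** — for a query pair (Q⁺ up-regulated, Q⁻
  down-regulated), SO/DO are cell-diversity-weighted log2 observed/expected
  overlaps with the stemness-on / stemness-off sets,
  SE = (SO − DO)/2, SI = SE(Q⁺) − SE(Q⁻), and TMO (total module overlap)
  measures how much module evidence backs the call; significance comes from
  a TMO-windowed band of 20 size-matched random query pairs.

## Worked example

The packaged generator builds a 12-cell-type, 40-list compendium with 30
planted stemness-on, 10 stemness-off, and 200 background modules
(`examples/02_score_and_classify.py`, `examples/03_stemness_index.py`):

```python
import smap

bench = smap.synth_compendium(seed=1)
calls = smap.score_and_classify(bench.modules, bench.compendium,
                                smap.ScoringParams(permutations=500, seed=1))
signature = smap.build_signature(calls, {m.id: m for m in bench.modules},
                                 bench.compendium.universe())
qp, qm = smap.planted_query(bench, rng=5)
print(smap.score_query_pair(qp, qm, signature,
                            tested_universe=bench.compendium.universe(),
                            reps=20, seed=5))
```

prints (abridged):

```
signature: 30 stemness-on, 9 stemness-off modules

stem-like query: |Q+|=117 |Q-|=74
  SO+=2.31 DO+=0.00 SE+=1.16 SE-=-1.51
  SI=2.67 TMO=2.94 null=0.02+-0.21 z=12.5

random query: |Q+|=60 |Q-|=60
  SI=0.02 TMO=0.64 null=0.00+-0.27 z=0.1
```

All 30 planted stemness-on modules are recovered (none of the 200
background modules is called), the stem-like query scores SI = 2.67 —
12.5 standard deviations above its matched-random null band, far past the
two-standard-deviation call line — and the random query is correctly
unremarkable (z = 0.1). Five-fold cross-validation on the same compendium
separates held-out SGLs from DGLs at Welch t = 32.8.

The CLI mirrors the library:

```sh
smap synth --seed 1 --outdir bench/
smap classify --manifest bench/manifest.yaml --modules-gmt bench/modules.gmt \
     --group-threshold 1e-20 --seed 1 --out calls.tsv
smap signature --calls calls.tsv --modules-gmt bench/modules.gmt \
     --manifest bench/manifest.yaml --out signature.json
```

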