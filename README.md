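# rges

Signature-reversal drug scoring: rank candidate compounds for a disease by
how strongly their induced gene-expression changes *reverse* the disease's
expression signature, summarize heterogeneous assay conditions into one
score per compound, and identify the individual disease genes that
effective compounds specifically reverse.

The package is aimed at computational drug-repurposing work with
LINCS-L1000-style perturbation profiles (landmark-gene differential
expression under many cell lines, doses and treatment durations) and
tumour-vs-normal differential-expression tables.

## The score

Genes in each drug profile are ranked by differential expression (rank 1 =
most upregulated).  For each direction of the disease signature a
Kolmogorov–Smirnov-type enrichment score measures positional bias: with
V(1..m) the ascending positions of the m signature genes among n ranked
genes,

    a = max_j [ j/m − V(j)/n ]        b = max_j [ V(j)/n − (j−1)/m ]
    es = a  if a > b  else −b

and the **reverse gene expression score** is

    RGES = es_up − es_down  ∈ [−2, 2]

with no zero-clamping.  Negative RGES = reversal (disease-up genes pushed
down the list, disease-down genes pulled up).  Per compound, scores are
normalized to a reference assay condition (10 μM, 24 h) via additive
per-condition-bin offsets learned from within-cell-line pairs, weighted by
each cell line's rank correlation to the tumours (max-normalized), and
combined into the summarized score

    sRGES = Σ_i w(cell_i) · (RGES_i + offset[bin_i]) / Σ_i w(cell_i).

Reversal genes are found by a one-sided Mann–Whitney–Wilcoxon test on
normalized gene positions between effective (median IC50 < 10 μM) and
ineffective compounds, Benjamini–Hochberg adjusted at 0.25, with
leave-one-compound-out robustness filtering.  See `docs/methods.md` for
the full model, conventions and limitations.

## Worked example

Every input format can be produced by the built-in study simulator, which
plants known reversal structure and records the ground truth:

```sh
rges simulate --out-dir study --seed 7 --sim-config sim.yaml
rges score    --profiles study/profiles.tsv --meta study/profile_meta.tsv \
              --signature study/signature.tsv --universe study/universe.txt \
              --out rges.tsv
rges srges    --scores rges.tsv --out srges.tsv --offsets-out offsets.tsv \
              --cell-expr study/cell_expr.tsv --tumour-expr study/tumour_expr.tsv
rges reversal --scores rges.tsv --profiles study/profiles.tsv \
              --meta study/profile_meta.tsv --signature study/signature.tsv \
              --universe study/universe.txt --efficacy study/efficacy.tsv \
              --out reversal.tsv
```

with `sim.yaml` shrinking the study for the demo (300 genes, 20+20
signature genes, 10+10 compounds, 8 tumours).  The run prints

```
simulated study (138 profiles) -> study
scored 133 profiles -> rges.tsv          # 5 profiles failed the quality flag
summarized 20 compounds -> srges.tsv
31 reversal genes (21 robust) -> reversal.tsv
```

`srges.tsv` is sorted most-reversing first; the top compounds are the
planted effective ones:

```
compound_id  srges                n_profiles  n_cell_lines
CPD0001      -1.0013838082069235  9           3
CPD0010      -0.7914155982905983  3           1
CPD0002      -0.7737993359175642  9           3
```

`offsets.tsv` holds the learned condition adjustments — negative, because
lower dose and shorter treatment weaken reversal, so scores from those
bins are adjusted downward toward the reference condition:

```
dose_class  time_class  offset                support
low         short       -0.3598717948717949   26
low         long        -0.18770833333333328  24
high        short       -0.2645679012345679   27
high        long        0.0                   45
```

`reversal.tsv` gives per-gene test results (`u_stat`, raw and adjusted P,
LOCO-robust flag).  On this study the sRGES ranking correlates with the
simulated efficacy at Spearman rho = 0.79 (log median IC50, 20 compounds).

The same steps run as library calls (`rges.simulate_study`,
`rges.batch_score`, `rges.estimate_offsets`, `rges.compute_cell_weights`,
`rges.summarize_srges`, `rges.find_reversal_genes`); a GCT v1.3 text
reader (`rges.read_gct`) accepts profile matrices with embedded
annotations in place of the TSV pair.

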