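# raftkit

Anthropogenic litter stranded on beaches is more than pollution: floating
plastic objects act as rafts that carry sessile and clinging macrofauna —
goose and acorn barnacles, bryozoan/hydrozoan colonies, polychaetes,
molluscs, decapods — across coastal seas, including non-native and
invasive species.  `raftkit` is a toolkit for marine ecologists working
with paired beach-litter surveys: standardized quadrat counts of litter
along the tidelines, and whole-beach inventories of fouled (macrofauna-
carrying) litter items.

The package provides:

* a survey **data model** with closed category vocabularies (materials
  HPl / OPl / Foam / NPl, sources Sewage / Fishing-Aquaculture /
  Household-Leisure / Not attributable, six rafting taxon groups),
  delimited-text readers/writers and dataset validation;
* a **synthetic survey generator** with known ground truth (Dirichlet
  beach compositions, negative-binomial patchy quadrat counts,
  multinomial attachment draws from material-specific taxon profiles);
* per-beach **community summaries**: compositions, litter density
  (items·m⁻²), beach classification by dominant material, and the
  regional attached-biota profile per material;
* distance-based **multivariate inference**: Bray–Curtis and Euclidean
  distance matrices, one-way PERMANOVA with permutation p-values,
  SIMPER similarity-percentage decomposition, and non-metric MDS
  (Kruskal stress-1, monotone regression + SMACOF);
* a compositional **predictor of expected rafting-taxon counts**.  For
  taxon *B* on beach *x*,

      T_B(x) = Σ_i  fM(i, x) · fT(B, i) · Nt(x)

  where `fM(i, x)` is the frequency of litter material *i* on the
  beach, `fT(B, i)` the regional frequency of taxon *B* among
  individuals attached to material *i*, and `Nt(x)` the total rafting
  individuals found on the beach.  Predictions are validated by
  Spearman rank correlation of expected against observed counts, with
  asymptotic, pairwise-permutation and beach-block-permutation
  p-values.

A reconstruction of a published survey of 15 Cantabrian-coast beaches
(12 with standardized counts, 94 fouled items) ships as a packaged
fixture, so the full analysis runs out of the box.

## Worked example

Run the full pipeline on the packaged regional survey:

```sh
raftkit run-all --out demo --seed 1 --perms 999
```

`demo/permanova.csv` then contains the General-litter-vs-Rafts
comparisons (Bray–Curtis on integer percentage tables, 12 beaches per
group):

```
          df_between  df_within  ss_between  ss_within  pseudo_F  p_perm
material           1         22     809.711    6687.02    2.6639   0.057
source             1         22    5573.490   20008.70    6.1282   0.006
```

The material mix of rafts is statistically indistinguishable from the
general beach litter (pseudo-F 2.66, p ≈ 0.06), but their sources
differ clearly (pseudo-F 6.13, p ≈ 0.006).  `demo/simper_source.csv`
decomposes that source difference (overall average between-group
dissimilarity 44.61%):

```
                    mean_General  mean_Rafts  avg_contribution  diss_sd_ratio  percent
NotAttributable            75.83       53.83             16.67           1.45    37.37
FishingAquaculture          8.67       33.08             15.36           1.06    34.44
HouseholdLeisure            3.83       13.08              6.90           0.77    15.47
Sewage                     11.33        0.00              5.68           1.22    12.72
```

Fishing/aquaculture litter is four times more frequent among rafts than
in general litter (33.1% vs 8.7% of items) and explains a third of the
difference, while sewage litter — 11% of beach litter — never carries
fauna.  The prediction stage writes the expected-vs-observed taxon
table and its rank correlations per scope (whole area and the coastal
halves west/east of Cape Peñas):

```
  scope     rho  p_value  n_pairs
0   all  0.9031        0       72
1  west  0.8968        0       36
2  east  0.9076        0       36
```

(On the packaged fixture the per-item attachments are a synthetic
reconstruction consistent with the regional per-material profiles, so
these correlations describe the fixture, not the original specimens;
see `docs/methods.md`.)

Synthetic experiments run the same machinery against known truth:

```python
import raftkit as rk

config = rk.SyntheticConfig(n_fouled_items_per_beach=84)
df = rk.recovery_experiment(config, n_replicates=15, seed=101)
print(df.rho.median())        # 0.988 — profiles recovered, prediction works
```

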