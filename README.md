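# ipadpy

Integrative penalized matrix decomposition for drug–pathway association
discovery.

## The problem

Anticancer drugs rarely act through a single gene: their effects are
mediated by pathways. Given a panel of cell lines profiled for both gene
expression and drug sensitivity, the question is which *pathways* explain
each drug's response. `ipadpy` answers it by jointly factoring the two
data matrices over a shared set of latent pathway activities:

    Y⁽¹⁾ = X B⁽¹⁾ + E⁽¹⁾        Y⁽²⁾ = X B⁽²⁾ + E⁽²⁾

where `Y⁽¹⁾` (N samples × G₁ genes) is expression, `Y⁽²⁾`
(N samples × G₂ drugs) is drug sensitivity (activity area or
−log₁₀ GI50 style readouts, possibly with missing cells), `X` (N × K) holds
pathway activity scores, `B⁽¹⁾` (K × G₁) is constrained to a binary
gene–pathway membership prior `H⁽¹⁾`, and `B⁽²⁾` (K × G₂) — the
drug–pathway association matrix — is what we want, sparse. The estimator
solves

    min ‖Y⁽¹⁾ − X B⁽¹⁾‖²_F + ‖Y⁽²⁾ − X B⁽²⁾‖²_F
        + λ₁‖B⁽²⁾‖₁ + λ₂‖B⁽²⁾‖₂,₁
    s.t. Σᵢ X²ᵢⱼ ≤ 1 ∀j,   B⁽¹⁾ᵢⱼ = 0 where H⁽¹⁾ᵢⱼ = 0.

The mixed penalty combines element-wise sparsity (the lasso ‖·‖₁) with
row-structured sparsity (the ‖·‖₂,₁ sum of row norms, which switches
whole pathways off across all drugs). Setting λ₂ = 0 gives the
lasso-only decomposition (iPaD); λ₁ = 0 gives the row-sparse variant
(L2,1-iPaD). Significance of each coefficient is assessed by a
permutation test (sample rows of `Y⁽²⁾` are reshuffled and the whole
model re-fitted), hyper-parameters by entry-level five-fold
cross-validation, and relative importance by the order in which
coefficients enter along a decreasing-λ regularization path.

## Worked example

```python
import ipadpy as ip

# a synthetic panel with the structure the model assumes:
# 100 cell lines, 8 pathways, 200 genes, 15 drugs, 3 active pathways
from ipadpy.synthetic_data import benchmark_spec
ds, prior, truth = ip.simulate(benchmark_spec(seed=9))

cfg = ip.PenaltyConfig(seed=3)
lmax = ip.lambda_max(ds, prior, "l1", cfg)          # top of the path
cfg = ip.PenaltyConfig(lambda1=0.3 * lmax, lambda2=0.3 * lmax, seed=3)

model = ip.fit(ds, prior, cfg)
perm = ip.permutation_test(ds, prior, cfg, T=200, seed=7, reference=model)
table = ip.rank_associations(model, perm, alpha=0.05,
                             pathway_ids=prior.pathway_ids,
                             drug_ids=ds.drug_ids)
print(f"identified {len(table.table)} pairs "
      f"(rate {table.identification_rate:.3f})")
print(table.table.head(5).to_string(index=False))
```

Output:

```
identified 26 pairs (rate 0.217)
  drug  pathway  coefficient  pvalue  qvalue  entry_rank
drug13 pathway5    -1.845166     0.0     0.0           0
 drug3 pathway2    -1.653034     0.0     0.0           0
drug13 pathway4    -1.469024     0.0     0.0           0
drug12 pathway2     1.168079     0.0     0.0           0
drug14 pathway4    -1.103986     0.0     0.0           0
```

Each row is a drug–pathway pair with its fitted coefficient (sign =
direction of the association, shrunk toward zero by the penalties), its
permutation P-value (0 means no null magnitude among the T permutations
reached the observed one), a Benjamini–Hochberg q-value, and — when a
regularization path has been computed — the grid index at which the pair
first entered the model (0 here, since none was run). In this run 26 of
the 8·15 = 120 possible pairs pass P ≤ 0.05 with a nonzero coefficient,
an identification rate of 0.217.

The same pipeline is available from the shell on TSV/GMT files:

```sh
ipad simulate --out sim --seed 9
ipad permute --expr sim/Y1.tsv --drug sim/Y2.tsv --gene-pathway sim/H1.gmt \
     --lambda1 0.9 --lambda2 0.9 --n-perm 200 --seed 3 --out run
ipad rank --run-dir run --alpha 0.05
```

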