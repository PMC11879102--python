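# cmtarget

Connectivity-map target inference for drugs, multi-component preparations
(e.g. herbal medicines) and diseases.

Given a differential-expression profile induced by a treatment or a disease,
`cmtarget` asks: *which molecular targets mediate this transcriptional
response, and which of them does the compound actually bind?*  It combines
two independent lines of evidence:

1. **Effect targets** — targets whose perturbation signature (from shRNA /
   CRISPR / over-expression / compound perturbation profiles) correlates
   significantly with the query profile, found by a permutation-calibrated
   connectivity statistic.
2. **Binding targets** — proteins a compound is predicted to bind, from a
   trainable sequence classifier over SMILES strings and amino-acid
   sequences.

Their intersection gives **direct targets** (bound *and* effect-mediating);
the remaining effect targets are **indirect** (downstream).  Comparing a
drug run against a disease run yields **reversal (therapeutic) targets** —
significant in both with opposite signs — and over-representation analysis
maps any target set onto pathways, annotated with its direct and indirect
members.

## The statistic

A target's signature is the pair (t_up, t_down) of the n most up- and
down-regulated genes of its consensus perturbation profile (a Spearman-
correlation-weighted average of replicates).  Against a query gene list L
ranked descending by a differential metric, each side gets a
Kolmogorov–Smirnov-style running-sum enrichment score ES ∈ [−1, 1]
(unweighted, rank-only), and the effect target score is

    ETS = (ES_up − ES_down) / 2,    set to 0 when ES_up, ES_down share a sign.

Significance comes from permuting the query's gene labels (default 1000
permutations): the nominal p compares ETS with the same-sign portion of its
null; NETS = ETS / |mean(same-sign null)| makes scores comparable across
signatures and queries; and the false discovery rate for each NETS is the
tail-frequency ratio A/B between the pooled null (all signatures × all
permutations) and the actual score distribution.  Targets with FDR ≤ 0.05
are called effect targets; binding calls use score ≥ 0.90.

## Worked example

Score a synthetic drug profile (activating target T1, reversing T2) against
a 5-target signature library:

```python
from cmtarget.connectivity import score_query
from cmtarget.fileio import build_signature_library
from cmtarget.simulate import (SimulationConfig, generate_signature_library,
                               generate_query)
from cmtarget.targets import call_effect_targets

config = SimulationConfig(n_genes=400, n_targets=5, replicates_per_target=3,
                          signature_size=10, seed=7)
signatures, truth = generate_signature_library(config)
library, profiles = build_signature_library(signatures, config.signature_size)
query = generate_query(truth, [("T1", +1), ("T2", -1)], seed=3, label="drug")
results = score_query(query, library, n_perm=300, seed=5)
for r in results:
    print(f"{r.target_id:<8}{r.ets:>8.3f}{r.p:>10.4f}{r.nets:>8.2f}{r.fdr:>8.3f}")
print("effect targets:", sorted(call_effect_targets(results, 0.05)))
```

prints

```
T1         0.906    0.0122    3.52   0.000
T5         0.290    0.2895    1.10   0.161
T4         0.000    1.0000    0.00   1.000
T3        -0.247    0.6438   -0.91   0.323
T2        -0.885    0.0145   -3.40   0.000
effect targets: ['T1', 'T2']
```

The two planted targets sit at the extremes of the NETS ranking with FDR 0;
T1 is activated (positive sign), T2 reversed (negative); unrelated targets
stay insignificant, and T4's two signature sides enriched with the same
sign, so its score is zeroed.

The same flow is available from the shell:

```sh
cmtarget simulate --outdir fx --seed 7
cmtarget build-signatures --profiles fx/profiles.tsv --meta fx/meta.tsv \
    --n 20 --out siglib.tsv
cmtarget score --query fx/drug.rnk --siglib siglib.tsv --nperm 1000 \
    --seed 5 --out ets.tsv
cmtarget run --siglib siglib.tsv --drug fx/drug.rnk --disease fx/disease.rnk \
    --gmt fx/target_pathways.gmt --outdir run/
```

`cmtarget run` writes both score tables, the target role calls
(effect/binding/direct/indirect/therapeutic), the compound–direct-target
network, the pathway enrichment and a manifest that reproduces the run
bit-for-bit.

## Layout

- `cmtarget.signatures` — consensus profiles, t_up/t_down extraction,
  DR-based signature-size selection
- `cmtarget.connectivity` — ES/ETS, permutation null, p, NETS, pooled FDR
- `cmtarget.binding` — tokenizers, the compound–protein classifier,
  binding-target calls
- `cmtarget.targets` — effect/reversal/direct/indirect algebra, the
  component–target network
- `cmtarget.enrichment` — hypergeometric ORA, BH adjustment, pathway
  annotation
- `cmtarget.simulate` — seeded synthetic data with planted ground truth
- `cmtarget.fileio` / `cmtarget.cli` — formats, run configuration, pipeline

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
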