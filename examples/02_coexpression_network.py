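"""Weighted co-expression network, hub genes and Obp56h connection scores.

Plants one correlated module containing an Obp56h-like family that is
also differentially expressed, then builds the unsigned network,
detects modules, ranks hubs by intramodular connectivity (kWithin), and
scores every other transcript's connection to the family:

    C_i = sum_j a_ij * |F_j|
"""

from protoy.connect import central_genes, chromosome_enrichment, connection_scores
from protoy.de import filter_low_expression, fit_de_model, normalize_vst
from protoy.network import (
    adjacency,
    correlation_matrix,
    detect_modules,
    intramodular_connectivity,
    module_eigengenes,
    module_trait_association,
    pick_soft_threshold,
    topological_overlap,
)
from protoy.simulate import SimConfig, simulate_counts
import pandas as pd
import numpy as np

# module genes 0..59; the first 3 are the "Obp56h family", DE between types
config = SimConfig(
    n_genes=400, n_samples=24, seed=21,
    module_spec=[(60, 0.8)], de_spec=[(i, -1.2) for i in range(3)],
)
counts, meta, truth = simulate_counts(config)
expr = normalize_vst(filter_low_expression(counts))
corr = correlation_matrix(expr)
fit = pick_soft_threshold(corr)
adj = adjacency(corr, fit.beta)
modules = detect_modules(topological_overlap(adj), expr)
kwithin = intramodular_connectivity(adj, modules)
eig = module_eigengenes(expr, modules)
assoc = module_trait_association(eig, (meta["genotype"] == "IIIM").astype(float))

obp_family = list(expr.index[:3])
de = fit_de_model(expr, meta["genotype"])
scores = connection_scores(adj, obp_family, de)
top = central_genes(scores, k=50)
annotation = pd.Series(np.where(np.arange(len(expr)) < 60, "III", "V"),
                       index=expr.index)
enr = chromosome_enrichment(top, annotation, "III")

print(f"chosen soft threshold beta   : {fit.beta} (scale-free R^2 table reported)")
print(f"modules detected (sizes)     : "
      f"{modules[modules != 0].value_counts().to_dict()}")
print(f"module-trait p_adj           : {assoc['p_adj'].round(4).to_dict()}")
hubs = kwithin[modules == 1].sort_values(ascending=False).head(3)
print(f"top hub genes by kWithin     : {list(hubs.index)}")
print(f"central genes on chr III     : {enr.table[0, 0]} of {len(top)} "
      f"(Fisher p = {enr.p:.2e})")
print("High connection scores concentrate in the planted module, so the")
print("central-gene set is enriched on the module's chromosome (III here).")
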