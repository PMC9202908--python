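"""WGCNA-style co-expression modules on the DE feature set.

Soft-threshold adjacency -> topological overlap -> average-linkage
clustering with a static cut; module significance is the mean -log10 DE p
of members. Recovery is scored against the planted module labels.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from tadscope import (
    CountMatrix, adjacency, condition_adjust, detect_modules, module_significance,
    run_de, simulate_study, size_factors_median_of_ratios, tom,
)
from tadscope.config import SimulationConfig

cfg = SimulationConfig(
    seed=3, n_mrna=300, n_lnc=100, n_mir=0,
    de_fraction_per_class=0.4, dispersion=0.05,
    n_modules=3, module_size=40, tad_plan=[], loci_plan=[],
)
study = simulate_study(cfg)
cm = CountMatrix(study.counts, study.design,
                 study.annotation.set_index("feature_id")["rna_class"])
sf = size_factors_median_of_ratios(cm)
de = run_de(cm, sf)

truth_de = study.truth.de_truth
union = sorted(truth_de.loc[truth_de["is_de"], "feature_id"])
expr = np.log2(study.counts.div(sf, axis=1) + 1).loc[union]
expr = condition_adjust(expr, study.design)  # remove the lesion/normal axis

t = tom(adjacency(expr, beta=6).to_numpy())
modules = detect_modules(t, union, min_size=30)
sig, selected = module_significance(modules.labels, de, top_k=3)

truth = study.truth.module_truth.set_index("feature_id")["module"]
ari = adjusted_rand_score(truth, modules.labels.reindex(truth.index).fillna("grey"))
print("module sizes:", modules.labels.value_counts().to_dict())
print("module significance (mean -log10 p):",
      {m: round(v, 2) for m, v in sig.items()})
print(f"selected modules: {selected}")
print(f"adjusted Rand index vs planted modules: {ari:.3f}")
# ARI of 1.0 means the three planted co-expression programs were
# reassembled exactly from six samples of counts.
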