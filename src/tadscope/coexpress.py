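"""PCC-based lncRNA-mRNA pairing and WGCNA-style co-expression modules.

The workflow mirrors the classic weighted co-expression analysis of a DE
feature set: Pearson correlation across samples, soft-threshold adjacency
``a_ij = |r_ij|^beta`` (unsigned), topological overlap (TOM), average-linkage
clustering of 1 - TOM with a static height cut, size-ordered WGCNA color
labels, module eigengenes (first principal component) and a DE-based module
significance score (mean -log10 p of members).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: WGCNA's conventional color order, assigned by decreasing module size.
WGCNA_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)

GREY = "grey"


# ----------------------------------------------------------------------
# correlation pairs


def pcc_pairs(
    expr_lnc: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    r_min: float = 0.9,
    use_abs: bool = False,
) -> pd.DataFrame:
    """lncRNA-mRNA pairs whose Pearson r exceeds ``r_min``.

    The published filter is the one-sided ``r > r_min`` (positive
    co-expression only); ``use_abs`` switches to ``|r| > r_min``. Expression
    rows are feature profiles across the same samples (log2 normalized
    scale). Zero-variance features cannot yield a correlation and are
    skipped (count logged).
    """
    if list(expr_lnc.columns) != list(expr_mrna.columns):
        raise ValueError("lncRNA and mRNA expression must share the same samples")
    if expr_lnc.shape[1] < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    A = expr_lnc.to_numpy(float)
    B = expr_mrna.to_numpy(float)
    sd_a = A.std(axis=1)
    sd_b = B.std(axis=1)
    ok_a, ok_b = sd_a > 0, sd_b > 0
    n_skipped = int((~ok_a).sum() + (~ok_b).sum())
    if n_skipped:
        logger.warning("pcc_pairs: skipped %d zero-variance feature(s)", n_skipped)
    Az = (A[ok_a] - A[ok_a].mean(axis=1, keepdims=True)) / sd_a[ok_a][:, None]
    Bz = (B[ok_b] - B[ok_b].mean(axis=1, keepdims=True)) / sd_b[ok_b][:, None]
    R = (Az @ Bz.T) / A.shape[1]
    R = np.clip(R, -1.0, 1.0)
    score = np.abs(R) if use_abs else R
    li, mi = np.nonzero(score > r_min)
    lnc_ids = expr_lnc.index[ok_a]
    mrna_ids = expr_mrna.index[ok_b]
    out = pd.DataFrame(
        {
            "lnc_id": lnc_ids[li],
            "mrna_id": mrna_ids[mi],
            "r": R[li, mi],
        }
    ).sort_values(["lnc_id", "mrna_id"]).reset_index(drop=True)
    return out


# ----------------------------------------------------------------------
# adjacency / soft power / TOM


def condition_adjust(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Remove each feature's per-condition mean from its expression.

    With samples spanning lesion and normal, every strongly DE feature
    co-varies with every other along the condition axis, so an unadjusted
    network degenerates into two direction-driven blobs. Centering within
    condition removes that axis and leaves the co-regulation structure the
    modules are meant to capture. ``design`` needs sample/condition columns
    (index or ``sample`` column matching ``expr`` columns).
    """
    design = design.set_index("sample") if "sample" in design.columns else design
    cond = design.loc[list(expr.columns), "condition"]
    adjusted = expr.copy().astype(float)
    for c in cond.unique():
        cols = expr.columns[(cond == c).to_numpy()]
        adjusted[cols] = expr[cols].sub(expr[cols].mean(axis=1), axis=0)
    return adjusted


def adjacency(expr: pd.DataFrame, beta: int = 6) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``|r|^beta`` with zero diagonal."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(expr.to_numpy(float))
    r = np.nan_to_num(r, nan=0.0)
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) ~ log10 k linear fit over a connectivity histogram."""
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    hist, edges = np.histogram(k, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = (hist > 0) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(hist[ok] / hist.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2) if np.isfinite(r) else 0.0


def pick_soft_power(
    expr: pd.DataFrame,
    candidate_powers=tuple(range(1, 13)),
    r2_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest soft power whose connectivity distribution fits a power law
    with R^2 >= target; falls back (with a warning) to the best-fitting power.

    Returns (beta, table of per-power R^2 and mean connectivity).
    """
    candidate_powers = list(candidate_powers)
    if not candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    if expr.shape[0] < 30:
        raise ValueError("scale-free fit needs at least 30 features")
    rows = []
    for b in candidate_powers:
        a = adjacency(expr, beta=b).to_numpy()
        k = a.sum(axis=1)
        rows.append({"power": b, "r2": scale_free_fit(k), "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    hits = table[table["r2"] >= r2_target]
    if len(hits):
        beta = int(hits["power"].iloc[0])
    else:
        # With a handful of samples the R^2 profile is dominated by noise
        # and its argmax is frequently beta=1 (no soft thresholding at all);
        # fall back to the conventional unsigned-network default instead.
        fallback = 6
        beta = fallback if fallback in candidate_powers else int(
            table.loc[table["r2"].idxmax(), "power"]
        )
        warnings.warn(
            f"no candidate power reached scale-free R^2 >= {r2_target}; "
            f"using beta={beta}",
            stacklevel=2,
        )
    return beta, table


def tom(adj) -> np.ndarray:
    """Topological overlap matrix.

    ``t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` (u != i, j) and ``t_ii = 1`` by convention.
    """
    a = adj.to_numpy(float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # zero diagonal makes u=i and u=j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


# ----------------------------------------------------------------------
# modules


@dataclass
class ModuleSet:
    """Module labels plus per-module eigengenes and DE significance."""

    labels: pd.Series  # feature -> color label or "grey"
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x sample
    significance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def members(self, module: str) -> list[str]:
        return sorted(self.labels.index[self.labels == module])

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.labels) - {GREY})


DEFAULT_CUT_HEIGHT = 0.95


def detect_modules(
    t: np.ndarray,
    feature_ids,
    min_size: int = 30,
    cut_height: float | None = None,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    ``cut_height=None`` uses the conventional absolute 0.95 on the TOM
    dissimilarity scale (a cut relative to the maximum merge height is
    unstable: unrelated features merge just below 1, so the top of the tree
    carries no usable scale). Clusters
    smaller than ``min_size`` are relabelled grey; surviving modules get
    WGCNA color names by decreasing size (ties broken by smallest member
    index, so the labelling is permutation-stable).
    """
    feature_ids = list(feature_ids)
    n = len(feature_ids)
    if t.shape != (n, n):
        raise ValueError("TOM shape does not match feature_ids")
    if n < 2:
        return ModuleSet(labels=pd.Series([GREY] * n, index=feature_ids, name="module"))
    d = 1.0 - t
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    cut = DEFAULT_CUT_HEIGHT if cut_height is None else cut_height
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = np.array([GREY] * n, dtype=object)
    clusters = []
    for c in np.unique(raw):
        idx = np.flatnonzero(raw == c)
        if idx.size >= min_size:
            clusters.append(idx)
    clusters.sort(key=lambda idx: (-idx.size, idx.min()))
    for color, idx in zip(WGCNA_COLORS, clusters):
        labels[idx] = color
    if len(clusters) > len(WGCNA_COLORS):
        for j, idx in enumerate(clusters[len(WGCNA_COLORS):]):
            labels[idx] = f"module_{len(WGCNA_COLORS) + j + 1}"
    if not clusters:
        warnings.warn("no module reached min_size; all features grey", stacklevel=2)
    return ModuleSet(labels=pd.Series(labels, index=feature_ids, name="module"))


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized expression,
    oriented so the mean member loading is positive. Rows = modules."""
    out = {}
    for module in sorted(set(labels) - {GREY}):
        sub = expr.loc[labels.index[labels == module]].to_numpy(float)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        zs = (sub - sub.mean(axis=1, keepdims=True)) / sd
        u, s, vt = np.linalg.svd(zs, full_matrices=False)
        eig = vt[0]
        if u[:, 0].mean() < 0:
            eig = -eig
        out[module] = eig
    return pd.DataFrame(out, index=expr.columns).T


def module_significance(
    labels: pd.Series, de: pd.DataFrame, top_k: int = 3
) -> tuple[pd.Series, list[str]]:
    """Module significance = mean -log10 raw DE p over members.

    Members absent from the DE table are excluded (count logged). Returns
    the per-module scores (descending) and the ``top_k`` selected modules.
    """
    scores = {}
    for module in sorted(set(labels) - {GREY}):
        members = labels.index[labels == module]
        present = [m for m in members if m in de.index]
        if len(present) < len(members):
            logger.warning(
                "module %s: %d member(s) missing from DE results",
                module,
                len(members) - len(present),
            )
        if not present:
            scores[module] = 0.0
            continue
        p = de.loc[present, "p"].to_numpy(float)
        p = p[~np.isnan(p)]  # undetected members carry no p-value
        scores[module] = (
            float(np.mean(-np.log10(np.clip(p, 1e-300, 1.0)))) if p.size else 0.0
        )
    order = sorted(scores, key=lambda m: (-scores[m], m))
    sig = pd.Series({m: scores[m] for m in order}, name="significance", dtype=float)
    selected = order[:top_k]
    return sig, selected
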