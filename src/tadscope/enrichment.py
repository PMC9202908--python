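"""Fisher's-exact (hypergeometric) gene-set over-representation analysis.

For a query list of n genes drawn from a universe of N, a set with K
members in the universe and overlap k, the one-sided enrichment p-value is
the hypergeometric upper tail P(X >= k). Only over-representation is
tested; results are BH-adjusted with the same step-up implementation used
for differential expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import adjust_bh
from .io import read_gmt

logger = logging.getLogger(__name__)

DEFAULT_P_CUT = 0.01  # the published Fisher significance threshold
DEFAULT_TOP_K = 8  # sets reported per module subnetwork


def hypergeom_upper_tail(k, N, K, n):
    """One-sided enrichment p-value P(X >= k) for overlap k out of a query
    of n against a set of K in a universe of N. Vectorized in k."""
    return hypergeom.sf(np.asarray(k) - 1, N, K, n)


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit background universe.

    Set members outside the universe do not count toward K; the universe is
    by default the union of all set members (the "annotated" background),
    but should usually be restricted to detected features via
    :meth:`restrict_universe`.
    """

    sets: dict[str, list[str]]
    universe: frozenset

    def __post_init__(self):
        self.sets = {name: list(dict.fromkeys(m)) for name, m in self.sets.items()}
        self.universe = frozenset(self.universe)

    @property
    def n_universe(self) -> int:
        return len(self.universe)

    @classmethod
    def from_gmt(cls, path, universe=None) -> "GeneSetCollection":
        sets = read_gmt(path)
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        return cls(sets=sets, universe=frozenset(universe))

    def restrict_universe(self, feature_ids) -> "GeneSetCollection":
        """Intersect the universe with ``feature_ids`` (e.g. detected genes
        carrying at least one set annotation)."""
        annotated = set().union(*self.sets.values()) if self.sets else set()
        return GeneSetCollection(
            sets=self.sets, universe=self.universe & set(feature_ids) & annotated
        )


def fisher_enrich(
    query, gsc: GeneSetCollection, p_cut: float = DEFAULT_P_CUT
) -> pd.DataFrame:
    """One-sided Fisher/hypergeometric enrichment of ``query`` against every set.

    Query ids outside the universe are dropped (count logged). Results are
    sorted by (p, set name); ``significant`` flags p < p_cut.
    """
    N = gsc.n_universe
    if N == 0:
        raise ValueError("empty universe")
    query = list(dict.fromkeys(query))
    inside = [g for g in query if g in gsc.universe]
    dropped = len(query) - len(inside)
    if dropped:
        logger.warning("fisher_enrich: dropped %d query id(s) outside the universe", dropped)
    qset = set(inside)
    n = len(qset)
    rows = []
    for name in sorted(gsc.sets):
        members = [m for m in gsc.sets[name] if m in gsc.universe]
        K = len(members)
        k = len(qset.intersection(members))
        p = float(hypergeom_upper_tail(k, N, K, n))
        # odds ratio of the 2x2 (query x set) table
        a, b, c, d = k, n - k, K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(
            {"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0), "odds_ratio": odds}
        )
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "odds_ratio"])
    out["q"] = adjust_bh(out["p"].to_numpy())
    out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    out["significant"] = out["p"] < p_cut
    return out


def enrich_modules(
    module_genes: dict[str, list[str]],
    gsc: GeneSetCollection,
    top_k: int = DEFAULT_TOP_K,
    p_cut: float = DEFAULT_P_CUT,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-module enrichment plus the union of each module's top-k sets by p.

    Returns ``(per_module_tables, reported)`` where ``reported`` has one row
    per (module, set) among the top-k of that module.
    """
    tables = {}
    reported_rows = []
    for module in sorted(module_genes):
        genes = module_genes[module]
        if not genes:
            raise ValueError(f"module {module!r} has an empty gene list")
        tab = fisher_enrich(genes, gsc, p_cut=p_cut)
        tables[module] = tab
        top = tab.head(top_k).copy()
        top.insert(0, "module", module)
        reported_rows.append(top)
    reported = (
        pd.concat(reported_rows, ignore_index=True)
        if reported_rows
        else pd.DataFrame(columns=["module", "set", "k", "K", "n", "N", "p", "odds_ratio", "q", "significant"])
    )
    return tables, reported


def lncrna_target_substitution(de_lncs, pairs: pd.DataFrame) -> list[str]:
    """The "lncRNA-targeted mRNA" query: replace each DE lncRNA with its
    correlation-paired mRNAs (union, sorted)."""
    de_lncs = set(de_lncs)
    hits = pairs[pairs["lnc_id"].isin(de_lncs)]["mrna_id"]
    return sorted(set(hits))
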