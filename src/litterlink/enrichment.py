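"""Hypergeometric over-representation analysis against GMT collections.

For a query gene list of size n drawn from a universe of N measured genes,
a term with K members in the universe and k members in the query gets the
exact upper-tail p = P(X >= k), X ~ Hypergeometric(N, K, n). p-values are
BH-adjusted across all tested terms of the collection for one query (the
family mirrors a single submission to an ORA service). Terms need at least
``min_overlap`` query genes to be called significant, suppressing
singleton-driven hits. The universe defaults to the prefiltered genes of
the tissue, not the whole genome — the defensible measured-gene background.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .screening import bh_adjust

logger = logging.getLogger("litterlink")


def ora(
    query_genes,
    universe_genes,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each term.

    Query genes outside the universe are dropped with a warning; term
    memberships are intersected with the universe and empty terms skipped.
    Results are sorted by p (term id breaking ties).
    """
    universe = set(map(str, universe_genes))
    if not universe:
        raise ValueError("empty universe")
    query_in = [g for g in dict.fromkeys(map(str, query_genes)) if g in universe]
    dropped = len(set(map(str, query_genes))) - len(query_in)
    if dropped:
        logger.warning("ora: %d query genes outside the universe dropped", dropped)
    if not query_in:
        raise ValueError("empty query after intersecting with the universe")
    query = set(query_in)
    n_universe = len(universe)
    n_query = len(query)

    term_ids, term_k, term_cap = [], [], []
    for gs in sets:
        members = set(gs.members) & universe
        if not members:
            continue
        term_ids.append(gs.term_id)
        term_cap.append(len(members))
        term_k.append(len(members & query))
    if not term_ids:
        return pd.DataFrame(
            columns=["term_id", "overlap", "term_size", "query_size",
                     "universe_size", "p", "p_adj", "significant"]
        )
    k = np.asarray(term_k)
    cap = np.asarray(term_cap)
    p = stats.hypergeom.sf(k - 1, n_universe, cap, n_query)
    p = np.clip(p, 0.0, 1.0)
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "term_id": term_ids,
            "overlap": k,
            "term_size": cap,
            "query_size": n_query,
            "universe_size": n_universe,
            "p": p,
            "p_adj": p_adj,
        }
    )
    out["significant"] = (out["p_adj"] < alpha) & (out["overlap"] >= min_overlap)
    return out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)


def ora_for_route(
    feature_id: str,
    route: str,
    route_genes,
    universe_genes,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    min_overlap: int = 2,
) -> tuple[str, str, int]:
    """Count significant ORA terms for one feature's route gene set.

    An empty route gene set is a legitimate outcome (the feature simply has
    no associated genes through that route) and yields a count of 0.
    """
    route_genes = list(route_genes)
    if not route_genes:
        return feature_id, route, 0
    try:
        res = ora(route_genes, universe_genes, sets, alpha=alpha, min_overlap=min_overlap)
    except ValueError:
        # all route genes fell outside the universe
        return feature_id, route, 0
    return feature_id, route, int(res["significant"].sum())
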