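"""Hypergeometric over-representation of selected genes in gene sets.

For each namespace of a collection the universe is the annotated genes
appearing in at least one of its sets (N). With K set members, n selected
genes inside the universe and k of them in the set, the enrichment p-value
is the upper tail P(X >= k) of the hypergeometric(N, K, n) distribution.
Sets with zero overlap are untestable for over-representation and are
suppressed. q-values are Benjamini-Hochberg within each namespace.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidParameterError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_upper", "enrich"]

ENRICHMENT_COLUMNS = ["set_id", "description", "namespace", "p_value",
                      "q_value", "N", "K", "n", "k"]


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts set members among ``n`` draws without replacement from a
    universe of ``N`` genes of which ``K`` are in the set.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise InvalidParameterError(
            f"invalid hypergeometric configuration N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(selected_genes: Iterable[str], annotation: pd.Series,
           sets: GeneSetCollection) -> pd.DataFrame:
    """Test every gene set for over-representation of the selected genes.

    ``selected_genes`` are gene symbols (case-insensitive); ``annotation``
    maps probe ids to symbols and defines which genes exist on the array.
    Returns one row per set with k >= 1, sorted by ascending p-value
    (ties by set id), with per-namespace BH q-values.
    """
    if len(sets) == 0:
        raise InvalidParameterError("gene-set collection is empty")
    annotated = {s for s in annotation.astype(str).str.upper() if s}
    selected = {str(g).upper() for g in selected_genes}

    rows: list[dict] = []
    for namespace in sets.namespaces():
        universe = annotated & set(sets.universe(namespace))
        N = len(universe)
        sel_u = selected & universe
        n = len(sel_u)
        if n == 0:
            logger.warning("no selected gene maps into the %r universe", namespace)
            continue
        for s in sets:
            if s.namespace != namespace:
                continue
            members = s.member_set() & universe
            K = len(members)
            k = len(sel_u & members)
            if k == 0:
                continue
            rows.append({
                "set_id": s.set_id, "description": s.description,
                "namespace": namespace,
                "p_value": hypergeom_upper(N, K, n, k),
                "N": N, "K": K, "n": n, "k": k,
            })
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    table = pd.DataFrame(rows)
    table["q_value"] = 1.0
    for namespace, idx in table.groupby("namespace").groups.items():
        _, q, _, _ = multipletests(table.loc[idx, "p_value"], method="fdr_bh")
        table.loc[idx, "q_value"] = q
    table = table.sort_values(["p_value", "set_id"], kind="mergesort")
    return table[ENRICHMENT_COLUMNS].reset_index(drop=True)
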