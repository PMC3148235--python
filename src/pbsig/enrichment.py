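"""Gene-set overlap annotation.

A probe or gene list is annotated against a GMT collection with the
upper-tail hypergeometric test: given a universe of U identifiers of
which K belong to the set, the p-value is P(X >= o) for the observed
overlap o when drawing the query's n identifiers at random.  Results are
ranked by p (ties by set name) and truncated to a top-N list — the same
"compute overlaps" usage the signature annotation workflow relies on; no
ranked-list enrichment statistic is computed here.

No multiple-testing correction enters the ranking; a Benjamini–Hochberg
column is emitted alongside as a labeled extension.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
from scipy import stats

from .formats import GeneSetCollection
from .signature import Signature

__all__ = ["EnrichmentResult", "hypergeometric_overlap", "annotate_signature"]


@dataclasses.dataclass
class EnrichmentResult:
    """Ranked gene-set overlaps for one query list."""

    query_name: str
    universe_size: int
    table: pd.DataFrame  # set_name, set_size, query_size, overlap, p_value, bh_fdr, members

    def save_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["members"] = out["members"].map(lambda ms: ",".join(ms))
        out.to_csv(path, sep="\t", index=False)


def _bh_fdr(p: pd.Series) -> pd.Series:
    n = len(p)
    order = p.sort_values().index
    ranked = p.loc[order].to_numpy() * n / (pd.RangeIndex(1, n + 1).to_numpy())
    # enforce monotonicity from the largest p down
    for i in range(n - 2, -1, -1):
        ranked[i] = min(ranked[i], ranked[i + 1])
    return pd.Series(ranked.clip(max=1.0), index=order).reindex(p.index)


def hypergeometric_overlap(
    query: list[str],
    collection: GeneSetCollection,
    universe_size: int,
    query_name: str = "query",
) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap of a query list with every set."""
    q = list(dict.fromkeys(query))
    n = len(q)
    if universe_size < n:
        raise ValueError(f"universe_size {universe_size} smaller than query size {n}")
    qset = set(q)
    rows = []
    for name in collection.names():
        members = collection.members(name)
        K = len(members)
        if universe_size < K:
            raise ValueError(
                f"universe_size {universe_size} smaller than set {name!r} ({K})"
            )
        hits = sorted(qset.intersection(members))
        o = len(hits)
        # P(X >= o) drawing n from a universe with K marked
        p = float(stats.hypergeom.sf(o - 1, universe_size, K, n)) if o > 0 else 1.0
        rows.append((name, K, n, o, min(p, 1.0), hits))
    table = pd.DataFrame(
        rows, columns=["set_name", "set_size", "query_size", "overlap", "p_value", "members"]
    ).sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    table.insert(5, "bh_fdr", _bh_fdr(table["p_value"]))
    return EnrichmentResult(query_name=query_name, universe_size=universe_size, table=table)


def annotate_signature(
    signature: Signature,
    collection: GeneSetCollection,
    universe_size: int,
    top: int = 20,
) -> dict[str, EnrichmentResult]:
    """Overlap annotation of the full, up-only and down-only probe lists.

    Each result table is truncated to the ``top`` best-ranked sets.
    """
    queries = {
        "all": signature.probe_ids,
        "up": signature.up_probes(),
        "down": signature.down_probes(),
    }
    out: dict[str, EnrichmentResult] = {}
    for name, probes in queries.items():
        if not probes:
            continue
        res = hypergeometric_overlap(probes, collection, universe_size, query_name=name)
        res.table = res.table.head(top).reset_index(drop=True)
        out[name] = res
    return out
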