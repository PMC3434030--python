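"""Category overrepresentation against the expressed background (EASE score).

The EASE score is a conservative one-tailed Fisher exact p-value: one gene
is removed from the list-and-category cell before computing the
hypergeometric upper tail, which penalizes categories supported by a
single gene.  The background must be the set of genes detected as
expressed in the experiment, not the whole array.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import AnnotationTable

__all__ = ["ease_score", "fisher_enrichment_p", "run_enrichment"]


def _check_counts(list_hits: int, list_size: int, bg_hits: int, bg_size: int) -> None:
    ok = (
        0 <= list_hits <= list_size <= bg_size
        and list_hits <= bg_hits <= bg_size
    )
    if not ok:
        raise ValueError(
            f"inconsistent counts: list_hits={list_hits}, list_size={list_size}, "
            f"bg_hits={bg_hits}, bg_size={bg_size}"
        )


def fisher_enrichment_p(
    list_hits: int, list_size: int, bg_hits: int, bg_size: int
) -> float:
    """Plain one-tailed Fisher (hypergeometric upper tail) P(X >= list_hits)."""
    _check_counts(list_hits, list_size, bg_hits, bg_size)
    return float(stats.hypergeom.sf(list_hits - 1, bg_size, bg_hits, list_size))


def ease_score(
    list_hits: int, list_size: int, bg_hits: int, bg_size: int
) -> float:
    """EASE score: the Fisher upper tail after removing one list hit.

    ``list_hits = 0`` returns 1 by convention.
    """
    _check_counts(list_hits, list_size, bg_hits, bg_size)
    if list_hits == 0:
        return 1.0
    return float(stats.hypergeom.sf(list_hits - 2, bg_size, bg_hits, list_size))


def run_enrichment(
    gene_list: Iterable[str],
    background: Iterable[str],
    annotation: AnnotationTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """EASE score per annotation category with >= 1 hit in the gene list.

    Genes outside the background raise: the background must be the
    expressed set that produced the list.
    """
    genes = set(gene_list)
    bg = set(background)
    stray = genes - bg
    if stray:
        raise ValueError(
            f"genes in list but not background (background must be the "
            f"expressed set): {sorted(stray)[:5]}"
        )
    rows = []
    for category in annotation.categories():
        members = annotation.members_of(category) & bg
        if not members:
            continue
        hits = members & genes
        if not hits:
            continue
        p = ease_score(len(hits), len(genes), len(members), len(bg))
        rows.append(
            {
                "category_id": category,
                "label": annotation.labels.get(category, category),
                "list_hits": len(hits),
                "list_size": len(genes),
                "bg_hits": len(members),
                "bg_size": len(bg),
                "ease_p": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "category_id", "label", "list_hits", "list_size",
            "bg_hits", "bg_size", "ease_p",
        ],
    )
    if len(result):
        result["adj_p"] = bh_adjust(result["ease_p"].to_numpy())
        result["overrepresented"] = result["ease_p"] < alpha
        result = result.sort_values(
            ["ease_p", "category_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["adj_p"] = np.array([], dtype=float)
        result["overrepresented"] = np.array([], dtype=bool)
    return result
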