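"""Category enrichment statistics and the imaging signal ratio.

Category (GO-style) enrichment uses the one-sided Fisher exact test
(hypergeometric upper tail) with Benjamini-Hochberg FDR correction across the
tested categories.  Only enrichment is tested, matching the fold > 1 reading
of category bars; ontology content is user-supplied as a plain
category -> protein-id map, no ontology is bundled.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fisher_enrichment(
    foreground: Iterable,
    background: Iterable,
    categories: Mapping[str, Iterable],
) -> pd.DataFrame:
    """One-sided category enrichment of ``foreground`` within ``background``.

    For each category with n background hits out of N background proteins and
    k foreground hits out of K foreground proteins:

        fold = (k/K) / (n/N)
        p    = P[X >= k],  X ~ Hypergeom(N, n, K)

    Categories are intersected with the background first; categories with
    k = 0 are reported with fold 0 and p = 1.  q is BH-adjusted across the
    tested categories.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        extra = sorted(map(str, fg - bg))[:3]
        raise DataError(f"foreground not a subset of background (e.g. {extra})")
    K, N = len(fg), len(bg)
    rows = []
    for cat, members in categories.items():
        in_cat = set(members) & bg
        n = len(in_cat)
        k = len(in_cat & fg)
        if k == 0:
            fold, p = 0.0, 1.0
        else:
            fold = (k / K) / (n / N)
            p = float(hypergeom.sf(k - 1, N, n, K))
        rows.append({"category": cat, "k": k, "K": K, "n": n, "N": N, "fold": fold, "p": p})
    result = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "fold", "p"])
    result["q"] = bh_fdr(result["p"]) if len(result) else []
    return result


def relative_signal_over_background(
    signal_mean_488: float,
    signal_mean_dapi: float,
    bg_mean_488: float,
    bg_mean_dapi: float,
) -> float:
    """Relative fluorescence signal over background.

    Ratio of the channel ratio (reporter / DNA counterstain) in the region of
    interest to the same ratio in a background region:

        (signal_488 / signal_dapi) / (bg_488 / bg_dapi)

    All four means must be strictly positive.
    """
    means = (signal_mean_488, signal_mean_dapi, bg_mean_488, bg_mean_dapi)
    if any(m <= 0 for m in means):
        raise DataError("all mean grey values must be > 0")
    return (signal_mean_488 / signal_mean_dapi) / (bg_mean_488 / bg_mean_dapi)


def read_category_map(path) -> dict:
    """Two-column TSV (category_id, protein_id) -> mapping category -> id set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["category", "protein_id"], comment="#")
    return {cat: set(sub["protein_id"]) for cat, sub in df.groupby("category", sort=False)}
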