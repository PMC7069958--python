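"""Interactome set comparison and replicate-level QC.

Compartment classification exploits the contrast between a wild-type bait and
a DNA-binding-deficient bait: interactors enriched only with the wild type
bind the bait on chromatin, interactors enriched with both are general
nuclear partners, and interactors enriched only with the mutant meet the bait
in the nucleoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .enrichment import Interactome
from .protein_groups import LfqMatrix

COMPARTMENTS = ("chromatin", "nucleus", "nucleoplasm")


def _as_set(obj) -> frozenset:
    if isinstance(obj, Interactome):
        return obj.members
    return frozenset(obj)


@dataclass
class CompartmentAssignment:
    """Partition of interactors into chromatin / nucleus / nucleoplasm."""

    chromatin: frozenset
    nucleus: frozenset
    nucleoplasm: frozenset
    tissue: str

    def label_of(self) -> dict:
        out = {}
        for label in COMPARTMENTS:
            for pid in getattr(self, label):
                out[pid] = label
        return out

    def get(self, protein_id, default=None):
        return self.label_of().get(protein_id, default)

    def counts(self) -> dict:
        return {label: len(getattr(self, label)) for label in COMPARTMENTS}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_id": pid, "compartment": label, "tissue": self.tissue}
            for label in COMPARTMENTS
            for pid in sorted(getattr(self, label))
        ]
        return pd.DataFrame(rows, columns=["protein_id", "compartment", "tissue"])


def classify_compartment(wt, n51a, tissue: str | None = None) -> CompartmentAssignment:
    """Set logic over the two bait contrasts.

    chromatin = wt \\ n51a, nucleus = wt & n51a, nucleoplasm = n51a \\ wt.
    The three sets are pairwise disjoint and partition wt | n51a.
    """
    if isinstance(wt, Interactome) and isinstance(n51a, Interactome):
        if wt.tissue != n51a.tissue:
            raise ConfigError(
                f"compartment classification mixes tissues {wt.tissue!r} and {n51a.tissue!r}"
            )
        tissue = wt.tissue
    wt_set, n51a_set = _as_set(wt), _as_set(n51a)
    return CompartmentAssignment(
        chromatin=wt_set - n51a_set,
        nucleus=wt_set & n51a_set,
        nucleoplasm=n51a_set - wt_set,
        tissue=tissue or "",
    )


@dataclass
class VennPartition:
    """Exact membership partition of several interactomes.

    ``combinations`` maps each non-empty tissue combination (frozenset of
    tissue labels) to the proteins found in exactly those tissues.
    """

    combinations: dict
    totals: dict

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.combinations.values())

    @property
    def n_unique(self) -> int:
        return sum(len(v) for combo, v in self.combinations.items() if len(combo) == 1)

    @property
    def n_shared(self) -> int:
        return sum(len(v) for combo, v in self.combinations.items() if len(combo) >= 2)

    @property
    def shared_multiplicity(self) -> int:
        """Sum over shared proteins of the number of tissues they occur in."""
        return sum(
            len(combo) * len(v) for combo, v in self.combinations.items() if len(combo) >= 2
        )

    def count(self, *tissues: str) -> int:
        return len(self.combinations.get(frozenset(tissues), frozenset()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tissues": "&".join(sorted(combo)), "n_proteins": len(members),
             "proteins": ";".join(sorted(map(str, members)))}
            for combo, members in sorted(self.combinations.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["tissues", "n_proteins", "proteins"])


def tissue_venn(interactomes: Mapping[str, object]) -> VennPartition:
    """Full Venn partition over >=2 tissue interactomes (or plain id sets)."""
    if len(interactomes) < 2:
        raise ConfigError("tissue_venn needs at least two tissues")
    sets = {tissue: _as_set(obj) for tissue, obj in interactomes.items()}
    tissues = list(sets)
    universe = frozenset().union(*sets.values())
    combos: dict = {}
    for r in range(1, len(tissues) + 1):
        for combo in combinations(tissues, r):
            key = frozenset(combo)
            inside = frozenset.intersection(*(sets[t] for t in combo)) if combo else universe
            outside = frozenset().union(*(sets[t] for t in tissues if t not in key), frozenset())
            members = inside - outside
            if members:
                combos[key] = members
    totals = {t: len(sets[t]) for t in tissues}
    return VennPartition(combinations=combos, totals=totals)


def pearson_qc(matrix: LfqMatrix, scale: str = "log10") -> pd.DataFrame:
    """Sample-sample Pearson correlation on pairwise-complete observations.

    Unquantified cells (intensity 0) are excluded pair-wise rather than
    imputed, so QC is not driven by the imputation model.  Pairs with fewer
    than 3 complete observations are NaN; the diagonal is 1.
    """
    if scale not in ("log10", "linear"):
        raise ConfigError("scale must be 'log10' or 'linear'")
    data = matrix.intensities[matrix.design.sample_ids].astype(float)
    data = data.where(data > 0)  # 0 -> NaN (not quantified)
    if scale == "log10":
        data = np.log10(data)
    corr = data.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def embedding_matrix(
    matrix: LfqMatrix,
    downshift: float = 1.8,
    width: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Dense log10 matrix with missing cells imputed from a downshifted normal.

    For each sample, missing cells are drawn from
    Normal(mean - downshift * SD, (width * SD)^2) computed on that sample's
    observed log10 intensities — the de-facto convention for visualising
    label-free data where missingness concentrates at low abundance.  The
    result is suitable for PCA or heat maps; deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    data = matrix.intensities[matrix.design.sample_ids].astype(float)
    data = np.log10(data.where(data > 0))
    out = data.copy()
    for col in data.columns:
        observed = data[col].dropna()
        if observed.size < 2:
            raise DataError(f"sample {col!r} has fewer than 2 observed values")
        mu, sd = observed.mean(), observed.std(ddof=1)
        missing = data[col].isna()
        n_missing = int(missing.sum())
        if n_missing:
            out.loc[missing, col] = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
    return out
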