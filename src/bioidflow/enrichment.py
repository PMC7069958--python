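"""Enrichment calling for proximity-labelling LFQ contrasts.

The statistic reproduced here is a per-replicate threshold rule on
label-free quantification ratios.  For each replicate the case/control
intensity ratio is taken on the log2 scale; ratios with a quantified case but
an unquantified control are "infinite" and imputed; finite values are centred
on their per-replicate median; the enrichment cutoff is

    upper = median + k * SD(central trim_mass of the distribution)

with defaults k = 2 and trim_mass = 0.90 (i.e. the standard deviation of the
values between the 5th and 95th percentile, inclusive).  A protein belongs to
the interactome when its ratio exceeds ``upper`` in at least
``min_replicates`` replicates.  Only the upper bound is interpreted: the
analysis calls enrichment, not depletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .protein_groups import LfqMatrix

IMPUTATION_STRATEGIES = ("control-floor", "max-finite-plus")


@dataclass
class RatioSet:
    """Per-protein, per-replicate log2 case/control ratios.

    ``values``: float DataFrame, index = protein_id, columns = replicate index.
    Cell states are mutually exclusive: finite log2 ratio; ``NaN`` (case
    unquantified); ``+inf`` (case quantified, control unquantified).
    """

    values: pd.DataFrame
    contrast: tuple[str, str]  # (case condition, control condition)
    tissue: str
    case_samples: dict[int, str] = field(default_factory=dict)
    control_samples: dict[int, str] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.contrast[0]}/{self.contrast[1]}"

    @property
    def replicates(self) -> list[int]:
        return list(self.values.columns)

    def n_infinite(self) -> int:
        return int(np.isposinf(self.values.to_numpy()).sum())


@dataclass
class EnrichmentThreshold:
    """Per-replicate enrichment cutoffs (all in log2-ratio units)."""

    per_replicate: pd.DataFrame  # columns: median, trimmed_sd, upper
    k: float
    trim_mass: float

    def upper(self, replicate: int) -> float:
        return float(self.per_replicate.at[replicate, "upper"])


@dataclass
class Interactome:
    """Proteins called enriched for one (tissue, contrast) pair."""

    tissue: str
    contrast: tuple[str, str]
    calls: pd.DataFrame  # bool, index = protein_id, columns = replicate
    n_enriched: pd.Series
    min_replicates: int

    @property
    def members(self) -> frozenset:
        return frozenset(self.n_enriched.index[self.n_enriched >= self.min_replicates])

    @property
    def proteins(self) -> frozenset:
        return self.members

    @property
    def label(self) -> str:
        return f"{self.contrast[0]}/{self.contrast[1]}"


@dataclass
class EnrichmentConfig:
    """Tunable knobs of the caller; logged into reports for provenance."""

    trim_mass: float = 0.90
    k: float = 2.0
    min_replicates: int = 2
    imputation: str = "control-floor"

    def to_dict(self) -> dict:
        return {
            "trim_mass": self.trim_mass,
            "k": self.k,
            "min_replicates": self.min_replicates,
            "imputation.strategy": self.imputation,
        }


def compute_log2_ratios(
    matrix: LfqMatrix, contrast: tuple[str, str], tissue: str
) -> RatioSet:
    """Per-replicate log2(case/control) with NA and +inf markers.

    case > 0 and control > 0  ->  log2(case/control)
    case > 0 and control == 0 ->  +inf (imputed later)
    case == 0                 ->  NaN
    """
    case_cond, control_cond = contrast
    pairs = matrix.design.pairs(case_cond, control_cond, tissue)
    out = {}
    case_samples, control_samples = {}, {}
    for case, ctrl in pairs:
        c = matrix.intensities[case.sample_id].to_numpy(dtype=float)
        g = matrix.intensities[ctrl.sample_id].to_numpy(dtype=float)
        vals = np.full(c.shape, np.nan)
        both = (c > 0) & (g > 0)
        vals[both] = np.log2(c[both] / g[both])
        vals[(c > 0) & (g == 0)] = np.inf
        out[case.replicate] = vals
        case_samples[case.replicate] = case.sample_id
        control_samples[case.replicate] = ctrl.sample_id
    values = pd.DataFrame(out, index=matrix.protein_ids)
    return RatioSet(values, contrast, tissue, case_samples, control_samples)


def impute_infinite(
    ratios: RatioSet, matrix: LfqMatrix, strategy: str = "control-floor"
) -> RatioSet:
    """Replace +inf markers with finite surrogates; NaN cells are untouched.

    ``control-floor``: +inf -> log2(case / m) with m the minimum positive
    intensity observed in that replicate's control sample (the detection
    floor), keeping the case-intensity information.
    ``max-finite-plus``: +inf -> (max finite ratio in that replicate) + 0.5.
    """
    if strategy not in IMPUTATION_STRATEGIES:
        raise ConfigError(
            f"unknown imputation strategy {strategy!r}; choose from {IMPUTATION_STRATEGIES}"
        )
    values = ratios.values.copy()
    for rep in values.columns:
        col = values[rep].to_numpy(dtype=float).copy()
        inf_mask = np.isposinf(col)
        if not inf_mask.any():
            continue
        if strategy == "control-floor":
            control = matrix.intensities[ratios.control_samples[rep]].to_numpy(dtype=float)
            positive = control[control > 0]
            if positive.size == 0:
                raise DataError(
                    f"control sample {ratios.control_samples[rep]!r} has no positive "
                    "intensities; cannot impute infinite ratios"
                )
            floor = positive.min()
            case = matrix.intensities[ratios.case_samples[rep]].to_numpy(dtype=float)
            col[inf_mask] = np.log2(case[inf_mask] / floor)
        else:  # max-finite-plus
            finite = col[np.isfinite(col)]
            if finite.size == 0:
                raise DataError(
                    f"replicate {rep} has no finite ratios to anchor max-finite-plus imputation"
                )
            col[inf_mask] = finite.max() + 0.5
        values[rep] = col
    return replace(ratios, values=values)


def median_normalize(ratios: RatioSet) -> RatioSet:
    """Subtract the per-replicate median of finite values; NaN (and any +inf) preserved."""
    values = ratios.values.copy()
    for rep in values.columns:
        col = values[rep].to_numpy(dtype=float)
        finite = col[np.isfinite(col)]
        if finite.size == 0:
            raise DataError(f"replicate {rep} has no finite ratios to normalize")
        med = np.median(finite)
        mask = np.isfinite(col)
        col = col.copy()
        col[mask] = col[mask] - med
        values[rep] = col
    return replace(ratios, values=values)


def compute_threshold(
    ratios: RatioSet, trim_mass: float = 0.90, k: float = 2.0
) -> EnrichmentThreshold:
    """Median + k * trimmed-SD cutoff per replicate.

    The trim retains values within the central ``trim_mass`` percentile
    interval (linear-interpolation percentiles, inclusive bounds); the SD of
    the retained values uses the n-1 denominator.  The median is taken over
    all finite values, before trimming.  Expects imputed ratios (no +inf) and
    at least 5 finite values per replicate.
    """
    if not 0.0 < trim_mass <= 1.0:
        raise ConfigError("trim_mass must be in (0, 1]")
    rows = {}
    for rep in ratios.values.columns:
        col = ratios.values[rep].to_numpy(dtype=float)
        if np.isposinf(col).any():
            raise DataError(
                f"replicate {rep} still contains infinite ratios; impute before thresholding"
            )
        finite = col[np.isfinite(col)]
        if finite.size < 5:
            raise DataError(
                f"replicate {rep} has only {finite.size} finite ratios (>=5 required)"
            )
        median = float(np.median(finite))
        lo_q = (1.0 - trim_mass) / 2.0 * 100.0
        lo, hi = np.percentile(finite, [lo_q, 100.0 - lo_q])
        retained = finite[(finite >= lo) & (finite <= hi)]
        trimmed_sd = float(np.std(retained, ddof=1)) if retained.size > 1 else 0.0
        rows[rep] = {"median": median, "trimmed_sd": trimmed_sd, "upper": median + k * trimmed_sd}
    per_replicate = pd.DataFrame.from_dict(rows, orient="index")
    per_replicate.index.name = "replicate"
    return EnrichmentThreshold(per_replicate, k=k, trim_mass=trim_mass)


def call_enriched(
    ratios: RatioSet, threshold: EnrichmentThreshold, min_replicates: int = 2
) -> Interactome:
    """Consensus enrichment calls: ratio strictly above the replicate cutoff.

    NaN counts as not enriched; membership requires at least ``min_replicates``
    enriched replicates.
    """
    calls = {}
    for rep in ratios.values.columns:
        col = ratios.values[rep].to_numpy(dtype=float)
        upper = threshold.upper(rep)
        with np.errstate(invalid="ignore"):
            calls[rep] = (col > upper) & ~np.isnan(col)
    calls_df = pd.DataFrame(calls, index=ratios.values.index)
    n_enriched = calls_df.sum(axis=1)
    return Interactome(
        tissue=ratios.tissue,
        contrast=ratios.contrast,
        calls=calls_df,
        n_enriched=n_enriched,
        min_replicates=min_replicates,
    )


def call_interactome(
    matrix: LfqMatrix,
    contrast: tuple[str, str],
    tissue: str,
    config: EnrichmentConfig | None = None,
) -> tuple[Interactome, RatioSet, EnrichmentThreshold]:
    """Full chain: ratios -> impute infinities -> median-centre -> threshold -> call."""
    config = config or EnrichmentConfig()
    ratios = compute_log2_ratios(matrix, contrast, tissue)
    ratios = impute_infinite(ratios, matrix, strategy=config.imputation)
    ratios = median_normalize(ratios)
    threshold = compute_threshold(ratios, trim_mass=config.trim_mass, k=config.k)
    interactome = call_enriched(ratios, threshold, min_replicates=config.min_replicates)
    return interactome, ratios, threshold
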