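"""Protein-group quantification tables: containers, readers, writers, filtering.

The on-disk dialect is the tab-separated ``proteinGroups`` table emitted by
common label-free quantification software: one row per protein group, boolean
flag columns marked with ``+`` (``Reverse``, ``Potential contaminant``,
``Only identified by site``) and one ``LFQ intensity <sample>`` column per
sample.  An intensity of 0 (or a blank cell) means "not quantified".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, ParseError, SchemaError

logger = logging.getLogger(__name__)

FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}
ID_COLUMN = "Majority protein IDs"
FALLBACK_ID_COLUMN = "Protein IDs"
GENE_COLUMN = "Gene names"
INTENSITY_PREFIX = "LFQ intensity "


@dataclass(frozen=True)
class Sample:
    """One quantified sample: identity plus experimental coordinates."""

    sample_id: str
    condition: str
    tissue: str
    replicate: int


class SampleDesign:
    """Maps sample ids to (condition, tissue, replicate) and pairs case with control.

    The pairing rule is by replicate index within a tissue: case replicate *r*
    is compared against the control-condition sample with the same tissue and
    replicate *r*.
    """

    def __init__(self, samples: Iterable[Sample], control_condition: str = "GFP"):
        self.samples: list[Sample] = list(samples)
        self.control_condition = control_condition
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate sample_id in design")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.tissue not in seen:
                seen.append(s.tissue)
        return seen

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    def select(self, condition: str | None = None, tissue: str | None = None) -> list[Sample]:
        out = self.samples
        if condition is not None:
            out = [s for s in out if s.condition == condition]
        if tissue is not None:
            out = [s for s in out if s.tissue == tissue]
        return out

    def pairs(self, case_condition: str, control_condition: str, tissue: str) -> list[tuple[Sample, Sample]]:
        """Case/control sample pairs for one tissue, one per replicate index."""
        cases = self.select(case_condition, tissue)
        controls = {s.replicate: s for s in self.select(control_condition, tissue)}
        if not cases:
            raise ConfigError(
                f"no samples for condition {case_condition!r} in tissue {tissue!r}"
            )
        paired = []
        for case in sorted(cases, key=lambda s: s.replicate):
            ctrl = controls.get(case.replicate)
            if ctrl is None:
                raise ConfigError(
                    f"case replicate {case.replicate} of {case_condition!r}/{tissue!r} "
                    f"has no {control_condition!r} control with the same replicate index"
                )
            paired.append((case, ctrl))
        return paired

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "control_condition": self.control_condition,
            "samples": {
                s.sample_id: {
                    "condition": s.condition,
                    "tissue": s.tissue,
                    "replicate": s.replicate,
                }
                for s in self.samples
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SampleDesign":
        samples = [
            Sample(sid, meta["condition"], meta["tissue"], int(meta["replicate"]))
            for sid, meta in data["samples"].items()
        ]
        return cls(samples, control_condition=data.get("control_condition", "GFP"))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class LfqMatrix:
    """Protein-group x sample LFQ intensity matrix with row flags.

    ``intensities``: float DataFrame, index = protein_id, columns = sample_id;
    0.0 encodes "not quantified".  ``annotations``: per-row metadata with at
    least ``gene_name``, ``reverse``, ``contaminant``, ``only_by_site``.
    Unknown input columns are preserved in ``annotations``.
    """

    intensities: pd.DataFrame
    annotations: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise SchemaError(f"duplicate protein_id {dup!r}")
        if not self.intensities.index.equals(self.annotations.index):
            raise SchemaError("intensities and annotations must share a row index")
        missing = set(self.design.sample_ids) - set(self.intensities.columns)
        if missing:
            raise SchemaError(f"designed samples absent from matrix: {sorted(missing)}")
        vals = self.intensities[self.design.sample_ids].to_numpy()
        if np.nanmin(vals, initial=0.0) < 0:
            raise DataError("negative LFQ intensity encountered")

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def n_proteins(self) -> int:
        return len(self.intensities)

    def intensity(self, protein_id: str, sample_id: str) -> float:
        return float(self.intensities.at[protein_id, sample_id])

    def subset(self, protein_ids: Iterable[str]) -> "LfqMatrix":
        idx = self.intensities.index.intersection(pd.Index(protein_ids))
        return LfqMatrix(self.intensities.loc[idx].copy(), self.annotations.loc[idx].copy(), self.design)


def read_protein_groups(path: str | Path, design: SampleDesign) -> LfqMatrix:
    """Read a protein-group TSV into an :class:`LfqMatrix`.

    Raises :class:`SchemaError` if a designed sample's intensity column or a
    flag column is missing, and :class:`ParseError` (with row/column context)
    on non-numeric intensities.  Blank and 0 intensities both become 0.0.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    for flag_col in FLAG_COLUMNS.values():
        if flag_col not in table.columns:
            raise SchemaError(f"missing flag column {flag_col!r} in {path.name}")

    id_col = ID_COLUMN if ID_COLUMN in table.columns else FALLBACK_ID_COLUMN
    if id_col not in table.columns:
        raise SchemaError(f"missing identifier column {ID_COLUMN!r} in {path.name}")

    intensity_cols = {}
    for sample_id in design.sample_ids:
        col = INTENSITY_PREFIX + sample_id
        if col not in table.columns:
            raise SchemaError(f"missing designed sample column {col!r} in {path.name}")
        intensity_cols[sample_id] = col

    # protein_id = first entry of the (majority) identifier list
    protein_ids = table[id_col].str.split(";").str[0].str.strip()
    if (protein_ids == "").any():
        row = int(np.argmax((protein_ids == "").to_numpy()))
        raise ParseError(f"empty protein identifier at row {row} of {path.name}")

    intens = {}
    for sample_id, col in intensity_cols.items():
        raw = table[col].str.strip()
        num = pd.to_numeric(raw.replace("", "0"), errors="coerce")
        bad = num.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"non-numeric intensity {raw.iloc[row]!r} at row {row}, "
                f"column {col!r} of {path.name}"
            )
        intens[sample_id] = num.astype(float)
    intensities = pd.DataFrame(intens)
    intensities.index = pd.Index(protein_ids, name="protein_id")

    ann = pd.DataFrame(index=intensities.index)
    ann["gene_name"] = (
        table[GENE_COLUMN].str.split(";").str[0].to_numpy()
        if GENE_COLUMN in table.columns
        else protein_ids.to_numpy()
    )
    for name, col in FLAG_COLUMNS.items():
        ann[name] = (table[col].str.strip() == "+").to_numpy()
    handled = set(intensity_cols.values()) | set(FLAG_COLUMNS.values()) | {id_col, GENE_COLUMN}
    for col in table.columns:  # unknown columns kept as metadata
        if col not in handled:
            ann[col] = table[col].to_numpy()
    return LfqMatrix(intensities, ann, design)


def write_protein_groups(matrix: LfqMatrix, path: str | Path) -> None:
    """Write an :class:`LfqMatrix` in the TSV dialect read by :func:`read_protein_groups`."""
    out = pd.DataFrame(index=matrix.protein_ids)
    out[ID_COLUMN] = matrix.protein_ids
    out[FALLBACK_ID_COLUMN] = matrix.protein_ids
    out[GENE_COLUMN] = matrix.annotations["gene_name"].to_numpy()
    for name, col in FLAG_COLUMNS.items():
        out[col] = np.where(matrix.annotations[name].to_numpy(), "+", "")
    for sample_id in matrix.design.sample_ids:
        out[INTENSITY_PREFIX + sample_id] = matrix.intensities[sample_id].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def filter_canonical(matrix: LfqMatrix) -> LfqMatrix:
    """Remove decoy (reverse), contaminant and only-identified-by-site rows.

    Idempotent; the count of rows removed per flag is logged.  An empty result
    is allowed and logged as a warning.
    """
    ann = matrix.annotations
    for name in FLAG_COLUMNS:
        n = int(ann[name].sum())
        if n:
            logger.info("filter_canonical: removing %d rows flagged %s", n, name)
    keep = ~(ann["reverse"] | ann["contaminant"] | ann["only_by_site"])
    if not keep.any():
        logger.warning("filter_canonical: no rows survive canonical filtering")
    return LfqMatrix(
        matrix.intensities.loc[keep].copy(),
        matrix.annotations.loc[keep].copy(),
        matrix.design,
    )


def write_interactome_report(
    results: Mapping[tuple[str, str], Mapping],
    out_dir: str | Path,
    config: Mapping | None = None,
) -> dict:
    """Write per-(tissue, contrast) TSVs plus a JSON summary of all counts.

    ``results`` maps ``(tissue, contrast_label)`` to a mapping with keys
    ``interactome`` (required), ``ratios`` (optional :class:`RatioSet
    <bioidflow.enrichment.RatioSet>`) and ``compartments`` (optional
    protein_id -> label mapping).  Returns the summary dict that was written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable path
        raise DataError(f"cannot create report directory {out_dir}: {exc}") from exc

    summary: dict = {"experiments": {}, "config": dict(config) if config else {}}
    for (tissue, contrast_label), payload in results.items():
        interactome = payload["interactome"]
        calls = interactome.calls
        table = pd.DataFrame(index=calls.index)
        ratios = payload.get("ratios")
        if ratios is not None:
            for rep in ratios.values.columns:
                table[f"log2_ratio_rep{rep}"] = ratios.values[rep]
        for rep in calls.columns:
            table[f"enriched_rep{rep}"] = calls[rep]
        table["n_enriched_replicates"] = interactome.n_enriched
        table["member"] = table.index.isin(interactome.members)
        compartments = payload.get("compartments")
        if compartments is not None:
            table["compartment"] = [compartments.get(p, "") for p in table.index]
        stem = f"{tissue}_{contrast_label.replace('/', '_vs_')}"
        table.index.name = "protein_id"
        table.to_csv(out_dir / f"{stem}.tsv", sep="\t")
        summary["experiments"][stem] = {
            "tissue": tissue,
            "contrast": contrast_label,
            "n_proteins_scored": int(len(table)),
            "n_members": int(len(interactome.members)),
            "min_replicates": interactome.min_replicates,
        }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
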