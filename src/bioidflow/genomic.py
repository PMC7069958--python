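"""Pairwise TF co-binding analysis on genomic intervals.

Peaks from two factors are resized to fixed windows (default 1 kb) centred on
their midpoints; a co-bound locus is a connected component of overlapping
resized intervals that contains at least one peak from each factor.  Loci are
assigned to genes through promoter windows (default 2 kb upstream of the TSS,
strand-aware), gene bodies, or a nearest-TSS fallback, and classified as
promoter / gene body / intergenic with promoter taking precedence.

Coordinates are BED-style internally: 0-based, half-open.  GFF3 input/output
(1-based, closed) is converted on the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError, DataError

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score"]
FEATURE_CLASSES = ("promoter", "gene_body", "intergenic")


@dataclass
class PeakSet:
    """A set of genomic intervals (0-based, half-open), sorted per chromosome."""

    intervals: pd.DataFrame  # columns: chrom, start, end, name, score
    source: str = ""

    def __post_init__(self) -> None:
        df = self.intervals.copy()
        for col in ("name", "score"):
            if col not in df.columns:
                df[col] = "." if col == "name" else 0.0
        df = df[PEAK_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise DataError(f"degenerate interval {bad.chrom}:{bad.start}-{bad.end}")
        if (df["start"] < 0).any():
            raise DataError("negative interval start")
        self.intervals = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def chromosomes(self) -> set:
        return set(self.intervals["chrom"].unique())

    @classmethod
    def from_bed(cls, path: str | Path, source: str = "") -> "PeakSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=PEAK_COLUMNS[: 5], usecols=range(5),
        )
        return cls(df, source=source or Path(path).stem)

    def to_bed(self, path: str | Path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GeneModels:
    """Gene annotations with strand-aware TSS (0-based coordinates).

    ``genes`` columns: gene_id, chrom, strand, start, end, tss.  The TSS is
    the first transcribed base: ``start`` on the + strand, ``end - 1`` on -.
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.genes.copy().reset_index(drop=True)
        if "tss" not in df.columns:
            df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        plus = df["strand"] == "+"
        if not ((df.loc[plus, "tss"] == df.loc[plus, "start"]).all()
                and (df.loc[~plus, "tss"] == df.loc[~plus, "end"] - 1).all()):
            raise DataError("TSS inconsistent with strand")
        self.genes = df

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneModels":
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        rows = []
        for gene in db.features_of_type("gene"):
            rows.append(
                {
                    "gene_id": gene.attributes.get("ID", [gene.id])[0],
                    "chrom": gene.seqid,
                    "strand": gene.strand,
                    "start": gene.start - 1,  # GFF3 is 1-based closed
                    "end": gene.end,
                }
            )
        return cls(pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"]))

    def to_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for g in self.genes.itertuples():
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            lines.append(
                f"{g.chrom}\tbioidflow\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

def _promoter_interval(tss: int, strand: str, upstream: int) -> tuple[int, int]:
    if strand == "+":
        return max(0, tss - upstream), tss
    return tss + 1, tss + 1 + upstream


@dataclass
class CobindingResult:
    """Connected components of overlapping resized peaks from two factors.

    ``loci`` holds every component with its contributor counts; co-bound loci
    are the components with at least one contributor from each side.
    """

    loci: pd.DataFrame  # chrom, start, end, n_a, n_b, a_names, b_names
    a_label: str = "A"
    b_label: str = "B"
    window: int = 1000

    @property
    def cobound(self) -> pd.DataFrame:
        return self.loci[(self.loci["n_a"] > 0) & (self.loci["n_b"] > 0)].reset_index(drop=True)

    @property
    def n_cobound(self) -> int:
        return int(len(self.cobound))

    @property
    def n_a_only(self) -> int:
        return int(((self.loci["n_a"] > 0) & (self.loci["n_b"] == 0)).sum())

    @property
    def n_b_only(self) -> int:
        return int(((self.loci["n_a"] == 0) & (self.loci["n_b"] > 0)).sum())

    def summary(self) -> dict:
        return {
            "n_cobound": self.n_cobound,
            f"n_{self.a_label}_only": self.n_a_only,
            f"n_{self.b_label}_only": self.n_b_only,
        }

    def cobound_bed(self, path: str | Path, gene_map: Mapping[int, Sequence] | None = None) -> None:
        """Export co-bound loci as BED; name = assigned genes, score = contributor count."""
        df = self.cobound
        names = (
            [",".join(sorted(map(str, gene_map.get(i, [])))) or "." for i in df.index]
            if gene_map is not None
            else ["." for _ in df.index]
        )
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": names,
                "score": df["n_a"] + df["n_b"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def resize_to_window(peaks: PeakSet, window: int = 1000) -> PeakSet:
    """Replace each interval by the ``window``-wide interval centred on its midpoint.

    mid = floor((start + end) / 2); the result is [mid - w/2, mid + w/2),
    clipped at 0 on the left.
    """
    if window < 2 or window % 2:
        raise ConfigError("window must be an even integer >= 2")
    df = peaks.intervals.copy()
    mid = (df["start"] + df["end"]) // 2
    df["start"] = np.maximum(0, mid - window // 2)
    df["end"] = mid + window // 2
    return PeakSet(df, source=peaks.source)


def _components(intervals: list[tuple[str, int, int, str, str]]):
    """Sweep-line merge of half-open intervals into connected components.

    ``intervals``: (chrom, start, end, side, name).  Touching intervals
    (end == start) do not overlap.  Yields dict rows.
    """
    by_chrom: dict = {}
    for chrom, start, end, side, name in intervals:
        by_chrom.setdefault(chrom, []).append((start, end, side, name))
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom])
        cur = None
        for start, end, side, name in items:
            if cur is not None and start < cur["end"]:
                cur["end"] = max(cur["end"], end)
                cur[side].append(name)
            else:
                if cur is not None:
                    yield cur
                cur = {"chrom": chrom, "start": start, "end": end, "a": [], "b": []}
                cur[side].append(name)
        if cur is not None:
            yield cur


def cobind(a: PeakSet, b: PeakSet, window: int = 1000) -> CobindingResult:
    """Co-binding between two peak sets after resizing both to ``window``.

    A co-bound locus is a connected component of overlapping resized A and B
    intervals containing at least one peak from each set; components with
    contributors from a single set are counted as A-only / B-only.
    """
    if not (a.chromosomes & b.chromosomes) and len(a) and len(b):
        warnings.warn(
            f"peak sets {a.source!r} and {b.source!r} share no chromosome names; "
            "empty co-binding result",
            stacklevel=2,
        )
        return CobindingResult(
            pd.DataFrame(columns=["chrom", "start", "end", "n_a", "n_b", "a_names", "b_names"]),
            a_label=a.source or "A",
            b_label=b.source or "B",
            window=window,
        )
    ra, rb = resize_to_window(a, window), resize_to_window(b, window)
    pool = [
        (t.chrom, t.start, t.end, "a", t.name) for t in ra.intervals.itertuples()
    ] + [
        (t.chrom, t.start, t.end, "b", t.name) for t in rb.intervals.itertuples()
    ]
    rows = []
    for comp in _components(pool):
        rows.append(
            {
                "chrom": comp["chrom"],
                "start": comp["start"],
                "end": comp["end"],
                "n_a": len(comp["a"]),
                "n_b": len(comp["b"]),
                "a_names": ",".join(map(str, comp["a"])),
                "b_names": ",".join(map(str, comp["b"])),
            }
        )
    loci = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_a", "n_b", "a_names", "b_names"])
    return CobindingResult(loci, a_label=a.source or "A", b_label=b.source or "B", window=window)


def signature_exclusivity(
    ab1: CobindingResult, ab2: CobindingResult
) -> tuple[int, int, int]:
    """Overlap between two co-binding signatures.

    Co-bound loci of both results are merged into connected components by
    >=1 bp overlap; ``n_shared`` is the number of components containing loci
    from both signatures (a symmetric count of shared regions).  Exclusivity
    per side is 1 - shared_loci/total_loci, as a percentage rounded to the
    nearest integer; an empty signature is reported 100% exclusive.
    """
    loci1, loci2 = ab1.cobound, ab2.cobound
    pool = [
        (t.chrom, t.start, t.end, "a", i) for i, t in enumerate(loci1.itertuples())
    ] + [
        (t.chrom, t.start, t.end, "b", i) for i, t in enumerate(loci2.itertuples())
    ]
    n_shared = 0
    shared1: set = set()
    shared2: set = set()
    for comp in _components(pool):
        if comp["a"] and comp["b"]:
            n_shared += 1
            shared1.update(comp["a"])
            shared2.update(comp["b"])
    pct1 = round(100 * (1 - len(shared1) / len(loci1))) if len(loci1) else 100
    pct2 = round(100 * (1 - len(shared2) / len(loci2))) if len(loci2) else 100
    return n_shared, pct1, pct2


def _gene_trees(genes: GeneModels, promoter_upstream: int):
    promoters: dict = {}
    bodies: dict = {}
    for g in genes.genes.itertuples():
        ps, pe = _promoter_interval(int(g.tss), g.strand, promoter_upstream)
        if pe > ps:
            promoters.setdefault(g.chrom, IntervalTree()).addi(ps, pe, g.gene_id)
        bodies.setdefault(g.chrom, IntervalTree()).addi(int(g.start), int(g.end), g.gene_id)
    return promoters, bodies


def classify_feature(
    region: tuple[str, int, int],
    genes: GeneModels,
    promoter_upstream: int = 2000,
) -> str:
    """Label a region promoter / gene_body / intergenic, promoter taking precedence.

    The promoter window is strand-aware: [TSS - u, TSS) on +, (TSS, TSS + u]
    on - (half-open in 0-based coordinates).
    """
    chrom, start, end = region
    promoters, bodies = _gene_trees(genes, promoter_upstream)
    if chrom in promoters and promoters[chrom].overlap(start, end):
        return "promoter"
    if chrom in bodies and bodies[chrom].overlap(start, end):
        return "gene_body"
    return "intergenic"


def classify_features(
    regions: Iterable[tuple[str, int, int]],
    genes: GeneModels,
    promoter_upstream: int = 2000,
) -> list[str]:
    """Vectorised :func:`classify_feature` (trees built once)."""
    promoters, bodies = _gene_trees(genes, promoter_upstream)
    labels = []
    for chrom, start, end in regions:
        if chrom in promoters and promoters[chrom].overlap(start, end):
            labels.append("promoter")
        elif chrom in bodies and bodies[chrom].overlap(start, end):
            labels.append("gene_body")
        else:
            labels.append("intergenic")
    return labels


def assign_genes(
    regions: Iterable[tuple[str, int, int]],
    genes: GeneModels,
    promoter_upstream: int = 2000,
    max_distance: int = 5000,
) -> list[frozenset]:
    """Genes in the vicinity of each region.

    A gene is assigned when its promoter window or gene body overlaps the
    region; if none does, the gene(s) with the nearest TSS within
    ``max_distance`` bp are assigned, keeping ties.  A region may map to
    several genes; a region may map to none.
    """
    promoters, bodies = _gene_trees(genes, promoter_upstream)
    tss_by_chrom: dict = {}
    for g in genes.genes.itertuples():
        tss_by_chrom.setdefault(g.chrom, []).append((int(g.tss), g.gene_id))
    out = []
    for chrom, start, end in regions:
        hits = set()
        if chrom in promoters:
            hits |= {iv.data for iv in promoters[chrom].overlap(start, end)}
        if chrom in bodies:
            hits |= {iv.data for iv in bodies[chrom].overlap(start, end)}
        if not hits and chrom in tss_by_chrom:
            best, best_d = [], None
            for tss, gene_id in tss_by_chrom[chrom]:
                if start <= tss < end:
                    d = 0
                elif tss < start:
                    d = start - tss
                else:
                    d = tss - (end - 1)
                if d <= max_distance and (best_d is None or d <= best_d):
                    if best_d is None or d < best_d:
                        best, best_d = [gene_id], d
                    else:
                        best.append(gene_id)
            hits = set(best)
        out.append(frozenset(hits))
    return out


@dataclass
class ExpressionOverlay:
    n_expressed: int
    n_inactive: int

    @property
    def fraction_expressed(self) -> float:
        return self.n_expressed / (self.n_expressed + self.n_inactive)


def expression_overlay(gene_ids: Iterable, expressed_set: Iterable) -> ExpressionOverlay:
    """Count expressed vs inactive genes among an assigned gene list.

    Genes absent from the expression universe are counted as inactive.
    """
    gene_ids = set(gene_ids)
    if not gene_ids:
        raise DataError("empty gene list; nothing to overlay with expression data")
    expressed_set = set(expressed_set)
    n_expressed = len(gene_ids & expressed_set)
    return ExpressionOverlay(n_expressed=n_expressed, n_inactive=len(gene_ids) - n_expressed)


def read_gene_list(path: str | Path) -> frozenset:
    """Newline-delimited gene ids (blank lines and '#' comments ignored)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return frozenset(out)
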