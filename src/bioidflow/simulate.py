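"""Synthetic proximity-proteomics experiments and genomic fixtures with known truth.

The LFQ generator emulates the design of a three-bait proximity-labelling
experiment: a wild-type bait (``WT``), a DNA-binding-deficient bait
(``N51A``) and a GFP control, each in four biological replicates.  Planted
interactors come in three compartment classes that map onto the bait
contrasts — chromatin partners are enriched with the WT bait only, nuclear
partners with both baits, nucleoplasm partners with the mutant bait only.
Baseline intensities are log10-normal, enrichment is additive on the log2
scale with per-sample Gaussian noise, and detection follows a logistic
dropout model in log10 intensity so that missingness concentrates at low
abundance (deliberately exercising the infinite-ratio imputation path).
Decoy and contaminant rows carry ordinary intensities but are flagged, so
they test the canonical filter rather than the statistic.

The genome generator plants a controlled fraction of co-bound peak pairs for
two factors on a toy chromosome.  Peaks are laid out on well-separated slots
so that the only co-binding events (after 1-kb midpoint resizing) are the
planted ones, making the recovered co-binding count an exact read-out.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .genomic import GeneModels, PeakSet
from .interactome import CompartmentAssignment
from .protein_groups import LfqMatrix, Sample, SampleDesign, write_protein_groups

LOG2_10 = np.log2(10.0)
TRUTH_CLASSES = ("chromatin", "nucleus", "nucleoplasm", "background", "decoy", "contaminant")


@dataclass
class LfqSimConfig:
    """Study conditions for one simulated BioID experiment.

    Baseline log10 intensities ~ Normal(6.5, 0.6), roughly the span of
    label-free intensities for a few thousand protein groups.  Detection
    probability is logistic in the realised log10 intensity with midpoint 5.1
    and slope 10 per decade — a 10-90% transition of ~0.44 decades around the
    detection limit, giving overall missingness around 5%, concentrated at
    low abundance.  ``noise_sd`` is the standard deviation of the
    per-replicate log2 case/control ratio noise (default effect_size / 4);
    each sample receives independent Gaussian noise of ``noise_sd / sqrt(2)``
    on its log2 intensity so ratios have exactly that spread.
    """

    n_proteins: int = 2000
    n_replicates: int = 4
    conditions: tuple = ("WT", "N51A", "GFP")
    control_condition: str = "GFP"
    tissue: str = "mesoderm"
    n_chromatin: int = 50
    n_nucleus: int = 50
    n_nucleoplasm: int = 50
    effect_size: float = 3.0  # mean log2 enrichment of planted interactors
    noise_sd: float | None = None  # per-replicate log2-ratio noise; default effect_size / 4
    intensity_log_mean: float = 6.5
    intensity_log_sd: float = 0.6
    dropout_midpoint: float = 5.1  # log10 intensity of 50% detection
    dropout_slope: float = 10.0  # logistic slope per log10 unit
    n_decoys: int = 25
    n_contaminants: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0 or self.n_replicates < 1:
            raise ConfigError("n_proteins must be positive and n_replicates >= 1")
        planted = self.n_chromatin + self.n_nucleus + self.n_nucleoplasm
        if min(self.n_chromatin, self.n_nucleus, self.n_nucleoplasm) < 0:
            raise ConfigError("planted class counts must be non-negative")
        if planted > self.n_proteins:
            raise ConfigError(
                f"{planted} planted interactors exceed n_proteins={self.n_proteins}"
            )
        if self.effect_size <= 0:
            raise ConfigError("effect_size must be > 0")
        if self.n_decoys < 0 or self.n_contaminants < 0:
            raise ConfigError("flagged row counts must be non-negative")
        if self.control_condition not in self.conditions:
            raise ConfigError("control_condition must be one of conditions")

    @property
    def effective_noise_sd(self) -> float:
        return self.effect_size / 4.0 if self.noise_sd is None else self.noise_sd

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["conditions"] = list(self.conditions)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LfqSimConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["conditions"] = tuple(data["conditions"])
        return cls(**data)


@dataclass
class SimTruth:
    """True class label per simulated row; every row has exactly one label."""

    labels: pd.Series  # index protein_id, values in TRUTH_CLASSES

    def members(self, *classes: str) -> frozenset:
        return frozenset(self.labels.index[self.labels.isin(classes)])

    def label_of(self, protein_id: str) -> str:
        return str(self.labels.at[protein_id])

    def to_tsv(self, path: str | Path) -> None:
        df = self.labels.rename("true_class").to_frame()
        df.index.name = "protein_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        return cls(df["true_class"])


def _wt_enriched(label: str) -> bool:
    return label in ("chromatin", "nucleus")


def _n51a_enriched(label: str) -> bool:
    return label in ("nucleus", "nucleoplasm")


def generate_lfq_experiment(config: LfqSimConfig) -> tuple[LfqMatrix, SimTruth]:
    """Simulate one protein-group matrix plus its ground-truth labels.

    Deterministic under ``config.seed`` (bit-identical output for equal
    configs).  Dropout is applied after enrichment, per sample, so planted
    interactors frequently go missing in the control and produce infinite
    ratios downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_main = config.n_proteins
    n_rows = n_main + config.n_decoys + config.n_contaminants
    ids = (
        [f"P{i:05d}" for i in range(n_main)]
        + [f"REV_P{i:05d}" for i in range(config.n_decoys)]
        + [f"CON_P{i:05d}" for i in range(config.n_contaminants)]
    )

    labels = np.array(["background"] * n_rows, dtype=object)
    planted = rng.permutation(n_main)[
        : config.n_chromatin + config.n_nucleus + config.n_nucleoplasm
    ]
    labels[planted[: config.n_chromatin]] = "chromatin"
    labels[planted[config.n_chromatin : config.n_chromatin + config.n_nucleus]] = "nucleus"
    labels[planted[config.n_chromatin + config.n_nucleus :]] = "nucleoplasm"
    labels[n_main : n_main + config.n_decoys] = "decoy"
    labels[n_main + config.n_decoys :] = "contaminant"

    samples = [
        Sample(f"{config.tissue}_{cond}_r{rep}", cond, config.tissue, rep)
        for cond in config.conditions
        for rep in range(1, config.n_replicates + 1)
    ]
    design = SampleDesign(samples, control_condition=config.control_condition)

    base_log10 = rng.normal(config.intensity_log_mean, config.intensity_log_sd, size=n_rows)
    per_sample_sd = config.effective_noise_sd / np.sqrt(2.0)  # ratio of two samples has sd noise_sd
    noise = rng.normal(0.0, per_sample_sd, size=(n_rows, len(samples)))
    detect_u = rng.random(size=(n_rows, len(samples)))

    wt_mask = np.array([_wt_enriched(l) for l in labels])
    n51a_mask = np.array([_n51a_enriched(l) for l in labels])

    intens = np.zeros((n_rows, len(samples)))
    for j, sample in enumerate(samples):
        effect = np.zeros(n_rows)
        if sample.condition == "WT":
            effect[wt_mask] = config.effect_size
        elif sample.condition == "N51A":
            effect[n51a_mask] = config.effect_size
        log2_int = base_log10 * LOG2_10 + effect + noise[:, j]
        log10_int = log2_int / LOG2_10
        p_detect = 1.0 / (1.0 + np.exp(-config.dropout_slope * (log10_int - config.dropout_midpoint)))
        detected = detect_u[:, j] < p_detect
        intens[:, j] = np.where(detected, np.exp2(log2_int), 0.0)

    index = pd.Index(ids, name="protein_id")
    intensities = pd.DataFrame(intens, index=index, columns=[s.sample_id for s in samples])
    annotations = pd.DataFrame(index=index)
    annotations["gene_name"] = [f"gene{i:05d}" for i in range(n_rows)]
    annotations["reverse"] = [l == "decoy" for l in labels]
    annotations["contaminant"] = [l == "contaminant" for l in labels]
    annotations["only_by_site"] = False
    matrix = LfqMatrix(intensities, annotations, design)
    truth = SimTruth(pd.Series(labels, index=index))
    return matrix, truth


def write_lfq_experiment(
    out_dir: str | Path, matrix: LfqMatrix, truth: SimTruth, config: LfqSimConfig | None = None
) -> None:
    """Write the protein-group TSV, truth table, design YAML and config YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_protein_groups(matrix, out_dir / "protein_groups.tsv")
    truth.to_tsv(out_dir / "truth.tsv")
    matrix.design.to_yaml(out_dir / "design.yaml")
    if config is not None:
        config.to_yaml(out_dir / "sim_config.yaml")


# ---------------------------------------------------------------------------
# evaluation against ground truth


def call_metrics(
    called: Iterable, truth: SimTruth, positive_classes: Sequence[str]
) -> dict:
    """Precision/recall of a call set against planted truth labels."""
    called = set(called)
    positives = truth.members(*positive_classes)
    tp = len(called & positives)
    fp = len(called - positives)
    fn = len(positives - called)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
    }


def compartment_accuracy(assignment: CompartmentAssignment, truth: SimTruth) -> dict:
    """Fraction of planted interactors assigned their true compartment.

    Planted interactors missing from both interactomes have no label and
    count as misclassified.
    """
    assigned = assignment.label_of()
    planted = truth.members("chromatin", "nucleus", "nucleoplasm")
    correct = sum(1 for pid in planted if assigned.get(pid) == truth.label_of(pid))
    return {"n": len(planted), "accuracy": correct / len(planted) if planted else float("nan")}


# ---------------------------------------------------------------------------
# genomic fixture


@dataclass
class GenomeSimConfig:
    """Toy single-chromosome genome with planted TF co-binding.

    ``planted_cobind_fraction`` of the A peaks receive an intentionally
    placed B peak whose ``window``-resized interval overlaps theirs; all
    other peaks sit on their own slots, at least 2 kb away from anything
    else, so chance co-binding is excluded by construction.
    """

    genome_length: int = 2_000_000
    chrom: str = "chrSim"
    n_genes: int = 250
    n_peaks_a: int = 200
    n_peaks_b: int = 200
    peak_width: int = 200
    window: int = 1000  # resize window used downstream
    planted_cobind_fraction: float = 0.3
    fraction_expressed: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.planted_cobind_fraction <= 1.0:
            raise ConfigError("planted_cobind_fraction must be in [0, 1]")
        if min(self.n_genes, self.n_peaks_a, self.n_peaks_b, self.peak_width) <= 0:
            raise ConfigError("feature counts and peak_width must be positive")
        if self.window < 2 or self.window % 2:
            raise ConfigError("window must be an even integer >= 2")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenomeSimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def generate_genome_fixture(
    config: GenomeSimConfig,
) -> tuple[GeneModels, PeakSet, PeakSet, frozenset]:
    """Gene models, two peak sets and an expressed-gene set with planted co-binding.

    Exactly round(planted_cobind_fraction * n_peaks_a) A peaks are paired
    with a B peak at a midpoint offset below ``window`` bp, so their resized
    intervals overlap; every unpaired peak occupies its own 3x-window slot,
    which keeps unplanted peaks more than 2 kb apart.  Genes are
    non-overlapping, strand-assigned, and independent of peak placement.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w = config.window
    slot_len = 3 * w
    n_slots = config.genome_length // slot_len
    n_planted = round(config.planted_cobind_fraction * config.n_peaks_a)
    n_lone_a = config.n_peaks_a - n_planted
    n_lone_b = config.n_peaks_b - n_planted
    if n_lone_b < 0:
        raise ConfigError("planted pairs exceed n_peaks_b")
    needed = n_planted + n_lone_a + n_lone_b
    if needed > n_slots:
        raise ConfigError(
            f"genome of {config.genome_length} bp has {n_slots} peak slots, "
            f"{needed} needed; enlarge the genome or reduce peak counts"
        )
    slots = rng.permutation(n_slots)[:needed] * slot_len

    half_peak = config.peak_width // 2
    jitter = w // 5

    def clamp(mid: np.ndarray) -> np.ndarray:
        return np.clip(mid, half_peak, config.genome_length - half_peak)

    planted_slots = slots[:n_planted]
    a_mids = clamp(planted_slots + w + rng.integers(-jitter, jitter + 1, size=n_planted))
    b_mids = clamp(a_mids + rng.integers(-(w - 200), w - 200 + 1, size=n_planted))
    lone_a_mids = clamp(
        slots[n_planted : n_planted + n_lone_a]
        + 3 * w // 2
        + rng.integers(-jitter, jitter + 1, size=n_lone_a)
    )
    lone_b_mids = clamp(
        slots[n_planted + n_lone_a :]
        + 3 * w // 2
        + rng.integers(-jitter, jitter + 1, size=n_lone_b)
    )

    def make_peaks(mids: np.ndarray, prefix: str, source: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": config.chrom,
                "start": mids - half_peak,
                "end": mids + half_peak,
                "name": [f"{prefix}_{i:04d}" for i in range(len(mids))],
                "score": np.round(rng.uniform(50, 1000, size=len(mids)), 2),
            }
        )

    peaks_a = PeakSet(
        pd.concat(
            [make_peaks(a_mids, "A_pair", "A"), make_peaks(lone_a_mids, "A_lone", "A")],
            ignore_index=True,
        ),
        source="A",
    )
    peaks_b = PeakSet(
        pd.concat(
            [make_peaks(b_mids, "B_pair", "B"), make_peaks(lone_b_mids, "B_lone", "B")],
            ignore_index=True,
        ),
        source="B",
    )

    # genes: one per equal-sized bin, non-overlapping by construction
    bin_len = config.genome_length // config.n_genes
    if bin_len < 1500:
        raise ConfigError("genome too small for the requested gene count")
    max_len = min(bin_len - 500, 8000)
    lengths = rng.integers(800, max_len + 1, size=config.n_genes)
    offsets = rng.integers(0, bin_len - lengths + 1)
    starts = np.arange(config.n_genes) * bin_len + offsets
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = GeneModels(
        pd.DataFrame(
            {
                "gene_id": [f"G{i:04d}" for i in range(config.n_genes)],
                "chrom": config.chrom,
                "strand": strands,
                "start": starts,
                "end": starts + lengths,
            }
        )
    )

    n_expressed = round(config.fraction_expressed * config.n_genes)
    expressed = frozenset(
        rng.choice(genes.genes["gene_id"].to_numpy(), size=n_expressed, replace=False)
    )
    return genes, peaks_a, peaks_b, expressed


def write_genome_fixture(
    out_dir: str | Path,
    genes: GeneModels,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    expressed: frozenset,
    config: GenomeSimConfig | None = None,
) -> None:
    """Write BED peak files, GFF3 gene models, expressed-gene list and config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    peaks_a.to_bed(out_dir / "peaks_a.bed")
    peaks_b.to_bed(out_dir / "peaks_b.bed")
    genes.to_gff3(out_dir / "genes.gff3")
    (out_dir / "expressed_genes.txt").write_text("\n".join(sorted(expressed)) + "\n")
    if config is not None:
        config.to_yaml(out_dir / "genome_config.yaml")
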