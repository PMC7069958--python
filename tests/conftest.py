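import numpy as np
import pandas as pd
import pytest

import bioidflow as bf


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated BioID experiment with planted interactors."""
    cfg = bf.LfqSimConfig(
        n_proteins=400,
        n_chromatin=15,
        n_nucleus=15,
        n_nucleoplasm=15,
        n_decoys=8,
        n_contaminants=4,
        seed=7,
    )
    matrix, truth = bf.generate_lfq_experiment(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def filtered_matrix(small_experiment):
    _, matrix, _ = small_experiment
    return bf.filter_canonical(matrix)


def make_matrix(intensities_by_sample, design, protein_ids=None, flags=None):
    """Hand-build an LfqMatrix from a sample_id -> list-of-intensities dict."""
    intens = pd.DataFrame(intensities_by_sample, dtype=float)
    n = len(intens)
    ids = protein_ids or [f"prot{i}" for i in range(n)]
    intens.index = pd.Index(ids, name="protein_id")
    ann = pd.DataFrame(index=intens.index)
    ann["gene_name"] = ids
    for name in ("reverse", "contaminant", "only_by_site"):
        ann[name] = (flags or {}).get(name, [False] * n)
    return bf.LfqMatrix(intens, ann, design)


@pytest.fixture
def two_rep_design():
    """One tissue, WT/N51A/GFP, two replicates."""
    samples = [
        bf.Sample(f"meso_{cond}_r{rep}", cond, "meso", rep)
        for cond in ("WT", "N51A", "GFP")
        for rep in (1, 2)
    ]
    return bf.SampleDesign(samples, control_condition="GFP")


def random_intervals(rng, n, n_chroms=2, span=60_000, max_width=2_000):
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(50, max_width))
        out.append((chroms[int(rng.integers(n_chroms))], start, start + width))
    return out


def peakset_from_tuples(intervals, source="x"):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    df["name"] = [f"{source}{i}" for i in range(len(df))]
    df["score"] = 0.0
    return bf.PeakSet(df, source=source)
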