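import numpy as np
import pandas as pd
import pytest

from embryotime import (
    CountMatrix,
    NormalizedMatrix,
    SimConfig,
    filter_embryos,
    filter_genes,
    simulate_cohort,
)
from embryotime.pipeline import refined_trajectory
from embryotime.simulate import marker_gene_ids

DESK_MIN_TOTAL = 5_000  # depth threshold matching the desk-scale simulated libraries


def make_normalized(values, genes=None, embryos=None) -> NormalizedMatrix:
    """Wrap a raw (possibly non-integer) value array as a NormalizedMatrix
    by median-of-totals scaling, mirroring `normalize`."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    embryos = embryos or [f"e{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=embryos)
    totals = df.sum(axis=0)
    target = float(np.median(totals.to_numpy()))
    size_factors = totals / target
    return NormalizedMatrix(
        values=df / size_factors, size_factors=size_factors, target_total=target
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """One default simulated cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_run(sim_cohort):
    """QC'd fertilized-subset trajectory of the shared cohort."""
    counts, annotation, truth = sim_cohort
    m, _ = filter_embryos(counts, DESK_MIN_TOTAL)
    m, _ = filter_genes(m)
    early = marker_gene_ids(annotation, "zygotic_minor")
    fertilized = [e for e in m.embryo_ids if truth.loc[e, "fertilized"]]
    nm, clustering, tree, order, k = refined_trajectory(
        CountMatrix(m.values[fertilized]), early, k=9, seed=7
    )
    return {
        "counts": m,
        "annotation": annotation,
        "truth": truth,
        "early_markers": early,
        "nm": nm,
        "clustering": clustering,
        "tree": tree,
        "order": order,
        "k": k,
    }
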