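"""Transcriptome-based sexing, sex-differential time-course DE, and
dosage-compensation quantification.

Sex is called from a female determinant (Sxl-like) and a male marker
(msl-2-like): embryos past marker onset separate cleanly by the log
ratio of the two, while embryos before onset stay undetermined.
Sex-differential expression along the trajectory uses a spline
time-course F-test: per gene, a full model with sex main effect and
sex x spline(time) interactions is compared with a reduced model
carrying the time spline only.  Dosage compensation is assessed as the
female:male ratio of summed zygotic (non-maternal) expression, X-linked
versus autosomal, per cluster along the path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy.stats import f as f_dist

from .cluster import Clustering
from .diffexp import bh_adjust
from .matrix import NormalizedMatrix

__all__ = [
    "SexCall",
    "SplineDEResult",
    "call_sex",
    "spline_de",
    "dosage_report",
    "smooth_series",
]


@dataclass(frozen=True)
class SexCall:
    """Per-embryo sex calls with the marker evidence behind them."""

    table: pd.DataFrame  # embryo_id, call, female_marker_count, male_marker_count, log_ratio

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def sexed_embryos(self) -> list[str]:
        return list(self.table.index[self.table["call"] != "undetermined"])


@dataclass(frozen=True)
class SplineDEResult:
    """Per-gene spline time-course F-test results."""

    table: pd.DataFrame  # gene_id, F_statistic, p_value, padj, significant
    df_num: int
    df_denom: int
    padj_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def call_sex(
    nm: NormalizedMatrix,
    female_marker: str,
    male_marker: str,
    floor: float = 1.0,
    pseudocount: float = 0.1,
) -> SexCall:
    """Call embryo sex from the two marker genes.

    Undetermined when both markers sit below the detection floor
    (markers not yet transcribed); otherwise female when
    log2((f + pc)/(m + pc)) > 0, male when <= 0.
    """
    for marker in (female_marker, male_marker):
        if marker not in nm.gene_ids:
            raise ValueError(f"marker gene {marker!r} absent from the matrix")
    f_counts = nm.values.loc[female_marker]
    m_counts = nm.values.loc[male_marker]
    log_ratio = np.log2((f_counts + pseudocount) / (m_counts + pseudocount))
    call = np.where(
        (f_counts < floor) & (m_counts < floor),
        "undetermined",
        np.where(log_ratio > 0, "female", "male"),
    )
    table = pd.DataFrame(
        {
            "embryo_id": nm.embryo_ids,
            "call": call,
            "female_marker_count": f_counts.to_numpy(),
            "male_marker_count": m_counts.to_numpy(),
            "log_ratio": log_ratio.to_numpy(),
        }
    ).set_index("embryo_id", drop=False)
    return SexCall(table=table)


def _spline_design(time: np.ndarray, sex_female: np.ndarray, df: int):
    """Full and reduced design matrices for the time-course F-test."""
    basis = np.asarray(
        dmatrix("cr(t, df=df) - 1", {"t": time, "df": df}, return_type="matrix")
    )
    n = len(time)
    intercept = np.ones((n, 1))
    sex_col = sex_female.reshape(-1, 1).astype(float)
    reduced = np.hstack([intercept, basis])
    full = np.hstack([intercept, sex_col, basis, basis * sex_col])
    return full, reduced


def spline_de(
    nm: NormalizedMatrix,
    time: pd.Series,
    sex: pd.Series,
    df: int = 3,
    padj_threshold: float = 0.01,
) -> SplineDEResult:
    """Sex-differential spline time-course test over all genes.

    ``time`` gives each embryo's timepoint index (its cluster position
    along the trajectory, every embryo a replicate of its timepoint) and
    ``sex`` its label in {female, male, F, M}; embryos with any other
    label (e.g. undetermined) are excluded before fitting.  Expression
    enters as log2(normalized + 1).  The F statistic compares the full
    model (intercept + sex + spline + sex x spline) against the
    time-spline-only model; BH over genes.
    """
    labels = sex.astype(str).str.lower().str[0]
    usable = labels.isin(["f", "m"])
    embryos = [e for e in nm.embryo_ids if e in labels.index and usable.get(e, False)]
    if len(set(time[embryos])) < 2:
        raise ValueError("need at least 2 distinct timepoints")
    for s in ("f", "m"):
        tp = set(time[e] for e in embryos if labels[e] == s)
        if len(tp) < 2:
            raise ValueError(f"sex {s!r} present at fewer than 2 timepoints")

    t = time[embryos].to_numpy(dtype=float)
    is_female = (labels[embryos] == "f").to_numpy()
    full, reduced = _spline_design(t, is_female, df)
    # the natural-spline basis spans the constant, so the full design is
    # structurally rank-deficient by 2; compare actual ranks instead
    rank_full = np.linalg.matrix_rank(full)
    rank_red = np.linalg.matrix_rank(reduced)
    d1 = rank_full - rank_red
    if d1 <= 0:
        raise ValueError(
            "rank-deficient design: no sex-associated term is estimable "
            "(sex and sex x spline columns are collinear with the time spline)"
        )
    d2 = len(embryos) - rank_full
    if d2 <= 0:
        raise ValueError("not enough embryos for the residual degrees of freedom")

    Y = np.log2(nm.values[embryos].to_numpy(dtype=float) + 1.0).T  # embryos x genes
    rss_full = _rss(full, Y)
    rss_red = _rss(reduced, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / d1) / (rss_full / d2)
    F = np.where(rss_full <= 1e-12, 0.0, F)  # perfectly fitted genes: no evidence
    F = np.clip(F, 0.0, None)
    pvals = f_dist.sf(F, d1, d2)
    pvals = np.where(F == 0.0, 1.0, pvals)
    padj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "gene_id": nm.gene_ids,
            "F_statistic": F,
            "p_value": pvals,
            "padj": padj,
            "significant": padj < padj_threshold,
        }
    ).set_index("gene_id", drop=False)
    return SplineDEResult(
        table=table, df_num=int(d1), df_denom=int(d2), padj_threshold=padj_threshold
    )


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid**2).sum(axis=0)


def dosage_report(
    nm: NormalizedMatrix,
    sex_calls: SexCall,
    clustering: Clustering,
    maternal: list[str],
    chromosomes: pd.Series,
    exclude=(),
) -> pd.DataFrame:
    """Per-cluster, per-sex zygotic X and autosomal expression with F:M ratios.

    The zygotic gene set is everything surviving QC minus the maternal
    set.  Per embryo, normalized counts are summed over X-linked and
    autosomal zygotic genes; means are taken within (cluster, sex) over
    embryos with determined sex, and per-cluster female/male ratios are
    reported (NaN where a sex is missing from a cluster).

    ``exclude`` removes named genes from the sums; the sexing marker
    genes belong there, since their sex bias reflects sex-determination
    regulation rather than chromosome dose.
    """
    drop = set(maternal) | set(exclude)
    zygotic = [g for g in nm.gene_ids if g not in drop]
    missing = [g for g in zygotic if g not in chromosomes.index]
    if missing:
        raise ValueError(
            f"chromosome annotation missing for {len(missing)} zygotic genes "
            f"(e.g. {missing[:3]})"
        )
    chrom = chromosomes[zygotic]
    x_genes = list(chrom.index[chrom == "X"])
    auto_genes = list(chrom.index[chrom != "X"])

    sums = pd.DataFrame(
        {
            "x_sum": nm.values.loc[x_genes].sum(axis=0),
            "autosome_sum": nm.values.loc[auto_genes].sum(axis=0),
        }
    )
    sums["cluster"] = clustering.labels
    sums["sex"] = sex_calls.calls
    sexed = sums[sums["sex"].isin(["female", "male"])]
    grouped = sexed.groupby(["cluster", "sex"])[["x_sum", "autosome_sum"]].mean()

    rows = []
    for cl in range(1, clustering.k + 1):
        rec = {"cluster": cl}
        for sex in ("female", "male"):
            if (cl, sex) in grouped.index:
                rec[f"{sex}_x"] = grouped.loc[(cl, sex), "x_sum"]
                rec[f"{sex}_autosome"] = grouped.loc[(cl, sex), "autosome_sum"]
            else:
                rec[f"{sex}_x"] = np.nan
                rec[f"{sex}_autosome"] = np.nan
        rec["x_ratio_f_over_m"] = rec["female_x"] / rec["male_x"]
        rec["autosome_ratio_f_over_m"] = rec["female_autosome"] / rec["male_autosome"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("cluster", drop=False)


def smooth_series(y, window: int = 5, poly_order: int = 2) -> np.ndarray:
    """Two-stage smoothing of a pseudo-time-ordered series.

    Stage one is a centered moving average of width ``window``; stage
    two a local least-squares polynomial of order ``poly_order`` over
    the same window.  Near the edges both stages shrink the window
    symmetrically (and the polynomial order with it) so the output keeps
    the input length.  Both stages reproduce polynomials up to degree
    min(1, poly_order) exactly at interior points, so linear trends pass
    through unchanged.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= poly_order:
        raise ValueError("window must exceed poly_order")
    if window >= n:
        raise ValueError(f"window={window} must be smaller than the series ({n})")
    half = window // 2

    averaged = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        averaged[i] = y[i - h : i + h + 1].mean()

    smoothed = np.empty(n)
    idx = np.arange(n, dtype=float)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        xs = idx[i - h : i + h + 1] - i
        ys = averaged[i - h : i + h + 1]
        order = min(poly_order, xs.size - 1)
        coeffs = np.polynomial.polynomial.polyfit(xs, ys, order)
        smoothed[i] = coeffs[0]  # value at the window center
    return smoothed
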