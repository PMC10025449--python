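"""Two-group negative-binomial exact differential expression.

The test follows the classic two-condition NB exact scheme: per-group
count sums are modelled as NB variables whose means come from the pooled
(null) per-gene expression level scaled by each group's summed size
factors, and whose variances add the overdispersion term alpha * mu^2.
The p-value sums the probabilities of all splits of the total K = kA+kB
that are at most as likely as the observed split.  Dispersion is a
per-gene moment estimate with a fitted alpha(m) = a0 + a1/m mean trend;
the larger of the two is used per gene (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson
from statsmodels.stats.multitest import multipletests

from .cluster import Clustering
from .matrix import NormalizedMatrix

__all__ = [
    "DispersionModel",
    "DEResult",
    "fit_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "compare_clusters",
    "regulatory_composition",
]

DEFAULT_PADJ = 0.01
DEFAULT_LFC = 1.0
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class DispersionModel:
    """Per-gene NB dispersion with a fitted 1/mean trend.

    ``alpha_used`` = max(moment estimate, fitted trend) per gene.
    """

    alpha_gene: pd.Series
    fit_a0: float
    fit_a1: float
    alpha_used: pd.Series
    mean: pd.Series

    def alpha_fit(self, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        with np.errstate(divide="ignore"):
            a = self.fit_a0 + self.fit_a1 / m
        return np.clip(np.where(m > 0, a, 0.0), 0.0, None)


@dataclass(frozen=True)
class DEResult:
    """Per-gene fold changes and (adjusted) p-values for one comparison."""

    table: pd.DataFrame  # gene_id, mean_A, mean_B, log2FC, p_value, padj, significant
    group_a: object
    group_b: object
    padj_threshold: float
    lfc_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def upregulated(self) -> list[str]:
        t = self.table
        return list(t.index[t["significant"] & (t["log2FC"] > 0)])

    def downregulated(self) -> list[str]:
        t = self.table
        return list(t.index[t["significant"] & (t["log2FC"] < 0)])


def fit_dispersion(nm: NormalizedMatrix, groups: dict) -> DispersionModel:
    """Estimate per-gene dispersion from within-group variability.

    ``groups`` maps group label -> list of embryo ids.  The moment
    estimator alpha_g = (s^2 - m) / m^2 uses the pooled within-group
    variance (between-group signal would otherwise inflate dispersion
    for genuinely changing genes), clamped at zero.  A least-squares
    trend alpha(m) = a0 + a1/m is fitted over genes with positive
    moment estimates; the per-gene dispersion actually used is the
    maximum of the two.
    """
    for label, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 embryos")
    x = nm.values
    m = pd.Series(0.0, index=x.index)
    ss = pd.Series(0.0, index=x.index)
    dof = 0
    n_total = 0
    for members in groups.values():
        sub = x[list(members)]
        n_g = sub.shape[1]
        m += sub.sum(axis=1)
        ss += sub.var(axis=1, ddof=1) * (n_g - 1)
        dof += n_g - 1
        n_total += n_g
    mean = m / n_total
    var_within = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_within - mean) / mean**2
    alpha = alpha.replace([np.inf, -np.inf], 0.0).fillna(0.0).clip(lower=0.0)

    fit_mask = (alpha > 0) & (mean > 0)
    if fit_mask.sum() >= 2:
        A = np.column_stack(
            [np.ones(fit_mask.sum()), 1.0 / mean[fit_mask].to_numpy()]
        )
        coef, *_ = np.linalg.lstsq(A, alpha[fit_mask].to_numpy(), rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        a0, a1 = 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mean > 0, a0 + a1 / mean, 0.0)
    trend = np.clip(trend, 0.0, None)
    alpha_used = pd.Series(np.maximum(alpha.to_numpy(), trend), index=x.index)
    return DispersionModel(
        alpha_gene=alpha, fit_a0=a0, fit_a1=a1, alpha_used=alpha_used, mean=mean
    )


def _log_pmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """NB log-pmf parameterized by mean/variance; Poisson when var <= mean."""
    if var <= mean:
        return poisson.logpmf(k, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return nbinom.logpmf(k, r, p)


def nb_exact_test(
    kA: int, kB: int, meanA: float, varA: float, meanB: float, varB: float
) -> float:
    """Exact two-group NB test on count sums kA, kB.

    Conditions on K = kA + kB and sums the probability of every split
    (a, K - a) whose joint probability does not exceed the observed
    split's, normalized over all splits.  Computed in log space.
    """
    if kA < 0 or kB < 0:
        raise ValueError("count sums must be non-negative")
    if varA < meanA or varB < meanB:
        if not np.isclose(varA, meanA) and varA < meanA:
            raise ValueError("varA must be >= meanA")
        if not np.isclose(varB, meanB) and varB < meanB:
            raise ValueError("varB must be >= meanB")
    K = int(kA + kB)
    if K == 0:
        return 1.0
    a = np.arange(K + 1)
    lp = _log_pmf(a, meanA, varA) + _log_pmf(K - a, meanB, varB)
    obs = lp[int(kA)]
    keep = lp <= obs + 1e-10
    p = float(np.exp(logsumexp(lp[keep]) - logsumexp(lp)))
    return min(p, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_clusters(
    nm: NormalizedMatrix,
    clustering: Clustering,
    a,
    b,
    padj_threshold: float = DEFAULT_PADJ,
    lfc_threshold: float = DEFAULT_LFC,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    genes=None,
) -> DEResult:
    """NB exact-test differential expression between two embryo clusters.

    Fold changes are log2((mean_B + pc) / (mean_A + pc)) on normalized
    means; positive log2FC means higher in cluster ``b``.  ``genes``
    optionally restricts the tested universe (BH correction then runs
    over that subset only).
    """
    members_a = clustering.members(a)
    members_b = clustering.members(b)
    if a == b:
        raise ValueError("cannot compare a cluster with itself")
    for label, members in ((a, members_a), (b, members_b)):
        if len(members) == 0:
            raise ValueError(f"cluster {label!r} is empty")
        if len(members) < 2:
            raise ValueError(f"cluster {label!r} has fewer than 2 embryos")

    x = nm.values
    if genes is not None:
        genes = [g for g in genes if g in x.index]
        if not genes:
            raise ValueError("no requested genes present in the matrix")
        x = x.loc[genes]
    sub = x[members_a + members_b]
    disp = fit_dispersion(
        _subset(nm, members_a + members_b, x.index), {a: members_a, b: members_b}
    )

    sf = nm.size_factors
    sA = sf[members_a].to_numpy()
    sB = sf[members_b].to_numpy()
    raw = x * sf[x.columns]  # undo normalization -> raw counts
    kA = raw[members_a].sum(axis=1).round().astype(np.int64)
    kB = raw[members_b].sum(axis=1).round().astype(np.int64)

    mean_A = x[members_a].mean(axis=1)
    mean_B = x[members_b].mean(axis=1)
    q_null = sub.mean(axis=1)  # pooled normalized mean under the null
    alpha = disp.alpha_used

    pvals = np.ones(len(x.index))
    flagged_zero = np.zeros(len(x.index), dtype=bool)
    for i, g in enumerate(x.index):
        q = q_null[g]
        if kA[g] + kB[g] == 0 or q == 0:
            flagged_zero[i] = True
            continue
        muA = q * sA.sum()
        muB = q * sB.sum()
        varA = muA + alpha[g] * (q**2) * (sA**2).sum()
        varB = muB + alpha[g] * (q**2) * (sB**2).sum()
        pvals[i] = nb_exact_test(int(kA[g]), int(kB[g]), muA, varA, muB, varB)

    padj = bh_adjust(pvals)
    log2fc = np.log2((mean_B + pseudocount) / (mean_A + pseudocount))
    significant = (padj < padj_threshold) & (np.abs(log2fc) > lfc_threshold)
    table = pd.DataFrame(
        {
            "gene_id": x.index,
            "mean_A": mean_A.to_numpy(),
            "mean_B": mean_B.to_numpy(),
            "log2FC": log2fc.to_numpy(),
            "p_value": pvals,
            "padj": padj,
            "significant": significant.to_numpy(),
            "zero_total": flagged_zero,
        }
    ).set_index("gene_id", drop=False)
    return DEResult(
        table=table,
        group_a=a,
        group_b=b,
        padj_threshold=padj_threshold,
        lfc_threshold=lfc_threshold,
    )


def _subset(nm: NormalizedMatrix, embryos, genes) -> NormalizedMatrix:
    """View of a NormalizedMatrix on given embryos/genes (skips revalidation)."""
    obj = object.__new__(NormalizedMatrix)
    object.__setattr__(obj, "values", nm.values.loc[genes, embryos])
    object.__setattr__(obj, "size_factors", nm.size_factors[embryos])
    object.__setattr__(obj, "target_total", nm.target_total)
    return obj


def regulatory_composition(de: DEResult, classes: pd.Series) -> pd.DataFrame:
    """Class shares of up- and down-regulated genes.

    ``classes`` maps gene_id -> regulatory class label (e.g.
    Zld-dependent / Zld-independent, H2A.Z+ / H2A.Z-).  Genes absent
    from the mapping count as "N/A".  Returns one row per
    (direction, class) with the within-direction fraction; fractions
    sum to 1 per direction.  Empty significant sets give an empty frame.
    """
    rows = []
    for direction, genes in (("up", de.upregulated()), ("down", de.downregulated())):
        if not genes:
            continue
        labels = [classes.get(g, "N/A") for g in genes]
        counts = pd.Series(labels).value_counts()
        for cls, n in counts.items():
            rows.append(
                {
                    "direction": direction,
                    "class": cls,
                    "n_genes": int(n),
                    "fraction": n / len(genes),
                }
            )
    return pd.DataFrame(rows, columns=["direction", "class", "n_genes", "fraction"])
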