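"""Ground-truth recovery benchmarks on synthetic cohorts.

Every analysis stage is exercised against the cohort generator's known
truth: pseudo-time ordering against true age, the fertility filter
against the fertilization flags, differential expression against
injected fold changes, the decay-quartile analysis against the
configured decay kinetics, sexing and dosage against the simulated sex
labels and X-dosage factors.  Each function runs one self-contained
study at a given seed and returns a flat dict of metrics; the
acceptance script and test-suite both consume these.

Harness sizes are chosen so that each study's sampling noise is small
against the effect it measures (larger cohorts for the dosage and
decay-quartile ratios, which compare small per-cluster group means).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import binom, nbinom, spearmanr

from .cluster import Clustering, KMedoids, kmedoids, select_k
from .decay import decay_de, maternal_set, quartile_decay
from .diffexp import bh_adjust, compare_clusters, nb_exact_test
from .matrix import CountMatrix
from .pipeline import refined_trajectory
from .qc import distance_matrix, filter_embryos, filter_genes, normalize
from .sexdiff import call_sex, dosage_report, smooth_series, spline_de
from .simulate import SimConfig, marker_gene_ids, simulate_cohort
from .trajectory import call_fertilization, lineage_tree, pseudotime

DESK_MIN_TOTAL = 5_000  # depth filter matching the desk-scale libraries

__all__ = [
    "ordering_recovery",
    "fertility_recovery",
    "de_null_calibration",
    "de_power_study",
    "nb_exact_mc_agreement",
    "nb_binomial_limit",
    "kmedoids_exhaustive_agreement",
    "mst_enumeration_agreement",
    "decay_quartile_study",
    "sexing_spline_study",
    "dosage_study",
    "spline_null_calibration",
    "smoothing_linear_fidelity",
    "bh_hand_agreement",
]


def _qc(counts):
    m, _ = filter_embryos(counts, DESK_MIN_TOTAL)
    m, _ = filter_genes(m)
    return m


def _coarse_trajectory(m, early, seed):
    """Full-cohort trajectory with silhouette-selected k (fertility stage)."""
    nm = normalize(m)
    d = distance_matrix(nm)
    k, _ = select_k(d, range(2, min(13, d.n_embryos)), seed=seed)
    clustering = kmedoids(d, k, seed)
    order = pseudotime(lineage_tree(nm, clustering), nm, early)
    return nm, clustering, order


def ordering_recovery(seed: int) -> dict:
    """Spearman agreement of pseudo-time rank with true age (fertilized
    subset of a default cohort)."""
    counts, annotation, truth = simulate_cohort(SimConfig(seed=seed))
    m = _qc(counts)
    early = marker_gene_ids(annotation, "zygotic_minor")
    fertilized = [e for e in m.embryo_ids if truth.loc[e, "fertilized"]]
    nm, clustering, order = _coarse_trajectory(CountMatrix(m.values[fertilized]), early, seed)
    rho = spearmanr(order.ranks, truth.loc[order.ranks.index, "age_min"]).statistic
    return {"spearman": float(rho), "oriented_correctly": bool(rho > 0)}


def fertility_recovery(seed: int) -> dict:
    """Sensitivity and false positives of the unfertilized-egg filter."""
    counts, annotation, truth = simulate_cohort(SimConfig(seed=seed))
    m = _qc(counts)
    early = marker_gene_ids(annotation, "zygotic_minor")
    nm, clustering, order = _coarse_trajectory(m, early, seed)
    calls = call_fertilization(nm, order, early)
    flagged = set(calls.index[calls["status"] == "unfertilized"])
    truly = set(truth.index[~truth["fertilized"]]) & set(m.embryo_ids)
    sens = len(flagged & truly) / len(truly) if truly else 1.0
    return {
        "sensitivity": sens,
        "false_positives": len(flagged - truly),
        "n_unfertilized": len(truly),
    }


def _nb_matrix(rng, mu, n_embryos, alpha):
    lam = rng.gamma(1 / alpha, alpha * np.asarray(mu)[:, None], (len(mu), n_embryos))
    return rng.poisson(lam)


def _two_group(counts):
    cm = CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"g{i}" for i in range(counts.shape[0])],
            columns=[f"e{j}" for j in range(counts.shape[1])],
        )
    )
    nm = normalize(cm)
    ids = list(nm.embryo_ids)
    half = len(ids) // 2
    labels = pd.Series([1] * half + [2] * (len(ids) - half), index=ids)
    cl = Clustering(labels=labels, medoid_ids=[ids[0], ids[half]], k=2, total_cost=0.0)
    return nm, cl


def de_null_calibration(seed: int, n_genes: int = 2000, n_per_group: int = 15) -> dict:
    """Fraction of null genes at p < 0.05 when both groups share one NB law."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(8), 1.0, n_genes)
    nm, cl = _two_group(_nb_matrix(rng, mu, 2 * n_per_group, 0.2))
    de = compare_clusters(nm, cl, 1, 2)
    return {"frac_p_lt_05": float((de.table["p_value"] < 0.05).mean())}


def de_power_study(seed: int) -> dict:
    """Detection of injected 4-fold changes (50 genes) among 500 nulls."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(8), 0.8, 550)
    counts_a = _nb_matrix(rng, mu, 15, 0.2)
    mu_b = mu.copy()
    mu_b[500:] *= 4.0
    counts_b = _nb_matrix(rng, mu_b, 15, 0.2)
    nm, cl = _two_group(np.hstack([counts_a, counts_b]))
    de = compare_clusters(nm, cl, 1, 2)
    sig = set(de.significant_genes)
    true_de = {f"g{i}" for i in range(500, 550)}
    nulls = {f"g{i}" for i in range(500)}
    return {
        "power": len(sig & true_de) / 50,
        "fpr": len(sig & nulls) / 500,
    }


def nb_exact_mc_agreement(seed: int, n_pairs: int = 400_000) -> dict:
    """Exact-test p-values vs conditional Monte-Carlo over small cases.

    For each (mean, alpha, K) the two-group null is sampled jointly and
    conditioned on the total; the reported z is |p_exact - p_mc| / SE.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for mean, alpha, K in itertools.product((5.0, 10.0), (0.05, 0.2), (10, 20, 30)):
        var = mean + alpha * mean**2
        r = mean**2 / (var - mean)
        p_nb = r / (r + mean)
        a = rng.negative_binomial(r, p_nb, n_pairs)
        b = rng.negative_binomial(r, p_nb, n_pairs)
        cond = a[(a + b) == K]
        if len(cond) < 500:
            continue
        lp = nbinom.logpmf(np.arange(K + 1), r, p_nb) + nbinom.logpmf(
            K - np.arange(K + 1), r, p_nb
        )
        for kA in {K // 4, K // 3, K // 2}:
            p_mc = float((lp[cond] <= lp[kA] + 1e-10).mean())
            p_exact = nb_exact_test(kA, K - kA, mean, var, mean, var)
            if p_exact * len(cond) < 10:
                continue  # too few expected tail hits for a normal SE
            se = np.sqrt(p_exact * (1 - p_exact) / len(cond))
            cases.append(abs(p_exact - p_mc) / max(se, 1e-12))
    return {"n_cases": len(cases), "max_z": float(np.max(cases))}


def nb_binomial_limit() -> dict:
    """Agreement with the binomial split test as alpha -> 0."""
    diffs = []
    mean = 5.0
    var = mean + 1e-6 * mean**2
    for K in (10, 20, 30, 40, 50):
        pmf = binom.pmf(np.arange(K + 1), K, 0.5)
        for kA in range(0, K + 1, max(1, K // 5)):
            p_bin = pmf[pmf <= pmf[kA] * (1 + 1e-9)].sum()
            p_nb = nb_exact_test(kA, K - kA, mean, var, mean, var)
            diffs.append(abs(p_nb - p_bin))
    return {"max_abs_diff": float(np.max(diffs)), "n_cases": len(diffs)}


def kmedoids_exhaustive_agreement(seed: int, n_instances: int = 40) -> dict:
    """PAM cost vs exhaustive medoid search on random <= 8-point instances."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(5, 9))
        k = int(rng.integers(2, 4))
        pts = rng.normal(0, 1, (n, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        est = KMedoids(n_clusters=k).fit(D)
        best = min(
            D[:, list(c)].min(axis=1).sum()
            for c in itertools.combinations(range(n), k)
        )
        agree += int(abs(est.inertia_ - best) < 1e-9)
    return {"n_instances": n_instances, "match_rate": agree / n_instances}


def _prufer_weight(D, seq):
    n = D.shape[0]
    degree = np.ones(n, dtype=int)
    for v in seq:
        degree[v] += 1
    weight = 0.0
    avail = sorted(range(n))
    for v in seq:
        leaf = min(u for u in avail if degree[u] == 1)
        weight += D[leaf, v]
        degree[leaf] -= 1
        degree[v] -= 1
        avail.remove(leaf)
    u, w = [x for x in avail if degree[x] == 1]
    return weight + D[u, w]


def mst_enumeration_agreement(seed: int) -> dict:
    """Medoid-MST weight vs enumeration over all labeled spanning trees
    (Prüfer sequences) for k in {4, 5}."""
    from scipy.sparse.csgraph import minimum_spanning_tree

    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in (4, 5):
        pts = rng.normal(0, 1, (k, 30))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        mst_w = minimum_spanning_tree(D).sum()
        best = min(
            _prufer_weight(D, seq)
            for seq in itertools.product(range(k), repeat=k - 2)
        )
        worst = max(worst, abs(mst_w - best))
    return {"max_weight_diff": float(worst)}


def decay_quartile_study(seed: int, coupled: bool = False) -> dict:
    """Quartile decay ratios on a cohort sized for near-complete DE power.

    With decay rates independent of deposit (default) the four
    last/first-cluster ratios should agree; with rates rank-coupled to
    deposit the top quartile must decay fastest (Q4 ratio < Q1 ratio).
    """
    cfg = SimConfig(seed=seed, n_embryos=400, couple_decay_to_abundance=coupled)
    counts, annotation, truth = simulate_cohort(cfg)
    m = _qc(counts)
    early = marker_gene_ids(annotation, "zygotic_minor")
    fertilized = [e for e in m.embryo_ids if truth.loc[e, "fertilized"]]
    nm, clustering, tree, order, _ = refined_trajectory(
        CountMatrix(m.values[fertilized]), early, k=6, seed=seed
    )
    maternal = maternal_set(nm, order)
    first = order.path[0]
    last = order.path[round(0.6 * (len(order.path) - 1))]
    degraded, _ = decay_de(nm, clustering, first, last, maternal)
    truly_decaying = set(
        annotation.index[annotation["program"].str.contains("decay")]
    ) & set(maternal)
    stable = set(annotation.index[annotation["program"] == "maternal_stable"]) & set(
        maternal
    )
    hit = set(degraded.index)
    report = quartile_decay(nm, clustering, list(degraded.index), first, last, maternal)
    ratios = report.ratios
    return {
        "power": len(hit & truly_decaying) / len(truly_decaying),
        "stable_fpr": len(hit & stable) / len(stable),
        "ratios": [float(v) for v in ratios],
        "spread": float(ratios.max() - ratios.min()),
        "q4_lt_q1": bool(ratios["Q4"] < ratios["Q1"]),
    }


MARKER_ONSET_BUFFER_MIN = 15.0  # transcript accumulation time after onset


def sexing_spline_study(seed: int, n_embryos: int = 120, compensation_onset: float | None = None) -> dict:
    """Sex calls vs truth and spline-DE recovery of sex-differential genes.

    The recovery target is the set of sex-differential genes expressed
    through the sexed window: X-linked minor-wave genes (onset before
    sexing becomes possible, carrying the female dosage factor
    throughout) plus the two markers.  Major-wave X genes only begin to
    express at the window's end, so their sex difference is weakly
    observable by construction; their recall is reported separately.
    """
    kw = {}
    if compensation_onset is not None:
        kw["compensation_onset_min"] = compensation_onset
    counts, annotation, truth = simulate_cohort(
        SimConfig(seed=seed, n_embryos=n_embryos, **kw)
    )
    m = _qc(counts)
    early = marker_gene_ids(annotation, "zygotic_minor")
    fertilized = [e for e in m.embryo_ids if truth.loc[e, "fertilized"]]
    nm, clustering, tree, order, _ = refined_trajectory(
        CountMatrix(m.values[fertilized]), early, k=9, seed=seed
    )
    female_marker = marker_gene_ids(annotation, "marker_female")[0]
    male_marker = marker_gene_ids(annotation, "marker_male")[0]
    sex_calls = call_sex(nm, female_marker, male_marker)
    calls = sex_calls.calls
    ages = truth.loc[calls.index, "age_min"]
    true_sex = truth.loc[calls.index, "sex"]
    # marker onsets are drawn in [85, 100] min
    past = ages > 100.0 + MARKER_ONSET_BUFFER_MIN
    pre = ages < 85.0
    accuracy = float(
        (calls[past].map({"female": "F", "male": "M"}) == true_sex[past]).mean()
    )
    pre_undetermined = float((calls[pre] == "undetermined").mean())

    position = {c: i for i, c in enumerate(order.path)}
    time = clustering.labels.map(position)
    res = spline_de(nm, time, calls, df=3)
    sig = set(res.significant_genes)

    def x_genes(program):
        return [
            g
            for g in annotation.index[
                (annotation["chromosome"] == "X") & (annotation["program"] == program)
            ]
            if g in nm.gene_ids
        ]

    sustained = x_genes("zygotic_minor") + [female_marker, male_marker]
    late_onset = x_genes("zygotic_major")
    return {
        "accuracy_past_onset": accuracy,
        "pre_onset_undetermined": pre_undetermined,
        "markers_significant": bool({female_marker, male_marker} <= sig),
        "sustained_x_recall": float(np.mean([g in sig for g in sustained])),
        "late_onset_x_recall": float(np.mean([g in sig for g in late_onset]))
        if late_onset
        else float("nan"),
        "n_significant": len(sig),
    }


def dosage_study(seed: int, compensation_onset: float) -> dict:
    """X and autosomal F:M expression ratios along the trajectory.

    ``compensation_onset`` = 180 disables the male X ramp entirely
    (pre-compensation condition); 60 completes it well before the oldest
    cluster.  Late clusters are those past the major-wave onset with
    enough sexed embryos of each sex for a stable ratio.
    """
    cfg = SimConfig(seed=seed, n_embryos=600, compensation_onset_min=compensation_onset)
    counts, annotation, truth = simulate_cohort(cfg)
    m = _qc(counts)
    early = marker_gene_ids(annotation, "zygotic_minor")
    fertilized = [e for e in m.embryo_ids if truth.loc[e, "fertilized"]]
    nm, clustering, tree, order, _ = refined_trajectory(
        CountMatrix(m.values[fertilized]), early, k=6, seed=seed
    )
    female_marker = marker_gene_ids(annotation, "marker_female")[0]
    male_marker = marker_gene_ids(annotation, "marker_male")[0]
    sex_calls = call_sex(nm, female_marker, male_marker)
    maternal = maternal_set(nm, order)
    report = dosage_report(
        nm,
        sex_calls,
        clustering,
        maternal,
        annotation["chromosome"],
        exclude=(female_marker, male_marker),
    )
    by_sex = (
        sex_calls.calls[sex_calls.calls.isin(["female", "male"])]
        .groupby([clustering.labels, sex_calls.calls])
        .size()
    )
    mean_age = truth.loc[clustering.labels.index].groupby(clustering.labels)[
        "age_min"
    ].mean()

    def occupancy(cluster, n):
        try:
            return (
                by_sex.loc[(cluster, "female")] >= n
                and by_sex.loc[(cluster, "male")] >= n
            )
        except KeyError:
            return False

    sexed = [c for c in order.path if occupancy(c, 4)]
    late = [c for c in order.path if mean_age[c] > 150.0 and occupancy(c, 10)]
    x_late = [float(report.loc[c, "x_ratio_f_over_m"]) for c in late]
    autosome_mean = float(report.loc[sexed, "autosome_ratio_f_over_m"].mean())
    final = late[-1] if late else sexed[-1]
    return {
        "x_ratios_late": x_late,
        "autosome_ratio_mean": autosome_mean,
        "x_ratio_final": float(report.loc[final, "x_ratio_f_over_m"]),
    }


def spline_null_calibration(seed: int) -> dict:
    """Type-I rate of the spline sex test under a stratified null.

    Sex labels are randomized balanced within each cluster, so no
    timepoint carries a chance sex-age imbalance; every gene is then a
    true null for the sex terms.
    """
    counts, annotation, truth = simulate_cohort(SimConfig(seed=seed))
    m = _qc(counts)
    early = marker_gene_ids(annotation, "zygotic_minor")
    fertilized = [e for e in m.embryo_ids if truth.loc[e, "fertilized"]]
    nm, clustering, tree, order, _ = refined_trajectory(
        CountMatrix(m.values[fertilized]), early, k=9, seed=seed
    )
    rng = np.random.default_rng(seed + 10_000)
    labels = pd.Series(index=nm.embryo_ids, dtype=object)
    for c in range(1, clustering.k + 1):
        members = [e for e in clustering.members(c) if e in labels.index]
        perm = rng.permutation(members)
        half = len(members) // 2
        labels[perm[:half]] = "female"
        labels[perm[half:]] = "male"
    position = {c: i for i, c in enumerate(order.path)}
    time = clustering.labels.map(position)
    res = spline_de(nm, time, labels, df=3)
    return {
        "frac_p_lt_05": float((res.table["p_value"] < 0.05).mean()),
        "n_significant": len(res.significant_genes),
    }


def smoothing_linear_fidelity() -> dict:
    """Worst interior deviation of the smoother on an exactly linear series."""
    y = 0.37 * np.arange(60) - 4.2
    out = smooth_series(y, window=5, poly_order=2)
    return {"max_interior_error": float(np.abs(out[2:-2] - y[2:-2]).max())}


def bh_hand_agreement() -> dict:
    """Step-up adjustment vs hand-evaluated fixed vectors."""
    cases = [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.001, 0.01, 0.9], [0.003, 0.015, 0.9]),
        ([0.03], [0.03]),
        ([0.04, 0.01, 0.02, 0.5], [0.04 * 4 / 3, 0.04, 0.04, 0.5]),
    ]
    worst = 0.0
    for p, expected in cases:
        worst = max(worst, float(np.abs(bh_adjust(p) - np.array(expected)).max()))
    return {"max_abs_diff": worst}
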