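"""Synthetic single-embryo cohort generator with ground truth.

Emulates the statistical structure of an early-development single-embryo
RNA-seq experiment: maternally deposited transcripts with class-specific
exponential decay (some classes decay even in unfertilized eggs), zygotic
genes switching on in a staggered minor wave (~NC 7-10) and a major wave
(~NC 14), optionally with sharp transient peaks, sex-specific X-linked
dosage with a late compensation ramp in males, sex-marker genes
(Sxl-like, msl-2-like), unfertilized eggs, egg withholding across
collection windows, and overdispersed UMI count noise with per-embryo
depth variation.

Ages are minutes post-fertilization (post-laying for unfertilized eggs),
clipped to the 10-180 min window the collection design covers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = [
    "SimConfig",
    "GeneProgram",
    "PROGRAMS",
    "expected_expression",
    "sample_counts",
    "make_gene_programs",
    "simulate_cohort",
]

PROGRAMS = (
    "maternal_stable",
    "maternal_decay_intrinsic",
    "maternal_decay_fertilization",
    "zygotic_minor",
    "zygotic_major",
    "zygotic_transient",
    "marker_female",
    "marker_male",
)

CHROMOSOMES = ("X", "2L", "2R", "3L", "3R", "4")
# roughly proportional to D. melanogaster gene content per chromosome arm
CHROM_WEIGHTS = (0.17, 0.19, 0.21, 0.19, 0.21, 0.03)
# the early zygotic gene set is autosome-biased (X-linked genes are
# under-represented among early transcribed genes)
CHROM_WEIGHTS_ZYGOTIC = (0.05, 0.225, 0.24, 0.225, 0.23, 0.03)

AGE_MIN = 10.0
AGE_MAX = 180.0
MALE_MARKER_RATIO = 10.0  # male:female expression ratio of the msl-2-like marker
WITHHOLD_EXTRA_MEAN = 45.0  # mean extra minutes of age for withheld embryos


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters (desk-scale defaults)."""

    n_embryos: int = 120
    n_genes: int = 2000
    p_unfertilized: float = 0.04
    p_withhold: float = 0.15
    collection_windows: tuple[tuple[float, float], ...] = (
        (0.0, 60.0),
        (60.0, 120.0),
        (120.0, 180.0),
    )
    depth_log_mean: float = math.log(2e4)
    depth_log_sd: float = 0.25
    nb_dispersion: float = 0.2
    # tightly regulated sex-determination markers are far less noisy than
    # the genome-wide default (gene-specific dispersion, as in real data)
    marker_dispersion: float = 0.02
    gene_class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "maternal_stable": 0.311,
            "maternal_decay_intrinsic": 0.30,
            "maternal_decay_fertilization": 0.05,
            "zygotic_minor": 0.06,
            "zygotic_major": 0.20,
            "zygotic_transient": 0.078,
            "marker_female": 0.0005,
            "marker_male": 0.0005,
        }
    )
    female_x_factor: float = 2.0
    compensation_onset_min: float = 165.0
    # rank-ties decay rates to initial abundance within each decay class
    # (default: independent) for decay-vs-deposit directionality studies
    couple_decay_to_abundance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_embryos < 2:
            raise ValueError("n_embryos must be >= 2")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        for name in ("p_unfertilized", "p_withhold"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.marker_dispersion < 0:
            raise ValueError("marker_dispersion must be >= 0")
        if self.female_x_factor <= 0:
            raise ValueError("female_x_factor must be positive")
        fr = self.gene_class_fractions
        unknown = set(fr) - set(PROGRAMS)
        if unknown:
            raise ValueError(f"unknown gene programs in fractions: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("gene class fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-8:
            raise ValueError("gene class fractions must sum to 1")


@dataclass(frozen=True)
class GeneProgram:
    """Kinetic parameters of one gene's expression program.

    ``a0`` is the initial relative abundance (maternal programs only;
    zygotic programs start at zero), ``lam`` the exponential decay rate
    per minute, ``tau`` the zygotic onset time, ``ramp`` the
    post-onset rise rate per minute (plateau = ramp * 60), and
    ``peak_width`` the width in minutes of a transient pulse.
    """

    gene_id: str
    program: str
    chromosome: str
    a0: float = 0.0
    lam: float = 0.0
    tau: float = float("nan")
    ramp: float = 0.0
    peak_width: float = float("nan")

    def __post_init__(self) -> None:
        if self.program not in PROGRAMS:
            raise ValueError(f"unknown gene program label: {self.program!r}")
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome: {self.chromosome!r}")

    @property
    def is_maternal(self) -> bool:
        return self.program.startswith("maternal")

    @property
    def is_zygotic(self) -> bool:
        return not self.is_maternal


def _zygotic_kinetic(g: GeneProgram, age: float) -> float:
    """Shared rise kinetics: ramp to plateau, or a Gaussian transient pulse."""
    if age < g.tau:
        return 0.0
    plateau = g.ramp * 60.0
    if g.program == "zygotic_transient":
        center = g.tau + g.peak_width
        width = g.peak_width / 2.0
        return plateau * math.exp(-((age - center) ** 2) / (2.0 * width**2))
    return min(g.ramp * (age - g.tau), plateau)


def _x_dosage_factor(sex: str, age: float, cfg: SimConfig) -> float:
    """Sex-specific multiplier for X-linked zygotic transcription.

    Females transcribe X-linked zygotic genes at ``female_x_factor`` (two
    X copies, no compensation yet); males ramp linearly from 1x up to the
    same factor between ``compensation_onset_min`` and 180 min (MSL-style
    upregulation of the single male X).
    """
    if sex == "F":
        return cfg.female_x_factor
    t0 = cfg.compensation_onset_min
    if age <= t0 or t0 >= AGE_MAX:
        return 1.0
    frac = min((age - t0) / (AGE_MAX - t0), 1.0)
    return 1.0 + frac * (cfg.female_x_factor - 1.0)


def expected_expression(
    g: GeneProgram, age: float, sex: str, fertilized: bool, cfg: SimConfig
) -> float:
    """Deterministic expected abundance of gene ``g`` in one embryo.

    Maternal programs start at ``a0``; the intrinsic-decay class decays
    regardless of fertilization, the fertilization-triggered class only
    in fertilized embryos.  Zygotic programs are silent in unfertilized
    eggs and before their onset ``tau``.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    p = g.program
    if p == "maternal_stable":
        return g.a0
    if p == "maternal_decay_intrinsic":
        return g.a0 * math.exp(-g.lam * age)
    if p == "maternal_decay_fertilization":
        return g.a0 * math.exp(-g.lam * age) if fertilized else g.a0
    # all remaining programs are zygotic: silent without fertilization
    if not fertilized:
        return 0.0
    base = _zygotic_kinetic(g, age)
    if p == "marker_female":
        return base if sex == "F" else 0.0
    if p == "marker_male":
        return base if sex == "M" else base / MALE_MARKER_RATIO
    if g.chromosome == "X":
        base *= _x_dosage_factor(sex, age, cfg)
    return base


def sample_counts(
    expected: np.ndarray, depth: float, alpha, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-gene integer UMI counts for one embryo.

    Gene proportions are ``expected / sum(expected)``; for alpha > 0
    counts are drawn gene-wise with mean ``depth * p_g`` and variance
    ``depth * p_g + alpha * (depth * p_g)^2`` (gamma-Poisson mixture),
    so totals vary around ``depth`` as real library sizes do.  With
    alpha = 0 the draw degenerates to a multinomial over genes (a
    single expressed gene then receives exactly ``depth`` counts).
    ``alpha`` may be a scalar or a per-gene vector.
    """
    expected = np.asarray(expected, dtype=float)
    if (expected < 0).any():
        raise ValueError("expected abundances must be non-negative")
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), expected.shape)
    if (alpha < 0).any():
        raise ValueError("dispersion must be non-negative")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return np.zeros(expected.shape, dtype=np.int64)
    total = expected.sum()
    if total == 0:
        raise ValueError("all-zero expected expression with positive depth")
    p = expected / total
    if (alpha == 0).all():
        return rng.multinomial(int(round(depth)), p).astype(np.int64)
    mu = depth * p
    lam = mu.copy()
    mix = (alpha > 0) & (mu > 0)
    # gamma shape 1/alpha, scale alpha*mu gives Var = mu + alpha*mu^2
    lam[mix] = rng.gamma(1.0 / alpha[mix], alpha[mix] * mu[mix])
    return rng.poisson(lam).astype(np.int64)


def make_gene_programs(cfg: SimConfig, rng: np.random.Generator) -> list[GeneProgram]:
    """Draw per-gene kinetic parameters for the configured program mix."""
    fractions = cfg.gene_class_fractions
    counts = {p: int(round(cfg.n_genes * fractions.get(p, 0.0))) for p in PROGRAMS}
    # markers are essential for sexing: keep at least one of each if requested
    for marker in ("marker_female", "marker_male"):
        if fractions.get(marker, 0.0) > 0 and counts[marker] == 0:
            counts[marker] = 1
    drift = cfg.n_genes - sum(counts.values())
    counts["maternal_stable"] += drift

    programs: list[GeneProgram] = []
    width = len(str(cfg.n_genes))
    i = 0
    for program in PROGRAMS:
        for _ in range(counts[program]):
            gene_id = f"g{i:0{width}d}_{program}"
            if program == "marker_female":
                chrom = "X"  # Sxl-like: an X-linked female determinant
            elif program == "marker_male":
                chrom = "2L"  # msl-2-like: autosomal
            elif program.startswith("maternal"):
                chrom = rng.choice(CHROMOSOMES, p=CHROM_WEIGHTS)
            else:
                chrom = rng.choice(CHROMOSOMES, p=CHROM_WEIGHTS_ZYGOTIC)
            a0 = lam = ramp = 0.0
            tau = peak_width = float("nan")
            if program.startswith("maternal"):
                a0 = float(rng.lognormal(math.log(20.0), 1.0))
                if program != "maternal_stable":
                    lam = float(rng.uniform(0.012, 0.035))
            else:
                # minor-wave and transient genes are lowly expressed
                # relative to the massive major wave
                if program == "zygotic_minor":
                    ramp = float(rng.uniform(0.1, 0.4))
                    tau = float(rng.uniform(35.0, 75.0))
                elif program == "zygotic_major":
                    # massive in gene number, but the library stays
                    # maternal-dominated through the 3-h window
                    ramp = float(rng.uniform(0.2, 0.7))
                    tau = float(rng.uniform(110.0, 140.0))
                elif program == "zygotic_transient":
                    ramp = float(rng.uniform(0.1, 0.4))
                    tau = float(rng.uniform(50.0, 110.0))
                    peak_width = float(rng.uniform(15.0, 30.0))
                else:  # sex markers: well expressed, onset just before
                    # the major wave (Sxl/msl-2 fire around NC 12-14)
                    ramp = float(rng.uniform(1.0, 2.0))
                    tau = float(rng.uniform(85.0, 100.0))
            programs.append(
                GeneProgram(
                    gene_id=gene_id,
                    program=program,
                    chromosome=str(chrom),
                    a0=a0,
                    lam=lam,
                    tau=tau,
                    ramp=ramp,
                    peak_width=peak_width,
                )
            )
            i += 1
    if cfg.couple_decay_to_abundance:
        programs = _couple_decay(programs)
    return programs


def _couple_decay(programs: list[GeneProgram]) -> list[GeneProgram]:
    """Reassign decay rates rank-matched to a0 within each decay class."""
    import dataclasses

    out = list(programs)
    for cls in ("maternal_decay_intrinsic", "maternal_decay_fertilization"):
        idx = [i for i, g in enumerate(out) if g.program == cls]
        if not idx:
            continue
        by_a0 = sorted(idx, key=lambda i: out[i].a0)
        lams = sorted(out[i].lam for i in idx)
        for i, lam in zip(by_a0, lams):
            out[i] = dataclasses.replace(out[i], lam=lam)
    return out


def _draw_embryo_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_windows = len(cfg.collection_windows)
    width = len(str(cfg.n_embryos))
    for i in range(cfg.n_embryos):
        w = int(rng.integers(n_windows))
        start, end = cfg.collection_windows[w]
        window_label = f"{int(start)}-{int(end)}"
        sex = "F" if rng.random() < 0.5 else "M"
        fertilized = rng.random() >= cfg.p_unfertilized
        withheld = False
        if not fertilized:
            # unfertilized eggs in a collection are typically retained/aged
            # eggs; their intrinsic maternal decay has progressed far enough
            # to place them at high pseudo-time despite silent zygotic genes
            age = float(rng.uniform(150.0, AGE_MAX))
        else:
            age = float(rng.uniform(max(AGE_MIN, start), end))
            if rng.random() < cfg.p_withhold:
                extra = float(rng.exponential(WITHHOLD_EXTRA_MEAN))
                aged = min(end + extra, AGE_MAX)
                if aged > end:  # cap can void withholding in the last window
                    age = aged
                    withheld = True
        depth = float(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd))
        rows.append(
            {
                "embryo_id": f"e{i:0{width}d}",
                "age_min": age,
                "sex": sex,
                "fertilized": fertilized,
                "collection_window": window_label,
                "withheld": withheld,
                "depth": depth,
            }
        )
    return pd.DataFrame(rows).set_index("embryo_id", drop=False)


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns the count matrix (genes x embryos), the gene annotation table
    (gene_id, chromosome, program) and the embryo ground-truth table
    (embryo_id, age_min, sex, fertilized, collection_window, withheld,
    depth).  Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = make_gene_programs(cfg, rng)
    truth = _draw_embryo_truth(cfg, rng)

    alpha = np.array(
        [
            cfg.marker_dispersion if g.program.startswith("marker") else cfg.nb_dispersion
            for g in genes
        ]
    )
    counts = np.empty((len(genes), cfg.n_embryos), dtype=np.int64)
    for j, row in enumerate(truth.itertuples(index=False)):
        expected = np.array(
            [
                expected_expression(g, row.age_min, row.sex, row.fertilized, cfg)
                for g in genes
            ]
        )
        counts[:, j] = sample_counts(expected, row.depth, alpha, rng)

    gene_ids = [g.gene_id for g in genes]
    matrix = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=truth["embryo_id"].tolist())
    )
    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": [g.chromosome for g in genes],
            "program": [g.program for g in genes],
        }
    ).set_index("gene_id", drop=False)
    return matrix, annotation, truth


def marker_gene_ids(annotation: pd.DataFrame, program: str) -> list[str]:
    """Gene ids annotated with one simulation program label."""
    if program not in PROGRAMS:
        raise ValueError(f"unknown gene program label: {program!r}")
    return annotation.index[annotation["program"] == program].tolist()
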