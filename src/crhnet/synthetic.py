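"""Synthetic two-color time-course datasets with known planted structure.

Emulates the experimental design of a CRH stimulation time course on spotted
cDNA arrays: 5 time points (1, 3, 6, 12, 24 h), 6 technical replicates per
time point with a dye swap (3 arrays per dye orientation), 30 two-color
arrays in total.  Three kinds of structure can be planted and are reported in
a :class:`SyntheticTruth` object so downstream stages can be scored against
ground truth:

* differentially expressed genes following early / mid / late / sustained
  response profiles over time,
* genes with a dye x time interaction (a dye-orientation-dependent offset
  whose sign alternates over time), the artifact class the interaction ANOVA
  is meant to exclude,
* a block of genes with a planted sparse partial-correlation network.

Two entry points exist: :func:`generate_ratio_matrix` produces the
genes x 30-samples log2-ratio matrix directly (for selector and network
tests), while :func:`generate_intensity_dataset` goes through per-spot
two-channel intensity space with an intensity-dependent, print-tip-specific
dye bias, so that the normalization stage is testable against the injected
bias function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RatioMatrix, TwoColorArraySet

#: Qualitative time-response shapes on the (1, 3, 6, 12, 24) h grid, each
#: scaled by ``SyntheticConfig.de_effect``.  They mirror the response classes
#: commonly seen after CRH stimulation: immediate-early induction that decays,
#: a mid-course peak, late induction, and a sustained long-term response.
DEFAULT_PROFILES = {
    "early_up": (1.0, 0.8, 0.4, 0.1, 0.0),
    "mid_up": (0.2, 0.7, 1.0, 0.6, 0.2),
    "late_up": (0.0, 0.1, 0.4, 0.8, 1.0),
    "sustained_up": (0.3, 0.6, 0.9, 1.0, 1.0),
}

#: Ten-gene, four-cluster partial-correlation topology used as the default
#: planted network: two pair clusters, one three-gene chain, one negatively
#: correlated pair, and two unconnected nodes.  Magnitudes are set so the
#: edges remain above the 0.35 filter after the ~40% attenuation that the
#: shrinkage estimator applies at 10 genes x 30 samples (pair edges 0.8;
#: chain edges limited to 0.65 by positive definiteness).
DEFAULT_PLANTED_EDGES = (
    (0, 1, 0.8),
    (2, 3, 0.65),
    (3, 4, 0.65),
    (5, 6, 0.8),
    (7, 8, -0.8),
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic generator.

    Defaults reproduce the study design: 30 arrays (5 times x 6 replicates,
    3 per dye orientation) and a technical-replicate noise of 0.25 on the
    log2 scale.  The planted differential-expression amplitude defaults to
    1.5 log2 units (a strong ~3-fold response, as immediate-early genes show
    after stimulation), large enough that 5-gene subsets of planted genes
    can discriminate the five time points perfectly; the planted dye x time
    interaction amplitude defaults to 0.75 (three times the noise standard
    deviation), the regime in which the interaction ANOVA is expected to
    recover it.
    """

    n_spots: int = 400
    n_print_tips: int = 48
    time_points_h: tuple = (1.0, 3.0, 6.0, 12.0, 24.0)
    replicates_per_time: int = 6
    n_de_genes: int = 10
    de_profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    de_effect: float = 1.5
    n_interaction_genes: int = 0
    interaction_effect: float = 0.75
    network_genes: int = 0
    planted_edges: tuple = DEFAULT_PLANTED_EDGES
    network_scale: float = 1.5     # marginal SD, matches de_effect amplitude
    noise_sd: float = 0.25
    dye_bias_amplitude: float = 0.0
    dye_bias_curvature: float = 0.0
    a_range: tuple = (6.0, 16.0)
    a_jitter: float = 0.3          # per-array SD around each spot's base A
    background_floor: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.replicates_per_time % 2:
            raise ValueError(
                "replicates_per_time must be even (half per dye orientation)"
            )
        planted = self.n_de_genes + self.n_interaction_genes + (
            self.network_genes
        )
        if planted > self.n_spots:
            raise ValueError("planted genes exceed n_spots")
        if self.network_genes:
            # raises on a non-positive-definite planted precision
            planted_precision(self.network_genes, self.planted_edges)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    de_genes: dict                 # gene id -> profile name
    interaction_genes: list
    network_genes: list
    edge_list: list                # (gene_id_i, gene_id_j, partial corr)
    true_means: pd.DataFrame       # genes x time points, planted log2 ratio

    @property
    def de_gene_ids(self) -> list:
        return list(self.de_genes)


def planted_precision(n_genes: int, edges) -> np.ndarray:
    """Precision (inverse covariance) matrix encoding planted edges.

    Off-diagonal entries are ``-pcor_ij`` with unit diagonal, so the implied
    partial correlation of a planted edge equals its configured value.
    Rejects non-positive-definite configurations with a diagnostic.
    """
    omega = np.eye(n_genes)
    for i, j, p in edges:
        if not (0 <= i < n_genes and 0 <= j < n_genes) or i == j:
            raise ValueError(f"invalid planted edge ({i}, {j})")
        if not -1 < p < 1:
            raise ValueError(f"planted partial correlation {p} out of (-1, 1)")
        omega[i, j] = omega[j, i] = -p
    eigmin = np.linalg.eigvalsh(omega).min()
    if eigmin <= 0:
        raise ValueError(
            "planted partial-correlation network is not positive definite "
            f"(min eigenvalue {eigmin:.4g}); weaken or remove edges"
        )
    return omega


def planted_covariance(
    n_genes: int, edges, scale: float = 1.0
) -> np.ndarray:
    """Covariance implied by the planted precision, normalized so every
    marginal variance equals ``scale**2`` (partial correlations are
    invariant under this diagonal rescaling)."""
    cov = np.linalg.inv(planted_precision(n_genes, edges))
    d = np.sqrt(np.diag(cov))
    return scale**2 * cov / np.outer(d, d)


def _gene_ids(n: int) -> list:
    return [f"g{i:05d}" for i in range(n)]


def _sample_table(config: SyntheticConfig) -> pd.DataFrame:
    """30-sample metadata: time, dye orientation (3 + 3 per time), replicate."""
    half = config.replicates_per_time // 2
    rows = []
    for t in config.time_points_h:
        for r in range(config.replicates_per_time):
            dye = "treated_cy3" if r < half else "treated_cy5"
            rows.append((f"t{t:g}h_r{r + 1}", float(t), dye, r + 1))
    return pd.DataFrame(
        rows, columns=["sample", "time_h", "dye", "replicate"]
    ).set_index("sample")


def _planted_means(config: SyntheticConfig, genes: list) -> tuple:
    """True per-time mean log2 ratio for every gene, plus truth bookkeeping."""
    n_time = len(config.time_points_h)
    means = np.zeros((config.n_spots, n_time))
    profiles = list(config.de_profiles.items())
    de = {}
    for g in range(config.n_de_genes):
        name, shape = profiles[g % len(profiles)]
        means[g] = config.de_effect * np.asarray(shape, dtype=float)
        de[genes[g]] = name
    inter = list(
        range(config.n_de_genes, config.n_de_genes + config.n_interaction_genes)
    )
    net0 = config.n_de_genes + config.n_interaction_genes
    net = list(range(net0, net0 + config.network_genes))
    truth = SyntheticTruth(
        de_genes=de,
        interaction_genes=[genes[i] for i in inter],
        network_genes=[genes[i] for i in net],
        edge_list=[
            (genes[net0 + i], genes[net0 + j], p)
            for i, j, p in (config.planted_edges if net else ())
        ],
        true_means=pd.DataFrame(
            means, index=genes, columns=list(config.time_points_h)
        ),
    )
    return means, inter, net, truth


def _true_sample_values(
    config: SyntheticConfig, samples: pd.DataFrame, rng: np.random.Generator
) -> tuple:
    """Noise-free planted value of every gene in every sample, plus truth.

    The dye x time interaction is planted as a dye-orientation offset whose
    sign alternates along the time grid; the alternating pattern is centered
    (zero time average) and scaled to root-mean-square ``interaction_effect``
    across time points, so the planted effect loads entirely on the
    interaction term of the two-way ANOVA and not on the dye main effect.
    """
    genes = _gene_ids(config.n_spots)
    means, inter, net, truth = _planted_means(config, genes)
    t_idx = np.searchsorted(
        np.asarray(config.time_points_h), samples["time_h"].to_numpy()
    )
    values = means[:, t_idx]                      # (genes, samples)
    dye_sign = np.where(samples["dye"].to_numpy() == "treated_cy3", 1.0, -1.0)
    n_time = len(config.time_points_h)
    pattern = (-1.0) ** np.arange(n_time)
    pattern = pattern - pattern.mean()
    pattern /= np.sqrt(np.mean(pattern**2))
    for g in inter:
        values[g] += (
            0.5 * config.interaction_effect * dye_sign * pattern[t_idx]
        )
    if net:
        cov = planted_covariance(
            config.network_genes, config.planted_edges, config.network_scale
        )
        draws = rng.multivariate_normal(
            np.zeros(len(net)), cov, size=len(samples), method="cholesky"
        )
        values[net, :] = draws.T
    return genes, values, truth


def generate_ratio_matrix(
    config: SyntheticConfig,
) -> tuple[RatioMatrix, SyntheticTruth]:
    """Generate the genes x 30-samples normalized log2-ratio matrix directly.

    Shortcut past intensity space: each entry is the planted mean for that
    gene/time/dye cell plus N(0, noise_sd) replicate noise (log-normal
    multiplicative noise on the raw ratio scale).  Network-block genes are
    drawn from the planted inverse-covariance structure instead.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _sample_table(config)
    genes, values, truth = _true_sample_values(config, samples, rng)
    noise = rng.normal(0.0, config.noise_sd, size=values.shape)
    ratios = pd.DataFrame(values + noise, index=genes, columns=samples.index)
    return RatioMatrix(ratios, samples), truth


def _dye_bias(
    config: SyntheticConfig, a: np.ndarray, tip: np.ndarray
) -> np.ndarray:
    """Smooth additive bias on measured M as a function of A, per print tip.

    ``u`` maps A onto [-1/2, 1/2] over the configured intensity range; the
    bias is ``amp_p * u + curv_p * (u^2 - 1/12)`` with per-tip coefficients
    fanned over [0.5, 1.5] of the configured amplitude/curvature with
    alternating sign, emulating pin-to-pin variation.  Both terms have zero
    mean over a uniform A, so the bias is a pure intensity-dependent trend of
    the kind print-tip loess normalization is designed to remove.
    """
    n_tips = max(int(tip.max()) + 1, 1)
    fan = np.linspace(0.5, 1.5, n_tips) * (-1.0) ** np.arange(n_tips)
    u = (a - config.a_range[0]) / (config.a_range[1] - config.a_range[0]) - 0.5
    amp = config.dye_bias_amplitude * fan[tip]
    curv = config.dye_bias_curvature * fan[tip]
    return amp * u + curv * (u**2 - 1.0 / 12.0)


def generate_intensity_dataset(
    config: SyntheticConfig,
) -> tuple[TwoColorArraySet, SyntheticTruth]:
    """Generate raw per-spot two-channel intensities for all 30 arrays.

    Each spot has a base mean log intensity drawn uniformly over ``a_range``
    (spot brightness is a property of the probe), jittered per array by
    N(0, a_jitter); the measured log ratio is reconstructed on the MA
    geometry: M_measured = s * M_true + bias(A, tip) + noise, where s = +1
    when the treated sample is on Cy3 and -1 otherwise, and the channel
    intensities are 2^(A + M/2) and 2^(A - M/2) plus the background floor.
    Because brightness is spot-specific, the dimmest (background) spots are
    largely the same on every array, as on real arrays.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _sample_table(config)
    genes, values, truth = _true_sample_values(config, samples, rng)
    n_spots, n_arrays = values.shape
    tip = (
        np.arange(n_spots) * config.n_print_tips // max(n_spots, 1)
    ).astype(int)

    a_base = rng.uniform(*config.a_range, size=n_spots)
    a = a_base[:, None] + rng.normal(
        0.0, config.a_jitter, size=(n_spots, n_arrays)
    )
    dye_sign = np.where(
        samples["dye"].to_numpy() == "treated_cy3", 1.0, -1.0
    )[None, :]
    m_true = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    m_measured = dye_sign * m_true + _dye_bias(config, a, tip[:, None])
    cy3 = 2.0 ** (a + m_measured / 2.0) + config.background_floor
    cy5 = 2.0 ** (a - m_measured / 2.0) + config.background_floor

    spots = pd.DataFrame({"print_tip": tip + 1}, index=genes)
    arrays = TwoColorArraySet(
        spots=spots,
        arrays=samples,
        cy3=pd.DataFrame(cy3, index=genes, columns=samples.index),
        cy5=pd.DataFrame(cy5, index=genes, columns=samples.index),
        mask=pd.DataFrame(True, index=genes, columns=samples.index),
    )
    return arrays, truth
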