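"""Synthetic translatome inputs with recorded ground truth.

The generator emulates every input the pipeline consumes - fraction-
resolved microarray intensities with empty-spot statistics, per-fraction
total RNA quantities, a polysome absorbance profile, and a per-gene
feature table - for a stated world mirroring an exponentially growing
bacterium:

* ribosome occupancy ~ truncated Gaussian, mean 0.66, SD 0.06 on [0, 1];
* two peak-fraction classes, monosome D (weight 0.17) vs heavy-polysome
  H (0.83);
* mRNA recovery through gradient fractionation 60% +/- 16%, drawn per
  replicate-and-fraction but constant across genes;
* per-fraction total RNA between ~30 and ~440 ug;
* 61% of the ribosomal A254 area in the translating fractions 4-11.

The forward model for intensities inverts the normalization chain: a
fixed mass of each fraction's RNA is hybridized, so observed signal is
gene abundance x within-gene fraction proportion x fraction recovery /
total fraction RNA, times a gain, a per-replicate affine distortion
(arrays B-H) and multiplicative log-normal noise. With zero noise,
identity distortions and fraction-independent recovery the pipeline
recovers the latent truth exactly; tests lean on that round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .normalize import ARRAY_LABELS, ArraySeries
from .profile import (
    FRACTION_LABELS,
    PolysomeProfile,
    RibosomeCalibration,
    TRANSLATING_FRACTIONS,
    fraction_ranges_from_boundaries,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "ProfileBundle",
    "generate_gene_truth",
    "synthesize_arrays",
    "synthesize_profile",
    "default_calibration",
    "default_pooled_boundaries",
    "ancova_dataset",
    "write_inputs",
]

#: Default calibration slope of ln(elution time) on ln(polysome size).
DEFAULT_A = 0.4
#: Default monosome elution time (minutes).
DEFAULT_MONOSOME_TIME = 7.0
#: Polysome sizes at the boundaries of pooled fractions E..H and at the
#: interior boundaries of the four elution fractions pooled into H.
_P_EDGES = {"E": 1.4, "F": 2.9, "G": 5.4, "H": 9.6, "end": 17.9}

_CATEGORIES = ("AMI", "COF", "ENE", "INT", "REG", "TRS")
_CATEGORY_P = (0.15, 0.10, 0.35, 0.10, 0.08, 0.22)

#: True standardized effects in the occupancy regime (null effects for
#: chromosome position, GRAVY and aromaticity are deliberate).
DEFAULT_ANCOVA_COEFFICIENTS: dict[str, float] = {
    "mrna_concentration": 0.12,
    "mrna_half_life": -0.38,
    "cds_length_nt": 0.24,
    "cai": 0.16,
    "dG_down": 0.12,
    "dG_up": 0.15,
    "functional_category=INT": 0.68,
    "functional_category=REG": 0.62,
    "functional_category=TRS": -0.23,
}

#: Residual SD of the log-response linear model. With the default
#: coefficients this puts the fitted adjusted R-squared near 0.34.
DEFAULT_ANCOVA_NOISE_SD = 0.84


@dataclass
class SyntheticConfig:
    """All knobs of the stated synthetic world (defaults ARE the world)."""

    n_genes: int
    n_replicates: int = 3
    seed: int = 0
    noise_cv: float = 0.10
    loss_mean: float = 0.60
    loss_sd: float = 0.16
    fraction_rna_range: tuple[float, float] = (29.7, 436.3)
    distortion_r_range: tuple[float, float] = (0.8, 1.25)
    distortion_b_range: tuple[float, float] = (0.0, 25.0)
    occupancy_mean: float = 0.66
    occupancy_sd: float = 0.06
    peak_weights: Mapping[str, float] = field(
        default_factory=lambda: {"D": 0.17, "H": 0.83}
    )
    kernel_width: float = 0.75
    below_cutoff_frac: float = 1.0 - 1619.0 / 1948.0
    protein_fraction: float = 0.14
    target_engaged_pct: float = 61.0
    ancova_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCOVA_COEFFICIENTS)
    )
    ancova_noise_sd: float = DEFAULT_ANCOVA_NOISE_SD

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 < self.loss_mean <= 1:
            raise ValueError("loss_mean must lie in (0, 1]")
        if self.loss_sd < 0:
            raise ValueError("loss_sd must be >= 0")
        if not 0 <= self.below_cutoff_frac < 1:
            raise ValueError("below_cutoff_frac must lie in [0, 1)")
        if self.fraction_rna_range[0] <= 0 or \
                self.fraction_rna_range[1] <= self.fraction_rna_range[0]:
            raise ValueError("fraction_rna_range must be a positive interval")
        weights = dict(self.peak_weights)
        if abs(sum(weights.values()) - 1.0) > 1e-9 or \
                not set(weights) <= set(TRANSLATING_FRACTIONS):
            raise ValueError("peak_weights must sum to 1 over fractions D-H")
        if self.ancova_noise_sd <= 0:
            raise ValueError("ancova_noise_sd must be positive")
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if not 0 < self.target_engaged_pct <= 100:
            raise ValueError("target_engaged_pct must lie in (0, 100]")


@dataclass
class GroundTruth:
    """Latent per-gene truth recorded by the generator."""

    gene_ids: list[str]
    true_occupancy: np.ndarray
    true_peak_fraction: np.ndarray          # labels among D..H
    true_proportions: np.ndarray            # (n_genes, 7) over B..H, rows sum to 1
    true_density: np.ndarray                # ribosomes per 100 nt
    true_ribosome_number: np.ndarray
    cds_length_nt: np.ndarray
    abundance: np.ndarray                   # unfractionated mRNA amount (a.u.)
    features: pd.DataFrame                  # indexed by gene_id

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ProfileBundle:
    """A synthetic absorbance trace plus the metadata a calibration needs."""

    profile: PolysomeProfile
    monosome_time: float
    resolved_peaks: list[tuple[float, float]]   # (polysome size, elution time)
    pooled_boundaries: dict[str, tuple[float, float]]


@dataclass
class ArraySynthesis:
    """Bookkeeping recorded while synthesizing an ArraySeries."""

    recovery: np.ndarray        # (7, n_replicates) fraction recovery rho
    distortions: np.ndarray     # (n_replicates, 2) affine (r, b) on arrays B-H
    cutoff: float
    kept_mask: np.ndarray
    gain: float


def _boundary_times(a: float, monosome_time: float) -> np.ndarray:
    """The 12 elution-fraction boundary times implied by the calibration."""
    if a <= 0:
        raise ValueError("calibration slope a must be positive")
    if monosome_time <= 0:
        raise ValueError("monosome elution time must be positive")
    p_h = np.exp(np.linspace(np.log(_P_EDGES["H"]), np.log(_P_EDGES["end"]), 5))
    sizes = [_P_EDGES["E"], _P_EDGES["F"], _P_EDGES["G"], *p_h]
    times = monosome_time * np.asarray(sizes) ** a
    lead = np.linspace(0.0, 6.0, 4)          # fractions 1-3 + start of D
    return np.concatenate([lead, times])


def default_pooled_boundaries(
    a: float = DEFAULT_A, monosome_time: float = DEFAULT_MONOSOME_TIME
) -> dict[str, tuple[float, float]]:
    """Boundary times of pooled fractions D-H under the default gradient."""
    b = _boundary_times(a, monosome_time)
    return {
        "D": (b[3], b[4]),
        "E": (b[4], b[5]),
        "F": (b[5], b[6]),
        "G": (b[6], b[7]),
        "H": (b[7], b[11]),
    }


def default_calibration(
    n_replicates: int = 3,
    a: float = DEFAULT_A,
    monosome_time: float = DEFAULT_MONOSOME_TIME,
) -> RibosomeCalibration:
    """Calibration of the default synthetic gradient, D-H ranges attached."""
    cal = RibosomeCalibration(a=a, b=np.full(n_replicates, np.log(monosome_time)))
    fraction_ranges_from_boundaries(cal, default_pooled_boundaries(a, monosome_time))
    return cal


def generate_gene_truth(config: SyntheticConfig) -> GroundTruth:
    """Draw the latent per-gene truth of the stated world.

    Occupancies follow a truncated Gaussian on [0, 1]; peak fractions a
    two-class D/H mixture; within-gene proportions put the non-translating
    mass half in B and half in C and spread the translating mass over D-H
    with a discretized Gaussian kernel centered on the peak (strict
    maximum at the peak by construction). Features follow log-normal or
    Gaussian families; occupancy is coupled to them through a Gaussian
    copula whose linear score uses ``config.ancova_coefficients``, so the
    marginal occupancy distribution is preserved exactly while the
    correlation structure matches the configured effects.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    features, cds_length = _draw_features(rng, n, config)

    # Linear score on the model's own (transformed, standardized) scale.
    score = _linear_score(features, config.ancova_coefficients)
    score = score + rng.normal(0.0, config.ancova_noise_sd, size=n)
    u = sps.norm.cdf((score - score.mean()) / score.std(ddof=0))
    lo, hi = ((0.0 - config.occupancy_mean) / config.occupancy_sd,
              (1.0 - config.occupancy_mean) / config.occupancy_sd)
    occupancy = sps.truncnorm.ppf(
        np.clip(u, 1e-12, 1 - 1e-12), lo, hi,
        loc=config.occupancy_mean, scale=config.occupancy_sd,
    )

    labels = list(config.peak_weights)
    probs = np.array([config.peak_weights[l] for l in labels], dtype=float)
    peak = rng.choice(labels, size=n, p=probs / probs.sum())

    proportions = np.zeros((n, 7))
    dh_index = {lab: i for i, lab in enumerate(TRANSLATING_FRACTIONS)}
    grid = np.arange(5, dtype=float)
    for i in range(n):
        proportions[i, 0] = proportions[i, 1] = (1.0 - occupancy[i]) / 2.0
        kernel = np.exp(-0.5 * ((grid - dh_index[peak[i]]) / config.kernel_width) ** 2)
        proportions[i, 2:] = occupancy[i] * kernel / kernel.sum()

    cal = default_calibration(config.n_replicates)
    rib = np.array([cal.fraction_ranges[p][2] for p in peak])
    density = rib * 100.0 / cds_length

    abundance = features["mrna_concentration"].to_numpy() * 1000.0
    return GroundTruth(
        gene_ids=gene_ids,
        true_occupancy=occupancy,
        true_peak_fraction=peak,
        true_proportions=proportions,
        true_density=density,
        true_ribosome_number=rib,
        cds_length_nt=cds_length,
        abundance=abundance,
        features=features,
    )


def _draw_features(rng: np.random.Generator, n: int,
                   config: SyntheticConfig) -> tuple[pd.DataFrame, np.ndarray]:
    cds_length = np.maximum(
        90, np.round(rng.lognormal(np.log(900.0), 0.45, size=n))
    ).astype(float)
    features = pd.DataFrame(
        {
            "chrom_position": rng.uniform(0.0, 2.4e6, size=n),
            "mrna_concentration": rng.lognormal(0.0, 0.8, size=n),
            "mrna_half_life": rng.lognormal(np.log(5.8), 0.35, size=n),
            "cds_length_nt": cds_length,
            "aromaticity": rng.lognormal(np.log(0.085), 0.25, size=n),
            "gravy": rng.normal(-0.2, 0.35, size=n),
            "cai": np.minimum(0.95, rng.lognormal(np.log(0.45), 0.15, size=n)),
            "dG_up": rng.normal(-8.0, 3.0, size=n),
            "dG_down": rng.normal(-8.0, 3.0, size=n),
            "functional_category": rng.choice(_CATEGORIES, size=n, p=_CATEGORY_P),
        },
        index=pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id"),
    )
    protein = rng.lognormal(0.0, 0.7, size=n)
    has_protein = rng.random(n) < config.protein_fraction
    features["protein_level"] = np.where(has_protein, protein, np.nan)
    return features, cds_length


#: Features whose model transform is log (matches stats._DEFAULT_QUANT).
_LOG_FEATURES = {"mrna_concentration", "mrna_half_life", "cds_length_nt",
                 "aromaticity", "cai", "occupancy", "density"}


def _linear_score(features: pd.DataFrame,
                  coefficients: Mapping[str, float]) -> np.ndarray:
    """Sum of true effects on the transformed, standardized covariate scale."""
    score = np.zeros(len(features))
    for name, beta in coefficients.items():
        if beta == 0:
            continue
        if "=" in name:
            col, level = name.split("=", 1)
            ind = (features[col].astype(str) == level).to_numpy(dtype=float)
            score += beta * (ind - ind.mean())
        else:
            x = features[name].to_numpy(dtype=float)
            if name in _LOG_FEATURES:
                x = np.log(x)
            score += beta * (x - x.mean()) / x.std(ddof=0)
    return score


def synthesize_arrays(truth: GroundTruth, config: SyntheticConfig) -> ArraySeries:
    """Forward-simulate the eight-array intensity tensor from the truth.

    Returns an :class:`ArraySeries`; the synthesis bookkeeping (recovery
    factors, distortions, cutoff and kept-gene mask) is attached as its
    ``synthesis`` attribute.
    """
    if truth.n_genes != config.n_genes:
        raise ValueError("truth and config disagree on n_genes")
    rng = np.random.default_rng([config.seed, 1])
    n, k = config.n_genes, config.n_replicates
    gain = 1000.0

    lo, hi = config.fraction_rna_range
    base = np.exp(np.linspace(np.log(lo), np.log(hi), 7))          # B..H means
    rna = np.empty((8, k))
    rna[0] = rng.uniform(400.0, 600.0, size=k)                     # reference A
    rna[1:] = base[:, None] * rng.lognormal(0.0, 0.25, size=(7, k))

    if config.loss_sd == 0:
        recovery = np.full((7, k), config.loss_mean)
    else:
        recovery = np.clip(
            rng.normal(config.loss_mean, config.loss_sd, size=(7, k)), 0.05, 1.0
        )

    def noise(shape):
        if config.noise_cv == 0:
            return np.ones(shape)
        sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
        return rng.lognormal(-sigma ** 2 / 2.0, sigma, size=shape)

    intensities = np.empty((n, 8, k))
    intensities[:, 0, :] = (
        gain * truth.abundance[:, None] / rna[0][None, :] * noise((n, k))
    )
    amounts = truth.abundance[:, None, None] * truth.true_proportions[:, :, None]
    intensities[:, 1:, :] = (
        gain * amounts * recovery[None, :, :] / rna[1:][None, :, :]
        * noise((n, 7, k))
    )

    r = rng.uniform(*config.distortion_r_range, size=k)
    b = rng.uniform(*config.distortion_b_range, size=k)
    intensities[:, 1:, :] = r[None, None, :] * intensities[:, 1:, :] + b[None, None, :]

    # Empty-spot statistics placed so that exactly the configured fraction
    # of genes falls below the cutoff (mean + 1 SD) on all eight arrays.
    per_gene = intensities.mean(axis=2).max(axis=1)
    n_below = int(round(config.below_cutoff_frac * n))
    order = np.sort(per_gene)
    if n_below == 0:
        cutoff = order[0] / 2.0
    else:
        cutoff = 0.5 * (order[n_below - 1] + order[n_below])
    empty_stats = np.tile([0.8 * cutoff, 0.2 * cutoff], (8, 1))

    series = ArraySeries(
        intensities=intensities,
        gene_ids=list(truth.gene_ids),
        empty_stats=empty_stats,
        rna_quantity=rna,
    )
    series.synthesis = ArraySynthesis(
        recovery=recovery,
        distortions=np.column_stack([r, b]),
        cutoff=float(cutoff),
        kept_mask=per_gene > cutoff,
        gain=gain,
    )
    return series


def synthesize_profile(
    calibration_a: float,
    calibration_b: float,
    config: SyntheticConfig,
) -> ProfileBundle:
    """Build a synthetic A254 trace as a sum of Gaussian peaks.

    Peak centers follow the log-linear elution model: the monosome at
    ``exp(calibration_b)`` and each resolved polysome of size P at
    ``exp(calibration_a * ln P + calibration_b)``. Subunit peak heights
    are rescaled so the area over elution fractions 4-11 is
    ``config.target_engaged_pct`` percent of the area over 2-11.
    """
    if calibration_a <= 0:
        raise ValueError("calibration_a must be positive (larger polysomes "
                         "elute later in this convention)")
    monosome_time = float(np.exp(calibration_b))
    boundaries = _boundary_times(calibration_a, monosome_time)
    t = np.arange(0.0, boundaries[-1] + 0.01, 0.01)

    def gauss(center, amp, width=0.35):
        return amp * np.exp(-0.5 * ((t - center) / width) ** 2)

    poly_sizes = np.arange(2, 19)
    poly_times = monosome_time * poly_sizes.astype(float) ** calibration_a
    ribosomal = gauss(monosome_time, 1.5)
    for p, tp in zip(poly_sizes, poly_times):
        ribosomal += gauss(tp, 1.2 * 0.85 ** (p - 2))
    subunits = gauss(3.0, 0.8) + gauss(5.0, 1.0)
    free_rna = gauss(1.0, 1.2)

    prof = PolysomeProfile(t, free_rna + subunits + ribosomal, boundaries)
    area_poly = prof.fraction_area(4, 11)
    area_sub = prof.fraction_area(2, 3)
    e = config.target_engaged_pct
    target_sub = area_poly * (100.0 - e) / e
    scale = target_sub / area_sub if area_sub > 0 else 0.0
    profile = PolysomeProfile(t, free_rna + scale * subunits + ribosomal, boundaries)

    resolved = [(float(p), float(tp)) for p, tp in
                zip(poly_sizes, poly_times) if p in (2, 3, 4, 6, 8)]
    pooled = {
        "D": (boundaries[3], boundaries[4]),
        "E": (boundaries[4], boundaries[5]),
        "F": (boundaries[5], boundaries[6]),
        "G": (boundaries[6], boundaries[7]),
        "H": (boundaries[7], boundaries[11]),
    }
    return ProfileBundle(profile, monosome_time, resolved, pooled)


def ancova_dataset(
    n: int = 814,
    coefficients: Mapping[str, float] | None = None,
    noise_sd: float = DEFAULT_ANCOVA_NOISE_SD,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Features plus a log-linear response with known true coefficients.

    The response is ``exp(sum_j beta_j z_j + lambda terms + eps)`` with
    ``z_j`` the covariates on the model's own transformed/standardized
    scale and ``eps ~ N(0, noise_sd)``, i.e. exactly the generative form
    the covariance model assumes. Used for parameter-recovery checks.
    """
    if coefficients is None:
        coefficients = dict(DEFAULT_ANCOVA_COEFFICIENTS)
    rng = np.random.default_rng(seed)
    cfg = SyntheticConfig(n_genes=max(10, n), seed=seed)
    features, _ = _draw_features(rng, n, cfg)
    eta = _linear_score(features, coefficients)
    response = pd.Series(
        np.exp(eta + rng.normal(0.0, noise_sd, size=n)),
        index=features.index, name="response",
    )
    return features, response, dict(coefficients)


def write_inputs(
    outdir: str | Path,
    config: SyntheticConfig,
    truth: GroundTruth,
    series: ArraySeries,
    bundle: ProfileBundle,
) -> dict[str, Path]:
    """Write every synthetic input as plain TSV/YAML under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for gi, gene in enumerate(series.gene_ids):
        for aj, arr in enumerate(ARRAY_LABELS):
            for kk in range(series.n_replicates):
                rows.append((gene, arr, kk, series.intensities[gi, aj, kk]))
    paths["intensities"] = outdir / "intensities.tsv"
    pd.DataFrame(rows, columns=["gene_id", "array", "replicate", "intensity"]) \
        .to_csv(paths["intensities"], sep="\t", index=False)

    meta = []
    for aj, arr in enumerate(ARRAY_LABELS):
        for kk in range(series.n_replicates):
            meta.append((arr, kk, series.rna_quantity[aj, kk],
                         series.empty_stats[aj, 0], series.empty_stats[aj, 1]))
    paths["fractions"] = outdir / "fractions.tsv"
    pd.DataFrame(meta, columns=["array", "replicate", "rna_quantity_ug",
                                "empty_mean", "empty_sd"]) \
        .to_csv(paths["fractions"], sep="\t", index=False)

    paths["profile"] = outdir / "profile.tsv"
    pd.DataFrame({"time": bundle.profile.time,
                  "absorbance": bundle.profile.absorbance}) \
        .to_csv(paths["profile"], sep="\t", index=False)

    paths["features"] = outdir / "features.tsv"
    truth.features.to_csv(paths["features"], sep="\t")

    tdf = pd.DataFrame(
        {
            "gene_id": truth.gene_ids,
            "true_occupancy": truth.true_occupancy,
            "true_peak_fraction": truth.true_peak_fraction,
            "true_density": truth.true_density,
            "cds_length_nt": truth.cds_length_nt,
        }
    )
    for j, lab in enumerate(FRACTION_LABELS):
        tdf[f"true_prop_{lab}"] = truth.true_proportions[:, j]
    paths["truth"] = outdir / "ground_truth.tsv"
    tdf.to_csv(paths["truth"], sep="\t", index=False)

    cfg = {k: (list(v) if isinstance(v, tuple) else
               dict(v) if isinstance(v, Mapping) else v)
           for k, v in vars(config).items()}
    paths["config"] = outdir / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
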