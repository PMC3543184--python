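"""Empty-spot cutoff filtering and three-stage intensity normalization.

The input is a gene x array x replicate tensor of post-background spot
intensities: array A carries unfractionated total RNA (the internal
reference), arrays B-H the seven pooled sucrose-gradient fractions.
Normalization proceeds in three stages:

1. intra-series standardization of each B-H intensity by the mean
   array-A intensity of the same replicate series (reference scaling);
2. correction by the ratio of total RNA quantity in the fraction to that
   of the unfractionated sample, converting per-aliquot signal (a fixed
   RNA mass is hybridized per array) back to fraction-level abundance;
3. inter-series adjustment: per array and replicate, ordinary least
   squares of the replicate's values on the across-replicate mean gives
   a gain r and offset b, and the replicate is centered by b and reduced
   by r. By construction the corrected values regress on the replicate
   mean with slope 1 and intercept 0.

Genes are kept when their across-replicate mean intensity exceeds the
empty-spot cutoff (empty mean + 1 SD) on at least one of the 8 arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ARRAY_LABELS",
    "ArraySeries",
    "NormalizedSeries",
    "apply_cutoff",
    "normalize_to_reference",
    "correct_rna_quantity",
    "center_reduce_interseries",
    "normalize_series",
]

#: All eight arrays, reference first.
ARRAY_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H")


@dataclass
class ArraySeries:
    """Raw intensity tensor with empty-spot statistics and RNA quantities.

    Attributes
    ----------
    intensities
        Array of shape (n_genes, 8, n_replicates); columns follow
        :data:`ARRAY_LABELS`. Values are post-background spot means
        (duplicate spots already averaged at ingest).
    gene_ids
        One identifier per gene row.
    empty_stats
        Shape (8, 2): per-array (mean, SD) of the empty spots.
    rna_quantity
        Shape (8, n_replicates): total RNA recovered per array (µg).
    """

    intensities: np.ndarray
    gene_ids: Sequence[str]
    empty_stats: np.ndarray
    rna_quantity: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.empty_stats = np.asarray(self.empty_stats, dtype=float)
        self.rna_quantity = np.asarray(self.rna_quantity, dtype=float)
        self.gene_ids = list(self.gene_ids)
        g, j, k = self.intensities.shape
        if j != 8:
            raise ValueError("intensities must cover the 8 arrays A-H")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length must match the gene axis")
        if self.empty_stats.shape != (8, 2):
            raise ValueError("empty_stats must hold (mean, SD) for each of the "
                             "8 arrays; missing empty-spot statistics")
        if self.rna_quantity.shape != (8, k):
            raise ValueError("rna_quantity must be (8 arrays, n_replicates)")
        if np.any(self.rna_quantity <= 0):
            raise ValueError("rna_quantity must be positive for arrays A-H")

    @property
    def n_genes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[2]


@dataclass
class NormalizedSeries:
    """Output bundle of the three normalization stages (arrays B-H only)."""

    n_values: np.ndarray          # after reference + RNA-quantity correction
    ncr_values: np.ndarray        # after inter-series center/reduce
    fit_params: np.ndarray        # (7, n_replicates, 2): per (j, k) (r_hat, b_hat)
    kept_genes: list[str]
    kept_mask: np.ndarray
    clipped: np.ndarray = field(default=None)  # bool, gene x array x rep, ncr < 0


def apply_cutoff(series: ArraySeries) -> np.ndarray:
    """Boolean mask of genes passing the empty-spot cutoff.

    A gene is kept iff its across-replicate mean intensity strictly
    exceeds (empty mean + 1 SD) on at least one of the 8 arrays.
    """
    if not np.all(np.isfinite(series.empty_stats)):
        raise ValueError("missing empty-spot statistics")
    cutoff = series.empty_stats[:, 0] + series.empty_stats[:, 1]   # (8,)
    mean_intensity = series.intensities.mean(axis=2)               # (genes, 8)
    return np.any(mean_intensity > cutoff[None, :], axis=1)


def normalize_to_reference(series: ArraySeries,
                           kept_mask: np.ndarray | None = None) -> np.ndarray:
    """Stage 1: standardize arrays B-H by the mean reference-A intensity.

    Each kept gene's intensity on arrays B-H is divided by the mean
    array-A intensity over kept genes of the same replicate (equivalently
    multiplied by G / sum of A intensities, G the kept-gene count).
    Invariant under uniform rescaling of a replicate's intensities.
    """
    if kept_mask is None:
        kept_mask = np.ones(series.n_genes, dtype=bool)
    ref_mean = series.intensities[kept_mask, 0, :].mean(axis=0)    # (k,)
    if np.any(ref_mean <= 0):
        raise ValueError("mean reference array-A intensity must be positive")
    return series.intensities[kept_mask, 1:, :] / ref_mean[None, None, :]


def correct_rna_quantity(n_values: np.ndarray,
                         rna_quantity: np.ndarray) -> np.ndarray:
    """Stage 2: rescale by total RNA quantity ratios (fraction / reference).

    Converts the per-aliquot signal back to the fraction-level scale:
    value * RNA_{j,k} / RNA_{A,k} for array j, replicate k.
    """
    rna_quantity = np.asarray(rna_quantity, dtype=float)
    if np.any(rna_quantity[0] <= 0):
        raise ValueError("reference RNA quantity RNA_A must be positive")
    ratio = rna_quantity[1:, :] / rna_quantity[0, :][None, :]      # (7, k)
    return n_values * ratio[None, :, :]


def center_reduce_interseries(
    n_values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 3: per (array, replicate) affine adjustment toward the mean.

    For each array j and replicate k, fit N_{j,k} = r * Nbar_j + b over
    genes by OLS, where Nbar_j is the across-replicate mean, then return
    (N - b_hat) / r_hat. When replicate values are exact affine images of
    a common profile this maps every replicate onto the replicate mean.

    Returns
    -------
    (ncr_values, fit_params)
        fit_params has shape (7, n_replicates, 2) holding (r_hat, b_hat).
    """
    n_values = np.asarray(n_values, dtype=float)
    g, j, k = n_values.shape
    if k < 2:
        raise ValueError("inter-series normalization requires >= 2 replicates")
    nbar = n_values.mean(axis=2)                                   # (g, 7)
    ncr = np.empty_like(n_values)
    fit_params = np.empty((j, k, 2))
    for jj in range(j):
        x = nbar[:, jj]
        for kk in range(k):
            y = n_values[:, jj, kk]
            r_hat, b_hat = _ols_line(x, y)
            if abs(r_hat) < 1e-12:
                raise ValueError(
                    f"degenerate inter-series regression (r_hat = 0) for "
                    f"array {ARRAY_LABELS[jj + 1]}, replicate {kk}"
                )
            fit_params[jj, kk] = (r_hat, b_hat)
            ncr[:, jj, kk] = (y - b_hat) / r_hat
    return ncr, fit_params


def normalize_series(series: ArraySeries) -> NormalizedSeries:
    """Run cutoff + all three normalization stages on a series."""
    kept_mask = apply_cutoff(series)
    if not np.any(kept_mask):
        raise ValueError("no gene passes the empty-spot cutoff")
    n1 = normalize_to_reference(series, kept_mask)
    n = correct_rna_quantity(n1, series.rna_quantity)
    ncr, fit_params = center_reduce_interseries(n)
    clipped = ncr < 0
    return NormalizedSeries(
        n_values=n,
        ncr_values=np.clip(ncr, 0.0, None),
        fit_params=fit_params,
        kept_genes=[g for g, m in zip(series.gene_ids, kept_mask) if m],
        kept_mask=kept_mask,
        clipped=clipped,
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of the least-squares line of y on x."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("degenerate inter-series regression: constant "
                         "replicate-mean intensities")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return float(slope), float(ym - slope * xm)
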