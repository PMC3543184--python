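"""Per-gene translatome variables: mRNA proportions, ribosome occupancy,
bootstrap peak fraction, and ribosome density.

For each gene the normalized intensities over pooled fractions B-H are
turned into per-replicate mRNA proportions (each vector sums to 1).
Ribosome occupancy is the summed proportion in the ribosome-containing
fractions D-H, averaged over replicates. The peak fraction - the modal
ribosome load - is the argmax over D-H, made robust by a bootstrap on
residuals: per-fraction residuals from the across-replicate mean are
pooled within the gene, resampled with replacement, and added back to
the means; the fraction that is modal in at least 95% of 10000 bootstrap
data sets is the peak. When no single fraction reaches that support the
search widens to sums over adjacent fractions (D+E, E+F, ... then
triples, and so on). Ribosome density is the representative ribosome
number of a single-fraction peak per 100 nt of coding sequence; one
ribosome footprint covers ~30 nt, so densities above 100/30 ~ 3.33 are
physically impossible and flag the gene out of downstream modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile import FRACTION_LABELS, RibosomeCalibration, TRANSLATING_FRACTIONS

__all__ = [
    "MAX_DENSITY_PER_100NT",
    "RIBOSOME_FOOTPRINT_NT",
    "PeakAssignment",
    "mrna_proportions",
    "ribosome_occupancy",
    "bootstrap_peak_fraction",
    "ribosome_density",
    "theoretical_max_density",
    "compute_translatome",
    "filter_max_density",
]

#: Nucleotides protected by one bound bacterial ribosome.
RIBOSOME_FOOTPRINT_NT = 30

#: Theoretical maximal ribosome density, ribosomes per 100 nt.
MAX_DENSITY_PER_100NT = 100.0 / RIBOSOME_FOOTPRINT_NT

# Indices of D..H within the B..H axis.
_DH = slice(2, 7)
_DH_LABELS = TRANSLATING_FRACTIONS


@dataclass(frozen=True)
class PeakAssignment:
    """Result of the bootstrap peak-fraction search.

    ``fractions`` is a tuple of adjacent fraction labels: length 1 for a
    single-fraction peak, longer when the widening rule was needed.
    ``support`` is the modal relative frequency at the accepted level;
    ``tie`` flags an exact argmax tie in the observed mean proportions
    (broken toward the lower fraction).
    """

    fractions: tuple[str, ...]
    support: float
    tie: bool = False

    @property
    def single(self) -> bool:
        return len(self.fractions) == 1


def mrna_proportions(values: np.ndarray) -> np.ndarray:
    """Normalize per-replicate B-H values to proportions summing to 1.

    Parameters
    ----------
    values
        Nonnegative array of shape (n_replicates, 7) or (7,). Replicates
        whose seven values are all zero yield a row of NaN (flagged
        upstream and excluded from averaging).
    """
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[1] != 7:
        raise ValueError("expected 7 values per replicate (fractions B-H)")
    if np.any(arr < 0):
        raise ValueError("proportions require nonnegative input; clip first")
    totals = arr.sum(axis=1)
    out = np.full_like(arr, np.nan)
    valid = totals > 0
    out[valid] = arr[valid] / totals[valid, None]
    if np.asarray(values).ndim == 1:
        return out[0]
    return out


def ribosome_occupancy(proportions: np.ndarray) -> tuple[np.ndarray, float]:
    """Occupancy per replicate (sum over D-H) and its mean over valid replicates.

    Replicates with NaN proportions (all-zero input) are excluded from
    the mean; if none is valid the mean is NaN (gene unassigned).
    """
    arr = np.atleast_2d(np.asarray(proportions, dtype=float))
    per_rep = arr[:, _DH].sum(axis=1)
    per_rep[np.any(np.isnan(arr), axis=1)] = np.nan
    valid = ~np.isnan(per_rep)
    mean = float(per_rep[valid].mean()) if np.any(valid) else float("nan")
    return per_rep, mean


def bootstrap_peak_fraction(
    proportions: np.ndarray,
    n_boot: int = 10000,
    conf: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> PeakAssignment:
    """Assign the peak fraction by a bootstrap on residuals.

    Residuals of each replicate's proportion from the per-fraction mean
    (all seven fractions) are pooled within the gene. Each bootstrap data
    set redraws one residual per (fraction, replicate) cell with
    replacement and adds it to the per-fraction mean; the argmax over
    D-H of the resulting mean proportions is recorded. A fraction modal
    in >= ``conf`` of the ``n_boot`` sets is the peak. Otherwise the
    candidate categories are widened to sums over adjacent windows of
    increasing width (pairs, triples, ...), re-running the bootstrap at
    each level, up to the full D-H window which always succeeds.

    Exact argmax ties are broken toward the lower fraction index and
    flagged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.atleast_2d(np.asarray(proportions, dtype=float))
    arr = arr[~np.any(np.isnan(arr), axis=1)]
    if arr.shape[0] < 2:
        raise ValueError("bootstrap peak assignment requires >= 2 valid replicates")
    if arr.shape[1] != 7:
        raise ValueError("expected 7 fractions B-H")
    n_rep = arr.shape[0]
    frac_mean = arr.mean(axis=0)                       # over replicates, Eq. mean
    pool = (arr - frac_mean[None, :]).ravel()          # residual pool, 7 * n_rep
    mean_dh = frac_mean[_DH]
    tie = int(np.sum(mean_dh == mean_dh.max())) > 1

    for width in range(1, 6):
        starts = range(0, 5 - width + 1)
        labels = [tuple(_DH_LABELS[s : s + width]) for s in starts]
        if width == 5:
            return PeakAssignment(labels[0], 1.0, tie)
        # Fresh bootstrap at this widening level.
        idx = rng.integers(0, pool.size, size=(n_boot, n_rep, 5))
        boot = mean_dh[None, :] + pool[idx].mean(axis=1)          # (n_boot, 5)
        window_sums = np.stack(
            [boot[:, s : s + width].sum(axis=1) for s in starts], axis=1
        )
        winners = np.argmax(window_sums, axis=1)
        counts = np.bincount(winners, minlength=len(labels))
        modal = int(np.argmax(counts))
        support = counts[modal] / n_boot
        if support >= conf:
            return PeakAssignment(labels[modal], float(support), tie)
    raise AssertionError("unreachable: full D-H window always attains support 1")


def ribosome_density(ribosome_number: float, cds_length_nt: float) -> float:
    """Ribosomes per 100 nt of coding sequence at the peak fraction."""
    if cds_length_nt <= 0:
        raise ValueError("cds_length_nt must be positive")
    if ribosome_number < 0:
        raise ValueError("ribosome_number must be nonnegative")
    return ribosome_number * 100.0 / cds_length_nt


def theoretical_max_density(footprint_nt: float = RIBOSOME_FOOTPRINT_NT) -> float:
    """Maximal density (per 100 nt) for ribosomes of the given footprint."""
    return ribosome_density(1.0, footprint_nt)


def compute_translatome(
    ncr_values: np.ndarray,
    gene_ids: list[str],
    cds_length_nt: np.ndarray,
    calibration: RibosomeCalibration,
    n_boot: int = 10000,
    conf: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-gene translatome table from normalized intensities.

    Parameters
    ----------
    ncr_values
        Nonnegative (n_genes, 7, n_replicates) tensor of normalized
        intensities over fractions B-H (clipped at zero upstream).
    cds_length_nt
        Coding-sequence length per gene, nt.
    calibration
        Calibration whose ``fraction_ranges`` provides representative
        ribosome numbers for D-H.
    seed
        Base seed; each gene's bootstrap uses an independent stream
        derived from (seed, gene index), so assignments do not depend on
        gene order upstream of the call.

    Returns
    -------
    pandas.DataFrame indexed by gene with proportions, occupancy, peak
    fraction and bootstrap support, ribosome number, density, and flags.
    """
    if not calibration.fraction_ranges:
        raise ValueError("calibration carries no fraction_ranges for D-H")
    ncr_values = np.asarray(ncr_values, dtype=float)
    g = ncr_values.shape[0]
    cds_length_nt = np.asarray(cds_length_nt, dtype=float)
    rows = []
    for i in range(g):
        values = ncr_values[i].T                       # (reps, 7)
        props = mrna_proportions(values)
        per_rep_occ, occ = ribosome_occupancy(props)
        valid = props[~np.any(np.isnan(props), axis=1)]
        row = {
            "gene_id": gene_ids[i],
            "occupancy": occ,
            "cds_length_nt": cds_length_nt[i],
        }
        for j, lab in enumerate(FRACTION_LABELS):
            row[f"prop_{lab}"] = valid[:, j].mean() if valid.size else np.nan
        if valid.shape[0] >= 2:
            peak = bootstrap_peak_fraction(
                valid, n_boot=n_boot, conf=conf,
                seed=np.random.default_rng([seed, i]),
            )
            row["peak_fraction"] = "+".join(peak.fractions)
            row["peak_support"] = peak.support
            row["peak_tie"] = peak.tie
            row["peak_unassigned"] = not peak.single
            if peak.single:
                rib = calibration.fraction_ranges[peak.fractions[0]][2]
                row["ribosome_number"] = rib
                row["density"] = ribosome_density(rib, cds_length_nt[i])
            else:
                row["ribosome_number"] = np.nan
                row["density"] = np.nan
        else:
            row.update(peak_fraction="", peak_support=np.nan, peak_tie=False,
                       peak_unassigned=True, ribosome_number=np.nan,
                       density=np.nan)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene_id")
    df["density_exceeds_max"] = df["density"] > MAX_DENSITY_PER_100NT
    return df


def filter_max_density(records: pd.DataFrame) -> pd.DataFrame:
    """Modeling gene set: single-peak genes with density <= 100/30.

    Genes strictly above the theoretical maximum stay in the full table,
    flagged ``density_exceeds_max``; the returned frame excludes them and
    genes without a single-fraction peak.
    """
    ok = (~records["peak_unassigned"]) & records["density"].notna()
    return records[ok & ~records["density_exceeds_max"]]
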