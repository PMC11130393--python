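"""Reference-channel ratio preprocessing of multiplexed PSM tables.

Converts PSM-level reporter intensities into a merged protein x sample ratio
matrix: every unique PSM is divided by the set's pooled-reference intensity
(tag 134N), the per-PSM ratios are averaged per protein, low-intensity outlier
samples are excluded, and the matrix is normalized against the median of an
invariant protein subset (the least-variant fraction of the fully covered
proteins, a median-variant of invariant-subset normalization).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthetic import REFERENCE_CHANNEL

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinMatrix",
    "psm_to_protein_ratios",
    "rank_invariance",
    "normalize_median_invariant",
    "exclude_intensity_outliers",
    "merge_sets",
    "identification_counts",
    "preprocess_cohort",
]


@dataclass
class ProteinMatrix:
    """Protein x sample reference-ratio matrix with quantitation provenance.

    Attributes
    ----------
    ratios : DataFrame, proteins x samples; NaN where the protein was not
        detected in the sample's set.
    psm_counts : DataFrame, proteins x sets; number of unique PSMs averaged
        per (protein, set); 0 where not detected.
    sample_sets : Series mapping sample -> set_id.
    normalization_subset : list of protein ids used for median normalization
        (empty until :func:`normalize_median_invariant` runs).
    invariance_rank : Series protein -> rank (1 = most invariant) over the
        fully covered proteins (empty until :func:`rank_invariance` runs).
    """

    ratios: pd.DataFrame
    psm_counts: pd.DataFrame
    sample_sets: pd.Series
    normalization_subset: list[str] = field(default_factory=list)
    invariance_rank: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    scaling_factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def detected(self) -> pd.DataFrame:
        """(protein, set) -> bool detection flags derived from psm_counts."""
        return self.psm_counts > 0

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            ratios=self.ratios.copy(),
            psm_counts=self.psm_counts.copy(),
            sample_sets=self.sample_sets.copy(),
            normalization_subset=list(self.normalization_subset),
            invariance_rank=self.invariance_rank.copy(),
            scaling_factors=self.scaling_factors.copy(),
        )


def psm_to_protein_ratios(
    psms: pd.DataFrame, sheet: pd.DataFrame, log_mean: bool = False
) -> ProteinMatrix:
    """Average per-PSM reference ratios into a protein x sample matrix.

    Only rows flagged ``unique`` are used.  For every unique PSM the reporter
    intensity in each sample channel is divided by the same PSM's intensity in
    the set's reference channel; the ratios of all unique PSMs of a protein
    are then averaged (arithmetic mean of raw ratios by default; geometric
    mean via ``log_mean=True``).  PSMs with reference intensity 0 are dropped
    with a warning; a set lacking a reference channel is an error.
    """
    ref_rows = sheet[sheet.tissue == "reference"]
    psm_sets = set(psms.set_id.unique())
    missing_ref = psm_sets - set(ref_rows.set_id)
    if missing_ref:
        raise ValueError(f"sets without a reference channel: {sorted(missing_ref)}")

    uniq = psms[psms["unique"].astype(bool)]
    ref_channel = dict(zip(ref_rows.set_id, ref_rows.channel))
    is_ref = uniq.channel == uniq.set_id.map(ref_channel).fillna(REFERENCE_CHANNEL)
    ref = uniq[is_ref].set_index(["set_id", "psm_id"]).intensity
    samp = uniq[~is_ref]

    ref_int = pd.MultiIndex.from_frame(samp[["set_id", "psm_id"]]).map(ref)
    ref_int = pd.Series(np.asarray(ref_int, dtype=float), index=samp.index)
    bad = ~(ref_int > 0)
    if bad.any():
        n_dropped = samp.loc[bad, "psm_id"].nunique()
        logger.warning("dropping %d PSMs with zero/missing reference intensity", n_dropped)
        samp, ref_int = samp[~bad], ref_int[~bad]

    sample_key = sheet[sheet.tissue != "reference"].set_index(["set_id", "channel"]).sample_id
    work = samp[["set_id", "channel", "protein_id", "psm_id"]].copy()
    work["ratio"] = samp.intensity.to_numpy() / ref_int.to_numpy()
    work["sample_id"] = pd.MultiIndex.from_frame(work[["set_id", "channel"]]).map(sample_key)
    work = work.dropna(subset=["sample_id"])
    if log_mean:
        work["ratio"] = np.log2(work["ratio"])
        agg = work.groupby(["protein_id", "sample_id"], sort=True).ratio.mean()
        agg = np.exp2(agg)
    else:
        agg = work.groupby(["protein_id", "sample_id"], sort=True).ratio.mean()
    ratios = agg.unstack("sample_id")

    counts = (
        work.drop_duplicates(["set_id", "protein_id", "psm_id"])
        .groupby(["protein_id", "set_id"], sort=True)
        .size()
        .unstack("set_id", fill_value=0)
        .reindex(ratios.index, fill_value=0)
    )
    sample_sets = sheet[sheet.tissue != "reference"].set_index("sample_id").set_id
    sample_sets = sample_sets.reindex(ratios.columns)
    # order samples as in the sheet
    order = [s for s in sheet.sample_id if s in ratios.columns]
    return ProteinMatrix(ratios=ratios[order], psm_counts=counts,
                         sample_sets=sample_sets[order])


def rank_invariance(matrix: ProteinMatrix, min_proteins: int = 10) -> pd.Series:
    """Rank fully covered proteins by invariance (1 = most invariant).

    The criterion is the variance of sample-median-centered log2 ratios: for
    the proteins quantified in every sample, each sample's log2 ratios are
    centered by that sample's median over the fully covered block (removing
    loading differences), and proteins are ranked by the variance of the
    centered values.  This is a variance-based stand-in for more elaborate
    invariance scores; downstream steps rely only on the ranking being a
    deterministic total order that is scale-invariant, which this criterion
    preserves.
    """
    full = matrix.ratios.dropna(axis=0)
    if len(full) < min_proteins:
        raise ValueError(
            f"only {len(full)} proteins with 100% sample coverage (< {min_proteins}); "
            "relax the coverage threshold or provide more data"
        )
    log = np.log2(full)
    centered = log - log.median(axis=0)
    variances = centered.var(axis=1, ddof=1)
    order = variances.sort_values(kind="mergesort").index
    rank = pd.Series(np.arange(1, len(order) + 1), index=order, name="invariance_rank")
    matrix.invariance_rank = rank
    return rank


def normalize_median_invariant(
    matrix: ProteinMatrix, subset_fraction: float = 0.40
) -> ProteinMatrix:
    """Divide each sample by its median ratio over the most invariant subset.

    The subset is the top ``subset_fraction`` of the invariance ranking
    (computed on demand).  After normalization every sample's median over the
    subset equals 1; within-sample relative ratios are unchanged.
    """
    out = matrix.copy()
    if out.invariance_rank.empty:
        rank_invariance(out)
    n_subset = max(1, int(round(subset_fraction * len(out.invariance_rank))))
    subset = out.invariance_rank.nsmallest(n_subset, keep="first").index.tolist()
    medians = out.ratios.loc[subset].median(axis=0)
    zero = medians[~(medians > 0)]
    if len(zero):
        raise ValueError(
            f"normalization-subset median is zero for sample(s) {list(zero.index)}"
        )
    out.ratios = out.ratios.div(medians, axis=1)
    out.normalization_subset = subset
    out.scaling_factors = medians.rename("scaling_factor")
    return out


def exclude_intensity_outliers(
    matrix: ProteinMatrix, fold_threshold: float = 8.0
) -> tuple[ProteinMatrix, list[str]]:
    """Drop samples whose median raw ratio is ``fold_threshold``-fold below peers.

    A sample is excluded when its median (non-normalized) ratio is below
    1/fold_threshold times the median of all other samples' medians.  Applied
    before normalization.
    """
    medians = matrix.ratios.median(axis=0)
    excluded = []
    for sample in matrix.ratios.columns:
        others = medians.drop(sample).median()
        if medians[sample] < others / fold_threshold:
            excluded.append(sample)
    if len(excluded) == len(matrix.ratios.columns):
        raise ValueError("outlier rule excluded every sample")
    out = matrix.copy()
    if excluded:
        logger.warning("excluding %d low-intensity outlier sample(s): %s",
                       len(excluded), excluded)
        out.ratios = out.ratios.drop(columns=excluded)
        out.sample_sets = out.sample_sets.drop(excluded)
    return out, excluded


def identification_counts(detected: pd.DataFrame) -> dict:
    """Distinct/shared protein counts and the shared-vs-#sets curve.

    ``detected`` is a proteins x sets boolean frame.  The curve entry at
    position i is the number of proteins detected in all of the first i+1
    sets (column order), which is non-increasing in i.
    """
    present_any = detected.any(axis=1)
    distinct = int(present_any.sum())
    shared_all = int(detected.all(axis=1).sum())
    curve = []
    running = np.ones(len(detected), dtype=bool)
    for col in detected.columns:
        running &= detected[col].to_numpy()
        curve.append(int(running.sum()))
    per_set = detected.sum(axis=0).astype(int).to_dict()
    return {"distinct": distinct, "shared_all_sets": shared_all,
            "shared_curve": curve, "per_set": per_set}


def merge_sets(matrices: list[ProteinMatrix]) -> tuple[ProteinMatrix, dict]:
    """Merge per-set matrices into one cohort matrix with identification stats."""
    all_samples: list[str] = []
    for m in matrices:
        for s in m.ratios.columns:
            if s in all_samples:
                raise ValueError(f"duplicate sample id across sets: {s}")
            all_samples.append(s)
    ratios = pd.concat([m.ratios for m in matrices], axis=1)
    counts = pd.concat([m.psm_counts for m in matrices], axis=1)
    counts = counts.T.groupby(level=0).sum().T.fillna(0).astype(int)
    counts = counts.reindex(ratios.index, fill_value=0)
    sample_sets = pd.concat([m.sample_sets for m in matrices])
    merged = ProteinMatrix(ratios=ratios, psm_counts=counts, sample_sets=sample_sets)
    return merged, identification_counts(merged.detected)


def preprocess_cohort(
    psms: pd.DataFrame,
    sheet: pd.DataFrame,
    subset_fraction: float = 0.40,
    fold_threshold: float = 8.0,
    log_mean: bool = False,
    deny_list: set[str] | None = None,
) -> tuple[ProteinMatrix, dict]:
    """Full preprocessing chain: ratios -> outlier exclusion -> normalization.

    ``deny_list`` optionally removes contaminant accessions before anything
    else.  Returns the normalized matrix and a report dict (identification
    counts, excluded samples, subset size, per-sample scaling factors).
    """
    matrix = psm_to_protein_ratios(psms, sheet, log_mean=log_mean)
    if deny_list:
        keep = [p for p in matrix.ratios.index if p not in deny_list]
        matrix.ratios = matrix.ratios.loc[keep]
        matrix.psm_counts = matrix.psm_counts.loc[keep]
    counts = identification_counts(matrix.detected)
    matrix, excluded = exclude_intensity_outliers(matrix, fold_threshold)
    normalized = normalize_median_invariant(matrix, subset_fraction)
    report = {
        "identification": counts,
        "excluded_samples": excluded,
        "normalization_subset_size": len(normalized.normalization_subset),
        "scaling_factors": normalized.scaling_factors.to_dict(),
    }
    return normalized, report
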