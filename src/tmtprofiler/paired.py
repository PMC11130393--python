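"""Sample-wise tumor/normal expression statistics against individualized nulls.

For every tumor sample with a paired normal, each protein's paired log2 ratio
a_{i,j} is tested against a pseudo-individual null distribution H(i): the log2
differences of the patient's normal sample versus every other normal sample in
the same multiplex set, across all proteins.  Because reporter-ratio variance
shrinks with the number of PSMs averaged, H(i) is first filtered to proteins
with a similar PSM count (the binning indicator B(p, p_j) = 1 iff
p_j/2 < p < 2*p_j).  The statistic is a_tilde = a / sd(filtered null) and the
p-value is the folded normal tail 1 - Phi(|a_tilde|), in (0, 0.5].  Calls are
directional: over if p < alpha and a > 0, under if p < alpha and a < 0.  Under
the null each *direction* is called at rate alpha (so over- and under-calls
together occur at 2*alpha); p-values are deliberately not corrected for
multiple testing - each tumor is tested against its own null, and cohort-level
conclusions rest on call frequencies across samples, not single tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ProteinMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "build_null",
    "psm_bin",
    "sample_statistic",
    "PairedExpressionModel",
    "PairedExpressionResults",
    "expression_rates",
    "rate_dispersion",
    "mean_fold_change",
    "pooled_differential_expression",
    "export_signatures",
]

#: default CMap-style signature list caps (service constraint)
SIGNATURE_CAP = 150


@dataclass
class NullDistribution:
    """Pooled healthy-vs-healthy log2 differences for one normal sample.

    ``values[k]`` is one log2 difference between the source sample and another
    normal sample of the same set for some protein; ``psm_tags[k]`` is that
    protein's PSM count in the set.
    """

    set_id: str
    source_sample: str
    values: np.ndarray
    psm_tags: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def build_null(matrix: ProteinMatrix, sheet: pd.DataFrame, sample: str) -> NullDistribution:
    """Build the pseudo-individual null for one normal-tissue sample."""
    info = sheet.set_index("sample_id")
    if info.loc[sample, "tissue"] != "normal":
        raise ValueError(f"{sample} is not a normal-tissue sample")
    set_id = info.loc[sample, "set_id"]
    normals = [
        s for s in info[(info.set_id == set_id) & (info.tissue == "normal")].index
        if s in matrix.ratios.columns
    ]
    others = [s for s in normals if s != sample]
    if not others:
        raise ValueError(
            f"set {set_id} has no other normal sample; the paired statistic is "
            f"undefined for the tumor paired with {sample}"
        )
    x_i = np.log2(matrix.ratios[sample].to_numpy(float))
    tags_all = matrix.psm_counts[set_id].to_numpy(int)
    values, tags = [], []
    for h in others:
        x_h = np.log2(matrix.ratios[h].to_numpy(float))
        ok = np.isfinite(x_i) & np.isfinite(x_h)
        values.append(x_i[ok] - x_h[ok])
        tags.append(tags_all[ok])
    return NullDistribution(
        set_id=set_id,
        source_sample=sample,
        values=np.concatenate(values),
        psm_tags=np.concatenate(tags),
    )


def psm_bin(
    null: NullDistribution | np.ndarray,
    p_j: int,
    lower: float = 0.5,
    upper: float = 2.0,
    tags: np.ndarray | None = None,
) -> np.ndarray:
    """Filter null values to proteins with a similar PSM count.

    Keeps values whose tag p satisfies the strict double inequality
    lower*p_j < p < upper*p_j; with the defaults this is the binning indicator
    B(p, p_j) = 1 iff p_j/2 < p < 2*p_j (so B(p_j, p_j) = 1 always).
    """
    if p_j < 1:
        raise ValueError("p_j must be a positive integer")
    if isinstance(null, NullDistribution):
        values, tags = null.values, null.psm_tags
    else:
        values = np.asarray(null)
        if tags is None:
            raise ValueError("tags required when passing a raw value array")
    mask = (tags > lower * p_j) & (tags < upper * p_j)
    return values[mask]


def sample_statistic(
    a_ij: float,
    filtered_null: np.ndarray,
    ddof: int = 1,
    center: bool = False,
) -> tuple[float, float]:
    """Normalize a paired log2 ratio by the filtered null sd; folded-tail p.

    Returns (a_tilde, pvalue) with a_tilde = a_ij / sd(filtered null) and
    pvalue = 1 - Phi(|a_tilde|), in (0, 0.5].  When the null sd is zero or the
    null is too small to estimate it, the statistic is undefined and (nan, nan)
    is returned - an undefined statistic is never reported as significant.
    """
    vals = np.asarray(filtered_null, float)
    if len(vals) <= ddof:
        return np.nan, np.nan
    sd = float(np.std(vals, ddof=ddof))
    if not np.isfinite(sd) or sd == 0.0:
        return np.nan, np.nan
    shift = float(np.mean(vals)) if center else 0.0
    a_tilde = (a_ij - shift) / sd
    pvalue = float(stats.norm.sf(abs(a_tilde)))
    return float(a_tilde), pvalue


def _pair_map(sheet: pd.DataFrame) -> list[tuple[str, str]]:
    """(tumor sample, paired normal sample) couples from the sheet."""
    paired = sheet[sheet.pair_id.astype(str) != ""]
    out = []
    for pid, grp in paired.groupby("pair_id", sort=True):
        tumors = grp[grp.tissue == "tumor"].sample_id.tolist()
        normals = grp[grp.tissue == "normal"].sample_id.tolist()
        if len(tumors) == 1 and len(normals) == 1:
            out.append((tumors[0], normals[0]))
    return out


class PairedExpressionModel:
    """Per-sample over/underexpression model with PSM-binned individual nulls.

    Parameters
    ----------
    matrix : normalized ProteinMatrix.
    sheet : sample sheet with tissue and pair_id columns.
    n_min : minimum filtered-null size to estimate the sd; below it the PSM
        bin is widened once (bounds doubled to p_j/4 .. 4*p_j) and if the null
        is still smaller the statistic is reported as undefined.
    ddof : degrees-of-freedom correction of the null sd estimate.
    center : subtract the null mean before normalizing (off by default; the
        statistic normalizes by spread only).
    """

    def __init__(
        self,
        matrix: ProteinMatrix,
        sheet: pd.DataFrame,
        n_min: int = 5,
        ddof: int = 1,
        center: bool = False,
    ):
        self.matrix = matrix
        self.sheet = sheet
        self.n_min = n_min
        self.ddof = ddof
        self.center = center

    def fit(self, alpha: float = 0.05) -> "PairedExpressionResults":
        matrix, sheet = self.matrix, self.sheet
        log_ratios = np.log2(matrix.ratios)
        proteins = matrix.ratios.index.to_numpy()
        rows = []
        null_cache: dict[str, NullDistribution] = {}
        sd_cache: dict[tuple[str, int], tuple[float, float, int]] = {}

        for tumor, normal in _pair_map(sheet):
            if tumor not in log_ratios.columns or normal not in log_ratios.columns:
                continue
            try:
                null = null_cache.get(normal)
                if null is None:
                    null = build_null(matrix, sheet, normal)
                    null_cache[normal] = null
            except ValueError as err:
                logger.warning("skipping pair (%s, %s): %s", tumor, normal, err)
                continue
            set_id = null.set_id
            a_vec = (log_ratios[tumor] - log_ratios[normal]).to_numpy(float)
            tags = matrix.psm_counts[set_id].to_numpy(int)
            defined = np.isfinite(a_vec)
            order = np.argsort(null.psm_tags, kind="mergesort")
            null_tags_sorted = null.psm_tags[order]
            null_vals_sorted = null.values[order]

            for idx in np.where(defined)[0]:
                p_j = int(tags[idx])
                key = (normal, p_j)
                cached = sd_cache.get(key)
                if cached is None:
                    cached = self._null_sd(null_vals_sorted, null_tags_sorted, p_j)
                    sd_cache[key] = cached
                sd, shift, n_null = cached
                a = a_vec[idx]
                if n_null == 0 or sd == 0.0 or not np.isfinite(sd):
                    a_t, p = np.nan, np.nan
                else:
                    a_t = (a - shift) / sd
                    p = float(stats.norm.sf(abs(a_t)))
                if np.isfinite(p) and p < alpha:
                    call = "over" if a > 0 else ("under" if a < 0 else "none")
                else:
                    call = "none"
                rows.append((tumor, str(proteins[idx]), a, a_t, p, call, n_null))

        profiles = pd.DataFrame(
            rows,
            columns=["sample_id", "protein_id", "a", "a_tilde", "pvalue", "call",
                     "null_size"],
        )
        profiles["fold_change"] = np.exp2(profiles["a"])
        return PairedExpressionResults(self, profiles, alpha)

    def _null_sd(
        self, vals_sorted: np.ndarray, tags_sorted: np.ndarray, p_j: int
    ) -> tuple[float, float, int]:
        """(sd, center shift, n) of the PSM-binned null, widening the bin once."""
        for lower, upper in ((0.5, 2.0), (0.25, 4.0)):
            lo = np.searchsorted(tags_sorted, lower * p_j, side="right")
            hi = np.searchsorted(tags_sorted, upper * p_j, side="left")
            vals = vals_sorted[lo:hi]
            if len(vals) >= self.n_min:
                sd = float(np.std(vals, ddof=self.ddof))
                shift = float(np.mean(vals)) if self.center else 0.0
                return sd, shift, len(vals)
        return np.nan, 0.0, 0


class PairedExpressionResults:
    """Fitted paired expression profiles and derived cohort summaries."""

    def __init__(self, model: PairedExpressionModel, profiles: pd.DataFrame, alpha: float):
        self.model = model
        self.profiles = profiles
        self.alpha = alpha

    def expression_rates(self, grouping: pd.Series) -> pd.DataFrame:
        return expression_rates(self.profiles, grouping)

    def rate_dispersion(self, grouping: pd.Series, ddof: int = 0) -> pd.Series:
        return rate_dispersion(self.expression_rates(grouping), ddof=ddof)

    def mean_fold_change(self) -> pd.Series:
        return mean_fold_change(self.profiles)

    def export_signatures(self, corr_table: pd.DataFrame, rho_min: float = 0.75,
                          cap: int = SIGNATURE_CAP) -> dict[str, tuple[list[str], list[str]]]:
        return export_signatures(self.profiles, corr_table, rho_min=rho_min, cap=cap)

    def summary(self) -> pd.DataFrame:
        """Per-sample tested/over/under counts at the fitted alpha."""
        prof = self.profiles
        evaluable = prof[np.isfinite(prof.pvalue)]
        out = evaluable.groupby("sample_id").agg(
            n_tested=("protein_id", "size"),
            n_over=("call", lambda c: int((c == "over").sum())),
            n_under=("call", lambda c: int((c == "under").sum())),
        )
        out["over_fraction"] = out.n_over / out.n_tested
        out["under_fraction"] = out.n_under / out.n_tested
        return out


def expression_rates(profiles: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Per (protein, group) over/under call rates among evaluable samples.

    ``grouping`` maps sample -> subset label (e.g. stage or cluster).  Samples
    without a label and non-evaluable (undefined-statistic) rows are ignored;
    a group with no evaluable sample for a protein simply yields no row.
    """
    prof = profiles[np.isfinite(profiles.pvalue)].copy()
    prof["group"] = prof.sample_id.map(grouping)
    prof = prof.dropna(subset=["group"])
    grouped = prof.groupby(["protein_id", "group"], sort=True)
    out = grouped.agg(
        n_evaluable=("call", "size"),
        over_rate=("call", lambda c: (c == "over").mean()),
        under_rate=("call", lambda c: (c == "under").mean()),
    )
    return out


def rate_dispersion(rates: pd.DataFrame, ddof: int = 0) -> pd.Series:
    """Per-protein variance of group-wise overexpression rates.

    Population variance (ddof=0) by convention; proteins present in fewer
    than 2 groups are dropped.
    """
    wide = rates.over_rate.unstack("group")
    wide = wide[wide.notna().sum(axis=1) >= 2]
    return wide.var(axis=1, ddof=ddof).rename("rate_variance")


def mean_fold_change(profiles: pd.DataFrame) -> pd.Series:
    """Mean linear fold change per protein over samples with a significant call."""
    called = profiles[profiles.call.isin(["over", "under"])]
    return called.groupby("protein_id").fold_change.mean().rename("mean_fold_change")


def pooled_differential_expression(
    matrix: ProteinMatrix,
    group_a: list[str],
    group_b: list[str],
    coverage: float = 0.20,
) -> pd.DataFrame:
    """Group-wise rank-sum differential expression with BH correction.

    Proteins with at least ``coverage`` non-missing fraction across the pooled
    groups are tested with a two-sided Mann-Whitney U on log2 ratios; p-values
    are Benjamini-Hochberg corrected.  Proteins with fewer than 2 values in
    either group are skipped.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    pooled = matrix.ratios[list(group_a) + list(group_b)]
    frac = pooled.notna().mean(axis=1)
    tested = pooled[frac >= coverage]
    log = np.log2(tested)
    rows = []
    for prot, vals in log.iterrows():
        va = vals[group_a].dropna().to_numpy()
        vb = vals[group_b].dropna().to_numpy()
        if len(va) < 2 or len(vb) < 2:
            continue
        stat_res = stats.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append((prot, float(np.mean(va) - np.mean(vb)), float(stat_res.pvalue)))
    out = pd.DataFrame(rows, columns=["protein_id", "log2_fc", "pvalue"]).set_index("protein_id")
    if len(out):
        out["qvalue"] = multipletests(out.pvalue, method="fdr_bh")[1]
    else:
        out["qvalue"] = pd.Series(dtype=float)
    return out


def export_signatures(
    profiles: pd.DataFrame,
    corr_table: pd.DataFrame,
    rho_min: float = 0.75,
    cap: int = SIGNATURE_CAP,
) -> dict[str, tuple[list[str], list[str]]]:
    """Correlation-filtered qualitative up/down signatures per tumor sample.

    Significant over-calls with tabulated protein-mRNA correlation >= rho_min
    form the up list, under-calls the down list, each truncated to ``cap``
    entries by ascending p-value.  Samples with both lists empty are skipped
    with a warning.  Lists are disjoint by construction (a call is either over
    or under).
    """
    rho = corr_table.set_index("feature").rho
    out: dict[str, tuple[list[str], list[str]]] = {}
    for sample, grp in profiles.groupby("sample_id", sort=True):
        keep = grp[grp.protein_id.map(rho).fillna(-np.inf) >= rho_min]
        up = keep[keep.call == "over"].nsmallest(cap, "pvalue").protein_id.tolist()
        down = keep[keep.call == "under"].nsmallest(cap, "pvalue").protein_id.tolist()
        if not up and not down:
            logger.warning("sample %s has no correlation-filtered calls; skipped", sample)
            continue
        out[sample] = (up, down)
    return out


def write_grp_signatures(signatures: dict, out_dir) -> None:
    """Write per-sample .up/.dn GRP files (one identifier per line)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sample, (up, down) in signatures.items():
        (out / f"{sample}.up.grp").write_text("\n".join(up) + "\n")
        (out / f"{sample}.dn.grp").write_text("\n".join(down) + "\n")
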