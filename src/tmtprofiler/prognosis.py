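"""Ordinal risk encoding, the combined prognostic score, and survival contracts.

Histopathological stage groups and proteomic clusters are treated as
quasi-continuous ordinal variables ordered by prognosis.  The combined score
normalizes the cluster code (1..5) and the stage code (1..6) and combines
them, by default multiplicatively:

    S = (S_cluster / 5) * (S_stage / 6)        (product mode, S in [1/30, 1])
    S = S_cluster / 5 + S_stage / 6            (sum mode, alternative reading)

Kaplan-Meier stratification, log-rank tests, restricted-mean survival
differences and Cox proportional-hazards fits are delegated to lifelines;
this module fixes the encodings, the restriction horizon (default 24 months)
and the AIC comparison between separate-covariate and combined-score models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time

__all__ = [
    "encode_ordinal",
    "combined_score",
    "stratify_survival",
    "cox_ordinal",
    "PrognosticModel",
]

#: default stage pooling: everything at or above pT2 collapses into one group
DEFAULT_STAGE_POOLING = {"pT2": "pT2+", "pT3": "pT2+", "pT3+": "pT2+", "pT4": "pT2+"}


def encode_ordinal(groups: pd.Series, ordering: list[str]) -> pd.Series:
    """Map group labels to integer codes 1..m following the prognostic order."""
    lookup = {label: i + 1 for i, label in enumerate(ordering)}
    unknown = set(groups.dropna()) - set(lookup)
    if unknown:
        raise ValueError(f"labels not in the supplied ordering: {sorted(unknown)}")
    return groups.map(lookup).astype("Int64")


def combined_score(
    s_cluster, s_stage, mode: str = "product",
    n_cluster: int = 5, n_stage: int = 6,
):
    """Combined prognostic score from cluster and stage codes.

    product mode: S = (s_cluster/n_cluster) * (s_stage/n_stage);
    sum mode:     S = s_cluster/n_cluster + s_stage/n_stage.
    Codes must lie in 1..n_cluster and 1..n_stage respectively.
    """
    sc = np.asarray(s_cluster, float)
    st = np.asarray(s_stage, float)
    if np.any((sc < 1) | (sc > n_cluster)) or np.any((st < 1) | (st > n_stage)):
        raise ValueError("ordinal codes out of range")
    if mode == "product":
        out = (sc / n_cluster) * (st / n_stage)
    elif mode == "sum":
        out = sc / n_cluster + st / n_stage
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.ndim else float(out)


def stratify_survival(
    times: pd.Series,
    events: pd.Series,
    groups: pd.Series,
    horizon: float = 24.0,
) -> dict:
    """Kaplan-Meier medians per group, log-rank p, restricted-mean differences.

    Medians that are never reached are reported as inf (open-ended).  The
    restricted mean survival time (RMST) is evaluated at ``horizon`` (default
    two years in months); pairwise differences are returned for every group
    couple.
    """
    df = pd.DataFrame({"time": times, "event": events, "group": groups}).dropna()
    if (df.time <= 0).any():
        raise ValueError("survival times must be positive")
    if df.group.nunique() < 2:
        raise ValueError("need >= 2 groups with subjects")
    medians, rmst = {}, {}
    for g, grp in df.groupby("group", sort=True):
        if len(grp) == 0:
            raise ValueError(f"group {g} has no subjects")
        km = KaplanMeierFitter().fit(grp.time, grp.event)
        medians[g] = float(km.median_survival_time_)
        rmst[g] = float(restricted_mean_survival_time(km, t=horizon))
    lr = multivariate_logrank_test(df.time, df.group, df.event)
    names = sorted(medians)
    rmst_diff = {
        f"{a} vs {b}": rmst[a] - rmst[b]
        for i, a in enumerate(names) for b in names[i + 1:]
    }
    return {
        "median_survival": medians,
        "logrank_p": float(lr.p_value),
        "rmst": rmst,
        "rmst_difference": rmst_diff,
        "horizon": horizon,
    }


def cox_ordinal(
    df: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: list[str] | None = None,
) -> dict:
    """Cox fit with per-unit hazard ratios, 95% CIs and the partial AIC.

    Covariates are used as supplied (ordinal codes enter as quasi-continuous
    numbers).  Constant covariates are rejected before fitting.
    """
    covariates = covariates or [c for c in df.columns
                                if c not in (duration_col, event_col)]
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c} is constant")
    fit_df = df[[duration_col, event_col] + covariates].dropna().astype(float)
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col=duration_col, event_col=event_col)
    summary = cph.summary
    return {
        "hazard_ratios": summary["exp(coef)"].to_dict(),
        "ci_lower": summary["exp(coef) lower 95%"].to_dict(),
        "ci_upper": summary["exp(coef) upper 95%"].to_dict(),
        "coef": summary["coef"].to_dict(),
        "aic": float(cph.AIC_partial_),
        "fitter": cph,
    }


@dataclass
class PrognosticModel:
    """Ordinal-risk survival model comparing separate and combined encodings.

    Parameters
    ----------
    data : frame with survival columns plus cluster and stage labels.
    cluster_order, stage_order : prognostic orderings (best to worst).
    stage_pooling : label remapping applied before encoding (default pools
        muscle-invasive stages into one group).
    """

    data: pd.DataFrame
    cluster_order: list[str]
    stage_order: list[str]
    time_col: str = "time"
    event_col: str = "event"
    cluster_col: str = "cluster"
    stage_col: str = "stage"
    stage_pooling: dict | None = None

    def encoded(self) -> pd.DataFrame:
        df = self.data.copy()
        stages = df[self.stage_col]
        if self.stage_pooling:
            stages = stages.replace(self.stage_pooling)
        df["s_cluster"] = encode_ordinal(df[self.cluster_col], self.cluster_order)
        df["s_stage"] = encode_ordinal(stages, self.stage_order)
        return df

    def fit(self, mode: str = "product") -> dict:
        """Separate-covariate and combined-score Cox fits with AICs.

        Returns a dict with the two fits and the combined-score column used;
        the score mode is recorded in the output metadata.
        """
        df = self.encoded().dropna(subset=["s_cluster", "s_stage"])
        df = df.astype({"s_cluster": float, "s_stage": float})
        df["combined"] = combined_score(
            df.s_cluster, df.s_stage, mode=mode,
            n_cluster=len(self.cluster_order), n_stage=len(self.stage_order),
        )
        separate = cox_ordinal(df, self.time_col, self.event_col,
                               ["s_cluster", "s_stage"])
        combined = cox_ordinal(df, self.time_col, self.event_col, ["combined"])
        return {
            "mode": mode,
            "separate": separate,
            "combined": combined,
            "aic_separate": separate["aic"],
            "aic_combined": combined["aic"],
            "scores": df["combined"],
        }

    def stratify(self, by: str = "cluster", horizon: float = 24.0) -> dict:
        col = self.cluster_col if by == "cluster" else self.stage_col
        return stratify_survival(self.data[self.time_col], self.data[self.event_col],
                                 self.data[col], horizon=horizon)
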