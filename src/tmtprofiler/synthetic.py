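"""Synthetic multiplexed (TMT) paired tumor/normal cohorts with known ground truth.

Emulates the statistical structure of a multi-set isobaric-label proteomics
cohort: ~dozens of TMT sets of up to 16 channels, one pooled reference channel
(tag 134N) per set, paired tumor/normal samples kept within a set, heavy-tailed
per-(protein, set) PSM counts, protein-wise between-set missingness with a
common detected core, latent molecular subtypes with signed protein signatures,
subtype-dependent exponential survival, and a correlated mRNA layer with
per-gene protein-mRNA correlation targets.

The generative model on the log2 scale, for protein j in sample channel i of
set s with m PSMs:

    log2 I(psm, i) = b_j + o_psm + s_i + delta_{i,j} + eps(psm, i)

where b_j is the protein baseline, o_psm a per-PSM ionisation offset (shared
across channels, cancelling in reporter ratios), s_i a per-sample loading
offset, delta the signed subtype-signature effect (tumor channels only) and
eps ~ N(0, noise_sd^2) independent measurement noise per (PSM, channel).  The
reference channel is a pooled sample: its clean level is the log2 of the
cohort-wide mean linear intensity of the protein, plus per-(protein, set)
lognormal pooling noise and per-PSM measurement noise.  Because averaging the
m per-PSM ratios shrinks the protein-level noise like 1/sqrt(m), the variance
of paired log-ratios genuinely depends on the PSM count - the structure the
PSM-binned null distribution downstream is designed to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "simulate_cohort",
    "simulate_mrna_layer",
    "TMT_CHANNELS",
    "REFERENCE_CHANNEL",
    "STAGE_LABELS",
]

# TMTpro 16-plex reporter tags; the last one is reserved for the pooled reference.
TMT_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
)
REFERENCE_CHANNEL = "134N"

# Pathological stage groups in prognostic order (>=pT2 progressively pooled upstream).
STAGE_LABELS = ("pTa-LG", "pTa-HG", "pTis", "pT1", "pT2", "pT3+")


class InvalidSpecError(ValueError):
    """Raised when a cohort specification cannot host the required channels."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated multiplexed cohort.

    Defaults approximate the cohort scale of a large paired urothelial-cancer
    study: 29 sets of 16 channels, ~9500 distinct proteins of which roughly a
    quarter form a core detected in every set, five latent subtypes, and ~80%
    of tumors with a paired normal.
    """

    n_sets: int = 29
    channels_per_set: int = 16
    n_proteins: int = 9500
    common_core_fraction: float = 0.26
    n_subtypes: int = 5
    signature_size: int = 30
    signature_effect: float = 1.0
    noise_sd: float = 0.3
    #: ("powerlaw", exponent, cap): P(m) ~ m**-exponent on 1..cap
    psm_count_law: tuple = ("powerlaw", 1.8, 200)
    pair_fraction: float = 0.8
    survival_hazard_ratios: tuple = (1.0, 1.4, 1.8, 1.4, 3.8)
    censoring_rate: float = 0.4
    #: per-gene protein-mRNA Spearman correlation law: ("point", rho) |
    #: ("uniform", lo, hi) | ("beta", a, b)
    mrna_correlation_law: tuple = ("beta", 5.0, 3.0)
    seed: int = 0
    # secondary knobs ------------------------------------------------------
    #: sd of per-sample loading offsets; None ties it to noise_sd so a single
    #: knob controls all technical variability
    sample_scale_sd: float | None = None
    #: per-set detection probability of non-core proteins
    detect_prob: float = 0.55
    #: extra biological tumor heterogeneity beyond the subtype signature
    tumor_bio_sd: float = 0.0
    #: fraction of additional decoy PSM rows flagged non-unique
    nonunique_fraction: float = 0.05
    baseline_log2_mean: float = 16.0
    baseline_log2_sd: float = 1.5
    #: baseline hazard such that a hazard-ratio-1 subtype has ~60 month median
    baseline_hazard: float = np.log(2) / 60.0

    def validate(self) -> None:
        if self.channels_per_set < 3:
            raise InvalidSpecError(
                "channels_per_set must be >= 3 (reference + one tumor/normal pair)"
            )
        if self.channels_per_set > len(TMT_CHANNELS):
            raise InvalidSpecError(
                f"channels_per_set must be <= {len(TMT_CHANNELS)} (TMTpro plex limit)"
            )
        for name in ("n_sets", "n_proteins", "n_subtypes", "signature_size"):
            if getattr(self, name) < 1:
                raise InvalidSpecError(f"{name} must be >= 1")
        for name in ("common_core_fraction", "pair_fraction", "censoring_rate",
                     "detect_prob", "nonunique_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name}={v} must lie in [0, 1]")
        if not np.isfinite(self.signature_effect):
            raise InvalidSpecError("signature_effect must be finite")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if len(self.survival_hazard_ratios) < self.n_subtypes:
            raise InvalidSpecError(
                "survival_hazard_ratios must provide one multiplier per subtype"
            )
        if self.n_subtypes * self.signature_size > self.n_proteins:
            raise InvalidSpecError("signatures cannot exceed the proteome size")

    @property
    def effective_scale_sd(self) -> float:
        return self.noise_sd if self.sample_scale_sd is None else self.sample_scale_sd


@dataclass
class GroundTruth:
    """Truth channel of a simulated cohort, for parameter-recovery tests."""

    subtype_of_sample: dict[str, int]
    #: subtype -> list of signature protein ids
    signature_proteins: dict[int, list[str]]
    #: (subtype, protein) -> +1 (overexpressed) or -1 (underexpressed)
    signature_direction: dict[tuple[int, str], int]
    true_survival_params: dict[int, float]
    #: realized clean+noise log2 tumor intensities (proteins x tumor samples)
    tumor_log2: pd.DataFrame
    #: per-protein true measurement sd at the protein level, per set
    stage_of_sample: dict[str, str] = field(default_factory=dict)

    def expected_call(self, sample: str, protein: str) -> str:
        """Planted direction {'over','under','none'} for a (tumor sample, protein)."""
        subtype = self.subtype_of_sample.get(sample)
        if subtype is None:
            return "none"
        d = self.signature_direction.get((subtype, protein))
        if d is None:
            return "none"
        return "over" if d > 0 else "under"

    def true_calls_frame(self) -> pd.DataFrame:
        """All non-'none' planted calls as a tidy frame."""
        rows = []
        for sample, subtype in sorted(self.subtype_of_sample.items()):
            for prot in self.signature_proteins[subtype]:
                d = self.signature_direction[(subtype, prot)]
                rows.append((sample, prot, "over" if d > 0 else "under"))
        return pd.DataFrame(rows, columns=["sample_id", "protein_id", "call"])


def _truncated_power_law(rng: np.random.Generator, size: int,
                         exponent: float, cap: int) -> np.ndarray:
    support = np.arange(1, cap + 1)
    probs = support.astype(float) ** (-exponent)
    probs /= probs.sum()
    return rng.choice(support, size=size, p=probs)


def _draw_correlations(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "point":
        return np.full(size, float(law[1]))
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=size)
    if kind == "beta":
        return rng.beta(law[1], law[2], size=size)
    raise ValueError(f"unknown correlation law {law!r}")


def _set_layout(spec: CohortSpec) -> tuple[int, int]:
    """(n_tumors, n_paired_normals) per set honoring pair_fraction."""
    usable = spec.channels_per_set - 1
    n_tumor = max(1, int(round(usable / (1.0 + spec.pair_fraction))))
    n_normal = min(usable - n_tumor, int(round(n_tumor * spec.pair_fraction)))
    return n_tumor, n_normal


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a PSM table, a sample sheet and the ground truth.

    Returns
    -------
    psms : DataFrame with columns (set_id, channel, protein_id, psm_id,
        intensity, unique) - one row per PSM x channel.
    sheet : DataFrame with columns (sample_id, patient_id, set_id, channel,
        tissue, pair_id, subset_label, time, event); tissue is one of
        {tumor, normal, reference}.
    truth : GroundTruth
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    protein_ids = np.array([f"P{i:05d}" for i in range(spec.n_proteins)])
    n_core = int(round(spec.common_core_fraction * spec.n_proteins))
    core_mask = np.zeros(spec.n_proteins, dtype=bool)
    core_idx = rng.choice(spec.n_proteins, size=n_core, replace=False)
    core_mask[core_idx] = True

    # detection: core in every set; non-core Bernoulli per set, never all sets
    detected = np.zeros((spec.n_proteins, spec.n_sets), dtype=bool)
    detected[core_mask, :] = True
    noncore = np.where(~core_mask)[0]
    if noncore.size and spec.n_sets > 1:
        draws = rng.random((noncore.size, spec.n_sets)) < spec.detect_prob
        full = draws.all(axis=1)
        if full.any():
            drop_set = rng.integers(0, spec.n_sets, size=int(full.sum()))
            draws[np.where(full)[0], drop_set] = False
        detected[noncore, :] = draws
    elif noncore.size:
        # single set: non-core proteins cannot be "shared across all sets",
        # so they are simply absent
        detected[noncore, 0] = False

    # subtype signatures drawn from the core so they are visible in every set
    sig_pool = rng.permutation(core_idx)[: spec.n_subtypes * spec.signature_size]
    signature_proteins: dict[int, list[str]] = {}
    signature_direction: dict[tuple[int, str], int] = {}
    delta_template = np.zeros((spec.n_subtypes, spec.n_proteins))
    for st in range(spec.n_subtypes):
        idx = sig_pool[st * spec.signature_size: (st + 1) * spec.signature_size]
        signs = np.where(np.arange(idx.size) % 2 == 0, 1.0, -1.0)
        delta_template[st, idx] = signs * spec.signature_effect
        signature_proteins[st] = [str(p) for p in protein_ids[idx]]
        for p, sg in zip(protein_ids[idx], signs):
            signature_direction[(st, str(p))] = int(sg)

    baselines = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd,
                           size=spec.n_proteins)

    # ----- sample sheet ---------------------------------------------------
    n_tumor_per_set, n_normal_per_set = _set_layout(spec)
    scale_sd = spec.effective_scale_sd
    hazards = np.asarray(spec.survival_hazard_ratios[: spec.n_subtypes], float)

    sheet_rows = []
    sample_meta = []           # (sample_id, set_index, tissue, subtype, delta_row)
    tumor_counter = 0
    patient_counter = 0
    for s in range(spec.n_sets):
        set_id = f"set{s + 1:02d}"
        sample_channels = list(TMT_CHANNELS[: spec.channels_per_set - 1])
        ch_iter = iter(sample_channels)
        for t in range(n_tumor_per_set):
            paired = t < n_normal_per_set
            patient_counter += 1
            tumor_counter += 1
            patient = f"PT{patient_counter:04d}"
            subtype = int(rng.integers(0, spec.n_subtypes))
            stage_p = 0.15 + 0.65 * (hazards[subtype] - hazards.min()) / max(
                hazards.max() - hazards.min(), 1e-12)
            stage = STAGE_LABELS[int(rng.binomial(len(STAGE_LABELS) - 1, stage_p))]
            # exponential survival with per-subtype hazard, uniform censoring
            t_true = rng.exponential(1.0 / (spec.baseline_hazard * hazards[subtype]))
            if rng.random() < spec.censoring_rate:
                time, event = rng.uniform(0.0, t_true), 0
            else:
                time, event = t_true, 1
            pair_id = f"pair{tumor_counter:04d}" if paired else ""
            tum_id = f"T{tumor_counter:04d}"
            sheet_rows.append((tum_id, patient, set_id, next(ch_iter), "tumor",
                               pair_id, stage, round(float(time), 2), event))
            sample_meta.append((tum_id, s, "tumor", subtype))
            if paired:
                nrm_id = f"N{tumor_counter:04d}"
                sheet_rows.append((nrm_id, patient, set_id, next(ch_iter), "normal",
                                   pair_id, stage, round(float(time), 2), event))
                sample_meta.append((nrm_id, s, "normal", subtype))
        sheet_rows.append((f"REF_{set_id}", "POOL", set_id, REFERENCE_CHANNEL,
                           "reference", "", "", np.nan, 0))
    sheet = pd.DataFrame(sheet_rows, columns=[
        "sample_id", "patient_id", "set_id", "channel", "tissue", "pair_id",
        "subset_label", "time", "event"])

    # per-sample loading offsets and clean log2 levels --------------------
    n_samples = len(sample_meta)
    s_offsets = rng.normal(0.0, scale_sd, size=n_samples) if scale_sd > 0 else np.zeros(n_samples)
    clean = np.empty((n_samples, spec.n_proteins))
    subtype_of_sample: dict[str, int] = {}
    for row, (sid, s, tissue, subtype) in enumerate(sample_meta):
        d = delta_template[subtype] if tissue == "tumor" else 0.0
        clean[row] = baselines + s_offsets[row] + d
        if tissue == "tumor":
            subtype_of_sample[sid] = subtype
            if spec.tumor_bio_sd > 0:
                clean[row] += rng.normal(0.0, spec.tumor_bio_sd, spec.n_proteins)

    # pooled reference level: cohort-wide mean linear intensity per protein
    pool_log2 = np.log2(np.mean(np.exp2(clean), axis=0))

    # ----- PSM table, one set at a time ----------------------------------
    law_kind, psm_exponent, psm_cap = spec.psm_count_law
    if law_kind != "powerlaw":
        raise InvalidSpecError(f"unknown psm_count_law {spec.psm_count_law!r}")
    sample_rows_by_set: dict[int, list[int]] = {s: [] for s in range(spec.n_sets)}
    for row, (_, s, _, _) in enumerate(sample_meta):
        sample_rows_by_set[s].append(row)

    frames = []
    for s in range(spec.n_sets):
        set_id = f"set{s + 1:02d}"
        prot_idx = np.where(detected[:, s])[0]
        if prot_idx.size == 0:
            continue
        m = _truncated_power_law(rng, prot_idx.size, psm_exponent, int(psm_cap))
        prot_rep = np.repeat(prot_idx, m)            # one entry per PSM
        n_psm = prot_rep.size
        psm_offsets = rng.normal(0.0, 1.0, size=n_psm)
        pool_noise = rng.normal(0.0, spec.noise_sd, size=prot_idx.size)
        pool_rep = np.repeat(pool_noise, m)

        rows = sample_rows_by_set[s]
        set_sheet = sheet[(sheet.set_id == set_id) & (sheet.tissue != "reference")]
        channels = set_sheet.channel.to_numpy()
        n_ch = len(rows)
        # (n_psm, n_ch) log2 intensities for sample channels
        base = clean[rows][:, prot_rep].T + psm_offsets[:, None]
        if spec.noise_sd > 0:
            base = base + rng.normal(0.0, spec.noise_sd, size=(n_psm, n_ch))
        ref = pool_log2[prot_rep] + psm_offsets + pool_rep
        if spec.noise_sd > 0:
            ref = ref + rng.normal(0.0, spec.noise_sd, size=n_psm)

        psm_ids = np.array([f"{set_id}_psm{i:06d}" for i in range(n_psm)])
        all_channels = np.concatenate([channels, [REFERENCE_CHANNEL]])
        inten = np.concatenate([np.exp2(base), np.exp2(ref)[:, None]], axis=1)
        frames.append(pd.DataFrame({
            "set_id": np.repeat(set_id, n_psm * (n_ch + 1)),
            "channel": np.tile(all_channels, n_psm),
            "protein_id": np.repeat(protein_ids[prot_rep], n_ch + 1),
            "psm_id": np.repeat(psm_ids, n_ch + 1),
            "intensity": inten.ravel(),
            "unique": 1,
        }))
        # decoy non-unique PSMs that downstream code must ignore
        n_decoy = int(round(spec.nonunique_fraction * n_psm))
        if n_decoy:
            pick = rng.choice(n_psm, size=n_decoy, replace=False)
            decoy_int = np.exp2(base[pick] + rng.normal(2.0, 1.0, size=(n_decoy, n_ch)))
            decoy_ref = np.exp2(ref[pick])
            frames.append(pd.DataFrame({
                "set_id": np.repeat(set_id, n_decoy * (n_ch + 1)),
                "channel": np.tile(all_channels, n_decoy),
                "protein_id": np.repeat(protein_ids[prot_rep[pick]], n_ch + 1),
                "psm_id": np.repeat(
                    np.array([f"{set_id}_nu{i:06d}" for i in range(n_decoy)]), n_ch + 1),
                "intensity": np.concatenate([decoy_int, decoy_ref[:, None]], axis=1).ravel(),
                "unique": 0,
            }))
    psms = pd.concat(frames, ignore_index=True)

    tumor_rows = [i for i, meta in enumerate(sample_meta) if meta[2] == "tumor"]
    tumor_ids = [sample_meta[i][0] for i in tumor_rows]
    # protein-level realized tumor log2 values (loading offset + signature + noise)
    tum_log2 = clean[tumor_rows].T
    if spec.noise_sd > 0:
        tum_log2 = tum_log2 + rng.normal(0.0, spec.noise_sd, size=tum_log2.shape)
    tumor_log2 = pd.DataFrame(tum_log2, index=protein_ids, columns=tumor_ids)

    truth = GroundTruth(
        subtype_of_sample=subtype_of_sample,
        signature_proteins=signature_proteins,
        signature_direction=signature_direction,
        true_survival_params={i: float(h) for i, h in enumerate(hazards)},
        tumor_log2=tumor_log2,
        stage_of_sample=dict(zip(sheet.sample_id, sheet.subset_label)),
    )
    return psms, sheet, truth


def simulate_mrna_layer(
    truth: GroundTruth,
    corr_law: tuple = ("beta", 5.0, 3.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an mRNA layer correlated gene-wise with the protein layer.

    Per gene a target Spearman correlation rho is drawn from ``corr_law``; the
    mRNA values are a Gaussian mixture of the standardized protein values and
    independent noise with the Pearson weight 2*sin(pi*rho/6) that yields the
    target Spearman correlation under bivariate normality.

    Returns (mrna matrix genes x samples, correlation table with the drawn
    target per gene).
    """
    rng = np.random.default_rng(seed)
    prot = truth.tumor_log2
    rho_s = _draw_correlations(rng, corr_law, prot.shape[0])
    rho_pearson = np.clip(2.0 * np.sin(np.pi * rho_s / 6.0), -1.0, 1.0)

    vals = prot.to_numpy(float)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd
    noise = rng.normal(size=vals.shape)
    mrna = rho_pearson[:, None] * z + np.sqrt(1.0 - rho_pearson[:, None] ** 2) * noise
    mrna_df = pd.DataFrame(mrna, index=prot.index, columns=prot.columns)
    corr_table = pd.DataFrame({
        "feature": prot.index,
        "rho": rho_s,
    }).reset_index(drop=True)
    return mrna_df, corr_table
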