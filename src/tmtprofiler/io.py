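"""Plain-text readers/writers for the pipeline's tables (TSV/JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ProteinMatrix

PSM_COLUMNS = ["set_id", "channel", "protein_id", "psm_id", "intensity", "unique"]
SHEET_COLUMNS = ["sample_id", "patient_id", "set_id", "channel", "tissue",
                 "pair_id", "subset_label", "time", "event"]


def write_psm_table(psms: pd.DataFrame, path) -> None:
    psms[PSM_COLUMNS].to_csv(path, sep="\t", index=False)


def read_psm_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"set_id": str, "channel": str,
                                              "protein_id": str, "psm_id": str})


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"set_id": str, "channel": str,
                                               "sample_id": str})
    sheet["pair_id"] = sheet["pair_id"].fillna("").astype(str)
    return sheet


def write_matrix(matrix: ProteinMatrix, out_dir) -> None:
    """Protein x sample ratios (empty cell = not detected) and PSM counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.ratios.to_csv(out / "protein_matrix.tsv", sep="\t")
    matrix.psm_counts.to_csv(out / "psm_counts.tsv", sep="\t")
    if not matrix.invariance_rank.empty:
        matrix.invariance_rank.to_csv(out / "invariance_rank.tsv", sep="\t")


def read_matrix(out_dir) -> ProteinMatrix:
    out = Path(out_dir)
    ratios = pd.read_csv(out / "protein_matrix.tsv", sep="\t", index_col=0)
    counts = pd.read_csv(out / "psm_counts.tsv", sep="\t", index_col=0)
    sample_sets = pd.Series(index=ratios.columns, dtype=object)
    matrix = ProteinMatrix(ratios=ratios, psm_counts=counts, sample_sets=sample_sets)
    rank_path = out / "invariance_rank.tsv"
    if rank_path.exists():
        matrix.invariance_rank = pd.read_csv(rank_path, sep="\t", index_col=0).iloc[:, 0]
    return matrix


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
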