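"""TSV input/output for the pipeline's tabular artifacts.

Everything is plain tab-separated text (optionally gzipped via the ``.gz``
suffix, handled by pandas): beta and detection-p matrices with probes in
rows and sample ids as header, the probe manifest, sample sheet, planted
truth and result tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_table",
    "read_manifest",
    "read_samplesheet",
]


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t", index_col="probe_id")
    for col in ("flag_sex_chrom", "flag_cross_reactive", "flag_snp"):
        man[col] = man[col].astype(bool)
    return man


def read_samplesheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
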