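"""Flat-file I/O for the pipeline's TSV tables and FASTQ reads."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam


def iter_fastq_sequences(path):
    """Yield read sequences from a (possibly gzipped) FASTQ file."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.sequence


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    """Count table TSV: construct_id, reporter, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if col not in ("construct_id", "reporter"):
            df[col] = df[col].astype(int)
    return df


def read_barcode_map(path, ok_only: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if ok_only and "status" in df.columns:
        df = df[df["status"] == "ok"].reset_index(drop=True)
    return df
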