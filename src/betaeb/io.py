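"""Reading and writing expression matrices and label files.

The primary on-disk format is a delimited text matrix: first column gene ids,
header row sample ids (tab-delimited by default, comma sniffed).  Labels come
either from a two-column ``sample_id<TAB>group`` file or a comma-separated
spec on the command line.  Raw (non-logged) intensities must be positive —
the lognormal observation model is undefined at or below zero — and are
natural-log transformed at ingestion.
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ExpressionData

__all__ = ["read_expression", "write_expression", "read_labels"]

logger = logging.getLogger(__name__)


class IngestionError(ValueError):
    pass


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_labels(path) -> dict[str, int]:
    """sample_id -> group (1 or 2) from a two-column delimited file."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, names=["sample_id", "group"])
    labels = {str(r.sample_id): int(r.group) for r in df.itertuples()}
    if not set(labels.values()) <= {1, 2}:
        raise IngestionError("group labels must be 1 or 2")
    return labels


def read_expression(path, label_spec, is_logged: bool = False) -> ExpressionData:
    """Load a genes × samples matrix with its two-group design.

    ``label_spec`` is a mapping sample_id -> group covering every sample.
    Rows with any missing value are dropped (with a logged count); raw
    intensities are natural-log transformed unless ``is_logged``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    n_before = df.shape[0]
    df = df.dropna(axis=0, how="any")
    if df.shape[0] < n_before:
        logger.warning("dropped %d genes with missing values", n_before - df.shape[0])
    missing = [s for s in df.columns if str(s) not in label_spec]
    if missing:
        raise IngestionError(f"samples without a group label: {missing}")
    labels = np.array([label_spec[str(s)] for s in df.columns], dtype=int)
    values = df.to_numpy(dtype=float)
    if not is_logged:
        if np.any(values <= 0):
            t, i = np.argwhere(values <= 0)[0]
            raise IngestionError(
                f"non-positive raw intensity at gene {df.index[t]!r}, sample "
                f"{df.columns[i]!r}; raw values must be positive to log-transform"
            )
        values = np.log(values)
    return ExpressionData(
        values=values,
        group_labels=labels,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        is_logged=True,
    )


def write_expression(data: ExpressionData, path, sep: str = "\t") -> None:
    pd.DataFrame(data.values, index=data.gene_ids, columns=data.sample_ids).to_csv(
        path, sep=sep, index_label="gene_id"
    )
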