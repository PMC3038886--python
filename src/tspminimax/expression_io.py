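"""Read expression matrices and labels from plain-text formats; write reports.

Supported matrix formats:

* delimited — header row of sample ids, first column of gene ids, tab or
  comma separated;
* GCT v1.2 — ``#1.2`` version line, a ``G<TAB>N`` dimensions line, then a
  ``Name``/``Description`` header (the Description column is ignored).

Class labels live in a separate two-column file (sample id, 0|1) and are
joined explicitly by sample id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file does not follow its declared format."""


class LabelError(ValueError):
    """Raised when a label file cannot be parsed or joined to a dataset."""


@dataclass
class ExpressionDataset:
    """A genes x samples intensity matrix with optional binary labels.

    Labels use 0 for normal and 1 for cancer; they may be absent until
    :func:`join_labels` attaches them.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValueError("labels length does not match sample count")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 or 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def sample_profile(self, sample_id: str) -> dict[str, float]:
        """Expression of one sample as a gene-id -> intensity mapping."""
        j = self.sample_ids.index(sample_id)
        return dict(zip(self.gene_ids, self.values[:, j]))

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        indices = list(indices)
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[j] for j in indices],
            values=self.values[:, indices].copy(),
            labels=None if self.labels is None else self.labels[indices].copy(),
        )


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _frame_to_dataset(frame: pd.DataFrame, source: str) -> ExpressionDataset:
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"{source}: duplicate gene ids {dupes}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{source}: non-numeric cell in matrix ({exc})") from exc
    if np.isnan(values).any():
        raise FormatError(f"{source}: missing values in matrix")
    return ExpressionDataset(
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        values=values,
    )


def read_expression(
    path,
    format: str = "delimited",
    orientation: str = "genes_by_samples",
) -> ExpressionDataset:
    """Load an expression matrix from ``delimited`` or ``gct`` text.

    ``orientation`` says how the file on disk is laid out; the returned
    dataset is always genes x samples.
    """
    path = str(path)
    if format == "delimited":
        with open(path) as fh:
            first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty header line")
        sep = _sniff_delimiter(first)
        frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        frame.columns = [str(c) for c in frame.columns]
        if orientation == "samples_by_genes":
            frame = frame.T
        elif orientation != "genes_by_samples":
            raise ValueError(f"unknown orientation {orientation!r}")
        return _frame_to_dataset(frame, path)
    if format == "gct":
        return _read_gct(path)
    raise ValueError(f"unknown format {format!r}")


def _read_gct(path: str) -> ExpressionDataset:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(
                f"{path}: first line must be '#1.2', found {version!r}"
            )
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed dimensions line {dims!r}")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError:
            raise FormatError(
                f"{path}: non-integer dimensions line {dims!r}"
            ) from None
    frame = pd.read_csv(path, sep="\t", skiprows=2, index_col=0,
                        float_precision="round_trip")
    if frame.shape[1] < 1:
        raise FormatError(f"{path}: GCT table lacks a Description column")
    frame = frame.iloc[:, 1:]  # drop Description
    frame.columns = [str(c) for c in frame.columns]
    if frame.shape != (n_genes, n_samples):
        raise FormatError(
            f"{path}: GCT declares {n_genes} genes x {n_samples} samples "
            f"but table contains {frame.shape[0]} x {frame.shape[1]}"
        )
    return _frame_to_dataset(frame, path)


def write_expression(
    dataset: ExpressionDataset, path, format: str = "delimited"
) -> None:
    """Write a dataset back to ``delimited`` or ``gct`` text losslessly."""
    path = str(path)
    frame = pd.DataFrame(
        dataset.values, index=dataset.gene_ids, columns=dataset.sample_ids
    )
    if format == "delimited":
        frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{dataset.n_genes}\t{dataset.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(dataset.sample_ids) + "\n")
            for g, row in zip(dataset.gene_ids, dataset.values):
                cells = "\t".join(f"{v:.17g}" for v in row)
                fh.write(f"{g}\tna\t{cells}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path) -> dict[str, int]:
    """Parse a two-column (sample id, 0|1) file, optional header row."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 2:
                parts = line.split()
            if len(parts) != 2:
                raise LabelError(f"{path}:{lineno}: expected two columns, got {line!r}")
            sid, value = parts
            if value not in ("0", "1"):
                if lineno == 1:
                    continue  # header row
                raise LabelError(
                    f"{path}:{lineno}: label must be 0 or 1, got {value!r}"
                )
            if sid in labels:
                raise LabelError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            labels[sid] = int(value)
    return labels


def join_labels(
    dataset: ExpressionDataset, labels: Mapping[str, int]
) -> ExpressionDataset:
    """Attach labels to a dataset, requiring an exact sample-id match."""
    missing = [s for s in dataset.sample_ids if s not in labels]
    if missing:
        raise LabelError(f"labels missing for samples: {missing}")
    extras = sorted(set(labels) - set(dataset.sample_ids))
    if extras:
        raise LabelError(f"labels for unknown samples: {extras}")
    bad = {s: v for s, v in labels.items() if v not in (0, 1)}
    if bad:
        raise LabelError(f"labels outside {{0,1}}: {bad}")
    return replace(
        dataset,
        labels=np.array([labels[s] for s in dataset.sample_ids], dtype=int),
    )


_REPORT_COLUMNS = (
    "sample_id",
    "F",
    "rho",
    "ci_low",
    "ci_high",
    "class_call",
    "cp_flag",
    "i_star",
    "sigma",
)


def _prediction_row(sample_id: str, pred) -> dict:
    return {
        "sample_id": sample_id,
        "F": float(pred.f_reported),
        "rho": float(pred.rmse_bound),
        "ci_low": float(pred.ci_low),
        "ci_high": float(pred.ci_high),
        "class_call": int(pred.class_call),
        "cp_flag": bool(pred.cp_flag),
        "i_star": int(pred.fit.i),
        "sigma": float(pred.fit.sigma),
    }


def write_report(predictions, summary, path, format: str = "tsv") -> None:
    """Write per-patient predictions (and, for JSON, the cohort summary).

    ``predictions`` is a sequence of ``(sample_id, Prediction)`` pairs.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("cannot write a report with no predictions")
    rows = [_prediction_row(sid, pred) for sid, pred in predictions]
    path = str(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_REPORT_COLUMNS) + "\n")
            for row in rows:
                cells = []
                for col in _REPORT_COLUMNS:
                    v = row[col]
                    if isinstance(v, bool):
                        cells.append("1" if v else "0")
                    elif isinstance(v, float):
                        cells.append(f"{v:.6g}")
                    else:
                        cells.append(str(v))
                fh.write("\t".join(cells) + "\n")
    elif format == "json":
        payload = {
            "predictions": rows,
            "summary": None if summary is None else summary.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
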