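"""Reading and writing of on-disk artifacts.

All files are tab-delimited text with headers.  A probe table carries
the annotation columns ``probe_id, cgi_id, genes, chrom, start, end``
(BED-style 0-based half-open coordinates, genes comma-joined) followed
by one numeric column of log ratios per sample; empty cells are missing
values.  Control gene lists are plain text, one identifier per line,
``#`` comments allowed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["probe_id", "cgi_id", "genes", "chrom", "start", "end"]

__all__ = [
    "ProbeAnnotation",
    "ControlSets",
    "LogRatioMatrix",
    "read_probe_table",
    "write_probe_table",
    "read_two_channel_table",
    "write_two_channel_table",
    "read_control_sets",
    "write_control_sets",
    "write_results",
    "read_score_table",
    "write_score_table",
    "read_eval_table",
]


@dataclass(frozen=True)
class ProbeAnnotation:
    """One tiling-array probe and the CpG island it belongs to."""

    probe_id: str
    cgi_id: str
    genes: tuple[str, ...]
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"probe {self.probe_id}: start must be >= 0")
        if self.end <= self.start:
            raise ValueError(
                f"probe {self.probe_id}: end ({self.end}) must exceed start ({self.start})"
            )


@dataclass
class ControlSets:
    """Positive (known methylated) and negative (housekeeping) control ids.

    ``n_methylated`` and ``n_housekeeping`` are the control-set sizes
    used as denominators of the evaluation statistics.
    """

    methylated_ids: list[str]
    housekeeping_ids: list[str]

    def __post_init__(self):
        overlap = set(self.methylated_ids) & set(self.housekeeping_ids)
        if overlap:
            raise ValueError(
                "control lists must be disjoint; found in both: "
                + ", ".join(sorted(overlap))
            )
        if not self.methylated_ids or not self.housekeeping_ids:
            raise ValueError("control lists must be non-empty")

    @property
    def n_methylated(self) -> int:
        return len(self.methylated_ids)

    @property
    def n_housekeeping(self) -> int:
        return len(self.housekeeping_ids)


class LogRatioMatrix:
    """Probes x samples matrix of normalized log2(Cy5/Cy3) values.

    Missing entries are NaN.  Row/column order is meaningful and is
    preserved on disk round trips.
    """

    def __init__(self, probe_ids, sample_ids, values):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(probe_ids), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(probe_ids)} probes x {len(sample_ids)} samples"
            )
        self.probe_ids = list(probe_ids)
        self.sample_ids = list(sample_ids)
        self.values = values
        self._probe_pos = {p: i for i, p in enumerate(self.probe_ids)}
        if len(self._probe_pos) != len(self.probe_ids):
            raise ValueError("duplicate probe ids in matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def probe_rows(self, probe_ids) -> np.ndarray:
        idx = [self._probe_pos[p] for p in probe_ids]
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


def _parse_annotation(df: pd.DataFrame) -> list[ProbeAnnotation]:
    ann = []
    for row in df.itertuples(index=False):
        genes = tuple(g for g in str(row.genes).split(",") if g and g != "nan")
        ann.append(
            ProbeAnnotation(
                probe_id=str(row.probe_id),
                cgi_id=str(row.cgi_id),
                genes=genes,
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
            )
        )
    return ann


def read_probe_table(path) -> tuple[list[ProbeAnnotation], LogRatioMatrix]:
    """Read an annotated probe x sample log-ratio table.

    Returns the probe annotation (file order) and the log-ratio matrix.
    Raises on duplicate probe ids, missing annotation columns, and
    non-numeric intensity cells (empty cells are missing values).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns: {missing_cols}")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate probe_id {dup.iloc[0]!r}")
    sample_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    values = np.empty((len(df), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        raw = df[col].str.strip()
        numeric = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = numeric.isna() & (raw != "")
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {raw.iloc[i]!r} in column {col!r}, "
                f"row {i + 2} (probe {df['probe_id'].iloc[i]!r})"
            )
        values[:, j] = numeric.to_numpy()
    annotation = _parse_annotation(df[ANNOTATION_COLUMNS])
    matrix = LogRatioMatrix(df["probe_id"].tolist(), sample_cols, values)
    logger.info(
        "read %s: %d probes, %d CGIs, %d samples",
        path,
        matrix.n_probes,
        len({a.cgi_id for a in annotation}),
        matrix.n_samples,
    )
    return annotation, matrix


def _annotation_frame(annotation) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [a.probe_id for a in annotation],
            "cgi_id": [a.cgi_id for a in annotation],
            "genes": [",".join(a.genes) for a in annotation],
            "chrom": [a.chrom for a in annotation],
            "start": [a.start for a in annotation],
            "end": [a.end for a in annotation],
        }
    )


def _format_float(x) -> str:
    if isinstance(x, float) and math.isnan(x):
        return ""
    return f"{x:.12g}"


def write_probe_table(path, annotation, matrix: LogRatioMatrix) -> Path:
    """Write annotation + log-ratio matrix as one tab-delimited table."""
    path = Path(path)
    df = _annotation_frame(annotation)
    for j, sid in enumerate(matrix.sample_ids):
        df[sid] = [_format_float(v) for v in matrix.values[:, j]]
    df.to_csv(path, sep="\t", index=False)
    return path


def write_two_channel_table(path, annotation, arrays) -> Path:
    """Write raw two-channel intensities (red_<id>, green_<id> columns)."""
    path = Path(path)
    df = _annotation_frame(annotation)
    for arr in arrays:
        df[f"red_{arr.sample_id}"] = [_format_float(v) for v in arr.red]
        df[f"green_{arr.sample_id}"] = [_format_float(v) for v in arr.green]
    df.to_csv(path, sep="\t", index=False)
    return path


def read_two_channel_table(path):
    """Read a two-channel intensity table written by ``write_two_channel_table``.

    Returns ``(annotation, arrays)`` where ``arrays`` is a list of
    :class:`~qrmeth.normalization.TwoChannelArray`.
    """
    from .normalization import TwoChannelArray

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns: {missing_cols}")
    red_cols = [c for c in df.columns if c.startswith("red_")]
    sample_ids = [c[len("red_"):] for c in red_cols]
    arrays = []
    for sid in sample_ids:
        if f"green_{sid}" not in df.columns:
            raise ValueError(f"{path}: red_{sid} present but green_{sid} missing")
        arrays.append(
            TwoChannelArray(
                sample_id=sid,
                red=df[f"red_{sid}"].to_numpy(float),
                green=df[f"green_{sid}"].to_numpy(float),
            )
        )
    annotation = _parse_annotation(
        df[ANNOTATION_COLUMNS].astype({"probe_id": str, "cgi_id": str, "genes": str})
    )
    return annotation, arrays


def _read_id_list(path) -> list[str]:
    ids = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line in seen:
            logger.warning("%s: duplicate id %r ignored", path, line)
            continue
        seen.add(line)
        ids.append(line)
    if not ids:
        raise ValueError(f"{path}: empty control list")
    return ids


def read_control_sets(path_pos, path_neg) -> ControlSets:
    """Read positive (methylated) and negative (housekeeping) control lists."""
    return ControlSets(
        methylated_ids=_read_id_list(path_pos),
        housekeeping_ids=_read_id_list(path_neg),
    )


def write_control_sets(controls: ControlSets, path_pos, path_neg):
    Path(path_pos).write_text("\n".join(controls.methylated_ids) + "\n")
    Path(path_neg).write_text("\n".join(controls.housekeeping_ids) + "\n")
    return Path(path_pos), Path(path_neg)


def write_score_table(score_table: pd.DataFrame, path) -> Path:
    """Write a per-CGI methylation score table (one column per p0 cutoff)."""
    path = Path(path)
    out = score_table.copy()
    out.columns = [f"{float(c):.12g}" for c in out.columns]
    out.index.name = "cgi_id"
    out.to_csv(path, sep="\t")
    return path


def read_score_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="cgi_id")
    df.columns = [float(c) for c in df.columns]
    return df


def _write_grid(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    out.index = [f"{float(t):.12g}" for t in out.index]
    out.columns = [f"{float(c):.12g}" for c in out.columns]
    out.index.name = "tau"
    out.to_csv(path, sep="\t", float_format="%.12g")
    return Path(path)


def read_eval_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="tau")
    df.index = [float(t) for t in df.index]
    df.columns = [float(c) for c in df.columns]
    return df


def write_results(score_table, eval_grid, out_dir) -> list[Path]:
    """Write a score table plus one tau x p0 table per evaluation measure.

    ``score_table`` may be None (evaluation-only runs) as may
    ``eval_grid``.  Integers round-trip exactly; reals to 12
    significant digits.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc
    written = []
    if score_table is not None:
        written.append(write_score_table(score_table, out_dir / "scores.tsv"))
    if eval_grid is not None:
        for name in ("auc", "mean_diff", "t_stat"):
            written.append(_write_grid(getattr(eval_grid, name), out_dir / f"{name}.tsv"))
    return written
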