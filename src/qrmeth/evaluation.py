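"""Control-gene evaluation of quantile levels.

Known methylated genes serve as positive controls and housekeeping
genes as negative controls.  At each (tau, p0) cell the per-CGI
methylation scores of the two control groups are compared with three
statistics:

* **AUC** — area under the ROC curve obtained by sweeping a score
  threshold C0 from 0 to N+1 and classifying a CGI as methylated when
  its score >= C0 (trapezoidal area; equals the tie-corrected
  Mann-Whitney pairwise statistic).
* **mean.diff** — difference of mean scores, x̄_m − x̄_HK.
* **T.stat** — Welch-type statistic
  (x̄_m − x̄_HK) / sqrt(s²_m/N_m + s²_HK/N_HK) with unbiased (n−1)
  variances.

Larger values mean the quantile level separates the two control groups
better.  The grid summary averages each measurement over the p0 grid
per tau and reports the maximising tau plus a "recommended band" of
tau values whose average lies within 5% of that maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TAU_GRID",
    "P0_GRID",
    "ScoreSets",
    "EvaluationGrid",
    "roc_points",
    "auc",
    "auc_pairwise",
    "mean_diff",
    "t_stat",
    "resolve_control_scores",
    "score_sets",
    "evaluation_grid",
]

#: quantile levels of the standard analysis grid (high tail first)
TAU_GRID = (0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.60)
#: per-sample p-value cutoffs of the standard grid
P0_GRID = (0.01, 0.02, 0.03, 0.04, 0.05)

MEASUREMENTS = ("auc", "mean_diff", "t_stat")


@dataclass
class ScoreSets:
    """Methylation scores of the two control groups at one (tau, p0)."""

    methylated: np.ndarray
    housekeeping: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.methylated = np.asarray(self.methylated, dtype=float)
        self.housekeeping = np.asarray(self.housekeeping, dtype=float)
        if self.methylated.size == 0 or self.housekeeping.size == 0:
            raise ValueError("control score sets must be non-empty")
        for name, arr in (("methylated", self.methylated),
                          ("housekeeping", self.housekeeping)):
            if arr.min() < 0 or arr.max() > self.n_samples:
                raise ValueError(
                    f"{name} scores must lie in [0, N={self.n_samples}]"
                )


def roc_points(sets: ScoreSets) -> list[tuple[int, float, float]]:
    """ROC sweep over integer score thresholds C0 = 0 .. N+1.

    A CGI is classified methylated when score >= C0; TPR is the fraction
    of positive-control scores >= C0 and FPR the fraction of
    housekeeping scores >= C0.  C0 = 0 gives (1, 1); C0 = N+1 closes the
    curve at (0, 0).
    """
    pts = []
    for c0 in range(sets.n_samples + 2):
        tpr = float(np.mean(sets.methylated >= c0))
        fpr = float(np.mean(sets.housekeeping >= c0))
        pts.append((c0, tpr, fpr))
    return pts


def auc(sets: ScoreSets) -> float:
    """Trapezoidal area under the ROC polyline (in [0, 1])."""
    pts = roc_points(sets)
    tpr = np.array([p[1] for p in pts])[::-1]  # ascending FPR
    fpr = np.array([p[2] for p in pts])[::-1]
    return float(np.trapezoid(tpr, fpr))


def auc_pairwise(sets: ScoreSets) -> float:
    """Tie-corrected Mann-Whitney form of the AUC (independent route)."""
    m = sets.methylated[:, None]
    h = sets.housekeeping[None, :]
    wins = (m > h).sum() + 0.5 * (m == h).sum()
    return float(wins / (sets.methylated.size * sets.housekeeping.size))


def mean_diff(sets: ScoreSets) -> float:
    """Mean score difference x̄_m − x̄_HK."""
    return float(sets.methylated.mean() - sets.housekeeping.mean())


def t_stat(sets: ScoreSets) -> float:
    """Welch-type statistic (x̄_m − x̄_HK) / sqrt(s²_m/N_m + s²_HK/N_HK)."""
    if sets.methylated.size < 2 or sets.housekeeping.size < 2:
        raise ValueError("t_stat needs at least two scores per group")
    num = mean_diff(sets)
    denom2 = (
        sets.methylated.var(ddof=1) / sets.methylated.size
        + sets.housekeeping.var(ddof=1) / sets.housekeeping.size
    )
    if denom2 == 0.0:
        if num == 0.0:
            raise ZeroDivisionError(
                "t_stat undefined: both variances and the mean difference are zero"
            )
        return float(np.sign(num) * np.inf)
    return float(num / np.sqrt(denom2))


def resolve_control_scores(
    scores: pd.Series,
    control_ids,
    annotation=None,
    collapse: str = "all",
) -> tuple[np.ndarray, list[str]]:
    """Map control identifiers to score values.

    Controls are matched by CGI id; an identifier not found among the
    CGI ids is treated as a gene symbol and resolved through the
    annotation to every CGI associated with that gene.  With
    ``collapse='all'`` each associated CGI contributes one score; with
    ``collapse='max'`` a control contributes its per-gene maximum.
    Returns ``(values, missing_ids)``.
    """
    if collapse not in ("all", "max"):
        raise ValueError(f"collapse must be 'all' or 'max', got {collapse!r}")
    gene_to_cgis: dict[str, list[str]] = {}
    if annotation is not None:
        for a in annotation:
            for g in a.genes:
                gene_to_cgis.setdefault(g, [])
                if a.cgi_id not in gene_to_cgis[g]:
                    gene_to_cgis[g].append(a.cgi_id)
    out = []
    missing = []
    for cid in control_ids:
        if cid in scores.index:
            cgis = [cid]
        else:
            cgis = [c for c in gene_to_cgis.get(cid, []) if c in scores.index]
        if not cgis:
            missing.append(cid)
            continue
        vals = [float(scores.loc[c]) for c in cgis]
        if collapse == "max":
            out.append(max(vals))
        else:
            out.extend(vals)
    return np.asarray(out, dtype=float), missing


def score_sets(
    score_table: pd.DataFrame,
    p0: float,
    controls,
    n_samples: int,
    annotation=None,
    collapse: str = "all",
) -> ScoreSets:
    """Build the control ScoreSets at one p0 column of a score table."""
    col = score_table[float(p0)]
    pos, miss_p = resolve_control_scores(col, controls.methylated_ids, annotation, collapse)
    neg, miss_n = resolve_control_scores(col, controls.housekeeping_ids, annotation, collapse)
    missing = miss_p + miss_n
    if missing:
        warnings.warn(
            f"{len(missing)} control ids not found in the score table and "
            f"excluded: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else ""),
            UserWarning,
            stacklevel=2,
        )
    return ScoreSets(methylated=pos, housekeeping=neg, n_samples=n_samples)


@dataclass
class EvaluationGrid:
    """tau x p0 tables of the three measurements plus grid summaries."""

    auc: pd.DataFrame
    mean_diff: pd.DataFrame
    t_stat: pd.DataFrame
    n_samples: int = 0

    def grid_average(self, measurement: str) -> pd.Series:
        """Average of one measurement over the p0 grid, per tau."""
        if measurement not in MEASUREMENTS:
            raise ValueError(f"unknown measurement {measurement!r}")
        return getattr(self, measurement).mean(axis=1)

    def best_tau(self, measurement: str) -> float:
        """tau maximising the grid average of one measurement."""
        return float(self.grid_average(measurement).idxmax())

    def recommended_band(self, measurement: str = "auc") -> list[float]:
        """tau values whose grid average is within 5% of the maximum."""
        avg = self.grid_average(measurement)
        top = avg.max()
        if top <= 0:
            return [float(avg.idxmax())]
        band = avg[avg >= 0.95 * top].index
        return sorted(float(t) for t in band)

    def has_separation(self, min_auc: float = 0.55) -> bool:
        """Whether the controls are separated at all (best average AUC)."""
        return bool(self.grid_average("auc").max() >= min_auc)


def evaluation_grid(
    score_tables: dict[float, pd.DataFrame],
    controls,
    n_samples: int,
    annotation=None,
    collapse: str = "all",
) -> EvaluationGrid:
    """Fill the tau x p0 grids of all three measurements.

    ``score_tables`` maps each tau to its per-CGI score frame (columns
    = p0 cutoffs).  Control ids missing from a score table are excluded
    with a warning (emitted by :func:`score_sets`).
    """
    taus = sorted(score_tables, reverse=True)
    if not taus:
        raise ValueError("no score tables supplied")
    p0s = sorted(float(c) for c in next(iter(score_tables.values())).columns)
    mats = {m: pd.DataFrame(index=taus, columns=p0s, dtype=float) for m in MEASUREMENTS}
    for tau in taus:
        table = score_tables[tau]
        for p0 in p0s:
            sets = score_sets(table, p0, controls, n_samples, annotation, collapse)
            mats["auc"].loc[tau, p0] = auc(sets)
            mats["mean_diff"].loc[tau, p0] = mean_diff(sets)
            try:
                mats["t_stat"].loc[tau, p0] = t_stat(sets)
            except ZeroDivisionError:
                # identical constant score sets: no separation at all
                mats["t_stat"].loc[tau, p0] = 0.0
    return EvaluationGrid(
        auc=mats["auc"],
        mean_diff=mats["mean_diff"],
        t_stat=mats["t_stat"],
        n_samples=n_samples,
    )
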