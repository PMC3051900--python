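"""Probe-level log-ratio cutoff baseline.

The comparison method calls a CGI methylated in a sample when at least
a fraction ``f`` of its probes have log ratio strictly greater than
1.5, with rules f in {30%, 50%, 100%}.  A per-CGI score is the number
of samples called under a rule, which makes the baseline directly
comparable to the quantile-regression methylation score through the
same control-gene AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import ScoreSets, auc as _auc, resolve_control_scores

__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_RULES",
    "CutoffCall",
    "cutoff_call",
    "cutoff_scores",
    "cutoff_scores_and_auc",
]

DEFAULT_THRESHOLD = 1.5
DEFAULT_RULES = (0.30, 0.50, 1.00)


@dataclass
class CutoffCall:
    """Cutoff decision for one (CGI, sample) pair.

    ``fraction_high`` is the share of non-missing probes with log ratio
    above the threshold; ``called[f]`` applies rule fraction ``f`` as
    ``fraction_high >= f``.  ``all_missing`` flags pairs with no data
    (never called).
    """

    cgi_id: str
    sample_id: str
    fraction_high: float
    called: dict[float, bool]
    all_missing: bool = False


def cutoff_call(
    m_values,
    cgi_id: str = "",
    sample_id: str = "",
    threshold: float = DEFAULT_THRESHOLD,
    rules=DEFAULT_RULES,
) -> CutoffCall:
    """Apply the probe-fraction cutoff rule to one CGI in one sample.

    ``fraction_high = #{M > threshold} / #non-missing`` (strict
    inequality at the threshold); a rule ``f`` calls the pair when
    ``fraction_high >= f`` ("at least" the fraction).
    """
    m = np.asarray(m_values, dtype=float)
    present = ~np.isnan(m)
    n = int(present.sum())
    if n == 0:
        return CutoffCall(
            cgi_id=cgi_id,
            sample_id=sample_id,
            fraction_high=0.0,
            called={float(f): False for f in rules},
            all_missing=True,
        )
    frac = float(np.sum(m[present] > threshold)) / n
    return CutoffCall(
        cgi_id=cgi_id,
        sample_id=sample_id,
        fraction_high=frac,
        called={float(f): frac >= float(f) for f in rules},
    )


def cutoff_scores(
    annotation,
    matrix,
    rule: float,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.Series:
    """Per-CGI score = number of samples called under one rule fraction."""
    rule = float(rule)
    cgi_probes: dict[str, list[str]] = {}
    for a in annotation:
        cgi_probes.setdefault(a.cgi_id, []).append(a.probe_id)
    scores = {}
    for cgi_id, probes in cgi_probes.items():
        sub = matrix.probe_rows(probes)  # P x S
        present = ~np.isnan(sub)
        n_present = present.sum(axis=0)
        high = np.sum(np.where(present, sub > threshold, False), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_present > 0, high / np.maximum(n_present, 1), 0.0)
        called = (frac >= rule) & (n_present > 0)
        scores[cgi_id] = int(called.sum())
    return pd.Series(scores, name=f"rule_{rule:g}")


def cutoff_scores_and_auc(
    annotation,
    matrix,
    controls,
    rule: float,
    threshold: float = DEFAULT_THRESHOLD,
    collapse: str = "all",
) -> tuple[pd.Series, float]:
    """Baseline score table and its control-gene AUC under one rule."""
    scores = cutoff_scores(annotation, matrix, rule, threshold)
    pos, _ = resolve_control_scores(scores, controls.methylated_ids, annotation, collapse)
    neg, _ = resolve_control_scores(scores, controls.housekeeping_ids, annotation, collapse)
    sets = ScoreSets(methylated=pos, housekeeping=neg, n_samples=matrix.n_samples)
    return scores, _auc(sets)
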