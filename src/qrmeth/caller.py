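"""Per-CGI model fitting and methylation scoring.

For each CpG island the probe-level log ratios are stacked in long
format and modelled as

    Q_{Y_sp}(tau) = sample_s(tau) + probe_p(tau),

an additive two-way layout in which every sample has its own testable
coefficient (full sample dummies, no intercept) and probe affinity is
absorbed by sum-to-zero probe contrasts — so ``sample_s`` is that
sample's tau-quantile signal at the "average probe" of the island.
Each sample effect gets a one-sided bootstrap p-value for the null
``sample_s(tau) = 0``; the methylation score of a CGI at cutoff ``p0``
is the number of samples with p-value strictly below ``p0``.

CGIs are fitted independently; per-(CGI, tau) bootstrap seeds are
derived from the master seed and the CGI id, so results do not depend
on execution order or worker count.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import _fnsolver
from .io import LogRatioMatrix, ProbeAnnotation
from .quantreg import _linprog_fit, _pvalues_from_normal, _validate_tau, check_loss

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceSettings",
    "CgiDesign",
    "QuantRegResult",
    "CgiSkipped",
    "build_design",
    "design_matrix",
    "call_cgi",
    "call_dataset",
    "methylation_scores",
    "derive_seed",
]

#: minimum surplus of observations over parameters before a CGI is fitted
MIN_SURPLUS = 5


class CgiSkipped(Exception):
    """A CGI that cannot be fitted; carries a machine-readable reason."""

    def __init__(self, cgi_id: str, reason: str, detail: str = ""):
        self.cgi_id = cgi_id
        self.reason = reason
        self.detail = detail
        super().__init__(f"CGI {cgi_id} skipped ({reason}): {detail}")


@dataclass
class InferenceSettings:
    """Bootstrap inference configuration for the per-sample tests."""

    method: str = "bootstrap"
    n_boot: int = 200
    seed: int = 0
    alternative: str = "greater"


@dataclass
class CgiDesign:
    """Long-format stacked design of one CGI.

    One entry per non-missing probe x sample cell; ``sample_code`` and
    ``probe_code`` are integer factor levels into ``sample_ids`` /
    ``probe_ids``.  Samples with no usable cell for this CGI are listed
    in ``excluded_samples`` (they are scored as not significant).
    """

    cgi_id: str
    y: np.ndarray
    sample_code: np.ndarray
    probe_code: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]
    excluded_samples: list[str] = field(default_factory=list)
    all_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.all_sample_ids:
            self.all_sample_ids = list(self.sample_ids) + list(self.excluded_samples)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_params(self) -> int:
        return self.n_samples + max(self.n_probes - 1, 0)


@dataclass
class QuantRegResult:
    """Fit of one CGI at one quantile level.

    ``sample_effects`` / ``sample_p_values`` are aligned with
    ``sample_ids`` (the full sample order of the input matrix);
    excluded samples carry effect NaN and p-value 1.  ``probe_effects``
    sum to zero.
    """

    cgi_id: str
    tau: float
    sample_ids: list[str]
    sample_effects: np.ndarray
    sample_p_values: np.ndarray
    probe_ids: list[str]
    probe_effects: np.ndarray
    objective: float
    residuals: np.ndarray
    excluded_samples: list[str]
    converged: bool


def derive_seed(master_seed: int, cgi_id: str, tau: float) -> int:
    """Deterministic per-(CGI, tau) bootstrap seed below 2**31."""
    tag = f"{cgi_id}|{tau:.6f}".encode()
    return int((int(master_seed) * 0x9E3779B1 + zlib.crc32(tag)) % (2**31))


def build_design(cgi_id: str, annotation, matrix: LogRatioMatrix) -> CgiDesign:
    """Stack the non-missing cells of one CGI into a long-format design.

    Samples with zero non-missing probes for this CGI are excluded and
    recorded; probes come in annotation order, samples in matrix order.
    """
    probe_ids = [a.probe_id for a in annotation if a.cgi_id == cgi_id]
    if not probe_ids:
        raise KeyError(f"CGI {cgi_id!r} has no probes in the annotation")
    sub = matrix.probe_rows(probe_ids)  # P x S
    present = ~np.isnan(sub)
    sample_has_data = present.any(axis=0)
    excluded = [s for s, ok in zip(matrix.sample_ids, sample_has_data) if not ok]
    keep = np.flatnonzero(sample_has_data)
    sample_ids = [matrix.sample_ids[j] for j in keep]
    pidx, sidx = np.nonzero(present[:, keep])
    # canonical row order (probe, then sample id) so stacking — and the
    # seeded bootstrap resampling built on it — does not depend on the
    # column order of the input matrix
    name_rank = np.argsort(np.argsort(np.asarray(sample_ids, dtype=object)))
    order = np.lexsort((name_rank[sidx], pidx))
    pidx, sidx = pidx[order], sidx[order]
    return CgiDesign(
        cgi_id=cgi_id,
        y=sub[:, keep][present[:, keep]][order],
        sample_code=sidx.astype(np.int64),
        probe_code=pidx.astype(np.int64),
        sample_ids=sample_ids,
        probe_ids=probe_ids,
        excluded_samples=excluded,
        all_sample_ids=list(matrix.sample_ids),
    )


def design_matrix(design: CgiDesign) -> np.ndarray:
    """Dense encoded design: sample dummies then sum-to-zero probe contrasts."""
    n = design.y.size
    N, P = design.n_samples, design.n_probes
    X = np.zeros((n, design.n_params))
    X[np.arange(n), design.sample_code] = 1.0
    if P > 1:
        C = np.vstack([np.eye(P - 1), -np.ones(P - 1)])
        X[:, N:] = C[design.probe_code]
    return X


def _full_probe_effects(gamma: np.ndarray, n_probes: int) -> np.ndarray:
    if n_probes <= 1:
        return np.zeros(n_probes)
    return np.concatenate([gamma, [-gamma.sum()]])


def call_cgi(
    design: CgiDesign,
    tau: float,
    inference: InferenceSettings | None = None,
) -> QuantRegResult:
    """Fit one CGI at one quantile level and test every sample effect.

    The point fit is the exact LP solution (vertex; at least one zero
    residual per parameter); standard errors come from the xy-pair
    bootstrap run through the fast structured solver.  Excluded samples
    (no data for this CGI) re-enter the output as not significant.
    """
    tau = _validate_tau(tau)
    inference = inference or InferenceSettings()
    n = design.y.size
    k = design.n_params
    if n <= k + MIN_SURPLUS:
        raise CgiSkipped(
            design.cgi_id,
            "insufficient_data",
            f"{n} non-missing cells for {k} parameters "
            f"(need > {k + MIN_SURPLUS})",
        )
    X = design_matrix(design)
    N, P = design.n_samples, design.n_probes
    try:
        beta = _linprog_fit(X, design.y, tau)
    except RuntimeError as exc:
        raise CgiSkipped(design.cgi_id, "fit_failed", str(exc)) from exc
    if not np.all(np.isfinite(beta)):
        raise CgiSkipped(
            design.cgi_id,
            "rank_deficient",
            f"design for CGI {design.cgi_id} is not identifiable",
        )
    resid = design.y - X @ beta
    objective = check_loss(resid, tau)

    seed = derive_seed(inference.seed, design.cgi_id, tau)
    rng = np.random.default_rng(seed)
    boots = _fnsolver.bootstrap_sample_effects(
        design.sample_code,
        design.probe_code,
        design.y,
        N,
        P,
        tau,
        inference.n_boot,
        rng,
    )
    se = boots.std(axis=0, ddof=1)
    p_inc = _pvalues_from_normal(beta[:N], se, inference.alternative)

    # merge included samples back into full matrix sample order
    full_ids = list(design.all_sample_ids)
    order = {s: i for i, s in enumerate(full_ids)}
    effects = np.full(len(full_ids), np.nan)
    pvals = np.ones(len(full_ids))
    for j, sid in enumerate(design.sample_ids):
        effects[order[sid]] = beta[j]
        pvals[order[sid]] = p_inc[j]
    return QuantRegResult(
        cgi_id=design.cgi_id,
        tau=tau,
        sample_ids=full_ids,
        sample_effects=effects,
        sample_p_values=pvals,
        probe_ids=list(design.probe_ids),
        probe_effects=_full_probe_effects(beta[N:], P),
        objective=objective,
        residuals=resid,
        excluded_samples=list(design.excluded_samples),
        converged=True,
    )


def methylation_scores(results, p0_grid) -> pd.DataFrame:
    """Count significant samples per CGI at each p-value cutoff.

    ``score(cgi, p0) = #{s : p_s < p0}`` (strict inequality).  All
    results must share one tau; duplicate CGI ids are an error.  The
    returned frame has CGI ids as index and the p0 cutoffs as columns.
    """
    results = list(results)
    if not results:
        return pd.DataFrame(columns=list(p0_grid), dtype=int)
    taus = {r.tau for r in results}
    if len(taus) != 1:
        raise ValueError(f"results mix quantile levels: {sorted(taus)}")
    seen = set()
    for r in results:
        if r.cgi_id in seen:
            raise ValueError(f"duplicate CGI id {r.cgi_id!r} among results")
        seen.add(r.cgi_id)
    p0_grid = [float(p) for p in p0_grid]
    data = {
        r.cgi_id: [int(np.sum(r.sample_p_values < p0)) for p0 in p0_grid]
        for r in results
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=p0_grid).astype(int)


def _call_one(design, taus, inference):
    out = {}
    for tau in taus:
        out[tau] = call_cgi(design, tau, inference)
    return out


def call_dataset(
    annotation,
    matrix: LogRatioMatrix,
    taus,
    p0_grid,
    inference: InferenceSettings | None = None,
    n_workers: int = 1,
):
    """Fit every CGI at every quantile level and build score tables.

    Returns ``(score_tables, results, report)`` where ``score_tables``
    maps tau -> per-CGI score frame, ``results`` maps tau -> list of
    :class:`QuantRegResult`, and ``report`` is a frame with one row per
    CGI recording fitted/skipped status and reason.

    Work is distributed per CGI; seeds are derived per (CGI, tau) from
    the master seed, so outputs are identical for any worker count.
    """
    inference = inference or InferenceSettings()
    taus = [_validate_tau(t) for t in taus]
    cgi_order = []
    seen = set()
    for a in annotation:
        if a.cgi_id not in seen:
            seen.add(a.cgi_id)
            cgi_order.append(a.cgi_id)

    designs = []
    report_rows = []
    for cgi_id in cgi_order:
        design = build_design(cgi_id, annotation, matrix)
        n, k = design.y.size, design.n_params
        if n <= k + MIN_SURPLUS:
            report_rows.append(
                {
                    "cgi_id": cgi_id,
                    "status": "skipped",
                    "reason": "insufficient_data",
                    "n_obs": n,
                    "n_params": k,
                    "n_excluded_samples": len(design.excluded_samples),
                }
            )
            continue
        designs.append(design)

    if n_workers > 1:
        fitted = Parallel(n_jobs=n_workers, prefer="threads")(
            delayed(_call_one)(d, taus, inference) for d in designs
        )
    else:
        fitted = [_call_one(d, taus, inference) for d in designs]

    results = {tau: [] for tau in taus}
    for design, per_tau in zip(designs, fitted):
        for tau in taus:
            results[tau].append(per_tau[tau])
        report_rows.append(
            {
                "cgi_id": design.cgi_id,
                "status": "fitted",
                "reason": "",
                "n_obs": design.y.size,
                "n_params": design.n_params,
                "n_excluded_samples": len(design.excluded_samples),
            }
        )
    score_tables = {
        tau: methylation_scores(results[tau], p0_grid) for tau in taus
    }
    report = pd.DataFrame(
        report_rows,
        columns=["cgi_id", "status", "reason", "n_obs", "n_params", "n_excluded_samples"],
    )
    n_skip = int((report["status"] == "skipped").sum())
    logger.info(
        "called %d CGIs at %d quantile levels (%d skipped)",
        len(designs),
        len(taus),
        n_skip,
    )
    return score_tables, results, report
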