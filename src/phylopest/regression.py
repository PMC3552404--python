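"""Resampling logistic regression of pest sharing on phylogenetic distance.

The inference emulates the practical situation of finding a pest on a single
host: for every pest one known host genus is drawn uniformly at random as the
"source", and for each other "target" genus in the universe the response is
whether the target is recorded susceptible. A logistic regression of that
response on log10(PD + 1) — optionally plus the pest's number of known host
genera — is fitted per pest group. Redrawing sources for a fixed number of
runs and taking 0.025/0.5/0.975 quantiles of the fitted coefficients yields
median estimates and 95% confidence intervals; a coefficient whose interval
excludes zero is called significant. The resampling also sidesteps the
pseudoreplication of treating every ordered host pair as independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from phylopest.errors import FitError
from phylopest.incidence import PEST_GROUPS, IncidenceMatrix
from phylopest.tree import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "LogisticFit",
    "CoefficientSummary",
    "CurveEnvelope",
    "draw_sources",
    "build_design",
    "fit_logistic",
    "run_resampling",
    "screen_interaction",
    "curve_envelope",
]

MAX_ITER = 100
#: |coefficient| beyond this on the logit scale is treated as (quasi-)complete
#: separation: the inverse logit saturates far below such magnitudes.
SEPARATION_THRESHOLD = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """One of the three nested logistic models.

    M1: logit(S) = b0 + b1 * log10(PD + 1)
    M2: M1 + b2 * n_known            (number of known host genera)
    M3: M2 + b3 * log10(PD + 1) * n_known   (interaction screen only)
    """

    model_id: str

    _PREDICTORS = {
        "M1": ("x1",),
        "M2": ("x1", "n_known"),
        "M3": ("x1", "n_known", "x1:n_known"),
    }

    def __post_init__(self):
        if self.model_id not in self._PREDICTORS:
            raise ValueError(f"unknown model {self.model_id!r}; expected M1, M2 or M3")

    @property
    def predictors(self) -> tuple[str, ...]:
        return self._PREDICTORS[self.model_id]

    @property
    def coef_names(self) -> tuple[str, ...]:
        return ("b0",) + tuple(f"b{i+1}" for i in range(len(self.predictors)))

    def design_columns(self, x1: np.ndarray, n_known: np.ndarray) -> np.ndarray:
        """Assemble the design matrix (with intercept) from raw predictors."""
        cols = [np.ones_like(x1)]
        for name in self.predictors:
            if name == "x1":
                cols.append(x1)
            elif name == "n_known":
                cols.append(n_known.astype(float))
            else:
                cols.append(x1 * n_known)
        return np.column_stack(cols)


@dataclass
class LogisticFit:
    """Result of a single maximum-likelihood logistic fit."""

    params: np.ndarray
    converged: bool
    separated: bool
    loglik: float
    coef_names: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return dict(zip(self.coef_names, self.params))


@dataclass
class CoefficientSummary:
    """Per group x coefficient resampling quantiles and significance calls."""

    table: pd.DataFrame
    model_id: str
    n_runs: int
    seed: int = None
    exclusions: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class CurveEnvelope:
    """Quantile band of predicted sharing probability on a PD grid."""

    table: pd.DataFrame  # columns: group, pd, q025, q50, q975 [, n_known]
    model_id: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def draw_sources(incidence: IncidenceMatrix, rng: np.random.Generator) -> dict:
    """Draw one source host per pest, uniformly among its recorded hosts."""
    breadths = incidence.breadths
    if (breadths < 2).any():
        bad = list(breadths.index[breadths < 2])
        raise FitError(
            f"pests with <2 host genera must be filtered before source draws: {bad[:5]}"
        )
    genera = np.array(incidence.genera)
    S = incidence.matrix.to_numpy()
    out = {}
    for pest, row in zip(incidence.pests, S):
        hosts = np.flatnonzero(row)
        out[pest] = str(genera[hosts[rng.integers(len(hosts))]])
    return out


def _aligned_arrays(incidence: IncidenceMatrix, distances: DistanceMatrix):
    """Incidence as int array and the distance matrix aligned to its genera."""
    genera = incidence.genera
    try:
        idx = distances.indices(genera)
    except KeyError as exc:
        raise FitError(f"incidence/distance genus mismatch: {exc}") from exc
    D = distances.values[np.ix_(idx, idx)]
    S = incidence.matrix.to_numpy(dtype=np.int8)
    return S, D


def _design_arrays(S: np.ndarray, D: np.ndarray, src: np.ndarray):
    """Vectorized source->target design: one row per (pest, non-source genus).

    Returns (y, x1, n_known, pest_row, target_col) flat arrays.
    """
    n_p, n_g = S.shape
    mask = np.ones((n_p, n_g), dtype=bool)
    mask[np.arange(n_p), src] = False
    x1_full = np.log10(D[src] + 1.0)
    n_known = S.sum(axis=1)
    y = S[mask].astype(float)
    x1 = x1_full[mask]
    nk = np.repeat(n_known, n_g - 1).astype(float)
    pest_row = np.repeat(np.arange(n_p), n_g - 1)
    target_col = np.broadcast_to(np.arange(n_g), (n_p, n_g))[mask]
    return y, x1, nk, pest_row, target_col


def build_design(
    incidence: IncidenceMatrix, sources: dict, distances: DistanceMatrix
) -> pd.DataFrame:
    """Build the long source->target design table for one source draw.

    One row per (pest, target genus != source) with the response S, the
    phylogenetic distance PD (My), x1 = log10(PD + 1), and the pest's
    in-universe host-genus count n_known.
    """
    genera = np.array(incidence.genera)
    genus_pos = {g: j for j, g in enumerate(genera)}
    missing = [p for p in incidence.pests if p not in sources]
    if missing:
        raise FitError(f"no source drawn for pests: {missing[:5]}")
    src = np.array([genus_pos[sources[p]] for p in incidence.pests])
    S, D = _aligned_arrays(incidence, distances)
    if not S[np.arange(len(src)), src].all():
        raise FitError("a source genus is not a recorded host of its pest")
    y, x1, nk, pest_row, target_col = _design_arrays(S, D, src)
    pests = np.array(incidence.pests)
    mask = np.ones_like(S, dtype=bool)
    mask[np.arange(len(src)), src] = False
    return pd.DataFrame(
        {
            "pest_id": pests[pest_row],
            "source_genus": genera[src][pest_row],
            "target_genus": genera[target_col],
            "S": y.astype(int),
            "PD": D[src][mask],
            "x1": x1,
            "n_known": nk.astype(int),
        }
    )


def _fit_arrays(y: np.ndarray, X: np.ndarray) -> LogisticFit:
    if y.min() == y.max():
        raise FitError("degenerate response: all targets share one outcome")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=MAX_ITER, tol=1e-10
            )
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.converged) and np.all(np.isfinite(params))
            loglik = float(res.llf)
        except Exception:
            return LogisticFit(
                params=np.full(X.shape[1], np.nan),
                converged=False,
                separated=True,
                loglik=-np.inf,
            )
    separated = bool(np.any(np.abs(params) > SEPARATION_THRESHOLD))
    return LogisticFit(params=params, converged=converged, separated=separated, loglik=loglik)


def fit_logistic(design: pd.DataFrame, spec: ModelSpec) -> LogisticFit:
    """Maximum-likelihood logistic fit of S on the model's predictors."""
    y = design["S"].to_numpy(dtype=float)
    X = spec.design_columns(
        design["x1"].to_numpy(dtype=float), design["n_known"].to_numpy(dtype=float)
    )
    fit = _fit_arrays(y, X)
    fit.coef_names = spec.coef_names
    return fit


def _summarize(runs: pd.DataFrame, spec: ModelSpec, group_meta: dict) -> pd.DataFrame:
    rows = []
    for group, sub in runs.groupby("group", sort=False):
        ok = sub[sub["converged"] & ~sub["separated"]]
        n_total = len(sub)
        for coef in spec.coef_names:
            if len(ok) == 0:
                med = lo = hi = np.nan
                sig = False
            else:
                vals = ok[coef].to_numpy()
                med = float(np.quantile(vals, 0.5))
                lo = float(np.quantile(vals, 0.025))
                hi = float(np.quantile(vals, 0.975))
                sig = bool(lo > 0 or hi < 0)
            rows.append(
                {
                    "pest_group": group,
                    "model": spec.model_id,
                    "coef": coef,
                    "median": med,
                    "ci_low": lo,
                    "ci_high": hi,
                    "significant": sig,
                    "n_pests": group_meta[group],
                    "n_runs_used": len(ok),
                    "n_runs_total": n_total,
                    "reliable": len(ok) >= 0.5 * n_total and len(ok) > 0,
                }
            )
    return pd.DataFrame(rows)


def run_resampling(
    incidence: IncidenceMatrix,
    distances: DistanceMatrix,
    spec: ModelSpec,
    n_runs: int = 1000,
    seed: int = 0,
    groups=None,
) -> tuple[CoefficientSummary, pd.DataFrame]:
    """Repeat source draws and per-group logistic fits; summarize by quantiles.

    Parameters
    ----------
    incidence :
        Pest x genus matrix already restricted to pests with >1 host genus.
    distances :
        Phylogenetic distance matrix covering every incidence genus.
    spec :
        Which nested model to fit (M1/M2/M3).
    n_runs :
        Number of independent source redraws (1000 in a full analysis).
    seed :
        Top-level seed; run ``r`` uses the dedicated stream ``(seed, r)`` so
        runs are independently reproducible.
    groups :
        Optional subset of pest groups; defaults to all groups present.

    Returns
    -------
    (CoefficientSummary, runs) where ``runs`` holds every per-run coefficient
    vector with convergence/separation flags. Runs flagged non-converged or
    separated are excluded from the quantile summary and counted in
    ``CoefficientSummary.exclusions``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    breadths = incidence.breadths
    if (breadths < 2).any():
        raise FitError("run_resampling requires filter_multihost() to be applied first")

    present = [g for g in PEST_GROUPS if g in set(incidence.groups)]
    if groups is not None:
        unknown = sorted(set(groups) - set(PEST_GROUPS))
        if unknown:
            raise ValueError(f"unknown pest groups: {unknown}")
        skipped = sorted(set(groups) - set(present))
        for g in skipped:
            logger.warning("group %s has no eligible pests; skipped", g)
        present = [g for g in present if g in set(groups)]

    S_all, D = _aligned_arrays(incidence, distances)
    group_arr = incidence.groups.to_numpy()
    per_group = {}
    for g in present:
        rows = np.flatnonzero(group_arr == g)
        S = S_all[rows]
        hosts = [np.flatnonzero(r) for r in S]
        per_group[g] = (S, hosts)

    records = []
    n_coef = len(spec.coef_names)
    for r in range(n_runs):
        rng = np.random.default_rng([seed, r])
        for g in present:
            S, hosts = per_group[g]
            src = np.array([h[rng.integers(len(h))] for h in hosts])
            y, x1, nk, _, _ = _design_arrays(S, D, src)
            X = spec.design_columns(x1, nk)
            try:
                fit = _fit_arrays(y, X)
            except FitError:
                fit = LogisticFit(
                    params=np.full(n_coef, np.nan),
                    converged=False,
                    separated=False,
                    loglik=-np.inf,
                )
            rec = {"run": r, "group": g, "converged": fit.converged, "separated": fit.separated}
            rec.update(zip(spec.coef_names, fit.params))
            records.append(rec)

    runs = pd.DataFrame(records)
    meta = {g: len(per_group[g][1]) for g in present}
    table = _summarize(runs, spec, meta)
    exclusions = {
        g: int((~(sub["converged"] & ~sub["separated"])).sum())
        for g, sub in runs.groupby("group", sort=False)
    }
    for g, n_bad in exclusions.items():
        if n_bad > 0.5 * n_runs:
            logger.warning(
                "group %s: %d/%d runs excluded; summary flagged unreliable", g, n_bad, n_runs
            )
    summary = CoefficientSummary(
        table=table, model_id=spec.model_id, n_runs=n_runs, seed=seed, exclusions=exclusions
    )
    return summary, runs


def curve_envelope(
    runs: pd.DataFrame,
    spec: ModelSpec,
    grid_step: float = 5.0,
    max_pd: float = 320.0,
    n_known_at: int = None,
) -> CurveEnvelope:
    """Predicted-probability quantile band on a PD grid (default 5-My steps).

    Each converged, non-separated run contributes one predicted curve
    invlogit(b0 + b1*log10(PD+1) [+ b2*n_known_at [+ b3*log10(PD+1)*n_known_at]]);
    the envelope is the 0.025/0.5/0.975 quantiles across runs at each grid PD.
    """
    if runs.empty:
        raise ValueError("empty run list")
    if len(spec.coef_names) > 2 and n_known_at is None:
        raise ValueError(f"{spec.model_id} envelope requires n_known_at")
    grid = np.arange(0.0, max_pd + 0.5 * grid_step, grid_step)
    x1 = np.log10(grid + 1.0)
    nk = float(n_known_at) if n_known_at is not None else 0.0
    out = []
    for group, sub in runs.groupby("group", sort=False):
        ok = sub[sub["converged"] & ~sub["separated"]]
        if ok.empty:
            continue
        eta = np.outer(ok["b0"].to_numpy(), np.ones_like(grid))
        eta += np.outer(ok["b1"].to_numpy(), x1)
        if "n_known" in spec.predictors:
            eta += ok["b2"].to_numpy()[:, None] * nk
        if "x1:n_known" in spec.predictors:
            eta += np.outer(ok["b3"].to_numpy(), x1) * nk
        prob = expit(eta)
        q = np.quantile(prob, [0.025, 0.5, 0.975], axis=0)
        df = pd.DataFrame(
            {"group": group, "pd": grid, "q025": q[0], "q50": q[1], "q975": q[2]}
        )
        if n_known_at is not None:
            df["n_known"] = n_known_at
        out.append(df)
    if not out:
        raise ValueError("no converged runs to build an envelope from")
    return CurveEnvelope(table=pd.concat(out, ignore_index=True), model_id=spec.model_id)


def screen_interaction(
    incidence: IncidenceMatrix,
    distances: DistanceMatrix,
    n_runs: int = 1000,
    seed: int = 0,
    groups=None,
) -> pd.DataFrame:
    """Fit the distance x host-breadth interaction model and screen its term.

    Per pest group, reports the resampling median and 95% CI of the
    interaction coefficient and recommends the main-effects model (M2) when
    the interaction CI includes zero — the model-selection rule used for the
    final host-breadth analysis.
    """
    spec = ModelSpec("M3")
    summary, _ = run_resampling(
        incidence, distances, spec, n_runs=n_runs, seed=seed, groups=groups
    )
    b3 = summary.table[summary.table["coef"] == "b3"].copy()
    b3 = b3.rename(
        columns={"median": "interaction_median", "ci_low": "ci_low", "ci_high": "ci_high"}
    )
    b3["recommended_model"] = np.where(b3["significant"], "M3", "M2")
    b3["low_replication"] = n_runs < 30
    if n_runs < 30:
        logger.warning(
            "interaction screen based on only %d run(s); CIs understate uncertainty", n_runs
        )
    cols = [
        "pest_group",
        "interaction_median",
        "ci_low",
        "ci_high",
        "significant",
        "recommended_model",
        "n_pests",
        "n_runs_used",
        "n_runs_total",
        "low_replication",
    ]
    return b3[cols].reset_index(drop=True)
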