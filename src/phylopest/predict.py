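"""Host-risk prediction: which genera is a novel pest likely to attack?

Given fitted (or packaged) group-level logistic coefficients, the predicted
probability that a genus at phylogenetic distance PD from a known host is
susceptible is invlogit(b0 + b1*log10(PD+1) [+ b2*n_known]). With several
known hosts, per-source predictions are combined per target (max, noisy-or,
or mean) and targets are ranked to give an at-risk list.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from phylopest.incidence import PEST_GROUPS
from phylopest.tree import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoefficientRegistry",
    "load_default_registry",
    "predict_prob",
    "rank_targets",
    "RiskReport",
]

COMBINE_RULES = ("max", "noisy-or", "mean")


@dataclass
class CoefficientRegistry:
    """Per pest-group, per-model coefficient medians and CI bounds."""

    groups: dict  # group -> model -> coef -> {"median": float, "ci": (lo, hi)}
    provenance: str = "fitted"
    meta: dict = None

    def entry(self, pest_group: str, model: str) -> dict:
        try:
            return self.groups[pest_group][model]
        except KeyError:
            raise KeyError(
                f"no registry entry for group {pest_group!r}, model {model!r}"
            ) from None

    def coefficients(self, pest_group: str, model: str) -> dict:
        e = self.entry(pest_group, model)
        return {k: v["median"] for k, v in e.items() if isinstance(v, dict)}

    def slope_significant(self, pest_group: str, model: str = "M1") -> bool:
        return bool(self.entry(pest_group, model).get("slope_significant", True))

    @classmethod
    def from_yaml(cls, path) -> "CoefficientRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: dict) -> "CoefficientRegistry":
        groups = {}
        for g, models in raw["groups"].items():
            if g not in PEST_GROUPS:
                raise ValueError(f"registry names unknown pest group {g!r}")
            groups[g] = {
                m: v for m, v in models.items() if m in ("M1", "M2", "M3")
            }
        meta = {k: v for k, v in raw.items() if k != "groups"}
        return cls(groups=groups, provenance=raw.get("provenance", "fitted"), meta=meta)

    @classmethod
    def from_summary(cls, summary) -> "CoefficientRegistry":
        """Build a registry from a fitted resampling CoefficientSummary."""
        groups = {}
        for (g, model), sub in summary.table.groupby(["pest_group", "model"]):
            entry = {}
            for _, row in sub.iterrows():
                entry[row["coef"]] = {
                    "median": float(row["median"]),
                    "ci": (float(row["ci_low"]), float(row["ci_high"])),
                }
                if row["coef"] == "b1":
                    entry["slope_significant"] = bool(row["significant"])
            groups.setdefault(g, {})[model] = entry
        tag = f"fitted:seed={summary.seed},runs={summary.n_runs}"
        return cls(groups=groups, provenance=tag)


def load_default_registry() -> CoefficientRegistry:
    """Load the packaged published-coefficient registry."""
    ref = resources.files("phylopest") / "data" / "registry.yaml"
    raw = yaml.safe_load(ref.read_text())
    return CoefficientRegistry._from_raw(raw)


def gilbert_webb_coefficients() -> dict:
    """Empirical fungal host-range equation (logit scale) for comparison."""
    ref = resources.files("phylopest") / "data" / "registry.yaml"
    raw = yaml.safe_load(ref.read_text())
    return dict(raw["empirical_fungi_gilbert_webb"])


def predict_prob(coeffs: dict, pd_my, n_known: int = None):
    """Probability a target at distance ``pd_my`` (My) is susceptible.

    ``coeffs`` holds at least b0 and b1 (medians); b2 requires ``n_known``.
    Accepts scalar or array PD.
    """
    pd_my = np.asarray(pd_my, dtype=float)
    if np.any(pd_my < 0):
        raise ValueError("phylogenetic distance must be >= 0")
    eta = coeffs["b0"] + coeffs["b1"] * np.log10(pd_my + 1.0)
    if "b2" in coeffs:
        if n_known is None:
            raise ValueError("n_known is required for a model with a b2 term")
        eta = eta + coeffs["b2"] * float(n_known)
    out = expit(eta)
    return float(out) if out.ndim == 0 else out


@dataclass
class RiskReport:
    """Ranked per-target susceptibility predictions for one pest."""

    pest_group: str
    table: pd.DataFrame  # target, per-source probs, combined, rank, known_host flag
    settings: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json_meta(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.settings, fh, indent=1)


def _combine(per_source: np.ndarray, rule: str) -> np.ndarray:
    if rule == "max":
        return per_source.max(axis=1)
    if rule == "noisy-or":
        return 1.0 - np.prod(1.0 - per_source, axis=1)
    if rule == "mean":
        return per_source.mean(axis=1)
    raise ValueError(f"unknown combine rule {rule!r}; expected one of {COMBINE_RULES}")


def rank_targets(
    registry: CoefficientRegistry,
    pest_group: str,
    known_hosts,
    targets,
    distances: DistanceMatrix,
    model: str = "M1",
    combine: str = "max",
) -> RiskReport:
    """Rank target genera by predicted susceptibility to a pest.

    For each target t and known host s, p_s(t) = predict_prob at PD(s, t)
    with n_known = number of known hosts; per-source probabilities are then
    combined per ``combine`` (max is the default: one close relative
    suffices; noisy-or treats sources as independent evidence). Targets that
    are themselves known hosts are reported with probability 1 and flagged.
    Ties share the minimum rank.
    """
    known_hosts = list(dict.fromkeys(known_hosts))
    targets = list(targets)
    if not known_hosts:
        raise ValueError("at least one known host is required")
    if not targets:
        raise ValueError("empty target list")
    distances.indices(known_hosts)  # raises on unknown genus
    distances.indices(targets)

    coeffs = registry.coefficients(pest_group, model)
    if model == "M1" and not registry.slope_significant(pest_group, "M1"):
        warnings.warn(
            f"phylogenetic signal for group {pest_group!r} is not significant "
            "in this registry; predictions are weakly informative"
        )
    n_known = len(known_hosts)
    per_source = np.column_stack(
        [
            predict_prob(
                coeffs,
                np.array([distances.loc(s, t) for t in targets]),
                n_known=n_known if "b2" in coeffs else None,
            )
            for s in known_hosts
        ]
    )
    combined = _combine(per_source, combine)
    known = np.array([t in set(known_hosts) for t in targets])
    combined = np.where(known, 1.0, combined)

    df = pd.DataFrame({"target_genus": targets})
    for i, s in enumerate(known_hosts):
        df[f"p_from_{s}"] = per_source[:, i]
    df["combined_prob"] = combined
    df["known_host"] = known
    df = df.sort_values("combined_prob", ascending=False, kind="mergesort")
    df["rank"] = (
        df["combined_prob"].rank(method="min", ascending=False).astype(int)
    )
    settings = {
        "pest_group": pest_group,
        "model": model,
        "combine": combine,
        "n_known": n_known,
        "known_hosts": known_hosts,
        "registry_provenance": registry.provenance,
    }
    return RiskReport(pest_group=pest_group, table=df.reset_index(drop=True), settings=settings)
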