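"""Pest-host records, the binary incidence matrix, and host-breadth structure.

Host-range compendia record only presences: a cell S[pest, genus] = 1 means
the genus is recorded susceptible, and 0 means susceptibility is *assumed*
absent (no-record, not a tested resistance). All downstream inference adopts
that assumption, so breadths and sharing probabilities are lower bounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from phylopest.errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "PEST_GROUPS",
    "IncidenceMatrix",
    "BreadthSummary",
    "load_records",
    "collapse_to_genus",
    "host_breadth",
    "compare_breadth",
    "filter_multihost",
]

#: Closed vocabulary of pest/pathogen groups: distinct kingdoms, and within
#: the animals the major feeding/life-history divisions.
PEST_GROUPS = (
    "bacteria",
    "fungi",
    "oomycetes",
    "insects",
    "mites",
    "mollusks",
    "nematodes",
    "viruses",
    "plants",
)

REQUIRED_COLUMNS = ("pest_id", "pest_group", "host_genus")


@dataclass
class IncidenceMatrix:
    """Binary pests x genera susceptibility matrix with per-pest group labels.

    ``matrix`` is a pandas DataFrame (index: pest_id, columns: genus,
    values in {0, 1}); ``groups`` maps pest_id -> pest group.
    """

    matrix: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        if self.matrix.columns.duplicated().any():
            raise DataError("duplicate genus columns in incidence matrix")
        if not self.matrix.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.matrix.index)
        if self.groups.isna().any():
            raise DataError("every pest needs a group label")

    @property
    def pests(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def genera(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def breadths(self) -> pd.Series:
        """Host breadth: number of recorded host genera per pest."""
        return self.matrix.sum(axis=1)

    @property
    def density(self) -> float:
        """Fraction of pest x genus cells that are recorded host associations."""
        return float(self.matrix.to_numpy().mean())

    def hosts_of(self, pest_id: str) -> list[str]:
        row = self.matrix.loc[pest_id]
        return list(row.index[row == 1])

    def to_long(self) -> pd.DataFrame:
        long = self.matrix.stack().rename("S").reset_index()
        long.columns = ["pest_id", "host_genus", "S"]
        return long

    def to_wide_csv(self, path) -> None:
        out = self.matrix.copy()
        out.insert(0, "pest_group", self.groups)
        out.to_csv(path, index_label="pest_id")

    @classmethod
    def from_wide_csv(cls, path) -> "IncidenceMatrix":
        df = pd.read_csv(path, index_col="pest_id")
        groups = df.pop("pest_group")
        return cls(matrix=df.astype(np.int8), groups=groups)


@dataclass
class BreadthSummary:
    """Host-breadth structure per pest group plus per-genus pest loads."""

    per_group: pd.DataFrame  # index: group; columns: n_pests, median, min, max, pct_single
    ecdfs: dict = field(repr=False, default_factory=dict)  # group -> (values, ecdf)
    pests_per_genus: pd.Series = None
    pests_per_genus_by_group: pd.DataFrame = None

    def to_json(self, path) -> None:
        payload = {
            "per_group": self.per_group.reset_index().to_dict(orient="records"),
            "pests_per_genus": self.pests_per_genus.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def load_records(path) -> pd.DataFrame:
    """Load and normalize a pest-host record CSV.

    Requires columns pest_id, pest_group, host_genus (host_species optional).
    Group names are case-normalized against the closed nine-group vocabulary;
    fully duplicated rows are dropped.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"records file missing required columns: {missing}")
    for col in REQUIRED_COLUMNS:
        df[col] = df[col].astype(str).str.strip()
    df["pest_group"] = df["pest_group"].str.lower()
    bad = sorted(set(df["pest_group"]) - set(PEST_GROUPS))
    if bad:
        raise DataError(
            f"unknown pest_group value(s) {bad}; expected one of {sorted(PEST_GROUPS)}"
        )
    ambiguous = df.groupby("pest_id")["pest_group"].nunique()
    ambiguous = ambiguous[ambiguous > 1]
    if not ambiguous.empty:
        raise DataError(f"pests with conflicting group labels: {list(ambiguous.index)}")
    before = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if before - len(df):
        logger.info("dropped %d duplicated record rows", before - len(df))
    return df


def collapse_to_genus(records: pd.DataFrame, genus_universe) -> IncidenceMatrix:
    """Collapse species-level records to the genus-level incidence matrix.

    A genus is susceptible to a pest if the pest is recorded on *any* species
    in the genus. Records on genera outside ``genus_universe`` are dropped
    (logged), as are pests left with zero in-universe hosts: distances are
    undefined off the tree.
    """
    genus_universe = list(genus_universe)
    if not genus_universe:
        raise DataError("genus universe is empty")
    if len(set(genus_universe)) != len(genus_universe):
        raise DataError("genus universe contains duplicates")

    in_universe = records["host_genus"].isin(set(genus_universe))
    n_dropped_records = int((~in_universe).sum())
    if n_dropped_records:
        logger.info(
            "dropped %d records on genera outside the %d-genus universe",
            n_dropped_records,
            len(genus_universe),
        )
    kept = records[in_universe]
    all_pests = records["pest_id"].unique()
    n_dropped_pests = len(all_pests) - kept["pest_id"].nunique()
    if n_dropped_pests:
        logger.info("dropped %d pests with no in-universe hosts", n_dropped_pests)
    if kept.empty:
        raise DataError("no pest has any host in the genus universe")

    pests = list(pd.unique(kept["pest_id"]))
    pest_pos = {p: i for i, p in enumerate(pests)}
    genus_pos = {g: j for j, g in enumerate(genus_universe)}
    arr = np.zeros((len(pests), len(genus_universe)), dtype=np.int8)
    arr[
        [pest_pos[p] for p in kept["pest_id"]],
        [genus_pos[g] for g in kept["host_genus"]],
    ] = 1
    mat = pd.DataFrame(
        arr, index=pd.Index(pests, name="pest_id"), columns=genus_universe
    )
    groups = kept.drop_duplicates("pest_id").set_index("pest_id")["pest_group"]
    return IncidenceMatrix(matrix=mat, groups=groups.loc[pests])


def host_breadth(incidence: IncidenceMatrix) -> BreadthSummary:
    """Summarize host breadth per pest group, plus pest loads per genus."""
    if incidence.matrix.empty:
        raise DataError("empty incidence matrix")
    breadths = incidence.breadths
    rows = []
    ecdfs = {}
    for group, idx in incidence.groups.groupby(incidence.groups).groups.items():
        b = breadths.loc[idx].to_numpy()
        rows.append(
            {
                "pest_group": group,
                "n_pests": len(b),
                "median_hosts": float(np.median(b)),
                "min_hosts": int(b.min()),
                "max_hosts": int(b.max()),
                "pct_single_genus": 100.0 * float((b == 1).mean()),
            }
        )
        xs = np.sort(b)
        ecdfs[group] = (xs, np.arange(1, len(xs) + 1) / len(xs))
    per_group = pd.DataFrame(rows).set_index("pest_group")
    per_genus = incidence.matrix.sum(axis=0)
    per_genus_by_group = incidence.matrix.groupby(incidence.groups).sum().T
    return BreadthSummary(
        per_group=per_group,
        ecdfs=ecdfs,
        pests_per_genus=per_genus,
        pests_per_genus_by_group=per_genus_by_group,
    )


def compare_breadth(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of host-count distributions.

    Returns (D, p) with D = sup |ECDF_a - ECDF_b| and an asymptotic two-sided
    p-value (breadth samples here are well above the small-sample regime).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("cannot compare empty host-count samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def filter_multihost(incidence: IncidenceMatrix) -> IncidenceMatrix:
    """Keep only pests with >1 recorded host genus.

    Single-host pests carry no source-to-target contrast: with their one host
    consumed as the source, every target row is 0 and the pest would only
    force the fitted intercept down. They are excluded from regression.
    """
    keep = incidence.breadths >= 2
    if not keep.any():
        logger.warning("no pest has more than one host genus; result is empty")
    return IncidenceMatrix(
        matrix=incidence.matrix.loc[keep],
        groups=incidence.groups.loc[keep[keep].index],
    )
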