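"""Scan-sampling observation tables and weighted bipartite ant-behaviour networks.

The observation design is instantaneous scan sampling: every ant in a colony is
censused for 5 minutes every 3 hours (8 scans per day at 00:00, 03:00, ...,
21:00) over 3 consecutive days, and each scan assigns the ant exactly one
behaviour from a closed vocabulary. A colony's data become a weighted bipartite
network whose rows are individuals, whose columns are behaviour-nodes (a
behaviour crossed with a day, a day/night period, or nothing), and whose
weights count how many scans showed that individual performing that behaviour
within the column's scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Closed behaviour vocabulary. "walking" is the active in-nest state (incl.
#: grooming, trophallaxis, in-nest feeding); "inactive" means completely
#: immobile for the whole scan; the three brood-care behaviours are separated
#: by brood stage; "foraging" is any activity outside the nest.
BEHAVIOURS: tuple[str, ...] = (
    "walking",
    "inactive",
    "egg_care",
    "larva_care",
    "pupa_care",
    "foraging",
)

#: Legal scan times (hours of day, every 3 h).
SLOTS: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18, 21)

#: Supported column schemes for network construction.
COLUMN_SCHEMES = ("behaviour_by_day", "behaviour_aggregate", "behaviour_by_period")

OBSERVATION_COLUMNS = ["colony_id", "ant_id", "day", "slot", "behaviour"]
METADATA_COLUMNS = ["ant_id", "age_days", "is_queen"]


class VocabularyError(ValueError):
    """A behaviour label outside the closed vocabulary."""


class IntegrityError(ValueError):
    """A violated record invariant (e.g. duplicate ant/day/slot)."""


@dataclass(frozen=True)
class ObservationRecord:
    """One scan sample: what one ant was doing at one time point."""

    colony_id: str
    ant_id: str
    day: int
    slot: int
    behaviour: str


@dataclass(frozen=True)
class AntMetadata:
    """Per-ant attributes: age since eclosion (days, may be unknown) and queen flag."""

    ant_id: str
    age_days: float | None = None
    is_queen: bool = False


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an observation table in place and return it.

    Raises :class:`VocabularyError` for unknown behaviour labels,
    :class:`IntegrityError` for duplicate (ant, day, slot) records and
    ``ValueError`` for malformed day/slot values or missing columns.
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    df = df.copy()
    for col in ("day", "slot"):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed integer values in column {col!r}") from exc
    bad_slots = sorted(set(df["slot"]) - set(SLOTS))
    if bad_slots:
        raise ValueError(f"illegal slot values {bad_slots}; legal slots are {SLOTS}")
    if (df["day"] < 1).any():
        raise ValueError("day indices must be >= 1")
    unknown = sorted(set(df["behaviour"]) - set(BEHAVIOURS))
    if unknown:
        raise VocabularyError(
            f"unknown behaviour label(s) {unknown}; vocabulary is {BEHAVIOURS}"
        )
    dup = df.duplicated(subset=["ant_id", "day", "slot"], keep=False)
    if dup.any():
        first = df.loc[dup, ["ant_id", "day", "slot"]].iloc[0]
        raise IntegrityError(
            "duplicate scan record(s): e.g. ant "
            f"{first['ant_id']!r} day {first['day']} slot {first['slot']}"
        )
    df["colony_id"] = df["colony_id"].astype(str)
    df["ant_id"] = df["ant_id"].astype(str)
    return df


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate an observation CSV/TSV (header: colony_id,ant_id,day,slot,behaviour).

    Missing scans are simply absent rows; nothing is imputed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return validate_observations(df)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read an ant metadata CSV (header: ant_id,age_days,is_queen)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    df = df.copy()
    df["ant_id"] = df["ant_id"].astype(str)
    if df["ant_id"].duplicated().any():
        raise IntegrityError("duplicate ant_id in metadata")
    df["age_days"] = pd.to_numeric(df["age_days"], errors="coerce")
    if (df["age_days"].dropna() < 0).any():
        raise ValueError("age_days must be non-negative")
    df["is_queen"] = df["is_queen"].astype(bool)
    return df


def records_to_frame(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    """Convert a sequence of :class:`ObservationRecord` into a validated table."""
    df = pd.DataFrame([vars(r) for r in records], columns=OBSERVATION_COLUMNS)
    return validate_observations(df)


@dataclass
class BipartiteNetwork:
    """Weighted individual x behaviour-node matrix with margins.

    ``A[i, j]`` counts the scans in which individual ``row_labels[i]`` showed
    the behaviour of column ``col_labels[j]`` within that column's day/period
    scope. Column labels are strings ``"behaviour"``, ``"behaviour|d<day>"`` or
    ``"behaviour|<period>"`` depending on the scheme.
    """

    A: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    scheme: str = "behaviour_by_day"
    colony_id: str | None = None
    prune_report: dict = field(default_factory=lambda: {"rows": [], "cols": []})

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.ndim != 2:
            raise ValueError("A must be a 2-d matrix")
        if self.A.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("A shape does not match label lengths")
        if (self.A < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def r(self) -> int:
        return self.A.shape[0]

    @property
    def s(self) -> int:
        return self.A.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Row margins (total weight per individual)."""
        return self.A.sum(axis=1)

    @property
    def z(self) -> np.ndarray:
        """Column margins (total weight per behaviour-node)."""
        return self.A.sum(axis=0)

    @property
    def M(self) -> int:
        """Total network weight."""
        return int(self.A.sum())

    def column_behaviour(self, j: int) -> str:
        return self.col_labels[j].split("|", 1)[0]

    def column_scope(self, j: int) -> str | None:
        parts = self.col_labels[j].split("|", 1)
        return parts[1] if len(parts) == 2 else None

    # -- serialization ------------------------------------------------------

    def to_edgelist(self, path: str | Path) -> None:
        """Write a long edge-list CSV plus a JSON sidecar with labels and scheme."""
        path = Path(path)
        rows = []
        for i, ant in enumerate(self.row_labels):
            for j, node in enumerate(self.col_labels):
                w = int(self.A[i, j])
                if w > 0:
                    rows.append((ant, node, w))
        pd.DataFrame(rows, columns=["ant_id", "behaviour_node", "weight"]).to_csv(
            path, index=False
        )
        sidecar = {
            "row_labels": self.row_labels,
            "col_labels": self.col_labels,
            "scheme": self.scheme,
            "colony_id": self.colony_id,
            "prune_report": self.prune_report,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def from_edgelist(cls, path: str | Path) -> "BipartiteNetwork":
        """Rebuild a network from :meth:`to_edgelist` output (exact round trip)."""
        path = Path(path)
        edges = pd.read_csv(path, dtype={"ant_id": str, "behaviour_node": str})
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        rows = list(sidecar["row_labels"])
        cols = list(sidecar["col_labels"])
        A = np.zeros((len(rows), len(cols)), dtype=int)
        ri = {a: i for i, a in enumerate(rows)}
        ci = {c: j for j, c in enumerate(cols)}
        for t in edges.itertuples(index=False):
            A[ri[t.ant_id], ci[t.behaviour_node]] = int(t.weight)
        return cls(
            A=A,
            row_labels=rows,
            col_labels=cols,
            scheme=sidecar["scheme"],
            colony_id=sidecar.get("colony_id"),
            prune_report=sidecar.get("prune_report", {"rows": [], "cols": []}),
        )


def build_network(
    records: pd.DataFrame | Iterable[ObservationRecord],
    column_scheme: str = "behaviour_by_day",
    prune_empty: bool = True,
    metadata: pd.DataFrame | None = None,
    exclude_queen: bool = False,
    period_map: Mapping[int, str] | None = None,
) -> BipartiteNetwork:
    """Build the weighted bipartite network from validated observation records.

    Parameters
    ----------
    records
        Validated observation table (or ObservationRecord sequence).
    column_scheme
        ``behaviour_by_day`` (default; behaviour x observation day, the unit of
        the main analysis), ``behaviour_aggregate`` (behaviour only, max weight
        ``8 x n_days``) or ``behaviour_by_period`` (behaviour x day/night
        period; requires ``period_map``).
    prune_empty
        Drop all-zero rows and columns and record them in ``prune_report``.
        Network statistics (modularity, nestedness, specialization) assume a
        pruned network.
    metadata, exclude_queen
        When metadata is given, its ants are candidate rows even with zero
        records (they are then pruned and reported); with ``exclude_queen``
        the queen's records are removed before building. The queen is an
        ordinary row by default.
    period_map
        slot -> period mapping for ``behaviour_by_period`` (see
        :data:`polyethnet.temporal_age.DEFAULT_PERIOD_MAP`).
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    else:
        records = validate_observations(records)
    if len(records) == 0:
        raise ValueError("empty record set: cannot build a network")
    if column_scheme not in COLUMN_SCHEMES:
        raise ValueError(
            f"unknown column scheme {column_scheme!r}; choose from {COLUMN_SCHEMES}"
        )

    colony_ids = records["colony_id"].unique()
    colony_id = str(colony_ids[0]) if len(colony_ids) == 1 else None

    if exclude_queen:
        if metadata is None:
            raise ValueError("exclude_queen requires a metadata table")
        queens = set(metadata.loc[metadata["is_queen"], "ant_id"])
        records = records[~records["ant_id"].isin(queens)]
        if len(records) == 0:
            raise ValueError("no records left after excluding the queen")

    ants = sorted(records["ant_id"].unique())
    if metadata is not None:
        extra = [a for a in sorted(metadata["ant_id"]) if a not in set(ants)]
        if exclude_queen:
            queens = set(metadata.loc[metadata["is_queen"], "ant_id"])
            extra = [a for a in extra if a not in queens]
        ants = ants + extra

    if column_scheme == "behaviour_by_day":
        days = sorted(records["day"].unique())
        cols = [f"{b}|d{d}" for b in BEHAVIOURS for d in days]
        key = records["behaviour"] + "|d" + records["day"].astype(str)
    elif column_scheme == "behaviour_aggregate":
        cols = list(BEHAVIOURS)
        key = records["behaviour"]
    else:  # behaviour_by_period
        if period_map is None:
            raise ValueError("behaviour_by_period requires a period_map")
        missing = sorted(set(SLOTS) - set(period_map))
        if missing:
            raise ValueError(f"period_map must cover all slots; missing {missing}")
        periods = list(dict.fromkeys(period_map[s] for s in SLOTS))
        cols = [f"{b}|{p}" for b in BEHAVIOURS for p in periods]
        key = records["behaviour"] + "|" + records["slot"].map(period_map)

    A = np.zeros((len(ants), len(cols)), dtype=int)
    ri = {a: i for i, a in enumerate(ants)}
    ci = {c: j for j, c in enumerate(cols)}
    counted = pd.DataFrame({"i": records["ant_id"].map(ri), "j": key.map(ci)})
    grouped = counted.value_counts().reset_index(name="w")
    A[grouped["i"].to_numpy(), grouped["j"].to_numpy()] = grouped["w"].to_numpy()

    report = {"rows": [], "cols": []}
    if prune_empty:
        row_keep = A.sum(axis=1) > 0
        col_keep = A.sum(axis=0) > 0
        report["rows"] = [a for a, k in zip(ants, row_keep) if not k]
        report["cols"] = [c for c, k in zip(cols, col_keep) if not k]
        A = A[np.ix_(row_keep, col_keep)]
        ants = [a for a, k in zip(ants, row_keep) if k]
        cols = [c for c, k in zip(cols, col_keep) if k]

    return BipartiteNetwork(
        A=A,
        row_labels=list(ants),
        col_labels=list(cols),
        scheme=column_scheme,
        colony_id=colony_id,
        prune_report=report,
    )


def load_deposited_colony(
    colony: str, data_dir: str | Path = "data/deposited"
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Load one of the published study colonies (a-e) from ``data_dir``.

    The original five-colony field tables are distributed as journal
    supplementary material and are not redistributed with this package;
    after downloading, convert them to the observation schema and save them as
    ``<data_dir>/colony_<id>_observations.csv`` (and optionally
    ``colony_<id>_metadata.csv``). Returns (observations, metadata-or-None).
    """
    data_dir = Path(data_dir)
    obs_path = data_dir / f"colony_{colony}_observations.csv"
    if not obs_path.exists():
        raise FileNotFoundError(
            f"deposited data for colony {colony!r} not found at {obs_path}; "
            "download the published supplementary tables and convert them to "
            "the observation CSV schema (colony_id,ant_id,day,slot,behaviour)"
        )
    records = read_observations(obs_path)
    meta_path = data_dir / f"colony_{colony}_metadata.csv"
    metadata = read_metadata(meta_path) if meta_path.exists() else None
    return records, metadata


def connectance(net: BipartiteNetwork) -> float:
    """Fraction of possible individual x behaviour-node links that are realized."""
    if net.r < 1 or net.s < 1:
        raise ValueError("connectance needs at least one row and one column")
    return float(np.count_nonzero(net.A)) / (net.r * net.s)
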