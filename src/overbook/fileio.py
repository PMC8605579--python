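"""Readers, writers, configuration files and run manifests.

Bookings travel as CSV with ISO-8601 dates; center configurations as YAML
(sets with prices and resource-name lists, resources with ideal levels and
either an explicit maximum allowable overage or an overage fraction of the
ideal level, and the marginal overage-cost schedule).  Every result written
by the CLI is accompanied by a JSON manifest — command, inputs, seed,
version, timestamp — sufficient to reproduce it.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .core_model import CenterConfig, ExaminationSet, Resource, SetResourceMatrix
from .cost_model import OverageCostSchedule
from .data_prep import REQUIRED_COLUMNS

__all__ = [
    "read_bookings",
    "write_bookings",
    "read_holidays",
    "write_holidays",
    "load_config",
    "save_config",
    "default_config_path",
    "RunManifest",
]

_DATE_COLUMNS = ("booking_date", "examination_date", "cancellation_date")


def read_bookings(path: str | Path) -> pd.DataFrame:
    """Read a booking CSV, validating the schema and parsing dates.

    Missing mandatory columns raise immediately; unparseable dates are
    collected and reported with their (1-based, header-inclusive) line
    numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    errors: list[str] = []
    for col in _DATE_COLUMNS:
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = df[col].notna() & parsed.isna()
        for idx in df.index[bad]:
            errors.append(f"line {idx + 2}: unparseable {col} {df.loc[idx, col]!r}")
        df[col] = parsed
    if errors:
        raise ValueError(f"{path}: {len(errors)} row error(s):\n" + "\n".join(errors))
    return df


def write_bookings(records: pd.DataFrame, path: str | Path) -> None:
    df = records.copy()
    for col in _DATE_COLUMNS:
        if col in df:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_holidays(path: str | Path) -> list[dt.date]:
    """One ISO date per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(dt.date.fromisoformat(line))
    return out


def write_holidays(holidays: Sequence[dt.date], path: str | Path) -> None:
    Path(path).write_text("\n".join(h.isoformat() for h in holidays) + "\n")


def load_config(path: str | Path) -> tuple[CenterConfig, OverageCostSchedule]:
    """Parse and validate a center-configuration YAML file.

    All structural invariants (binary V with no empty set column, positive
    prices, nondecreasing marginal costs) are enforced at load time by the
    domain types.
    """
    payload = yaml.safe_load(Path(path).read_text())
    resources_cfg = payload["resources"]
    sets_cfg = payload["sets"]
    resource_objs = []
    for rc in resources_cfg:
        K = int(rc["ideal_consumer_level"])
        if "max_allowable_overage" in rc:
            U = int(rc["max_allowable_overage"])
        elif "overage_fraction" in rc:
            U = int(K * float(rc["overage_fraction"]))  # floor
        else:
            U = 0
        resource_objs.append(Resource(rc["name"], K, U))
    names = [r.name for r in resource_objs]
    set_objs, columns = [], []
    for sc in sets_cfg:
        set_objs.append(
            ExaminationSet(
                sc["name"],
                float(sc["price"]),
                int(sc.get("original_booking_limit", 0)),
            )
        )
        unknown = set(sc["resources"]) - set(names)
        if unknown:
            raise ValueError(f"set {sc['name']!r} uses unknown resource(s) {unknown}")
        columns.append([1 if n in sc["resources"] else 0 for n in names])
    matrix = SetResourceMatrix([[col[i] for col in columns] for i in range(len(names))])
    config = CenterConfig(tuple(set_objs), tuple(resource_objs), matrix)
    sched_cfg = payload.get("cost_schedule", {})
    kwargs = {}
    if sched_cfg.get("marginal_costs"):
        kwargs["marginal_costs"] = tuple(sched_cfg["marginal_costs"])
    if "extrapolation" in sched_cfg:  # explicit override for reproducibility
        kwargs["extrapolation"] = tuple(sched_cfg["extrapolation"])
    schedule = OverageCostSchedule(**kwargs)
    return config, schedule


def save_config(
    config: CenterConfig, schedule: OverageCostSchedule, path: str | Path
) -> None:
    names = [r.name for r in config.resources]
    payload = {
        "resources": [
            dict(
                name=r.name,
                ideal_consumer_level=r.ideal_consumer_level,
                max_allowable_overage=r.max_allowable_overage,
            )
            for r in config.resources
        ],
        "sets": [
            dict(
                name=s.name,
                price=s.price,
                original_booking_limit=s.original_booking_limit,
                resources=[
                    names[i]
                    for i in range(config.n_resources)
                    if config.matrix.entries[i, j]
                ],
            )
            for j, s in enumerate(config.sets)
        ],
        "cost_schedule": {"marginal_costs": list(schedule.marginal_costs)},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def default_config_path() -> Path:
    """Path of the shipped default center configuration."""
    return Path(resources.files("overbook") / "data" / "default_config.yaml")


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record written next to every CLI result."""

    command: str
    inputs: Mapping[str, str]
    seed: int | None
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: dt.datetime.now(dt.timezone.utc).isoformat()
    )

    def write(self, result_path: str | Path) -> Path:
        path = Path(str(result_path) + ".manifest.json")
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
        return path
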