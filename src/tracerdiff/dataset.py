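"""Diffusivity database records, CSV I/O, polarity partitioning and the
70/30 train/test split.

A *record* is one measurement of D12 for a (solvent, solute) pair at a given
state point; a *system* is the unique pair. Splitting is at the record level
and seeded, so the same partition can be reused by the machine-learning and
the classic-model evaluations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .compounds import CompoundLookupError, CompoundTable

__all__ = [
    "SCHEMA_VERSION",
    "SCHEMA_COLUMNS",
    "DatasetError",
    "DiffusionRecord",
    "SplitDataset",
    "read_dataset",
    "write_dataset",
    "records_to_frame",
    "system_key",
    "n_systems",
    "split_train_test",
    "partition_polarity",
]

SCHEMA_VERSION = "tracerdiff-dataset-v1"
#: Column dialect: units are frozen in the names.
SCHEMA_COLUMNS = [
    "solvent_cas", "solute_cas", "T_K", "rho1_g_cm3", "mu1_cP",
    "D12_cm2_s", "polarity", "source",
]
_SCHEMA_HEADER = (
    f"# {SCHEMA_VERSION}: T_K in K, rho1_g_cm3 in g/cm3, mu1_cP in cP, "
    "D12_cm2_s in cm2/s"
)
_POLARITIES = {"polar", "nonpolar"}


class DatasetError(ValueError):
    """Schema or content violation in a diffusivity data file."""


@dataclass(frozen=True)
class DiffusionRecord:
    """One D12 measurement: system key plus state point."""

    solvent: str
    solute: str
    T: float           # K
    rho1: float        # g/cm3
    mu1: float         # cP
    D12: float         # cm2/s
    polarity: str
    source: str = ""

    def __post_init__(self) -> None:
        if min(self.T, self.mu1, self.D12) <= 0:
            raise DatasetError("T, mu1 and D12 must be positive")
        if self.rho1 <= 0:
            raise DatasetError("rho1 must be positive")
        if self.polarity not in _POLARITIES:
            raise DatasetError(f"polarity must be one of {sorted(_POLARITIES)}")


def system_key(record: DiffusionRecord) -> tuple[str, str]:
    """The (solvent, solute) ordered pair identifying a system."""
    return (record.solvent, record.solute)


def n_systems(records: Iterable[DiffusionRecord]) -> int:
    return len({system_key(r) for r in records})


def records_to_frame(records: Iterable[DiffusionRecord]) -> pd.DataFrame:
    rows = [
        {
            "solvent_cas": r.solvent, "solute_cas": r.solute, "T_K": r.T,
            "rho1_g_cm3": r.rho1, "mu1_cP": r.mu1, "D12_cm2_s": r.D12,
            "polarity": r.polarity, "source": r.source,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=SCHEMA_COLUMNS)


def write_dataset(records: Iterable[DiffusionRecord], path: str | Path) -> None:
    """Write records as a comma-delimited file with a schema header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_SCHEMA_HEADER + "\n")
        # %.17g round-trips doubles exactly
        records_to_frame(records).to_csv(fh, index=False, float_format="%.17g")


def read_dataset(
    path: str | Path, compounds: CompoundTable | None = None
) -> list[DiffusionRecord]:
    """Read and validate a diffusivity data file.

    Errors cite the offending data row (1-based, excluding header lines) and
    column. If a compound table is given, solvent/solute keys must resolve.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            comment="#",
            dtype={"solvent_cas": str, "solute_cas": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # malformed CSV
        raise DatasetError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns and c != "source"]
    if missing:
        raise DatasetError(f"{path}: missing column(s) {missing}")
    if "source" not in df.columns:
        df["source"] = ""
    records: list[DiffusionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        for col in ("T_K", "rho1_g_cm3", "mu1_cP", "D12_cm2_s"):
            val = getattr(row, col)
            try:
                val = float(val)
            except (TypeError, ValueError):
                raise DatasetError(f"{path}: row {i}, column {col}: non-numeric cell")
            if not np.isfinite(val) or val <= 0:
                raise DatasetError(
                    f"{path}: row {i}, column {col}: must be a positive number"
                )
        if row.polarity not in _POLARITIES:
            raise DatasetError(
                f"{path}: row {i}, column polarity: expected polar|nonpolar, "
                f"got {row.polarity!r}"
            )
        if compounds is not None:
            for col in ("solvent_cas", "solute_cas"):
                key = getattr(row, col)
                try:
                    compounds.lookup(key)
                except CompoundLookupError as exc:
                    raise DatasetError(
                        f"{path}: row {i}, column {col}: unknown compound {key!r}"
                    ) from exc
        records.append(
            DiffusionRecord(
                solvent=str(row.solvent_cas),
                solute=str(row.solute_cas),
                T=float(row.T_K),
                rho1=float(row.rho1_g_cm3),
                mu1=float(row.mu1_cP),
                D12=float(row.D12_cm2_s),
                polarity=str(row.polarity),
                source="" if pd.isna(row.source) else str(row.source),
            )
        )
    return records


@dataclass(frozen=True)
class SplitDataset:
    """A seeded record-level train/test partition."""

    train: list[DiffusionRecord]
    test: list[DiffusionRecord]
    seed: int
    fraction: float

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_dataset(self.train, directory / "train.csv")
        write_dataset(self.test, directory / "test.csv")
        meta = {"schema": SCHEMA_VERSION, "seed": self.seed, "fraction": self.fraction}
        (directory / "split.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SplitDataset":
        directory = Path(directory)
        meta = json.loads((directory / "split.json").read_text())
        return cls(
            train=read_dataset(directory / "train.csv"),
            test=read_dataset(directory / "test.csv"),
            seed=int(meta["seed"]),
            fraction=float(meta["fraction"]),
        )


def split_train_test(
    records: list[DiffusionRecord], fraction: float = 0.70, seed: int = 0
) -> SplitDataset:
    """Random record-level split, reproducible under `seed`.

    The train share is floor(n * fraction); with n = 1431 and the default
    70% fraction this yields 1001 train and 430 test records.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(len(records) * fraction)
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    return SplitDataset(
        train=[records[i] for i in train_idx],
        test=[records[i] for i in test_idx],
        seed=seed,
        fraction=fraction,
    )


def partition_polarity(
    records: Iterable[DiffusionRecord],
) -> Mapping[str, list[DiffusionRecord]]:
    """Disjoint, exhaustive partition by the solvent polarity label."""
    out: dict[str, list[DiffusionRecord]] = {"polar": [], "nonpolar": []}
    for r in records:
        out[r.polarity].append(r)
    return out
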