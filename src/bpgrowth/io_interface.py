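"""Tabular I/O, run configuration, and result writing.

The canonical on-disk format is a flat CSV with one row per bird:
identity columns (bird, nest, species, sex), the 13 nest indicators,
the eight masses at odd days 1-15, and — after fitting — the best-fit
parameter block (a, b, c, p, q, SSLE, RL², ratio).  The layout mirrors
the spreadsheet convention of nestling growth studies (IDs, indicators,
masses, fitted parameters in consecutive column groups) but avoids any
binary format; a positional importer for such spreadsheets is provided
via pandas/openpyxl when needed.

Run configuration round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_fitting import AnnealingConfig, FitResult, GridSpec, MassSeries
from .shape_stats import INDICATORS, SEXES, SPECIES, BirdRecord, NestEnvironment, TestBatteryResult
from .synthetic_data import StudyDesign

__all__ = [
    "ID_COLUMNS",
    "StudyTable",
    "RunConfig",
    "mass_columns",
    "read_study_table",
    "write_study_table",
    "write_results",
    "FIT_COLUMNS",
]

logger = logging.getLogger(__name__)

ID_COLUMNS = ("bird_id", "nest_id", "species", "sex")
FIT_COLUMNS = ("fit_a", "fit_b", "fit_c", "fit_p", "fit_q",
               "fit_ssle", "fit_rl2", "fit_ratio")
DEFAULT_DAYS = (1, 3, 5, 7, 9, 11, 13, 15)


def mass_columns(days=DEFAULT_DAYS) -> tuple[str, ...]:
    return tuple(f"mass_d{d}" for d in days)


@dataclass
class StudyTable:
    """Validated per-bird study table.

    ``df`` holds one row per bird; ``rejected`` records row-numbered
    messages for rows that violated invariants and were excluded;
    ``days`` are the weighing days encoded in the mass columns.
    """

    df: pd.DataFrame
    days: tuple[int, ...] = DEFAULT_DAYS
    rejected: list[str] = field(default_factory=list)

    @property
    def n_birds(self) -> int:
        return len(self.df)

    def stratum_counts(self) -> pd.Series:
        return self.df.groupby(["species", "sex"]).size()

    def mass_series(self, row: pd.Series) -> MassSeries:
        """Mass series with t = day - first day (t=0 at first weighing)."""
        t0 = self.days[0]
        return MassSeries(
            times=tuple(float(d - t0) for d in self.days),
            masses=tuple(float(row[c]) for c in mass_columns(self.days)),
        )

    def birds(self) -> list[BirdRecord]:
        return [
            BirdRecord(bird_id=r["bird_id"], nest_id=r["nest_id"],
                       species=r["species"], sex=r["sex"],
                       series=self.mass_series(r))
            for _, r in self.df.iterrows()
        ]

    def environments(self) -> list[NestEnvironment]:
        out = []
        for nest_id, g in self.df.groupby("nest_id", sort=True):
            first = g.iloc[0]
            out.append(NestEnvironment(
                nest_id=str(nest_id),
                **{k: (int(first[k]) if k.startswith("hatchlings") or k == "nest_size_difference"
                       else float(first[k]))
                   for k in INDICATORS}))
        return out

    def analysis_frame(self) -> pd.DataFrame:
        """Columns needed by the statistical battery (requires fits)."""
        if "fit_ratio" not in self.df.columns:
            raise ValueError("table has no fitted-parameter block; run the fit first")
        cols = list(ID_COLUMNS) + list(INDICATORS) + ["fit_ratio", "fit_a"]
        out = self.df[cols].rename(columns={"fit_ratio": "ratio"})
        out["sigmoidal"] = self.df["fit_a"] > 0
        return out.drop(columns=["fit_a"])


def _validate_rows(df: pd.DataFrame, days) -> tuple[pd.DataFrame, list[str]]:
    msgs = []
    keep = np.ones(len(df), dtype=bool)
    mcols = mass_columns(days)
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        problems = []
        if row["species"] not in SPECIES:
            problems.append(f"unknown species {row['species']!r}")
        if row["sex"] not in SEXES:
            problems.append(f"unknown sex {row['sex']!r}")
        masses = pd.to_numeric(row[list(mcols)], errors="coerce")
        if masses.isna().any():
            problems.append("missing or non-numeric mass")
        elif (masses <= 0).any():
            problems.append("non-positive mass")
        if problems:
            keep[df.index.get_loc(i)] = False
            msgs.append(f"row {rowno} ({row.get('bird_id', '?')}): " + "; ".join(problems))
    dup = df.loc[keep, "bird_id"].duplicated()
    if dup.any():
        for i in df.loc[keep].index[dup]:
            keep[df.index.get_loc(i)] = False
            msgs.append(f"row {i + 2}: duplicate bird_id {df.loc[i, 'bird_id']!r}")
    return df[keep].reset_index(drop=True), msgs


def read_study_table(path: str | Path, days=DEFAULT_DAYS) -> StudyTable:
    """Read and validate a study CSV.

    Missing mandatory columns raise a schema error listing them; rows
    violating invariants (unknown stratum, non-positive or missing
    mass, duplicate ids) are rejected with row-numbered messages kept
    on the returned table and logged.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = list(ID_COLUMNS) + list(INDICATORS) + list(mass_columns(days))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")
    df, msgs = _validate_rows(df, days)
    for m in msgs:
        logger.warning("%s: %s", path.name, m)
    return StudyTable(df=df, days=tuple(days), rejected=msgs)


def write_study_table(table: StudyTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False, lineterminator="\n")
    return path


def attach_fits(table: StudyTable, fits: dict[str, FitResult]) -> StudyTable:
    """Append the best-fit parameter block to the table."""
    missing = [b for b in table.df["bird_id"] if b not in fits]
    if missing:
        raise ValueError(f"no fit for bird ids: {missing[:5]}")
    df = table.df.copy()
    order = df["bird_id"].tolist()
    df["fit_a"] = [fits[b].params.a for b in order]
    df["fit_b"] = [fits[b].params.b for b in order]
    df["fit_c"] = [fits[b].params.c for b in order]
    df["fit_p"] = [fits[b].params.p for b in order]
    df["fit_q"] = [fits[b].params.q for b in order]
    df["fit_ssle"] = [fits[b].ssle for b in order]
    df["fit_rl2"] = [fits[b].rl2 for b in order]
    df["fit_ratio"] = [fits[b].shape.ratio for b in order]
    return StudyTable(df=df, days=table.days, rejected=list(table.rejected))


def write_results(table: StudyTable, fits: dict[str, FitResult],
                  battery: TestBatteryResult | None, out_dir: str | Path,
                  config: "RunConfig | None" = None) -> dict[str, Path]:
    """Write the fitted table, battery report, and run metadata.

    Returns the paths written.  An empty battery produces a table-only
    output with a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fitted = attach_fits(table, fits)
    paths = {"study_fitted": write_study_table(fitted, out / "study_fitted.csv")}
    if battery is not None and len(battery.table):
        battery.table.to_csv(out / "battery.csv", index=False, lineterminator="\n")
        paths["battery"] = out / "battery.csv"
    else:
        logger.warning("no battery results; writing fitted table only")
    meta = {
        "n_birds": int(fitted.n_birds),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    if config is not None:
        meta["config"] = config.to_dict()
    (out / "run_metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    paths["metadata"] = out / "run_metadata.yaml"
    return paths


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips through YAML."""

    grid: GridSpec = field(default_factory=GridSpec)
    annealing: AnnealingConfig = field(default_factory=AnnealingConfig)
    design: StudyDesign = field(default_factory=StudyDesign)
    alpha: float = 0.05
    alpha_high: float = 0.01
    ratio_threshold: float = 0.5
    rl2_thresholds: tuple[float, ...] = (0.95, 0.995)
    n_shuffles: int = 10_000
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        d = dataclasses.asdict(self)
        d["design"]["strata_sizes"] = {
            f"{sp}|{sex}": n for (sp, sex), n in self.design.strata_sizes.items()}
        d["design"]["correlations"] = {
            f"{x}|{y}": v for (x, y), v in self.design.correlations.items()}
        return plain(d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        grid = GridSpec(**d.pop("grid", {}))
        annealing = AnnealingConfig(**d.pop("annealing", {}))
        design_d = dict(d.pop("design", {}))
        if "strata_sizes" in design_d:
            design_d["strata_sizes"] = {
                tuple(k.split("|")): v for k, v in design_d["strata_sizes"].items()}
        if "correlations" in design_d:
            design_d["correlations"] = {
                tuple(k.split("|")): v for k, v in design_d["correlations"].items()}
        for tup_key in ("measurement_days", "brood_size_range", "exponent_box"):
            if tup_key in design_d:
                design_d[tup_key] = tuple(design_d[tup_key])
        design = StudyDesign(**design_d)
        if "rl2_thresholds" in d:
            d["rl2_thresholds"] = tuple(d["rl2_thresholds"])
        return cls(grid=grid, annealing=annealing, design=design, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
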