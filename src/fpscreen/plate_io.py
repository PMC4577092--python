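"""Reading, validating and writing 384-well screening tables.

The on-disk format is a long-format CSV, one row per well:

    plate_id,well,compound_id,role,fp_mP,total_intensity,compound_conc_uM

Well coordinates follow the universal 384-well convention: rows A-P, columns
1-24, A1 top-left, serialized zero-padded ("A01").  Roles are ``sample``,
``neg_control`` (DMSO vehicle, high FP: probe fully bound), ``pos_control``
(10 µM unlabeled RNA, low FP: probe fully displaced) and ``empty``.  A
separate plate-map CSV (plate_id,well,role,compound_id) may supply roles when
the data file carries only readings.

If a data file carries raw polarization channels (``i_parallel``,
``i_perpendicular``) instead of ``fp_mP``, FP is computed as
1000·(I∥ − G·I⊥)/(I∥ + G·I⊥) with configurable G factor.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "WellRecord",
    "AssayMeta",
    "ScreenTable",
    "ScreenFormatError",
    "ScreenValidationError",
    "read_screen",
    "write_screen",
    "dilute",
    "fp_from_channels",
    "well_name",
    "parse_well",
]

ROLES = ("sample", "neg_control", "pos_control", "empty")
ROWS = "ABCDEFGHIJKLMNOP"  # 384-well rows
N_COLS = 24

COLUMNS = [
    "plate_id",
    "well",
    "compound_id",
    "role",
    "fp_mP",
    "total_intensity",
    "compound_conc_uM",
]

_WELL_RE = re.compile(r"^([A-P])0*([1-9][0-9]?)$")


class ScreenFormatError(ValueError):
    """File-level problem: missing column, unreadable CSV."""


class ScreenValidationError(ValueError):
    """Row-level problem: duplicate well, out-of-range coordinate, bad value."""


def well_name(row: str, col: int) -> str:
    """Serialize (row letter, 1-based column) as e.g. ('A', 1) -> 'A01'."""
    if row not in ROWS or not (1 <= col <= N_COLS):
        raise ScreenValidationError(f"well {row}{col} outside 384-well bounds")
    return f"{row}{col:02d}"


def parse_well(name: str) -> tuple[str, int]:
    """Parse 'A01' (or 'A1') into ('A', 1); raise on out-of-bounds wells."""
    m = _WELL_RE.match(str(name).strip().upper())
    if not m or int(m.group(2)) > N_COLS:
        raise ScreenValidationError(f"cannot parse well coordinate {name!r}")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class WellRecord:
    """A single measured well."""

    plate_id: str
    row: str
    col: int
    compound_id: str
    role: str
    fp: float
    total_intensity: float
    compound_conc: float  # µM; 0 for controls without compound

    @property
    def well(self) -> str:
        return well_name(self.row, self.col)

    def validate(self) -> None:
        well_name(self.row, self.col)
        if self.role not in ROLES:
            raise ScreenValidationError(f"unknown role {self.role!r}")
        if not (np.isfinite(self.fp) and np.isfinite(self.total_intensity)):
            raise ScreenValidationError(
                f"non-finite reading in {self.plate_id} {self.well}"
            )
        if self.total_intensity < 0:
            raise ScreenValidationError(
                f"negative total_intensity in {self.plate_id} {self.well}"
            )
        if self.role == "sample" and not self.compound_id:
            raise ScreenValidationError(
                f"sample well {self.plate_id} {self.well} lacks compound_id"
            )
        if self.role in ("neg_control", "pos_control") and self.compound_id:
            raise ScreenValidationError(
                f"control well {self.plate_id} {self.well} carries a compound_id"
            )


@dataclass(frozen=True)
class AssayMeta:
    """Assay constants: 50 nM protein, 10 nM labeled probe, 10 µM compound."""

    protein_conc_nM: float = 50.0
    probe_conc_nM: float = 10.0
    compound_conc_uM: float = 10.0
    min_controls: int = 4  # per plate, per control class


@dataclass
class ScreenTable:
    """A validated collection of wells plus assay constants.

    Canonical storage is a DataFrame with the on-disk column layout; rows are
    sorted by (plate_id, row, col) so that serialization is stable.
    """

    df: pd.DataFrame
    meta: AssayMeta = field(default_factory=AssayMeta)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: list[WellRecord], meta: AssayMeta | None = None
    ) -> "ScreenTable":
        rows = [
            {
                "plate_id": r.plate_id,
                "well": r.well,
                "compound_id": r.compound_id,
                "role": r.role,
                "fp_mP": r.fp,
                "total_intensity": r.total_intensity,
                "compound_conc_uM": r.compound_conc,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=COLUMNS)
        return cls(df=df, meta=meta or AssayMeta())

    def records(self) -> Iterator[WellRecord]:
        for t in self.df.itertuples(index=False):
            row, col = parse_well(t.well)
            yield WellRecord(
                plate_id=t.plate_id,
                row=row,
                col=col,
                compound_id=t.compound_id,
                role=t.role,
                fp=t.fp_mP,
                total_intensity=t.total_intensity,
                compound_conc=t.compound_conc_uM,
            )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ScreenFormatError(f"missing required columns: {missing}")
        df["compound_id"] = df["compound_id"].fillna("").astype(str)
        df["plate_id"] = df["plate_id"].astype(str)

        problems: list[str] = []
        # line numbers are 1-based CSV body lines (header = line 1)
        for idx, t in enumerate(df.itertuples(index=False), start=2):
            where = f"line {idx} ({t.plate_id} {t.well})"
            try:
                parse_well(t.well)
            except ScreenValidationError as e:
                problems.append(f"{where}: {e}")
                continue
            if t.role not in ROLES:
                problems.append(f"{where}: unknown role {t.role!r}")
                continue
            for colname, val in (
                ("fp_mP", t.fp_mP),
                ("total_intensity", t.total_intensity),
                ("compound_conc_uM", t.compound_conc_uM),
            ):
                try:
                    fval = float(val)
                except (TypeError, ValueError):
                    problems.append(f"{where}: non-numeric {colname} = {val!r}")
                    continue
                if not np.isfinite(fval):
                    problems.append(f"{where}: non-finite {colname}")
            if t.role == "sample" and not t.compound_id:
                problems.append(f"{where}: sample well lacks compound_id")
            if t.role in ("neg_control", "pos_control") and t.compound_id:
                problems.append(f"{where}: control well carries compound_id")
        if problems:
            raise ScreenValidationError("; ".join(problems))

        df["fp_mP"] = df["fp_mP"].astype(float)
        df["total_intensity"] = df["total_intensity"].astype(float)
        df["compound_conc_uM"] = df["compound_conc_uM"].astype(float)
        if (df["total_intensity"] < 0).any():
            bad = df.loc[df["total_intensity"] < 0, "well"].tolist()
            raise ScreenValidationError(f"negative total_intensity in wells {bad}")

        dup = df.duplicated(subset=["plate_id", "well"], keep=False)
        if dup.any():
            dups = df.loc[dup, ["plate_id", "well"]].drop_duplicates()
            pairs = [f"({p}, {w})" for p, w in dups.itertuples(index=False)]
            raise ScreenValidationError(f"duplicate wells: {', '.join(pairs)}")

        # keep serialization stable: sort by plate, then row letter, then column
        key = df["well"].map(lambda w: (w[0], int(w[1:])))
        order = (
            df.assign(_r=key.map(lambda rc: rc[0]), _c=key.map(lambda rc: rc[1]))
            .sort_values(["plate_id", "_r", "_c"], kind="mergesort")
            .index
        )
        self.df = df.loc[order, COLUMNS].reset_index(drop=True)

    def check_control_minima(self) -> None:
        """Every plate must carry at least ``meta.min_controls`` of each class."""
        for plate, grp in self.df.groupby("plate_id"):
            for role in ("neg_control", "pos_control"):
                n = int((grp["role"] == role).sum())
                if n < self.meta.min_controls:
                    raise ScreenValidationError(
                        f"plate {plate}: {n} {role} wells "
                        f"(minimum {self.meta.min_controls})"
                    )

    # -- convenience views -------------------------------------------------
    def samples(self) -> pd.DataFrame:
        return self.df[self.df["role"] == "sample"]

    def controls(self, role: str) -> pd.DataFrame:
        if role not in ("neg_control", "pos_control"):
            raise ValueError(f"not a control role: {role}")
        return self.df[self.df["role"] == role]

    def plates(self) -> list[str]:
        return sorted(self.df["plate_id"].unique())

    def with_meta(self, **kwargs) -> "ScreenTable":
        return ScreenTable(df=self.df.copy(), meta=replace(self.meta, **kwargs))


def fp_from_channels(i_parallel, i_perpendicular, g_factor: float = 1.0):
    """Polarization in mP from raw channel intensities: 1000·(I∥−G·I⊥)/(I∥+G·I⊥)."""
    ipar = np.asarray(i_parallel, dtype=float)
    iperp = np.asarray(i_perpendicular, dtype=float)
    denom = ipar + g_factor * iperp
    if np.any(denom <= 0):
        raise ValueError("channel intensities must sum to a positive total")
    out = 1000.0 * (ipar - g_factor * iperp) / denom
    return float(out) if out.ndim == 0 else out


def read_screen(
    path: str | Path,
    layout: str | Path | None = None,
    meta: AssayMeta | None = None,
    g_factor: float = 1.0,
) -> ScreenTable:
    """Read a long-format screen CSV (optionally merging roles from a plate map).

    Raises :class:`ScreenFormatError` for missing columns and
    :class:`ScreenValidationError` (with CSV line numbers) for bad rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"plate_id": str, "well": str, "compound_id": str},
        float_precision="round_trip",
    )
    if {"i_parallel", "i_perpendicular"}.issubset(df.columns) and "fp_mP" not in df:
        df["fp_mP"] = fp_from_channels(
            df["i_parallel"], df["i_perpendicular"], g_factor
        )
        df = df.drop(columns=["i_parallel", "i_perpendicular"])

    if layout is not None:
        lay = pd.read_csv(
            Path(layout), dtype={"plate_id": str, "well": str, "compound_id": str}
        )
        need = {"plate_id", "well", "role"}
        if not need.issubset(lay.columns):
            raise ScreenFormatError(
                f"plate map lacks columns {sorted(need - set(lay.columns))}"
            )
        lay["well"] = lay["well"].map(lambda w: well_name(*parse_well(w)))
        df["well"] = df["well"].map(lambda w: well_name(*parse_well(w)))
        keep = ["plate_id", "well", "role"] + (
            ["compound_id"] if "compound_id" in lay.columns else []
        )
        df = df.drop(columns=[c for c in ("role", "compound_id") if c in df.columns])
        df = df.merge(lay[keep], on=["plate_id", "well"], how="left", validate="1:1")
        if df["role"].isna().any():
            orphans = df.loc[df["role"].isna(), "well"].tolist()
            raise ScreenValidationError(f"wells absent from plate map: {orphans}")

    missing = [c for c in COLUMNS if c not in df.columns and c != "compound_conc_uM"]
    if missing:
        raise ScreenFormatError(f"missing required columns: {missing}")
    if "compound_conc_uM" not in df.columns:
        m = meta or AssayMeta()
        df["compound_conc_uM"] = np.where(df["role"] == "sample", m.compound_conc_uM, 0.0)
    try:
        df["well"] = df["well"].map(lambda w: well_name(*parse_well(w)))
    except ScreenValidationError:
        pass  # per-row diagnosis with line numbers happens in validate()
    return ScreenTable(df=df[COLUMNS], meta=meta or AssayMeta())


def write_screen(table: ScreenTable, path: str | Path) -> Path:
    """Write the long-format CSV with stable column order and full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    table.df[COLUMNS].to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue())
    return path


def dilute(stock_conc: float, stock_vol: float, assay_vol_before: float) -> float:
    """Final concentration after adding ``stock_vol`` of stock to an assay volume.

    ``dilute(50, 5, 20) == 10``: 5 µL of 50 µM stock into 20 µL of assay mixture
    gives 10 µM in the final 25 µL.
    """
    if stock_vol <= 0:
        raise ValueError(f"stock_vol must be > 0, got {stock_vol}")
    if assay_vol_before < 0:
        raise ValueError(f"assay_vol_before must be >= 0, got {assay_vol_before}")
    if stock_conc < 0:
        raise ValueError(f"stock_conc must be >= 0, got {stock_conc}")
    return stock_conc * stock_vol / (stock_vol + assay_vol_before)
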