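"""Data model and I/O for multiplex cytokine panels and clinical tables.

Multiplex bead assays report each analyte in pg/mL, but a sizeable fraction
of cells is censored: below the lower detection limit (reported as ``<x``),
above the upper limit (``>x``), or exactly zero.  This module parses those
encodings, resolves censoring so that every value is strictly positive
(limit-censored cells keep the limit value; zeros are replaced by half the
smallest nonzero value observed anywhere in the matrix), and converts pg/mL
to picomolar using mature-peptide molecular weights from the analyte catalog.

The on-disk assay schema is a long-format TSV with columns
``patient_id, analyte_id, timepoint, value`` where ``value`` is a plain
number, ``<x`` or ``>x``.  Clinical tables are wide TSVs keyed by
``patient_id``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# censor flags
FLAG_NONE = "none"
FLAG_BELOW = "below_limit"
FLAG_ABOVE = "above_limit"
FLAG_ZERO = "zero"
CENSOR_FLAGS = (FLAG_NONE, FLAG_BELOW, FLAG_ABOVE, FLAG_ZERO)

TIMEPOINTS = ("baseline", "24h")

#: clinical columns that are not binary features
CLINICAL_CORE_COLUMNS = (
    "apache2",
    "survival_time",
    "event",
    "death_day28",
    "death_day90",
)


class PanelDataError(ValueError):
    """Raised for malformed or inconsistent panel/clinical inputs."""


@dataclass(frozen=True)
class AnalyteCatalog:
    """Catalog of panel analytes: naming, molecular weight, class.

    ``table`` is indexed by ``analyte_id`` with columns ``current_name``,
    ``historical_name``, ``mw_daltons`` (mature-peptide molecular weight,
    Da) and ``class_label``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"current_name", "historical_name", "mw_daltons", "class_label"}
        missing = required - set(self.table.columns)
        if missing:
            raise PanelDataError(f"catalog missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise PanelDataError(f"duplicate analyte_id in catalog: {dupes}")
        if (self.table["mw_daltons"] <= 0).any():
            bad = self.table.index[self.table["mw_daltons"] <= 0].tolist()
            raise PanelDataError(f"non-positive molecular weight for: {bad}")

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.table.index)

    def mw(self, analyte_id: str) -> float:
        if analyte_id not in self.table.index:
            raise PanelDataError(f"unknown analyte_id: {analyte_id!r}")
        return float(self.table.loc[analyte_id, "mw_daltons"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnalyteCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"analyte_id": str})
        if "analyte_id" not in df.columns:
            raise PanelDataError(f"{path}: catalog needs an analyte_id column")
        return cls(df.set_index("analyte_id"))

    @classmethod
    def default(cls) -> "AnalyteCatalog":
        """The 39-analyte Luminex panel shipped with the package."""
        ref = resources.files("cytostrat.data").joinpath("analyte_catalog.tsv")
        with resources.as_file(ref) as p:
            return cls.from_tsv(p)


def _parse_assay_value(raw: object) -> tuple[float, str]:
    """Parse one assay cell into (value pg/mL, censor flag)."""
    s = str(raw).strip()
    flag = FLAG_NONE
    if s.startswith("<"):
        flag = FLAG_BELOW
        s = s[1:]
    elif s.startswith(">"):
        flag = FLAG_ABOVE
        s = s[1:]
    try:
        value = float(s)
    except ValueError:
        raise PanelDataError(f"non-numeric assay value: {raw!r}") from None
    if not math.isfinite(value) or value < 0:
        raise PanelDataError(f"assay value must be finite and >= 0, got {raw!r}")
    if flag == FLAG_NONE and value == 0.0:
        flag = FLAG_ZERO
    if flag != FLAG_NONE and flag != FLAG_ZERO and value == 0.0:
        raise PanelDataError(f"censored value with zero limit: {raw!r}")
    return value, flag


@dataclass
class AssayMatrix:
    """Patients x analytes of raw assay values (pg/mL) with censor flags."""

    values: pd.DataFrame  # float pg/mL
    flags: pd.DataFrame  # str, one of CENSOR_FLAGS
    timepoint: str
    #: set by resolve_censored: zero-flagged cells then hold the half-minimum
    zero_resolved: bool = False

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise PanelDataError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if not self.values.index.equals(self.flags.index) or not self.values.columns.equals(
            self.flags.columns
        ):
            raise PanelDataError("values and flags must share index and columns")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise PanelDataError(
                f"duplicate patient_id at timepoint {self.timepoint}: {dupes}"
            )
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise PanelDataError("assay values must be finite and non-negative")
        bad = ~self.flags.isin(CENSOR_FLAGS)
        if bad.to_numpy().any():
            raise PanelDataError("unknown censor flag present")
        zero_flagged = (self.flags == FLAG_ZERO).to_numpy()
        if ((vals == 0) & ~zero_flagged).any():
            raise PanelDataError("raw_value 0 requires censor_flag 'zero'")
        if self.zero_resolved:
            if (vals[zero_flagged] <= 0).any():
                raise PanelDataError("resolved zero cells must be positive")
        elif (zero_flagged & (vals != 0)).any():
            raise PanelDataError("censor_flag 'zero' must coincide with raw_value 0")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "AssayMatrix":
        return AssayMatrix(
            self.values.copy(), self.flags.copy(), self.timepoint, self.zero_resolved
        )


@dataclass
class MolarMatrix:
    """Patients x analytes in pM; strictly positive so log10 is defined."""

    values: pd.DataFrame  # float pM
    timepoint: str

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClinicalTable:
    """Per-patient clinical data: binary features, APACHE II, survival.

    ``table`` is indexed by patient_id.  Core columns: ``apache2`` (integer
    illness-severity score), ``survival_time`` (days), ``event`` (1 = died
    within follow-up), ``death_day28`` and ``death_day90`` (binary flags).
    Every other column is treated as a categorical clinical feature.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CLINICAL_CORE_COLUMNS) - set(self.table.columns)
        if missing:
            raise PanelDataError(f"clinical table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise PanelDataError(f"duplicate patient_id in clinical table: {dupes}")
        if (self.table["survival_time"] < 0).any():
            raise PanelDataError("survival_time must be >= 0")
        for col in ("event", "death_day28", "death_day90"):
            if not self.table[col].isin([0, 1]).all():
                raise PanelDataError(f"{col} must be 0/1")
        if ((self.table["death_day28"] == 1) & (self.table["death_day90"] == 0)).any():
            raise PanelDataError("death_day28 implies death_day90")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in CLINICAL_CORE_COLUMNS]

    def subset(self, patient_ids) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(patient_ids)].copy())


# ---------------------------------------------------------------------------
# readers / writers


def read_assay_tsv(path: str | Path, catalog: AnalyteCatalog | None = None) -> dict[str, AssayMatrix]:
    """Read a long-format assay TSV into one AssayMatrix per timepoint."""
    df = pd.read_csv(
        path, sep="\t", dtype={"patient_id": str, "analyte_id": str, "value": str}
    )
    required = {"patient_id", "analyte_id", "timepoint", "value"}
    missing = required - set(df.columns)
    if missing:
        raise PanelDataError(f"{path}: assay file missing columns {sorted(missing)}")
    if catalog is not None:
        unknown = set(df["analyte_id"]) - set(catalog.analyte_ids)
        if unknown:
            raise PanelDataError(f"unknown analyte_id in assay file: {sorted(unknown)}")
    matrices: dict[str, AssayMatrix] = {}
    for tp, sub in df.groupby("timepoint", sort=False):
        dup = sub.duplicated(subset=["patient_id", "analyte_id"])
        if dup.any():
            pair = sub.loc[dup, ["patient_id", "analyte_id"]].iloc[0].tolist()
            raise PanelDataError(
                f"duplicate (patient_id, analyte_id) at timepoint {tp}: {pair}"
            )
        parsed = []
        for row in sub.itertuples(index=False):
            try:
                value, flag = _parse_assay_value(row.value)
            except PanelDataError as exc:
                raise PanelDataError(
                    f"{exc} (patient {row.patient_id}, analyte {row.analyte_id}, "
                    f"timepoint {tp})"
                ) from None
            parsed.append((row.patient_id, row.analyte_id, value, flag))
        long = pd.DataFrame(parsed, columns=["patient_id", "analyte_id", "value", "flag"])
        values = long.pivot(index="patient_id", columns="analyte_id", values="value")
        flags = long.pivot(index="patient_id", columns="analyte_id", values="flag")
        if values.isna().any().any():
            raise PanelDataError(
                f"incomplete patient x analyte grid at timepoint {tp}"
            )
        matrices[str(tp)] = AssayMatrix(values, flags, str(tp))
    return matrices


def write_assay_tsv(matrices: dict[str, AssayMatrix] | AssayMatrix, path: str | Path) -> None:
    """Write matrices back to the long-format TSV schema (flags re-encoded)."""
    if isinstance(matrices, AssayMatrix):
        matrices = {matrices.timepoint: matrices}
    rows = []
    for tp, m in matrices.items():
        for pid in m.patient_ids:
            for aid in m.analyte_ids:
                v = m.values.at[pid, aid]
                f = m.flags.at[pid, aid]
                if f == FLAG_BELOW:
                    s = f"<{v:g}"
                elif f == FLAG_ABOVE:
                    s = f">{v:g}"
                else:
                    s = f"{v:g}"
                rows.append((pid, aid, tp, s))
    pd.DataFrame(rows, columns=["patient_id", "analyte_id", "timepoint", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_clinical_tsv(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise PanelDataError(f"{path}: clinical file needs a patient_id column")
    return ClinicalTable(df.set_index("patient_id"))


def write_clinical_tsv(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.rename_axis("patient_id").to_csv(path, sep="\t")


def load_cohort(
    assay_path: str | Path,
    clinical_path: str | Path,
    catalog_path: str | Path | None = None,
) -> tuple[dict[str, AssayMatrix], ClinicalTable, AnalyteCatalog]:
    """Load and align assay matrices, clinical table and analyte catalog.

    Patients missing from either the clinical table or an assay timepoint
    are dropped from that matrix; every exclusion is logged.
    """
    catalog = (
        AnalyteCatalog.default()
        if catalog_path is None
        else AnalyteCatalog.from_tsv(catalog_path)
    )
    matrices = read_assay_tsv(assay_path, catalog=catalog)
    clinical = read_clinical_tsv(clinical_path)
    clinical_ids = set(clinical.patient_ids)
    aligned: dict[str, AssayMatrix] = {}
    for tp, m in matrices.items():
        keep = [p for p in m.patient_ids if p in clinical_ids]
        dropped = sorted(set(m.patient_ids) - set(keep))
        if dropped:
            logger.warning(
                "timepoint %s: dropping %d patients missing from clinical table: %s",
                tp,
                len(dropped),
                dropped,
            )
        aligned[tp] = AssayMatrix(m.values.loc[keep], m.flags.loc[keep], tp)
    return aligned, clinical, catalog


# ---------------------------------------------------------------------------
# censoring and unit conversion


def global_nonzero_min(*matrices: AssayMatrix) -> float:
    """Smallest nonzero raw value over all analytes/patients of the inputs."""
    mins = []
    for m in matrices:
        vals = m.values.to_numpy(dtype=float)
        nz = vals[vals > 0]
        if nz.size:
            mins.append(nz.min())
    if not mins:
        raise PanelDataError("all assay values are zero; no global minimum definable")
    return float(min(mins))


def resolve_censored(matrix: AssayMatrix, zero_fill: float | None = None) -> AssayMatrix:
    """Resolve censored cells so every value is strictly positive.

    Limit-censored cells already carry the limit as their value and are kept
    as-is.  Zero cells are replaced by half the smallest nonzero value over
    the whole matrix (all analytes jointly), or by ``zero_fill`` when given —
    pass ``global_nonzero_min(baseline, late) / 2`` to scope the minimum over
    both timepoints.  Flags are preserved for provenance.  Idempotent.
    """
    zero_mask = ((matrix.flags == FLAG_ZERO) & (matrix.values == 0)).to_numpy()
    if not zero_mask.any():
        out = matrix.copy()
        out.zero_resolved = True
        return out
    if zero_fill is None:
        zero_fill = global_nonzero_min(matrix) / 2.0
    if zero_fill <= 0:
        raise PanelDataError("zero_fill must be positive")
    values = matrix.values.copy()
    values.values[zero_mask] = zero_fill
    return AssayMatrix(values, matrix.flags.copy(), matrix.timepoint, zero_resolved=True)


def to_molar(matrix: AssayMatrix, catalog: AnalyteCatalog) -> MolarMatrix:
    """Convert pg/mL to pM: pM = 1000 * (pg/mL) / MW(Da).

    Censoring must be resolved first so all values are strictly positive.
    """
    if (matrix.values.to_numpy() <= 0).any():
        raise PanelDataError(
            "non-positive values present; run resolve_censored before to_molar"
        )
    mw = []
    for aid in matrix.analyte_ids:
        mw.append(catalog.mw(aid))  # raises for unknown/missing analytes
    values = matrix.values * (1000.0 / np.asarray(mw, dtype=float))
    return MolarMatrix(values, matrix.timepoint)


def from_molar(matrix: MolarMatrix, catalog: AnalyteCatalog) -> pd.DataFrame:
    """Inverse of :func:`to_molar`; returns pg/mL values (round-trip check)."""
    mw = np.asarray([catalog.mw(a) for a in matrix.analyte_ids], dtype=float)
    return matrix.values * (mw / 1000.0)


def log10_view(matrix: MolarMatrix) -> pd.DataFrame:
    """Elementwise log10 of the pM matrix (the clustering input)."""
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise PanelDataError("log10 undefined: non-positive values present")
    return pd.DataFrame(
        np.log10(vals), index=matrix.values.index, columns=matrix.values.columns
    )
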