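"""Study dataset I/O in the NONMEM-style rectangular layout.

The interchange object for the whole pipeline is :class:`StudyDataset`: an
event-level table (dose and observation records) plus one row of enrolment
covariates per subject. Files are comma-separated text with ``#`` comment
lines and ``.`` for missing values, columns::

    ID TIME DV WT EVID MDV AMT CMT BQL PREG LNPC HB AST ALT BIL EGA

``DV`` holds natural-log concentrations (log ng/mL). ``CMT`` is 1 for the
dose depot, 2 for artesunate and 3 for dihydroartemisinin observations.
``BQL=1`` marks a sample below the assay lower limit of quantification
(LLOQ); its ``DV`` is missing and the record enters the likelihood only
through the censoring probability.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Assay lower limits of quantification (ng/mL). Single source of truth for
#: likelihood censoring and simulation.
LLOQ_ARS = 1.2
LLOQ_DHA = 2.0

#: Canonical column order of the rectangular file layout.
COLUMNS = [
    "ID", "TIME", "DV", "WT", "EVID", "MDV", "AMT", "CMT",
    "BQL", "PREG", "LNPC", "HB", "AST", "ALT", "BIL", "EGA",
]

_COVARIATE_COLS = ["WT", "PREG", "LNPC", "HB", "AST", "ALT", "BIL", "EGA"]


class DatasetError(ValueError):
    """Raised when a dataset violates the event-record contract."""


@dataclass
class SubjectCovariates:
    """Enrolment covariates for one subject.

    wt
        body weight (kg), > 0
    preg
        pregnancy indicator (0/1)
    lnpc
        natural log of enrolment parasite count
    hb
        haemoglobin (g/dL)
    ast, alt
        transaminases (units/L)
    bil
        bilirubin (mg/dL)
    ega
        estimated gestational age (months); 0 for non-pregnant women
    """

    wt: float
    preg: int
    lnpc: float
    hb: float
    ast: float
    alt: float
    bil: float
    ega: float = 0.0

    def __post_init__(self) -> None:
        if not self.wt > 0:
            raise DatasetError(f"wt must be positive, got {self.wt}")
        if self.preg not in (0, 1):
            raise DatasetError(f"preg must be 0/1, got {self.preg}")
        if self.preg == 0 and self.ega != 0:
            raise DatasetError("ega must be 0 for non-pregnant subjects")
        if not 0 <= self.ega <= 8:
            raise DatasetError(f"ega must be within 0-8 months, got {self.ega}")


@dataclass
class StudyDataset:
    """Event-level study data plus per-subject covariates.

    ``records`` is a DataFrame with the canonical columns (lower-cased
    internally is avoided; columns keep their file names). ``covariates``
    is indexed by subject ID with the covariate columns.
    """

    records: pd.DataFrame
    covariates: pd.DataFrame
    lloq_ars: float = LLOQ_ARS
    lloq_dha: float = LLOQ_DHA

    def __post_init__(self) -> None:
        validate_records(self.records)
        rec_ids = set(self.records["ID"].unique())
        cov_ids = set(self.covariates.index)
        missing = rec_ids - cov_ids
        if missing:
            raise DatasetError(f"covariates missing for subject ids {sorted(missing)}")
        obs = self.records[self.records["EVID"] == 0]
        doses = self.records[self.records["EVID"] == 1]
        dosed = set(doses["ID"].unique())
        undosed = set(obs["ID"].unique()) - dosed
        if undosed:
            raise DatasetError(
                f"observation subjects without any dose record: {sorted(undosed)}"
            )

    @property
    def subject_ids(self) -> np.ndarray:
        return self.records["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def observations(self, quantified_only: bool = False) -> pd.DataFrame:
        """Observation records (EVID=0, excluding missing-DV screening rows)."""
        obs = self.records[(self.records["EVID"] == 0)]
        obs = obs[(obs["MDV"] == 0) | (obs["BQL"] == 1)]
        if quantified_only:
            obs = obs[obs["BQL"] == 0]
        return obs

    def lloq(self, cmt: int) -> float:
        """LLOQ (ng/mL) for an observation compartment (2=ARS, 3=DHA)."""
        if cmt == 2:
            return self.lloq_ars
        if cmt == 3:
            return self.lloq_dha
        raise DatasetError(f"no LLOQ for compartment {cmt}")

    def subject_covariates(self, subject_id) -> SubjectCovariates:
        row = self.covariates.loc[subject_id]
        return SubjectCovariates(
            wt=float(row["WT"]), preg=int(row["PREG"]), lnpc=float(row["LNPC"]),
            hb=float(row["HB"]), ast=float(row["AST"]), alt=float(row["ALT"]),
            bil=float(row["BIL"]), ega=float(row["EGA"]),
        )


def validate_records(records: pd.DataFrame) -> None:
    """Check the event-record invariants, reporting offending row numbers."""
    unknown = set(records.columns) - set(COLUMNS)
    if unknown:
        raise DatasetError(f"unknown columns: {sorted(unknown)}")
    missing = set(COLUMNS) - set(records.columns)
    if missing:
        raise DatasetError(f"missing columns: {sorted(missing)}")

    for i, row in enumerate(records.itertuples(index=False)):
        evid, cmt, mdv = int(row.EVID), int(row.CMT), int(row.MDV)
        if evid not in (0, 1):
            raise DatasetError(f"row {i}: EVID must be 0 or 1, got {evid}")
        if cmt not in (1, 2, 3):
            raise DatasetError(f"row {i}: CMT outside {{1,2,3}}: {cmt}")
        if row.TIME < 0 or not np.isfinite(row.TIME):
            raise DatasetError(f"row {i}: negative or non-finite TIME {row.TIME}")
        if evid == 1:
            if not (np.isfinite(row.AMT) and row.AMT > 0):
                raise DatasetError(f"row {i}: dose record with missing/non-positive AMT")
            if cmt != 1:
                raise DatasetError(f"row {i}: dose record must have CMT=1, got {cmt}")
            if mdv != 1:
                raise DatasetError(f"row {i}: dose record must have MDV=1")
        else:
            if cmt not in (2, 3):
                raise DatasetError(f"row {i}: observation CMT must be 2 or 3, got {cmt}")
            if int(row.BQL) == 0 and mdv == 0 and not np.isfinite(row.DV):
                raise DatasetError(f"row {i}: quantified observation with missing DV")

    # times non-decreasing within subject (file order)
    for sid, grp in records.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            bad = int(np.argmax(np.diff(t) < 0))
            raise DatasetError(
                f"subject {sid}: times not non-decreasing at record {bad + 1}"
            )


def _extract_covariates(records: pd.DataFrame) -> pd.DataFrame:
    cov = records.groupby("ID", sort=False)[_COVARIATE_COLS].first()
    for sid in cov.index:
        sub = records.loc[records["ID"] == sid, _COVARIATE_COLS]
        if not (sub.nunique(dropna=False) <= 1).all():
            raise DatasetError(f"subject {sid}: covariates vary across records")
    return cov


def read_dataset(
    path,
    dialect: dict | None = None,
    lloq_ars: float = LLOQ_ARS,
    lloq_dha: float = LLOQ_DHA,
) -> StudyDataset:
    """Read a study dataset from delimited text.

    Parameters
    ----------
    path
        File path or file-like object. Lines starting with ``#`` are
        ignored; ``.`` denotes a missing value.
    dialect
        Optional layout config: ``{"header": False}`` parses a headerless
        file positionally in the canonical column order;
        ``{"dv_scale": "raw"}`` declares DV on the raw ng/mL scale, logged
        on read; ``{"columns": {...}}`` maps file column names to canonical
        names.

    Returns
    -------
    StudyDataset
        Validated dataset with DV on the natural-log scale.
    """
    dialect = dialect or {}
    header = dialect.get("header", True)
    kwargs = dict(comment="#", na_values=["."], skip_blank_lines=True,
                  float_precision="round_trip")
    if header:
        df = pd.read_csv(path, **kwargs)
        df.columns = [c.strip().upper() for c in df.columns]
        colmap = dialect.get("columns")
        if colmap:
            df = df.rename(columns={k.upper(): v.upper() for k, v in colmap.items()})
    else:
        df = pd.read_csv(path, header=None, names=COLUMNS, **kwargs)
    unknown = set(df.columns) - set(COLUMNS)
    if unknown:
        raise DatasetError(f"unknown column(s) in file: {sorted(unknown)}")
    df = df.reindex(columns=COLUMNS)
    for col in ["EVID", "MDV", "CMT", "BQL", "PREG"]:
        df[col] = df[col].fillna(0).astype(int)
    df["ID"] = df["ID"].astype(int)
    for col in ["TIME", "DV", "WT", "AMT", "LNPC", "HB", "AST", "ALT", "BIL", "EGA"]:
        df[col] = df[col].astype(float)
    if dialect.get("dv_scale", "log") == "raw":
        with np.errstate(divide="ignore", invalid="ignore"):
            df["DV"] = np.log(df["DV"])
    covariates = _extract_covariates(df)
    return StudyDataset(df.reset_index(drop=True), covariates, lloq_ars, lloq_dha)


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write a dataset re-readable by :func:`read_dataset` with identical content.

    Floats are written with full (round-trippable) precision; missing values
    as ``.``.
    """
    df = dataset.records.reindex(columns=COLUMNS)
    out = df.copy()
    for col in ["ID", "EVID", "MDV", "CMT", "BQL", "PREG"]:
        out[col] = out[col].astype(int)

    def _fmt(x) -> str:
        if pd.isna(x):
            return "."
        return repr(float(x))

    buf = io.StringIO()
    buf.write(",".join(COLUMNS) + "\n")
    for row in out.itertuples(index=False):
        cells = []
        for col, val in zip(COLUMNS, row):
            if col in ("ID", "EVID", "MDV", "CMT", "BQL", "PREG"):
                cells.append(str(int(val)))
            else:
                cells.append(_fmt(val))
        buf.write(",".join(cells) + "\n")
    Path(path).write_text(buf.getvalue())


def summarize_cohort(dataset: StudyDataset) -> pd.DataFrame:
    """Demographic summary: median and range per covariate, per pregnancy group.

    Also reports the fraction of post-dose observations below the LLOQ per
    analyte (pooled across groups, and per group), mirroring how trial
    demographics tables are reported.
    """
    if len(dataset.records) == 0:
        raise DatasetError("empty dataset")
    rows = []
    cov = dataset.covariates
    for preg, grp in cov.groupby("PREG"):
        label = "pregnant" if preg == 1 else "non-pregnant"
        rows.append({"group": label, "variable": "n", "median": float(len(grp)),
                     "min": float(len(grp)), "max": float(len(grp))})
        for col in ["WT", "LNPC", "HB", "AST", "ALT", "BIL", "EGA"]:
            vals = grp[col].astype(float)
            rows.append({
                "group": label, "variable": col.lower(),
                "median": float(vals.median()),
                "min": float(vals.min()), "max": float(vals.max()),
            })
        obs = dataset.observations()
        obs = obs[obs["ID"].isin(grp.index) & (obs["TIME"] > 0)]
        for cmt, name in ((2, "blq_fraction_ars"), (3, "blq_fraction_dha")):
            sub = obs[obs["CMT"] == cmt]
            frac = float(sub["BQL"].mean()) if len(sub) else np.nan
            rows.append({"group": label, "variable": name,
                         "median": frac, "min": frac, "max": frac})
    return pd.DataFrame(rows)


def summary_to_json(summary: pd.DataFrame) -> str:
    """Serialize a cohort summary table to JSON (records orientation)."""
    return json.dumps(summary.to_dict(orient="records"), indent=2)
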