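"""Cohort input/output: ROI time series, phenotypes, atlas labels, result tables.

The on-disk dialects follow the ABIDE-I preprocessed release: one
whitespace/tab-delimited text file per subject holding the region-mean BOLD
series (rows = volumes, columns = atlas regions, optional single header row
of region names), plus a phenotype CSV keyed by subject ID with numerically
coded diagnosis and sex columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dynconn")

STRATEGY_TAGS = ("filt_global", "filt_noglobal", "nofilt_global", "nofilt_noglobal")
ATLAS_TAGS = ("AAL", "TT")

#: Default ABIDE phenotype column map and code books.
PHENOTYPE_COLUMNS = {
    "subject_id": "SUB_ID",
    "dx": "DX_GROUP",
    "site": "SITE_ID",
    "age_years": "AGE_AT_SCAN",
    "sex": "SEX",
    "fiq": "FIQ",
}
DX_CODES = {1: "ASD", 2: "TD"}
SEX_CODES = {1: "M", 2: "F"}

#: Fixed factor vocabularies of the configuration grid.
FACTOR_LEVELS = {
    "feat": ("FC", "dFC"),
    "atls": ATLAS_TAGS,
    "strat": STRATEGY_TAGS,
    "kernel": ("lsvm", "lr", "rf", "lgbm"),
    "classifier": ("lsvm", "lr", "rf", "lgbm", "nn", "svm"),
}


class ParseError(ValueError):
    """Malformed numeric content in an input file."""


class SchemaError(ValueError):
    """Structurally valid file whose shape or vocabulary disagrees with expectations."""


@dataclass
class RoiTimeSeries:
    """One subject's region-mean BOLD series: a T x A matrix plus metadata.

    T is the number of acquired volumes (the series length L), A the number
    of atlas regions. ``tr_seconds`` is the repetition time, i.e. the
    sampling interval of the series.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    region_labels: list[str]
    strategy_tag: str = "filt_global"
    atlas_tag: str = "AAL"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SchemaError(f"{self.subject_id}: expected a 2-D time-by-region matrix")
        t, a = self.data.shape
        if t < 2 or a < 2:
            raise SchemaError(f"{self.subject_id}: need T >= 2 and A >= 2, got {t}x{a}")
        if len(self.region_labels) != a:
            raise SchemaError(
                f"{self.subject_id}: {a} columns but {len(self.region_labels)} region labels"
            )
        if not (0 < self.tr_seconds < 10):
            raise SchemaError(f"{self.subject_id}: implausible TR {self.tr_seconds} s")
        if self.strategy_tag not in STRATEGY_TAGS:
            raise SchemaError(f"unknown strategy tag {self.strategy_tag!r}")
        if self.atlas_tag not in ATLAS_TAGS:
            raise SchemaError(f"unknown atlas tag {self.atlas_tag!r}")
        self._impute_nonfinite()

    def _impute_nonfinite(self) -> None:
        # A region with sporadic non-finite samples is mean-imputed so A stays
        # fixed across the cohort; a fully non-finite region is unusable.
        bad = ~np.isfinite(self.data)
        if not bad.any():
            return
        for j in np.flatnonzero(bad.any(axis=0)):
            col = self.data[:, j]
            ok = np.isfinite(col)
            if not ok.any():
                raise SchemaError(
                    f"{self.subject_id}: region {self.region_labels[j]!r} entirely non-finite"
                )
            col[~ok] = col[ok].mean()
            logger.warning(
                "%s: imputed %d non-finite samples in region %s",
                self.subject_id, int((~ok).sum()), self.region_labels[j],
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class Phenotype:
    subject_id: str
    dx: str
    site: str = "UNKNOWN"
    age_years: float = float("nan")
    sex: str = "M"
    fiq: float | None = None

    def __post_init__(self) -> None:
        if self.dx not in ("ASD", "TD"):
            raise SchemaError(f"{self.subject_id}: diagnosis must be ASD or TD, got {self.dx!r}")
        if self.sex not in ("M", "F"):
            raise SchemaError(f"{self.subject_id}: sex must be M or F, got {self.sex!r}")


@dataclass
class Cohort:
    """Subjects plus phenotypes, sharing one atlas and region ordering."""

    subjects: list[RoiTimeSeries]
    phenotypes: dict[str, Phenotype]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise SchemaError("cohort has no subjects")
        ref = self.subjects[0]
        for s in self.subjects:
            if s.subject_id not in self.phenotypes:
                raise SchemaError(f"subject {s.subject_id} has no phenotype")
            if s.atlas_tag != ref.atlas_tag or s.region_labels != ref.region_labels:
                raise SchemaError(
                    f"subject {s.subject_id} disagrees with cohort atlas/region labels"
                )

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def labels(self) -> np.ndarray:
        """Diagnosis labels in subject order, ASD=1 (positive class), TD=0."""
        return np.array(
            [1 if self.phenotypes[sid].dx == "ASD" else 0 for sid in self.subject_ids]
        )

    @property
    def region_labels(self) -> list[str]:
        return self.subjects[0].region_labels


def read_roi_series(
    path: str | Path,
    tr_seconds: float,
    labels: Sequence[str] | None = None,
    strategy_tag: str = "filt_global",
    atlas_tag: str = "AAL",
    subject_id: str | None = None,
    transposed: bool = False,
) -> RoiTimeSeries:
    """Read one whitespace-delimited ROI-series file.

    Files are time-by-region (the ABIDE ``.1D`` convention); pass
    ``transposed=True`` for region-by-time input. A single leading header row
    of region names is detected and, when present, overrides ``labels``.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header: list[str] | None = None
    first = lines[0].replace(",", " ").split()
    if any(not _is_number(tok) for tok in first):
        header = first
        lines = lines[1:]
    rows: list[list[float]] = []
    width = None
    for i, ln in enumerate(lines):
        toks = ln.replace(",", " ").split()
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise ParseError(f"{path}: ragged row {i + 1}: {len(toks)} fields, expected {width}")
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value in data row {i + 1}") from exc
    data = np.asarray(rows, dtype=float)
    if transposed:
        data = data.T
    use_labels = list(header) if header is not None else (list(labels) if labels else None)
    if use_labels is None:
        use_labels = [f"R{j + 1}" for j in range(data.shape[1])]
    if len(use_labels) != data.shape[1]:
        raise SchemaError(
            f"{path}: {data.shape[1]} region columns but {len(use_labels)} labels supplied"
        )
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        data=data,
        tr_seconds=tr_seconds,
        region_labels=use_labels,
        strategy_tag=strategy_tag,
        atlas_tag=atlas_tag,
    )


def write_roi_series(ts: RoiTimeSeries, path: str | Path, header: bool = True) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write("\t".join(ts.region_labels) + "\n")
        np.savetxt(fh, ts.data, fmt="%.10g", delimiter="\t")


def read_atlas_labels(path: str | Path) -> list[str]:
    """Atlas label list: one region name per line, blanks ignored."""
    names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not names:
        raise SchemaError(f"{path}: no region names found")
    return names


def read_phenotype(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    dx_codes: Mapping[int, str] | None = None,
    sex_codes: Mapping[int, str] | None = None,
) -> dict[str, Phenotype]:
    """Read a phenotype CSV into a dict keyed by subject ID.

    Column names and diagnosis/sex code books default to the ABIDE dialect
    (DX_GROUP 1=ASD 2=TD, SEX 1=M 2=F). Rows with a missing diagnosis are
    dropped with a warning; duplicate IDs are an error.
    """
    cols = dict(PHENOTYPE_COLUMNS, **(column_map or {}))
    dx_codes = dict(DX_CODES if dx_codes is None else dx_codes)
    sex_codes = dict(SEX_CODES if sex_codes is None else sex_codes)
    df = pd.read_csv(path)
    if cols["subject_id"] not in df.columns or cols["dx"] not in df.columns:
        raise SchemaError(
            f"{path}: phenotype CSV must contain {cols['subject_id']!r} and {cols['dx']!r}"
        )
    out: dict[str, Phenotype] = {}
    for _, row in df.iterrows():
        sid = str(row[cols["subject_id"]])
        raw_dx = row.get(cols["dx"])
        if pd.isna(raw_dx):
            logger.warning("%s: dropping subject %s with missing diagnosis", path, sid)
            continue
        dx = dx_codes.get(int(raw_dx)) if _is_number(str(raw_dx)) else str(raw_dx)
        if dx is None:
            logger.warning("%s: dropping subject %s with unknown diagnosis code %r", path, sid, raw_dx)
            continue
        if sid in out:
            raise SchemaError(f"{path}: duplicate subject id {sid}")
        raw_sex = row.get(cols["sex"], 1)
        sex = sex_codes.get(int(raw_sex), "M") if not pd.isna(raw_sex) else "M"
        raw_fiq = row.get(cols["fiq"], np.nan)
        fiq = None if pd.isna(raw_fiq) else float(raw_fiq)
        age = row.get(cols["age_years"], np.nan)
        out[sid] = Phenotype(
            subject_id=sid,
            dx=dx,
            site=str(row.get(cols["site"], "UNKNOWN")),
            age_years=float(age) if not pd.isna(age) else float("nan"),
            sex=sex,
            fiq=fiq,
        )
    return out


def write_phenotype(phenotypes: Mapping[str, Phenotype], path: str | Path) -> None:
    """Write phenotypes back out in the ABIDE-coded CSV dialect."""
    inv_dx = {v: k for k, v in DX_CODES.items()}
    inv_sex = {v: k for k, v in SEX_CODES.items()}
    rows = [
        {
            "SUB_ID": p.subject_id,
            "DX_GROUP": inv_dx[p.dx],
            "SITE_ID": p.site,
            "AGE_AT_SCAN": p.age_years,
            "SEX": inv_sex[p.sex],
            "FIQ": "" if p.fiq is None else p.fiq,
        }
        for p in phenotypes.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_cohort(
    directory: str | Path,
    tr_seconds: float = 2.0,
    labels: Sequence[str] | None = None,
    strategy_tag: str = "filt_global",
    atlas_tag: str = "AAL",
    phenotype_csv: str | Path | None = None,
) -> Cohort:
    """Load every ``*.1D``/``*.tsv`` series in a directory plus its phenotype CSV."""
    directory = Path(directory)
    phenotype_csv = phenotype_csv or directory / "phenotype.csv"
    phenos = read_phenotype(phenotype_csv)
    files = sorted(list(directory.glob("*.1D")) + list(directory.glob("*.tsv")))
    subjects = [
        read_roi_series(f, tr_seconds, labels, strategy_tag, atlas_tag)
        for f in files
        if f.stem in phenos
    ]
    return Cohort(subjects=subjects, phenotypes={s.subject_id: phenos[s.subject_id] for s in subjects})


# ---------------------------------------------------------------------------
# Configuration-grid result tables

RESULT_FACTORS = ["feat", "atls", "strat", "kernel", "classifier"]


def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format configuration score table (factors + score columns)."""
    _check_factor_levels(table)
    table.to_csv(path, index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    _check_factor_levels(table)
    return table


def _check_factor_levels(table: pd.DataFrame) -> None:
    for col, levels in FACTOR_LEVELS.items():
        if col in table.columns and len(table):
            bad = set(table[col].astype(str)) - set(levels)
            if bad:
                raise SchemaError(f"unknown {col} level(s): {sorted(bad)}")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
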