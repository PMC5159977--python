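"""Raw subject records -> scaled clustering matrix.

Transforms mirror the clustering protocol: methacholine PC20 and FENO are
log-transformed (natural log; the base is irrelevant after rescaling),
blood eosinophils stay as absolute counts, and every variable is centered
at its observed mean and divided by its mean absolute deviation (MAD about
the mean).  Scaling parameters are stored on the matrix so validation
cohorts and classifier inputs can be scaled with the training parameters.

Sputum quality control masks differential counts whose cytospin squamous
cell content exceeds 30% (missing squamous content is treated as a QC
failure).  Screening and baseline visits are merged by arithmetic mean for
differential cell counts and geometric mean for analyte measurements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from phenoclust.cohort import CLUSTERING_VARIABLES

log = logging.getLogger(__name__)

#: variables entered on the log scale
LOG_VARIABLES = ("pc20", "feno")

#: the three analysis variable sets: full clustering set, the 8-variable
#: classification set without PC20 (model A), and the 7-variable set also
#: without blood eosinophils (model B, used longitudinally)
VARIABLE_SETS: dict[str, tuple[str, ...]] = {
    "clinical9": CLUSTERING_VARIABLES,
    "model_a": tuple(v for v in CLUSTERING_VARIABLES if v != "pc20"),
    "model_b": tuple(v for v in CLUSTERING_VARIABLES if v not in ("pc20", "blood_eos")),
}

SPUTUM_COLUMNS = ("sputum_eos", "sputum_pmn")


@dataclass
class FeatureMatrix:
    """n x p matrix of (possibly scaled) clustering variables.

    ``values`` holds NaN where ``mask`` is False; masked cells carry no
    numeric meaning.  After :func:`mad_scale`, ``center``/``scale`` record
    the per-variable statistics used so the transform is reusable.
    """

    values: np.ndarray
    mask: np.ndarray
    var_names: tuple[str, ...]
    subject_ids: tuple[str, ...]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape[1] != len(self.var_names):
            raise ValueError("column count does not match variable names")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def complete_rows(self) -> np.ndarray:
        """Boolean index of rows with every variable observed."""
        return self.mask.all(axis=1)


def transform_variables(
    records: pd.DataFrame,
    variables: tuple[str, ...] | str = "clinical9",
) -> FeatureMatrix:
    """Assemble the clustering matrix with log transforms applied.

    ``variables`` is one of the named sets (``"clinical9"``, ``"model_a"``,
    ``"model_b"``) or an explicit tuple of column names.  Non-positive
    values reaching a log transform are flagged and masked; the row is
    retained (the clustering tolerates missing cells).
    """
    if isinstance(variables, str):
        variables = VARIABLE_SETS[variables]
    missing_cols = [v for v in variables if v not in records.columns]
    if missing_cols:
        raise KeyError(f"records lack clustering variables {missing_cols}")

    values = records.loc[:, list(variables)].to_numpy(dtype=float).copy()
    for j, name in enumerate(variables):
        if name in LOG_VARIABLES:
            col = values[:, j]
            bad = np.isfinite(col) & (col <= 0)
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} non-positive {name} value(s) masked before log",
                    stacklevel=2,
                )
                col[bad] = np.nan
            with np.errstate(invalid="ignore"):
                values[:, j] = np.log(col)
    mask = np.isfinite(values)
    values[~mask] = np.nan
    if "subject_id" in records.columns:
        ids = tuple(str(s) for s in records["subject_id"])
    else:
        ids = tuple(str(i) for i in records.index)
    return FeatureMatrix(values=values, mask=mask, var_names=tuple(variables),
                         subject_ids=ids)


def mad_scale(fm: FeatureMatrix) -> FeatureMatrix:
    """Center each variable at its observed mean, divide by its MAD.

    The spread statistic is ``s = mean(|x - mean(x)|)`` over observed cells.
    Variables with zero spread are dropped with a warning.  The returned
    matrix stores ``center`` and ``scale`` for reuse on new data.
    """
    centers, scales, keep = [], [], []
    for j, name in enumerate(fm.var_names):
        obs = fm.values[fm.mask[:, j], j]
        if obs.size < 2:
            warnings.warn(f"variable {name!r} has <2 observed values; dropped",
                          stacklevel=2)
            continue
        c = obs.mean()
        s = np.abs(obs - c).mean()
        if s == 0:
            warnings.warn(f"variable {name!r} has zero spread; dropped", stacklevel=2)
            continue
        keep.append(j)
        centers.append(c)
        scales.append(s)
    values = (fm.values[:, keep] - np.array(centers)) / np.array(scales)
    mask = fm.mask[:, keep]
    values = np.where(mask, values, np.nan)
    return FeatureMatrix(
        values=values,
        mask=mask,
        var_names=tuple(fm.var_names[j] for j in keep),
        subject_ids=fm.subject_ids,
        center=np.array(centers),
        scale=np.array(scales),
    )


def apply_scaling(fm: FeatureMatrix, center: np.ndarray, scale: np.ndarray,
                  var_names: tuple[str, ...] | None = None) -> FeatureMatrix:
    """Scale ``fm`` with previously stored (training) parameters.

    Applying a matrix's own stored parameters reproduces the scaled matrix
    bit-identically (scaling is idempotent given the parameters).
    """
    if var_names is not None:
        idx = [fm.var_names.index(v) for v in var_names]
        fm = replace(fm, values=fm.values[:, idx], mask=fm.mask[:, idx],
                     var_names=tuple(var_names), center=None, scale=None)
    center = np.asarray(center, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if center.shape[0] != fm.p or scale.shape[0] != fm.p:
        raise ValueError("scaling parameter length does not match variables")
    values = (fm.values - center) / scale
    values = np.where(fm.mask, values, np.nan)
    return FeatureMatrix(values=values, mask=fm.mask.copy(),
                         var_names=fm.var_names, subject_ids=fm.subject_ids,
                         center=center, scale=scale)


def sputum_qc(records: pd.DataFrame, squamous_max: float = 30.0) -> pd.DataFrame:
    """Mask sputum differentials failing the squamous-cell QC rule.

    Samples with squamous content strictly above ``squamous_max`` percent
    (default 30) — or with missing squamous content — have their sputum
    fields set missing.  All other fields are untouched.
    """
    out = records.copy()
    squamous = out.get("squamous_pct")
    if squamous is None:
        raise KeyError("records lack 'squamous_pct'")
    fail = squamous.isna() | (squamous > squamous_max)
    n_missing = int(squamous.isna().sum())
    if n_missing:
        log.info("sputum QC: %d rows with missing squamous content masked", n_missing)
    for col in SPUTUM_COLUMNS:
        if col in out.columns:
            out.loc[fail, col] = np.nan
    return out


def merge_screening_baseline(
    records: pd.DataFrame,
    cell_count_columns: tuple[str, ...] = SPUTUM_COLUMNS,
    analyte_columns: tuple[str, ...] = ("feno", "blood_eos"),
    visits: tuple[str, str] = ("screening", "baseline"),
) -> pd.DataFrame:
    """Merge screening and baseline visits into one row per subject.

    Differential cell counts are averaged arithmetically, analyte
    measurements geometrically; every other column takes the baseline value
    when present, otherwise the screening value.  Subjects with only one of
    the two visits pass through with that visit's values.
    """
    screening, baseline = visits
    sub = records[records["visit"].isin(visits)]
    merged_rows = []
    for sid, grp in sub.groupby("subject_id", sort=False):
        by_visit = {v: grp[grp["visit"] == v] for v in visits}
        base = by_visit[baseline].iloc[0] if len(by_visit[baseline]) else None
        scr = by_visit[screening].iloc[0] if len(by_visit[screening]) else None
        primary = base if base is not None else scr
        row = primary.copy()
        row["visit"] = baseline
        if base is not None and scr is not None:
            for col in cell_count_columns:
                if col in grp.columns:
                    vals = np.array([scr[col], base[col]], dtype=float)
                    vals = vals[np.isfinite(vals)]
                    row[col] = vals.mean() if vals.size else np.nan
            for col in analyte_columns:
                if col in grp.columns:
                    vals = np.array([scr[col], base[col]], dtype=float)
                    vals = vals[np.isfinite(vals) & (vals > 0)]
                    row[col] = float(np.exp(np.log(vals).mean())) if vals.size else np.nan
        else:
            # single visit: fill any missing value from the other visit (absent)
            pass
        merged_rows.append(row)
    return pd.DataFrame(merged_rows).reset_index(drop=True)
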