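"""Design-matrix construction from cohort tables.

Two layouts mirror the two analysis arms. The frequentist arm fits
separate models within strata defined by program (SSI / SSDI /
Concurrent) and RFC-assessment availability (physical vs mental), so a
record holding *both* assessments appears in both RFC strata of its
program — six overlapping strata in total. The Bayesian arm instead uses
one pooled design in which every record appears exactly once, labelled by
its (program, rfc) stratum, which is what lets the joint model avoid
double-counting concurrent-assessment records.

Encoding is deterministic: categorical covariates expand to k-1
indicators with the lexicographically first observed level as reference,
missing values become a per-covariate missing-indicator column (no record
is ever dropped for missingness), and zero-variance columns are dropped
with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import covariate_names, validate_cohort

logger = logging.getLogger(__name__)

__all__ = ["DesignMatrix", "build_design", "pool_design", "RFC_AVAILABILITY"]

RFC_AVAILABILITY = ("PRFC", "MRFC")


@dataclass
class DesignMatrix:
    """Numeric predictor matrix aligned with treatment/outcome vectors."""

    row_ids: np.ndarray
    columns: list[str]
    X: np.ndarray
    treatment: np.ndarray
    outcome: np.ndarray
    subgroup: str | None = None
    subgroup_labels: list[str] = field(default_factory=list)
    subgroup_index: np.ndarray | None = None
    dropped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]


def _encode_covariate(series: pd.Series, name: str) -> tuple[list[str], list[np.ndarray]]:
    missing = series.isna().to_numpy()
    names, cols = [], []
    if series.dtype == object:
        levels = sorted(series.dropna().unique())
        for level in levels[1:]:  # lexicographically first level is reference
            names.append(f"{name}[{level}]")
            cols.append((series == level).to_numpy().astype(float))
    else:
        values = pd.to_numeric(series, errors="coerce").fillna(0.0).to_numpy(float)
        names.append(name)
        cols.append(values)
    if missing.any():
        names.append(f"{name}[missing]")
        cols.append(missing.astype(float))
    return names, cols


def _encode(subset: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    names: list[str] = []
    cols: list[np.ndarray] = []
    for name in predictors:
        cn, cc = _encode_covariate(subset[name], name)
        names.extend(cn)
        cols.extend(cc)
    X = np.column_stack(cols) if cols else np.empty((len(subset), 0))
    keep, dropped = [], []
    for j, cname in enumerate(names):
        if np.ptp(X[:, j]) == 0.0:
            dropped.append(cname)
            logger.warning("dropping constant column %s", cname)
        else:
            keep.append(j)
    return X[:, keep], [names[j] for j in keep], dropped


def _resolve_predictors(cohort: pd.DataFrame, predictors) -> list[str]:
    available = covariate_names(cohort)
    if predictors is None:
        return available
    for name in predictors:
        if name not in available:
            raise KeyError(f"predictor {name!r} not present in the cohort")
    return list(predictors)


def build_design(cohort: pd.DataFrame, stratum: tuple[str, str], predictors=None) -> DesignMatrix:
    """Design matrix for one frequentist stratum.

    ``stratum`` is ``(program, rfc_availability)`` with availability in
    {"PRFC", "MRFC"}; records holding both assessments are included in
    both availability strata of their program.
    """
    validate_cohort(cohort)
    program, avail = stratum
    if avail not in RFC_AVAILABILITY:
        raise ValueError(f"rfc availability must be one of {RFC_AVAILABILITY}, got {avail!r}")
    mask = (cohort["program"] == program) & cohort["rfc"].isin([f"{avail}-only", "both"])
    if not mask.any():
        raise ValueError(f"stratum {program}:{avail} is empty")
    subset = cohort.loc[mask].reset_index(drop=True)
    predictors = _resolve_predictors(cohort, predictors)
    X, columns, dropped = _encode(subset, predictors)
    return DesignMatrix(
        row_ids=subset["record_id"].to_numpy(),
        columns=columns,
        X=X,
        treatment=subset["treatment"].to_numpy(np.int64),
        outcome=subset["outcome"].to_numpy(np.int64),
        subgroup=f"{program}:{avail}",
        dropped=dropped,
    )


def pool_design(cohort: pd.DataFrame, predictors=None) -> DesignMatrix:
    """Single design over all records, each appearing exactly once.

    Rows carry a (program, rfc) stratum label; covariates tied to an
    absent assessment enter through their missing indicators.
    """
    validate_cohort(cohort)
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    subset = cohort.reset_index(drop=True)
    predictors = _resolve_predictors(cohort, predictors)
    X, columns, dropped = _encode(subset, predictors)
    labels_per_row = (subset["program"] + ":" + subset["rfc"]).to_numpy()
    subgroup_labels = sorted(set(labels_per_row))
    lut = {lab: i for i, lab in enumerate(subgroup_labels)}
    index = np.fromiter((lut[lab] for lab in labels_per_row), np.int64, len(subset))
    return DesignMatrix(
        row_ids=subset["record_id"].to_numpy(),
        columns=columns,
        X=X,
        treatment=subset["treatment"].to_numpy(np.int64),
        outcome=subset["outcome"].to_numpy(np.int64),
        subgroup=None,
        subgroup_labels=subgroup_labels,
        subgroup_index=index,
        dropped=dropped,
    )
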