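"""Cohort I/O, population summary tables, and the craniectomy subgroup filter.

The summary table mirrors the usual "Table 1" layout of a clinical cohort
study: one row per variable, per-outcome-group cells, and an omnibus p-value.
Categorical variables are shown as count (%) and tested with chi-square or
Fisher's exact; continuous variables are shown as mean +- SD or, when clearly
skewed, median (Q1-Q3), and tested with ANOVA or Kruskal-Wallis.

Decompressive craniectomy removes part of the skull and can alter the
cranial-deformation signal, so a sensitivity analysis excluding those
patients is supported via ``subgroup_filter``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import group_compare_categorical, group_compare_continuous
from .errors import InvalidParameterError
from .metrics import STO_GROUPS

logger = logging.getLogger("icpw")

SKEW_THRESHOLD = 1.0  # |skewness| above which a continuous row reports quartiles


@dataclass(frozen=True)
class SummaryRow:
    variable: str
    overall: str
    per_group: dict[str, str]
    pvalue: float | None
    test_used: str | None


@dataclass(frozen=True)
class SummaryTable:
    rows: tuple[SummaryRow, ...]
    groups: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"variable": r.variable, "overall": r.overall}
            rec.update({g: r.per_group.get(g, "") for g in self.groups})
            rec["p_value"] = r.pvalue
            rec["test"] = r.test_used
            recs.append(rec)
        return pd.DataFrame(recs)


def _fmt_count(k: int, n: int) -> str:
    pct = 100.0 * k / n if n else 0.0
    return f"{k} ({pct:.0f}%)"


def _fmt_continuous(x: np.ndarray, skewed: bool) -> str:
    if skewed:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return f"{med:.1f} ({q1:.1f}-{q3:.1f})"
    return f"{np.mean(x):.1f} ± {np.std(x, ddof=1):.1f}"


def build_summary_table(
    patients: pd.DataFrame,
    variables: list[tuple[str, str]] | None = None,
    group_col: str = "group",
) -> SummaryTable:
    """Table-1-style summary of a cohort, stratified by outcome group.

    ``variables`` is a list of (column, kind) with kind "binary", "categorical"
    or "continuous"; the default covers the columns ``simulate_cohort`` emits.
    Categorical overall counts are computed by summation across groups, so the
    per-group cells always add up to the overall cell.
    """
    df = patients
    groups = tuple(g for g in STO_GROUPS if g in set(df[group_col]))
    unknown = set(df[group_col]) - set(STO_GROUPS)
    if unknown:
        raise InvalidParameterError(f"unknown group labels: {sorted(unknown)}")
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 outcome groups")
    if variables is None:
        variables = [
            ("age", "continuous"),
            ("micp", "continuous"),
            ("p2p1", "continuous"),
            ("bci", "continuous"),
            ("iht", "binary"),
            ("p2p1_high", "binary"),
            ("sex", "categorical"),
            ("pathology", "categorical"),
            ("neurosurgery", "categorical"),
        ]
        variables = [(v, k) for v, k in variables if v in df.columns]

    subsets = {g: df[df[group_col] == g] for g in groups}
    rows: list[SummaryRow] = []
    for var, kind in variables:
        if kind == "binary":
            counts = [int(subsets[g][var].sum()) for g in groups]
            ns = [len(subsets[g]) for g in groups]
            overall_k, overall_n = sum(counts), sum(ns)
            table = np.array([[k, n - k] for k, n in zip(counts, ns)])
            comp = group_compare_categorical(table)
            rows.append(
                SummaryRow(
                    variable=var,
                    overall=_fmt_count(overall_k, overall_n),
                    per_group={
                        g: _fmt_count(k, n) for g, k, n in zip(groups, counts, ns)
                    },
                    pvalue=comp.pvalue,
                    test_used=comp.test_used,
                )
            )
        elif kind == "categorical":
            levels = sorted(df[var].astype(str).unique())
            table = np.array(
                [
                    [int((subsets[g][var].astype(str) == lev).sum()) for lev in levels]
                    for g in groups
                ]
            )
            comp = group_compare_categorical(table)
            rows.append(
                SummaryRow(
                    variable=var, overall="", per_group={}, pvalue=comp.pvalue,
                    test_used=comp.test_used,
                )
            )
            for j, lev in enumerate(levels):
                overall_k = int(table[:, j].sum())
                rows.append(
                    SummaryRow(
                        variable=f"  {var}={lev}",
                        overall=_fmt_count(overall_k, len(df)),
                        per_group={
                            g: _fmt_count(int(table[i, j]), len(subsets[g]))
                            for i, g in enumerate(groups)
                        },
                        pvalue=None,
                        test_used=None,
                    )
                )
        elif kind == "continuous":
            samples = [subsets[g][var].to_numpy(dtype=float) for g in groups]
            skewed = abs(float(pd.Series(df[var]).skew())) > SKEW_THRESHOLD
            comp = group_compare_continuous(samples)
            rows.append(
                SummaryRow(
                    variable=var,
                    overall=_fmt_continuous(df[var].to_numpy(dtype=float), skewed),
                    per_group={
                        g: _fmt_continuous(s, skewed) for g, s in zip(groups, samples)
                    },
                    pvalue=comp.pvalue,
                    test_used=comp.test_used,
                )
            )
        else:
            raise InvalidParameterError(f"unknown variable kind {kind!r}")
    return SummaryTable(rows=tuple(rows), groups=groups)


def subgroup_filter(
    patients: pd.DataFrame, exclude_craniectomy: bool = True
) -> pd.DataFrame:
    """Optionally drop decompressive-craniectomy patients (sensitivity analysis)."""
    if not exclude_craniectomy:
        return patients
    if "neurosurgery" not in patients.columns:
        raise InvalidParameterError("cohort lacks a 'neurosurgery' column")
    kept = patients[patients["neurosurgery"] != "craniectomy"]
    n_removed = len(patients) - len(kept)
    logger.info("subgroup filter: removed %d craniectomy patients, %d retained",
                n_removed, len(kept))
    if len(kept) == 0:
        logger.warning("subgroup filter left an empty cohort")
    return kept


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

_COHORT_REQUIRED = ("id", "group", "micp", "p2p1")
_COHORT_FLOATS = ("micp", "p2p1", "age")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table, skipping (and logging) malformed rows.

    Required columns: id, group, micp, p2p1.  A row with a non-numeric value
    in a numeric column or an unknown group label is logged with its line
    number and excluded; the run continues.
    """
    path = Path(path)
    rows: list[dict] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_COHORT_REQUIRED) <= set(
            reader.fieldnames
        ):
            raise InvalidParameterError(
                f"cohort CSV must have columns {_COHORT_REQUIRED}"
            )
        for lineno, raw in enumerate(reader, start=2):
            try:
                row = dict(raw)
                for col in _COHORT_FLOATS:
                    if col in row and row[col] not in (None, ""):
                        row[col] = float(row[col])
                if row["group"] not in STO_GROUPS:
                    raise ValueError(f"unknown group {row['group']!r}")
                rows.append(row)
            except (TypeError, ValueError) as exc:
                logger.warning("%s line %d: skipping malformed row (%s)",
                               path.name, lineno, exc)
    df = pd.DataFrame(rows)
    if "bci" not in df.columns and {"micp", "p2p1"} <= set(df.columns):
        df["bci"] = df["micp"] * df["p2p1"]
    if "iht" not in df.columns and "micp" in df.columns:
        df["iht"] = df["micp"] > 20.0
    else:
        if "iht" in df.columns:
            df["iht"] = df["iht"].astype(str).str.lower().isin(("1", "true", "yes"))
    return df


def write_recording_csv(
    path: str | Path, samples: np.ndarray, fs_hz: float, icp: np.ndarray | None = None
) -> None:
    t = np.arange(len(samples)) / fs_hz
    cols = {"time_s": t, "nicpw_au": samples}
    if icp is not None:
        cols["icp_mmhg"] = icp
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def read_recording_csv(path: str | Path):
    """Read a recording CSV (time_s, nicpw_au[, icp_mmhg]); fs inferred from time."""
    from .pipeline import RawRecording

    df = pd.read_csv(path)
    if not {"time_s", "nicpw_au"} <= set(df.columns):
        raise InvalidParameterError("recording CSV needs time_s and nicpw_au columns")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise InvalidParameterError("recording too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    icp = df["icp_mmhg"].to_numpy(dtype=float) if "icp_mmhg" in df.columns else None
    return RawRecording(
        samples=df["nicpw_au"].to_numpy(dtype=float), fs_hz=fs, icp_samples=icp, t0=t[0]
    )


def scatter_export(patients: pd.DataFrame) -> pd.DataFrame:
    """Plain (micp, p2p1, group) triplets for external plotting."""
    return patients[["micp", "p2p1", "group"]].copy()
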