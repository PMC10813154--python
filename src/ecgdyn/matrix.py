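"""Statistical compression of per-window feature series and matrix assembly.

Each (lead, feature, sub-band) triple yields one value per 1-s window;
that short time series is compressed with 6 fixed statistics — Avg,
Std, P95, Var, Med, Kur — giving, for the reference configuration of
10 features x 4 sub-bands x 6 statistics, 240 columns per lead and
3600 columns for a full 15-lead record.  Columns are named
``lead__feature__m<subband>__stat`` and ordered lead-major, then
feature, then sub-band, then statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kurtosis

from .features import FEATURE_NAMES
from .records import GroupLabel

__all__ = ["STAT_NAMES", "FeatureMatrix", "compress_series", "column_name",
           "assemble", "zscore", "write_feature_matrix", "read_feature_matrix"]

#: The 6 compressors, fixed order.  Std/Var use sample (n-1) denominators;
#: Kur is the non-excess convention (Gaussian -> 3); P95 interpolates
#: linearly between order statistics.
STAT_NAMES: tuple[str, ...] = ("Avg", "Std", "P95", "Var", "Med", "Kur")


def compress_series(series: np.ndarray) -> dict[str, float]:
    """Compress one per-window feature series with the 6 statistics.

    A constant series gets the kurtosis sentinel 0 (the moment ratio is
    undefined); series of length 1 get Std = Var = 0.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot compress an empty series")
    if series.size == 1:
        std = var = 0.0
    else:
        std = float(np.std(series, ddof=1))
        var = float(np.var(series, ddof=1))
    if np.ptp(series) == 0.0:
        kur = 0.0
    else:
        kur = float(kurtosis(series, fisher=False, bias=True))
    return {
        "Avg": float(np.mean(series)),
        "Std": std,
        "P95": float(np.percentile(series, 95)),
        "Var": var,
        "Med": float(np.median(series)),
        "Kur": kur,
    }


def column_name(lead: str, feature: str, m: int, stat: str) -> str:
    return f"{lead}__{feature}__m{m}__{stat}"


def parse_column(col: str) -> tuple[str, str, int, str]:
    lead, feature, m, stat = col.split("__")
    return lead, feature, int(m[1:]), stat


@dataclass
class FeatureMatrix:
    """records x (lead x feature x sub-band x statistic) table.

    ``data`` is indexed by record_id; ``groups`` carries the diagnostic
    label per record; ``flags`` records provenance notes such as
    zero-variance columns neutralised by the z-score.
    """

    data: pd.DataFrame
    groups: pd.Series
    flags: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def leads(self) -> list[str]:
        seen: list[str] = []
        for col in self.data.columns:
            lead = col.split("__")[0]
            if lead not in seen:
                seen.append(lead)
        return seen

    def select_lead(self, lead: str) -> "FeatureMatrix":
        cols = [c for c in self.data.columns if c.split("__")[0] == lead]
        if not cols:
            raise KeyError(f"lead {lead!r} not present in matrix")
        return FeatureMatrix(self.data[cols].copy(), self.groups.copy(),
                             dict(self.flags))

    def select_groups(self, groups) -> "FeatureMatrix":
        labels = {GroupLabel(g).value for g in groups}
        mask = self.groups.astype(str).isin(labels)
        return FeatureMatrix(self.data[mask.values].copy(),
                             self.groups[mask.values].copy(), dict(self.flags))


def assemble(
    per_record: dict[str, tuple[GroupLabel, dict[str, dict[int, dict[str, np.ndarray]]]]],
) -> FeatureMatrix:
    """Assemble compressed features into the canonical matrix layout.

    Parameters
    ----------
    per_record : mapping
        ``record_id -> (group, {lead: {m: {feature: series}}})`` where
        ``series`` is the per-window value sequence of one feature in
        one sub-band of one lead.

    Raises
    ------
    ValueError
        If the lead sets differ between records (the offender is named)
        or no records are given.
    """
    if not per_record:
        raise ValueError("no records to assemble")
    ids = list(per_record)
    ref_leads = list(per_record[ids[0]][1])
    rows = []
    groups = []
    columns: list[str] | None = None
    for rid in ids:
        group, leads = per_record[rid]
        if list(leads) != ref_leads:
            raise ValueError(
                f"record {rid!r} has lead set {list(leads)}, expected {ref_leads}"
            )
        row: dict[str, float] = {}
        for lead in ref_leads:
            bands = leads[lead]
            for feature in FEATURE_NAMES:
                for m in sorted(bands):
                    stats = compress_series(np.asarray(bands[m][feature]))
                    for stat in STAT_NAMES:
                        row[column_name(lead, feature, m, stat)] = stats[stat]
        if columns is None:
            columns = list(row)
        rows.append(row)
        groups.append(GroupLabel(group).value)
    data = pd.DataFrame(rows, index=pd.Index(ids, name="record_id"),
                        columns=columns)
    return FeatureMatrix(
        data=data,
        groups=pd.Series(groups, index=data.index, name="group"),
    )


def zscore(
    matrix: FeatureMatrix,
    scope: str = "global",
    train_index: np.ndarray | None = None,
) -> FeatureMatrix:
    """Standardise every column to zero mean and unit SD.

    ``scope="global"`` (the default, mirroring the extraction pipeline)
    standardises over all rows; ``scope="per_fold"`` learns mean and SD
    on ``train_index`` rows only, which is the leakage-safe variant for
    cross-validated analyses.  Columns with zero SD are set to 0 and
    listed under ``flags["constant_columns"]``.
    """
    if matrix.n_records < 2:
        raise ValueError("z-score needs at least 2 rows")
    values = matrix.data.to_numpy(dtype=float)
    if scope == "global":
        fit = values
    elif scope == "per_fold":
        if train_index is None:
            raise ValueError("per_fold z-score requires train_index")
        fit = values[np.asarray(train_index)]
    else:
        raise ValueError(f"unknown z-score scope {scope!r}")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=1)
    constant = sd == 0.0
    sd_safe = np.where(constant, 1.0, sd)
    out = (values - mean) / sd_safe
    out[:, constant] = 0.0
    flags = dict(matrix.flags)
    flags["constant_columns"] = [
        c for c, bad in zip(matrix.data.columns, constant) if bad
    ]
    flags["zscore_scope"] = scope
    return FeatureMatrix(
        data=pd.DataFrame(out, index=matrix.data.index,
                          columns=matrix.data.columns),
        groups=matrix.groups.copy(),
        flags=flags,
    )


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Write the matrix as ``record_id,group,<columns...>`` CSV."""
    df = matrix.data.copy()
    df.insert(0, "group", matrix.groups.astype(str).values)
    df.to_csv(path, index=True, float_format="%.17g")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a matrix written by :func:`write_feature_matrix` (round trips)."""
    df = pd.read_csv(path, index_col="record_id",
                     float_precision="round_trip")
    if "group" not in df.columns:
        raise ValueError(f"{path}: missing 'group' column")
    groups = df.pop("group").astype(str)
    groups.name = "group"
    df.index = df.index.astype(str)
    groups.index = df.index
    return FeatureMatrix(data=df.astype(float), groups=groups)
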