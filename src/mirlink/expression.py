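"""Control-normalized fold-change trajectories and qPCR quantification.

The expression matrix holds nonnegative fluorescence-index (or
abundance) values for each entity over an ordered set of timepoints with
replicates, one timepoint being the uncultured control.  Each entity is
normalized to its own control mean, giving a fold-change trajectory
FC_t = mean_t / mean_control; entities whose trajectory reaches the
fold threshold (default 5) in either direction are called differential.
Relative qPCR expression uses the 2^-ddCt method: Ct values are
normalized to a housekeeping gene within each sample and to a reference
sample across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ParameterError

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Entities x (timepoint, replicate) nonnegative value matrix.

    Columns of ``data`` are labelled ``<timepoint>_<replicate>``
    (e.g. ``d4_r1``); ``control`` names the designated control timepoint.
    """

    data: pd.DataFrame
    control: str

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate entity ids: {dupes}")
        if (self.data.to_numpy() < 0).any():
            raise FormatError("negative expression values")
        if self.control not in self.timepoints_all:
            raise ConfigError(
                f"control timepoint {self.control!r} not among columns"
            )

    @staticmethod
    def split_column(col: str) -> tuple[str, str]:
        if "_" not in col:
            raise FormatError(f"column {col!r} not in <timepoint>_<replicate> form")
        tp, rep = col.rsplit("_", 1)
        return tp, rep

    @property
    def timepoints_all(self) -> list[str]:
        """Timepoints in first-appearance column order, control included."""
        seen = []
        for col in self.data.columns:
            tp, _ = self.split_column(col)
            if tp not in seen:
                seen.append(tp)
        return seen

    @property
    def timepoints(self) -> list[str]:
        """Non-control timepoints in order."""
        return [t for t in self.timepoints_all if t != self.control]

    def timepoint_means(self, method: str = "arithmetic") -> pd.DataFrame:
        """Replicate means per timepoint (NaN-skipping)."""
        groups = {}
        for tp in self.timepoints_all:
            cols = [c for c in self.data.columns if self.split_column(c)[0] == tp]
            block = self.data[cols]
            if method == "arithmetic":
                groups[tp] = block.mean(axis=1)
            elif method == "geometric":
                groups[tp] = np.exp(np.log(block.where(block > 0)).mean(axis=1))
            else:
                raise ParameterError(f"unknown replicate-combining method {method!r}")
        return pd.DataFrame(groups)


@dataclass
class DifferentialCall:
    entity_id: str
    direction: str  # "up" | "down"
    extreme_fc: float
    extreme_timepoint: str
    threshold: float
    ambiguous: bool = False


def read_expression_table(
    path: str | Path, control_label: str = "control"
) -> ExpressionMatrix:
    """Parse a TSV of entities x condition_replicate columns.

    The header row holds ``<timepoint>_<replicate>`` labels; lines
    starting with '#' are comments.  Duplicate entity ids and negative
    values are rejected; a missing control column is a configuration
    error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    if df.empty and len(df.columns) > 0:
        log.warning("expression table %s has a header but no rows", path)
    return ExpressionMatrix(data=df.astype(float), control=control_label)


def normalize_to_control(
    matrix: ExpressionMatrix,
    floor: float = 1.0,
    method: str = "arithmetic",
    include_control: bool = False,
) -> pd.DataFrame:
    """Fold change of each entity at each timepoint relative to its control.

    FC_t = max(mean_t, floor) / max(mean_control, floor).  The floor
    (default 1.0 fluorescence unit) keeps log2 ratios finite at zero or
    low signal.  Entities with an all-missing control are dropped with
    a warning.  Returns entities x non-control timepoints (control
    column of exact 1.0 prepended when ``include_control``).
    """
    if floor <= 0:
        raise ParameterError(f"floor must be positive, got {floor}")
    means = matrix.timepoint_means(method=method)
    ctrl = means[matrix.control]
    missing = ctrl.isna()
    if missing.any():
        log.warning(
            "dropping %d entities with all-missing control: %s",
            missing.sum(),
            list(means.index[missing])[:10],
        )
        means = means[~missing]
        ctrl = ctrl[~missing]
    floored = means.clip(lower=floor)
    fc = floored.div(ctrl.clip(lower=floor), axis=0)
    cols = matrix.timepoints if not include_control else matrix.timepoints_all
    out = fc[cols]
    if include_control:
        out = out.copy()
        out[matrix.control] = 1.0
    return out


def select_differential(
    fold_changes: pd.DataFrame,
    threshold: float = 5.0,
    endpoint_only: bool = False,
) -> list[DifferentialCall]:
    """Call entities whose trajectory reaches the fold threshold.

    An entity is called up iff max_t FC_t >= threshold and down iff
    min_t FC_t <= 1/threshold (inclusive comparisons).  When both hold
    the direction with the larger |log2 FC| wins; an exact tie is
    classified up and flagged ambiguous.  ``endpoint_only`` restricts
    the test to the final timepoint.
    """
    if threshold <= 1:
        raise ParameterError(f"threshold must exceed 1, got {threshold}")
    fc = fold_changes.iloc[:, [-1]] if endpoint_only else fold_changes
    calls = []
    for entity, row in fc.iterrows():
        vals = row.dropna()
        if vals.empty:
            continue
        hi, lo = vals.max(), vals.min()
        up = hi >= threshold
        down = lo <= 1.0 / threshold
        if not up and not down:
            continue
        ambiguous = False
        if up and down:
            mag_up, mag_down = abs(np.log2(hi)), abs(np.log2(lo))
            if np.isclose(mag_up, mag_down):
                direction, ambiguous = "up", True
            else:
                direction = "up" if mag_up > mag_down else "down"
        else:
            direction = "up" if up else "down"
        extreme = hi if direction == "up" else lo
        tp = vals.idxmax() if direction == "up" else vals.idxmin()
        calls.append(
            DifferentialCall(
                entity_id=str(entity),
                direction=direction,
                extreme_fc=float(extreme),
                extreme_timepoint=str(tp),
                threshold=threshold,
                ambiguous=ambiguous,
            )
        )
    calls.sort(key=lambda c: c.entity_id)
    return calls


def summarize_directions(calls: list[DifferentialCall]) -> tuple[int, int, int]:
    """(n_up, n_down, n_total) over a list of differential calls."""
    n_up = sum(1 for c in calls if c.direction == "up")
    n_down = sum(1 for c in calls if c.direction == "down")
    return n_up, n_down, n_up + n_down


def relative_expression_ddct(
    ct: pd.DataFrame,
    housekeeping: str,
    reference_sample: str,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct`` is long-format with columns (gene, sample, ct); replicate Ct
    values are averaged per (gene, sample) before any normalization.
    dCt(g,s) = Ct(g,s) - Ct(hk,s); ddCt(g,s) = dCt(g,s) - dCt(g,ref);
    relative expression = 2^-ddCt.  The reference sample maps to 1.0.
    """
    required = {"gene", "sample", "ct"}
    if not required.issubset(ct.columns):
        raise FormatError(f"Ct table needs columns {sorted(required)}")
    if not np.isfinite(ct["ct"].to_numpy(dtype=float)).all():
        raise FormatError("non-finite Ct values")
    wide = ct.pivot_table(index="gene", columns="sample", values="ct", aggfunc="mean")
    if housekeeping not in wide.index:
        raise ParameterError(f"housekeeping gene {housekeeping!r} absent from Ct table")
    if reference_sample not in wide.columns:
        raise ParameterError(f"reference sample {reference_sample!r} absent")
    hk = wide.loc[housekeeping]
    missing = hk.index[hk.isna()].tolist()
    if missing:
        raise ParameterError(
            f"housekeeping Ct missing for sample(s): {', '.join(map(str, missing))}"
        )
    dct = wide.sub(hk, axis=1)
    ddct = dct.sub(dct[reference_sample], axis=0)
    return np.power(2.0, -ddct).drop(index=housekeeping)
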