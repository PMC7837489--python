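"""qPCR relative quantification and circadian extrema.

Technical replicates are averaged on the Ct scale; each target gene is
normalized to a reference gene (beta-actin by default), giving
rel_expr = efficiency^-(Ct_target - Ct_reference) with the amplification
efficiency fixed at 2. Fold changes divide by the geometric mean of a
control group, so the control group's geometric-mean fold is 1 and all
quantities are invariant to a uniform Ct offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_REFERENCE_GENE = "beta-actin"
DEFAULT_EFFICIENCY = 2.0

#: canonical qPCR well-table columns
WELL_COLUMNS = ["sample_id", "group", "gene", "replicate", "ct"]

CT_RANGE = (0.0, 45.0)


@dataclass(frozen=True)
class ExtremaResult:
    """Peak/trough timing of a sampled time series."""

    peak_time: float | None
    trough_time: float | None
    peak_tie: bool
    trough_tie: bool
    defined: bool


def _validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    missing = set(["sample_id", "gene", "ct"]) - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns {sorted(missing)}")
    ct = wells["ct"].astype(float)
    bad = ~((ct > CT_RANGE[0]) & (ct < CT_RANGE[1]))
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} Ct values outside the valid range {CT_RANGE}"
        )
    return wells


def relative_expression(
    wells: pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """Per-sample, per-gene relative expression normalized to a reference gene.

    Returns a table with columns (sample_id[, group], gene, delta_ct,
    rel_expr) where delta_ct = mean Ct_target - mean Ct_reference over
    technical replicates and rel_expr = efficiency**(-delta_ct). Samples
    lacking the reference gene are dropped with a warning.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    wells = _validate_wells(wells)
    keys = ["sample_id", "gene"]
    mean_ct = wells.groupby(keys, sort=False)["ct"].mean().reset_index()

    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("sample_id")["ct"]
    targets = mean_ct[mean_ct["gene"] != reference_gene].copy()
    if targets.empty:
        raise ValueError("no target genes besides the reference gene")

    has_ref = targets["sample_id"].isin(ref.index)
    if not has_ref.all():
        dropped = sorted(targets.loc[~has_ref, "sample_id"].unique())
        warnings.warn(
            f"dropping samples without reference gene {reference_gene!r}: {dropped}",
            stacklevel=2,
        )
        targets = targets[has_ref]
    if targets.empty:
        raise ValueError("no sample carries the reference gene")

    targets["delta_ct"] = targets["ct"].to_numpy() - ref.loc[
        targets["sample_id"]
    ].to_numpy()
    targets["rel_expr"] = np.power(efficiency, -targets["delta_ct"])
    out = targets.drop(columns=["ct"]).reset_index(drop=True)

    if "group" in wells.columns:
        group_of = wells.drop_duplicates("sample_id").set_index("sample_id")["group"]
        out.insert(1, "group", group_of.loc[out["sample_id"]].to_numpy())
    return out


def fold_change(rel: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-sample fold change versus a control group, per gene.

    fold = rel_expr / geometric mean of the control group's rel_expr for the
    same gene; by construction the control group's geometric-mean fold is 1.
    """
    required = {"sample_id", "group", "gene", "rel_expr"}
    missing = required - set(rel.columns)
    if missing:
        raise ValueError(f"relative-expression table missing {sorted(missing)}")
    out = rel.copy()
    out["fold_change"] = np.nan
    for gene, grp in rel.groupby("gene"):
        ctrl = grp.loc[grp["group"] == control_group, "rel_expr"]
        if ctrl.empty:
            raise ValueError(
                f"control group {control_group!r} has no samples for gene {gene!r}"
            )
        geo = float(np.exp(np.mean(np.log(ctrl.to_numpy()))))
        out.loc[grp.index, "fold_change"] = grp["rel_expr"] / geo
    return out


def group_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-gene mean/SEM of rel_expr and fold_change."""
    g = folds.groupby(["gene", "group"])
    out = g.agg(
        n=("rel_expr", "count"),
        mean_rel_expr=("rel_expr", "mean"),
        sem_rel_expr=("rel_expr", "sem"),
        mean_fold=("fold_change", "mean"),
        sem_fold=("fold_change", "sem"),
    ).reset_index()
    return out.fillna({"sem_rel_expr": 0.0, "sem_fold": 0.0})


def circadian_extrema(times_h, values) -> ExtremaResult:
    """Peak and trough times of a sampled series (e.g. expression vs ZT).

    Extrema are taken on the raw sampled points, no smoothing. Ties are
    broken to the earliest time and flagged; a constant series has no
    extremum and returns ``defined=False``.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ValueError("times and values differ in length")
    if t.size < 3:
        raise ValueError("need at least three timepoints")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if np.all(v == v[0]):
        return ExtremaResult(None, None, False, False, defined=False)
    vmax, vmin = v.max(), v.min()
    peak_idx = np.nonzero(v == vmax)[0]
    trough_idx = np.nonzero(v == vmin)[0]
    return ExtremaResult(
        peak_time=float(t[peak_idx[0]]),
        trough_time=float(t[trough_idx[0]]),
        peak_tie=peak_idx.size > 1,
        trough_tie=trough_idx.size > 1,
        defined=True,
    )
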