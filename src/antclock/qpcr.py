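"""Relative qPCR quantification by the comparative-Ct (ddCt) method.

The threshold cycle (Ct) is the PCR cycle at which fluorescence crosses a
detection threshold; each unit of Ct corresponds to roughly one doubling of
starting template, so lower Ct means more transcript.  Expression of a target
gene is quantified relative to a housekeeping reference (here EF1-alpha)
measured on the same cDNA:

    dCt(colony, zt)  = mean_reps Ct_target - mean_reps Ct_reference
    ddCt(colony, zt) = dCt - calibrator(colony)
    fold             = 2 ** (-ddCt)

Technical replicates are averaged on the Ct scale before differencing and no
automatic outlier rejection is applied.  Downstream rhythm statistics operate
on per-colony z-scores of the log2 relative expression (-ddCt), which removes
colony baseline differences and is invariant to the calibrator choice.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CT_COLUMNS",
    "compute_delta_ct",
    "relative_quantity",
    "standardize",
    "expression_series",
    "aggregate_colonies",
]

#: Required columns of a tidy Ct table, one row per technical replicate.
CT_COLUMNS = ("gene", "colony", "zt", "replicate", "ct")

CALIBRATOR_RULES = ("mean_over_time", "first_timepoint")


def _check_ct_frame(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    if len(ct) == 0:
        raise ValueError("Ct table is empty")
    ctv = pd.to_numeric(ct["ct"], errors="coerce")
    bad = ct[~np.isfinite(ctv) | (ctv <= 0)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            "non-finite or non-positive Ct value for "
            f"(gene={row['gene']}, colony={row['colony']}, zt={row['zt']}, "
            f"replicate={row['replicate']}): ct={row['ct']!r}"
        )
    dup = ct.duplicated(subset=["gene", "colony", "zt", "replicate"])
    if dup.any():
        row = ct[dup].iloc[0]
        raise ValueError(
            "duplicate Ct record for key "
            f"(gene={row['gene']}, colony={row['colony']}, zt={row['zt']}, "
            f"replicate={row['replicate']})"
        )
    return ct


def compute_delta_ct(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Per-(gene, colony, zt) dCt = mean replicate Ct of target minus reference.

    Parameters
    ----------
    ct
        Tidy Ct table with columns ``gene, colony, zt, replicate, ct``
        containing the reference gene alongside the targets.
    reference_gene
        Identifier of the housekeeping gene (e.g. ``"EF1a"``).

    Returns
    -------
    DataFrame with columns ``gene, colony, zt, delta_ct``, one row per
    target-gene cell.  Every target cell must have a matching reference cell;
    a missing one raises ``ValueError`` naming the cell.
    """
    ct = _check_ct_frame(ct)
    if reference_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} not in Ct table")

    means = (
        ct.groupby(["gene", "colony", "zt"], sort=True)["ct"]
        .mean()
        .rename("mean_ct")
        .reset_index()
    )
    ref = means[means["gene"] == reference_gene].set_index(["colony", "zt"])["mean_ct"]
    targets = means[means["gene"] != reference_gene]

    rows = []
    for (gene, colony, zt), mean_ct in targets.set_index(["gene", "colony", "zt"])[
        "mean_ct"
    ].items():
        key = (colony, zt)
        if key not in ref.index:
            raise ValueError(
                f"no reference-gene measurement for cell (colony={colony}, zt={zt}) "
                f"required by target gene {gene!r}"
            )
        rows.append((gene, colony, zt, mean_ct - ref.loc[key]))
    out = pd.DataFrame(rows, columns=["gene", "colony", "zt", "delta_ct"])
    return out.sort_values(["gene", "colony", "zt"], ignore_index=True)


def relative_quantity(
    delta_ct: pd.DataFrame, calibrator_rule: str = "mean_over_time"
) -> pd.DataFrame:
    """Turn dCt values into ddCt and fold changes, 2**(-ddCt).

    ``calibrator_rule`` picks the per-(gene, colony) calibrator subtracted
    from each dCt: ``"mean_over_time"`` (the series' own across-time mean, so
    the geometric mean fold over the day is 1) or ``"first_timepoint"``.
    """
    if calibrator_rule not in CALIBRATOR_RULES:
        raise ValueError(
            f"unknown calibrator_rule {calibrator_rule!r}; expected one of {CALIBRATOR_RULES}"
        )
    if len(delta_ct) == 0:
        raise ValueError("empty dCt series")

    out = delta_ct.sort_values(["gene", "colony", "zt"], ignore_index=True).copy()

    def _calib(g: pd.DataFrame) -> float:
        if calibrator_rule == "mean_over_time":
            return g["delta_ct"].mean()
        return g.sort_values("zt")["delta_ct"].iloc[0]

    calib = out.groupby(["gene", "colony"]).apply(_calib, include_groups=False)
    calib.name = "calibrator"
    out = out.merge(calib.reset_index(), on=["gene", "colony"])
    out["ddct"] = out["delta_ct"] - out["calibrator"]
    out["fold"] = 2.0 ** (-out["ddct"])
    return out.drop(columns="calibrator")


def standardize(values: Iterable[float]) -> np.ndarray:
    """z-scores with the sample (n-1) standard deviation.

    A constant input has no spread to standardize against; it returns all
    zeros and emits a ``RuntimeWarning`` rather than dividing by zero.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize requires a 1-d sequence of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("standardize requires finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant series: z-scores set to 0", RuntimeWarning, stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def expression_series(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_rule: str = "mean_over_time",
) -> pd.DataFrame:
    """Full quantification chain: Ct records -> dCt, fold and z-scores.

    The z-score standardizes the log2 relative expression (-ddCt) of each
    (gene, colony) series across its timepoints, i.e. expression is expressed
    as the number of standard deviations above or below that series' own
    mean.  Because z-scoring is affine-invariant, the result does not depend
    on the calibrator rule.

    Returns a tidy frame with columns
    ``gene, colony, zt, delta_ct, ddct, fold, zscore``.
    """
    dct = compute_delta_ct(ct, reference_gene)
    out = relative_quantity(dct, calibrator_rule)
    zs = np.empty(len(out))
    for _, idx in out.groupby(["gene", "colony"]).groups.items():
        sub = out.loc[idx].sort_values("zt")
        zts = sub["zt"].to_numpy(float)
        if np.any(np.diff(zts) <= 0):
            raise ValueError("duplicate zt within a (gene, colony) series")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            zs[out.index.get_indexer(sub.index)] = standardize(-sub["ddct"].to_numpy())
    out["zscore"] = zs
    return out


def aggregate_colonies(series: pd.DataFrame) -> pd.DataFrame:
    """Average per-colony z-score series into a per-gene consensus profile.

    Expects the output of :func:`expression_series` (or at minimum columns
    ``gene, colony, zt, zscore``) where every colony of a gene was sampled on
    the same ZT grid.  Returns ``gene, zt, mean_z, se_z, n_colonies`` where
    ``se_z`` is the cross-colony sample standard deviation over sqrt(n).
    """
    for col in ("gene", "colony", "zt", "zscore"):
        if col not in series.columns:
            raise ValueError(f"expression series is missing column {col!r}")
    rows = []
    for gene, g in series.groupby("gene"):
        grids = {
            colony: tuple(sub.sort_values("zt")["zt"]) for colony, sub in g.groupby("colony")
        }
        grid_set = set(grids.values())
        if len(grid_set) > 1:
            raise ValueError(f"colonies of gene {gene!r} have mismatched ZT grids: {grids}")
        n = len(grids)
        if n == 1:
            warnings.warn(
                f"gene {gene!r} has a single colony: se_z reported as 0",
                RuntimeWarning,
                stacklevel=2,
            )
        for zt, cell in g.groupby("zt"):
            z = cell["zscore"].to_numpy(float)
            se = 0.0 if n == 1 else z.std(ddof=1) / np.sqrt(n)
            rows.append((gene, zt, z.mean(), se, n))
    return pd.DataFrame(rows, columns=["gene", "zt", "mean_z", "se_z", "n_colonies"])
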