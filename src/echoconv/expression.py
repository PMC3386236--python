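"""Relative quantification of qPCR data by the comparative Ct method.

Target-gene threshold cycles are normalized to a reference (housekeeping)
gene within each sample (dCt = Ct_target - Ct_reference), referred to a
calibrator cell (ddCt = dCt - mean dCt of the calibrator), and converted to
fold changes as 2^-ddCt, assuming 100% amplification efficiency (exact
doubling per cycle).  Technical replicates are averaged on the Ct scale per
individual first; individuals are then summarized on the fold scale, and
all folds are rescaled so the calibrator cell's mean is exactly 1 (the
calibrator mean defines the baseline unit).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["group", "region", "individual", "replicate", "gene", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited Ct table with a header row and validate it."""
    df = pd.read_csv(path, sep="\t")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {', '.join(missing)}")
    ct = pd.to_numeric(df["ct"], errors="raise")
    if ((ct <= 0) | (ct >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45) cycles")
    genes = set(df["gene"])
    if not genes <= {"target", "reference"}:
        raise ValueError(f"gene column must be target/reference, got {genes}")
    return df


def ddct_fold_changes(table: pd.DataFrame,
                      calibrator: tuple[str, str]) -> pd.DataFrame:
    """Fold-change table (mean +/- s.d. across individuals) per cell.

    ``calibrator`` is the (group, region) cell whose mean expression defines
    the baseline unit.  Individuals lacking the reference gene are dropped
    with a warning column; a missing calibrator cell raises.
    Returns a DataFrame with columns group, region, n_individuals,
    fold_mean, fold_sd.
    """
    df = validate_ct_table(table)
    # replicate average on the Ct scale, per individual and gene
    mean_ct = (df.groupby(["group", "region", "individual", "gene"])["ct"]
               .mean().unstack("gene"))
    if "reference" not in mean_ct.columns or "target" not in mean_ct.columns:
        raise ValueError("table must contain both target and reference genes")
    ok = mean_ct["reference"].notna() & mean_ct["target"].notna()
    if not ok.all():
        import warnings
        dropped = mean_ct.index[~ok].tolist()
        warnings.warn(f"dropping samples without both genes: {dropped}")
        mean_ct = mean_ct[ok]
    delta = (mean_ct["target"] - mean_ct["reference"]).rename("dct")

    cal_mask = (delta.index.get_level_values("group") == calibrator[0]) & \
               (delta.index.get_level_values("region") == calibrator[1])
    if not cal_mask.any():
        raise ValueError(f"calibrator cell {calibrator} not present")
    cal_dct = float(delta[cal_mask].mean())
    fold = np.power(2.0, -(delta - cal_dct))
    # baseline unit: the calibrator cell's mean fold is exactly 1
    fold = fold / float(fold[cal_mask].mean())

    out = (fold.groupby(["group", "region"])
           .agg(n_individuals="count", fold_mean="mean", fold_sd="std")
           .reset_index())
    out["fold_sd"] = out["fold_sd"].fillna(0.0)
    return out
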