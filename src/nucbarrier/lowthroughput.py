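"""Nucleosome-scanning qPCR and strand-specific RT-qPCR quantification.

Quantities are linear-scale abundances (already converted from Ct values
with the amplification-efficiency curve).  Scanning occupancy is the
MNase-protected (mononucleosomal) quantity relative to an undigested
input, which is 1 by construction; strain and transcript comparisons are
ratios of per-group means with SEM propagated by the delta method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["relative_occupancy", "strain_ratio", "transcript_fold_change"]

_QPCR_COLUMNS = ["target", "position", "replicate", "mono_quantity", "input_quantity"]
_RT_COLUMNS = ["gene", "strand_sense", "quantity", "replicate", "strain"]


def relative_occupancy(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-amplicon occupancy relative to the undigested input.

    For each replicate, occupancy = mono_quantity / input_quantity, so the
    input itself scores exactly 1.  Returns one row per (target, position)
    with the mean over replicates, the SEM (sd/sqrt(n), NaN when n < 2)
    and n.
    """
    missing = set(_QPCR_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns {sorted(missing)}")
    if (measurements["input_quantity"] <= 0).any():
        raise ValueError("input_quantity must be positive for every replicate")
    df = measurements.assign(occupancy=measurements["mono_quantity"] / measurements["input_quantity"])
    grouped = df.groupby(["target", "position"], sort=True)["occupancy"]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "sem"] = np.nan
    return out[["target", "position", "mean", "sem", "n"]]


def _ratio_with_sem(mean_t, sem_t, mean_r, sem_r):
    if np.any(mean_r == 0):
        raise ValueError("reference mean occupancy is zero; ratio undefined")
    ratio = mean_t / mean_r
    rel = np.sqrt((sem_t / mean_t) ** 2 + (sem_r / mean_r) ** 2)
    return ratio, np.abs(ratio) * rel


def strain_ratio(occ_test: pd.DataFrame, occ_ref: pd.DataFrame,
                 control_target: str | None = None) -> pd.DataFrame:
    """Per-target occupancy of a test strain relative to a reference strain.

    Inputs are ``relative_occupancy`` outputs.  The ratio of means is
    reported with a delta-method SEM (relative variances added in
    quadrature).  When ``control_target`` names a control locus its ratio
    is flagged in the ``is_control`` column as a sanity value, expected
    near 1.
    """
    merged = occ_test.merge(occ_ref, on=["target", "position"], suffixes=("_test", "_ref"))
    if merged.empty:
        raise ValueError("test and reference share no (target, position) rows")
    ratio, sem = _ratio_with_sem(
        merged["mean_test"].to_numpy(), merged["sem_test"].to_numpy(),
        merged["mean_ref"].to_numpy(), merged["sem_ref"].to_numpy(),
    )
    out = merged[["target", "position"]].copy()
    out["ratio"] = ratio
    out["sem"] = sem
    out["is_control"] = out["target"] == control_target if control_target else False
    if control_target and not out["is_control"].any():
        raise ValueError(f"control target {control_target!r} not present in the tables")
    return out


def transcript_fold_change(measurements: pd.DataFrame,
                           reference_strain: str) -> pd.DataFrame:
    """Per-gene, per-strand transcript levels relative to a reference strain.

    For every (gene, strand_sense, strain) the mean quantity over
    replicates is divided by the reference strain's mean for the same gene
    and strand; the reference thus scores 1.  SEM is propagated by the
    delta method.
    """
    missing = set(_RT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"transcript table missing columns {sorted(missing)}")
    if reference_strain not in set(measurements["strain"]):
        raise ValueError(f"reference strain {reference_strain!r} not in the table")

    stats = (measurements.groupby(["gene", "strand_sense", "strain"], sort=True)["quantity"]
             .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index())
    stats["sem"] = stats["sd"] / np.sqrt(stats["n"])
    ref = stats[stats["strain"] == reference_strain].set_index(["gene", "strand_sense"])

    rows = []
    for (gene, sense, strain), grp in stats.groupby(["gene", "strand_sense", "strain"]):
        if (gene, sense) not in ref.index:
            raise ValueError(f"gene {gene!r} ({sense}) missing from reference strain")
        r = ref.loc[(gene, sense)]
        g = grp.iloc[0]
        fold, sem = _ratio_with_sem(g["mean"], g["sem"], r["mean"], r["sem"])
        rows.append({"gene": gene, "strand_sense": sense, "strain": strain,
                     "fold_change": float(fold), "sem": float(sem), "n": int(g["n"])})
    return pd.DataFrame(rows)
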