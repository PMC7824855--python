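"""Comparative-Ct (2^-ddCt) relative quantification for qPCR.

Each well reports a threshold cycle (Ct) for a target gene and a reference
(housekeeping) gene. The target's abundance in a sample relative to a
calibrator sample is

    RQ = E^(-ddCt),   ddCt = (Ct_target - Ct_ref)_sample
                            - (Ct_target - Ct_ref)_calibrator

with amplification efficiency E = 2 (perfect doubling per cycle) unless
stated otherwise. Within a genotype group the delta-Ct values are averaged
before the point estimate (so the calibrator group's mean RQ is exactly 1),
while per-replicate RQs provide the spread.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def _check_finite(**cts: float) -> None:
    for name, v in cts.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


def relative_quantity(
    target_ct_sample: float,
    ref_ct_sample: float,
    target_ct_calibrator: float,
    ref_ct_calibrator: float,
    efficiency: float = 2.0,
) -> float:
    """Relative quantity E^(-ddCt) of a sample against a calibrator."""
    _check_finite(
        target_ct_sample=target_ct_sample,
        ref_ct_sample=ref_ct_sample,
        target_ct_calibrator=target_ct_calibrator,
        ref_ct_calibrator=ref_ct_calibrator,
    )
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ddct = (target_ct_sample - ref_ct_sample) - (target_ct_calibrator - ref_ct_calibrator)
    return float(efficiency**-ddct)


def summarize_by_genotype(
    records: pd.DataFrame,
    calibrator_role: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-genotype mean and s.d. of relative quantity.

    Parameters
    ----------
    records
        One row per replicate with columns ``sample_id``, ``genotype``,
        ``replicate``, ``target_ct``, ``reference_ct``.
    calibrator_role
        Genotype used as the calibrator (its mean RQ is 1 by
        construction).
    efficiency
        Amplification efficiency per cycle (default 2.0).

    Returns
    -------
    DataFrame indexed by genotype with columns ``n``, ``mean_rq``
    (from the group-mean delta-Ct) and ``sd_rq`` (population s.d. of
    per-replicate RQs, so exact duplication of the replicate structure
    leaves the summary unchanged; 0 for singleton groups).
    """
    required = {"genotype", "target_ct", "reference_ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing column(s): {sorted(missing)}")
    cts = records[["target_ct", "reference_ct"]].to_numpy(float)
    if not np.isfinite(cts).all():
        raise ValueError("Ct values must be finite")

    dct = records["target_ct"].astype(float) - records["reference_ct"].astype(float)
    grouped = dct.groupby(records["genotype"])
    if calibrator_role not in grouped.groups:
        raise ValueError(f"calibrator genotype {calibrator_role!r} has no records")
    cal_dct = grouped.get_group(calibrator_role).mean()

    rows = {}
    for genotype, values in grouped:
        rq_point = float(efficiency ** -(values.mean() - cal_dct))
        per_rep = efficiency ** -(values - cal_dct)
        sd = float(per_rep.std(ddof=0)) if len(per_rep) > 1 else 0.0
        rows[genotype] = {"n": len(values), "mean_rq": rq_point, "sd_rq": sd}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "genotype"
    out["n"] = out["n"].astype(int)
    return out
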