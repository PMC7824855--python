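"""FPKM quantification.

FPKM (fragments per kilobase of exon per million mapped fragments)
normalises a raw fragment count by the feature's effective length and the
sample's sequencing depth:

    FPKM = count * 1e9 / (effective_length_bp * total_mapped)

Depth defaults to the column sum of the count matrix; a per-sample override
is accepted for workflows where the mapped-fragment total is known from the
alignment rather than the matrix.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd


def fpkm(count: float, effective_length_bp: float, total_mapped: float) -> float:
    """FPKM of a single count.

    Parameters
    ----------
    count
        Nonnegative fragment count.
    effective_length_bp
        Feature length in base pairs, >= 1.
    total_mapped
        Total mapped fragments in the sample, >= 1.
    """
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count}")
    if effective_length_bp < 1:
        raise ValueError(f"effective_length_bp must be >= 1, got {effective_length_bp}")
    if total_mapped < 1:
        raise ValueError(f"total_mapped must be >= 1, got {total_mapped}")
    return count * 1e9 / (effective_length_bp * total_mapped)


def fpkm_matrix(
    counts: pd.DataFrame,
    lengths: pd.Series | Mapping[str, int],
    total_mapped: pd.Series | Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Elementwise FPKM of a genes x samples count matrix.

    ``lengths`` must cover every gene in ``counts``. ``total_mapped``
    defaults to each column's sum; the values used are recorded in the
    result's ``attrs["total_mapped"]``.

    Returns a genes x samples DataFrame of nonnegative reals with the same
    index and columns as ``counts``.
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no effective length for gene(s): {', '.join(map(str, missing[:5]))}")
    lens = lengths.reindex(counts.index)
    if (lens < 1).any():
        bad = lens.index[lens < 1][0]
        raise ValueError(f"effective length of {bad!r} must be >= 1 bp")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")

    if total_mapped is None:
        totals = counts.sum(axis=0).astype(float)
    else:
        totals = pd.Series(total_mapped, dtype=float).reindex(counts.columns)
        if totals.isna().any():
            missing_s = totals.index[totals.isna()].tolist()
            raise ValueError(f"total_mapped missing for sample(s): {missing_s}")
    if (totals < 1).any():
        bad = totals.index[totals < 1][0]
        raise ValueError(f"total_mapped for sample {bad!r} must be >= 1")

    out = counts.astype(float).div(lens, axis=0).div(totals, axis=1) * 1e9
    out.attrs["total_mapped"] = totals.to_dict()
    return out
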