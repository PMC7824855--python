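"""Directional rescue filter and gene-set intersection.

The screen's core question, asked gene by gene: is the transcript altered
in the pathogenic genotype relative to wild-type, and is that alteration
*reversed* — opposite sign, past the same magnitude cutoff — in every
protective/rescue comparison?

A gene passes the pathogenic gate when its WT->PATHOGENIC contrast is
significant (q below threshold) with |log2FC| strictly above the cutoff
(default 0.3 log2 units). It is then called RESTORED_UP or RESTORED_DOWN
when every reversal contrast (PATHOGENIC -> protective or rescue genotype)
shows the opposite sign, magnitude strictly above the cutoff, and — by
default — its own significance. Genes passing the pathogenic gate but
failing any reversal condition are NOT_RESTORED; everything else is
NOT_SIGNIFICANT.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Verdict(str, enum.Enum):
    RESTORED_UP = "RESTORED_UP"
    RESTORED_DOWN = "RESTORED_DOWN"
    NOT_RESTORED = "NOT_RESTORED"
    NOT_SIGNIFICANT = "NOT_SIGNIFICANT"

    def __str__(self) -> str:
        return self.value

    @property
    def restored(self) -> bool:
        return self in (Verdict.RESTORED_UP, Verdict.RESTORED_DOWN)


@dataclass
class DirectionalCriteria:
    """Thresholds of the directional screen.

    q_threshold
        BH q-value significance threshold (default 0.05).
    logfc_cutoff
        Strict magnitude cutoff on |log2FC| (default 0.3 log2 units);
        ties at exactly the cutoff are excluded.
    require_reversal_significance
        Whether each reversal contrast must itself pass q < threshold
        (default True) or only the sign/magnitude conditions.
    """

    q_threshold: float = 0.05
    logfc_cutoff: float = 0.3
    require_reversal_significance: bool = True

    def validate(self) -> None:
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if self.logfc_cutoff <= 0:
            raise ValueError("logfc_cutoff must be positive")


@dataclass
class RescueCall:
    """Per-gene screen verdict with the evidence it rests on."""

    gene_id: str
    verdict: Verdict
    pathogenic_log2fc: float
    pathogenic_q: float
    reversal_log2fcs: tuple[float, ...]
    reversal_qs: tuple[float, ...]


def classify_gene(
    pathogenic: Mapping[str, object],
    reversals: Sequence[Mapping[str, object]],
    criteria: DirectionalCriteria | None = None,
) -> RescueCall:
    """Classify one gene from its pathogenic and reversal contrast records.

    Each record is a mapping with keys ``gene_id``, ``log2fc`` and ``q``
    (a DataFrame row converted with ``.to_dict()`` works). All records
    must refer to the same gene and ``reversals`` must be nonempty.
    """
    criteria = criteria or DirectionalCriteria()
    criteria.validate()
    if not reversals:
        raise ValueError("at least one reversal contrast record is required")
    gene = str(pathogenic["gene_id"])
    for rec in reversals:
        if str(rec["gene_id"]) != gene:
            raise ValueError(
                f"gene-ID mismatch: pathogenic record is {gene!r}, "
                f"reversal record is {rec['gene_id']!r}"
            )

    p_lfc = float(pathogenic["log2fc"])
    p_q = float(pathogenic["q"])
    r_lfcs = tuple(float(r["log2fc"]) for r in reversals)
    r_qs = tuple(float(r["q"]) for r in reversals)

    if p_q >= criteria.q_threshold or abs(p_lfc) <= criteria.logfc_cutoff:
        verdict = Verdict.NOT_SIGNIFICANT
    else:
        reversed_everywhere = all(
            np.sign(lfc) == -np.sign(p_lfc)
            and abs(lfc) > criteria.logfc_cutoff
            and (not criteria.require_reversal_significance or q < criteria.q_threshold)
            for lfc, q in zip(r_lfcs, r_qs)
        )
        if reversed_everywhere:
            verdict = Verdict.RESTORED_UP if p_lfc > 0 else Verdict.RESTORED_DOWN
        else:
            verdict = Verdict.NOT_RESTORED
    return RescueCall(gene, verdict, p_lfc, p_q, r_lfcs, r_qs)


def passing_set(
    table: pd.DataFrame,
    criteria: DirectionalCriteria,
    apply_cutoff: bool = True,
) -> set[str]:
    """Genes significant in one contrast (q < threshold, optionally
    |log2FC| strictly above the cutoff)."""
    mask = table["q"] < criteria.q_threshold
    if apply_cutoff:
        mask &= table["log2fc"].abs() > criteria.logfc_cutoff
    return set(table.index[mask].astype(str))


@dataclass
class ScreenResult:
    """Output of :func:`apply_screen`.

    calls
        Per-gene verdict table indexed by gene id.
    contrast_sets
        Per contrast, the set of genes passing significance (and, with the
        default ordering, the magnitude cutoff) in that contrast alone —
        the inputs of the Venn intersection.
    criteria
        The thresholds used.
    """

    calls: pd.DataFrame
    contrast_sets: dict[str, set[str]]
    criteria: DirectionalCriteria

    @property
    def restored_genes(self) -> set[str]:
        mask = self.calls["verdict"].isin(
            [Verdict.RESTORED_UP.value, Verdict.RESTORED_DOWN.value]
        )
        return set(self.calls.index[mask].astype(str))


def apply_screen(
    tables: Mapping[str, pd.DataFrame],
    criteria: DirectionalCriteria | None = None,
    pathogenic: str | None = None,
    reversals: Sequence[str] | None = None,
    cutoff_before_intersect: bool = True,
) -> ScreenResult:
    """Run the directional screen over full contrast tables.

    Parameters
    ----------
    tables
        Mapping contrast-name -> per-gene table with ``log2fc`` and ``q``
        columns, all sharing one gene universe.
    criteria
        Screen thresholds.
    pathogenic
        Name of the WT -> pathogenic contrast; defaults to the first key.
    reversals
        Names of the reversal contrasts; defaults to every other key.
    cutoff_before_intersect
        If True (default) the per-contrast gene sets used for the Venn
        intersection apply the |log2FC| cutoff as well as q; if False the
        cutoff is deferred and the sets are q-significant genes only.
    """
    criteria = criteria or DirectionalCriteria()
    criteria.validate()
    names = list(tables)
    if pathogenic is None:
        pathogenic = names[0]
    if reversals is None:
        reversals = [n for n in names if n != pathogenic]
    if not reversals:
        raise ValueError("at least one reversal contrast table is required")

    universe = tables[pathogenic].index
    for name in reversals:
        other = tables[name].index
        if not universe.equals(other):
            diff = set(universe).symmetric_difference(other)
            raise ValueError(
                f"contrast {name!r} gene universe differs from "
                f"{pathogenic!r}; symmetric difference: {sorted(diff)[:10]}"
            )

    p_tab = tables[pathogenic]
    r_tabs = [tables[n] for n in reversals]
    p_lfc = p_tab["log2fc"].to_numpy(float)
    p_q = p_tab["q"].to_numpy(float)
    r_lfc = np.column_stack([t["log2fc"].reindex(universe).to_numpy(float) for t in r_tabs])
    r_q = np.column_stack([t["q"].reindex(universe).to_numpy(float) for t in r_tabs])

    sig = (p_q < criteria.q_threshold) & (np.abs(p_lfc) > criteria.logfc_cutoff)
    rev_ok = (np.sign(r_lfc) == -np.sign(p_lfc)[:, None]) & (
        np.abs(r_lfc) > criteria.logfc_cutoff
    )
    if criteria.require_reversal_significance:
        rev_ok &= r_q < criteria.q_threshold
    all_rev = rev_ok.all(axis=1)

    verdict = np.where(
        ~sig,
        Verdict.NOT_SIGNIFICANT.value,
        np.where(
            all_rev,
            np.where(p_lfc > 0, Verdict.RESTORED_UP.value, Verdict.RESTORED_DOWN.value),
            Verdict.NOT_RESTORED.value,
        ),
    )
    calls = pd.DataFrame(
        {
            "verdict": verdict,
            "pathogenic_log2fc": p_lfc,
            "pathogenic_q": p_q,
            "reversal_log2fcs": [";".join(f"{v:.6g}" for v in row) for row in r_lfc],
            "reversal_qs": [";".join(f"{v:.6g}" for v in row) for row in r_q],
        },
        index=universe,
    )
    sets = {
        name: passing_set(tables[name], criteria, apply_cutoff=cutoff_before_intersect)
        for name in [pathogenic, *reversals]
    }
    return ScreenResult(calls=calls, contrast_sets=sets, criteria=criteria)


@dataclass
class VennCounts:
    """Region cardinalities of a three-set Venn diagram.

    ``regions`` maps the exclusive regions — keys ``"A"``, ``"B"``,
    ``"C"``, ``"AB"``, ``"AC"``, ``"BC"``, ``"ABC"`` — to their counts;
    ``totals`` maps each set label to its full size.
    """

    labels: tuple[str, str, str]
    regions: dict[str, int]
    totals: dict[str, int]

    @property
    def triple_overlap(self) -> int:
        return self.regions["ABC"]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def venn_counts(
    set_a: Iterable[str],
    set_b: Iterable[str],
    set_c: Iterable[str],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> VennCounts:
    """Exact region counts of three gene sets (empty sets allowed)."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    regions = {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }
    totals = {labels[0]: len(a), labels[1]: len(b), labels[2]: len(c)}
    return VennCounts(labels=tuple(labels), regions=regions, totals=totals)
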