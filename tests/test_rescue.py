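import numpy as np
import pandas as pd
import pytest

from rescuescreen.rescue import (
    DirectionalCriteria,
    Verdict,
    apply_screen,
    classify_gene,
    venn_counts,
)


def rec(gene, lfc, q):
    return {"gene_id": gene, "log2fc": lfc, "q": q}


# --- single-gene classification --------------------------------------------


def test_restored_up_when_all_reversals_oppose():
    call = classify_gene(
        rec("g1", 1.2, 0.01), [rec("g1", -0.8, 0.02), rec("g1", -0.9, 0.01)]
    )
    assert call.verdict is Verdict.RESTORED_UP


def test_restored_down_mirror_image():
    call = classify_gene(
        rec("g1", -1.2, 0.01), [rec("g1", 0.8, 0.02), rec("g1", 0.9, 0.01)]
    )
    assert call.verdict is Verdict.RESTORED_DOWN


def test_below_cutoff_is_not_significant_despite_tiny_q():
    call = classify_gene(rec("g1", 0.2, 0.001), [rec("g1", -0.8, 0.01)])
    assert call.verdict is Verdict.NOT_SIGNIFICANT


def test_exact_cutoff_tie_excluded():
    call = classify_gene(rec("g1", 0.3, 0.001), [rec("g1", -0.8, 0.01)])
    assert call.verdict is Verdict.NOT_SIGNIFICANT


def test_one_agreeing_reversal_spoils_restoration():
    call = classify_gene(
        rec("g1", 1.0, 0.01), [rec("g1", 0.7, 0.01), rec("g1", -0.9, 0.01)]
    )
    assert call.verdict is Verdict.NOT_RESTORED


def test_reversal_significance_toggle():
    reversals = [rec("g1", -0.8, 0.5)]  # right sign and size, not significant
    strict = classify_gene(rec("g1", 1.0, 0.01), reversals)
    relaxed = classify_gene(
        rec("g1", 1.0, 0.01),
        reversals,
        DirectionalCriteria(require_reversal_significance=False),
    )
    assert strict.verdict is Verdict.NOT_RESTORED
    assert relaxed.verdict is Verdict.RESTORED_UP


def test_gene_mismatch_and_empty_reversals_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        classify_gene(rec("g1", 1.0, 0.01), [rec("g2", -1.0, 0.01)])
    with pytest.raises(ValueError, match="reversal"):
        classify_gene(rec("g1", 1.0, 0.01), [])


# --- whole-screen application ----------------------------------------------


def _null_table(genes):
    return pd.DataFrame(
        {"log2fc": 0.0, "q": 1.0, "p": 1.0}, index=pd.Index(genes, name="gene_id")
    )


def test_all_null_tables_give_zero_restored():
    genes = [f"g{i}" for i in range(30)]
    tables = {name: _null_table(genes) for name in ("a", "b", "c")}
    result = apply_screen(tables, pathogenic="a")
    assert result.restored_genes == set()
    assert set(result.calls["verdict"]) == {Verdict.NOT_SIGNIFICANT.value}


def test_screen_matches_gene_by_gene_oracle(standard_tables, standard_screen):
    """The vectorised screen equals a brute-force loop of classify_gene."""
    path = standard_tables["wt_vs_path"]
    revs = [standard_tables["path_vs_prot"], standard_tables["path_vs_resc"]]
    for gene in path.index:
        expected = classify_gene(
            {"gene_id": gene, **path.loc[gene, ["log2fc", "q"]].to_dict()},
            [{"gene_id": gene, **t.loc[gene, ["log2fc", "q"]].to_dict()} for t in revs],
        )
        assert standard_screen.calls.at[gene, "verdict"] == expected.verdict.value


def test_row_permutation_only_permutes_verdicts(standard_tables, standard_screen):
    rng = np.random.default_rng(2)
    perm = rng.permutation(len(standard_tables["wt_vs_path"]))
    shuffled = {k: t.iloc[perm] for k, t in standard_tables.items()}
    result = apply_screen(shuffled, pathogenic="wt_vs_path")
    reordered = result.calls.loc[standard_screen.calls.index]
    assert (reordered["verdict"] == standard_screen.calls["verdict"]).all()


def test_mismatched_universes_rejected(standard_tables):
    tables = dict(standard_tables)
    tables["path_vs_resc"] = tables["path_vs_resc"].iloc[:-1]
    with pytest.raises(ValueError, match="symmetric difference"):
        apply_screen(tables, pathogenic="wt_vs_path")


def test_restored_calls_within_triple_intersection(standard_screen):
    """Every RESTORED gene is significant in all three contrasts, so the
    RESTORED count cannot exceed the Venn triple overlap."""
    venn = venn_counts(*standard_screen.contrast_sets.values())
    assert standard_screen.restored_genes <= set.intersection(
        *map(set, standard_screen.contrast_sets.values())
    )
    assert len(standard_screen.restored_genes) <= venn.triple_overlap


def test_tightening_criteria_is_monotone(standard_tables):
    """Shrinking q or raising the log2FC cutoff never adds RESTORED calls."""
    baseline = apply_screen(standard_tables, DirectionalCriteria(), pathogenic="wt_vs_path")
    for criteria in (
        DirectionalCriteria(q_threshold=0.01),
        DirectionalCriteria(logfc_cutoff=0.8),
        DirectionalCriteria(q_threshold=0.01, logfc_cutoff=0.8),
    ):
        tightened = apply_screen(standard_tables, criteria, pathogenic="wt_vs_path")
        assert tightened.restored_genes <= baseline.restored_genes


def test_parameter_recovery_sensitivity_and_fdp(standard_dataset, standard_screen):
    """Planted-truth recovery on the standard simulation: at least 90% of
    RESTORED genes are called and at most 10% of calls are false."""
    truth = standard_dataset.truth
    planted = set(truth.index[truth["gene_class"] == "RESTORED"])
    called = standard_screen.restored_genes
    sensitivity = len(called & planted) / len(planted)
    fdp = len(called - planted) / max(len(called), 1)
    assert sensitivity >= 0.90
    assert fdp <= 0.10


# --- Venn regions -----------------------------------------------------------


def test_venn_disjoint_singletons():
    v = venn_counts({"a"}, {"b"}, {"c"})
    assert v.regions == {"A": 1, "B": 1, "C": 1, "AB": 0, "AC": 0, "BC": 0, "ABC": 0}
    assert v.union_size == 3


def test_venn_identical_sets():
    s = {f"g{i}" for i in range(9)}
    v = venn_counts(s, s, s)
    assert v.triple_overlap == 9
    assert v.union_size == 9
    assert sum(v.regions.values()) - v.regions["ABC"] == 0


def test_venn_matches_membership_enumeration():
    """Random 50-gene subsets vs a brute-force 3-bit membership count."""
    rng = np.random.default_rng(17)
    universe = [f"g{i}" for i in range(100)]
    a, b, c = (set(rng.choice(universe, 50, replace=False)) for _ in range(3))
    v = venn_counts(a, b, c)
    expected = {k: 0 for k in v.regions}
    for g in universe:
        key = "".join(ch for ch, s in zip("ABC", (a, b, c)) if g in s)
        if key:
            expected[key] += 1
    assert v.regions == expected
    assert v.totals == {"A": len(a), "B": len(b), "C": len(c)}
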