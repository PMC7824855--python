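"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated text. Gene and sample identifiers are opaque
strings; nothing assumes an organism or an ID scheme. Every writer's
output is readable by the matching reader (round-trip closure), which the
pipeline relies on for byte-exact reruns.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rescuescreen.enrichment import AnnotationCatalog, EnrichmentRow
from rescuescreen.rescue import VennCounts
from rescuescreen.simulate import ROLES, SyntheticDataset


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix.

    Header row holds sample IDs; the first column holds gene IDs.
    Duplicated gene or sample IDs, non-integer cells and negative counts
    are rejected with the offending address.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene ID {dup!r} in {path}")
    if pd.Index(df.columns).duplicated().any():
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r} in {path}")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (gene, raw) in enumerate(df[col].items()):
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {raw!r} at gene {gene!r}, sample {col!r} in {path}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"negative count {value} at gene {gene!r}, sample {col!r} in {path}"
                )
            values[i, j] = value
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.index.name = "gene_id"
    return out


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read sample_id / genotype_role / replicate assignments."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str})
    required = {"sample_id", "genotype", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")
    bad = set(df["genotype"]) - set(ROLES)
    if bad:
        raise ValueError(f"unknown genotype role(s) {sorted(bad)}; expected one of {ROLES}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in sample sheet")
    out = df.set_index("sample_id")[["genotype", "replicate"]]
    out["replicate"] = out["replicate"].astype(int)
    return out


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def read_lengths_tsv(path: str | Path) -> pd.Series:
    """Read gene_id -> effective_length_bp."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "effective_length_bp"} <= set(df.columns):
        raise ValueError("lengths table needs columns gene_id, effective_length_bp")
    s = df.set_index("gene_id")["effective_length_bp"].astype(int)
    if (s < 1).any():
        bad = s.index[s < 1][0]
        raise ValueError(f"effective length of {bad!r} must be >= 1")
    return s


def write_lengths_tsv(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("effective_length_bp").to_csv(path, sep="\t", index_label="gene_id")


def write_fpkm_tsv(fpkm: pd.DataFrame, path: str | Path) -> None:
    fpkm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_fpkm_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_contrast_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene contrast table; the contrast name and orientation
    travel in a ``#`` comment header line."""
    name = table.attrs.get("contrast", "contrast")
    frm = table.attrs.get("group_from", "")
    to = table.attrs.get("group_to", "")
    with open(path, "w") as fh:
        fh.write(f"# contrast={name}\tgroup_from={frm}\tgroup_to={to}\n")
        table.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.10g")


def read_contrast_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if header.startswith("#"):
        for piece in header[1:].strip().split("\t"):
            if "=" in piece:
                key, value = piece.split("=", 1)
                df.attrs[key.strip()] = value
    return df


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_venn_tsv(venn: VennCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tsets\tcount\n")
        label_of = dict(zip("ABC", venn.labels))
        for region, count in venn.regions.items():
            names = "&".join(label_of[ch] for ch in region)
            fh.write(f"{region}\t{names}\t{count}\n")


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write counts, sample sheet, truth and lengths of a simulated dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "truth": outdir / "truth.tsv",
        "lengths": outdir / "lengths.tsv",
    }
    write_counts_tsv(dataset.counts, paths["counts"])
    write_sample_sheet(dataset.sample_sheet, paths["sample_sheet"])
    write_truth_tsv(dataset.truth, paths["truth"])
    write_lengths_tsv(dataset.lengths, paths["lengths"])
    return paths


def read_gmt(
    path: str | Path,
    background: Iterable[str] | None = None,
    category: str | None = None,
) -> AnnotationCatalog:
    """Read an annotation catalog from GMT.

    Each line: term, description, then >= 1 tab-separated gene IDs.
    The description field is used as the term's category label when
    nonempty, otherwise ``category`` (or the file stem) applies. Duplicate
    genes within a line are stored once. The universe defaults to the
    union of all member sets unless ``background`` is given.
    """
    path = Path(path)
    default_category = category or path.stem
    terms: dict[str, frozenset[str]] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and >= 1 gene "
                    f"({len(fields)} field(s) found)"
                )
            term, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = frozenset(genes)
            categories[term] = description if description else default_category
    universe = frozenset(background) if background is not None else frozenset()
    return AnnotationCatalog(terms=terms, categories=categories, universe=universe)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


#: Column order of the enrichment chart, mirroring DAVID's output.
ENRICHMENT_COLUMNS: Sequence[str] = (
    "Category",
    "Term",
    "Count",
    "%",
    "p-Value",
    "Gene IDs",
    "List Total",
    "Pop Hits",
    "Pop Total",
    "Fold Enrichment",
    "FDR p-Value",
)


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ENRICHMENT_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.category,
                    r.term,
                    r.count,
                    f"{r.percent:.9f}".rstrip("0").rstrip("."),
                    f"{r.ease_p:.9g}",
                    ", ".join(r.gene_ids),
                    r.list_total,
                    r.pop_hits,
                    r.pop_total,
                    f"{r.fold_enrichment:.9g}",
                    f"{r.fdr:.9g}",
                ]
            )


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    """Read a long-format Ct table and pivot to one row per replicate.

    Input columns: sample_id, genotype, replicate, gene (``target`` or
    ``reference``), ct. Output columns: sample_id, genotype, replicate,
    target_ct, reference_ct.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str, "gene": str})
    required = {"sample_id", "genotype", "replicate", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    bad = set(df["gene"]) - {"target", "reference"}
    if bad:
        raise ValueError(f"gene column must be 'target' or 'reference', got {sorted(bad)}")
    wide = df.pivot_table(
        index=["sample_id", "genotype", "replicate"], columns="gene", values="ct"
    ).reset_index()
    if (
        "target" not in wide.columns
        or "reference" not in wide.columns
        or wide[["target", "reference"]].isna().any().any()
    ):
        raise ValueError("every replicate needs both a target and a reference Ct")
    wide = wide.rename(columns={"target": "target_ct", "reference": "reference_ct"})
    wide.columns.name = None
    return wide


def write_coordinates_tsv(
    coordinates: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    explained: Sequence[float],
    path: str | Path,
) -> None:
    out = coordinates.join(sample_sheet["genotype"])
    out = out[["genotype", *coordinates.columns]]
    for i, frac in enumerate(explained, start=1):
        out[f"var_frac{i}"] = frac
    out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")
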