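"""End-to-end orchestration: simulate -> FPKM -> contrasts -> screen ->
enrichment -> ordination, with a reproducibility manifest.

A :class:`PipelineConfig` (built in code or loaded from YAML/JSON) names
the inputs — either a simulation block or paths to a count matrix, sample
sheet and length table — plus the screen thresholds and output directory.
:func:`run_all` executes the stages in order, writes every intermediate
as TSV, and records a manifest (stage order, parameters, seed, SHA-256 of
every input and output file) from which a rerun can be verified
byte-for-byte. Stages without inputs (no annotation catalog, no Ct table)
are skipped and the skip is recorded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from rescuescreen import io as rsio
from rescuescreen.differential import Contrast, TestParams, test_contrast
from rescuescreen.ordination import genotype_mean_coordinates, pca_map
from rescuescreen.qpcr import summarize_by_genotype
from rescuescreen.quantify import fpkm_matrix
from rescuescreen.rescue import DirectionalCriteria, apply_screen, venn_counts
from rescuescreen.simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("rescuescreen")

#: Default contrast design: pathogenic vs wild-type, then the pathogenic
#: genotype against one protective and one rescue genotype.
DEFAULT_CONTRASTS: tuple[tuple[str, str, str], ...] = (
    ("wt_vs_path", "WT", "PATHOGENIC"),
    ("path_vs_prot", "PATHOGENIC", "PROTECTIVE_A"),
    ("path_vs_resc", "PATHOGENIC", "RESCUE_A"),
)


@dataclass
class PipelineConfig:
    """Everything one ``run-all`` execution needs.

    Exactly one of ``simulation`` or (``counts``, ``sample_sheet``,
    ``lengths``) provides the expression data. ``seed`` is mandatory
    whenever a stochastic stage (simulation) runs — there is no silent
    default.
    """

    outdir: str | Path = "rescuescreen_out"
    seed: int | None = None
    simulation: SimulationConfig | None = None
    counts: str | Path | None = None
    sample_sheet: str | Path | None = None
    lengths: str | Path | None = None
    gmt: str | Path | None = None
    background: str | Path | None = None
    ct_table: str | Path | None = None
    calibrator: str = "WT"
    contrasts: tuple[tuple[str, str, str], ...] = DEFAULT_CONTRASTS
    pathogenic_contrast: str = "wt_vs_path"
    criteria: DirectionalCriteria = field(default_factory=DirectionalCriteria)
    test_params: TestParams = field(default_factory=TestParams)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML or JSON key-value file."""
        with open(path) as fh:
            raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        if "criteria" in kwargs and isinstance(kwargs["criteria"], Mapping):
            kwargs["criteria"] = DirectionalCriteria(**kwargs["criteria"])
        if "test_params" in kwargs and isinstance(kwargs["test_params"], Mapping):
            kwargs["test_params"] = TestParams(**kwargs["test_params"])
        if "contrasts" in kwargs and kwargs["contrasts"] is not None:
            kwargs["contrasts"] = tuple(tuple(c) for c in kwargs["contrasts"])
        return cls(**kwargs)

    def validate(self) -> None:
        simulating = self.simulation is not None
        loading = self.counts is not None
        if simulating == loading:
            raise ValueError(
                "config must provide exactly one of a simulation block or a counts path"
            )
        if simulating and self.seed is None:
            raise ValueError("a seed is required when simulating; none was given")
        if loading:
            for name in ("counts", "sample_sheet", "lengths"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
        for opt in ("gmt", "background", "ct_table"):
            p = getattr(self, opt)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{opt} file not found: {p}")
        self.criteria.validate()
        self.test_params.validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and return the manifest (also written to
    ``outdir/manifest.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            "criteria": _jsonable(config.criteria),
            "test_params": _jsonable(config.test_params),
            "contrasts": _jsonable(config.contrasts),
            "pathogenic_contrast": config.pathogenic_contrast,
            "calibrator": config.calibrator,
        },
        "stages": [],
    }

    def relpath(p: Path) -> str:
        # paths are stored relative to outdir so reruns into a different
        # directory still produce byte-identical manifests
        try:
            return str(Path(p).relative_to(outdir))
        except ValueError:
            return str(p)

    def record(stage: str, outputs: dict[str, Path], **extra: Any) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {k: relpath(p) for k, p in outputs.items()},
                "sha256": {k: _sha256(p) for k, p in outputs.items()},
                **extra,
            }
        )

    t0 = time.perf_counter()

    # --- expression data -------------------------------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=int(config.seed))
        dataset = simulate_dataset(sim)
        paths = rsio.write_dataset(dataset, outdir / "simulated")
        record("simulate", paths, parameters=_jsonable(sim), n_genes=sim.n_genes)
        counts, sheet, lengths = dataset.counts, dataset.sample_sheet, dataset.lengths
    else:
        counts = rsio.read_counts_tsv(config.counts)
        sheet = rsio.read_sample_sheet(config.sample_sheet)
        lengths = rsio.read_lengths_tsv(config.lengths)
        inputs = {k: Path(getattr(config, k)) for k in ("counts", "sample_sheet", "lengths")}
        manifest["stages"].append(
            {
                "stage": "load",
                "inputs": {k: str(p) for k, p in inputs.items()},
                "sha256": {k: _sha256(p) for k, p in inputs.items()},
            }
        )
    log.info("expression data ready: %d genes x %d samples", *counts.shape)

    # --- quantify ---------------------------------------------------------
    fpkm = fpkm_matrix(counts, lengths)
    fpkm_path = outdir / "fpkm.tsv"
    rsio.write_fpkm_tsv(fpkm, fpkm_path)
    record("quantify", {"fpkm": fpkm_path}, total_mapped=fpkm.attrs["total_mapped"])

    # --- differential -----------------------------------------------------
    tables = {}
    de_counts = {}
    contrast_paths = {}
    for name, group_from, group_to in config.contrasts:
        table = test_contrast(fpkm, Contrast(name, group_from, group_to), sheet, config.test_params)
        tables[name] = table
        de_counts[name] = int((table["q"] < config.criteria.q_threshold).sum())
        path = outdir / f"contrast_{name}.tsv"
        rsio.write_contrast_tsv(table, path)
        contrast_paths[name] = path
        log.info("contrast %s: %d genes at q<%g", name, de_counts[name], config.criteria.q_threshold)
    record("differential", contrast_paths, de_genes=de_counts)

    # --- rescue screen ----------------------------------------------------
    reversal_names = [n for n, _, _ in config.contrasts if n != config.pathogenic_contrast]
    screen = apply_screen(
        tables,
        config.criteria,
        pathogenic=config.pathogenic_contrast,
        reversals=reversal_names,
    )
    calls_path = outdir / "rescue_calls.tsv"
    rsio.write_calls_tsv(screen.calls, calls_path)
    set_names = list(screen.contrast_sets)
    venn = venn_counts(
        *(screen.contrast_sets[n] for n in set_names[:3]),
        labels=tuple(set_names[:3]),
    )
    venn_path = outdir / "venn.tsv"
    rsio.write_venn_tsv(venn, venn_path)
    restored = sorted(screen.restored_genes)
    restored_path = outdir / "restored_genes.txt"
    restored_path.write_text("".join(g + "\n" for g in restored))
    record(
        "rescue",
        {"calls": calls_path, "venn": venn_path, "restored": restored_path},
        restored=len(restored),
        triple_overlap=venn.triple_overlap,
    )
    log.info("screen: %d restored genes, triple overlap %d", len(restored), venn.triple_overlap)

    # --- enrichment -------------------------------------------------------
    if config.gmt is None:
        manifest["stages"].append({"stage": "enrich", "skipped": "no annotation catalog"})
    elif not restored:
        manifest["stages"].append({"stage": "enrich", "skipped": "no restored genes"})
    else:
        background = rsio.read_gene_list(config.background) if config.background else None
        catalog = rsio.read_gmt(config.gmt, background=background)
        from rescuescreen.enrichment import enrich

        rows = enrich(restored, catalog)
        enrich_path = outdir / "enrichment.tsv"
        rsio.write_enrichment_tsv(rows, enrich_path)
        record("enrich", {"enrichment": enrich_path}, terms=len(rows))

    # --- qPCR -------------------------------------------------------------
    if config.ct_table is None:
        manifest["stages"].append({"stage": "qpcr", "skipped": "no Ct table"})
    else:
        records = rsio.read_ct_tsv(config.ct_table)
        summary = summarize_by_genotype(records, calibrator_role=config.calibrator)
        qpcr_path = outdir / "qpcr_summary.tsv"
        summary.to_csv(qpcr_path, sep="\t", float_format="%.10g")
        record("qpcr", {"summary": qpcr_path})

    # --- ordination -------------------------------------------------------
    ordination = pca_map(fpkm, pseudocount=config.test_params.pseudocount)
    coords_path = outdir / "pca_coordinates.tsv"
    rsio.write_coordinates_tsv(
        ordination.coordinates, sheet, ordination.explained_variance_ratio, coords_path
    )
    means = genotype_mean_coordinates(ordination, sheet)
    record(
        "report",
        {"coordinates": coords_path},
        explained_variance=[float(v) for v in ordination.explained_variance_ratio],
        genotype_means={g: [float(v) for v in row] for g, row in means.iterrows()},
    )

    log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
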