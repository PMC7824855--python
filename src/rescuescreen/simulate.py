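"""Seeded six-genotype count simulator with planted ground truth.

The simulator emulates a rescue-screen RNA-seq design: six genotype roles
(wild-type, a pathogenic mutant, two protective variants, and two
protective/pathogenic double-mutant "rescue" genotypes), each measured in a
small number of technical replicates. Counts are drawn from a
negative-binomial model with mean--dispersion parameterisation
``Var = mu + phi * mu**2``, which degenerates to Poisson at ``phi = 0``.

Each gene belongs to one of three planted effect classes:

``NULL``
    same expected expression in every role.
``RESTORED``
    shifted by ``direction * effect_log2fc`` (log2 units) in the pathogenic
    role only — wild-type, protective and rescue roles share the baseline,
    so the pathogenic alteration is "rescued".
``NOT_RESTORED``
    the pathogenic shift persists in the rescue roles (and optionally the
    protective roles), i.e. the double mutant fails to restore expression.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from ``SimulationConfig.seed``; identical configs produce bit-identical
datasets.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The six genotype roles of the screen design, in canonical order.
ROLES: tuple[str, ...] = (
    "WT",
    "PATHOGENIC",
    "PROTECTIVE_A",
    "PROTECTIVE_B",
    "RESCUE_A",
    "RESCUE_B",
)

#: Roles carrying the pathogenic allele without protection.
PATHOGENIC_ROLES: frozenset[str] = frozenset({"PATHOGENIC"})

#: Double-mutant roles (protective + pathogenic allele).
RESCUE_ROLES: frozenset[str] = frozenset({"RESCUE_A", "RESCUE_B"})

#: Protective-variant-only roles.
PROTECTIVE_ROLES: frozenset[str] = frozenset({"PROTECTIVE_A", "PROTECTIVE_B"})


class GeneClass(str, enum.Enum):
    """Planted per-gene effect class."""

    NULL = "NULL"
    RESTORED = "RESTORED"
    NOT_RESTORED = "NOT_RESTORED"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen dataset.

    Parameters
    ----------
    n_null, n_restored, n_not_restored
        Number of genes planted in each effect class.
    effect_log2fc
        Magnitude (log2 units, nonnegative) of the pathogenic shift for
        non-NULL genes. Each affected gene is assigned a random sign.
    n_replicates
        Technical replicates per genotype role (default 3).
    baseline_mean
        Median expected count of a gene at library size 1e6. Per-gene
        baselines are drawn lognormally around this value with natural-log
        sigma ``baseline_sigma`` to mimic the dynamic range of expression.
    baseline_sigma
        Spread (natural-log scale) of per-gene baseline means.
    dispersion
        Negative-binomial dispersion phi in ``Var = mu + phi mu^2``;
        ``0`` gives Poisson counts.
    library_sizes
        Per-sample library sizes (mapping sample id -> size, or a sequence
        in sample order). Defaults to 1e6 for every sample. Means scale
        multiplicatively with ``library_size / 1e6``.
    gene_length_bp
        Per-gene effective lengths. Defaults to lengths drawn uniformly in
        [500, 5000] bp.
    shift_protective
        If True, NOT_RESTORED genes are also shifted in the protective-only
        roles; by default the protective genotypes alone resemble wild-type.
    seed
        Seed of the single generator driving all randomness.
    """

    n_null: int = 2000
    n_restored: int = 100
    n_not_restored: int = 0
    effect_log2fc: float = 1.5
    n_replicates: int = 3
    baseline_mean: float = 200.0
    baseline_sigma: float = 1.0
    dispersion: float = 0.05
    library_sizes: Mapping[str, int] | Sequence[int] | None = None
    gene_length_bp: Sequence[int] | None = None
    shift_protective: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_null", "n_restored", "n_not_restored"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be nonnegative (sign is per-gene)")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.n_null + self.n_restored + self.n_not_restored


@dataclass
class SyntheticDataset:
    """A simulated screen dataset with its planted truth.

    Attributes
    ----------
    counts
        Genes x samples integer count matrix.
    sample_sheet
        Indexed by sample id; columns ``genotype`` and ``replicate``.
    truth
        Indexed by gene id; columns ``gene_class``, ``direction``,
        ``effect_log2fc``.
    lengths
        Per-gene effective length (bp).
    config
        The configuration the dataset was drawn from.
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame
    lengths: pd.Series
    config: SimulationConfig = field(repr=False)


def shifted_roles(gene_class: GeneClass, shift_protective: bool = False) -> frozenset[str]:
    """Roles in which a gene of the given class deviates from baseline."""
    if gene_class is GeneClass.NULL:
        return frozenset()
    if gene_class is GeneClass.RESTORED:
        return PATHOGENIC_ROLES
    roles = PATHOGENIC_ROLES | RESCUE_ROLES
    if shift_protective:
        roles = roles | PROTECTIVE_ROLES
    return roles


def expected_log2_shift(
    gene_class: GeneClass,
    direction: int,
    effect_log2fc: float,
    role: str,
    shift_protective: bool = False,
) -> float:
    """Generative log2 shift of a gene's mean in ``role`` relative to WT."""
    if role not in ROLES:
        raise ValueError(f"unknown genotype role {role!r}")
    if role in shifted_roles(gene_class, shift_protective):
        return direction * effect_log2fc
    return 0.0


def _sample_ids(n_replicates: int) -> list[str]:
    return [f"{role}_r{i}" for role in ROLES for i in range(1, n_replicates + 1)]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a seeded synthetic dataset from the screen's generative model.

    Counts for gene *g* in sample *s* are negative-binomial with mean

    ``mu_gs = baseline_g * (library_size_s / 1e6) * 2**shift(role_s, class_g)``

    and variance ``mu + phi mu^2``. The same seed always yields the same
    dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    samples = _sample_ids(config.n_replicates)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    classes = (
        [GeneClass.NULL] * config.n_null
        + [GeneClass.RESTORED] * config.n_restored
        + [GeneClass.NOT_RESTORED] * config.n_not_restored
    )
    directions = np.where(rng.random(n_genes) < 0.5, -1, 1)
    directions[np.array([c is GeneClass.NULL for c in classes], dtype=bool)] = 0
    effects = np.array(
        [0.0 if c is GeneClass.NULL else config.effect_log2fc for c in classes]
    )

    baselines = rng.lognormal(np.log(config.baseline_mean), config.baseline_sigma, n_genes)

    if config.gene_length_bp is not None:
        lengths = np.asarray(config.gene_length_bp, dtype=int)
        if lengths.shape != (n_genes,):
            raise ValueError(
                f"gene_length_bp must have length {n_genes}, got {lengths.shape}"
            )
    else:
        lengths = rng.integers(500, 5001, n_genes)
    if n_genes and (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")

    if config.library_sizes is None:
        lib = pd.Series(1_000_000, index=samples, dtype=float)
    elif isinstance(config.library_sizes, Mapping):
        lib = pd.Series(config.library_sizes, dtype=float).reindex(samples)
        if lib.isna().any():
            missing = lib.index[lib.isna()].tolist()
            raise ValueError(f"library_sizes missing samples: {missing}")
    else:
        sizes = list(config.library_sizes)
        if len(sizes) != len(samples):
            raise ValueError(
                f"library_sizes must have {len(samples)} entries, got {len(sizes)}"
            )
        lib = pd.Series(sizes, index=samples, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")

    role_of = {s: s.rsplit("_r", 1)[0] for s in samples}
    # per-gene log2 shift for each role, assembled once
    shift_by_role = {
        role: np.array(
            [
                expected_log2_shift(c, d, e, role, config.shift_protective)
                for c, d, e in zip(classes, directions, effects)
            ]
        )
        for role in ROLES
    }

    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = baselines * (lib[s] / 1e6) * np.exp2(shift_by_role[role_of[s]])
        if config.dispersion == 0 or n_genes == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            size = 1.0 / config.dispersion
            p = size / (size + mu)
            counts[:, j] = rng.negative_binomial(size, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    sheet = pd.DataFrame(
        {
            "genotype": [role_of[s] for s in samples],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = pd.DataFrame(
        {
            "gene_class": [c.value for c in classes],
            "direction": directions,
            "effect_log2fc": effects,
        },
        index=counts_df.index,
    )
    lengths_s = pd.Series(lengths, index=counts_df.index, name="effective_length_bp")
    return SyntheticDataset(
        counts=counts_df,
        sample_sheet=sheet,
        truth=truth,
        lengths=lengths_s,
        config=dataclasses.replace(config),
    )
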