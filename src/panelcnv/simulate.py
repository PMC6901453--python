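"""Seeded synthetic capture-panel generator with known deletion truth.

Counts follow the same conditional model the caller assumes: each target
carries a log-normal capture propensity, each sample a log-normal library
size, and target counts are beta-binomial draws
``k_ij ~ BetaBinomial(N_j, q_i * c_ij, rho)`` with ``c_ij`` the copy ratio
inside an injected deletion (1 elsewhere) and propensities renormalized per
sample. This keeps the generator exactly inside the caller's likelihood so
simulation checks probe the calling logic, not a model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, PanelError, SampleMeta, TargetRegion, TargetSet

__all__ = [
    "DeletionSpec",
    "SimulationConfig",
    "TruthSet",
    "simulate_panel",
    "inject_deletion",
]


@dataclass(frozen=True)
class DeletionSpec:
    """An injected deletion: a run of ordinals within one gene of one sample."""

    sample_id: str
    gene: str
    first_ordinal: int
    last_ordinal: int
    copy_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.copy_ratio <= 1.5):
            raise PanelError("copy ratio must be in [0, 1.5]")
        if self.first_ordinal > self.last_ordinal or self.first_ordinal < 1:
            raise PanelError("bad ordinal span")

    @property
    def zygosity(self) -> str:
        return "homozygous" if self.copy_ratio < 0.05 else "heterozygous"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated panel run.

    Defaults mirror the data regime the caller targets: ten controls,
    ~500 reads per target, modest library-size variation (CV 0.2) and
    log-normal capture propensities (sigma 0.5). The default panel size,
    2000 targets, is the scale of a comprehensive disease-gene capture
    design (~140 genes with promoters, exons with flanks, and UTRs). rho
    is the intraclass correlation of the beta-binomial, whose
    between-sample coverage-ratio CV at a target is ~sqrt(rho/p); the
    default 3e-6 yields a ratio CV near 8% on the default panel, typical
    of replicate capture libraries.
    """

    n_targets: int = 2000
    n_controls: int = 10
    n_tests: int = 1
    mean_depth: float = 500.0
    library_cv: float = 0.2
    propensity_sigma: float = 0.5
    rho: float = 3e-6
    deletions: tuple[DeletionSpec, ...] = ()
    female_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.n_controls < 1 or self.n_tests < 0:
            raise PanelError("sizes must be positive")
        if self.mean_depth <= 0 or self.library_cv < 0 or self.propensity_sigma < 0:
            raise PanelError("depth/cv/sigma must be non-negative")
        if not (0 <= self.rho < 1):
            raise PanelError("rho must be in [0, 1)")


@dataclass(frozen=True)
class TruthSet:
    deletions: tuple[DeletionSpec, ...]

    def for_sample(self, sample_id: str) -> list[DeletionSpec]:
        return [d for d in self.deletions if d.sample_id == sample_id]


def _make_targets(n_targets: int, rng: np.random.Generator) -> TargetSet:
    """Gene-structured panel: genes of 4-10 regions (promoter then exons),
    plausible lengths >= 60 bp so single-target calls clear the 50 bp rule."""
    regions: list[TargetRegion] = []
    gene_no, made, pos, chrom_no = 0, 0, 10_000, 1
    while made < n_targets:
        gene_no += 1
        gene = f"GENE{gene_no:03d}"
        n_regions = min(int(rng.integers(4, 11)), n_targets - made)
        chrom = f"chr{chrom_no}"
        chrom_no = chrom_no % 20 + 1 if gene_no % 8 == 0 else chrom_no
        for k in range(n_regions):
            label = "promoter" if k == 0 else f"exon{k}"
            length = int(rng.integers(60, 301))
            regions.append(TargetRegion(chrom, pos, pos + length, gene, label))
            pos += length + int(rng.integers(200, 2000))
        pos += 50_000
        made += n_regions
    return TargetSet(regions)


def _betabinom_draw(
    rng: np.random.Generator, n: int, p: np.ndarray, rho: float
) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    if rho < 1e-8:
        return rng.binomial(n, p)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return rng.binomial(n, rng.beta(a, b))


def simulate_panel(config: SimulationConfig) -> tuple[TargetSet, CountMatrix, TruthSet]:
    """Generate (targets, counts, truth) reproducibly from ``config.seed``.

    Deletions are applied in propensity space: copy ratios scale the
    affected targets' propensities before per-sample renormalization, so an
    injected ratio is recovered (up to sampling noise) as the observed
    coverage ratio against unaffected controls.
    """
    rng = np.random.default_rng(config.seed)
    targets = _make_targets(config.n_targets, rng)
    n = len(targets)
    q = rng.lognormal(0.0, config.propensity_sigma, size=n) if config.propensity_sigma > 0 \
        else np.ones(n)
    q = q / q.sum()

    sample_ids = [f"C{i + 1:02d}" for i in range(config.n_controls)] + \
                 [f"T{i + 1:02d}" for i in range(config.n_tests)]
    roles = ["control"] * config.n_controls + ["test"] * config.n_tests
    sexes = [
        "female" if rng.random() < config.female_fraction else "male"
        for _ in sample_ids
    ]
    samples = [SampleMeta(s, x, r) for s, x, r in zip(sample_ids, sexes, roles)]

    # validate deletion specs against the generated panel
    gene_sizes = {g: len(targets.gene_indices(g)) for g in targets.genes}
    for d in config.deletions:
        if d.gene not in gene_sizes or d.last_ordinal > gene_sizes[d.gene]:
            raise PanelError(f"deletion span {d.gene}:{d.first_ordinal}-{d.last_ordinal} "
                             "outside the generated panel")
        if d.sample_id not in sample_ids:
            raise PanelError(f"deletion sample {d.sample_id} not simulated")

    mean_library = config.mean_depth * n
    if config.library_cv > 0:
        sigma = np.sqrt(np.log1p(config.library_cv**2))
        mu = np.log(mean_library) - sigma**2 / 2
        libraries = rng.lognormal(mu, sigma, size=len(sample_ids))
    else:
        libraries = np.full(len(sample_ids), mean_library)

    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        c = np.ones(n)
        for d in config.deletions:
            if d.sample_id == sid:
                idx = targets.gene_indices(d.gene)[d.first_ordinal - 1:d.last_ordinal]
                c[idx] = d.copy_ratio
        qj = q * c
        qj = qj / qj.sum()
        counts[:, j] = _betabinom_draw(rng, int(round(libraries[j])), qj, config.rho)

    frame = pd.DataFrame(counts, index=targets.names, columns=sample_ids)
    return targets, CountMatrix(targets, samples, frame), TruthSet(config.deletions)


def inject_deletion(
    matrix: CountMatrix,
    sample_id: str,
    gene: str,
    first_ordinal: int,
    last_ordinal: int,
    copy_ratio: float,
    seed: int,
) -> CountMatrix:
    """Post-hoc deletion by binomial thinning of existing counts.

    Unlike propensity-space injection this leaves off-span counts untouched
    (no renormalization), which is useful for robustness checks. A copy
    ratio of 1 is the identity; 0 zeroes the span exactly.
    """
    if not (0.0 <= copy_ratio <= 1.5):
        raise PanelError("copy ratio must be in [0, 1.5]")
    if gene not in matrix.targets.genes:
        raise PanelError(f"unknown gene {gene}")
    idx = matrix.targets.gene_indices(gene)
    if last_ordinal > len(idx) or first_ordinal < 1 or first_ordinal > last_ordinal:
        raise PanelError("ordinal span outside gene")
    span = idx[first_ordinal - 1:last_ordinal]
    if copy_ratio == 1.0:
        return matrix
    counts = matrix.counts.copy()
    col = counts[sample_id].to_numpy().copy()
    if copy_ratio == 0.0:
        col[span] = 0
    elif copy_ratio < 1.0:
        rng = np.random.default_rng(seed)
        col[span] = rng.binomial(col[span], copy_ratio)
    else:  # gain: add binomial extra mass
        rng = np.random.default_rng(seed)
        col[span] = col[span] + rng.binomial(col[span], copy_ratio - 1.0)
    counts[sample_id] = col
    return matrix.with_counts(counts)
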