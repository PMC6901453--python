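"""Shared fixtures: small hand-built panels, count matrices and fits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panelcnv.caller import CallerConfig, RatioProfile
from panelcnv.core import CountMatrix, SampleMeta, TargetRegion, TargetSet
from panelcnv.dispersion import DispersionFit


@pytest.fixture
def toy_targets() -> TargetSet:
    """Two genes, 5 + 3 targets, 300 bp each, one chromosome."""
    regions = []
    pos = 1000
    for gene, labels in [
        ("RPS19", ["promoter", "exon1", "exon2", "exon3", "exon4"]),
        ("RPL5", ["promoter", "exon1", "exon2"]),
    ]:
        for lab in labels:
            regions.append(TargetRegion("chr19", pos, pos + 300, gene, lab))
            pos += 1000
    return TargetSet(regions)


def make_matrix(targets: TargetSet, counts: np.ndarray, n_controls: int = 10,
                test_ids: tuple[str, ...] = ("TEST",)) -> CountMatrix:
    """Counts is (targets, n_controls + len(test_ids)); controls first."""
    ids = [f"C{i:02d}" for i in range(n_controls)] + list(test_ids)
    metas = [SampleMeta(i, "male", "control") for i in ids[:n_controls]] + [
        SampleMeta(i, "male", "test") for i in ids[n_controls:]
    ]
    frame = pd.DataFrame(counts, index=targets.names, columns=ids)
    return CountMatrix(targets, metas, frame)


@pytest.fixture
def flat_matrix(toy_targets) -> CountMatrix:
    """Uniform counts of 1000 everywhere, 10 controls + 1 test."""
    counts = np.full((len(toy_targets), 11), 1000, dtype=int)
    return make_matrix(toy_targets, counts)


def make_fit(n_targets: int, p: np.ndarray | None = None,
             rho: float | np.ndarray = 1e-4, n_controls: int = 10) -> DispersionFit:
    """Directly-constructed fit for caller-level tests."""
    if p is None:
        p = np.full(n_targets, 1.0 / n_targets)
    rho_arr = np.full(n_targets, rho, dtype=float) if np.isscalar(rho) else np.asarray(rho)
    return DispersionFit(
        p=np.asarray(p, dtype=float),
        rho=rho_arr,
        rho_raw=rho_arr.copy(),
        rho_global=float(np.median(rho_arr)),
        low_coverage=np.zeros(n_targets, dtype=bool),
        n_controls=n_controls,
    )


def make_profile(ratios: np.ndarray, config: CallerConfig | None = None,
                 sd: float = 0.1, usable: np.ndarray | None = None) -> RatioProfile:
    """RatioProfile from a (targets, 3) ratio array (or (targets,) applied
    to all three comparisons)."""
    config = config or CallerConfig()
    r = np.asarray(ratios, dtype=float)
    if r.ndim == 1:
        r = np.repeat(r[:, None], 3, axis=1)
    n = r.shape[0]
    return RatioProfile(
        ratios=r,
        usable=np.ones(n, dtype=bool) if usable is None else usable,
        het_flags=r <= config.t_het,
        hom_flags=r < config.t_hom,
        log2_mean_ratio=np.log2(np.maximum(r[:, 0], 1e-8)),
        emission_sd=np.full(n, sd),
    )
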