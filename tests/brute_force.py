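"""Independent span-enumeration caller used as an oracle.

Classifies every usable target directly from its three ratios (homozygous
if all < t_hom, heterozygous if all <= t_het, else normal), takes maximal
per-gene runs of equal class over usable targets, and applies the filter
cascade span by span — no HMM, no Viterbi. On panels whose ratios are
well separated this must agree exactly with the pipeline.
"""

from __future__ import annotations

import numpy as np

from panelcnv.caller import CallerConfig, RatioProfile, classify_zygosity
from panelcnv.core import TargetSet
from panelcnv.dispersion import DispersionFit


def brute_force_calls(
    profile: RatioProfile,
    targets: TargetSet,
    fit: DispersionFit,
    within_fraction: float,
    config: CallerConfig,
) -> list[tuple[str, int, int, str]]:
    """Return (gene, first_index, last_index, zygosity) for every span that
    survives the filters, enumerated without segmentation machinery."""
    r = profile.ratios
    hom = (r < config.t_hom).all(axis=1)
    het = (r <= config.t_het).all(axis=1) & ~hom
    cls = np.where(hom, 2, np.where(het, 1, 0))

    runs: list[tuple[str, list[int], int]] = []
    for gene in targets.genes:
        idx = [i for i in targets.gene_indices(gene) if profile.usable[i]]
        start = 0
        for k in range(1, len(idx) + 1):
            if k == len(idx) or cls[idx[k]] != cls[idx[start]]:
                runs.append((gene, idx[start:k], int(cls[idx[start]])))
                start = k

    n_usable = int(profile.usable.sum())
    n_cnv = sum(len(ix) for _, ix, c in runs if c != 0)
    if n_usable == 0 or n_cnv / n_usable > config.max_cnv_fraction:
        return []
    if within_fraction < config.min_within_fraction:
        return []

    calls = []
    for gene, ix, c in runs:
        if c == 0:
            continue
        ranges = {
            comp: (float(r[ix, k].min()), float(r[ix, k].max()))
            for k, comp in enumerate(("mean", "median", "closest"))
        }
        zyg = classify_zygosity(ranges, config)
        if zyg == "none":
            continue
        span = targets[ix[-1]].end - targets[ix[0]].start
        if span < config.min_length_bp:
            continue
        if fit.rho[ix].max() > config.max_dispersion:
            continue
        calls.append((gene, ix[0], ix[-1], zyg))
    return calls
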