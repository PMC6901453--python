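"""Bundled reference data: the ten validated deletions of the method's
clinical validation cohort, as published ratio and dispersion ranges.

These ranges are the printed per-call summaries (min-max normalized
coverage ratio over the deleted span, applied identically under all three
comparisons) and serve as a worked example for the zygosity rules: nine
heterozygous calls with ratio minima 0.20-0.32 and one homozygous call at
0.002-0.004. The cohort they came from comprised 165 analyzed samples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_validated_deletion_ranges", "COHORT_N_ANALYZED"]

# samples analyzed for CNVs in the validation cohort (point-variant negative)
COHORT_N_ANALYZED = 165


def load_validated_deletion_ranges() -> pd.DataFrame:
    """Ratio/dispersion ranges of the ten validated deletion calls.

    Columns: patient, gene, reported_zygosity, region, ratio_min,
    ratio_max, dispersion_min, dispersion_max.
    """
    with resources.files("panelcnv.data").joinpath(
        "validated_deletion_ranges.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
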