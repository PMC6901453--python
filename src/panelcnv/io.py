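"""Readers and writers for the formats the caller touches.

Targets come in as 4+ column BED with the name field encoding "gene|label";
counts as TSV (targets x samples); per-base depth in the three-column
samtools-depth dialect; calls go out as BED, VCF 4.2 (symbolic <DEL>) or a
TSV mirroring the per-call report layout (gene, zygosity, region span as
"firstLabel-lastLabel", ratio range, dispersion range).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, PanelError, SampleMeta, TargetRegion, TargetSet

if TYPE_CHECKING:  # pragma: no cover
    from .caller import CNVCall

logger = logging.getLogger(__name__)

__all__ = [
    "read_targets",
    "read_meta",
    "read_count_matrix",
    "write_count_matrix",
    "aggregate_depth",
    "write_calls",
]


def read_targets(path: str | Path) -> TargetSet:
    """Parse a BED file of panel targets into a validated :class:`TargetSet`.

    Requires >= 4 columns (chrom, start, end, name) with name "gene|label".
    Input order is irrelevant; the returned set is sorted by (chrom, start)
    with per-gene ordinals assigned along genomic order.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: non-integer coordinates") from exc
            if "|" in name:
                gene, label = name.split("|", 1)
            else:
                gene, label = name, "region"
            try:
                regions.append(TargetRegion(chrom, start, end, gene, label))
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
    return TargetSet(regions)


def read_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV with columns sample_id, sex, role."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex", "role"}
    if not required.issubset(df.columns):
        raise PanelError(f"metadata must have columns {sorted(required)}")
    return [
        SampleMeta(row.sample_id, row.sex, row.role)
        for row in df.itertuples(index=False)
    ]


def read_count_matrix(
    path: str | Path, targets: TargetSet, meta: Sequence[SampleMeta]
) -> CountMatrix:
    """Read a targets-x-samples count TSV against a known panel.

    Rows are keyed either by a ``target`` column holding "gene|label" names
    or by (chrom, start, end) columns. Every (target, sample) cell must be
    a non-negative integer; every TSV sample must appear in ``meta``.
    """
    df = pd.read_csv(path, sep="\t")
    if "target" in df.columns:
        df = df.set_index("target")
        df = df.drop(columns=[c for c in ("chrom", "start", "end") if c in df.columns])
    elif {"chrom", "start", "end"}.issubset(df.columns):
        key = df["chrom"].astype(str) + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)
        coord_to_name = {f"{r.chrom}:{r.start}-{r.end}": r.name for r in targets}
        unknown = [k for k in key if k not in coord_to_name]
        if unknown:
            raise PanelError(f"count rows not in target set: {unknown[:3]}")
        df.index = [coord_to_name[k] for k in key]
        df = df.drop(columns=["chrom", "start", "end"])
    else:
        raise PanelError("count TSV needs a 'target' column or chrom/start/end columns")
    if df.shape[0] != len(targets):
        raise PanelError(f"count TSV has {df.shape[0]} rows, panel has {len(targets)} targets")
    if df.isna().any().any():
        raise PanelError("count TSV has missing cells")
    known = {m.sample_id for m in meta}
    missing_meta = [c for c in df.columns if c not in known]
    if missing_meta:
        raise PanelError(f"samples missing from metadata: {missing_meta}")
    samples = [m for m in meta if m.sample_id in df.columns]
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.all(np.mod(arr, 1) == 0):
        raise PanelError("count TSV cells must be integers")
    if (arr < 0).any():
        raise PanelError("count TSV cells must be non-negative")
    return CountMatrix(targets, samples, df.astype(np.int64))


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "target"
    out.to_csv(path, sep="\t")


def aggregate_depth(path: str | Path, targets: TargetSet) -> np.ndarray:
    """Sum per-base depth (samtools-depth TSV: chrom, 1-based pos, depth)
    onto the panel targets for one sample.

    A 1-based position p falls in 0-based half-open target [start, end)
    iff start < p <= end. Positions outside all targets are ignored and
    summarised in a log line.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"],
                     dtype={"chrom": str, "pos": np.int64, "depth": np.int64})
    out = np.zeros(len(targets), dtype=np.int64)
    if df.empty:
        return out
    off_target = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        depth = sub["depth"].to_numpy()
        assigned = np.zeros(len(pos), dtype=bool)
        for i, r in enumerate(targets):
            if r.chrom != chrom:
                continue
            mask = (pos > r.start) & (pos <= r.end)
            out[i] += int(depth[mask].sum())
            assigned |= mask
        off_target += int((~assigned).sum())
    if off_target:
        logger.info(
            "aggregate_depth: %d of %d depth rows off-target (%.1f%%)",
            off_target, len(df), 100.0 * off_target / len(df),
        )
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##ALT=<ID=DEL,Description="Deletion">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=RATIO_MIN,Number=1,Type=Float,Description="Minimum normalized coverage ratio across span and comparisons">
##INFO=<ID=RATIO_MAX,Number=1,Type=Float,Description="Maximum normalized coverage ratio across span and comparisons">
##INFO=<ID=DISP_MIN,Number=1,Type=Float,Description="Minimum fitted beta-binomial dispersion over span">
##INFO=<ID=DISP_MAX,Number=1,Type=Float,Description="Maximum fitted beta-binomial dispersion over span">
##INFO=<ID=N_TARGETS,Number=1,Type=Integer,Description="Number of panel targets in the call">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_calls(
    calls: Sequence["CNVCall"],
    targets: TargetSet,
    fmt: str,
    path: str | Path,
    sample_id: str = "SAMPLE",
) -> None:
    """Serialize deletion calls as BED, VCF 4.2 or report TSV.

    BED spans stay 0-based half-open with name "gene:zygosity" and score
    round(1000*(1-min ratio)); VCF uses 1-based POS, symbolic <DEL> and
    GT 0/1 (het) or 1/1 (hom). The TSV mirrors the per-call report: gene,
    zygosity, region as "firstLabel-lastLabel", ratio range, dispersion
    range.
    """
    fmt = fmt.upper()
    if fmt not in ("BED", "VCF", "TSV"):
        raise PanelError(f"unknown call format {fmt!r} (use BED, VCF or TSV)")
    lines: list[str] = []
    if fmt == "BED":
        for c in calls:
            score = int(round(1000 * (1 - c.ratio_min)))
            lines.append(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.gene}:{c.zygosity}\t{score}\t."
            )
        text = "\n".join(lines) + ("\n" if lines else "")
    elif fmt == "VCF":
        body = []
        for c in calls:
            gt = "1/1" if c.zygosity == "homozygous" else "0/1"
            info = (
                f"END={c.end};SVTYPE=DEL;GENE={c.gene};"
                f"RATIO_MIN={c.ratio_min:.4g};RATIO_MAX={c.ratio_max:.4g};"
                f"DISP_MIN={c.disp_min:.4g};DISP_MAX={c.disp_max:.4g};"
                f"N_TARGETS={c.n_targets}"
            )
            body.append(
                f"{c.chrom}\t{c.start + 1}\t.\tN\t<DEL>\t.\tPASS\t{info}\tGT\t{gt}"
            )
        text = _VCF_HEADER.format(sample=sample_id) + "\n".join(body) + ("\n" if body else "")
    else:
        header = "gene\tzygosity\tregion\tratio_min\tratio_max\tdispersion_min\tdispersion_max\tn_targets\tchrom\tstart\tend"
        for c in calls:
            lines.append(
                f"{c.gene}\t{c.zygosity}\t{c.region_label}\t"
                f"{c.ratio_min:.4f}\t{c.ratio_max:.4f}\t"
                f"{c.disp_min:.4g}\t{c.disp_max:.4g}\t{c.n_targets}\t"
                f"{c.chrom}\t{c.start}\t{c.end}"
            )
        text = header + "\n" + "\n".join(lines) + ("\n" if lines else "")
    Path(path).write_text(text)
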