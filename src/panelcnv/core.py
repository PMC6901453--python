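"""Core domain types: panel targets, sample metadata, and the count matrix.

Coordinates are BED-style 0-based half-open everywhere in memory; conversion
to 1-based happens only at VCF serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetRegion",
    "TargetSet",
    "SampleMeta",
    "CountMatrix",
    "PanelError",
]


class PanelError(ValueError):
    """Raised for malformed panel definitions or inconsistent inputs."""


@dataclass(frozen=True, order=True)
class TargetRegion:
    """One captured interval of the panel (promoter, exon with flanks, UTR).

    ``ordinal`` is the 1-based rank of the region within its gene along
    genomic order; it is assigned by :class:`TargetSet`, not by the caller.
    """

    chrom: str
    start: int
    end: int
    gene: str
    label: str
    ordinal: int = 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise PanelError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                f"({self.gene}|{self.label}): require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.gene}|{self.label}"


class TargetSet:
    """Ordered, non-overlapping panel regions with a per-gene index.

    Regions are sorted by (chrom, start); ordinals are assigned per gene in
    genomic order so every region is addressable both by genomic position
    and by (gene, ordinal).
    """

    def __init__(self, regions: Iterable[TargetRegion]):
        raw = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
        if not raw:
            raise PanelError("empty target set")
        # detect overlaps on the same chromosome
        for a, b in zip(raw, raw[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise PanelError(
                    f"overlapping targets {a.chrom}:{a.start}-{a.end} and "
                    f"{b.chrom}:{b.start}-{b.end}"
                )
        # assign ordinals per gene by genomic order
        counters: dict[str, int] = {}
        fixed: list[TargetRegion] = []
        for r in raw:
            counters[r.gene] = counters.get(r.gene, 0) + 1
            fixed.append(
                TargetRegion(r.chrom, r.start, r.end, r.gene, r.label, counters[r.gene])
            )
        self.regions: tuple[TargetRegion, ...] = tuple(fixed)
        self._gene_index: dict[str, list[int]] = {}
        for i, r in enumerate(self.regions):
            self._gene_index.setdefault(r.gene, []).append(i)
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            dup = pd.Series(names).value_counts()
            raise PanelError(f"duplicate target names: {dup[dup > 1].index.tolist()}")
        self._names = names
        self._name_to_idx = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> TargetRegion:
        return self.regions[i]

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def genes(self) -> list[str]:
        """Genes in order of first genomic appearance."""
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.gene, None)
        return list(seen)

    def gene_indices(self, gene: str) -> list[int]:
        """Row indices of a gene's regions, in ordinal order."""
        return list(self._gene_index[gene])

    def index_of(self, name: str) -> int:
        return self._name_to_idx[name]

    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.regions], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "gene": [r.gene for r in self.regions],
                "label": [r.label for r in self.regions],
                "ordinal": [r.ordinal for r in self.regions],
            }
        )


Sex = Literal["male", "female", "unknown"]
Role = Literal["test", "control"]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    sex: Sex = "unknown"
    role: Role = "control"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise PanelError(f"sample {self.sample_id}: bad sex {self.sex!r}")
        if self.role not in ("test", "control"):
            raise PanelError(f"sample {self.sample_id}: bad role {self.role!r}")


class CountMatrix:
    """Raw read counts, targets x samples, with sample metadata.

    ``counts`` is an integer DataFrame indexed by target name ("gene|label")
    with one column per sample id.
    """

    def __init__(
        self,
        targets: TargetSet,
        samples: Sequence[SampleMeta],
        counts: pd.DataFrame,
    ):
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate sample ids")
        if list(counts.columns) != ids:
            counts = counts.loc[:, ids]
        if counts.shape[0] != len(targets):
            raise PanelError(
                f"count rows ({counts.shape[0]}) != targets ({len(targets)})"
            )
        expected_index = targets.names
        if list(counts.index) != expected_index:
            try:
                counts = counts.loc[expected_index]
            except KeyError as exc:
                raise PanelError(f"count rows do not match targets: {exc}") from exc
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise PanelError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise PanelError("counts must be non-negative")
        self.targets = targets
        self.samples = list(samples)
        self.counts = counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[sample_id].to_numpy()

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def with_counts(self, counts: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(self.targets, self.samples, counts)
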