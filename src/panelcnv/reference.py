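"""Library-size normalization and construction of the three control baselines.

A test sample is compared to (1) the mean of its ten sex-matched controls,
(2) their median, and (3) the single control whose normalized profile is
closest to the test. "Closest" is the control minimizing the median absolute
log2 ratio over targets (pseudocounted), a metric deliberately robust to the
few-target deletions the caller is looking for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CountMatrix, PanelError, SampleMeta, TargetSet

__all__ = [
    "SampleProfile",
    "ReferenceSet",
    "BaselineTriple",
    "normalize_counts",
    "select_controls",
    "closest_control",
    "build_baselines",
    "profile_distance",
]

DEFAULT_LIBRARY_CONSTANT = 1e6
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_N_CONTROLS = 10


@dataclass(frozen=True)
class SampleProfile:
    """One sample's normalized per-target coverage.

    ``coverage`` sums to the common library constant, making samples
    directly comparable target-by-target.
    """

    sample_id: str
    scale_factor: float
    coverage: np.ndarray
    raw_counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise PanelError(f"{self.sample_id}: scale factor must be positive")
        if (self.coverage < 0).any():
            raise PanelError(f"{self.sample_id}: negative normalized coverage")


@dataclass(frozen=True)
class ReferenceSet:
    controls: tuple[SampleProfile, ...]
    sex_matched: bool
    n_controls: int = DEFAULT_N_CONTROLS

    def __post_init__(self) -> None:
        if len(self.controls) != self.n_controls:
            raise PanelError(
                f"reference has {len(self.controls)} controls, expected {self.n_controls}"
            )
        ids = [c.sample_id for c in self.controls]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate control ids in reference")

    @property
    def ids(self) -> list[str]:
        return [c.sample_id for c in self.controls]

    def coverage_matrix(self) -> np.ndarray:
        """targets x controls normalized coverage."""
        return np.column_stack([c.coverage for c in self.controls])

    def raw_matrix(self) -> np.ndarray:
        return np.column_stack([c.raw_counts for c in self.controls])

    def totals(self) -> np.ndarray:
        return np.array([c.total for c in self.controls], dtype=np.int64)


@dataclass(frozen=True)
class BaselineTriple:
    """Per-target mean, median and closest-control baselines."""

    mean: np.ndarray
    median: np.ndarray
    closest: np.ndarray
    closest_id: str


def normalize_counts(
    matrix: CountMatrix, library_constant: float = DEFAULT_LIBRARY_CONSTANT
) -> dict[str, SampleProfile]:
    """Rescale each sample's counts so its per-target coverage sums to
    ``library_constant``; multiplying a sample's raw counts by any positive
    constant therefore leaves its profile unchanged."""
    totals = matrix.totals()
    zero = totals[totals == 0]
    if len(zero):
        raise PanelError(f"samples with zero total count: {list(zero.index)}")
    profiles = {}
    for sid in matrix.sample_ids:
        total = int(totals[sid])
        scale = library_constant / total
        raw = matrix.column(sid)
        profiles[sid] = SampleProfile(
            sample_id=sid,
            scale_factor=scale,
            coverage=raw * scale,
            raw_counts=raw,
            total=total,
        )
    return profiles


def select_controls(
    profiles: dict[str, SampleProfile],
    metas: dict[str, SampleMeta],
    test: SampleMeta,
    n_controls: int = DEFAULT_N_CONTROLS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ReferenceSet:
    """Pick the ``n_controls`` sex-matched candidates most similar to the test.

    If the test's sex is unknown, all candidates are eligible and the
    reference is flagged not sex-matched (downstream masks sex chromosomes).
    Ties in similarity break lexicographically by sample id so runs are
    reproducible.
    """
    candidates = [
        m for sid, m in metas.items()
        if sid != test.sample_id and m.role == "control"
    ]
    if test.sex in ("male", "female"):
        eligible = [m for m in candidates if m.sex == test.sex]
        sex_matched = True
    else:
        eligible = candidates
        sex_matched = False
    if len(eligible) < n_controls:
        raise PanelError(
            f"only {len(eligible)} eligible controls for {test.sample_id}, "
            f"need {n_controls}"
        )
    test_profile = profiles[test.sample_id]
    ranked = sorted(
        eligible,
        key=lambda m: (
            profile_distance(test_profile, profiles[m.sample_id], pseudocount),
            m.sample_id,
        ),
    )
    chosen = tuple(profiles[m.sample_id] for m in ranked[:n_controls])
    return ReferenceSet(controls=chosen, sex_matched=sex_matched, n_controls=n_controls)


def profile_distance(
    a: SampleProfile, b: SampleProfile, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Median over targets of |log2((a+c)/(b+c))| on normalized coverage.

    The median makes the metric insensitive to a deletion spanning a small
    fraction of targets, so a true deletion carrier still finds honest
    closest controls.
    """
    la = np.log2(a.coverage + pseudocount)
    lb = np.log2(b.coverage + pseudocount)
    return float(np.median(np.abs(la - lb)))


def closest_control(
    test: SampleProfile,
    reference: ReferenceSet,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> str:
    """Id of the reference control closest to the test; lexicographic
    tie-break."""
    best = min(
        reference.controls,
        key=lambda c: (profile_distance(test, c, pseudocount), c.sample_id),
    )
    return best.sample_id


def build_baselines(
    test: SampleProfile,
    reference: ReferenceSet,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> BaselineTriple:
    """Per-target mean / median / closest-control baselines.

    The median of an even number of controls is the average of the two
    central order statistics.
    """
    cov = reference.coverage_matrix()
    closest_id = closest_control(test, reference, pseudocount)
    closest = next(
        c.coverage for c in reference.controls if c.sample_id == closest_id
    )
    return BaselineTriple(
        mean=cov.mean(axis=1),
        median=np.median(cov, axis=1),
        closest=closest.copy(),
        closest_id=closest_id,
    )
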