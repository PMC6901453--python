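"""Ratio computation, HMM segmentation, zygosity rules and the filter
cascade."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from panelcnv.caller import (
    CallerConfig,
    QCReport,
    STATES,
    apply_call_filters,
    call_cnvs,
    classify_zygosity,
    coverage_ratios,
    segment_hmm,
    _hmm_params,
    _state_means,
    _viterbi,
)
from panelcnv.core import PanelError, TargetRegion, TargetSet
from panelcnv.io import write_calls
from panelcnv.reference import BaselineTriple, normalize_counts, select_controls, build_baselines
from panelcnv.dispersion import fit_beta_binomial, within_interval_fraction
from panelcnv.simulate import DeletionSpec, SimulationConfig, simulate_panel

from brute_force import brute_force_calls
from conftest import make_fit, make_matrix, make_profile


def uniform_targets(n: int, gene_size: int = 10, length: int = 100,
                    lengths: list[int] | None = None) -> TargetSet:
    regions = []
    pos = 1000
    for i in range(n):
        gene = f"G{i // gene_size:02d}"
        k = i % gene_size
        label = "promoter" if k == 0 else f"exon{k}"
        L = lengths[i] if lengths else length
        regions.append(TargetRegion("chr1", pos, pos + L, gene, label))
        pos += L + 500
    return TargetSet(regions)


class TestClassifyZygosity:
    @pytest.mark.parametrize("rng,expected", [
        ((0.32, 0.38), "heterozygous"),
        ((0.28, 0.40), "heterozygous"),   # min below threshold suffices
        ((0.27, 0.33), "heterozygous"),
        ((0.20, 0.35), "heterozygous"),
        ((0.002, 0.004), "homozygous"),
        ((0.40, 0.55), "none"),
        ((0.049, 0.049), "homozygous"),
        ((0.05, 0.05), "heterozygous"),   # hom bound is strict
        ((0.33, 0.50), "heterozygous"),   # het bound is inclusive
        ((0.331, 0.50), "none"),
    ])
    def test_range_rules(self, rng, expected):
        assert classify_zygosity(rng) == expected

    def test_consensus_requires_all_three(self):
        ranges = {"mean": (0.30, 0.32), "median": (0.30, 0.32), "closest": (0.45, 0.5)}
        assert classify_zygosity(ranges) == "none"

    def test_mixed_hom_het_comparisons_fall_back_to_het(self):
        ranges = {"mean": (0.002, 0.004), "median": (0.002, 0.004), "closest": (0.06, 0.06)}
        assert classify_zygosity(ranges) == "heterozygous"

    def test_removing_a_comparison_never_shrinks_the_call_set(self):
        """Consensus is an intersection: any 2-comparison subset classifies
        at least everything the full triple classifies."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            lows = rng.uniform(0, 1.2, size=3)
            highs = lows + rng.uniform(0, 0.4, size=3)
            ranges = dict(zip(("mean", "median", "closest"), zip(lows, highs)))
            full = classify_zygosity(ranges)
            for drop in ranges:
                sub = {k: v for k, v in ranges.items() if k != drop}
                if full != "none":
                    assert classify_zygosity(sub) != "none"

    def test_empty_or_inverted_range_rejected(self):
        with pytest.raises(PanelError):
            classify_zygosity({})
        with pytest.raises(PanelError):
            classify_zygosity((0.5, 0.3))


class TestCoverageRatios:
    def setup_case(self, test_cov, base_cov, n=10):
        ts = uniform_targets(n)
        from panelcnv.reference import SampleProfile
        test = SampleProfile("T", 1.0, np.asarray(test_cov, float),
                             np.asarray(test_cov).astype(np.int64),
                             int(np.sum(test_cov)))
        b = np.asarray(base_cov, float)
        baselines = BaselineTriple(mean=b, median=b.copy(), closest=b.copy(), closest_id="C00")
        fit = make_fit(n, rho=1e-4)
        return test, baselines, fit

    def test_equal_profiles_give_unit_ratios(self):
        test, baselines, fit = self.setup_case([1000] * 10, [1000] * 10)
        prof = coverage_ratios(test, baselines, fit, CallerConfig())
        np.testing.assert_allclose(prof.ratios, 1.0)
        assert prof.usable.all()
        assert not prof.het_flags.any() and not prof.hom_flags.any()

    def test_half_dosage_is_not_flagged_but_point_three_is(self):
        """0.5 > 0.33: naive half-dosage does not trip the het rule; 0.30
        does."""
        cov = np.full(10, 1000.0)
        half, third = cov.copy(), cov.copy()
        half[2:7] *= 0.5
        third[2:7] *= 0.3
        _, baselines, fit = self.setup_case(cov, cov)
        from panelcnv.reference import SampleProfile
        for values, expect in [(half, False), (third, True)]:
            test = SampleProfile("T", 1.0, values, values.astype(np.int64), int(values.sum()))
            prof = coverage_ratios(test, baselines, fit, CallerConfig())
            assert prof.het_flags[2:7].all() == expect

    def test_low_baseline_targets_unusable(self):
        base = np.full(10, 1000.0)
        base[3] = 50.0   # below min_norm_reads
        test, baselines, fit = self.setup_case([1000] * 10, base)
        prof = coverage_ratios(test, baselines, fit, CallerConfig())
        assert not prof.usable[3] and prof.usable.sum() == 9

    def test_self_comparison_refused(self):
        test, baselines, fit = self.setup_case([1000] * 10, [1000] * 10)
        with pytest.raises(PanelError, match="reference"):
            coverage_ratios(test, baselines, fit, CallerConfig(), reference_ids={"T"})


class TestSegmentHmm:
    def test_flat_profile_is_one_normal_segment_per_gene(self):
        ts = uniform_targets(20, gene_size=10)
        prof = make_profile(np.ones(20))
        segs = segment_hmm(prof, ts, CallerConfig())
        assert [(s.gene, s.state, len(s.indices)) for s in segs] == [
            ("G00", "NORMAL", 10), ("G01", "NORMAL", 10)]

    def test_het_run_recovered_exactly(self):
        ts = uniform_targets(20, gene_size=20)
        ratios = np.ones(20)
        ratios[5:10] = 0.3
        segs = segment_hmm(make_profile(ratios), ts, CallerConfig())
        assert [(s.state, s.indices.tolist()) for s in segs] == [
            ("NORMAL", list(range(5))),
            ("HET_DEL", [5, 6, 7, 8, 9]),
            ("NORMAL", list(range(10, 20))),
        ]

    def test_hom_run_recovered(self):
        ts = uniform_targets(12, gene_size=12)
        ratios = np.ones(12)
        ratios[3:8] = 0.003
        segs = segment_hmm(make_profile(ratios), ts, CallerConfig())
        states = [s.state for s in segs]
        assert states == ["NORMAL", "HOM_DEL", "NORMAL"]
        assert segs[1].indices.tolist() == [3, 4, 5, 6, 7]

    def test_viterbi_agrees_with_exhaustive_path_enumeration(self):
        """On short tracks the decoded path attains the maximum joint
        log-probability over all 4^n paths."""
        config = CallerConfig()
        pi, A = _hmm_params(config)
        log_pi, log_A = np.log(pi), np.log(A)
        means = _state_means(config)
        rng = np.random.default_rng(1)
        for trial in range(10):
            n = int(rng.integers(3, 8))
            x = rng.choice([np.log2(0.3), 0.0, np.log2(0.01)], size=n) \
                + rng.normal(0, 0.2, size=n)
            sd = rng.uniform(0.08, 0.3, size=n)
            z = (x[:, None] - means[None, :]) / sd[:, None]
            log_emit = -0.5 * z ** 2 - np.log(sd[:, None])
            path = _viterbi(log_emit, log_pi, log_A)

            def score(p):
                s = log_pi[p[0]] + log_emit[0, p[0]]
                for t in range(1, n):
                    s += log_A[p[t - 1], p[t]] + log_emit[t, p[t]]
                return s

            best = max(itertools.product(range(4), repeat=n), key=score)
            assert score(tuple(path)) == pytest.approx(score(best))

    def test_gene_boundaries_reset_the_chain(self):
        """A deletion ending at a gene boundary does not leak into the
        next gene."""
        ts = uniform_targets(10, gene_size=5)
        ratios = np.ones(10)
        ratios[3:5] = 0.3    # last two targets of G00
        segs = segment_hmm(make_profile(ratios), ts, CallerConfig())
        g01 = [s for s in segs if s.gene == "G01"]
        assert len(g01) == 1 and g01[0].state == "NORMAL"

    def test_stationary_non_normal_mass_respects_cap(self):
        config = CallerConfig()
        pi, A = _hmm_params(config)
        evals, evecs = np.linalg.eig(A.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat /= stat.sum()
        non_normal = 1.0 - stat[STATES.index("NORMAL")]
        assert non_normal <= config.max_cnv_fraction + 1e-12


class TestApplyFilters:
    def run_cascade(self, ratios, ts=None, rho=1e-4, wif=0.97, config=None,
                    usable=None):
        config = config or CallerConfig()
        ts = ts or uniform_targets(len(np.atleast_1d(ratios[..., 0] if np.ndim(ratios) > 1 else ratios)), gene_size=10)
        prof = make_profile(ratios, config, usable=usable)
        fit = make_fit(len(ts), rho=rho)
        qc = QCReport("T", wif, 0.0, True, "C00", [], True)
        segs = segment_hmm(prof, ts, config)
        calls = apply_call_filters(segs, prof, fit, ts, wif, config, qc)
        return calls, qc

    def test_worked_example_only_consistent_long_segment_survives(self):
        """(a) 5-target run at 0.30 under all three baselines passes;
        (b) a 40 bp target at 0.30 fails min_length; (c) a 5-target run at
        0.30 under mean/median but 0.45 under closest fails consensus."""
        lengths = [100] * 30
        lengths[10] = 40  # gene G01's promoter is the short segment (b)
        ts = uniform_targets(30, gene_size=10, lengths=lengths)
        config = CallerConfig(max_cnv_fraction=0.5)
        r = np.ones((30, 3))
        r[2:7, :] = 0.30          # (a) in G00
        r[10, :] = 0.30           # (b) single 40 bp target in G01
        r[22:27, 0] = 0.30        # (c) in G02
        r[22:27, 1] = 0.30
        r[22:27, 2] = 0.45
        calls, qc = self.run_cascade(r, ts=ts, config=config)
        assert [(c.gene, c.zygosity, c.n_targets) for c in calls] == [
            ("G00", "heterozygous", 5)]
        reasons = dict(qc.rejected)
        assert reasons["G01:promoter-promoter"] == "min_length"
        assert reasons["G02:exon2-exon6"] == "consensus"

    def test_high_dispersion_region_rejected(self):
        ratios = np.ones(10)
        ratios[2:7] = 0.3
        rho = np.full(10, 1e-3)
        rho[4] = 0.27   # one noisy target poisons the span
        calls, qc = self.run_cascade(ratios, rho=rho, config=CallerConfig(max_cnv_fraction=0.6))
        assert calls == []
        assert ("G00:exon2-exon6", "dispersion") in qc.rejected

    def test_atypical_sample_blocked_by_within_fraction(self):
        ratios = np.ones(10)
        ratios[2:7] = 0.3
        calls, qc = self.run_cascade(ratios, wif=0.90, config=CallerConfig(max_cnv_fraction=0.6))
        assert calls == []
        assert ("G00:exon2-exon6", "within_fraction") in qc.rejected

    def test_runaway_sample_fails_qc_and_emits_nothing(self):
        ratios = np.ones(40)
        ratios[0:10] = 0.3   # 25% of targets deleted
        ts = uniform_targets(40, gene_size=10)
        calls, qc = self.run_cascade(ratios, ts=ts)
        assert calls == [] and not qc.qc_pass
        assert ("sample", "max_cnv_fraction") in qc.rejected

    def test_hom_call_reports_hom_zygosity(self):
        ratios = np.ones(10)
        ratios[2:7] = 0.002
        calls, _ = self.run_cascade(ratios, config=CallerConfig(max_cnv_fraction=0.6))
        assert [c.zygosity for c in calls] == ["homozygous"]
        assert calls[0].ratio_max < 0.05

    def test_lowering_t_het_never_adds_calls(self):
        rng = np.random.default_rng(4)
        base = CallerConfig(max_cnv_fraction=0.6)
        strict = CallerConfig(t_het=0.25, max_cnv_fraction=0.6)
        for _ in range(20):
            ratios = np.ones(12)
            k = rng.integers(1, 4)
            start = rng.integers(0, 12 - k)
            ratios[start:start + k] = rng.uniform(0.2, 0.45)
            loose_calls, _ = self.run_cascade(ratios, ts=uniform_targets(12, 12), config=base)
            strict_calls, _ = self.run_cascade(ratios, ts=uniform_targets(12, 12), config=strict)
            loose_set = {(c.gene, c.start, c.end) for c in loose_calls}
            strict_set = {(c.gene, c.start, c.end) for c in strict_calls}
            assert strict_set <= loose_set


class TestEndToEnd:
    def small_sim(self, seed, deletions=()):
        # default panel scale: the typicality filter needs a full-size
        # panel to have its operating margin
        cfg = SimulationConfig(seed=seed, deletions=deletions)
        return simulate_panel(cfg)

    def find_gene(self, ts, span=5):
        for g in ts.genes:
            if len(ts.gene_indices(g)) >= span:
                return g

    def test_injected_het_deletion_called_with_exact_span(self):
        ts0, _, _ = self.small_sim(42)
        g = self.find_gene(ts0)
        ts, m, truth = self.small_sim(42, (DeletionSpec("T01", g, 1, 5, 0.3),))
        calls, qc = call_cnvs(m, "T01")
        assert len(calls) == 1
        c = calls[0]
        assert c.gene == g and c.zygosity == "heterozygous"
        idx = ts.gene_indices(g)[0:5]
        assert c.start == ts[idx[0]].start and c.end == ts[idx[-1]].end
        assert 0.2 <= c.ratio_min <= 0.33 and c.ratio_max <= 0.45

    def test_injected_hom_deletion_called_homozygous(self):
        ts0, _, _ = self.small_sim(43)
        g = self.find_gene(ts0)
        _, m, _ = self.small_sim(43, (DeletionSpec("T01", g, 1, 5, 0.0),))
        calls, _ = call_cnvs(m, "T01")
        assert [c.zygosity for c in calls if c.gene == g] == ["homozygous"]

    def test_calling_is_deterministic_to_the_byte(self, tmp_path):
        ts0, _, _ = self.small_sim(44)
        g = self.find_gene(ts0)
        ts, m, _ = self.small_sim(44, (DeletionSpec("T01", g, 1, 5, 0.3),))
        outputs = []
        for run in range(2):
            calls, _ = call_cnvs(m, "T01")
            p = tmp_path / f"run{run}.tsv"
            write_calls(calls, ts, "TSV", p)
            outputs.append(p.read_bytes())
        assert outputs[0] == outputs[1]


class TestBruteForceAgreement:
    def test_pipeline_equals_span_enumeration_on_separated_panels(self):
        """Random small panels with band-separated ratios: HMM + filters
        and direct span enumeration produce identical call sets."""
        rng = np.random.default_rng(123)
        config = CallerConfig(max_cnv_fraction=0.5)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            lengths = [int(l) for l in rng.choice([40, 100, 200], size=n, p=[0.2, 0.4, 0.4])]
            ts = uniform_targets(n, gene_size=max(2, n // 2), lengths=lengths)
            band = rng.choice([0, 1, 2], size=n, p=[0.7, 0.2, 0.1])
            ratios = np.empty((n, 3))
            for i, b in enumerate(band):
                if b == 0:
                    ratios[i] = rng.uniform(0.9, 1.1, size=3)
                elif b == 1:
                    ratios[i] = rng.uniform(0.2501, 0.33, size=3)
                else:
                    ratios[i] = rng.uniform(0.0, 0.049, size=3)
            prof = make_profile(ratios, config, sd=0.1)
            rho = rng.choice([1e-3, 5e-3, 2e-2], size=n, p=[0.6, 0.3, 0.1])
            fit = make_fit(n, rho=rho)
            wif = float(rng.choice([0.97, 0.93], p=[0.9, 0.1]))
            segs = segment_hmm(prof, ts, config)
            qc = QCReport("T", wif, 0.0, True, "C", [], True)
            calls = apply_call_filters(segs, prof, fit, ts, wif, config, qc)
            got = sorted((c.gene, ts.index_of(f"{c.gene}|" + c.region_label.split("-")[0]),
                          c.zygosity) for c in calls)
            expected = sorted((g, i0, z) for g, i0, i1, z in
                              brute_force_calls(prof, ts, fit, wif, config))
            assert got == expected
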