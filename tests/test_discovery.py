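import numpy as np
import pytest

from cfsubtype import discovery
from cfsubtype.types import Fragment, Marker, ValidationError

from conftest import make_sample, random_region_samples


def brute_force_scan(
    targets, others, direction, region_id="r",
    min_cpgs=3, min_fragments=1, thresholds=None,
):
    """Reference scan: try every grid threshold, keep n_other < 2, maximise
    n_target, break ties toward the extreme threshold."""
    if thresholds is None:
        thresholds = np.arange(101) / 100
    best = None
    best_key = None
    for t in thresholds:
        nt = sum(
            discovery.sample_qualifies(s, region_id, t, direction,
                                       min_fragments, min_cpgs)
            for s in targets
        )
        no = sum(
            discovery.sample_qualifies(s, region_id, t, direction,
                                       min_fragments, min_cpgs)
            for s in others
        )
        if no >= 2 or nt < 1:
            continue
        key = (nt, -t) if direction == "hypo" else (nt, t)
        if best_key is None or key > best_key:
            best_key = key
            best = (float(t), nt, no)
    return best


class TestAlphaValue:
    def test_examples(self):
        assert discovery.alpha_value(Fragment("r", 4, 2)) == 0.5
        assert discovery.alpha_value(Fragment("r", 5, 5)) == 1.0

    def test_zero_cpgs_error(self):
        with pytest.raises(ValidationError):
            Fragment("r", 0, 0)


class TestSampleQualifies:
    def test_hypo_inclusive(self):
        s = make_sample([("r", 10, 1), ("r", 10, 2), ("r", 10, 9)])
        assert discovery.sample_qualifies(s, "r", 0.2, "hypo")
        assert discovery.sample_qualifies(s, "r", 0.2, "hypo", min_fragments=2)
        assert not discovery.sample_qualifies(s, "r", 0.2, "hypo", min_fragments=3)

    def test_hyper_not_met(self):
        s = make_sample([("r", 100, 50), ("r", 100, 79)])
        assert not discovery.sample_qualifies(s, "r", 0.8, "hyper")

    def test_empty_region(self):
        s = make_sample([("other", 4, 2)])
        assert not discovery.sample_qualifies(s, "r", 0.5, "hypo")


class TestScanThresholds:
    def test_clean_separation(self):
        targets = [
            make_sample([("r", 10, 1)], sample_id=f"T{i}") for i in range(5)
        ]
        others = [
            make_sample([("r", 10, 8)], sample_id=f"O{i}", label="LUSC")
            for i in range(3)
        ]
        res = discovery.scan_thresholds("r", targets, others, "hypo")
        assert res.alpha_threshold == pytest.approx(0.1)
        assert (res.n_target, res.n_other) == (5, 0)

    def test_two_contaminated_others_kill_candidate(self):
        # two other-class samples share the lowest alpha: any threshold
        # admitting a target admits both of them -> no candidate
        targets = [make_sample([("r", 10, 1)], sample_id=f"T{i}") for i in range(5)]
        others = [
            make_sample([("r", 10, 1)], sample_id=f"O{i}", label="LUSC")
            for i in range(2)
        ]
        assert discovery.scan_thresholds("r", targets, others, "hypo") is None

    def test_no_signal_direction(self):
        # targets are fully methylated while both other samples carry the
        # lowest alphas: no admissible hypo threshold reaches a target
        targets = [make_sample([("r", 10, 9)], sample_id="T0")]
        others = [
            make_sample([("r", 10, 0)], sample_id=f"O{i}", label="LUSC")
            for i in range(2)
        ]
        assert discovery.scan_thresholds("r", targets, others, "hypo") is None

    def test_one_tolerated_other(self):
        targets = [make_sample([("r", 10, 2)], sample_id=f"T{i}") for i in range(4)]
        others = [make_sample([("r", 10, 1)], sample_id="O0", label="LUSC")] + [
            make_sample([("r", 10, 9)], sample_id=f"O{i}", label="LUSC")
            for i in range(1, 4)
        ]
        res = discovery.scan_thresholds("r", targets, others, "hypo")
        assert (res.n_target, res.n_other) == (4, 1)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValidationError):
            discovery.scan_thresholds("r", [], [make_sample([("r", 4, 2)])], "hypo")

    def test_matches_brute_force_oracle(self, rng):
        mismatches = 0
        for _ in range(300):
            targets, others = random_region_samples(
                rng, int(rng.integers(1, 6)), int(rng.integers(1, 6))
            )
            for direction in ("hypo", "hyper"):
                exact = discovery.scan_thresholds("r", targets, others, direction)
                brute = brute_force_scan(targets, others, direction)
                if exact is None:
                    assert brute is None
                else:
                    assert brute is not None
                    assert exact.alpha_threshold == pytest.approx(brute[0])
                    assert (exact.n_target, exact.n_other) == brute[1:]
        assert mismatches == 0

    def test_hyper_mirror_symmetry(self, rng):
        # flipping methylation (m -> n_cpgs - m) swaps hypo and hyper
        targets, others = random_region_samples(rng, 4, 4)

        def flipped(samples):
            out = []
            for s in samples:
                f = s.frame.copy()
                f["n_methylated"] = f["n_cpgs"] - f["n_methylated"]
                out.append(make_sample(
                    list(f.itertuples(index=False, name=None)),
                    sample_id=s.sample_id, label=s.label,
                ))
            return out

        res_hypo = discovery.scan_thresholds("r", targets, others, "hypo")
        res_hyper = discovery.scan_thresholds(
            "r", flipped(targets), flipped(others), "hyper"
        )
        if res_hypo is None:
            assert res_hyper is None
        else:
            assert res_hyper.alpha_threshold == pytest.approx(
                1 - res_hypo.alpha_threshold
            )
            assert res_hyper.n_target == res_hypo.n_target

    def test_adding_qualifying_fragment_monotone(self, rng):
        for _ in range(50):
            targets, others = random_region_samples(rng, 3, 3)
            res = discovery.scan_thresholds("r", targets, others, "hypo")
            if res is None:
                continue
            # give one target sample an extra clearly qualifying fragment
            augmented = [
                make_sample(
                    list(targets[0].frame.itertuples(index=False, name=None))
                    + [("r", 10, 0)],
                    sample_id="T0x",
                )
            ] + targets[1:]
            res2 = discovery.scan_thresholds("r", augmented, others, "hypo")
            assert res2 is not None and res2.n_target >= res.n_target


class TestBackgroundFilter:
    def _candidate(self):
        return Marker("r", "LUAD", "hypo", 0.2, 10, 0)

    def _background(self, n_qualifying, n_total=30):
        cohort = []
        for i in range(n_total):
            meth = 1 if i < n_qualifying else 9
            cohort.append(
                make_sample([("r", 10, meth)], sample_id=f"N{i}",
                            label="noncancer", material="plasma")
            )
        return cohort

    def test_above_threshold_removed(self):
        kept = discovery.apply_background_filter(
            [self._candidate()], self._background(7)
        )
        assert kept == []

    def test_boundary_kept(self):
        cand = self._candidate()
        kept = discovery.apply_background_filter([cand], self._background(6))
        assert kept == [cand]
        assert cand.bg_fraction == pytest.approx(0.2)

    def test_zero_background(self):
        cand = self._candidate()
        kept = discovery.apply_background_filter([cand], self._background(0))
        assert kept == [cand] and cand.bg_fraction == 0.0

    def test_empty_cohort_errors(self):
        with pytest.raises(ValidationError):
            discovery.apply_background_filter([self._candidate()], [])


class TestRankAndSelect:
    def _markers(self, n_targets):
        return [
            Marker(f"r{i}", "LUAD", "hypo", 0.1, nt, 0, 0.0)
            for i, nt in enumerate(n_targets)
        ]

    def test_ties_included(self):
        selected = discovery.rank_and_select(self._markers([9, 8, 8, 7]), k=2)
        assert [m.n_target for m in selected] == [9, 8, 8]
        assert [m.rank for m in selected] == [1, 2, 3]

    def test_k_exceeds_candidates(self):
        markers = self._markers([3, 2])
        assert discovery.rank_and_select(markers, k=10) == markers

    def test_empty(self):
        assert discovery.rank_and_select([], k=5) == []

    def test_strict_trims_ties(self):
        selected = discovery.rank_and_select(
            self._markers([9, 8, 8, 7]), k=2, strict=True
        )
        assert len(selected) == 2

    def test_deterministic_secondary_key(self):
        markers = self._markers([5, 5, 5])
        selected = discovery.rank_and_select(markers, k=1)
        assert [m.region_id for m in selected] == ["r0", "r1", "r2"]


@pytest.fixture(scope="module")
def benchmark():
    from cfsubtype import simulate

    return simulate.make_discovery_benchmark(
        7, n_regions=600, n_planted_per_cell=12, n_per_class=10,
        n_noncancer=10, depth=30,
    )


class TestDiscoverMarkers:

    def test_recovers_planted_markers(self, benchmark):
        res = discovery.discover_markers(
            benchmark.luad, benchmark.lusc, benchmark.noncancer, k=12
        )
        truth = set(
            zip(benchmark.truth.region_id, benchmark.truth.target_class,
                benchmark.truth.direction)
        )
        found = set(
            (m.region_id, m.target_class, m.direction) for m in res.combined
        )
        assert len(found & truth) / len(truth) >= 0.8
        assert len(found & truth) / len(found) >= 0.9

    def test_swapping_cohorts_swaps_labels(self, benchmark):
        res = discovery.discover_markers(
            benchmark.luad, benchmark.lusc, benchmark.noncancer, k=12
        )
        swapped = discovery.discover_markers(
            benchmark.lusc, benchmark.luad, benchmark.noncancer, k=12
        )
        flip = {"LUAD": "LUSC", "LUSC": "LUAD"}
        for cls, direction in discovery.CELLS:
            a = {(m.region_id, m.alpha_threshold, m.n_target, m.n_other)
                 for m in res.cells[(cls, direction)]}
            b = {(m.region_id, m.alpha_threshold, m.n_target, m.n_other)
                 for m in swapped.cells[(flip[cls], direction)]}
            assert a == b

    def test_invariants_on_output(self, benchmark):
        res = discovery.discover_markers(
            benchmark.luad, benchmark.lusc, benchmark.noncancer, k=12
        )
        for m in res.combined:
            m.check_invariants()
            assert 0.0 <= m.alpha_threshold <= 1.0

    def test_order_invariance(self, benchmark):
        res = discovery.discover_markers(
            benchmark.luad, benchmark.lusc, benchmark.noncancer, k=12
        )
        # reverse sample order and shuffle fragments inside each sample
        def scrambled(cohort):
            out = []
            for s in reversed(cohort):
                f = s.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
                out.append(type(s)(s.sample_id, s.label, s.material,
                                   s.total_fragments, f))
            return out

        res2 = discovery.discover_markers(
            scrambled(benchmark.luad), scrambled(benchmark.lusc),
            scrambled(benchmark.noncancer), k=12,
        )
        key = lambda r: sorted(
            (m.region_id, m.target_class, m.direction, m.alpha_threshold,
             m.n_target, m.n_other)
            for m in r.combined
        )
        assert key(res) == key(res2)

    def test_k1_keeps_at_least_one_per_cell(self, benchmark):
        res = discovery.discover_markers(
            benchmark.luad, benchmark.lusc, benchmark.noncancer, k=1
        )
        for cell, markers in res.cells.items():
            assert len(markers) >= 1

    def test_empty_cohort_errors(self, benchmark):
        with pytest.raises(ValidationError):
            discovery.discover_markers([], benchmark.lusc, benchmark.noncancer)

    def test_cell_scan_agrees_with_public_scan(self, benchmark):
        # the vectorised per-cell scan must equal the per-region operation
        res = discovery.discover_markers(
            benchmark.luad, benchmark.lusc, benchmark.noncancer, k=12
        )
        for m in res.combined[:10]:
            target = benchmark.luad if m.target_class == "LUAD" else benchmark.lusc
            other = benchmark.lusc if m.target_class == "LUAD" else benchmark.luad
            exact = discovery.scan_thresholds(
                m.region_id, target, other, m.direction
            )
            assert exact is not None
            assert exact.alpha_threshold == pytest.approx(m.alpha_threshold)
            assert (exact.n_target, exact.n_other) == (m.n_target, m.n_other)
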