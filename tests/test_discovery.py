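"""Filter cascade: boundary behavior of each rule and oracle equivalence."""

import numpy as np
import pytest

from pavpan import discovery as disc
from pavpan import simulate as sim


def _cand(start=0, end=2000, **kw):
    return disc.CandidateSV(id=kw.pop("id", "c1"), contig=kw.pop("contig", "chr1"),
                            start=start, end=end, **kw)


def _profile(depth, proper=None, contig="chr1", start=0):
    return disc.CoverageProfile(contig, start, start + len(depth),
                                np.asarray(depth), None if proper is None else np.asarray(proper))


class TestSelfConsistency:
    def test_flagged_candidate_removed(self):
        out = disc.filter_self_consistency([_cand(detected_in_self_mapping=True)])
        assert out == []

    def test_no_self_detections_passes_everything(self):
        cands = [_cand(id="a"), _cand(id="b", start=5000, end=7000)]
        assert disc.filter_self_consistency(cands) == cands

    def test_one_bp_overlap_rules(self):
        """Any-overlap removes a 1-bp overlap; reciprocal-50% retains it."""
        cand = _cand(start=1000, end=3000)
        det = [_cand(id="self", start=2999, end=5000)]
        assert disc.filter_self_consistency([cand], det, mode="any_overlap") == []
        assert disc.filter_self_consistency([cand], det, mode="reciprocal_50") == [cand]


class TestMinSize:
    @pytest.mark.parametrize("length,kept", [(999, False), (1000, True), (39_900, True)])
    def test_one_kb_boundary_is_inclusive(self, length, kept):
        out = disc.filter_min_size([_cand(end=length)])
        assert (len(out) == 1) is kept

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            disc.filter_min_size([], min_bp=0)


class TestSpecificity:
    def test_eighty_percent_uncovered_kept_with_reported_fraction(self):
        depth = np.concatenate([np.zeros(1600), np.full(400, 12)])
        keep, frac = disc.filter_specificity(_cand(end=2000), _profile(depth))
        assert keep and frac == pytest.approx(0.80)

    def test_half_low_dropped(self):
        depth = np.concatenate([np.zeros(1000), np.full(1000, 30)])
        keep, _ = disc.filter_specificity(_cand(end=2000), _profile(depth))
        assert not keep

    def test_boundaries_strict_below_cutoff_inclusive_fraction(self):
        """Exactly 70% at depth 4 (below 5) and 30% at depth 5 keeps the call."""
        depth = np.concatenate([np.full(1400, 4), np.full(600, 5)])
        keep, frac = disc.filter_specificity(_cand(end=2000), _profile(depth))
        assert keep and frac == pytest.approx(0.70)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            disc.filter_specificity(_cand(end=2000), _profile(np.zeros(100)))


class TestAssemblySupport:
    @pytest.mark.parametrize("covered,kept", [(0.95, True), (0.90, False), (0.0, False)])
    def test_ninety_percent_boundary_is_strict(self, covered, kept):
        n = 1000
        proper = np.zeros(n)
        proper[: int(covered * n)] = 3
        keep, frac = disc.filter_assembly_support(_cand(end=n), _profile(np.zeros(n), proper))
        assert keep is kept and frac == pytest.approx(covered)


class TestIncompleteScaffolds:
    def _scaffold_profiles(self, covered_frac, low_frac, n=8000):
        depth = np.zeros(n)
        n_cov = int(covered_frac * n)
        depth[:n_cov] = 30  # covered bases, all >= 5x
        n_high = n - int(low_frac * n)
        depth[:n_high] = np.maximum(depth[:n_high], 5)
        return {"s1": _profile(depth, contig="s1")}

    def test_barely_covered_scaffold_becomes_incomplete(self):
        profs = {"s1": _profile(np.zeros(8000), contig="s1")}
        recs = disc.classify_incomplete_scaffolds({"s1": "A" * 8000}, profs)
        assert len(recs) == 1
        assert recs[0].category == "incomplete" and recs[0].breakpoint is None

    def test_quarter_covered_scaffold_is_not_incomplete(self):
        depth = np.zeros(8000)
        depth[:2000] = 1  # 25% covered, still low depth
        recs = disc.classify_incomplete_scaffolds(
            {"s1": "A" * 8000}, {"s1": _profile(depth, contig="s1")})
        assert recs == []

    def test_both_criteria_required(self):
        # 19% covered but only 60% of bases below 5x -> rejected
        depth = np.full(8000, 5)
        depth[: int(0.60 * 8000)] = 0
        depth[: int(0.19 * 8000)] = 30
        recs = disc.classify_incomplete_scaffolds(
            {"s1": "A" * 8000}, {"s1": _profile(depth, contig="s1")})
        assert recs == []


class TestOversize:
    def test_boundary_is_strict(self):
        at_limit = _cand(id="at", end=200_000)
        above = _cand(id="above", end=250_000)
        kept, flagged = disc.flag_oversize([at_limit, above])
        assert kept == [at_limit] and flagged == [above]

    def test_empty_input(self):
        assert disc.flag_oversize([]) == ([], [])


class TestAnchoring:
    @pytest.mark.parametrize("hits,category", [
        (0, "unanchored"), (1, "anchored_unique"), (3, "anchored_ambiguous")])
    def test_category_from_hit_count(self, hits, category):
        assert disc.assign_anchor_category(hits) == category

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            disc.assign_anchor_category(-1)

    def test_exact_flank_counting(self, adversarial_bundle):
        """Unique PAVs place once on the acceptor, ambiguous ones twice."""
        donor = adversarial_bundle["donor"]["chr1"]
        acceptor = adversarial_bundle["acceptor"]["chr1"]
        truth = adversarial_bundle["truth"]
        for f in truth.true_pavs:
            if f.contig != "chr1":
                continue
            cand = _cand(id=f.id, start=f.start, end=f.end)
            hits, pos = disc.count_anchor_hits(donor, cand, acceptor)
            assert hits == f.anchor_copies
            if hits == 1:
                assert pos == truth.acceptor_breakpoint(f.id)


def _brute_force_verdicts(bundle, params):
    """Independent re-application of the five written rules, candidate by candidate."""
    verdicts = {}
    opp = bundle["opposite"]
    own = bundle["own"]
    for cand in bundle["candidates"]:
        depth = opp[cand.contig].depth[cand.start : cand.end]
        proper = own[cand.contig].properly_paired_depth[cand.start : cand.end]
        ok = (
            not cand.detected_in_self_mapping
            and cand.length >= params.min_bp
            and np.mean(depth < params.depth_cutoff) >= params.specificity_frac
            and np.mean(proper >= 1) > params.assembly_frac
            and cand.length <= params.oversize_bp
        )
        verdicts[cand.id] = ok
    return verdicts


class TestPipeline:
    def test_matches_brute_force_oracle(self, adversarial_bundle):
        params = disc.DiscoveryParams()
        records, report = disc.run_discovery_pipeline(
            adversarial_bundle["candidates"], {}, adversarial_bundle["opposite"],
            adversarial_bundle["own"], adversarial_bundle["donor"],
            adversarial_bundle["acceptor"]["chr1"], params)
        expected = _brute_force_verdicts(adversarial_bundle, params)
        assert {r.id for r in records} == {cid for cid, ok in expected.items() if ok}

    def test_each_stage_rejects_at_least_one_decoy(self, adversarial_bundle):
        _, report = disc.run_discovery_pipeline(
            adversarial_bundle["candidates"], adversarial_bundle["scaffolds"],
            adversarial_bundle["opposite"], adversarial_bundle["own"],
            adversarial_bundle["donor"], adversarial_bundle["acceptor"]["chr1"])
        stages_hit = {stage for stage, _ in report.rejections.values()}
        assert {"self_consistency", "min_size", "specificity",
                "assembly_support", "oversize"} <= stages_hit

    def test_report_telescopes(self, adversarial_bundle):
        _, report = disc.run_discovery_pipeline(
            adversarial_bundle["candidates"], adversarial_bundle["scaffolds"],
            adversarial_bundle["opposite"], adversarial_bundle["own"],
            adversarial_bundle["donor"], adversarial_bundle["acceptor"]["chr1"])
        assert report.telescopes()
        n_rejected = sum(i - o for _, i, o in report.stages)
        assert n_rejected == len(report.rejections)

    def test_recall_and_decoy_exclusion(self, adversarial_bundle):
        """>= 95% of planted true PAVs retained; every duplication decoy rejected."""
        records, _ = disc.run_discovery_pipeline(
            adversarial_bundle["candidates"], adversarial_bundle["scaffolds"],
            adversarial_bundle["opposite"], adversarial_bundle["own"],
            adversarial_bundle["donor"], adversarial_bundle["acceptor"]["chr1"])
        truth = adversarial_bundle["truth"]
        retained = {r.id for r in records}
        true_ids = {f.id for f in truth.true_pavs}
        assert len(retained & true_ids) / len(true_ids) >= 0.95
        dup_ids = {f.id for f in truth.features if f.category == "duplication_decoy"}
        assert retained & dup_ids == set()

    def test_verdict_order_insensitive(self, adversarial_bundle):
        """Filters are conjunctive: reversing candidate order changes nothing."""
        args = (adversarial_bundle["scaffolds"], adversarial_bundle["opposite"],
                adversarial_bundle["own"], adversarial_bundle["donor"],
                adversarial_bundle["acceptor"]["chr1"])
        fwd, _ = disc.run_discovery_pipeline(adversarial_bundle["candidates"], *args)
        rev, _ = disc.run_discovery_pipeline(
            list(reversed(adversarial_bundle["candidates"])), *args)
        assert {r.id: r.category for r in fwd} == {r.id: r.category for r in rev}

    def test_all_pass_set_is_untouched(self):
        cfg = sim.SimulationConfig(seed=2, n_pavs=8, n_incomplete=0)
        donor, acceptor, truth = sim.simulate_genome_pair(cfg)
        opp, own = sim.simulate_coverage(truth, cfg)
        cands = sim.candidates_from_truth(truth)
        records, _ = disc.run_discovery_pipeline(
            cands, {}, opp, own, donor, acceptor["chr1"])
        assert len(records) == len(cands)

    def test_missing_profile_reported_with_offender(self):
        with pytest.raises(KeyError, match="c1"):
            disc.run_discovery_pipeline([_cand()], {}, {}, {}, {}, "ACGT")
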