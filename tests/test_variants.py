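"""UMI dedup consensus, the binomial stand-in caller, and the call filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chipdyn import (SiteObservation, apply_call_filters, call_variants,
                     dedup_umis, filter_recurrent_artifacts,
                     simulate_umi_reads)
from chipdyn.simulate import RawReadRecord


def read(umi, allele, probe="p1", pos=100):
    return RawReadRecord(probe_id=probe, umi=umi, chrom="1", pos=pos,
                         ref="A", alt="G", observed_allele=allele)


class TestDedup:
    def test_majority_vote_consensus(self):
        obs, stats = dedup_umis([read("AAAAAAAAA", a) for a in "AAG"])
        assert len(obs) == 1
        assert (obs[0].depth, obs[0].alt_count) == (1, 0)  # majority A = ref
        assert stats.n_molecules == 1

    def test_exact_tie_drops_group(self):
        obs, stats = dedup_umis([read("AAAAAAAAA", "A"), read("AAAAAAAAA", "G")])
        assert obs == []
        assert stats.n_tied_dropped == 1

    def test_distinct_umis_counted_separately(self):
        umis = ["AAAAAAAAA", "CCCCCCCCC", "GGGGGGGGG", "TTTTTTTTT", "ACGTACGTA"]
        obs, _ = dedup_umis([read(u, "G") for u in umis])
        assert (obs[0].depth, obs[0].alt_count) == (5, 5)

    def test_malformed_umi_rejected_with_count(self):
        obs, stats = dedup_umis([read("SHORT", "G"), read("AAAAAAAAA", "G")])
        assert stats.n_malformed == 1
        assert obs[0].depth == 1

    def test_order_independence(self):
        reads = [read(u, a) for u, a in
                 [("AAAAAAAAA", "A"), ("AAAAAAAAA", "A"), ("CCCCCCCCC", "G"),
                  ("GGGGGGGGG", "G"), ("GGGGGGGGG", "A"), ("GGGGGGGGG", "G")]]
        baseline, _ = dedup_umis(reads)
        for perm in itertools.permutations(reads):
            obs, _ = dedup_umis(list(perm))
            assert obs == baseline

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        counts=st.lists(
            st.tuples(st.integers(1, 30), st.integers(0, 30)).filter(
                lambda t: t[1] <= t[0]
            ),
            min_size=1, max_size=4,
        ),
        seed=st.integers(0, 2**20),
    )
    def test_roundtrip_at_any_duplication_rate(self, counts, seed):
        """dedup(simulate_umi_reads(x, rate)) == x when copies carry no error."""
        obs_in = [
            {"chrom": "1", "pos": 10 * (i + 1), "ref": "A", "alt": "G",
             "depth": d, "alt_count": a}
            for i, (d, a) in enumerate(counts)
        ]
        rate = 1.0 + (seed % 3)
        reads = simulate_umi_reads(obs_in, rate, seed=seed)
        obs_out, stats = dedup_umis(reads)
        assert stats.n_tied_dropped == 0
        got = {o.pos: (o.depth, o.alt_count) for o in obs_out}
        want = {o["pos"]: (o["depth"], o["alt_count"]) for o in obs_in}
        assert got == want

    def test_idempotent_at_count_level(self):
        reads = [read(u, a) for u, a in
                 [("AAAAAAAAA", "G"), ("CCCCCCCCC", "A"), ("GGGGGGGGG", "G")]]
        once, _ = dedup_umis(reads)
        re_expanded = simulate_umi_reads(
            [{"chrom": o.chrom, "pos": o.pos, "ref": o.ref, "alt": o.alt,
              "depth": o.depth, "alt_count": o.alt_count} for o in once],
            1.0, seed=0)
        twice, _ = dedup_umis(re_expanded)
        assert [(o.depth, o.alt_count) for o in twice] == \
            [(o.depth, o.alt_count) for o in once]


class TestCaller:
    def obs(self, depth, alt):
        return SiteObservation("1", 100, "A", "G", depth=depth, alt_count=alt)

    def test_zero_alt_is_null(self):
        call = call_variants(self.obs(1000, 0), 0.00045)
        assert call.p_value == 1.0 and not call.is_candidate

    def test_clear_clone_is_candidate(self):
        call = call_variants(self.obs(2800, 56), 0.00045)
        assert call.p_value < 1e-6 and call.is_candidate

    def test_single_read_tail_closed_form(self):
        # P(X >= 1) = 1 - (1-e)^40
        call = call_variants(self.obs(40, 1), 0.00045)
        assert call.p_value == pytest.approx(1 - (1 - 0.00045) ** 40, rel=1e-12)
        assert not call.is_candidate

    def test_bad_error_rate(self):
        with pytest.raises(ValueError):
            call_variants(self.obs(10, 1), 0.0)

    def test_null_calibration_is_conservative(self, rng):
        """With no true variant, candidate rate stays at or below alpha."""
        alpha, n = 1e-3, 4000
        depths = rng.integers(200, 3000, size=n)
        e = 0.00045
        alts = rng.binomial(depths, e / 3)  # specific alternate base
        false_pos = sum(
            call_variants(self.obs(int(d), int(a)), e, alpha).is_candidate
            for d, a in zip(depths, alts)
        )
        # conservative discrete test: FP rate <= alpha + 3 MC s.e.
        assert false_pos / n <= alpha + 3 * np.sqrt(alpha / n)


class TestCallFilters:
    @pytest.mark.parametrize(
        "depth,alt,expected_flags",
        [
            (40, 5, set()),  # all thresholds met exactly at the boundary
            (39, 10, {"low_coverage"}),
            (10_000, 9, {"low_vaf"}),  # alt 9 >= 5 passes support, vaf 9e-4 < 1e-3
            (39, 4, {"low_coverage", "low_alt_support"}),
        ],
        ids=["boundary-pass", "depth-boundary", "vaf-only", "depth-and-support"],
    )
    def test_threshold_flags(self, depth, alt, expected_flags):
        obs = SiteObservation("1", 1, "A", "G", depth=depth, alt_count=alt)
        call = apply_call_filters(call_variants(obs, 0.00045))
        got = {
            name
            for name in ("low_coverage", "low_alt_support", "low_vaf")
            if getattr(call, name)
        }
        assert got == expected_flags
        assert call.is_pass == (not expected_flags)

    def test_boundary_pass_has_vaf_at_min(self):
        obs = SiteObservation("1", 1, "A", "G", depth=4000, alt_count=5)
        call = apply_call_filters(call_variants(obs, 0.00045))
        assert obs.vaf == 0.00125 and not call.low_vaf


class TestRecurrentArtifacts:
    def _calls(self, n_samples, variant_vafs):
        """variant_vafs: {variant: {sample_index: vaf}} over n_samples."""
        rows = []
        for s in range(n_samples):
            for vid, by_sample in variant_vafs.items():
                if s in by_sample:
                    rows.append({"sample_id": f"s{s}", "variant_id": vid,
                                 "vaf": by_sample[s]})
        return pd.DataFrame(rows)

    def test_five_percent_boundary_flags(self):
        calls = self._calls(100, {"v1": {i: 0.05 for i in range(5)}})
        out = filter_recurrent_artifacts(calls, n_total_samples=100)
        assert out["recurrent_artifact"].all()

    def test_below_boundary_kept(self):
        calls = self._calls(100, {"v1": {i: 0.05 for i in range(4)}})
        out = filter_recurrent_artifacts(calls, n_total_samples=100)
        assert not out["recurrent_artifact"].any()

    def test_outside_vaf_window_kept(self):
        calls = self._calls(100, {"v1": {i: 0.30 for i in range(50)}})
        out = filter_recurrent_artifacts(calls, n_total_samples=100)
        assert not out["recurrent_artifact"].any()

    def test_flag_applies_to_all_samples_of_variant(self):
        by_sample = {i: 0.05 for i in range(5)}
        by_sample[90] = 0.40  # outside window, still flagged via the variant
        calls = self._calls(100, {"v1": by_sample})
        out = filter_recurrent_artifacts(calls, n_total_samples=100)
        assert out["recurrent_artifact"].all()


def test_whole_pipeline_recovery_sensitivity():
    """Simulated clones at true VAF >= 1% and depth >= 1000 are recovered as
    PASS calls with sensitivity > 99% through call + filter stages."""
    from chipdyn import CohortSimConfig, simulate_cohort

    cfg = CohortSimConfig(n_subjects=40, clone_rate=2.0, seed=77,
                          n_invariant_sites=0)
    sim = simulate_cohort(cfg)
    truth = {c.variant_id: c for c in sim.truth}
    ages = sim.manifest.set_index(["subject_id", "timepoint"])["age"]

    rows = []
    for (sid, tp), obs in sim.observations.items():
        age = float(ages.loc[(sid, tp)])
        for r in obs.itertuples():
            vid = f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
            true_vaf = truth[vid].vaf_at(age)
            if true_vaf < 0.01 or r.depth < 1000:
                continue
            so = SiteObservation(str(r.chrom), int(r.pos), r.ref, r.alt,
                                 int(r.depth), int(r.alt_count))
            call = apply_call_filters(call_variants(so, cfg.error_rate))
            rows.append({"sample_id": f"{sid}:{tp}", "variant_id": vid,
                         "vaf": so.vaf, "pass_thresholds": call.is_pass,
                         "is_candidate": call.is_candidate})
    df = pd.DataFrame(rows)
    n_samples = len(sim.observations)
    flagged = filter_recurrent_artifacts(df, n_total_samples=n_samples)
    recovered = (df["is_candidate"] & df["pass_thresholds"]
                 & ~flagged["recurrent_artifact"])
    assert len(df) > 100
    assert recovered.mean() > 0.99
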