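import numpy as np
import pytest

from rnaplast.design import (
    DesignError,
    InsertionPlan,
    MimicDesignError,
    RetentionThresholds,
    assess_retention,
    design_mimic,
    recommended_dg,
    regional_ape_change,
)
from rnaplast.fold import EntropyProfile, fold
from rnaplast.sequences import RnaSequence, reverse_complement
from rnaplast.simulate import random_hairpin, synth_backbone
from rnaplast.structure import HairpinRecord, characterize_hairpin


def synthetic_record(name, length, delta_g, ape, profile=None):
    """Synthetic stand-in record built from summary values (no real fold)."""
    values = np.full(length, ape) if profile is None else np.asarray(profile)
    return HairpinRecord(
        sequence=RnaSequence(name, "A" * length),
        structure=None,
        delta_g=delta_g,
        ape=ape,
        entropy=EntropyProfile(values),
        provenance="designed",
    )


class TestThresholds:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(DesignError):
            RetentionThresholds(ape_global_max=0)
        with pytest.raises(DesignError):
            RetentionThresholds(ape_window_len=0)
        with pytest.raises(DesignError):
            RetentionThresholds(dg_band_level=1.5)


class TestAssessRetention:
    def test_in_band_low_ape_hairpin_is_retained_likely(self, reference_fit):
        a = assess_retention(synthetic_record("ok", 159, -70.0, 0.10), reference_fit)
        assert a.verdict == "retained-likely"
        assert a.checks["dg_in_band"].passed

    def test_overstable_hairpin_fails_band(self, reference_fit):
        a = assess_retention(synthetic_record("deep", 160, -102.0, 0.10), reference_fit)
        assert not a.checks["dg_in_band"].passed
        assert a.verdict == "retained-unlikely"
        assert any("dg_in_band: FAIL" in r for r in a.reasons)

    def test_weak_hairpin_warns_but_does_not_fail_band(self, reference_fit):
        a = assess_retention(synthetic_record("weak", 160, -20.0, 0.10), reference_fit)
        assert a.checks["dg_in_band"].passed
        assert any("above band" in w for w in a.warnings)

    def test_high_global_ape_fails(self, reference_fit):
        a = assess_retention(synthetic_record("hot", 61, -28.0, 0.40), reference_fit)
        assert not a.checks["ape_global"].passed

    def test_hot_apical_window_fails(self, reference_fit):
        # low global APE, but a hot 20-residue apical region
        prof = np.concatenate([np.full(60, 0.05), np.full(20, 1.0)])
        rec = synthetic_record("hotspot", 80, -35.0, float(prof.mean()), profile=prof)
        a = assess_retention(rec, reference_fit)
        assert not a.checks["ape_window"].passed

    def test_window_longer_than_hairpin_rejected(self, reference_fit):
        rec = synthetic_record("short", 12, -6.0, 0.05)
        with pytest.raises(DesignError):
            assess_retention(rec, reference_fit,
                             RetentionThresholds(ape_window_len=15))

    def test_missing_profile_skips_window_with_warning(self, reference_fit):
        rec = synthetic_record("noprof", 61, -28.0, 0.10)
        rec.entropy = None
        a = assess_retention(rec, reference_fit)
        assert "ape_window" not in a.checks
        assert any("skipped" in w for w in a.warnings)

    def test_multi_loop_topology_fails_on_real_fold(self, reference_fit):
        # two hairpins joined by a linker: not a single simple hairpin
        rng = np.random.default_rng(8)
        h1 = random_hairpin(12, 5, 100, rng).residues
        h2 = random_hairpin(12, 5, 100, rng).residues
        rec = characterize_hairpin(RnaSequence("two_hairpins", h1 + "CUCUCU" + h2))
        a = assess_retention(rec, reference_fit)
        assert not a.checks["topology"].passed


class TestInsertion:
    def test_position_bounds_validated(self):
        ctx = RnaSequence("ctx", "ACGUACGUAC")
        with pytest.raises(DesignError):
            InsertionPlan(context=ctx, position=11, insert=None)
        with pytest.raises(DesignError):
            InsertionPlan(context=ctx, position=-1, insert=None)

    def test_modified_sequence_composition(self):
        ctx = RnaSequence("ctx", "AAAACCCC")
        ins = RnaSequence("ins", "GGG")
        plan = InsertionPlan(context=ctx, position=4, insert=ins)
        assert plan.modified_sequence().residues == "AAAAGGGCCCC"

    def test_empty_insert_changes_nothing(self, rng):
        ctx, _ = synth_backbone(2, 15, rng)
        before, after, delta = regional_ape_change(
            InsertionPlan(context=ctx, position=7, insert=None)
        )
        assert delta == 0.0
        assert before == after

    def test_unstructured_insert_raises_regional_ape(self):
        ctx, _ = synth_backbone(3, 20, np.random.default_rng(3))
        ins = RnaSequence("caa60", "CAA" * 20)
        _, _, delta = regional_ape_change(
            InsertionPlan(context=ctx, position=10, insert=ins)
        )
        assert delta > 0

    def test_strong_hairpin_insert_leaves_region_unchanged(self):
        ctx, _ = synth_backbone(3, 20, np.random.default_rng(3))
        ins = random_hairpin(10, 5, 100, np.random.default_rng(5), seq_id="hp25")
        _, _, delta = regional_ape_change(
            InsertionPlan(context=ctx, position=10, insert=ins)
        )
        assert abs(delta) < 0.1


GC_RICH_ARM = "GCGGCCGCAUGGCCGGAUCCGGCACGGC"  # 28 nt


class TestDesignMimic:
    def test_reaches_target_and_reverifies_by_refolding(self):
        arm = RnaSequence("arm", GC_RICH_ARM)
        rec, trace = design_mimic(arm, target_dg=-29.9, tolerance=2.0,
                                  rng=np.random.default_rng(11), max_iter=400)
        assert abs(rec.delta_g - (-29.9)) <= 2.0
        assert rec.simple_hairpin
        # internal consistency: refolding reproduces the reported energy
        refold = fold(rec.sequence)
        assert refold.delta_g == rec.delta_g
        assert rec.sequence.residues.startswith(GC_RICH_ARM)

    def test_unreachable_target_fails_explicitly(self):
        arm = RnaSequence("arm15", "GCGCGCGCAUGCGCG")
        with pytest.raises(MimicDesignError):
            design_mimic(arm, target_dg=-100.0, tolerance=2.0,
                         rng=np.random.default_rng(1), max_iter=60)

    def test_start_within_tolerance_returns_unchanged(self):
        arm = RnaSequence("arm", GC_RICH_ARM)
        start = characterize_hairpin(
            RnaSequence("s", GC_RICH_ARM + "UAAC" + reverse_complement(GC_RICH_ARM))
        )
        rec, trace = design_mimic(arm, target_dg=start.delta_g, tolerance=1.0,
                                  rng=np.random.default_rng(0), max_iter=10)
        assert len(trace) == 1 and trace[0]["move"] == "start"
        assert rec.sequence.residues == start.sequence.residues

    def test_deterministic_given_seed(self):
        arm = RnaSequence("arm", GC_RICH_ARM)
        r1, _ = design_mimic(arm, -29.9, 2.0, rng=np.random.default_rng(11), max_iter=400)
        r2, _ = design_mimic(arm, -29.9, 2.0, rng=np.random.default_rng(11), max_iter=400)
        assert r1.sequence.residues == r2.sequence.residues

    def test_mismatches_never_stabilize_a_perfect_stem(self):
        """Forcing a true mismatch (a base that can form neither a
        Watson-Crick nor a G:U wobble pair with its mirror) into a fully
        paired stem never makes the fold more stable, over 100 seeded
        trials."""
        from rnaplast.sequences import WC_COMPLEMENT
        from rnaplast.simulate import BASES

        wobble = {"G": "U", "U": "G", "A": None, "C": None}
        r = np.random.default_rng(21)
        for _ in range(100):
            seq = random_hairpin(12, 5, 100, r, seq_id="p")
            base_dg = fold(seq).delta_g
            k = int(r.integers(0, 12))
            arm5, loop, arm3 = seq.residues[:12], seq.residues[12:17], list(seq.residues[17:])
            mirror = arm5[12 - 1 - k]
            choices = [b for b in BASES
                       if b != WC_COMPLEMENT[mirror] and b != wobble[mirror]]
            arm3[k] = choices[int(r.integers(0, len(choices)))]
            mutated = RnaSequence("m", arm5 + loop + "".join(arm3))
            assert fold(mutated).delta_g >= base_dg


class TestRecommendedDg:
    @pytest.mark.parametrize("length,expected", [(160, -70.04), (61, -28.46), (0, -2.84)])
    def test_point_from_published_line(self, reference_fit, length, expected):
        pr = recommended_dg(length, reference_fit)
        assert pr.point == pytest.approx(expected, abs=1e-9)
        assert pr.lower <= pr.point <= pr.upper
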