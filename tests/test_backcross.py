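"""Tests for backcross simulation, block inference, donor fractions and
duplication detection."""

import math

import numpy as np
import pandas as pd
import pytest

import lipidqtl as lq
from lipidqtl.backcross_analysis import UNASSIGNED
from lipidqtl.synthetic_cross import AWRI, BY, ORIGIN_LABELS


def calls_from(chrom_pos_calls, seg_id="seg"):
    df = pd.DataFrame(chrom_pos_calls, columns=["chrom", "pos", "call"])
    return lq.SegregantCalls(seg_id, df)


def variant_map_at(positions, length=1000, chrom="c1"):
    pos = np.asarray(positions, dtype=np.int64)
    return lq.VariantMap(
        {chrom: length},
        {chrom: pos},
        {chrom: np.full(pos.size, "A")},
        {chrom: np.full(pos.size, "C")},
    )


def blocks_oracle(positions, calls, length, min_run):
    """Exhaustive scan oracle: list (start, end, origin_label) tiling [0, length)."""
    runs = []
    i = 0
    while i < len(calls):
        j = i
        while j < len(calls) and calls[j] == calls[i]:
            j += 1
        if j - i >= min_run:
            runs.append((positions[i] - 1, positions[j - 1], ORIGIN_LABELS[calls[i]]))
        i = j
    out, cursor = [], 0
    for start, end, lab in runs:
        if start > cursor:
            out.append((cursor, start, UNASSIGNED))
        out.append((start, end, lab))
        cursor = end
    if cursor < length:
        out.append((cursor, length, UNASSIGNED))
    return out


class TestInferBlocks:
    def test_five_consecutive_snvs_make_a_block(self):
        """Five BY calls at 100..500 on a 1 kb chromosome: one BY block [99,500)
        between the furthest two SNVs, flanked by unassigned."""
        vmap = variant_map_at([100, 200, 300, 400, 500])
        calls = calls_from([("c1", p, BY) for p in (100, 200, 300, 400, 500)])
        blocks = lq.infer_blocks(calls, vmap, min_run=5)
        assert [(b.start, b.end, b.origin) for b in blocks] == [
            (0, 99, UNASSIGNED),
            (99, 500, "BY"),
            (500, 1000, UNASSIGNED),
        ]
        assert blocks[1].n_supporting_snvs == 5

    def test_four_consecutive_calls_stay_unassigned(self):
        vmap = variant_map_at([100, 200, 300, 400])
        calls = calls_from([("c1", p, AWRI) for p in (100, 200, 300, 400)])
        blocks = lq.infer_blocks(calls, vmap, min_run=5)
        assert all(b.origin == UNASSIGNED for b in blocks)

    def test_blocks_tile_chromosome(self):
        vmap = variant_map_at(list(range(10, 1000, 37)))
        rng = np.random.default_rng(1)
        calls = calls_from(
            [("c1", p, int(rng.integers(2))) for p in range(10, 1000, 37)]
        )
        blocks = lq.infer_blocks(calls, vmap, min_run=3)
        cursor = 0
        for b in blocks:
            assert b.start == cursor
            cursor = b.end
        assert cursor == 1000

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_scan_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        n = int(rng.integers(5, 80))
        positions = np.sort(rng.choice(5000, size=n, replace=False)) + 1
        call_vals = rng.integers(0, 2, size=n)
        vmap = variant_map_at(positions, length=6000)
        calls = calls_from([("c1", int(p), int(c)) for p, c in zip(positions, call_vals)])
        blocks = lq.infer_blocks(calls, vmap, min_run=5)
        expected = blocks_oracle(list(positions), list(call_vals), 6000, 5)
        assert [(b.start, b.end, b.origin) for b in blocks] == expected

    def test_error_free_dense_calls_recover_generating_mosaic(self, tiny_map, tiny_gmap):
        mosaic = lq.simulate_meiosis(tiny_map, tiny_gmap, seed=5)
        calls = lq.simulate_segregant_calls(mosaic, tiny_map, seed=6)
        blocks = lq.infer_blocks(calls, tiny_map, min_run=5)
        # every assigned block matches the true origin throughout its span
        for b in blocks:
            if b.origin == UNASSIGNED:
                continue
            probe = np.arange(b.start + 1, b.end + 1, 997)
            truth = mosaic.origin_at(b.chrom, probe)
            assert np.all(truth == lq.synthetic_cross.origin_code(b.origin))

    def test_regenerated_calls_reach_a_fixed_point(self):
        """Re-running inference on error-free calls regenerated from the
        inferred blocks is idempotent: the second pass is a fixed point, and
        assigned coverage never shrinks or changes origin."""

        def regenerate(blocks, positions):
            regen = []
            for b in blocks:
                if b.origin == UNASSIGNED:
                    continue
                code = lq.synthetic_cross.origin_code(b.origin)
                for p in positions[(positions - 1 >= b.start) & (positions - 1 < b.end)]:
                    regen.append(("c1", int(p), code))
            return calls_from(regen)

        def origin_at(blocks, coord):
            for b in blocks:
                if b.start <= coord < b.end:
                    return b.origin
            return None

        for seed in (9, 10, 11):
            rng = np.random.default_rng(seed)
            positions = np.sort(rng.choice(5000, size=60, replace=False)) + 1
            call_vals = rng.integers(0, 2, size=60)
            vmap = variant_map_at(positions, length=6000)
            calls = calls_from([("c1", int(p), int(c)) for p, c in zip(positions, call_vals)])
            b1 = lq.infer_blocks(calls, vmap, min_run=5)
            b2 = lq.infer_blocks(regenerate(b1, positions), vmap, min_run=5)
            b3 = lq.infer_blocks(regenerate(b2, positions), vmap, min_run=5)
            assert [(b.start, b.end, b.origin) for b in b2] == [
                (b.start, b.end, b.origin) for b in b3
            ]
            # assigned bp keep their origin through regeneration
            for b in b1:
                if b.origin != UNASSIGNED:
                    for coord in (b.start, (b.start + b.end) // 2, b.end - 1):
                        assert origin_at(b2, coord) == b.origin

    def test_midpoint_boundary_mode(self):
        vmap = variant_map_at([100, 200, 300, 400, 500, 600, 700, 800, 900, 950])
        seq = [BY] * 5 + [AWRI] * 5
        calls = calls_from([("c1", p, c) for p, c in zip([100, 200, 300, 400, 500, 600, 700, 800, 900, 950], seq)])
        blocks = lq.infer_blocks(calls, vmap, min_run=5, boundary="midpoint")
        assert [(b.start, b.end, b.origin) for b in blocks] == [
            (0, 550, "BY"),
            (550, 1000, "AWRI"),
        ]

    def test_calls_off_map_rejected(self):
        vmap = variant_map_at([100, 200])
        calls = calls_from([("c1", 150, BY)])
        with pytest.raises(ValueError):
            lq.infer_blocks(calls, vmap)


class TestDonorFraction:
    def test_all_and_none(self):
        blocks = [lq.HaplotypeBlock("c1", 0, 1000, "AWRI", 10)]
        assert lq.donor_fraction(blocks, "AWRI") == 100.0
        assert lq.donor_fraction(blocks, "BY") == 0.0

    def test_matches_base_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            cuts = np.sort(rng.choice(np.arange(1, 10000), size=6, replace=False))
            bounds = np.concatenate(([0], cuts, [10000]))
            labels = rng.choice(["BY", "AWRI", UNASSIGNED], size=bounds.size - 1)
            blocks = [
                lq.HaplotypeBlock("c1", int(s), int(e), lab, 5)
                for s, e, lab in zip(bounds[:-1], bounds[1:], labels)
            ]
            base_count = sum(e - s for s, e, lab in zip(bounds[:-1], bounds[1:], labels) if lab == "AWRI")
            assert lq.donor_fraction(blocks, "AWRI") == pytest.approx(100 * base_count / 10000)

    def test_assigned_denominator(self):
        blocks = [
            lq.HaplotypeBlock("c1", 0, 400, "AWRI", 5),
            lq.HaplotypeBlock("c1", 400, 600, UNASSIGNED, 0),
            lq.HaplotypeBlock("c1", 600, 1000, "BY", 5),
        ]
        assert lq.donor_fraction(blocks, "AWRI", denominator="assigned") == pytest.approx(50.0)
        assert lq.donor_fraction(blocks, "AWRI", denominator="genome") == pytest.approx(40.0)

    def test_assigned_denominator_without_assigned_blocks_errors(self):
        blocks = [lq.HaplotypeBlock("c1", 0, 1000, UNASSIGNED, 0)]
        with pytest.raises(ValueError):
            lq.donor_fraction(blocks, "AWRI", denominator="assigned")
        assert lq.donor_fraction(blocks, "AWRI", denominator="genome") == 0.0

    def test_excluded_duplicated_region(self):
        blocks = [
            lq.HaplotypeBlock("c1", 0, 500, "AWRI", 5),
            lq.HaplotypeBlock("c1", 500, 1000, "BY", 5),
        ]
        frac = lq.donor_fraction(blocks, "AWRI", exclude=[("c1", 0, 250)])
        assert frac == pytest.approx(100 * 250 / 750)


class TestExpectedDonorFraction:
    def test_first_generation_is_half(self):
        assert lq.expected_donor_fraction(1) == 50.0

    def test_seventh_generation_prints_as_0_8_pct(self):
        val = lq.expected_donor_fraction(7)
        assert val == pytest.approx(0.78125)
        assert round(val, 1) == 0.8

    def test_halving_recurrence(self):
        for g in range(1, 12):
            assert lq.expected_donor_fraction(g + 1) == lq.expected_donor_fraction(g) / 2


class TestRunBackcross:
    @pytest.fixture()
    def setup(self, tiny_map, tiny_gmap):
        founder = lq.simulate_meiosis(tiny_map, tiny_gmap, seed=30)
        model = lq.TraitModel(100.0, noise_sd=5.0)
        return founder, model, tiny_map, tiny_gmap

    def test_founder_only_at_one_generation(self, setup):
        founder, model, vmap, gmap = setup
        recs = lq.run_backcross(founder, "BY", vmap, gmap, model, generations=1, seed=1)
        assert len(recs) == 1 and recs[0].generation == 1
        assert recs[0].donor_fraction_pct == pytest.approx(100 * founder.fraction(AWRI))

    def test_generation_structure_and_determinism(self, setup):
        founder, model, vmap, gmap = setup
        kwargs = dict(generations=4, n_per_gen=12, seed=2)
        recs = lq.run_backcross(founder, "BY", vmap, gmap, model, **kwargs)
        assert [r.generation for r in recs] == [1, 2, 3, 4]
        recs2 = lq.run_backcross(founder, "BY", vmap, gmap, model, **kwargs)
        assert [r.donor_fraction_pct for r in recs] == [r.donor_fraction_pct for r in recs2]

    def test_donor_fraction_decays_towards_drift_expectation(self, setup):
        """Zero-effect selection: mean donor fraction tracks 100*(1/2)^g."""
        founder, model, vmap, gmap = setup
        rng = np.random.default_rng(3)
        finals = {2: [], 4: []}
        for _ in range(60):
            recs = lq.run_backcross(founder, "BY", vmap, gmap, model, generations=4, n_per_gen=8, seed=rng)
            finals[2].append(recs[1].donor_fraction_pct)
            finals[4].append(recs[3].donor_fraction_pct)
        for g, vals in finals.items():
            vals = np.array(vals)
            se = vals.std(ddof=1) / math.sqrt(vals.size)
            assert abs(vals.mean() - lq.expected_donor_fraction(g)) < 3 * max(se, 0.2)

    def test_strong_qtl_region_is_retained(self, setup):
        """With one strong AWRI-beneficial locus, backcrossing to BY under
        top-FI selection keeps the donor region around the locus."""
        founder, _, vmap, gmap = setup
        pos = vmap.positions["c1"]
        locus = ("c1", int(pos[len(pos) // 2]))
        model = lq.TraitModel(100.0, [(locus[0], locus[1], 0.0, 30.0)], noise_sd=3.0)
        # founder must carry the beneficial allele for it to be retainable
        founder_aw = lq.Mosaic.uniform(AWRI, vmap.chrom_lengths)
        rng = np.random.default_rng(4)
        kept = 0
        donor_frs = []
        for _ in range(10):
            recs = lq.run_backcross(
                founder_aw, "BY", vmap, gmap, model, generations=5, n_per_gen=30, seed=rng
            )
            final = recs[-1].mosaic
            kept += final.origin_at(*locus) == AWRI
            donor_frs.append(recs[-1].donor_fraction_pct)
        assert kept >= 9
        assert np.mean(donor_frs) > lq.expected_donor_fraction(5)

    def test_marker_regions_always_retained(self, setup):
        """Marker loci forced from the recurrent... rather, the marker-bearing
        parent are present in every generation's selected segregant."""
        _, model, vmap, gmap = setup
        marker = ("c1", 150000)
        # the F1 founder itself survived marker selection, so it is BY there
        candidates = lq.simulate_f1_segregants(vmap, gmap, 50, seed=55)
        founder = lq.apply_marker_selection(candidates, [marker], BY)[0]
        rng = np.random.default_rng(5)
        for _ in range(5):
            recs = lq.run_backcross(
                founder, "AWRI", vmap, gmap, model, generations=4, n_per_gen=12,
                marker_loci=[marker], marker_origin=BY, seed=rng,
            )
            for rec in recs[1:]:
                assert rec.mosaic.origin_at(*marker) == BY

    def test_infer_route_populates_blocks(self, setup):
        founder, model, vmap, gmap = setup
        recs = lq.run_backcross(
            founder, "BY", vmap, gmap, model, generations=2, n_per_gen=6, seed=6, infer=True
        )
        assert recs[-1].blocks is not None
        total = sum(b.length for b in recs[-1].blocks)
        assert total == sum(vmap.chrom_lengths.values())
        # inferred donor fraction close to the true mosaic fraction (dense SNVs)
        truth = 100 * recs[-1].mosaic.fraction(AWRI)
        assert recs[-1].donor_fraction_pct == pytest.approx(truth, abs=2.0)

    def test_impossible_marker_errors_out(self, setup):
        founder, model, vmap, gmap = setup
        founder_aw = lq.Mosaic.uniform(AWRI, vmap.chrom_lengths)
        # recurrent parent AWRI and founder AWRI: no child can ever be BY here
        with pytest.raises(RuntimeError):
            lq.run_backcross(
                founder_aw, "AWRI", vmap, gmap, model, generations=2, n_per_gen=4,
                marker_loci=[("c1", 1000)], marker_origin=BY, seed=7, max_batches=3,
            )


class TestDetectDuplication:
    def test_uniform_depth_no_calls(self):
        depth = lq.simulate_depth_track({"c1": 500000}, mean_depth=30, seed=1)
        assert lq.detect_duplication(depth) == []

    def test_planted_two_fold_segment_recovered(self):
        """A 200 kb segment at 2x depth yields one call covering >=90% of it."""
        lengths = {"c1": 948066}
        dup = ("c1", 300000, 500000, 2.0)
        depth = lq.simulate_depth_track(lengths, mean_depth=30, dup_regions=[dup], seed=2)
        calls = lq.detect_duplication(depth, fold_threshold=1.5, min_len=50000)
        assert len(calls) == 1
        call = calls[0]
        overlap = min(call.end, dup[2]) - max(call.start, dup[1])
        assert overlap >= 0.9 * (dup[2] - dup[1])
        assert call.mean_fold == pytest.approx(2.0, rel=0.1)

    def test_infinite_threshold_no_calls(self):
        depth = lq.simulate_depth_track({"c1": 200000}, dup_regions=[("c1", 0, 200000, 3.0)], seed=3)
        assert lq.detect_duplication(depth, fold_threshold=math.inf) == []

    def test_short_gain_below_min_len_ignored(self):
        depth = lq.simulate_depth_track(
            {"c1": 500000}, mean_depth=30, dup_regions=[("c1", 100000, 120000, 2.0)], seed=4
        )
        assert lq.detect_duplication(depth, min_len=50000) == []

    def test_all_zero_depth_rejected(self):
        depth = pd.DataFrame({"chrom": "c1", "start": [0], "end": [5000], "depth": [0.0]})
        with pytest.raises(ValueError):
            lq.detect_duplication(depth)


def test_lineage_summary_table(tiny_map, tiny_gmap):
    founder = lq.simulate_meiosis(tiny_map, tiny_gmap, seed=40)
    model = lq.TraitModel(100.0, noise_sd=1.0)
    recs = lq.run_backcross(founder, "BY", tiny_map, tiny_gmap, model, generations=3, n_per_gen=5, seed=41)
    df = lq.lineage_summary(recs)
    assert df["generation"].tolist() == [1, 2, 3]
    assert df["expected_pct"].tolist() == [50.0, 25.0, 12.5]
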