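import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from distrank import combine, metrics, synth
from distrank.ranking import ModelPool, Ranking
from distrank.structio import Structure


def shifted(s: Structure, delta: np.ndarray) -> Structure:
    return Structure(s.target_id, s.sequence, s.residue_index,
                     s.ca_coords + delta)


def rigid(s: Structure, seed: int) -> Structure:
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    return Structure(s.target_id, s.sequence, s.residue_index,
                     s.ca_coords @ rot.T + rng.normal(scale=10.0, size=3))


@pytest.fixture(scope="module")
def scene(native30):
    """Pool of near-copies and far decoys with a known ranking."""
    near = synth.make_decoys(
        native30, synth.DecoySpec(n_decoys=25, noise_levels=(0.4,), seed=31))
    far = synth.make_decoys(
        native30, synth.DecoySpec(n_decoys=3, noise_levels=(25.0,), seed=32))
    ids = ["ref"] + [f"n{i}" for i in range(25)] + [f"f{i}" for i in range(3)]
    models = [native30] + near.models + far.models
    pool = ModelPool(target_id="t", model_ids=ids, models=models)
    ranking = Ranking(entries=[(m, 1.0 - 0.01 * k)
                               for k, m in enumerate(ids)])
    return pool, ranking


class TestSelectCombinationSet:
    def test_rank_beyond_top_n_excluded(self, native30):
        # 70 identical models: every one qualifies on similarity, but only
        # those ranked within the top-60 window are eligible
        ids = ["ref"] + [f"m{i:02d}" for i in range(70)]
        pool = ModelPool(target_id="t", model_ids=ids,
                         models=[native30] * 71)
        rk = Ranking(entries=[(m, 1.0 - 0.001 * k)
                              for k, m in enumerate(ids)])
        got = combine.select_combination_set("ref", pool, rk, cap=100)
        assert "m63" not in got          # rank 65 > 60
        assert "m10" in got

    def test_similar_top_ranked_model_included(self, scene):
        pool, rk = scene
        got = combine.select_combination_set("ref", pool, rk)
        assert "n0" in got

    def test_dissimilar_model_excluded(self, scene):
        pool, rk = scene
        got = combine.select_combination_set("ref", pool, rk)
        assert not any(m.startswith("f") for m in got)

    def test_cap_20_in_rank_order(self, scene):
        pool, rk = scene
        got = combine.select_combination_set("ref", pool, rk)
        assert len(got) == 20
        assert got == [f"n{i}" for i in range(20)]

    def test_monotone_in_gdt_min(self, scene):
        pool, rk = scene
        loose = combine.select_combination_set(
            "ref", pool, rk, gdt_min=0.5, rmsd_max=None, cap=100)
        tight = combine.select_combination_set(
            "ref", pool, rk, gdt_min=0.95, rmsd_max=None, cap=100)
        assert set(tight) <= set(loose)

    def test_empty_set_allowed_for_hard_targets(self, native30):
        far = synth.make_decoys(
            native30, synth.DecoySpec(n_decoys=3, noise_levels=(30.0,),
                                      seed=33))
        pool = ModelPool(target_id="t", model_ids=["ref"] + far.model_ids,
                         models=[native30] + far.models)
        rk = Ranking(entries=[(m, 1.0 - 0.01 * k) for k, m in
                              enumerate(pool.model_ids)])
        assert combine.select_combination_set("ref", pool, rk) == []


class TestConsensusCombine:
    def test_identical_members_return_reference(self, native30):
        cand = combine.consensus_combine(native30, [native30, native30])
        np.testing.assert_allclose(cand.ca_coords, native30.ca_coords,
                                   atol=1e-9)

    def test_symmetric_members_cancel(self, native30):
        rng = np.random.default_rng(0)
        delta = rng.normal(scale=0.5, size=native30.ca_coords.shape)
        # members at +delta and -delta around the reference average back
        # to the reference (their optimal superpositions mirror each other
        # only approximately, hence the loose tolerance)
        cand = combine.consensus_combine(
            native30, [shifted(native30, delta), shifted(native30, -delta)])
        rms = np.sqrt(np.mean(np.sum(
            (cand.ca_coords - native30.ca_coords) ** 2, axis=1)))
        assert rms < 0.2

    def test_empty_members_warns_and_returns_reference(self, native30):
        with pytest.warns(UserWarning, match="no members"):
            cand = combine.consensus_combine(native30, [])
        assert cand is native30

    def test_matches_independent_superposition_oracle(self, native30):
        """Five rigidly moved decoys: candidate equals the mean after
        superposing each with scipy's independent Kabsch."""
        decoys = [rigid(d, 40 + k) for k, d in enumerate(synth.make_decoys(
            native30, synth.DecoySpec(n_decoys=5, noise_levels=(1.0,),
                                      seed=35)).models)]
        cand = combine.consensus_combine(native30, decoys)
        stack = [native30.ca_coords]
        for d in decoys:
            a, b = d.ca_coords, native30.ca_coords
            ac, bc = a.mean(0), b.mean(0)
            rot, _ = Rotation.align_vectors(b - bc, a - ac)
            stack.append((a - ac) @ rot.as_matrix().T + bc)
        np.testing.assert_allclose(cand.ca_coords, np.mean(stack, axis=0),
                                   atol=1e-6)

    def test_averaging_moves_toward_truth(self, native30):
        """Consensus of symmetric decoys lies closer to the truth than the
        average member — the mechanism that makes combination pay off."""
        wins = 0
        for seed in range(10):
            decoys = synth.make_decoys(
                native30, synth.DecoySpec(n_decoys=8, noise_levels=(2.0,),
                                          mode_share=0.0,
                                          seed=50 + seed)).models
            cand = combine.consensus_combine(decoys[0], decoys[1:])
            cand_rmsd = metrics.superpose(cand, native30).rmsd
            member_rmsd = np.mean([
                metrics.superpose(d, native30).rmsd for d in decoys])
            wins += cand_rmsd < member_rmsd
        assert wins >= 9


class TestAcceptCandidate:
    def test_identical_candidate_accepted(self, native30):
        assert combine.accept_candidate(native30, native30) == "accepted"

    def test_drifted_candidate_rejected(self, native30):
        drifted = synth.make_decoys(
            native30, synth.DecoySpec(n_decoys=2, noise_levels=(6.0,),
                                      seed=36)).models[0]
        assert metrics.gdt_ts(drifted, native30) < 0.9
        assert combine.accept_candidate(drifted, native30) == "rejected"

    def test_zero_threshold_always_accepts(self, native30):
        drifted = synth.make_decoys(
            native30, synth.DecoySpec(n_decoys=2, noise_levels=(9.0,),
                                      seed=37)).models[0]
        assert combine.accept_candidate(drifted, native30, threshold=0.0) \
            == "accepted"


class TestSpliceRegions:
    def test_identical_donor_is_noop(self, native30):
        out, rep = combine.splice_regions(native30, native30, (10, 20))
        np.testing.assert_allclose(out.ca_coords, native30.ca_coords,
                                   atol=1e-6)

    def test_keep_coordinates_preserved_bitwise(self, native30, pool30):
        donor = pool30.models[0]
        out, _ = combine.splice_regions(native30, donor, (10, 20))
        keep_mask = (native30.residue_index < 10) | (native30.residue_index > 20)
        np.testing.assert_array_equal(
            out.ca_coords[keep_mask], native30.ca_coords[keep_mask])

    def test_rigidly_moved_donor_gives_clean_junctions(self, native30):
        donor = rigid(native30, 77)
        out, rep = combine.splice_regions(native30, donor, (10, 20))
        assert not rep.breaks

    def test_whole_chain_region_rejected(self, native30):
        with pytest.raises(ValueError):
            combine.splice_regions(native30, native30, (1, len(native30)))

    def test_region_outside_structure_rejected(self, native30):
        with pytest.raises(ValueError):
            combine.splice_regions(native30, native30, (25, 60))


class TestProtocol:
    def test_full_protocol_accepts_tight_pool(self, scene):
        pool, rk = scene
        plan = combine.combine_for_reference("ref", pool, rk, preset="human")
        assert plan.acceptance == "accepted"
        assert plan.candidate_gdt >= 0.9
        assert len(plan.member_ids) == 20
        assert plan.reference_id not in plan.member_ids

    def test_presets_differ(self):
        assert combine.PRESETS["server"]["gdt_min"] == 0.6
        assert combine.PRESETS["human"]["gdt_min"] == 0.7
        assert combine.PRESETS["human"]["rmsd_max"] == 3.0
        assert combine.PRESETS["human"]["top_n"] == 60
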