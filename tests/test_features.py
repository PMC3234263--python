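"""Weighting factors, patches, PSSM encodings, propensities, assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbpsite.features import (
    AA_ORDER,
    FEATURE_SETS,
    PssmProfile,
    WEIGHT_SCHEMES,
    assemble_feature_vector,
    build_surface_patch,
    c_pssm,
    feature_names,
    interface_propensity_table,
    read_pssm,
    rw_pssm,
    scale_pssm,
    weighted_scalar_feature,
    weighting_factor,
    write_pssm,
)
from dbpsite.structure import Atom, Residue


def _res(num, name="ALA", ca=(0.0, 0.0, 0.0), chain="A"):
    return Residue(
        chain, num, "", name, [Atom("CA", "C", ca, True)], "protein"
    )


class TestWeightingFactor:
    @pytest.mark.parametrize("scheme", sorted(WEIGHT_SCHEMES))
    def test_central_residue_weight_is_one(self, scheme):
        assert weighting_factor(0.0, scheme) == pytest.approx(1.0)

    def test_default_reciprocal_value(self):
        assert weighting_factor(3.8) == pytest.approx(1 / 4.8, abs=1e-4)

    @pytest.mark.parametrize("scheme", sorted(WEIGHT_SCHEMES))
    def test_strictly_decreasing(self, scheme):
        assert weighting_factor(2.0, scheme) > weighting_factor(5.0, scheme)

    @settings(derandomize=True, max_examples=50)
    @given(
        d1=st.floats(0.0, 40.0),
        d2=st.floats(0.0, 40.0),
        scheme=st.sampled_from(sorted(WEIGHT_SCHEMES)),
    )
    def test_monotone_and_bounded_property(self, d1, d2, scheme):
        lo, hi = sorted((d1, d2))
        w_lo, w_hi = weighting_factor(lo, scheme), weighting_factor(hi, scheme)
        assert 0.0 < w_hi <= w_lo <= 1.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            weighting_factor(-1.0)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(KeyError):
            weighting_factor(1.0, "cubic")


class TestScalePssm:
    def test_logistic_values(self):
        profile = PssmProfile(
            matrix=np.array([[0.0] * 20, [10.0] * 20]), sequence="AA"
        )
        scaled = scale_pssm(profile)
        assert scaled.matrix[0, 0] == pytest.approx(0.5)
        assert scaled.matrix[1, 0] == pytest.approx(1 / (1 + math.e**-10), abs=1e-9)
        assert scaled.matrix[1, 0] > 0.9999

    @settings(derandomize=True, max_examples=30)
    @given(x=st.floats(-30, 30))
    def test_logistic_symmetry(self, x):
        profile = PssmProfile(
            matrix=np.array([[x] * 20, [-x] * 20]), sequence="AA"
        )
        scaled = scale_pssm(profile)
        assert scaled.matrix[0, 0] + scaled.matrix[1, 0] == pytest.approx(1.0)


class TestPssmIo:
    PSI_BLAST_SNIPPET = "\n".join(
        [
            "",
            "Last position-specific scoring matrix computed, weighted observed ...",
            "            A   R   N   D   C   Q   E   G   H   I   L   K   M   F"
            "   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I"
            "   L   K   M   F   P   S   T   W   Y   V",
            "    1 M    -2  -2  -3  -4  -2  -1  -3  -4  -3   1   2  -2   8   0"
            "  -3  -2  -1  -2  -2   0   0   0   0   0   0   0   0   0   0   0"
            "   0   0  46   0   0   0   0   0   0   0",
            "    2 K    -1   2   0  -1  -4   1   1  -2  -1  -3  -3   5  -2  -4"
            "  -1   0  -1  -4  -2  -3   0  12   0   0   0   6   6   0   0   0"
            "   0  64   0   0   0   5   0   0   0   0",
        ]
    )

    def test_reads_first_20_columns(self):
        profile = read_pssm(self.PSI_BLAST_SNIPPET)
        assert profile.matrix.shape == (2, 20)
        assert profile.sequence == "MK"
        assert profile.matrix[0, AA_ORDER.index("M")] == 8
        assert profile.matrix[1, AA_ORDER.index("K")] == 5

    def test_round_trip_through_writer(self):
        profile = read_pssm(self.PSI_BLAST_SNIPPET)
        again = read_pssm(write_pssm(profile))
        np.testing.assert_array_equal(profile.matrix, again.matrix)
        assert again.sequence == "MK"

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="no PSSM rows"):
            read_pssm("nothing here\n")

    def test_attach_checks_sequence_consistency(self):
        profile = read_pssm(self.PSI_BLAST_SNIPPET)
        good = [_res(1, "MET"), _res(2, "LYS", ca=(3.8, 0, 0))]
        attached = profile.attach(good)
        assert attached.keys == [r.key for r in good]
        bad = [_res(1, "MET"), _res(2, "ALA", ca=(3.8, 0, 0))]
        with pytest.raises(ValueError, match="mismatch"):
            profile.attach(bad)


class TestSurfacePatch:
    def test_truncates_to_available_surface_residues(self):
        residues = [_res(i + 1, ca=(4.0 * i, 0, 0)) for i in range(5)]
        patch = build_surface_patch(residues[0], residues, L=25)
        assert patch.size == 5

    def test_members_match_brute_force_sort(self, rng):
        coords = rng.uniform(0, 20, size=(15, 3))
        residues = [_res(i + 1, ca=c) for i, c in enumerate(coords)]
        central = residues[4]
        patch = build_surface_patch(central, residues, L=5)
        dists = sorted(
            (float(np.linalg.norm(c - coords[4])), i)
            for i, c in enumerate(coords)
            if i != 4
        )
        expected = [central.key] + [residues[i].key for _, i in dists[:4]]
        assert patch.members == expected
        assert patch.distances[0] == 0.0
        assert patch.weights[0] == 1.0

    def test_single_member_patch(self):
        central = _res(1)
        patch = build_surface_patch(central, [central], L=1)
        assert patch.members == [central.key]
        np.testing.assert_array_equal(patch.distances, [0.0])
        np.testing.assert_array_equal(patch.weights, [1.0])

    def test_distance_ties_broken_by_sequence_index(self):
        central = _res(5, ca=(0, 0, 0))
        left = _res(2, ca=(-4.0, 0, 0))
        right = _res(9, ca=(4.0, 0, 0))
        patch = build_surface_patch(central, [central, right, left], L=2)
        assert patch.members == [central.key, left.key]

    def test_non_surface_central_rejected(self):
        central = _res(1)
        with pytest.raises(ValueError, match="not a surface residue"):
            build_surface_patch(central, [_res(2, ca=(4, 0, 0))], L=5)


def _patch_and_profile():
    """Five-residue patch (central 16K with neighbors 17S, 15S, 19K, 13A)
    and a hand-made scaled profile with constant rows."""
    central = _res(16, "LYS", ca=(0, 0, 0))
    neighbors = [
        _res(17, "SER", ca=(3.8, 0, 0)),
        _res(15, "SER", ca=(0, 4.2, 0)),
        _res(19, "LYS", ca=(0, 0, 6.0)),
        _res(13, "ALA", ca=(0, -8.1, 0)),
    ]
    rows = {16: 0.5, 17: 0.2, 15: 0.4, 19: 0.6, 13: 0.8}
    residues = sorted([central] + neighbors, key=lambda r: r.seq_index)
    profile = PssmProfile(
        matrix=np.array([[rows[r.seq_index]] * 20 for r in residues]),
        sequence="".join(r.one_letter for r in residues),
        keys=[r.key for r in residues],
        scaled=True,
    )
    patch = build_surface_patch(central, [central] + neighbors, L=5)
    return patch, profile


class TestRwPssm:
    def test_constant_profile_averages_to_constant(self):
        patch, profile = _patch_and_profile()
        const = PssmProfile(
            matrix=np.full((5, 20), 0.5),
            sequence=profile.sequence,
            keys=profile.keys,
            scaled=True,
        )
        vec = rw_pssm(patch, const)
        np.testing.assert_allclose(vec, 0.5)

    def test_hand_computed_weighted_average(self):
        patch, profile = _patch_and_profile()
        vec = rw_pssm(patch, profile)
        # neighbors in ascending distance: 17S (3.8), 15S (4.2), 19K (6.0),
        # 13A (8.1); reciprocal weights 1/(1+d)
        w = [1 / 4.8, 1 / 5.2, 1 / 7.0, 1 / 9.1]
        v = [0.2, 0.4, 0.6, 0.8]
        expected = sum(wi * vi for wi, vi in zip(w, v)) / sum(w)
        np.testing.assert_allclose(vec[:20], 0.5)
        np.testing.assert_allclose(vec[20:], expected, rtol=1e-12)

    @pytest.mark.parametrize("L", [1, 5, 25, 35])
    def test_fixed_40_dimension_for_any_patch_size(self, L):
        residues = [_res(i + 1, ca=(4.0 * i, 0, 0)) for i in range(8)]
        profile = PssmProfile(
            matrix=np.full((8, 20), 0.5),
            sequence="A" * 8,
            keys=[r.key for r in residues],
            scaled=True,
        )
        patch = build_surface_patch(residues[0], residues, L=L)
        assert rw_pssm(patch, profile).shape == (40,)

    def test_no_neighbors_gives_zero_average_block(self):
        central = _res(1)
        profile = PssmProfile(
            matrix=np.full((1, 20), 0.7), sequence="A",
            keys=[central.key], scaled=True,
        )
        patch = build_surface_patch(central, [central], L=25)
        vec = rw_pssm(patch, profile)
        np.testing.assert_allclose(vec[:20], 0.7)
        np.testing.assert_allclose(vec[20:], 0.0)

    def test_unscaled_profile_rejected(self):
        patch, profile = _patch_and_profile()
        raw = PssmProfile(
            matrix=profile.matrix, sequence=profile.sequence,
            keys=profile.keys, scaled=False,
        )
        with pytest.raises(ValueError, match="scaled"):
            rw_pssm(patch, raw)

    def test_missing_row_names_residue(self):
        patch, profile = _patch_and_profile()
        short = PssmProfile(
            matrix=profile.matrix[:1], sequence=profile.sequence[:1],
            keys=profile.keys[:1], scaled=True,
        )
        with pytest.raises(KeyError, match="no PSSM row"):
            rw_pssm(patch, short)


class TestCPssm:
    @pytest.mark.parametrize("L,expected", [(25, 500), (1, 20), (5, 100)])
    def test_dimension_is_20_L(self, L, expected):
        patch, profile = _patch_and_profile()
        assert c_pssm(patch, profile, L).shape == (expected,)

    def test_rows_in_ascending_distance_order(self):
        patch, profile = _patch_and_profile()
        vec = c_pssm(patch, profile, 5)
        np.testing.assert_allclose(
            vec.reshape(5, 20)[:, 0], [0.5, 0.2, 0.4, 0.6, 0.8]
        )

    def test_small_patch_zero_padded(self):
        central = _res(1)
        profile = PssmProfile(
            matrix=np.full((1, 20), 0.9), sequence="A",
            keys=[central.key], scaled=True,
        )
        patch = build_surface_patch(central, [central], L=5)
        vec = c_pssm(patch, profile, 5)
        np.testing.assert_allclose(vec[:20], 0.9)
        np.testing.assert_allclose(vec[20:], 0.0)


class TestInterfacePropensity:
    def test_equal_frequencies_give_zero(self):
        labeled = [("ARG", "binding")] * 50 + [("ARG", "nonbinding")] * 50
        labeled += [("ALA", "binding")] * 50 + [("ALA", "nonbinding")] * 50
        table = interface_propensity_table(labeled)
        assert table.values["R"] == pytest.approx(0.0)

    def test_twofold_enrichment_is_one_bit(self):
        # binding: 2000 ARG of 10000; nonbinding: 1000 ARG of 10000
        labeled = (
            [("ARG", "binding")] * 2000
            + [("ALA", "binding")] * 8000
            + [("ARG", "nonbinding")] * 1000
            + [("ALA", "nonbinding")] * 9000
        )
        table = interface_propensity_table(labeled)
        assert table.values["R"] == pytest.approx(1.0, abs=0.01)

    def test_planted_arginine_excess_is_positive(self, toy_complex):
        from dbpsite.surface import annotate_chain

        anns = annotate_chain(toy_complex.protein_residues, toy_complex.dna_residues)
        labeled = [
            (a.residue.parent_name, a.binding_label)
            for a in anns
            if a.is_surface
        ]
        table = interface_propensity_table(labeled)
        assert table.values["R"] > 0 or table.values["K"] > 0

    def test_label_swap_negates_every_value(self):
        labeled = [("ARG", "binding")] * 7 + [("ALA", "nonbinding")] * 13
        swapped = [
            (nm, "binding" if lab == "nonbinding" else "nonbinding")
            for nm, lab in labeled
        ]
        t1 = interface_propensity_table(labeled)
        t2 = interface_propensity_table(swapped)
        for a in AA_ORDER:
            assert t1.values[a] == pytest.approx(-t2.values[a], abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            interface_propensity_table([("ARG", "binding")])


class TestWeightedScalar:
    def test_constant_values_return_constant(self):
        patch, _ = _patch_and_profile()
        values = {k: 3.25 for k in patch.members}
        assert weighted_scalar_feature(patch, values) == pytest.approx(3.25)

    def test_single_member_returns_own_value(self):
        central = _res(1)
        patch = build_surface_patch(central, [central], L=1)
        assert weighted_scalar_feature(patch, {central.key: 7.0}) == 7.0

    def test_hand_computed_average_includes_central(self):
        patch, _ = _patch_and_profile()
        values = dict(zip(patch.members, [1.0, 2.0, 3.0, 4.0, 5.0]))
        w = [1.0, 1 / 4.8, 1 / 5.2, 1 / 7.0, 1 / 9.1]
        expected = sum(wi * vi for wi, vi in zip(w, [1, 2, 3, 4, 5])) / sum(w)
        assert weighted_scalar_feature(patch, values) == pytest.approx(expected)

    def test_missing_value_names_residue(self):
        patch, _ = _patch_and_profile()
        with pytest.raises(KeyError, match="missing value"):
            weighted_scalar_feature(patch, {patch.members[0]: 1.0})

    @settings(derandomize=True, max_examples=30)
    @given(values=st.lists(st.floats(-100, 100), min_size=5, max_size=5))
    def test_average_within_value_range(self, values):
        patch, _ = _patch_and_profile()
        mapping = dict(zip(patch.members, values))
        avg = weighted_scalar_feature(patch, mapping)
        assert min(values) - 1e-9 <= avg <= max(values) + 1e-9

    def test_equal_weights_limit_is_arithmetic_mean(self):
        patch, _ = _patch_and_profile()
        patch.weights = np.ones(patch.size)
        values = dict(zip(patch.members, [1.0, 2.0, 3.0, 4.0, 10.0]))
        assert weighted_scalar_feature(patch, values) == pytest.approx(4.0)


class TestAssembly:
    def _components(self):
        patch, profile = _patch_and_profile()
        labeled = [("LYS", "binding")] * 3 + [("SER", "nonbinding")] * 5 + [
            ("ALA", "nonbinding")
        ] * 4
        table = interface_propensity_table(labeled)
        bc = {k: 0.1 * i for i, k in enumerate(patch.members)}
        sc = {patch.central: 42.0}
        return patch, profile, table, bc, sc

    def test_full_vector_has_43_dimensions(self):
        vec = assemble_feature_vector(*self._components())
        assert vec.values.shape == (43,)
        assert len(vec.names) == 43
        assert vec.values[-1] == 42.0  # central residue's raw ScASA

    @pytest.mark.parametrize(
        "feature_set,expected",
        [("no_rw_pssm", 3), ("no_wip", 42), ("no_wbc", 42), ("no_sc_asa", 42)],
    )
    def test_leave_one_out_dimensions(self, feature_set, expected):
        vec = assemble_feature_vector(*self._components(), feature_set=feature_set)
        assert vec.values.shape == (expected,)

    def test_deterministic(self):
        v1 = assemble_feature_vector(*self._components())
        v2 = assemble_feature_vector(*self._components())
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_feature_names_cover_all_sets(self):
        for fs in FEATURE_SETS:
            assert len(feature_names(fs)) == sum(
                {"rw_pssm": 40, "wip": 1, "wbc": 1, "sc_asa": 1}[b]
                for b in FEATURE_SETS[fs]
            )
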