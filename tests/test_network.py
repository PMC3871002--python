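"""Domain types, stoichiometric matrix, bound policy and grouping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dopafba import (
    CANONICAL_GROUPS,
    BoundsPolicy,
    CellModel,
    Metabolite,
    Reaction,
    apply_bounds_policy,
    assign_groups,
    build_stoichiometric_matrix,
    group_sums,
)
from dopafba.errors import GroupingError, ModelIntegrityError, PolicyError
from dopafba.network import groups_from_model, normalize_group_label
from dopafba.skeleton import skeleton_tag_table
from dopafba.synthetic import SyntheticSpec, generate_random_network


def _chain():
    return CellModel(
        [Metabolite("A", "A")],
        [
            Reaction("IN", "in", {"A": 1}, boundary_kind="input"),
            Reaction("OUT", "out", {"A": -1}, boundary_kind="output"),
        ],
    )


class TestStoichiometricMatrix:
    def test_single_metabolite_chain(self):
        S = build_stoichiometric_matrix(_chain())
        assert S.tolist() == [[1.0, -1.0]]

    def test_entries_match_reaction_records(self, skeleton):
        S = build_stoichiometric_matrix(skeleton)
        assert S.shape == (len(skeleton.metabolites), len(skeleton.reactions))
        met_index = {m.id: i for i, m in enumerate(skeleton.metabolites)}
        for j, rxn in enumerate(skeleton.reactions):
            col = {m: S[met_index[m], j] for m in met_index if S[met_index[m], j]}
            assert col == dict(rxn.stoichiometry)

    def test_random_network_round_trip(self):
        model, _ = generate_random_network(SyntheticSpec(seed=42))
        S = build_stoichiometric_matrix(model)
        met_index = {m.id: i for i, m in enumerate(model.metabolites)}
        for j, rxn in enumerate(model.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                assert S[met_index[met_id], j] == coeff

    def test_unresolved_metabolite_is_integrity_error(self):
        with pytest.raises(ModelIntegrityError, match="unresolved"):
            CellModel(
                [Metabolite("A", "A")],
                [
                    Reaction("IN", "in", {"A": 1}, boundary_kind="input"),
                    Reaction("OUT", "out", {"GHOST": -1}, boundary_kind="output"),
                ],
            )


class TestModelInvariants:
    def test_duplicate_reaction_id_rejected(self):
        with pytest.raises(ModelIntegrityError, match="duplicate reaction"):
            CellModel(
                [Metabolite("A", "A")],
                [
                    Reaction("R", "in", {"A": 1}, boundary_kind="input"),
                    Reaction("R", "out", {"A": -1}, boundary_kind="output"),
                ],
            )

    def test_input_with_negative_coefficient_rejected(self):
        with pytest.raises(ModelIntegrityError, match="input"):
            CellModel(
                [Metabolite("A", "A")],
                [
                    Reaction("IN", "in", {"A": -1}, boundary_kind="input"),
                    Reaction("OUT", "out", {"A": -1}, boundary_kind="output"),
                ],
            )

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelIntegrityError, match="bounds"):
            CellModel(
                [Metabolite("A", "A")],
                [
                    Reaction("IN", "in", {"A": 1}, lower_bound=5, upper_bound=1,
                             boundary_kind="input"),
                    Reaction("OUT", "out", {"A": -1}, boundary_kind="output"),
                ],
            )


class TestBoundsPolicy:
    @pytest.mark.parametrize(
        "tag,ref,expected",
        [
            ("default", None, (0.0, 100.0)),
            ("slow", None, (0.0, 30.0)),
            ("best_et_al", 2.0, (1.8, 2.2)),
        ],
    )
    def test_tag_to_bounds(self, tag, ref, expected):
        model = CellModel(
            [Metabolite("A", "A")],
            [
                Reaction("IN", "in", {"A": 1}, boundary_kind="input"),
                Reaction("R", "r", {"A": -1}, boundary_kind="output",
                         speed_tag=tag, best_reference_flux=ref),
            ],
        )
        out = apply_bounds_policy(model).reaction("R")
        assert (out.lower_bound, out.upper_bound) == pytest.approx(expected)

    def test_zero_lb_override_after_tolerance_window(self):
        """A measured reaction of 10 gets (9, 11), then the lower bound of the
        four documented COMT/MAO reactions is forced to 0 → (0, 11)."""
        model = CellModel(
            [Metabolite("DA_c", "DA")],
            [
                Reaction("IN", "in", {"DA_c": 1}, boundary_kind="input"),
                Reaction("OMSynthesis1", "comt", {"DA_c": -1},
                         boundary_kind="output", speed_tag="best_et_al",
                         best_reference_flux=10.0),
            ],
        )
        out = apply_bounds_policy(model).reaction("OMSynthesis1")
        assert out.lower_bound == 0.0
        assert out.upper_bound == pytest.approx(11.0)

    def test_missing_reference_flux_is_policy_error(self):
        model = CellModel(
            [Metabolite("A", "A")],
            [
                Reaction("IN", "in", {"A": 1}, boundary_kind="input"),
                Reaction("R", "r", {"A": -1}, boundary_kind="output",
                         speed_tag="best_et_al"),
            ],
        )
        with pytest.raises(PolicyError, match="reference"):
            apply_bounds_policy(model)

    def test_idempotent_and_ordered(self, skeleton):
        once = apply_bounds_policy(skeleton)
        twice = apply_bounds_policy(once)
        assert once == twice
        assert all(r.lower_bound <= r.upper_bound for r in once.reactions)

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(PolicyError):
            BoundsPolicy(best_tolerance=1.5)


class TestGroups:
    def test_skeleton_covers_all_canonical_labels(self, groups):
        for label in CANONICAL_GROUPS:
            assert label in groups and len(groups[label]) > 0

    def test_apoptosis_groups_non_empty_from_tag_table(self, skeleton):
        fg = assign_groups(skeleton, skeleton_tag_table())
        assert len(fg["Apoptosis (LBs)"]) >= 1
        assert len(fg["Apoptosis (mitochondria)"]) >= 1

    def test_empty_tag_table(self, skeleton):
        assert assign_groups(skeleton, {}).labels() == ()

    def test_unknown_reaction_id_rejected(self, skeleton):
        with pytest.raises(GroupingError):
            assign_groups(skeleton, {"NOPE": ["Apoptosis (LBs)"]})

    def test_ascii_alias_normalized(self):
        assert normalize_group_label("aSYN aggregation") == "αSYN aggregation"

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_group_sums_match_independent_summation(self, groups, seed):
        """Two independent summation orders agree on grouped fluxes."""
        rng = np.random.default_rng(seed)
        ids = sorted(groups.reactions_in(groups.labels()))
        fluxes = {rid: float(rng.uniform(0, 50)) for rid in ids}
        sums = group_sums(groups, fluxes)
        total = sum(sums.values())
        membership_total = sum(
            fluxes[rid]
            for label in groups.labels()
            for rid in groups[label]
        )
        assert total == pytest.approx(membership_total, abs=1e-9)


class TestSkeleton:
    def test_shape_and_provenance(self, skeleton):
        assert skeleton.provenance == "curated-skeleton"
        assert 40 <= len(skeleton.reactions) <= 60
        ids = set(skeleton.reaction_ids)
        assert {"OMSynthesis1", "OMSynthesis2", "HVASynthesis3",
                "HVASynthesis4"} <= ids

    def test_extracellular_da_is_an_output(self, skeleton, groups):
        (rid,) = groups["Extracellular DA"]
        assert skeleton.reaction(rid).boundary_kind == "output"

    def test_policy_application_succeeds(self, skeleton):
        assert apply_bounds_policy(skeleton) == skeleton  # shipped with policy bounds

    def test_currency_metabolites_flagged(self, skeleton):
        flagged = {m.name for m in skeleton.metabolites if m.is_currency}
        assert {"O2", "H2O", "NAD+", "NADH", "Fe2+", "Fe3+", "ATP",
                "ADP+Pi"} == flagged

    def test_groups_field_matches_tag_table(self, skeleton):
        assert groups_from_model(skeleton).members == \
            assign_groups(skeleton, skeleton_tag_table()).members
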