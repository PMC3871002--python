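"""Objective suite, input scans, feasibility windows and onset detection."""

import copy

import pytest

from dopafba import (
    CellModel,
    Metabolite,
    Reaction,
    ScanSpec,
    find_feasibility_window,
    find_onset,
    run_objective_suite,
    run_scan,
)
from dopafba.errors import SpecError
from dopafba.experiments import ScanPoint, ScanResult, scan_summary
from dopafba.fba import OBJECTIVE_LABELS
from dopafba.network import APOPTOSIS_GROUPS
from dopafba.synthetic import generate_neuronlike_network


class TestObjectiveSuite:
    def test_shape_contract(self, skeleton, groups):
        suite = run_objective_suite(skeleton, groups)
        assert set(suite.values) == set(OBJECTIVE_LABELS)
        for label in OBJECTIVE_LABELS:
            assert set(suite.values[label]) == set(groups.labels())
            for flux in suite.values[label].values():
                assert flux >= -1e-9

    def test_min_apoptosis_is_zero_on_basic_model(self, skeleton, groups):
        """A healthy cell admits a steady state without any apoptosis."""
        suite = run_objective_suite(skeleton, groups)
        for g in APOPTOSIS_GROUPS:
            assert suite.values["minApo"][g] == pytest.approx(0.0, abs=1e-9)

    def test_objective_equals_its_group_sum(self, skeleton, groups):
        suite = run_objective_suite(skeleton, groups)
        apo = [g for g in APOPTOSIS_GROUPS]
        for label in ("minApo", "maxApo"):
            total = sum(suite.values[label][g] for g in apo)
            assert total == pytest.approx(suite.objective_values[label], abs=1e-6)

    def test_table_column_order(self, skeleton, groups):
        frame = run_objective_suite(skeleton, groups).to_frame()
        assert list(frame.columns) == list(OBJECTIVE_LABELS)


class TestRunScan:
    def test_rejects_non_input_reaction(self, skeleton, groups):
        with pytest.raises(SpecError, match="not a boundary input"):
            run_scan(skeleton, ScanSpec.sweep("DA_OUT", stop=3), groups)

    def test_disconnected_input_gives_flat_series(self, groups):
        """An input whose metabolite feeds nothing can never carry flux, so
        relaxing its ceiling leaves every group series at the baseline."""
        net = generate_neuronlike_network(seed=0)
        model = CellModel(
            net.model.metabolites + [Metabolite("ORPHAN", "orphan")],
            net.model.reactions
            + [Reaction("ORPHAN_IN", "orphan input", {"ORPHAN": 1},
                        boundary_kind="input")],
            provenance="synthetic",
        )
        spec = ScanSpec.sweep("ORPHAN_IN", stop=5, pin_mode="relax_ub",
                              objective_label="maxDeg")
        scan = run_scan(model, spec, net.groups)
        baseline = scan.points[0].group_fluxes
        for p in scan.points:
            assert p.optimal
            for g, f in p.group_fluxes.items():
                assert f == pytest.approx(baseline[g], abs=1e-6)

    def test_scan_is_pure_and_deterministic(self, skeleton, groups):
        spec = ScanSpec.sweep("MPTP_IN", stop=5, objective_label="maxDeg")
        before = copy.deepcopy(skeleton)
        a = run_scan(skeleton, spec, groups)
        b = run_scan(skeleton, spec, groups)
        assert a == b
        assert skeleton == before

    def test_relax_ub_objective_is_monotone(self, groups):
        net = generate_neuronlike_network(seed=3)
        spec = ScanSpec.sweep(net.window_input_id, stop=60, step=5,
                              pin_mode="relax_ub", objective_label="maxDeg")
        scan = run_scan(net.model, spec, net.groups)
        values = [p.objective_value for p in scan.points if p.optimal]
        assert all(b >= a - 1e-7 for a, b in zip(values, values[1:]))

    def test_infeasible_points_recorded_not_skipped(self, groups):
        net = generate_neuronlike_network(seed=0)
        a, _ = net.window
        spec = ScanSpec.sweep(net.window_input_id, stop=a - 1,
                              objective_label="maxDeg")
        scan = run_scan(net.model, spec, net.groups)
        assert len(scan.points) == int(a)
        assert all(p.status == "infeasible" for p in scan.points)

    def test_skeleton_mptp_scan_triggers_apoptosis(self, skeleton, groups):
        """Increasing neurotoxin influx eventually overwhelms the repair and
        mitophagy capacity and forces mitochondria-induced apoptosis."""
        spec = ScanSpec.sweep("MPTP_IN", stop=100, objective_label="maxDeg")
        scan = run_scan(skeleton, spec, groups)
        onset = find_onset(scan, "Apoptosis (mitochondria)", "appears")
        assert onset.threshold is not None
        assert 0 < onset.threshold <= 100
        assert onset.threshold in spec.values


class TestFeasibilityWindow:
    def test_all_points_optimal(self, skeleton, groups):
        spec = ScanSpec.sweep("MPTP_IN", stop=4, objective_label="maxDeg")
        w = find_feasibility_window(run_scan(skeleton, spec, groups))
        assert (w.min_feasible, w.max_feasible) == (0.0, 4.0)

    def test_no_feasible_point(self):
        scan = ScanResult(
            spec=ScanSpec("X", values=(0.0, 1.0)),
            points=(
                ScanPoint(0.0, "infeasible"),
                ScanPoint(1.0, "infeasible"),
            ),
        )
        w = find_feasibility_window(scan)
        assert w.min_feasible is None and w.max_feasible is None

    @pytest.mark.parametrize("seed", [0, 4, 11])
    def test_constructed_window_recovered_exactly(self, seed):
        net = generate_neuronlike_network(seed=seed)
        a, b = net.window
        spec = ScanSpec.sweep(net.window_input_id, stop=100,
                              objective_label="maxDeg")
        scan = run_scan(net.model, spec, net.groups)
        w = find_feasibility_window(scan)
        assert (w.min_feasible, w.max_feasible) == (a, b)


class TestOnset:
    def _series_scan(self, fluxes, values=None):
        values = values or tuple(float(i) for i in range(len(fluxes)))
        points = tuple(
            ScanPoint(v, "optimal", {"G": f}, f) if f is not None
            else ScanPoint(v, "infeasible")
            for v, f in zip(values, fluxes)
        )
        return ScanResult(spec=ScanSpec("X", values=values), points=points)

    def test_step_function_appears_at_two(self):
        scan = self._series_scan([0.0, 0.0, 5.0, 5.0])
        assert find_onset(scan, "G", "appears").threshold == 2.0

    def test_all_quiet_gives_none_for_appears(self):
        scan = self._series_scan([0.0, 0.0, 0.0])
        assert find_onset(scan, "G", "appears").threshold is None

    def test_vanishing_requires_persistence(self):
        """A transient dip below tolerance is not a vanishing threshold."""
        scan = self._series_scan([3.0, 0.0, 2.0, 0.0, 0.0])
        assert find_onset(scan, "G", "vanishes").threshold == 3.0

    def test_never_vanishes_gives_none(self):
        scan = self._series_scan([1.0, 1.0, 2.0])
        assert find_onset(scan, "G", "vanishes").threshold is None

    def test_unknown_group_raises(self):
        scan = self._series_scan([0.0, 1.0])
        with pytest.raises(KeyError):
            find_onset(scan, "NOPE", "appears")

    def test_neuronlike_min_apoptosis_is_zero(self):
        net = generate_neuronlike_network(seed=1)
        suite = run_objective_suite(net.model, net.groups)
        for g in APOPTOSIS_GROUPS:
            assert suite.values["minApo"][g] == pytest.approx(0.0, abs=1e-9)

    def test_scan_summary_is_json_ready(self, skeleton, groups):
        import json

        spec = ScanSpec.sweep("MPTP_IN", stop=3, objective_label="maxDeg")
        summary = scan_summary(run_scan(skeleton, spec, groups),
                               onset_groups=["Apoptosis (LBs)"])
        text = json.dumps(summary)
        assert "feasibility_window" in text
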