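"""Worklist validation, batch state machine, isolation and reporting."""

import json
import re

import numpy as np
import pytest

import facsort as fs
from facsort.errors import (
    CapacityError,
    DuplicateEntryError,
    ValidationError,
    WellError,
)


def _write_worklist(path, rows):
    path.write_text("name,position,well\n" + "\n".join(rows) + "\n")
    return path


@pytest.fixture(scope="module")
def mini_panel(axis):
    """3 samples x 8,000 events: enough for gating, fast in a batch."""
    specs = fs.make_panel(3, seed=5, n_events=8_000)
    return {s.sample_id: fs.simulate_sample(s) for s in specs}


@pytest.fixture(scope="module")
def mini_worklist(mini_panel):
    wells = fs.valid_wells()
    return [
        fs.WorklistEntry(name, i + 1, wells[i])
        for i, name in enumerate(sorted(mini_panel))
    ]


def _mini_plan():
    return fs.SortPlan(n_profile=4_000, n_sort=50)


class TestWorklistParsing:
    def test_valid_twelve_entry_file(self, tmp_path):
        rows = [f"s{i:02d},{i},A{i}" for i in range(1, 13)]
        entries = fs.parse_worklist(_write_worklist(tmp_path / "wl.csv", rows))
        assert len(entries) == 12
        assert [e.sample_name for e in entries] == [f"s{i:02d}" for i in range(1, 13)]

    def test_position_over_capacity(self, tmp_path):
        with pytest.raises(CapacityError):
            fs.parse_worklist(_write_worklist(tmp_path / "wl.csv", ["s1,19,A1"]))

    @pytest.mark.parametrize("well", ["I1", "A13", "A0", "H13", "a1", "B"])
    def test_invalid_wells(self, tmp_path, well):
        with pytest.raises(WellError):
            fs.parse_worklist(_write_worklist(tmp_path / "wl.csv", [f"s1,1,{well}"]))

    def test_well_enumeration_is_96(self):
        wells = fs.valid_wells()
        assert len(wells) == 96
        assert len(set(wells)) == 96
        # exhaustive: exactly the labels accepted by the entry validator
        accepted = []
        for row in "ABCDEFGHI":
            for col in range(0, 14):
                try:
                    fs.WorklistEntry("s", 1, f"{row}{col}")
                except (WellError, ValidationError):
                    continue
                accepted.append(f"{row}{col}")
        assert sorted(accepted) == sorted(wells)

    @pytest.mark.parametrize(
        "rows", [["dup,1,A1", "dup,2,A2"], ["s1,3,A1", "s2,3,A2"]]
    )
    def test_duplicates_rejected(self, tmp_path, rows):
        with pytest.raises(DuplicateEntryError):
            fs.parse_worklist(_write_worklist(tmp_path / "wl.csv", rows))

    def test_missing_column(self, tmp_path):
        path = tmp_path / "wl.csv"
        path.write_text("name,position\ns1,1\n")
        with pytest.raises(ValidationError, match="well"):
            fs.parse_worklist(path)


class TestRunState:
    def test_terminal_statuses_immutable(self):
        state = fs.RunState(2)
        state.set_status(0, "profiling")
        state.set_status(0, "done")
        with pytest.raises(ValidationError, match="terminal"):
            state.set_status(0, "sorting")

    def test_single_active_sample(self):
        state = fs.RunState(3)
        state.set_status(0, "profiling")
        with pytest.raises(ValidationError, match="active"):
            state.set_status(1, "gating")

    def test_stop_skips_pending(self):
        state = fs.RunState(3)
        state.set_status(0, "profiling")
        state.set_status(0, "done")
        state.stop()
        assert state.statuses == ["done", "skipped", "skipped"]

    def test_pause_resume(self):
        state = fs.RunState(1)
        state.pause()
        assert state.paused
        state.resume()
        assert not state.paused


class TestRunBatch:
    def test_happy_path(self, mini_worklist, mini_panel):
        sink = fs.CollectingSink()
        outcomes = fs.run_batch(
            mini_worklist, mini_panel, plan=_mini_plan(), notifier=sink, seed=1
        )
        assert [o.status for o in outcomes] == ["done"] * 3
        assert [o.entry.sample_name for o in outcomes] == [
            e.sample_name for e in mini_worklist
        ]
        assert len(sink.of_severity("info")) >= 3
        assert all(o.fit.converged for o in outcomes)

    def test_empty_worklist_rejected(self, mini_panel):
        with pytest.raises(ValidationError, match="empty"):
            fs.run_batch([], mini_panel)

    def test_missing_sample_fails_batch_continues(self, mini_worklist, mini_panel):
        samples = dict(mini_panel)
        missing = mini_worklist[1].sample_name
        del samples[missing]
        sink = fs.CollectingSink()
        outcomes = fs.run_batch(
            mini_worklist, samples, plan=_mini_plan(), notifier=sink, seed=1
        )
        assert [o.status for o in outcomes] == ["done", "failed", "done"]
        errors = sink.of_severity("error")
        assert any(n.sample == missing and n.phase for n in errors)

    def test_failure_isolation(self, mini_worklist, mini_panel, axis):
        """Replacing one sample's data with a 50-event table fails only that
        sample and leaves every other result bit-identical."""
        baseline = fs.run_batch(
            mini_worklist, mini_panel, plan=_mini_plan(),
            notifier=fs.CollectingSink(), seed=1,
        )
        broken = dict(mini_panel)
        victim = mini_worklist[1].sample_name
        broken[victim] = fs.EventTable(
            victim, [axis.fluorescence_channel, axis.backscatter_channel],
            np.zeros((50, 2)),
        )
        sink = fs.CollectingSink()
        outcomes = fs.run_batch(
            mini_worklist, broken, plan=_mini_plan(), notifier=sink, seed=1
        )
        assert outcomes[1].status == "failed"
        assert "events" in outcomes[1].error
        for i in (0, 2):
            assert outcomes[i].status == "done"
            assert outcomes[i].fit.achieved_fraction == baseline[i].fit.achieved_fraction
            assert outcomes[i].sort.events_sorted == baseline[i].sort.events_sorted

    def test_failed_samples_are_notified_by_name(self, mini_worklist, mini_panel, axis):
        broken = dict(mini_panel)
        for entry in mini_worklist:
            broken[entry.sample_name] = fs.EventTable(
                entry.sample_name,
                [axis.fluorescence_channel, axis.backscatter_channel],
                np.zeros((10, 2)),
            )
        sink = fs.CollectingSink()
        outcomes = fs.run_batch(
            mini_worklist, broken, plan=_mini_plan(), notifier=sink, seed=1
        )
        failed = {o.entry.sample_name for o in outcomes if o.status == "failed"}
        notified = {n.sample for n in sink.messages if n.severity in ("error", "warning")}
        assert failed <= notified


class TestNotifications:
    def test_error_requires_sample_and_phase(self):
        with pytest.raises(ValidationError):
            fs.Notification("error", "boom")

    def test_severity_validated(self):
        with pytest.raises(ValidationError):
            fs.Notification("fatal", "boom")

    def test_collecting_sink_filters(self):
        sink = fs.CollectingSink()
        sink.info("a")
        sink.warning("b", sample="s1")
        sink.error("c", sample="s1", phase="gating")
        assert len(sink.of_severity("info")) == 1
        assert sink.of_severity("error")[0].format() == "ERROR [s1/gating]: c"


def _count_pdf_pages(path):
    return len(re.findall(rb"/Type\s*/Page[^s]", path.read_bytes()))


@pytest.fixture(scope="module")
def outcomes(mini_worklist, mini_panel):
    return fs.run_batch(
        mini_worklist, mini_panel, plan=_mini_plan(),
        notifier=fs.CollectingSink(), seed=1,
    )


class TestReporting:
    def test_single_result_single_panel(self, outcomes, tmp_path):
        path = tmp_path / "one.pdf"
        fs.render_report(outcomes[:1], path)
        assert _count_pdf_pages(path) == 2  # header table + 1 sample panel

    def test_page_and_header_counts(self, outcomes, tmp_path):
        path = tmp_path / "all.pdf"
        fs.render_report(outcomes, path)
        assert _count_pdf_pages(path) == 1 + len(outcomes)
        summary = json.loads(path.with_suffix(".json").read_text())
        assert summary["n_samples"] == len(outcomes)
        assert len(summary["samples"]) == len(outcomes)

    def test_report_deterministic_bytes(self, outcomes, tmp_path):
        a, b = tmp_path / "a.pdf", tmp_path / "b.pdf"
        fs.render_report(outcomes, a)
        fs.render_report(outcomes, b)
        assert a.read_bytes() == b.read_bytes()
        assert a.with_suffix(".json").read_bytes() == b.with_suffix(".json").read_bytes()

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            fs.render_report([], tmp_path / "x.pdf")

    def test_summary_fields(self, outcomes):
        summary = fs.summarize(outcomes)
        rec = summary["samples"][0]
        assert rec["status"] == "done"
        assert rec["gate"]["n_vertices"] <= 60
        assert rec["sort"]["events_sorted"] >= 0
        assert abs(sum(rec["sort"]["phase_times"].values()) - rec["sort"]["total_time"]) < 1e-9

    def test_render_from_summary(self, outcomes, tmp_path):
        from facsort.run_orchestrator import render_from_summary

        path = tmp_path / "orig.pdf"
        fs.render_report(outcomes, path)
        summary = json.loads(path.with_suffix(".json").read_text())
        out = tmp_path / "re.pdf"
        render_from_summary(summary, out)
        assert _count_pdf_pages(out) >= 1 + sum(
            1 for r in summary["samples"] if r.get("gate")
        )
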