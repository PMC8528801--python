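"""Circle-glyph specs, week grids and figure rendering."""

import datetime as dt
import math

import pytest

import esmview as ev
from esmview import viz
from esmview.schema import MISSING, SchemaError
from conftest import make_record

T0 = dt.datetime(2017, 3, 6, 9)


class TestCircleSpec:
    @pytest.mark.parametrize("value,frac", [(100, 1.0), (0, 0.0), (50, 0.5)])
    def test_fill_fraction_is_value_over_100(self, questionnaire, value, frac):
        rec = make_record(questionnaire, T0, {"Sad": value})
        spec = ev.build_circle_spec(rec, questionnaire)
        node = next(n for n in spec.nodes if n.item_code == "Sad")
        assert node.fill_fraction == frac
        assert not node.missing

    def test_missing_node_is_grey_zero_fill(self, questionnaire):
        rec = make_record(questionnaire, T0, {"Sad": MISSING})
        spec = ev.build_circle_spec(rec, questionnaire)
        node = next(n for n in spec.nodes if n.item_code == "Sad")
        assert node.missing and node.fill_fraction == 0.0

    def test_every_item_maps_to_node_or_badge_role(self, questionnaire):
        """Conservation: nothing the participant scores is silently dropped."""
        ring = set(viz.ring_item_codes(questionnaire))
        badge_backed = {c for codes in viz.DEFAULT_BADGE_ROLES.values() for c in codes}
        scored = {i.code for i in questionnaire.items
                  if i.response_kind != "free_text"}
        assert ring | badge_backed | {"Event"} == scored
        assert ring.isdisjoint(badge_backed)

    def test_polarity_arcs_are_contiguous_halves(self, questionnaire):
        rec = make_record(questionnaire, T0)
        spec = ev.build_circle_spec(rec, questionnaire)
        for node in spec.nodes:
            polarity = questionnaire.item(node.item_code).polarity
            if polarity == "positive":
                assert 0 < node.angle_deg < 180  # right half, clockwise from top
            else:
                assert 180 < node.angle_deg < 360
        assert len({n.angle_deg for n in spec.nodes}) == len(spec.nodes)

    def test_badges_follow_answers(self, questionnaire):
        rec = make_record(questionnaire, T0, {
            "Slep": "yes", "SlQu": 80, "Comp": "no", "Canc": "yes",
            "Cont": 3, "Event": "yes", "Pleas": 60, "Unpl": MISSING})
        spec = ev.build_circle_spec(rec, questionnaire)
        badges = {b.kind: b for b in spec.badges}
        assert badges["sleep"].intensity == pytest.approx(0.8)
        assert "company" not in badges
        assert badges["cancelled_appointment"].text == "c"
        assert badges["contact_count"].text == "3"
        assert badges["pleasant_event"].intensity == pytest.approx(0.6)
        assert "unpleasant_event" not in badges

    def test_zero_contact_renders_no_badge(self, questionnaire):
        rec = make_record(questionnaire, T0, {"Cont": 0})
        spec = ev.build_circle_spec(rec, questionnaire)
        assert all(b.kind != "contact_count" for b in spec.badges)

    def test_unanswered_prompt_is_explicit(self, questionnaire):
        rec = make_record(questionnaire, T0, answered=False)
        spec = ev.build_circle_spec(rec, questionnaire)
        assert not spec.answered
        assert spec.badges == ()
        assert all(n.missing for n in spec.nodes)

    def test_deterministic_spec(self, questionnaire):
        rec = make_record(questionnaire, T0, comment="hello")
        assert ev.build_circle_spec(rec, questionnaire) == \
            ev.build_circle_spec(rec, questionnaire)

    def test_unknown_badge_role_rejected(self, questionnaire):
        rec = make_record(questionnaire, T0)
        with pytest.raises(SchemaError):
            ev.build_circle_spec(rec, questionnaire, badge_roles={"sleep": ("Nope",)})


class TestRendering:
    def test_circle_png_deterministic(self, questionnaire):
        rec = make_record(questionnaire, T0, comment="same bytes")
        spec = ev.build_circle_spec(rec, questionnaire)
        assert ev.render_circle(spec) == ev.render_circle(spec)

    def test_size_does_not_change_geometry(self, questionnaire):
        """Specs are resolution-independent; rendering leaves them unchanged."""
        rec = make_record(questionnaire, T0)
        spec = ev.build_circle_spec(rec, questionnaire)
        ev.render_circle(spec, size=2.0)
        spec2 = ev.build_circle_spec(rec, questionnaire)
        assert spec == spec2

    def test_svg_output_supported(self, questionnaire):
        rec = make_record(questionnaire, T0)
        spec = ev.build_circle_spec(rec, questionnaire)
        svg = ev.render_circle(spec, fmt="svg")
        assert b"<svg" in svg

    def test_legend_lists_all_ring_items(self, questionnaire):
        svg = ev.render_legend(questionnaire, fmt="svg").decode()
        for code in viz.ring_item_codes(questionnaire):
            assert code in svg
        assert "not" in svg and "zero" in svg  # grey-ambiguity caveat text


class TestWeekGrid:
    def test_complete_week_is_3x7(self, four_week_dataset):
        grid = ev.build_week_grid(four_week_dataset, dt.date(2017, 3, 6))
        assert len(grid) == 3 and all(len(row) == 7 for row in grid)
        assert sum(cell is not None for row in grid for cell in row) == 21

    def test_unanswered_prompts_become_placeholders(self, four_week_dataset):
        grid = ev.build_week_grid(four_week_dataset, dt.date(2017, 3, 27))
        cells = [c for row in grid for c in row if c is not None]
        unanswered = [c for c in cells if not c.answered]
        # the fixture's 2-day block window lies in this week: >= 6 placeholders
        assert len(unanswered) >= 6
        assert all(c.badges == () for c in unanswered)

    def test_partial_week_has_blank_cells(self, four_week_dataset):
        before = four_week_dataset.study_start - dt.timedelta(days=3)
        grid = ev.build_week_grid(four_week_dataset, before)
        for row in grid:
            assert row[0] is None and row[2] is None and row[3] is not None

    def test_rows_are_slots_columns_weekdays(self, four_week_dataset):
        grid = ev.build_week_grid(four_week_dataset, dt.date(2017, 3, 6))
        assert [row[0].slot for row in grid] == ["morning", "afternoon", "evening"]
        assert grid[0][4].scheduled_time.date() == dt.date(2017, 3, 10)


class TestFigures:
    def test_week_png_deterministic(self, four_week_dataset):
        a = ev.render_week(four_week_dataset, dt.date(2017, 3, 6))
        b = ev.render_week(four_week_dataset, dt.date(2017, 3, 6))
        assert a == b and a[:8] == b"\x89PNG\r\n\x1a\n"

    def test_timeline_requires_three_answered_prompts(self, questionnaire):
        records = [make_record(questionnaire, dt.datetime(2017, 3, 6, 9))]
        ds = ev.ESMDataset(questionnaire=questionnaire, schedule=ev.PromptSchedule(),
                           records=records, study_start=dt.date(2017, 3, 6),
                           study_end=dt.date(2017, 3, 6))
        with pytest.raises(Exception, match="3"):
            ev.render_timeline(ds)

    def test_timeline_highlight_must_be_in_range(self, four_week_dataset):
        with pytest.raises(ValueError, match="highlight"):
            viz.build_timeline_spec(
                four_week_dataset,
                highlight=(dt.datetime(2020, 1, 1), dt.datetime(2020, 1, 7)))

    def test_timeline_renders_with_overlay_and_raw(self, four_week_dataset):
        png = ev.render_timeline(
            four_week_dataset,
            highlight=(dt.datetime(2017, 3, 13), dt.datetime(2017, 3, 19, 23, 59)),
            show_raw=True)
        assert png[:8] == b"\x89PNG\r\n\x1a\n"

    def test_boxplot_panel_excludes_sometimes_absent_items(self, four_week_dataset):
        fig = viz.boxplot_figure(four_week_dataset)
        labels = [t.get_text() for t in fig.axes[0].get_xticklabels()]
        assert set(labels) == set(viz.ring_item_codes(four_week_dataset.questionnaire))
        for absent in ("Cont", "SlQu", "Pleas", "Unpl", "Comp"):
            assert absent not in labels

    def test_poster_page_count(self, four_week_dataset, tmp_path):
        path = tmp_path / "poster.pdf"
        pages = ev.make_poster(four_week_dataset, path, weeks_per_page=3)
        assert pages == math.ceil(len(viz.study_week_starts(four_week_dataset)) / 3) == 2
        assert path.stat().st_size > 0
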