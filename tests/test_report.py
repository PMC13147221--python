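import json

import numpy as np
import pytest

from scribe_audit.config import RunConfig
from scribe_audit.diff_engine import ADDITION
from scribe_audit.note_io import DEFAULT_START_MARKER
from scribe_audit.report import median_iqr, render_report, run_pipeline
from scribe_audit.synthetic_data import GeneratorConfig, generate_corpus, write_corpus
from scribe_audit.time_model import CorpusCounts, paper_rounding_report


class TestMedianIqr:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 2, 3, 4, 5], (3, 2, 4)), ([5], (5, 5, 5)), ([1, 3], (2, 1.5, 2.5))],
    )
    def test_examples(self, values, expected):
        assert median_iqr(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    def test_uniform_draws_near_theoretical_quartiles(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, size=2000)
        med, q1, q3 = median_iqr(values)
        assert med == pytest.approx(0.5, abs=0.05)
        assert q1 == pytest.approx(0.25, abs=0.05)
        assert q3 == pytest.approx(0.75, abs=0.05)


class TestRunPipeline:
    def test_report_matches_ground_truth(self, corpus_dir):
        manifest, truth = corpus_dir
        report = run_pipeline(manifest)
        gt_edits = [e for edits in truth.edits.values() for e in edits]
        assert report.stats.n_alterations == len(gt_edits)
        assert report.stats.words_added == sum(
            len(e.tokens) for e in gt_edits if e.kind == ADDITION
        )
        assert report.stats.words_deleted == sum(
            len(e.tokens) for e in gt_edits if e.kind != ADDITION
        )
        # every in-transcript planted addition is recovered as in-transcript
        assert report.table.totals.n_additions_in_transcript == sum(
            1 for e in gt_edits if e.kind == ADDITION and e.in_transcript
        )

    def test_counts_conserved_across_modules(self, corpus_dir):
        manifest, _ = corpus_dir
        report = run_pipeline(manifest)
        assert report.counts.w_added == sum(
            r.stats.words_added for r in report.encounters
        )
        assert report.counts.w_final == sum(r.w_final for r in report.encounters)
        assert report.counts.n_notes == report.n_encounters
        # the time model consumed exactly these counts
        avg, fast = paper_rounding_report(report.counts, report.config.time)
        assert (avg, fast) == report.time_paper_rounding

    def test_zero_edit_corpus(self, tmp_path):
        cfg = GeneratorConfig(
            n_encounters=4, seed=9, p_addition_per_section=0.0, p_deletion_per_section=0.0
        )
        encounters, truth = generate_corpus(cfg)
        manifest = write_corpus(encounters, truth, tmp_path / "zero")
        report = run_pipeline(manifest)
        assert report.stats.n_alterations == 0
        exact_avg = report.time_exact[0]
        assert exact_avg.t_edit_h == 0.0
        assert exact_avg.savings_h == pytest.approx(
            exact_avg.t_manual_h - exact_avg.t_gen_h - exact_avg.t_read_h
        )

    def test_markerless_encounter_is_skipped_not_fatal(self, tmp_path, small_corpus):
        encounters, truth = small_corpus
        manifest = write_corpus(encounters, truth, tmp_path / "skip")
        victim = manifest.parent / f"{encounters[0].id}.emr.txt"
        victim.write_text("a manually typed note, no banner\n")
        report = run_pipeline(manifest)
        assert report.n_encounters == len(encounters) - 1
        assert report.skipped == (
            {"id": encounters[0].id, "reason": "no banner markers"},
        )

    def test_malformed_note_is_skipped_with_reason(self, tmp_path, small_corpus):
        encounters, truth = small_corpus
        manifest = write_corpus(encounters, truth, tmp_path / "mal")
        victim = manifest.parent / f"{encounters[1].id}.emr.txt"
        victim.write_text(f"{DEFAULT_START_MARKER}\nbody without end\n")
        report = run_pipeline(manifest)
        assert report.n_encounters == len(encounters) - 1
        assert "end marker" in report.skipped[0]["reason"]

    def test_deterministic_reports(self, corpus_dir, tmp_path):
        manifest, _ = corpus_dir
        out_a, out_b = tmp_path / "a.json", tmp_path / "b.json"
        render_report(run_pipeline(manifest), "json", out_a)
        render_report(run_pipeline(manifest), "json", out_b)
        assert out_a.read_bytes() == out_b.read_bytes()


class TestRenderReport:
    def test_json_and_csv_bundle_and_markdown(self, corpus_dir, tmp_path):
        manifest, _ = corpus_dir
        report = run_pipeline(manifest)
        payload = json.loads(
            render_report(report, "json", tmp_path / "r.json").read_text()
        )
        assert payload["counts"]["n_notes"] == report.n_encounters
        bundle = render_report(report, "csv-bundle", tmp_path / "bundle")
        assert (bundle / "section_table.csv").exists()
        md = render_report(report, "markdown", tmp_path / "r.md").read_text()
        assert "alterations" in md

    def test_markdown_contains_study_headline_figures(self, tmp_path, corpus_dir):
        """With the study's aggregate counts the narrative shows 10.3 h / 40.8%."""
        manifest, _ = corpus_dir
        report = run_pipeline(manifest)
        counts = CorpusCounts(
            w_final=54140, w_ai=44589, w_added=18140, w_deleted=2274, n_notes=248
        )
        from dataclasses import replace as dc_replace

        study_report = dc_replace(
            report,
            counts=counts,
            time_paper_rounding=paper_rounding_report(counts, report.config.time),
        )
        md = render_report(study_report, "markdown", tmp_path / "s.md").read_text()
        assert "10.3" in md and "40.8" in md

    def test_unknown_format_rejected(self, corpus_dir, tmp_path):
        manifest, _ = corpus_dir
        with pytest.raises(ValueError):
            render_report(run_pipeline(manifest), "xml", tmp_path / "x")
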