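"""Ground-truth generator: invariants, determinism, and rendering contracts."""

import io
from datetime import date

import numpy as np
import pytest

from forumrx.context import detect_negation, resolve_time
from forumrx.ingest import build_sentence_table
from forumrx.lexicon import find_mentions
from forumrx.synthetic import (ConfigError, NoiseConfig, SimulationConfig,
                               generate_truth, render_comparators,
                               render_posts, truth_lines_table)


def _point_mass_config(**kwargs):
    defaults = dict(
        n_patients=10,
        year_counts={2014: 1},
        regimen_weights={1: {"ipilimumab": 1.0}},
        p_second_line=0.0,
        p_third_line=0.0,
        adjuvant_decoy_rate=0.0,
        noise=NoiseConfig.zero(),
        seed=0,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestGenerateTruth:
    def test_degenerate_probabilities_give_single_line(self):
        journeys = generate_truth(_point_mass_config(n_patients=25))
        assert all(len(j.lines) == 1 for j in journeys)

    def test_point_mass_regimen_and_year(self):
        journeys = generate_truth(_point_mass_config())
        assert len(journeys) == 10
        for j in journeys:
            assert j.lines[0].regimen == {"ipilimumab"}
            assert j.lines[0].start_date.year == 2014

    def test_first_line_year_distribution_converges(self):
        # configured year mix: (40,96,140,180,127,127,107)/817 over 2011-2017
        config = SimulationConfig(n_patients=10_000, seed=11)
        journeys = generate_truth(config)
        years = np.array([j.lines[0].start_date.year for j in journeys])
        total = sum(config.year_counts.values())
        for year, count in config.year_counts.items():
            observed = (years == year).mean()
            assert observed == pytest.approx(count / total, abs=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_truth_invariants(self, seed):
        config = SimulationConfig(n_patients=300, seed=seed)
        for journey in generate_truth(config):
            numbers = [line.line_number for line in journey.lines]
            assert numbers == list(range(1, len(numbers) + 1))
            starts = [line.start_date for line in journey.lines]
            assert starts == sorted(starts) and len(set(starts)) == len(starts)
            for line in journey.lines:
                assert line.regimen
                assert line.regimen not in ({"interferon"}, {"docetaxel"})

    def test_reproducible(self):
        config = SimulationConfig(n_patients=100, seed=9)
        assert generate_truth(config) == generate_truth(config)


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ConfigError):
            SimulationConfig(p_second_line=1.5)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(regimen_weights={1: {"ipilimumab": 0.6}})

    def test_empty_regimen_distribution(self):
        with pytest.raises(ConfigError):
            SimulationConfig(regimen_weights={1: {}})

    def test_negative_pool(self):
        with pytest.raises(ConfigError):
            SimulationConfig(comparator_pools={"db": {2014: -1}})

    def test_negative_noise(self):
        with pytest.raises(ConfigError):
            NoiseConfig(typo_rate=-0.1).validate()


class TestRenderPosts:
    def test_zero_noise_every_line_resolvable_to_start_month(self, lexicon):
        config = SimulationConfig(n_patients=40, noise=NoiseConfig.zero(),
                                  seed=3)
        journeys = generate_truth(config)
        posts, _ = render_posts(journeys, config, lexicon)
        sentences = build_sentence_table(posts)
        covered = set()
        for row in sentences.itertuples():
            mentions = find_mentions(row, lexicon)
            if not mentions:
                continue
            event, _ = resolve_time(row.text, row.post_date)
            for m in mentions:
                covered.add((row.user_id, m.canonical, event.year, event.month))
        for journey in journeys:
            for line in journey.lines:
                for drug in line.regimen:
                    key = (journey.patient_id, drug, line.start_date.year,
                           line.start_date.month)
                    assert key in covered

    def test_full_negation_noise_matches_cue_grammar(self, lexicon):
        config = SimulationConfig(
            n_patients=60, seed=4,
            noise=NoiseConfig(typo_rate=0, negation_rate=1.0, offtopic_rate=0,
                              discussion_rate=0, relative_date_rate=0))
        journeys = generate_truth(config)
        posts, labels = render_posts(journeys, config, lexicon)
        sentences = build_sentence_table(posts)
        labeled = sentences.merge(labels, on=["user_id", "post_id",
                                              "sentence_index"])
        negated = labeled[labeled["label"] == "non_receipt"]
        assert len(negated) >= 30  # negation fires for every patient
        for row in negated.itertuples():
            mentions = find_mentions(row, lexicon)
            assert mentions
            assert detect_negation(row.text, mentions[0].start)

    def test_full_typo_noise_remains_detectable(self, lexicon):
        config = SimulationConfig(
            n_patients=60, seed=5, brand_rate=0.0,
            noise=NoiseConfig(typo_rate=1.0, negation_rate=0, offtopic_rate=0,
                              discussion_rate=0, relative_date_rate=0))
        journeys = generate_truth(config)
        posts, _ = render_posts(journeys, config, lexicon)
        sentences = build_sentence_table(posts)
        found = set()
        surfaces_checked = 0
        for row in sentences.itertuples():
            for m in find_mentions(row, lexicon):
                found.add((row.user_id, m.canonical))
                if len(m.surface) >= 6 and " " not in m.canonical:
                    surfaces_checked += 1
                    assert m.surface.lower() != m.canonical
        assert surfaces_checked > 0
        for journey in journeys:  # recall 1.0 on the one-edit corpus
            for line in journey.lines:
                for drug in line.regimen:
                    assert (journey.patient_id, drug) in found

    def test_labels_cover_every_rendered_sentence(self, lexicon):
        config = SimulationConfig(n_patients=30, seed=6)
        journeys = generate_truth(config)
        posts, labels = render_posts(journeys, config, lexicon)
        sentences = build_sentence_table(posts)
        merged = sentences.merge(labels, on=["user_id", "post_id",
                                             "sentence_index"], how="left")
        assert merged["label"].notna().all()

    def test_empty_journeys_rejected(self, lexicon):
        with pytest.raises(ValueError):
            render_posts([], SimulationConfig(n_patients=0), lexicon)


class TestRenderComparators:
    def test_empty_pool_year(self):
        config = _point_mass_config(comparator_pools={"dbA": {2014: 0}})
        assert render_comparators(config).empty

    def test_exact_pool_counts(self):
        config = _point_mass_config(comparator_pools={"dbA": {2014: 720}})
        table = render_comparators(config)
        assert table["patient_id"].nunique() == 720
        assert (table["first_line_year"] == 2014).all()

    def test_identical_seed_byte_identical_csv(self):
        config = SimulationConfig(n_patients=5, seed=8)
        buffers = []
        for _ in range(2):
            buf = io.StringIO()
            render_comparators(config).to_csv(buf, index=False)
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]


def test_truth_lines_table_schema():
    journeys = generate_truth(_point_mass_config())
    table = truth_lines_table(journeys)
    assert list(table.columns) == ["patient_id", "line_number", "regimen",
                                   "start_date"]
    assert len(table) == 10
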