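"""Generative model: reporter integration, clone expansion, ground truth."""

import numpy as np
import pandas as pd
import pytest

from xfpclone import (
    IntegrationProfile,
    SimulationConfig,
    generate_cohort,
    sample_clone,
    sample_integration_profile,
)
from xfpclone._schema import INTENSITY_COLUMNS
from xfpclone.clone_calling import check_intensity_consistency
from xfpclone.barcoding import annotate_barcodes


class TestIntegrationProfile:
    def test_forced_full_integration(self, rng):
        cfg = SimulationConfig(
            p_integration=1.0, copy_number_law="constant", copy_number_params={"value": 1}
        )
        profile = sample_integration_profile(cfg, rng)
        assert profile.copies == (1,) * 12

    def test_zero_integration_probability_rejected(self, rng):
        with pytest.raises(ValueError, match="labeled progenitor"):
            sample_integration_profile(SimulationConfig(p_integration=0.0), rng)

    def test_never_all_zero(self, rng):
        cfg = SimulationConfig(p_integration=0.05)
        for _ in range(200):
            assert any(sample_integration_profile(cfg, rng).copies)

    def test_presence_fraction_matches_binomial(self, rng):
        """Each reporter integrates independently with p_integration."""
        cfg = SimulationConfig(p_integration=0.5)
        n = 10_000
        hits = sum(sample_integration_profile(cfg, rng).copies[0] > 0 for _ in range(n))
        band = 3 * np.sqrt(0.5 * 0.5 / n)
        assert abs(hits / n - 0.5) < band

    def test_collision_probability_matches_closed_form(self, rng):
        """P(two profiles share a presence pattern) = (q^2 + (1-q)^2)^12."""
        q = 0.9
        cfg = SimulationConfig(p_integration=q)
        expected = (q**2 + (1 - q) ** 2) ** 12
        n = 10_000
        same = sum(
            sample_integration_profile(cfg, rng).presence
            == sample_integration_profile(cfg, rng).presence
            for _ in range(n)
        )
        band = 3 * np.sqrt(expected * (1 - expected) / n)
        assert abs(same / n - expected) < band


class TestSampleClone:
    def test_zero_noise_siblings_identical(self, rng):
        cfg = SimulationConfig(noise_sd=0.0)
        profile = sample_integration_profile(cfg, rng)
        clone = sample_clone(profile, "Ast", cfg, rng)
        for col in INTENSITY_COLUMNS:
            assert clone[col].nunique() == 1

    def test_mixed_clone_equal_split(self, rng):
        cfg = SimulationConfig(
            clone_size_law="constant",
            clone_size_means={k: 12 for k in SimulationConfig().clone_size_means},
        )
        profile = sample_integration_profile(cfg, rng)
        clone = sample_clone(profile, "Ast+OL", cfg, rng)
        counts = clone["cell_type"].value_counts()
        assert set(counts.index) == {"astrocyte", "oligodendrocyte"}
        assert counts["astrocyte"] == counts["oligodendrocyte"] == 6

    def test_span_realized_exactly(self, rng):
        """Both endpoints of the drawn section run are always occupied."""
        cfg = SimulationConfig(span_law="constant", span_p=7, n_sections=10)
        profile = sample_integration_profile(cfg, rng)
        clone = sample_clone(profile, "NG2", cfg, rng)
        sections = clone["section_index"]
        assert sections.max() - sections.min() + 1 == 7

    def test_unknown_fate_class_rejected(self, rng):
        cfg = SimulationConfig()
        profile = sample_integration_profile(cfg, rng)
        with pytest.raises(ValueError, match="fate_class"):
            sample_clone(profile, "neuron", cfg, rng)

    def test_bounds_respected_across_cohort(self, default_cohort):
        _, cells, truth = default_cohort
        merged = cells.merge(truth.assignments, on="cell_id")
        sizes = merged.groupby("progenitor_id").size()
        assert sizes.between(4, 49).all()
        spans = merged.groupby("progenitor_id")["section_index"].agg(
            lambda s: s.max() - s.min() + 1
        )
        assert spans.between(1, 7).all()
        assert cells["section_index"].between(0, SimulationConfig().n_sections - 1).all()

    def test_mixed_classes_contain_both_types(self, default_cohort):
        _, cells, truth = default_cohort
        merged = cells.merge(truth.assignments, on="cell_id")
        for fate in ("NG2+OL", "Ast+NG2", "Ast+OL"):
            for _, grp in merged[merged["fate_class"] == fate].groupby("progenitor_id"):
                assert grp["cell_type"].nunique() == 2


class TestGenerateCohort:
    def test_seeded_determinism_byte_identical(self):
        cfg = SimulationConfig(n_progenitors=15, seed=42)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        assert a.to_csv(sep="\t", index=False) == b.to_csv(sep="\t", index=False)

    def test_empty_cohort(self):
        cells, truth = generate_cohort(SimulationConfig(n_progenitors=0))
        assert len(cells) == 0 and len(truth.assignments) == 0

    def test_negative_progenitors_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            generate_cohort(SimulationConfig(n_progenitors=-1))

    def test_ground_truth_partitions_cells(self, default_cohort):
        _, cells, truth = default_cohort
        assert sorted(truth.assignments["cell_id"]) == sorted(cells["cell_id"])
        assert not truth.assignments["cell_id"].duplicated().any()
        assert set(truth.assignments["progenitor_id"]) == set(truth.profiles)

    def test_fate_class_probabilities_honored(self):
        """Empirical Ast-clone fraction within the binomial 3σ band."""
        cfg = SimulationConfig(n_progenitors=2000, seed=9, noise_sd=0.0)
        _, truth = generate_cohort(cfg)
        fates = pd.Series(truth.fate_classes)
        p = 0.26
        band = 3 * np.sqrt(p * (1 - p) / len(fates))
        assert abs((fates == "Ast").mean() - p) < band

    def test_collision_injection_shares_profile(self):
        cells, truth = generate_cohort(SimulationConfig(n_progenitors=10, seed=2),
                                       n_shared_profile=3)
        assert truth.profiles[0] == truth.profiles[1] == truth.profiles[2]
        assert truth.profiles[3] != truth.profiles[0] or truth.profiles[4] != truth.profiles[0]

    def test_invalid_fate_probs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(fate_class_probs=(0.5, 0.5, 0.1, 0, 0, 0)).validate()

    def test_default_noise_keeps_clones_consistent(self):
        """At noise_sd=8 (6σ√2 < 80) ground-truth clones pass the 80-point rule."""
        cfg = SimulationConfig(n_progenitors=1000, seed=17)
        cells, truth = generate_cohort(cfg)
        coded = annotate_barcodes(cells, cfg.presence_threshold)
        merged = coded.merge(truth.assignments, on="cell_id")
        ok = sum(
            check_intensity_consistency(grp)[0]
            for _, grp in merged.groupby("progenitor_id")
        )
        assert ok / 1000 > 0.99
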