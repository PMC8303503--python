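"""The synthetic study generator: determinism, planted effects, calibration hooks."""

import numpy as np
import pytest

from gbmscreen.io_formats import ValidationError
from gbmscreen.preprocess import log_transform, quantile_normalize
from gbmscreen.survival_stats import screen_features
from gbmscreen.synthetic_data import (
    ConfigError,
    PlantedMarker,
    SyntheticConfig,
    generate_study,
    null_fraction_check,
    write_study,
)


def small_config(**kw):
    base = dict(
        n_datasets=2,
        genes_per_dataset=60,
        samples_per_dataset=(80, 80),
        shared_gene_fraction=0.5,
        seed=0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


def screen_dataset(ds):
    matrix = log_transform(quantile_normalize(ds.counts))
    return screen_features(matrix, ds.os)


class TestConfigValidation:
    def test_sample_list_length_mismatch(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_datasets=3, samples_per_dataset=(10, 10))

    @pytest.mark.parametrize(
        "kw",
        [
            {"shared_gene_fraction": 1.5},
            {"baseline_hazard": 0.0},
            {"censoring_time_max": -1.0},
            {"nb_dispersion": 0.0},
        ],
    )
    def test_invalid_parameters(self, kw):
        with pytest.raises(ConfigError):
            small_config(**kw)

    def test_planted_gene_outside_universe(self):
        cfg = small_config(planted_markers=(PlantedMarker("NOT_A_GENE", 1.0, "all"),))
        with pytest.raises(ConfigError):
            generate_study(cfg)

    def test_planted_gene_unknown_dataset(self):
        cfg = small_config(planted_markers=(PlantedMarker("GS00001", 1.0, ("DS9",)),))
        with pytest.raises(ConfigError):
            generate_study(cfg)


class TestGenerateStudy:
    def test_same_seed_identical_studies(self):
        a = generate_study(small_config())
        b = generate_study(small_config())
        for da, db in zip(a.datasets, b.datasets):
            assert np.array_equal(da.counts.values, db.counts.values)
            assert da.os.data.equals(db.os.data)
            assert da.pfs.data.equals(db.pfs.data)

    def test_different_seed_differs(self):
        a = generate_study(small_config(seed=0))
        b = generate_study(small_config(seed=1))
        assert not np.array_equal(a.datasets[0].counts.values, b.datasets[0].counts.values)

    def test_no_markers_empty_truth(self):
        study = generate_study(small_config())
        assert study.truth == {}

    def test_planted_marker_recorded_in_truth_and_universe(self):
        cfg = small_config(planted_markers=(PlantedMarker("GS00001", 1.0, "all"),))
        study = generate_study(cfg)
        assert study.truth == {"GS00001": (1.0, ("DS1", "DS2"))}
        for ds in study.datasets:
            assert "GS00001" in ds.counts.gene_ids

    def test_shared_genes_common_specific_disjoint(self):
        study = generate_study(small_config())
        g1 = set(study.datasets[0].counts.gene_ids)
        g2 = set(study.datasets[1].counts.gene_ids)
        shared = g1 & g2
        assert len(shared) == 30
        assert all(g.startswith("GS") for g in shared)

    def test_event_fraction_monotone_in_censoring_horizon(self):
        fractions = []
        for cmax in (10.0, 30.0, 90.0):
            study = generate_study(small_config(censoring_time_max=cmax))
            events = np.concatenate([ds.os.data["event"].to_numpy() for ds in study.datasets])
            fractions.append(events.mean())
        assert fractions[0] < fractions[1] < fractions[2]

    def test_positive_beta_recovers_positive_log_hr(self):
        # average sign of the screened coefficient across seeds matches the
        # planted direction under the generating model
        # enough genes that quantile normalization leaves per-gene variation
        # (with very few genes a gene keeps one rank in every sample and its
        # normalized row collapses to a constant)
        betas = []
        for seed in range(6):
            cfg = SyntheticConfig(
                n_datasets=1,
                genes_per_dataset=200,
                samples_per_dataset=(200,),
                shared_gene_fraction=1.0,
                planted_markers=(PlantedMarker("GS00001", 1.0, "all"),),
                seed=seed,
            )
            study = generate_study(cfg)
            results = screen_dataset(study.datasets[0])
            planted = next(r for r in results if r.feature_id == "GS00001")
            betas.append(planted.beta)
        assert np.mean(betas) > 0
        assert sum(b > 0 for b in betas) >= 5

    def test_selection_probability_increases_with_effect_size(self):
        rates = []
        for beta in (0.0, 0.5, 1.0):
            hits = 0
            for seed in range(4):
                cfg = SyntheticConfig(
                    n_datasets=1,
                    genes_per_dataset=150,
                    samples_per_dataset=(150,),
                    shared_gene_fraction=1.0,
                    planted_markers=(PlantedMarker("GS00001", beta, "all"),) if beta else (),
                    seed=100 + seed,
                )
                study = generate_study(cfg)
                results = screen_dataset(study.datasets[0])
                planted = next(r for r in results if r.feature_id == "GS00001")
                if (
                    planted.skip_reason is None
                    and planted.converged
                    and planted.wald_p < 0.05
                    and planted.logrank_p < 0.05
                ):
                    hits += 1
            rates.append(hits / 4)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_write_study_round_trips(self, tmp_path):
        import json

        from gbmscreen.io_formats import read_counts_matrix, read_survival_table

        cfg = small_config(planted_markers=(PlantedMarker("GS00001", 0.8, "all"),))
        study = generate_study(cfg)
        write_study(study, tmp_path)
        back = read_counts_matrix(tmp_path / "DS1_counts.tsv", "DS1")
        assert np.array_equal(back.values, study.datasets[0].counts.values)
        surv = read_survival_table(tmp_path / "DS1_os.tsv", "OS")
        assert len(surv) == 80
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth == {"GS00001": {"beta": 0.8, "datasets": ["DS1", "DS2"]}}


class TestNullFractionCheck:
    def test_planted_study_rejected(self):
        cfg = small_config(planted_markers=(PlantedMarker("GS00001", 1.0, "all"),))
        study = generate_study(cfg)
        with pytest.raises(ValidationError):
            null_fraction_check(study, [])

    def test_empty_results_rejected(self):
        study = generate_study(small_config())
        with pytest.raises(ValidationError):
            null_fraction_check(study, [])

    def test_null_pass_fraction_near_alpha(self):
        study = generate_study(small_config(genes_per_dataset=400, samples_per_dataset=(150, 150)))
        results = {ds.counts.dataset_label: screen_dataset(ds) for ds in study.datasets}
        frac = null_fraction_check(study, results)
        # dual criterion under the null: at most alpha up to Monte Carlo noise
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 800)
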