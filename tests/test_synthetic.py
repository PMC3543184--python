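"""The synthetic world: determinism, stated distributions, bookkeeping."""

import numpy as np
import pytest
from scipy import stats as sps

import translatome_kit as tk


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_genes": 5}, "n_genes"),
            ({"n_genes": 50, "noise_cv": -0.1}, "noise_cv"),
            ({"n_genes": 50, "loss_mean": 0.0}, "loss_mean"),
            ({"n_genes": 50, "loss_mean": 1.5}, "loss_mean"),
            ({"n_genes": 50, "ancova_noise_sd": 0.0}, "ancova_noise_sd"),
            ({"n_genes": 50, "peak_weights": {"D": 0.5, "H": 0.6}},
             "peak_weights"),
        ],
    )
    def test_invalid_field_named(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            tk.SyntheticConfig(**kwargs)


class TestGeneTruth:
    def test_seed_determinism(self):
        cfg = tk.SyntheticConfig(n_genes=50, seed=1)
        a, b = tk.generate_gene_truth(cfg), tk.generate_gene_truth(cfg)
        np.testing.assert_array_equal(a.true_occupancy, b.true_occupancy)
        np.testing.assert_array_equal(a.true_proportions, b.true_proportions)
        assert a.features.equals(b.features)
        sa = tk.synthesize_arrays(a, cfg)
        sb = tk.synthesize_arrays(b, cfg)
        np.testing.assert_array_equal(sa.intensities, sb.intensities)

    def test_occupancy_marginal(self):
        """1000 genes from the truncated Gaussian (0.66, 0.06) have a
        sample mean within 0.01 of 0.66 (SE ~ 0.002)."""
        cfg = tk.SyntheticConfig(n_genes=1000, seed=2)
        truth = tk.generate_gene_truth(cfg)
        assert truth.true_occupancy.mean() == pytest.approx(0.66, abs=0.01)
        assert np.all((truth.true_occupancy > 0) & (truth.true_occupancy <= 1))

    def test_peak_class_counts(self):
        """At 1177 genes the D/H split (weights 0.17/0.83) lands inside
        the binomial 99% interval around (200, 977)."""
        cfg = tk.SyntheticConfig(n_genes=1177, seed=3)
        truth = tk.generate_gene_truth(cfg)
        n_d = int((truth.true_peak_fraction == "D").sum())
        lo = sps.binom.ppf(0.005, 1177, 0.17)
        hi = sps.binom.ppf(0.995, 1177, 0.17)
        assert lo <= n_d <= hi
        assert n_d + int((truth.true_peak_fraction == "H").sum()) == 1177

    def test_proportion_invariants(self):
        cfg = tk.SyntheticConfig(n_genes=300, seed=4)
        truth = tk.generate_gene_truth(cfg)
        np.testing.assert_allclose(truth.true_proportions.sum(axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(truth.true_proportions[:, 2:].sum(axis=1),
                                   truth.true_occupancy, atol=1e-12)
        # peak fraction is the strict argmax over D..H
        dh = truth.true_proportions[:, 2:]
        labels = np.array(tk.TRANSLATING_FRACTIONS)
        np.testing.assert_array_equal(labels[np.argmax(dh, axis=1)],
                                      truth.true_peak_fraction)

    def test_density_consistency(self, default_calibration):
        cfg = tk.SyntheticConfig(n_genes=100, seed=5)
        truth = tk.generate_gene_truth(cfg)
        rep = {f: default_calibration.fraction_ranges[f][2]
               for f in tk.TRANSLATING_FRACTIONS}
        expected = np.array([rep[f] for f in truth.true_peak_fraction])
        np.testing.assert_allclose(
            truth.true_density, expected * 100.0 / truth.cds_length_nt,
            rtol=1e-12,
        )


class TestArraySynthesis:
    def test_mean_mrna_recovery(self):
        """The per-gene recovered fraction of mRNA after fractionation
        averages near the configured 60% loss level."""
        cfg = tk.SyntheticConfig(n_genes=500, seed=9)
        truth = tk.generate_gene_truth(cfg)
        series = tk.synthesize_arrays(truth, cfg)
        per_gene = (truth.true_proportions[:, :, None]
                    * series.synthesis.recovery[None, :, :]).sum(axis=1)
        assert per_gene.mean() == pytest.approx(0.60, abs=0.06)

    def test_rna_quantities_in_stated_range(self):
        cfg = tk.SyntheticConfig(n_genes=50, seed=10)
        series = tk.synthesize_arrays(tk.generate_gene_truth(cfg), cfg)
        fraction_rna = series.rna_quantity[1:]
        assert fraction_rna.min() > 29.7 / 3 and fraction_rna.max() < 436.3 * 3
        assert series.rna_quantity.shape == (8, 3)

    def test_mismatched_truth_rejected(self):
        cfg_a = tk.SyntheticConfig(n_genes=50, seed=1)
        cfg_b = tk.SyntheticConfig(n_genes=60, seed=1)
        truth = tk.generate_gene_truth(cfg_a)
        with pytest.raises(ValueError, match="n_genes"):
            tk.synthesize_arrays(truth, cfg_b)


class TestProfileSynthesis:
    def test_calibration_round_trip(self):
        """A profile generated from (a, b) refits to (a, b) to machine
        precision: peak times sit exactly on the log-linear law."""
        cfg = tk.SyntheticConfig(n_genes=10, seed=6)
        a, b = 0.4, np.log(7.0)
        bundle = tk.synthesize_profile(a, b, cfg)
        cal = tk.fit_ribosome_calibration([bundle.monosome_time],
                                          [bundle.resolved_peaks])
        assert cal.a == pytest.approx(a, abs=1e-12)
        assert cal.b[0] == pytest.approx(b, abs=1e-12)

    def test_engaged_fraction_target(self):
        cfg = tk.SyntheticConfig(n_genes=10, seed=7, target_engaged_pct=61.0)
        bundle = tk.synthesize_profile(0.4, np.log(7.0), cfg)
        assert tk.engaged_ribosome_fraction(bundle.profile) == pytest.approx(
            61.0, abs=0.5
        )

    def test_subunit_roles_assigned(self):
        cfg = tk.SyntheticConfig(n_genes=10, seed=8)
        bundle = tk.synthesize_profile(0.4, np.log(7.0), cfg)
        assert bundle.profile.roles[2] == "subunit_30S"
        assert bundle.profile.roles[3] == "subunit_50S"
        assert len(bundle.profile.boundaries) == 12

    def test_nonpositive_slope_rejected(self):
        cfg = tk.SyntheticConfig(n_genes=10, seed=8)
        with pytest.raises(ValueError, match="positive"):
            tk.synthesize_profile(-0.4, np.log(7.0), cfg)


class TestParameterRecoveryWorld:
    def test_occupancy_recovery_under_noise(self, default_calibration):
        """With 10% multiplicative intensity noise (recovery held constant
        across fractions, as the fractionation loss was observed to be),
        estimated and true occupancy correlate above 0.9 and >= 95% of
        single-peak genes get the true peak fraction."""
        cfg = tk.SyntheticConfig(n_genes=600, seed=5, loss_sd=0.0)
        truth = tk.generate_gene_truth(cfg)
        series = tk.synthesize_arrays(truth, cfg)
        res = tk.run_pipeline(tk.PipelineConfig(
            series=series, features=truth.features,
            calibration=default_calibration, n_boot=2000, seed=1,
            fit_models=False,
        ))
        kept = series.synthesis.kept_mask
        r = np.corrcoef(res.translatome["occupancy"],
                        truth.true_occupancy[kept])[0, 1]
        assert r >= 0.9
        single = ~res.translatome["peak_unassigned"]
        acc = (res.translatome.loc[single, "peak_fraction"].to_numpy()
               == truth.true_peak_fraction[kept][single.to_numpy()]).mean()
        assert acc >= 0.95


def test_write_inputs_round_trip(tmp_path, noiseless_world):
    cfg, truth, series = noiseless_world
    bundle = tk.synthesize_profile(0.4, np.log(7.0), cfg)
    paths = tk.write_inputs(tmp_path, cfg, truth, series, bundle)
    loaded = tk.load_array_series(paths["intensities"], paths["fractions"])
    np.testing.assert_allclose(loaded.intensities, series.intensities,
                               rtol=1e-12)
    np.testing.assert_allclose(loaded.rna_quantity, series.rna_quantity,
                               rtol=1e-12)
    assert loaded.gene_ids == series.gene_ids
    assert paths["config"].read_text().startswith(("ancova", "below"))
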