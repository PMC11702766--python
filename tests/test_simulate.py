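import numpy as np
import pandas as pd
import pytest

from ciberdyn import SimConfig, default_design, generate_constructs, generate_guide_library, generate_truth
from ciberdyn.design import SampleMeta
from ciberdyn.library import ParameterError
from ciberdyn.simulate import (
    expected_counts_for_sample,
    simulate_counts,
    simulate_screen,
)
from ciberdyn.truth import TruthModel
from conftest import make_truth_frame


def _two_construct_setup(gamma=0.0):
    frame = make_truth_frame(
        {
            "c1": {}, "c2": {},
            "t1": {"growth_effect": gamma / 2}, "t2": {"growth_effect": gamma / 2},
        }
    )
    truth = TruthModel(guides=frame)
    constructs = pd.DataFrame(
        {
            "construct_id": ["C1", "C2"],
            "perturbation": ["c1+c2", "t1+t2"],
            "guide_first": ["c1", "t1"],
            "guide_second": ["c2", "t2"],
            "barcode_ubc6": ["A" * 22, "C" * 22],
            "barcode_pcl5": ["A" * 23, "C" * 23],
        }
    )
    return truth, constructs


class TestCountModel:
    def test_determinism_byte_identical(self, small_screen):
        s = small_screen
        again = simulate_screen(s["library"], s["constructs"], s["truth"], s["design"], s["cfg"])
        assert again.counts.to_csv() == s["sim"].counts.to_csv()
        assert again.manifest.to_csv() == s["sim"].manifest.to_csv()

    def test_expected_count_conservation(self, small_screen):
        exp = small_screen["sim"].expected
        L = small_screen["cfg"].library_size_per_sample
        for s in exp.columns:
            if s in ("construct_id", "reporter"):
                continue
            assert exp[s].sum() == pytest.approx(L, rel=1e-9)

    def test_null_model_reporter_symmetry(self):
        # phi = 0, no growth effects, zero activity: expected PCL5 == UBC6
        truth, constructs = _two_construct_setup(gamma=0.0)
        cfg = SimConfig(
            rng_seed=1, library_size_per_sample=100_000, nb_dispersion=0.0,
            initial_abundance_sd_log2=0.0,
        )
        counts, expected = simulate_counts(constructs, truth, default_design(), cfg)
        for s in [c for c in expected.columns if c not in ("construct_id", "reporter")]:
            u = expected.loc[expected.reporter == "UBC6", s].to_numpy()
            p = expected.loc[expected.reporter == "PCL5", s].to_numpy()
            np.testing.assert_allclose(p, u, rtol=1e-9)

    def test_growth_law_closed_form(self):
        # gamma = -0.5 over two doubling times: the deleterious construct's
        # UBC6 frequency ratio post/pre is 2**(2*(1-0.5)) / 2**2 = 1/2 of a
        # neutral construct's
        truth, constructs = _two_construct_setup(gamma=-0.5)
        cfg = SimConfig(library_size_per_sample=1_000_000, initial_abundance_sd_log2=0.0)
        design = [
            SampleMeta("pre", "pre_induction", 0.0, None, 0.0),
            SampleMeta("post", "post_induction", 0.0, None, 2 * cfg.doubling_time_h),
        ]
        _, expected = simulate_counts(constructs, truth, design, cfg)
        u = expected[expected.reporter == "UBC6"].set_index("construct_id")
        ratio_neutral = u.loc["C1", "post"] / u.loc["C1", "pre"]
        ratio_slow = u.loc["C2", "post"] / u.loc["C2", "pre"]
        assert ratio_slow / ratio_neutral == pytest.approx(0.5, rel=1e-9)

    def test_negative_binomial_moments(self):
        # empirical mean/variance over replicate draws match NB(mu, phi)
        truth, constructs = _two_construct_setup()
        phi = 0.1
        cfg = SimConfig(
            library_size_per_sample=400, nb_dispersion=phi, initial_abundance_sd_log2=0.0
        )
        design = [SampleMeta("post", "post_induction", 0.0, None, 0.0)]
        n_rep = 1000
        draws = np.empty(n_rep)
        rng = np.random.default_rng(123)
        for i in range(n_rep):
            counts, expected = simulate_counts(constructs, truth, design, cfg, rng)
            draws[i] = counts.loc[0, "post"]
        mu = expected.loc[0, "post"]
        var_expected = mu + phi * mu**2
        se_mean = draws.std(ddof=1) / np.sqrt(n_rep)
        assert abs(draws.mean() - mu) < 3 * se_mean
        dev = (draws - draws.mean()) ** 2
        se_var = dev.std(ddof=1) / np.sqrt(n_rep)
        assert abs(draws.var(ddof=1) - var_expected) < 3 * se_var

    def test_zero_library_size_warns_and_zeroes(self):
        truth, constructs = _two_construct_setup()
        cfg = SimConfig(library_size_per_sample=0)
        with pytest.warns(UserWarning):
            counts, _ = simulate_counts(constructs, truth, default_design(), cfg)
        sample_cols = [c for c in counts.columns if c not in ("construct_id", "reporter")]
        assert (counts[sample_cols].to_numpy() == 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            SimConfig(base_error_rate=1.5)
        with pytest.raises(ParameterError):
            SimConfig(nb_dispersion=-0.1)


class TestManifestAndTruthTable:
    def test_manifest_marks_singletons_and_controls(self, small_screen):
        man = small_screen["sim"].manifest
        sizes = man.groupby("perturbation").size()
        for r in man.itertuples():
            assert r.n_barcodes == sizes[r.perturbation]
            assert r.single_barcode == (sizes[r.perturbation] == 1)
        ctrl = set(small_screen["library"].control_ids)
        expected_flag = man.guide_first.isin(ctrl) & man.guide_second.isin(ctrl)
        assert (man.is_control_pair == expected_flag).all()

    def test_truth_table_covers_post_induction_samples(self, small_screen):
        tp = small_screen["sim"].truth_phenotypes
        assert set(tp.sample_id) == {
            s.sample_id for s in small_screen["design"] if s.phase != "pre_induction"
        }
        assert tp.perturbation.nunique() == small_screen["constructs"].perturbation.nunique()
        # control pairs have zero truth everywhere
        ctrl_perts = small_screen["sim"].manifest.loc[
            small_screen["sim"].manifest.is_control_pair, "perturbation"
        ].unique()
        sub = tp[tp.perturbation.isin(ctrl_perts)]
        assert np.allclose(sub.isr_true, 0.0) and np.allclose(sub.growth_true, 0.0)
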