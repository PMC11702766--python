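import math

import numpy as np
import pandas as pd
import pytest

from ciberdyn.dynamics import (
    contrast,
    dose_contrast,
    gc_filter_guides,
    pair_interaction,
    profile_matrix,
    single_guide_phenotypes,
)
from ciberdyn.library import Guide, GuideLibrary, ParameterError


def _pheno(rows):
    return pd.DataFrame(
        rows,
        columns=["perturbation", "sample_id", "isr_log2fc", "isr_se", "growth_log2fc", "growth_se"],
    )


class TestContrast:
    def _table(self):
        return _pheno(
            [
                ["p1", "a", 2.0, 0.1, 0.0, 0.1],
                ["p1", "b", 1.0, 0.1, 0.0, 0.1],
                ["p2", "a", -0.5, 0.2, 0.0, 0.1],
                ["p2", "b", -0.5, 0.2, 0.0, 0.1],
            ]
        )

    def test_difference_and_propagated_se(self):
        c = contrast(self._table(), "a", "b").set_index("perturbation")
        assert c.loc["p1", "delta"] == pytest.approx(1.0)
        assert c.loc["p1", "se"] == pytest.approx(math.sqrt(0.01 + 0.01))
        assert c.loc["p1", "se"] == pytest.approx(0.1414214, abs=1e-6)
        assert c.loc["p2", "delta"] == pytest.approx(0.0)

    def test_antisymmetry(self):
        ab = contrast(self._table(), "a", "b").set_index("perturbation")
        ba = contrast(self._table(), "b", "a").set_index("perturbation")
        np.testing.assert_allclose(ab.delta, -ba.delta)
        np.testing.assert_allclose(ab.se, ba.se)

    def test_identical_condition_zero(self):
        c = contrast(self._table(), "a", "a")
        assert (c.delta == 0).all()

    def test_missing_condition_errors(self):
        with pytest.raises(ParameterError):
            contrast(self._table(), "a", "missing")


class TestPairInteraction:
    def test_arithmetic(self):
        eta, se = pair_interaction(3.0, 0.1, 1.0, 0.1, 1.5, 0.1)
        assert eta == pytest.approx(0.5)
        assert se == pytest.approx(math.sqrt(3) * 0.1)
        assert se == pytest.approx(0.1732051, abs=1e-6)

    def test_additive_truth_centers_at_zero(self):
        eta, _ = pair_interaction(2.5, 0.1, 1.0, 0.1, 1.5, 0.1)
        assert eta == pytest.approx(0.0)

    def test_missing_component_errors(self):
        with pytest.raises(ParameterError):
            pair_interaction(float("nan"), 0.1, 1.0, 0.1, 1.0, 0.1)


class TestGcFilter:
    def _lib(self):
        seqs = {
            "low": "AT" * 8 + "GCAT",  # 5/20 -> wait: recompute below
            "boundary": "AAAAAAAAAAAAAAAGCGCG",  # 5 G/C of 20 = 0.25
            "mid": "GCGCGCGCGCATATATATAT",  # 10/20 = 0.50
            "verylow": "ATATATATATATGCGCATAT",  # 4 G/C of 20 = 0.20
        }
        guides = []
        for name, seq in seqs.items():
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            guides.append(Guide(name, name.upper(), seq, gc))
        return GuideLibrary(guides)

    def test_strict_boundary_and_flagging(self):
        lib = self._lib()
        kept, flagged = gc_filter_guides(lib, min_gc=0.25)
        kept_ids = set(kept.guide_id)
        flagged_ids = set(flagged.guide_id)
        df = lib.to_frame().set_index("guide_id")
        # 4 G/C in 20 nt (gc = 0.20) is flagged
        assert df.loc["verylow", "gc_fraction"] == pytest.approx(0.20)
        assert "verylow" in flagged_ids
        # gc exactly 0.25 is kept (strict inequality)
        assert df.loc["boundary", "gc_fraction"] == pytest.approx(0.25)
        assert "boundary" in kept_ids
        # optimal-range guide is kept
        assert df.loc["mid", "gc_fraction"] == pytest.approx(0.50)
        assert "mid" in kept_ids
        assert kept_ids | flagged_ids == set(df.index)


class TestSingleGuides:
    def _map(self):
        return pd.DataFrame(
            {
                "construct_id": ["C1", "C2", "C3"],
                "perturbation": ["g1+HO_01", "g1+HO_02", "HO_01+HO_02"],
                "guide_first": ["g1", "HO_02", "HO_01"],
                "guide_second": ["HO_01", "g1", "HO_02"],
            }
        )

    def test_single_control_pairing_passthrough(self):
        pheno = _pheno([["g1+HO_01", "s", 1.4, 0.2, -0.3, 0.1]])
        singles, unpaired = single_guide_phenotypes(pheno, self._map(), ["HO_01", "HO_02"])
        row = singles.iloc[0]
        assert row.guide == "g1"
        assert row.isr_log2fc == pytest.approx(1.4)
        assert row.isr_se == pytest.approx(0.2)
        assert row.n_control_partners == 1
        assert unpaired == []

    def test_two_equal_se_pairings_average(self):
        pheno = _pheno(
            [
                ["g1+HO_01", "s", 1.0, 0.2, 0.0, 0.1],
                ["g1+HO_02", "s", 2.0, 0.2, 0.0, 0.1],
            ]
        )
        singles, _ = single_guide_phenotypes(pheno, self._map(), ["HO_01", "HO_02"])
        row = singles.iloc[0]
        assert row.isr_log2fc == pytest.approx(1.5)
        assert row.n_control_partners == 2

    def test_control_control_pairs_excluded(self):
        pheno = _pheno([["HO_01+HO_02", "s", 0.1, 0.2, 0.0, 0.1]])
        singles, unpaired = single_guide_phenotypes(pheno, self._map(), ["HO_01", "HO_02"])
        assert singles.empty
        assert unpaired == ["g1"]


def test_profile_matrix_drops_pre():
    pheno = _pheno(
        [
            ["p1", "pre", 0.0, 0.1, np.nan, np.nan],
            ["p1", "post", 1.0, 0.1, 0.0, 0.1],
            ["p1", "high_1h", 2.0, 0.1, 0.0, 0.1],
        ]
    )
    prof = profile_matrix(pheno)
    assert list(prof.columns) == ["high_1h", "post"]
    assert prof.loc["p1", "post"] == 1.0


def test_dose_contrast_label_convention():
    pheno = _pheno(
        [
            ["p1", "high_1h", 2.0, 0.1, 0.0, 0.1],
            ["p1", "low_1h", 0.5, 0.1, 0.0, 0.1],
        ]
    )
    c = dose_contrast(pheno, "1h")
    assert c.delta.iloc[0] == pytest.approx(1.5)
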