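"""Summary-statistics I/O, harmonization, meta-analysis subtraction, models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expresso.sumstats import (
    MarginalEqtlStats,
    WeightModel,
    harmonize_alleles,
    meta_subtract,
    read_eqtl_sumstats,
    read_weight_models,
    write_weight_models,
)


def _write(tmp_path, name, df):
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


def _eqtl_frame(**overrides):
    base = dict(
        gene=["G1"] * 3,
        chrom=["1"] * 3,
        pos=[100, 200, 300],
        ref=["A", "C", "A"],
        alt=["G", "T", "G"],
        beta=[0.3, -0.1, 0.0],
        se=[0.1, 0.1, 0.2],
        n=[500, 500, 500],
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestReadEqtl:
    def test_identity_read(self, tmp_path):
        stats = read_eqtl_sumstats(_write(tmp_path, "e.tsv", _eqtl_frame()), "G1")
        assert len(stats) == 3
        assert list(stats.table["pos"]) == [100, 200, 300]

    def test_z_derived_from_beta_se(self, tmp_path):
        stats = read_eqtl_sumstats(_write(tmp_path, "e.tsv", _eqtl_frame()), "G1")
        assert np.isclose(stats.table.loc[stats.table["pos"] == 100, "z"].iloc[0], 3.0)

    def test_se_zero_rejected_with_warning(self, tmp_path, caplog):
        df = _eqtl_frame(se=[0.1, 0.0, 0.2])
        with caplog.at_level("WARNING"):
            stats = read_eqtl_sumstats(_write(tmp_path, "e.tsv", df), "G1")
        assert len(stats) == 2
        assert "se = 0" in caplog.text

    def test_duplicate_variant_errors_with_name(self, tmp_path):
        df = _eqtl_frame(pos=[100, 100, 300], ref=["A", "A", "A"], alt=["G", "G", "G"])
        with pytest.raises(ValueError, match="1:100"):
            read_eqtl_sumstats(_write(tmp_path, "e.tsv", df), "G1")

    def test_unmappable_column_errors(self, tmp_path):
        df = _eqtl_frame().drop(columns=["n"])
        with pytest.raises(ValueError, match="required column"):
            read_eqtl_sumstats(_write(tmp_path, "e.tsv", df), "G1")

    def test_column_mapping(self, tmp_path):
        df = _eqtl_frame().rename(columns={"n": "NrSamples", "z": "Zscore"})
        stats = read_eqtl_sumstats(
            _write(tmp_path, "e.tsv", df), "G1", colmap={"n": "NrSamples", "z": "Zscore"}
        )
        assert len(stats) == 3


class TestHarmonize:
    def _stats(self):
        return MarginalEqtlStats(
            gene_id="G1",
            table=pd.DataFrame(
                dict(
                    chrom=["1", "1", "1"],
                    pos=[100, 200, 300],
                    id=["v1", "v2", "v3"],
                    ref=["A", "T", "A"],
                    alt=["G", "C", "T"],
                    beta=[0.3, -0.1, 0.2],
                    se=[0.1, 0.1, 0.1],
                    z=[3.0, -1.0, 2.0],
                    n=[500, 500, 500],
                )
            ),
        )

    def _panel(self):
        return pd.DataFrame(
            dict(chrom=["1", "1", "1"], pos=[100, 200, 300], ref=["A", "C", "A"], alt=["G", "T", "T"])
        )

    def test_same_orientation_unchanged_and_swap_negated(self):
        out = harmonize_alleles(self._stats(), self._panel())
        tab = out.table.set_index("pos")
        assert tab.loc[100, "z"] == 3.0  # same alleles
        assert tab.loc[200, "z"] == 1.0  # swapped -> negated

    def test_palindromic_dropped(self):
        out = harmonize_alleles(self._stats(), self._panel())
        assert 300 not in set(out.table["pos"])  # A/T ambiguous

    def test_idempotent(self):
        once = harmonize_alleles(self._stats(), self._panel())
        twice = harmonize_alleles(once, self._panel())
        pd.testing.assert_frame_equal(
            once.table.reset_index(drop=True), twice.table.reset_index(drop=True)
        )


class TestMetaSubtract:
    def _mk(self, beta, se, n=1000):
        k = len(beta)
        return MarginalEqtlStats(
            gene_id="G1",
            table=pd.DataFrame(
                dict(
                    chrom=["1"] * k,
                    pos=np.arange(100, 100 + k),
                    id=[f"v{i}" for i in range(k)],
                    ref=["A"] * k,
                    alt=["G"] * k,
                    beta=beta,
                    se=se,
                    z=np.array(beta) / np.array(se),
                    n=[n] * k,
                )
            ),
        )

    def test_inverse_variance_arithmetic(self):
        meta = self._mk([1.0], [1 / np.sqrt(2)], n=300)
        cohort = self._mk([0.5], [1.0], n=100)
        out = meta_subtract(meta, cohort)
        assert np.isclose(out.table["beta"].iloc[0], 1.5)
        assert np.isclose(out.table["se"].iloc[0], 1.0)
        assert out.table["n"].iloc[0] == 200

    def test_equal_weight_cancellation(self):
        # meta of two equal-weight cohorts, subtract one -> the other remains
        b1, b2, se = 0.8, -0.4, 0.3
        w = se**-2
        beta_meta = (w * b1 + w * b2) / (2 * w)
        se_meta = (2 * w) ** -0.5
        meta = self._mk([beta_meta], [se_meta], n=200)
        out = meta_subtract(meta, self._mk([b2], [se], n=100))
        assert np.isclose(out.table["beta"].iloc[0], b1, atol=1e-12)
        assert np.isclose(out.table["se"].iloc[0], se, atol=1e-12)

    def test_cohort_not_subset_errors(self):
        meta = self._mk([1.0], [1.0])
        cohort = self._mk([0.5], [0.5])  # more precise than the meta
        with pytest.raises(ValueError, match="not a subset"):
            meta_subtract(meta, cohort)

    @settings(max_examples=50, deadline=None)
    @given(
        b_a=st.floats(-2, 2),
        b_c=st.floats(-2, 2),
        se_a=st.floats(0.05, 2),
        se_c=st.floats(0.05, 2),
    )
    def test_exact_inverse_of_meta_analysis(self, b_a, b_c, se_a, se_c):
        """subtract(meta(a, c), c) recovers a to 1e-12."""
        w_a, w_c = se_a**-2, se_c**-2
        beta_m = (w_a * b_a + w_c * b_c) / (w_a + w_c)
        se_m = (w_a + w_c) ** -0.5
        meta = self._mk([beta_m], [se_m], n=500)
        out = meta_subtract(meta, self._mk([b_c], [se_c], n=200))
        assert abs(out.table["beta"].iloc[0] - b_a) < 1e-9 * max(1, abs(b_a))
        assert abs(out.table["se"].iloc[0] - se_a) < 1e-12 * max(1, se_a)


class TestWeightModels:
    def _model(self, gene="G1", ct="B", weights=(0.5, -0.25)):
        k = len(weights)
        return WeightModel(
            gene_id=gene,
            cell_type=ct,
            variants=pd.DataFrame(
                dict(chrom=["1"] * k, pos=range(100, 100 + k), ref=["A"] * k, alt=["G"] * k)
            ),
            beta_hat=np.array(weights),
            essential_flags=np.array([True, False][:k]),
            chosen_lambda=0.123456789012345,
            chosen_phi=1 / 6,
            chosen_window="linear_100k",
            training_n=1000.0,
        )

    def test_round_trip_lossless(self, tmp_path):
        m = self._model(weights=(1 / 3, -2 / 7))
        write_weight_models([m], str(tmp_path / "wm"))
        back = read_weight_models(str(tmp_path / "wm"))[("G1", "B")]
        assert np.array_equal(back.beta_hat, m.beta_hat)  # bit-exact via repr()
        assert back.chosen_lambda == m.chosen_lambda
        assert back.chosen_phi == m.chosen_phi
        assert np.array_equal(back.essential_flags, m.essential_flags)

    def test_all_zero_model_refused(self):
        with pytest.raises(ValueError, match="nonzero"):
            self._model(weights=(0.0, 0.0))

    def test_two_cell_types_same_gene(self, tmp_path):
        ms = [self._model(ct="B"), self._model(ct="T", weights=(0.1, 0.9))]
        write_weight_models(ms, str(tmp_path / "wm"))
        back = read_weight_models(str(tmp_path / "wm"))
        assert set(back) == {("G1", "B"), ("G1", "T")}

    def test_version_mismatch_errors(self, tmp_path):
        import json

        write_weight_models([self._model()], str(tmp_path / "wm"))
        meta_path = tmp_path / "wm.meta.json"
        meta = json.loads(meta_path.read_text())
        meta["version"] = "999"
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="version"):
            read_weight_models(str(tmp_path / "wm"))
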