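"""PC1 composite index: eigen oracle, sign convention, invariances."""

import numpy as np
import pytest

from qsarcov import ModelRecord, ModelTable, metric_correlations, pc1_index
from qsarcov.errors import DegenerateDataError, InsufficientDataError, ValidationError

PRINTED_R = np.array([[1.0, 0.859, 0.922], [0.859, 1.0, 0.943], [0.922, 0.943, 1.0]])


def table_from_columns(ba, mcc, f1, cov=None):
    n = len(ba)
    cov = cov if cov is not None else [90.0] * n
    return ModelTable(records=[
        ModelRecord(model_uid=i + 1, cov=cov[i], ba=float(ba[i]), mcc=float(mcc[i]), f1=float(f1[i]))
        for i in range(n)
    ])


class TestPC1Index:
    def test_perfect_collinearity(self):
        latent = np.array([60.0, 65.0, 70.0, 75.0, 80.0])
        t = table_from_columns(latent, (latent - 60) / 50, latent - 10)
        res = pc1_index(t)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert res.variance_fraction[1:] == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_variance_fraction_matches_eigen_oracle(self, rng):
        """PC1 fraction equals the largest eigenvalue of the sample correlation
        matrix divided by the metric count (independent eigensolver)."""
        X = rng.multivariate_normal([70, 0.3, 50], np.diag([25, 0.01, 49]), size=60)
        X[:, 1] = np.clip(X[:, 1], -1, 1)
        t = table_from_columns(np.clip(X[:, 0], 0, 100), X[:, 1], np.clip(X[:, 2], 0, 100))
        res = pc1_index(t)
        R = np.corrcoef(np.column_stack([[r.ba for r in t], [r.mcc for r in t], [r.f1 for r in t]]),
                        rowvar=False)
        eigvals = np.linalg.eigvalsh(R)
        assert res.variance_fraction[0] == pytest.approx(eigvals[-1] / 3, abs=1e-9)

    def test_simulated_tables_match_printed_correlation_eigenvalue(self, default_table):
        """Tables generated at the published inter-metric correlations give a
        PC1 fraction near the printed matrix's top eigenvalue / 3 (~0.939)."""
        expected = np.linalg.eigvalsh(PRINTED_R)[-1] / 3
        res = pc1_index(default_table)
        assert res.variance_fraction[0] == pytest.approx(expected, abs=0.05)

    def test_sign_convention_all_loadings_positive(self, default_table):
        res = pc1_index(default_table)
        assert np.all(res.pc1_loadings > 0)

    def test_negating_columns_flips_then_reflips(self, default_table):
        res = pc1_index(default_table)
        neg = table_from_columns(
            [100 - r.ba for r in default_table],
            [-r.mcc for r in default_table],
            [100 - r.f1 for r in default_table],
        )
        res_neg = pc1_index(neg)
        assert res_neg.variance_fraction == pytest.approx(res.variance_fraction, abs=1e-9)
        assert np.all(res_neg.pc1_loadings > 0)  # convention re-flips PC1
        # scores are mirrored relative to the original table
        assert np.corrcoef(res.scores["PC1"], res_neg.scores["PC1"])[0, 1] == pytest.approx(-1.0)

    def test_scores_zero_mean_and_variance_equals_eigenvalue(self, default_table):
        res = pc1_index(default_table)
        R = np.array(metric_correlations(default_table))
        eigvals = np.sort(np.linalg.eigvalsh(R))[::-1]
        for k in range(3):
            s = res.scores[f"PC{k + 1}"].to_numpy()
            assert s.mean() == pytest.approx(0.0, abs=1e-9)
            assert s.var(ddof=1) == pytest.approx(eigvals[k], abs=1e-9)

    def test_affine_rescaling_invariance(self, default_table):
        """Correlation-matrix PCA ignores affine changes of metric units."""
        res = pc1_index(default_table)
        rescaled = table_from_columns(
            [r.ba / 2 + 10 for r in default_table],
            [r.mcc / 4 for r in default_table],
            [r.f1 / 2 + 5 for r in default_table],
            cov=[r.cov for r in default_table],
        )
        res2 = pc1_index(rescaled)
        assert res2.scores["PC1"].to_numpy() == pytest.approx(res.scores["PC1"].to_numpy(), abs=1e-9)

    def test_loadings_orthonormal(self, default_table):
        L = pc1_index(default_table).loadings
        assert L @ L.T == pytest.approx(np.eye(3), abs=1e-9)

    def test_errors(self):
        t = table_from_columns([70.0] * 5, [0.3, 0.4, 0.5, 0.2, 0.1], [50, 51, 52, 53, 54])
        with pytest.raises(DegenerateDataError, match="ba"):
            pc1_index(t)
        small = table_from_columns([70.0, 71.0], [0.3, 0.4], [50, 51])
        with pytest.raises(InsufficientDataError):
            pc1_index(small)
        missing = ModelTable(records=[
            ModelRecord(model_uid=1, cov=90, ba=70.0, mcc=0.3, f1=50.0),
            ModelRecord(model_uid=2, cov=90, ba=71.0, mcc=0.4),
            ModelRecord(model_uid=3, cov=90, ba=72.0, mcc=0.5, f1=52.0),
        ])
        with pytest.raises(ValidationError, match="2"):
            pc1_index(missing)


class TestMetricCorrelations:
    def test_identical_and_negated_columns(self):
        x = np.array([60, 65, 70, 75, 80.0])
        t = table_from_columns(x, (x - 70) / 50, x)
        R = metric_correlations(t)
        assert R.loc["ba", "f1"] == pytest.approx(1.0)
        t2 = table_from_columns(x, -(x - 70) / 50, x)
        assert metric_correlations(t2).loc["ba", "mcc"] == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        ba = np.array([60, 62, 65, 71, 80.0])
        f1 = np.array([40, 45, 44, 52, 60.0])
        mcc = np.array([0.2, 0.25, 0.24, 0.33, 0.41])
        t = table_from_columns(ba, mcc, f1)
        # textbook formula: cov(x, y) / (sigma_x sigma_y)
        def r(x, y):
            return float(np.sum((x - x.mean()) * (y - y.mean()))
                         / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        R = metric_correlations(t)
        assert R.loc["ba", "f1"] == pytest.approx(r(ba, f1), abs=1e-12)
        assert R.loc["mcc", "f1"] == pytest.approx(r(mcc, f1), abs=1e-12)
        assert np.allclose(np.array(R), np.array(R).T)
        assert np.all(np.diag(np.array(R)) == 1.0)
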