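"""Cell-count regression: fitting, prediction, serialization, well totals."""

import math
from dataclasses import replace

import numpy as np
import pytest

from orgquant.cellcount import (
    CountModel,
    CountRecord,
    estimate_well,
    fit,
    load_model,
    predict_cells,
    read_records_csv,
    save_model,
    write_records_csv,
)
from orgquant.core import OrgquantError
from orgquant.synthgen import SynthConfig, generate_training_table

from conftest import detset, square_instance

TRUE_LAW = dict(intercept=0.5, log_area=1.0, sample_type=-0.2, morphology=-0.3)


def law_records(rng, n, sigma, beta=TRUE_LAW):
    """Synthetic rows drawn directly from the log-linear law (no imaging)."""
    areas = np.exp(rng.normal(8.0, 0.5, n))
    S = rng.integers(0, 2, n)
    M = rng.integers(0, 2, n)
    eps = rng.normal(0, sigma, n) if sigma > 0 else np.zeros(n)
    log_n = (
        beta["intercept"] + beta["log_area"] * np.log(areas)
        + beta["sample_type"] * S + beta["morphology"] * M + eps
    )
    counts = np.maximum(1, np.round(np.exp(log_n)))
    return [
        CountRecord(area=float(a), sample_type=int(s), morphology=int(m),
                    real_nuclei=int(c),
                    perimeter=float(2 * math.sqrt(math.pi * a)))
        for a, s, m, c in zip(areas, S, M, counts)
    ]


def exact_law_records():
    """Zero-noise rows whose counts are exactly integral under the law, so
    the integer-count constraint does not perturb the fit."""
    # coefficients: b0 = ln 2, bA = 1, bS = -ln 2, bM = -ln 4
    # N = 2 * A * 2^-S * 4^-M is an exact integer for A a power of 2 >= 4
    rows = []
    for k in range(4, 16):
        A = 2**k
        for S in (0, 1):
            for M in (0, 1):
                N = 2 * A // (2**S) // (4**M)
                rows.append(
                    CountRecord(area=A, sample_type=S, morphology=M, real_nuclei=N)
                )
    truth = {
        "intercept": math.log(2), "log_area": 1.0,
        "sample_type": -math.log(2), "morphology": -math.log(4),
    }
    return rows, truth


class TestFit:
    def test_recovers_generator_law_within_3_se(self):
        """OLS on ~3000 generator records (sigma = 0.2) recovers every
        coefficient within 3 standard errors."""
        cfg = SynthConfig(n_organoids=100, seed=11)
        records = []
        for s in ("healthy", "tumor"):
            for m in ("cystic", "budded"):
                records += generate_training_table(
                    replace(cfg, sample_type=s, morphology=m, seed=17), 8
                )
        assert len(records) >= 3000
        model = fit(records)
        for name, true_val in TRUE_LAW.items():
            z = abs(model.coefficients[name] - true_val) / model.stderr[name]
            assert z < 3, f"{name}: z = {z:.2f}"

    def test_zero_noise_exact_recovery(self):
        rows, truth = exact_law_records()
        model = fit(rows)
        for name, true_val in truth.items():
            assert model.coefficients[name] == pytest.approx(true_val, abs=1e-8)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_saturated_system_exact(self):
        """n just above p with no noise: exact interpolation, ~zero residuals."""
        rows, _ = exact_law_records()
        model = fit(rows[:6])
        preds = [
            predict_cells(model, r.area, r.sample_type, r.morphology) for r in rows[:6]
        ]
        for p, r in zip(preds, rows[:6]):
            assert p == pytest.approx(r.real_nuclei, rel=1e-9)

    def test_degenerate_column_named(self):
        rows = [
            CountRecord(area=100 * (i + 1), sample_type=0, morphology=i % 2,
                        real_nuclei=100 + i)
            for i in range(20)
        ]
        with pytest.raises(OrgquantError, match="sample_type"):
            fit(rows)

    def test_too_few_records(self):
        rows, _ = exact_law_records()
        with pytest.raises(OrgquantError, match="at least"):
            fit(rows[:4])

    def test_residuals_sum_to_zero_in_log_space(self):
        rng = np.random.default_rng(21)
        rows = law_records(rng, 500, sigma=0.2)
        model = fit(rows)
        resid = [
            math.log(r.real_nuclei)
            - math.log(predict_cells(model, r.area, r.sample_type, r.morphology))
            for r in rows
        ]
        assert abs(sum(resid)) < 1e-8 * len(rows)

    def test_log_base_equivariance(self):
        """Fitting with base-10 logs rescales coefficients but yields
        identical predictions."""
        rng = np.random.default_rng(31)
        rows = law_records(rng, 400, sigma=0.2)
        m_e = fit(rows, log_base=math.e)
        m_10 = fit(rows, log_base=10.0)
        assert m_10.coefficients["intercept"] == pytest.approx(
            m_e.coefficients["intercept"] / math.log(10)
        )
        for r in rows[:25]:
            assert predict_cells(m_10, r.area, r.sample_type, r.morphology) == pytest.approx(
                predict_cells(m_e, r.area, r.sample_type, r.morphology), rel=1e-9
            )

    def test_ci_coverage_over_replicates(self):
        """95% coefficient CIs cover the true values in [0.85, 1.0] of 50
        seeded replicates (n = 1000, sigma = 0.2)."""
        rng = np.random.default_rng(77)
        hits = {k: 0 for k in TRUE_LAW}
        n_rep = 50
        for _ in range(n_rep):
            model = fit(law_records(rng, 1000, sigma=0.2))
            for name, true_val in TRUE_LAW.items():
                half = 1.96 * model.stderr[name]
                if abs(model.coefficients[name] - true_val) <= half:
                    hits[name] += 1
        for name, h in hits.items():
            assert 0.85 <= h / n_rep <= 1.0, f"{name}: coverage {h / n_rep}"

    def test_extended_formula_requires_perimeter(self):
        rows, _ = exact_law_records()  # records without perimeter
        with pytest.raises(OrgquantError, match="perimeter"):
            fit(rows, formula="extended")

    def test_extended_formula_fits_and_predicts(self):
        rng = np.random.default_rng(41)
        rows = law_records(rng, 500, sigma=0.1)
        # vary shape so perimeter is not an exact function of area
        rows = [
            replace(r, perimeter=r.perimeter * rng.uniform(1.0, 1.4)) for r in rows
        ]
        model = fit(rows, formula="extended")
        assert set(model.coefficients) >= {"perimeter", "area_perimeter_ratio"}
        p = predict_cells(model, 3000.0, 0, 0, perimeter=200.0)
        assert np.isfinite(p) and p > 0


class TestPredict:
    def _identity_model(self):
        return CountModel(
            formula="base",
            coefficients={"intercept": 0.0, "log_area": 1.0,
                          "sample_type": 0.0, "morphology": 0.0},
            stderr={k: 0.0 for k in TRUE_LAW},
            log_base=math.e, fit_n=10, residual_sd=0.0,
        )

    def test_identity_model_returns_area(self):
        assert predict_cells(self._identity_model(), 100.0, 0, 0) == pytest.approx(100.0)

    def test_rounded_variant_at_least_one(self):
        model = self._identity_model()
        assert predict_cells(model, 1.0, 0, 0, rounded=True) == 1

    def test_monotone_in_area(self):
        rng = np.random.default_rng(51)
        model = fit(law_records(rng, 300, sigma=0.2))
        assert model.coefficients["log_area"] > 0
        areas = np.sort(rng.uniform(10, 1e5, 50))
        preds = predict_cells(model, areas, 1, 0)
        assert np.all(np.diff(preds) > 0)

    def test_invalid_area_rejected(self):
        with pytest.raises(OrgquantError, match="area"):
            predict_cells(self._identity_model(), 0.5, 0, 0)

    def test_base_model_rejects_perimeter(self):
        with pytest.raises(OrgquantError, match="no perimeter"):
            predict_cells(self._identity_model(), 100.0, 0, 0, perimeter=40.0)

    def test_string_covariates_accepted(self):
        m = self._identity_model()
        assert predict_cells(m, 64.0, "healthy", "cystic") == pytest.approx(64.0)
        with pytest.raises(OrgquantError, match="sample_type"):
            predict_cells(m, 64.0, "weird", "cystic")


class TestEstimateWell:
    def _model(self):
        return CountModel(
            formula="base",
            coefficients={"intercept": 0.0, "log_area": 1.0,
                          "sample_type": 0.0, "morphology": 0.0},
            stderr={k: 0.0 for k in TRUE_LAW},
            log_base=math.e, fit_n=10, residual_sd=0.0,
        )

    def test_empty_set_total_zero(self):
        est = estimate_well(detset([], deduplicated=True), self._model(), 0, 0)
        assert est.total == 0.0 and est.total_rounded == 0

    def test_singleton_total_equals_prediction(self):
        inst = square_instance(10, 10, 10, id=1)
        est = estimate_well(detset([inst], deduplicated=True), self._model(), 0, 0)
        assert est.total == pytest.approx(100.0)
        assert list(est.table["id"]) == [1]

    def test_non_deduplicated_rejected(self):
        inst = square_instance(10, 10, 10, id=1)
        with pytest.raises(OrgquantError, match="deduplicated"):
            estimate_well(detset([inst], deduplicated=False), self._model(), 0, 0)

    def test_total_is_sum_of_unrounded(self):
        insts = [square_instance(i * 20, 10, 7, id=i + 1) for i in range(5)]
        est = estimate_well(detset(insts, deduplicated=True), self._model(), 0, 0)
        assert est.total == pytest.approx(est.table["est_cells"].sum())
        assert est.total_rounded == est.table["est_cells_rounded"].sum()


class TestSerialization:
    def test_roundtrip_field_identical(self, tmp_path):
        rng = np.random.default_rng(61)
        model = fit(law_records(rng, 200, sigma=0.2))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back == model

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(OrgquantError, match="corrupt"):
            load_model(path)

    def test_schema_version_mismatch(self, tmp_path):
        rng = np.random.default_rng(62)
        model = fit(law_records(rng, 200, sigma=0.2))
        path = tmp_path / "model.json"
        save_model(model, path)
        import json as _json

        doc = _json.loads(path.read_text())
        doc["schema_version"] = 99
        path.write_text(_json.dumps(doc))
        with pytest.raises(OrgquantError, match="99"):
            load_model(path)

    def test_loaded_base_model_rejects_extended_args(self, tmp_path):
        rng = np.random.default_rng(63)
        model = fit(law_records(rng, 200, sigma=0.2))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        with pytest.raises(OrgquantError):
            predict_cells(back, 100.0, 0, 0, perimeter=40.0)

    def test_records_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(64)
        rows = law_records(rng, 30, sigma=0.2)
        path = tmp_path / "records.csv"
        write_records_csv(rows, path)
        back = read_records_csv(path)
        assert len(back) == len(rows)
        for a, b in zip(rows, back):
            assert b.area == pytest.approx(a.area, rel=1e-12)
            assert (b.sample_type, b.morphology, b.real_nuclei) == (
                a.sample_type, a.morphology, a.real_nuclei
            )
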