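"""QC, batch adjustment, media normalization and induction testing."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import betainc

from cytoarch import qc
from cytoarch.containers import ResponseTensor
from cytoarch.panels import (
    CytokineEntry,
    CytokinePanel,
    StimulusEntry,
    StimulusPanel,
    default_cytokine_panel,
    default_stimulus_panel,
)


def _tiny_panels():
    sp = StimulusPanel(
        (
            StimulusEntry("media", "media", 1, 0.0),
            StimulusEntry("LPS", "bacterial", 2, 0.0),
        )
    )
    cp = CytokinePanel(
        (CytokineEntry("IL6", "pro_inflammatory", {1: 10.0, 2: 10.0}),)
    )
    return sp, cp


def _tensor(values, batch, viability, sp=None, cp=None):
    if sp is None:
        sp, cp = _tiny_panels()
    values = np.asarray(values, dtype=float)
    return ResponseTensor(
        values=values,
        children=[f"c{i}" for i in range(values.shape[0])],
        batch=np.asarray(batch),
        viability=np.asarray(viability, dtype=float),
        stimulus_panel=sp,
        cytokine_panel=cp,
    )


@pytest.mark.parametrize(
    "value, lod, expected",
    [(3.0, 10.0, 5.0), (12.0, 10.0, 12.0), (np.nan, 10.0, np.nan), (10.0, 10.0, 10.0)],
)
def test_floor_to_lod_examples(value, lod, expected):
    out = qc.floor_to_lod(value, lod)
    if np.isnan(expected):
        assert np.isnan(out)
    else:
        assert out == expected


def test_floor_to_lod_rejects_nonpositive_lod():
    with pytest.raises(ValueError):
        qc.floor_to_lod(1.0, 0.0)


def _sentinel_tensor(viability, sentinel_values):
    """Full-panel single-child tensor with chosen sentinel responses."""
    sp = default_stimulus_panel()
    cp = default_cytokine_panel()
    values = np.full((1, 28, 16), 100.0)
    t = _tensor(values, [2], [viability], sp, cp)
    for (cyto, stim, _), v in zip(qc.SENTINELS, sentinel_values):
        t.values[0, t.cytokine_index(cyto), t.stimulus_index(stim)] = v
    return t


def test_low_viability_excluded():
    t = _sentinel_tensor(4.0, (100, 100, 100, 100))
    _, report = qc.apply_sample_exclusions(t)
    assert report.excluded_low_viability == ["c0"]
    assert report.retained == []


def test_inadequate_responder_requires_all_sentinels_to_fail():
    t = _sentinel_tensor(15.0, (4.0, 3.0, 5.0, 2.0))
    _, report = qc.apply_sample_exclusions(t)
    assert report.excluded_inadequate == ["c0"]

    # one sentinel above threshold breaks the conjunction
    t2 = _sentinel_tensor(15.0, (4.0, 3.0, 8.0, 2.0))
    _, report2 = qc.apply_sample_exclusions(t2)
    assert report2.retained == ["c0"]


def test_exclusion_report_partitions_children():
    t = _sentinel_tensor(32.0, (100, 100, 100, 100))
    _, report = qc.apply_sample_exclusions(t, extra_exclusions={"c0": "no response"})
    s = report.summary()
    assert s["input"] == 1 and s["excluded_other"] == 1


def test_batch_coefficient_equals_mean_log2_difference():
    # batch1 {4, 4}, batch2 {8, 8} pg/mL -> coefficient -1 on log2 scale
    values = np.array([[[4.0, 4]], [[4, 4]], [[8, 8]], [[8, 8]]])
    t = _tensor(values, [1, 1, 2, 2], [90, 90, 90, 90])
    model = qc.estimate_batch_model(t)
    assert np.allclose(model.coefficient.to_numpy(), -1.0)


def test_batch_coefficient_matches_ols_oracle(rng):
    import statsmodels.api as sm

    x = np.exp2(rng.normal(3, 1, size=40))
    t = _tensor(
        x.reshape(40, 1, 1).repeat(2, axis=2),
        np.repeat([1, 2], 20),
        np.full(40, 90.0),
    )
    model = qc.estimate_batch_model(t)
    design = sm.add_constant((t.batch == 1).astype(float))
    fit = sm.OLS(np.log2(x), design).fit()
    assert np.isclose(model.coefficient.iloc[0, 0], fit.params[1], atol=1e-10)
    assert np.isclose(model.se.iloc[0, 0], fit.bse[1], atol=1e-10)


def test_batch_coefficient_null_within_3se(rng):
    hits = 0
    n_sim = 400
    for _ in range(n_sim):
        x = np.exp2(rng.normal(3, 1, size=30))
        t = _tensor(
            x.reshape(30, 1, 1).repeat(2, axis=2),
            np.repeat([1, 2], 15),
            np.full(30, 90.0),
        )
        m = qc.estimate_batch_model(t)
        if abs(m.coefficient.iloc[0, 0]) < 3 * m.se.iloc[0, 0]:
            hits += 1
    # |coef| < 3 SE should hold in ~99.6% of null simulations
    assert hits / n_sim > 0.97


def test_simulated_batch_shift_recovered():
    from cytoarch.synth import SimConfig, generate_cohort
    from cytoarch.panels import default_cytokine_panel

    cfg = SimConfig(
        n_children=300,
        batch_sizes=(150, 150),
        seed=21,
        n_null_snps=0,
        n_low_viability=0,
        n_inadequate=0,
        n_nonresponder=0,
        cytokine_panel=default_cytokine_panel({1: 1e-9, 2: 1e-9}),
    )
    cfg.model.batch_shift.loc[:, :] = -0.7
    tensor, _, _, _ = generate_cohort(cfg)
    model = qc.estimate_batch_model(tensor)
    mean_coef = np.nanmean(model.coefficient.to_numpy())
    assert abs(mean_coef - (-0.7)) < 0.05


def test_adjust_batch_arithmetic_and_reflooring():
    sp, cp = _tiny_panels()
    values = np.array([[[40.0, 40.0]], [[40.0, 40.0]], [[80.0, 80.0]], [[80.0, 80.0]]])
    t = _tensor(values, [1, 1, 2, 2], [90, 90, 90, 90], sp, cp)
    model = qc.estimate_batch_model(t)
    # coefficient -1 -> batch1 doubled; batch2 untouched bit-identically
    assert np.allclose(model.coefficient.to_numpy(), -1.0)
    out = qc.adjust_batch(t, model)
    assert np.allclose(out.values[:2], 80.0)
    assert out.values[2:].tobytes() == t.values[2:].tobytes()

    # an adjusted value below the batch-2 LOD re-floors to half that LOD
    model.coefficient.loc["IL6", :] = 1.0  # adjustment halves batch-1 values
    t3 = _tensor(
        np.array([[[40.0, 12.0]], [[40.0, 12.0]], [[80.0, 80.0]], [[80.0, 80.0]]]),
        [1, 1, 2, 2],
        [90, 90, 90, 90],
        sp,
        cp,
    )
    out3 = qc.adjust_batch(t3, model)
    assert np.allclose(out3.values[0, 0, 0], 20.0)
    assert out3.values[0, 0, 1] == 5.0  # 12 / 2 = 6 < LOD 10 -> half LOD


def test_post_adjustment_coefficient_is_zero():
    rng = np.random.default_rng(4)
    x = np.exp2(rng.normal(9, 1, size=60))  # well above LOD, no re-flooring
    t = _tensor(
        x.reshape(60, 1, 1).repeat(2, axis=2),
        np.repeat([1, 2], 30),
        np.full(60, 90.0),
    )
    adj = qc.adjust_batch(t, qc.estimate_batch_model(t))
    re = qc.estimate_batch_model(adj)
    assert np.all(np.abs(re.coefficient.to_numpy()) < 1e-10)


def test_media_normalize_examples():
    sp, cp = _tiny_panels()
    t = _tensor(np.array([[[10.0, 80.0]]]), [2], [90], sp, cp)
    folds = qc.media_normalize(t)
    assert folds.loc["c0", ("IL6", "LPS")] == pytest.approx(3.0)  # log2(80/10)

    t_eq = _tensor(np.array([[[10.0, 10.0]]]), [2], [90], sp, cp)
    assert qc.media_normalize(t_eq).loc["c0", ("IL6", "LPS")] == 0.0

    # censored pairs (both at half LOD) carry no induction signal
    t_cens = _tensor(np.array([[[5.0, 5.0]]]), [2], [90], sp, cp)
    assert qc.media_normalize(t_cens).loc["c0", ("IL6", "LPS")] == 0.0

    t_miss = _tensor(np.array([[[np.nan, 80.0]]]), [2], [90], sp, cp)
    assert np.isnan(qc.media_normalize(t_miss).loc["c0", ("IL6", "LPS")])


def test_flooring_then_normalization_is_idempotent():
    rng = np.random.default_rng(8)
    sp = default_stimulus_panel()
    cp = default_cytokine_panel()
    values = np.exp2(rng.normal(2, 3, size=(12, 28, 16)))
    t = _tensor(values, np.repeat([1, 2], 6), np.full(12, 90.0), sp, cp)
    once = qc.floor_tensor_to_lod(t)
    twice = qc.floor_tensor_to_lod(once)
    np.testing.assert_array_equal(once.values, twice.values)
    f1 = qc.media_normalize(once)
    f2 = qc.media_normalize(qc.floor_tensor_to_lod(twice))
    pd.testing.assert_frame_equal(f1, f2)


@pytest.mark.parametrize(
    "nk, ns, expected",
    [(28, 15, 0.05 / 420), (1, 1, 0.05), (2, 5, 0.005)],
)
def test_bonferroni_alpha(nk, ns, expected):
    assert np.isclose(qc.bonferroni_alpha(nk, ns), expected, rtol=1e-12)


def test_bonferroni_alpha_rejects_bad_counts():
    with pytest.raises(ValueError):
        qc.bonferroni_alpha(0, 15)


def _folds_frame(values_by_pair):
    cols = pd.MultiIndex.from_tuples(
        list(values_by_pair), names=["cytokine", "stimulus"]
    )
    n = max(len(v) for v in values_by_pair.values())
    data = np.full((n, len(cols)), np.nan)
    for j, v in enumerate(values_by_pair.values()):
        data[: len(v), j] = v
    return pd.DataFrame(data, columns=cols)


def test_induction_t_statistic_hand_value():
    folds = _folds_frame({("IL6", "LPS"): [1.0, 1.0, 2.0]})
    res = qc.test_induction(folds, alpha=0.05)
    row = res.iloc[0]
    assert np.isclose(row["t"], 4.0)
    assert np.isclose(row["p"], 0.0286, atol=5e-4)
    assert np.isclose(row["mean_fold"], 2 ** (4 / 3))


def test_induction_zero_folds_not_significant():
    folds = _folds_frame({("IL6", "LPS"): [0.0, 0.0, 0.0]})
    res = qc.test_induction(folds, alpha=0.05)
    assert bool(res.iloc[0]["untestable"])  # zero variance is untestable
    assert not bool(res.iloc[0]["significant"])
    assert np.isclose(res.iloc[0]["mean_fold"], 1.0)


def test_induction_p_matches_independent_t_cdf(rng):
    """p equals the regularized-incomplete-beta survival value to 1e-10."""
    x = rng.normal(0.5, 1.0, size=25)
    folds = _folds_frame({("IL6", "LPS"): x})
    row = qc.test_induction(folds, alpha=0.05).iloc[0]
    t, df = row["t"], len(x) - 1
    p_oracle = 0.5 * betainc(df / 2.0, 0.5, df / (df + t * t))
    if t < 0:
        p_oracle = 1.0 - p_oracle
    assert abs(row["p"] - p_oracle) < 1e-10


def test_induction_type_one_error_calibrated(rng):
    """Null rejection rate at the multiplicity-adjusted level is ~alpha."""
    alpha = qc.bonferroni_alpha(28, 15)
    n_sim, n = 200_000, 30
    x = rng.normal(size=(n_sim, n))
    t = x.mean(1) / (x.std(ddof=1, axis=1) / np.sqrt(n))
    from scipy import stats

    crit = stats.t.isf(alpha, df=n - 1)
    rate = float(np.mean(t > crit))
    se = np.sqrt(alpha * (1 - alpha) / n_sim)
    assert abs(rate - alpha) < 4 * se + 1e-6


def test_viability_diagnostics_reports_planted_correlation(rng):
    sp, cp = _tiny_panels()
    n = 300
    viability = rng.uniform(30, 100, n)
    stim = np.exp2(0.02 * viability + rng.normal(0, 0.35, n))  # r ~ 0.25 planted
    media = np.exp2(rng.normal(0, 1, n))
    values = np.stack([media, stim], axis=1).reshape(n, 1, 2)
    t = _tensor(values, np.repeat([1, 2], n // 2), viability, sp, cp)
    diag = qc.viability_diagnostics(t)
    df = diag["response_viability"]
    r = df[(df.cytokine == "IL6") & (df.stimulus == "LPS")]["r"].iloc[0]
    planted = 0.02 * np.std(viability) / np.sqrt((0.02 * np.std(viability)) ** 2 + 0.35**2)
    assert abs(r - planted) < 0.1
    assert np.isfinite(diag["viability_batch_p"])


def test_viability_copied_as_response_gives_r_one():
    sp, cp = _tiny_panels()
    viability = np.linspace(30, 90, 20)
    values = np.stack([np.exp2(viability), np.exp2(viability)], axis=1).reshape(20, 1, 2)
    t = _tensor(values, np.repeat([1, 2], 10), viability, sp, cp)
    df = qc.viability_diagnostics(t)["response_viability"]
    assert np.allclose(df["r"].dropna(), 1.0)
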