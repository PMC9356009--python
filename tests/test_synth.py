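"""Generator behaviour: determinism, censoring, rank missingness, GINA steps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoarch import qc
from cytoarch.panels import default_cytokine_panel, default_stimulus_panel
from cytoarch.synth import (
    DRUG_CLASSES,
    ClinicalRecord,
    GeneticEffect,
    PhenotypeLink,
    SimConfig,
    apply_rank_missingness,
    default_signature_model,
    derive_gina_step,
    generate_cohort,
)


def _null_model():
    m = default_signature_model()
    m.signature.loc[:, :] = 0.0
    m.batch_shift.loc[:, :] = 0.0
    m.child_reactivity_sd = {g: 0.0 for g in m.child_reactivity_sd}
    m.noise_sd = 0.0
    m.genetic_effects = []
    m.phenotype_links = []
    return m


def _clean_config(**kw):
    defaults = dict(
        n_low_viability=0,
        n_inadequate=0,
        n_nonresponder=0,
        n_null_snps=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_seed_fixed_generation_is_bit_reproducible():
    cfg = lambda: SimConfig(n_children=40, batch_sizes=(6, 34), seed=5, n_null_snps=30)  # noqa: E731
    t1, g1, c1, _ = generate_cohort(cfg())
    t2, g2, c2, _ = generate_cohort(cfg())
    np.testing.assert_array_equal(t1.values, t2.values)
    np.testing.assert_array_equal(g1.dosage, g2.dosage)
    assert [r.medication_events for r in c1] == [r.medication_events for r in c2]


def test_zero_variance_null_model_gives_unit_fold_induction():
    cfg = _clean_config(
        n_children=20, batch_sizes=(4, 16), seed=1, model=_null_model()
    )
    tensor, _, _, _ = generate_cohort(cfg)
    media = tensor.stimulus_index(tensor.stimulus_panel.media_name)
    obs = ~np.isnan(tensor.values)
    both = obs & obs[:, :, media][:, :, None]
    ratio = tensor.values / tensor.values[:, :, media][:, :, None]
    assert np.allclose(ratio[both], 1.0)


def test_left_censoring_stores_exactly_half_lod():
    tensor, _, _, _ = generate_cohort(SimConfig(n_children=100, batch_sizes=(20, 80), seed=3, n_null_snps=0))
    for b in (1, 2):
        lods = tensor.cytokine_panel.lod_matrix(b)
        vals = tensor.values[tensor.batch == b]
        for k in range(vals.shape[1]):
            v = vals[:, k, :]
            v = v[~np.isnan(v)]
            below = v[v < lods[k]]
            assert below.size  # weak cytokines do get censored
            assert np.all(below == lods[k] / 2.0)


def test_rank_missingness_is_monotone_and_truncates_at_count():
    cfg = _clean_config(n_children=10, batch_sizes=(2, 8), seed=2)
    tensor, _, _, _ = generate_cohort(cfg)
    panel = tensor.stimulus_panel
    counts = np.full(10, len(panel.entries))
    full = apply_rank_missingness(tensor, counts, panel)
    # count = n_stimuli leaves the tensor untouched
    np.testing.assert_array_equal(full.values, tensor.values)

    counts[0] = 5
    cut = apply_rank_missingness(tensor, counts, panel)
    present = [
        s
        for s in cut.stimuli
        if not np.isnan(cut.values[0, :, cut.stimulus_index(s)]).all()
    ]
    # rank order: media, RV16, RSV, Hin, Strpn
    assert present == ["media", "RV16", "RSV", "Hin", "Strpn"]
    ranks = np.array([panel.rank_of(s) for s in cut.stimuli])
    miss = np.isnan(cut.values[0, 0, :])
    order = np.argsort(ranks)
    assert np.all(np.diff(miss[order].astype(int)) >= 0)  # monotone in rank


def test_realized_missing_rates_match_targets_within_3pp():
    cfg = _clean_config(n_children=1000, batch_sizes=(160, 840), seed=7)
    tensor, _, _, _ = generate_cohort(cfg)
    targets = tensor.stimulus_panel.monotone_missing_rates()
    stims = [e.name for e in tensor.stimulus_panel.by_rank()]
    realized = np.array(
        [
            np.isnan(tensor.values[:, 0, tensor.stimulus_index(s)]).mean()
            for s in stims
        ]
    )
    assert np.all(np.abs(realized - targets) < 0.03)


def test_batch_shift_recovered_in_group_means():
    # marginal check: constant shift applied to batch 1 appears as the
    # difference of batch log2 means, within 3 standard errors
    model = _null_model()
    model.noise_sd = 1.0
    model.batch_shift.loc[:, :] = -0.7
    # negligible LODs so censoring cannot bias the marginal means
    panel = default_cytokine_panel({1: 1e-9, 2: 1e-9})
    diffs = []
    for seed in range(30):
        cfg = _clean_config(
            n_children=120,
            batch_sizes=(40, 80),
            seed=seed,
            model=model,
            cytokine_panel=panel,
        )
        tensor, _, _, _ = generate_cohort(cfg)
        log2v = tensor.log2_values()
        d = np.nanmean(log2v[tensor.batch == 1]) - np.nanmean(log2v[tensor.batch == 2])
        diffs.append(d)
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - (-0.7)) < 3 * se + 1e-3


def test_large_reactivity_sd_spreads_folds_over_1000_fold():
    model = _null_model()
    model.child_reactivity_sd["anti_viral"] = 5.0
    model.noise_sd = 0.0
    cfg = _clean_config(n_children=1000, batch_sizes=(160, 840), seed=9, model=model)
    tensor, _, _, _ = generate_cohort(cfg)
    ki = tensor.cytokine_index("IFNa2")
    si = tensor.stimulus_index("RSV")
    mi = tensor.stimulus_index("media")
    fold = tensor.values[:, ki, si] / tensor.values[:, ki, mi]
    fold = fold[~np.isnan(fold)]
    lo, hi = np.percentile(fold, [2.5, 97.5])
    assert hi / lo > 1000.0


def test_planted_genetic_effect_recovered_by_score_test():
    from cytoarch.cqtl import score_test_additive

    model = _null_model()
    model.noise_sd = 1.0
    model.genetic_effects = [
        GeneticEffect("rs_sim00", "IL6", ("Hin",), beta=1.0, maf=0.3)
    ]
    cfg = _clean_config(n_children=2000, batch_sizes=(300, 1700), seed=13, model=model)
    tensor, genotypes, _, _ = generate_cohort(cfg)
    folds = qc.media_normalize(tensor)
    res = score_test_additive(
        folds[("IL6", "Hin")].to_numpy(),
        genotypes.dosage_of("rs_sim00").reindex(folds.index).to_numpy(),
    )
    assert abs(res.beta - 1.0) < 0.1


def test_phenotype_link_must_reference_known_snp():
    model = _null_model()
    model.phenotype_links = [PhenotypeLink("rs_unknown", "gina_step2", 0.5)]
    with pytest.raises(ValueError, match="unknown SNP"):
        _clean_config(n_children=10, batch_sizes=(2, 8), model=model)


def test_nonpositive_cohort_size_rejected():
    with pytest.raises(ValueError):
        SimConfig(n_children=0, batch_sizes=(0, 0))


@pytest.mark.parametrize(
    "drugs, step",
    [
        (set(), 1),
        ({"SABA"}, 1),
        ({"SABA", "ICS_low"}, 2),
        ({"LTRA"}, 2),
        ({"ICS_low", "LABA"}, 3),
        ({"ICS_medium_high"}, 3),
        ({"ICS_low", "theophylline_SR"}, 3),
        ({"combination"}, 3),
        ({"ICS_medium_high", "LABA"}, 4),
        ({"ICS_medium_high", "LTRA"}, 4),
        ({"OCS"}, 5),
        ({"SABA", "anti_IgE"}, 5),
    ],
)
def test_gina_step_rules(drugs, step):
    record = ClinicalRecord(
        child="c0",
        medication_events=[(8 * 365 + 10, d) for d in sorted(drugs)],
        unscheduled_asthma_visit=False,
        oral_steroid_receipt=False,
        admission_after_age3=False,
    )
    assert derive_gina_step(record, 8) == step


def test_gina_step_ignores_other_years():
    record = ClinicalRecord("c0", [(5 * 365, "OCS")], False, False, False)
    assert derive_gina_step(record, 8) == 1
    assert derive_gina_step(record, 5) == 5


def test_gina_step_rejects_unknown_drug_class():
    record = ClinicalRecord("c0", [], False, False, False)
    record.medication_events = [(8 * 365, "aspirin")]  # bypass constructor check
    with pytest.raises(ValueError, match="unknown drug class"):
        derive_gina_step(record, 8)


@settings(max_examples=200, deadline=None)
@given(
    base=st.sets(st.sampled_from(DRUG_CLASSES)),
    extra=st.sampled_from(DRUG_CLASSES),
)
def test_gina_step_monotone_in_medication(base, extra):
    """Adding a medication never lowers the treatment step."""

    def step_of(drugs):
        rec = ClinicalRecord(
            "c0", [(8 * 365, d) for d in sorted(drugs)], False, False, False
        )
        return derive_gina_step(rec, 8)

    assert step_of(base | {extra}) >= step_of(base)


def test_count_distribution_sums_to_one_and_matches_rates():
    panel = default_stimulus_panel()
    p = panel.count_distribution()
    assert np.isclose(p.sum(), 1.0)
    m = panel.monotone_missing_rates()
    # P(count < rank r) telescopes back to the monotone rates
    cum = np.cumsum(p)
    np.testing.assert_allclose(cum[: len(m)], m, atol=1e-12)


def test_default_panels_shapes():
    sp = default_stimulus_panel()
    cp = default_cytokine_panel()
    assert len(sp.entries) == 16  # media + 15 stimuli
    assert len(cp.names) == 28
    assert sp.media_name == "media"
    assert len(sp.group_members("bacterial")) == 8
    assert len([s for s in sp.group_members("viral") if s != "polyIC"]) == 5
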