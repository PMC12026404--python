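"""Synthetic cohort generator: determinism, allocation, planted effects."""

import numpy as np
import pandas as pd
import pytest

from ibdatlas import cohort as co
from ibdatlas.cohort import CohortConfig, largest_remainder


def test_config_validates_proportions_and_counts():
    with pytest.raises(ValueError, match="sum"):
        CohortConfig(seed=1, disease_mix={"CD": 0.5, "UC": 0.4})
    with pytest.raises(ValueError, match="positive"):
        CohortConfig(seed=1, n_patients=0)


@pytest.mark.parametrize(
    "props,total,expected",
    [
        ([0.5, 0.3, 0.2], 100, [50, 30, 20]),
        ([1 / 3, 1 / 3, 1 / 3], 10, [4, 3, 3]),
        ([0.55, 0.45], 9, [5, 4]),
    ],
)
def test_largest_remainder_apportionment(props, total, expected):
    got = largest_remainder(props, total)
    assert got == expected
    assert sum(got) == total


def test_disease_allocation_is_exact():
    cfg = CohortConfig(seed=7, n_patients=100, disease_mix={"CD": 0.5, "UC": 0.3, "nonIBD": 0.2})
    c = co.generate_cohort(cfg)
    counts = c.patients["disease"].value_counts().to_dict()
    assert counts == {"CD": 50, "UC": 30, "nonIBD": 20}


def test_non_ibd_severity_is_zero():
    cfg = CohortConfig(seed=3, n_patients=40, disease_mix={"nonIBD": 1.0})
    c = co.generate_cohort(cfg)
    assert (c.contexts["severity"] == 0).all()


def test_same_seed_identical_cohorts():
    a = co.simulate_all(CohortConfig(seed=5, n_patients=30))
    b = co.simulate_all(CohortConfig(seed=5, n_patients=30))
    pd.testing.assert_frame_equal(a.cohort.contexts, b.cohort.contexts)
    pd.testing.assert_frame_equal(a.histo, b.histo)
    pd.testing.assert_frame_equal(a.npx, b.npx)
    pd.testing.assert_frame_equal(a.tpm, b.tpm)
    for x, y in zip(a.bags, b.bags):
        np.testing.assert_array_equal(x.features, y.features)
    pd.testing.assert_frame_equal(a.clinical, b.clinical)


def test_histo_severity_limits():
    # severity 0 (all nonIBD) -> raw always 0; forced severity 1 -> raw = max
    cfg = CohortConfig(seed=9, n_patients=30, disease_mix={"nonIBD": 1.0})
    c = co.generate_cohort(cfg)
    h0 = co.simulate_histo(c)
    assert (h0["raw"] == 0).all()
    c.contexts["severity"] = 1.0
    h1 = co.simulate_histo(c)
    from ibdatlas.atlas import max_score

    for _, r in h1.iterrows():
        assert r["raw"] == max_score(r["system"], r["tissue_group"], r["method"])
        assert r["normalized"] == 1.0


def test_histo_binomial_mean():
    # severity 0.5 on CD colon resection: mean raw over many draws ~ 10
    n = 2000
    cfg = CohortConfig(seed=13, n_patients=n, disease_mix={"CD": 1.0})
    c = co.generate_cohort(cfg)
    c.contexts["severity"] = 0.5
    c.contexts["tissue"] = "colon"
    c.contexts["tissue_group"] = "colon_group"
    c.contexts["method"] = "resection"
    draws = co.simulate_histo(c)["raw"].to_numpy()
    se = np.sqrt(20 * 0.25 / n)  # SE of the mean of Binomial(20, 0.5) draws
    assert abs(draws.mean() - 10.0) < 3 * se


def test_npx_noise_free_shift_equals_delta():
    cfg = CohortConfig(
        seed=21,
        n_patients=40,
        disease_mix={"CD": 1.0},
        remission_prob=0.0,
        npx_noise_sd=1e-12,
        lod_quantile=1e-12,
    )
    c = co.generate_cohort(cfg)
    c.contexts.loc[: len(c.contexts) // 2 - 1, "severity"] = 1.0
    c.contexts.loc[len(c.contexts) // 2 :, "severity"] = 0.0
    npx = co.simulate_npx(c)
    wide = co.npx_wide(npx)
    sev = c.truth["serum_severity"].set_index("sample_id")["severity"]
    hot = sev.index[sev == 1.0]
    cold = sev.index[sev == 0.0]
    planted = c.truth["planted_proteins"]["protein"]
    diff = wide.loc[planted, hot].mean(axis=1) - wide.loc[planted, cold].mean(axis=1)
    assert np.allclose(diff, cfg.npx_delta, atol=1e-9)
    others = wide.index.difference(planted)
    diff0 = wide.loc[others, hot].mean(axis=1) - wide.loc[others, cold].mean(axis=1)
    assert np.allclose(diff0, 0.0, atol=1e-9)


def test_npx_lod_at_median_gives_half_missing():
    cfg = CohortConfig(
        seed=22, n_patients=400, disease_mix={"nonIBD": 1.0}, lod_quantile=0.5
    )
    c = co.generate_cohort(cfg)
    npx = co.simulate_npx(c)
    frac = npx.groupby("protein")["below_lod"].mean()
    assert abs(frac.mean() - 0.5) < 0.02


def test_tpm_columns_sum_to_million(small_bundle):
    sums = small_bundle.tpm.sum(axis=0)
    assert np.allclose(sums, 1e6, atol=1e-3)


def test_bag_lesion_fraction_tracks_severity(small_bundle):
    sev = small_bundle.cohort.contexts.set_index("context_id")["severity"]
    for bag in small_bundle.bags:
        s = sev[f"C{bag.slide_id[1:]}"]
        if s == 0:
            assert bag.lesion.sum() == 0
    fracs = np.array([b.lesion.mean() for b in small_bundle.bags])
    r = np.corrcoef(fracs, sev.to_numpy())[0, 1]
    assert r > 0.9


def test_clinical_noise_free_is_monotone_map():
    cfg = CohortConfig(seed=31, n_patients=80, disease_mix={"UC": 1.0}, clinical_noise_frac=0.0)
    c = co.generate_cohort(cfg)
    clin = co.simulate_clinical(c)
    uceis = clin[clin["index"] == "UCEIS"].set_index("sample_id")["value"]
    sev = c.contexts.set_index("context_id")["severity"]
    sev.index = [f"K{i[1:]}" for i in sev.index]
    # rounding to the integer range makes the map non-strictly monotone:
    # index values sorted by severity must be non-decreasing
    ordered = uceis[sev[uceis.index].sort_values().index].to_numpy()
    assert (np.diff(ordered) >= 0).all()
    zero = sev.index[sev == 0]
    assert (uceis[uceis.index.intersection(zero)] == 0).all()


def test_clinical_indices_respect_entity():
    b = co.simulate_all(CohortConfig(seed=33, n_patients=60))
    disease = b.cohort.patients.set_index("patient_id")["disease"]
    clin = b.clinical.copy()
    clin["disease"] = clin["patient_id"].map(disease)
    assert (clin.loc[clin["index"].isin(["UCEIS", "PMS"]), "disease"] == "UC").all()
    assert (clin.loc[clin["index"].isin(["SES-CD", "HBI"]), "disease"] == "CD").all()
    assert set(clin.loc[clin["index"] == "Bristol", "disease"]) == {"CD", "UC", "nonIBD"}


def test_every_sample_links_to_cohort(small_bundle):
    ctx = set(small_bundle.cohort.contexts["context_id"])
    for sid in small_bundle.counts.columns:
        assert f"C{sid[1:]}" in ctx
    for bag in small_bundle.bags:
        assert f"C{bag.slide_id[1:]}" in ctx
    visits = set(small_bundle.cohort.visits["visit_id"])
    for sid in small_bundle.npx["sample_id"].unique():
        assert f"V{sid[1:]}" in visits
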