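"""Standardization chain: season ratios, Rosner capping, species-area and
depth regressions, unit conversion, and exact inversion of the generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from globeseed import standardize as std
from globeseed import synth
from conftest import make_record


# ------------------------------------------------------------- season logic

@pytest.mark.parametrize(
    "month, latitude, expected",
    [
        (1, 40.0, "winter"),
        (1, -40.0, "summer"),
        (7, 40.0, "summer"),
        (7, -40.0, "winter"),
        (4, 10.0, "spring"),
        (10, -10.0, "spring"),
        (12, 60.0, "winter"),
    ],
)
def test_hemisphere_aware_season_assignment(month, latitude, expected):
    rec = make_record(sampling_month=month, latitude=latitude)
    assert std.assign_season(rec) == expected


def test_explicit_season_wins_over_month():
    rec = make_record(sampling_month=None, season="autumn")
    assert std.assign_season(rec) == "autumn"
    rec = make_record(sampling_month=1, season="autumn", latitude=40.0)
    assert std.assign_season(rec) == "autumn"


def test_no_time_information_gives_none():
    rec = make_record(sampling_month=None, season=None)
    assert std.assign_season(rec) is None


def test_season_ratio_arithmetic():
    """Winter mean 20, summer mean 10 -> r_summer = 2; an 8 becomes 16."""
    records = [
        make_record(record_id=f"w{i}", season="winter", value=v)
        for i, v in enumerate([18.0, 22.0])
    ] + [
        make_record(record_id=f"s{i}", season="summer", value=v)
        for i, v in enumerate([8.0, 12.0])
    ]
    ratios = std.fit_season_ratios(records)
    assert ratios.ratio("diversity", "summer") == pytest.approx(2.0)
    assert ratios.ratio("diversity", "winter") == 1.0
    out, flagged = std.apply_season_standardization(records, ratios)
    summer = [r for r in out if r.record_id == "s0"][0]
    assert summer.value == pytest.approx(16.0)
    assert "season" in summer.standardized_flags
    winter = [r for r in out if r.record_id == "w0"][0]
    assert winter.value == pytest.approx(18.0)


def test_equal_season_means_give_unit_ratios():
    records = [
        make_record(record_id=f"{s}{i}", season=s, value=20.0)
        for s in ("winter", "spring", "summer", "autumn")
        for i in range(3)
    ]
    ratios = std.fit_season_ratios(records)
    for s in ("winter", "spring", "summer", "autumn"):
        assert ratios.ratio("diversity", s) == pytest.approx(1.0)


def test_tropical_records_are_exempt():
    records = [
        make_record(record_id="w", season="winter", value=20.0),
        make_record(record_id="s", season="summer", value=10.0),
        make_record(record_id="t", season="summer", value=7.0, biome="TSMF"),
    ]
    ratios = std.fit_season_ratios(records)
    out, _ = std.apply_season_standardization(records, ratios)
    tropical = [r for r in out if r.record_id == "t"][0]
    assert tropical.value == pytest.approx(7.0)
    assert "season" in tropical.standardized_flags  # exempt = already at convention


def test_all_tropical_dataset_is_a_ratio_error():
    records = [make_record(biome="TSMF", season="summer")]
    with pytest.raises(ValueError, match="winter"):
        std.fit_season_ratios(records)


# ------------------------------------------------------------ Rosner capping

def _esd_brute_force(x, alpha=0.05, max_k=None):
    """Independent generalized-ESD: recompute mean/sd from scratch on the
    reduced sample at each step, using list arithmetic rather than arrays."""
    x = list(map(float, x))
    n = len(x)
    if n < 10:
        return []
    k = max_k if max_k is not None else max(1, math.ceil(0.05 * n))
    k = min(k, n - 2)
    remaining = list(enumerate(x))
    candidates = []
    for step in range(1, k + 1):
        vals = [v for _, v in remaining]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        sd = math.sqrt(var)
        if sd == 0:
            break
        far = max(remaining, key=lambda iv: abs(iv[1] - mean))
        r = abs(far[1] - mean) / sd
        p = 1 - alpha / (2 * (n - step + 1))
        t = stats.t.ppf(p, n - step - 1)
        lam = (n - step) * t / math.sqrt((n - step - 1 + t * t) * (n - step + 1))
        candidates.append((far[0], r > lam))
        remaining.remove(far)
    n_out = 0
    for i, (_, sig) in enumerate(candidates, start=1):
        if sig:
            n_out = i
    return [candidates[i][0] for i in range(n_out)]


def test_rosner_flags_match_brute_force_on_100_seeded_vectors():
    rng = np.random.default_rng(2024)
    for trial in range(100):
        n = int(rng.integers(10, 31))
        x = rng.standard_normal(n)
        if trial % 2 == 0:  # plant 1-2 gross outliers
            x[rng.integers(0, n)] += rng.choice([-1, 1]) * rng.uniform(8, 40)
        if trial % 5 == 0:
            x[rng.integers(0, n)] = rng.uniform(20, 60)
        assert sorted(std.rosner_outliers(x)) == sorted(_esd_brute_force(x)), trial


def test_rosner_caps_high_outlier_at_95th_percentile():
    rng = np.random.default_rng(11)
    x = np.concatenate([rng.standard_normal(29), [50.0]])
    capped, flagged, warnings = std.rosner_cap(x)
    assert 29 in flagged
    assert capped[29] == pytest.approx(np.percentile(x, 95))
    assert not warnings
    # low-side outliers are flagged but untouched
    y = np.concatenate([rng.standard_normal(29), [-50.0]])
    capped_y, flagged_y, _ = std.rosner_cap(y)
    assert 29 in flagged_y
    assert capped_y[29] == -50.0


def test_rosner_trivial_cases():
    const = np.full(20, 3.0)
    capped, flagged, _ = std.rosner_cap(const)
    np.testing.assert_array_equal(capped, const)
    assert flagged == []
    short = np.arange(5.0)
    capped, flagged, warnings = std.rosner_cap(short)
    np.testing.assert_array_equal(capped, short)
    assert warnings and "skipped" in warnings[0]
    with pytest.raises(ValueError):
        std.rosner_cap([1.0, np.nan] + [0.0] * 10)


# -------------------------------------------------------- species-area curve

def _records_from_power_law(C, Z, areas, noise=None, biome="TBMF"):
    recs = []
    for i, a in enumerate(areas):
        v = C * a**Z
        if noise is not None:
            v *= noise[i]
        recs.append(
            make_record(record_id=f"a{i}", value=v, sample_area_m2=a, biome=biome)
        )
    return recs


def test_species_area_exact_on_noise_free_power_law():
    areas = [0.005, 0.01, 0.02, 0.04] * 5
    recs = _records_from_power_law(5.0, 0.3, areas)
    model = std.fit_species_area(recs, biome="TBMF", cap=False)
    assert model.C == pytest.approx(5.0, rel=1e-10)
    assert model.Z == pytest.approx(0.3, rel=1e-10)
    assert model.r_squared == pytest.approx(1.0)


def test_species_area_matches_normal_equations_oracle():
    rng = np.random.default_rng(8)
    areas = list(rng.choice([0.0025, 0.005, 0.01, 0.02, 0.04, 0.1], size=200))
    noise = np.exp(0.2 * rng.standard_normal(200))
    recs = _records_from_power_law(5.0, 0.3, areas, noise=noise)
    model = std.fit_species_area(recs, biome="TBMF", cap=False)
    # closed-form OLS on (1, log A)
    X = np.column_stack([np.ones(200), np.log(areas)])
    y = np.log([r.value for r in recs])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert model.C == pytest.approx(np.exp(beta[0]), abs=1e-10)
    assert model.Z == pytest.approx(beta[1], abs=1e-10)


def test_species_area_excludes_zero_values_and_counts_them():
    areas = [0.005, 0.01, 0.02, 0.04] * 5
    recs = _records_from_power_law(5.0, 0.3, areas)
    recs.append(make_record(record_id="z", value=0.0, sample_area_m2=0.01))
    model = std.fit_species_area(recs, biome="TBMF", cap=False)
    assert model.n_excluded_nonpositive == 1
    assert model.Z == pytest.approx(0.3, rel=1e-10)


def test_species_area_single_area_is_insufficient():
    recs = _records_from_power_law(5.0, 0.3, [0.01] * 15)
    model = std.fit_species_area(recs, biome="TBMF")
    assert model.insufficient_data and model.Z is None


def test_area_standardization_values():
    model = std.BiomeAreaModel(
        biome="TBMF", C=5.0, Z=0.3, n=20, r_squared=0.9, insufficient_data=False
    )
    rec = make_record(value=12.0, sample_area_m2=0.04)
    out, applied = std.standardize_area(rec, model)
    assert applied
    assert out.value == pytest.approx(12.0 * 0.25**0.3)  # ~7.918
    # identity at the target area
    rec = make_record(value=12.0, sample_area_m2=0.01)
    out, _ = std.standardize_area(rec, model)
    assert out.value == pytest.approx(12.0)
    # degenerate exponent
    model0 = std.BiomeAreaModel(
        biome="TBMF", C=5.0, Z=0.0, n=20, r_squared=0.0, insufficient_data=False
    )
    rec = make_record(value=12.0, sample_area_m2=0.1)
    out, _ = std.standardize_area(rec, model0)
    assert out.value == pytest.approx(12.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    area=st.floats(min_value=0.0101, max_value=1.0),
    z=st.floats(min_value=0.05, max_value=1.0),
    value=st.floats(min_value=0.1, max_value=1e3),
)
def test_area_standardization_monotonicity(area, z, value):
    """For Z > 0 rescaling from A > 0.01 strictly decreases diversity and
    from A < 0.01 strictly increases it."""
    model = std.BiomeAreaModel(
        biome="TBMF", C=1.0, Z=z, n=20, r_squared=1.0, insufficient_data=False
    )
    big = make_record(value=value, sample_area_m2=area)
    out_big, _ = std.standardize_area(big, model)
    assert out_big.value < value
    small = make_record(value=value, sample_area_m2=0.01 * 0.01 / area)
    out_small, _ = std.standardize_area(small, model)
    assert out_small.value > value


# ------------------------------------------------------------ depth models

def _records_from_depth_plane(b0, b1, b2, slices, measure="density", noise=None):
    recs = []
    for i, (u, low) in enumerate(slices):
        v = 10.0 ** (b0 + b1 * u + b2 * low)
        if noise is not None:
            v *= noise[i]
        recs.append(
            make_record(
                record_id=f"d{i}", measure=measure, value=v,
                depth_upper_cm=float(u), depth_lower_cm=float(low),
            )
        )
    return recs


def test_depth_fit_exact_on_noise_free_plane():
    slices = [(0, 5), (0, 10), (5, 10), (0, 2), (2, 5)] * 4
    recs = _records_from_depth_plane(1.0, 0.02, 0.03, slices)
    model = std.fit_depth_model(recs, "TBMF", "density")
    assert model.b0 == pytest.approx(1.0, abs=1e-10)
    assert model.b1 == pytest.approx(0.02, abs=1e-10)
    assert model.b2 == pytest.approx(0.03, abs=1e-10)


def test_depth_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(9)
    slices = [(0, 5), (0, 10), (5, 10), (0, 2), (2, 5)] * 10
    noise = np.exp(0.3 * rng.standard_normal(len(slices)))
    recs = _records_from_depth_plane(1.0, 0.02, 0.03, slices, noise=noise)
    model = std.fit_depth_model(recs, "TBMF", "density")
    X = np.column_stack(
        [np.ones(len(slices)), [s[0] for s in slices], [s[1] for s in slices]]
    )
    y = np.log10([r.value for r in recs])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    for got, want in zip((model.b0, model.b1, model.b2), beta):
        assert got == pytest.approx(want, abs=1e-10)


def test_depth_fit_collinear_boundaries_reduced_rank():
    slices = [(0, 5), (5, 10), (10, 15)] * 5  # upper always lower - 5
    recs = _records_from_depth_plane(1.0, 0.0, 0.03, slices)
    model = std.fit_depth_model(recs, "TBMF", "density")
    assert model.reduced_rank and model.b1 == 0.0
    assert model.b2 == pytest.approx(0.03, abs=1e-10)


def test_depth_fit_single_slice_insufficient():
    recs = _records_from_depth_plane(1.0, 0.02, 0.03, [(0, 5)] * 15)
    model = std.fit_depth_model(recs, "TBMF", "density")
    assert model.insufficient_data


def test_depth_standardization_values():
    model = std.BiomeDepthModel(
        biome="TBMF", measure="density", b0=1.0, b1=0.0, b2=0.03,
        n=20, r_squared=0.9, insufficient_data=False,
    )
    rec = make_record(measure="density", value=100.0, depth_upper_cm=0, depth_lower_cm=10)
    out, applied = std.standardize_depth(rec, model)
    assert applied
    assert out.value == pytest.approx(100.0 * 10 ** (0.03 * (5 - 10)))  # ~70.79
    # identity at the target slice
    rec = make_record(measure="density", value=100.0, depth_upper_cm=0, depth_lower_cm=5)
    out, _ = std.standardize_depth(rec, model)
    assert out.value == pytest.approx(100.0)
    # zero slopes
    model0 = std.BiomeDepthModel(
        biome="TBMF", measure="density", b0=1.0, b1=0.0, b2=0.0,
        n=20, r_squared=0.0, insufficient_data=False,
    )
    rec = make_record(measure="density", value=100.0, depth_upper_cm=3, depth_lower_cm=20)
    out, _ = std.standardize_depth(rec, model0)
    assert out.value == pytest.approx(100.0)


# -------------------------------------------------------------- density unit

def test_density_conversion_arithmetic_and_idempotence():
    rec = make_record(measure="density", value=250.0, sample_area_m2=0.25)
    out = std.density_to_per_m2(rec)
    assert out.value == pytest.approx(1000.0)
    assert "density_unit" in out.standardized_flags
    again = std.density_to_per_m2(out)
    assert again.value == pytest.approx(1000.0)


def test_density_conversion_rejects_bad_area():
    rec = make_record(measure="density", value=250.0)
    object.__setattr__(rec, "sample_area_m2", 0.0)
    with pytest.raises(ValueError):
        std.density_to_per_m2(rec)


# ---------------------------------------------------------------- pipeline

def test_pipeline_is_identity_on_already_standard_records():
    records = [
        make_record(record_id=f"s{i}", season="winter", value=10.0 + i)
        for i in range(12)
    ]
    for r in records[::2]:
        r.standardized_flags.add("density_unit")  # irrelevant for diversity
    res = std.run_standardization(records)
    for before, after in zip(records, res.records):
        assert after.value == pytest.approx(before.value)


def test_pipeline_inverts_generator_at_sigma_zero():
    cfg = synth.inversion_config(n_records=200)
    records, _, truth = synth.generate_dataset(cfg, seed=4)
    res = std.run_standardization(records)
    for r in res.records:
        latent = truth["latent"][r.record_id]
        assert abs(r.value - latent) / latent < 1e-6, r.record_id


def test_pipeline_conserves_records_and_reports_counts():
    cfg = synth.default_config(n_records=120)
    records, _, _ = synth.generate_dataset(cfg, seed=6)
    res = std.run_standardization(records)
    assert res.report["n_input"] == len(records)
    assert res.report["n_output"] + res.report["n_rejected"] == len(records)
    assert set(res.report["steps"]) == {"units", "season", "area", "depth"}
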