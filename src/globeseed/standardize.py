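"""Harmonization of heterogeneous seed bank records.

Surveys differ in sampling season, quadrat area, soil depth slice and the
unit used for density.  Seed banks peak in winter, so all non-(sub)tropical
records are scaled to winter equivalents with per-season ratios; diversity
is rescaled to the most commonly reported quadrat area (0.01 m2) via a
per-biome species-area power law S = C * A^Z; all records are rescaled to
the 0-5 cm slice via per-biome log-scale regressions on the upper and lower
depth boundaries; density is converted to seeds per m2.  Extreme diversity
values are capped at the 95th percentile using the generalized extreme
studentized deviate (Rosner) test before the species-area fit.

Default step order: units -> season -> area (diversity only) -> depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import BIOMES, MEASURES, SEASONS, SeedBankRecord, is_tropical

__all__ = [
    "TARGET_AREA_M2",
    "TARGET_DEPTH_CM",
    "SeasonRatios",
    "BiomeAreaModel",
    "BiomeDepthModel",
    "StandardizationModels",
    "StandardizationOptions",
    "StandardizationResult",
    "assign_season",
    "fit_season_ratios",
    "apply_season_standardization",
    "rosner_outliers",
    "rosner_cap",
    "fit_species_area",
    "standardize_area",
    "fit_depth_model",
    "standardize_depth",
    "density_to_per_m2",
    "run_standardization",
]

TARGET_AREA_M2 = 0.01
TARGET_DEPTH_CM = (0.0, 5.0)

_MONTH_SEASON_N = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}
_SHIFT = {"winter": "summer", "summer": "winter", "spring": "autumn", "autumn": "spring"}


def assign_season(record: SeedBankRecord) -> str | None:
    """Hemisphere-aware meteorological season of a record.

    An explicit ``season`` field wins over the month; otherwise the month is
    mapped through DJF = northern winter / JJA = southern winter.  Returns
    ``None`` when neither is available (record is unstandardizable for
    season and passes through unchanged).
    """
    if record.season is not None:
        return record.season
    if record.sampling_month is None:
        return None
    season_n = _MONTH_SEASON_N[record.sampling_month]
    return season_n if record.latitude >= 0 else _SHIFT[season_n]


@dataclass
class SeasonRatios:
    """Winter-standardization ratios per measure and season.

    ``ratios[measure][season]`` is mean(winter values) / mean(season values)
    computed from non-(sub)tropical records only; r_winter = 1 by definition.
    Seasons without data carry ``None``.
    """

    ratios: dict[str, dict[str, float | None]]
    n_per_season: dict[str, dict[str, int]]
    method: str = "ratio_of_means"

    def ratio(self, measure: str, season: str) -> float | None:
        return self.ratios.get(measure, {}).get(season)


@dataclass
class BiomeAreaModel:
    """Fitted species-area power law S = C * A^Z for one biome (or pooled)."""

    biome: str  # biome code or "pooled"
    C: float | None
    Z: float | None
    n: int
    r_squared: float | None
    insufficient_data: bool
    n_excluded_nonpositive: int = 0


@dataclass
class BiomeDepthModel:
    """log10(value) ~ b0 + b1 * depth_upper + b2 * depth_lower for one biome."""

    biome: str
    measure: str
    b0: float | None
    b1: float | None
    b2: float | None
    n: int
    r_squared: float | None
    insufficient_data: bool
    reduced_rank: bool = False  # boundaries collinear -> lower-only model


@dataclass
class StandardizationModels:
    season_ratios: SeasonRatios | None = None
    area_models: dict[str, BiomeAreaModel] = field(default_factory=dict)
    depth_models: dict[tuple[str, str], BiomeDepthModel] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        out: dict = {}
        if self.season_ratios is not None:
            out["season_ratios"] = {
                "method": self.season_ratios.method,
                "ratios": self.season_ratios.ratios,
                "n_per_season": self.season_ratios.n_per_season,
            }
        out["area_models"] = {b: vars(m) for b, m in self.area_models.items()}
        out["depth_models"] = {
            f"{b}:{msr}": vars(m) for (b, msr), m in self.depth_models.items()
        }
        return out


def fit_season_ratios(
    records: Sequence[SeedBankRecord], method: str = "ratio_of_means"
) -> SeasonRatios:
    """Per-measure, per-season winter ratios from non-(sub)tropical records.

    ``ratio_of_means`` (default): r_s = mean(winter) / mean(season s).
    ``mean_of_ratios``: mean over all cross pairs (w_i / s_j), i.e.
    mean(winter) * mean(1/s); per-study pairing does not exist in pooled
    survey data so the cross-pair mean is the natural alternative reading.
    """
    if method not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown method {method!r}")
    eligible = [
        r for r in records if not is_tropical(r.biome) and assign_season(r) is not None
    ]
    if not any(assign_season(r) == "winter" for r in eligible):
        raise ValueError(
            "no eligible (non-tropical) winter records: season ratios undefined"
        )
    ratios: dict[str, dict[str, float | None]] = {}
    counts: dict[str, dict[str, int]] = {}
    for measure in MEASURES:
        values: dict[str, list[float]] = {s: [] for s in SEASONS}
        for r in eligible:
            if r.measure == measure:
                values[assign_season(r)].append(r.value)
        counts[measure] = {s: len(v) for s, v in values.items()}
        out: dict[str, float | None] = {}
        winter = np.asarray(values["winter"], dtype=float)
        for s in SEASONS:
            v = np.asarray(values[s], dtype=float)
            if s == "winter":
                out[s] = 1.0 if len(v) else None
                continue
            if len(v) == 0 or len(winter) == 0:
                out[s] = None
            elif method == "ratio_of_means":
                m = v.mean()
                out[s] = float(winter.mean() / m) if m > 0 else None
            else:
                if (v <= 0).any():
                    out[s] = None
                else:
                    out[s] = float(winter.mean() * np.mean(1.0 / v))
        ratios[measure] = out
    return SeasonRatios(ratios=ratios, n_per_season=counts, method=method)


def apply_season_standardization(
    records: Iterable[SeedBankRecord], ratios: SeasonRatios
) -> tuple[list[SeedBankRecord], list[str]]:
    """Multiply each eligible record's value by its season ratio.

    Winter records and (sub)tropical records pass through (ratio 1 /
    exemption); both still gain the ``season`` flag as "at winter
    convention".  Records with no assignable season or a missing ratio are
    returned unchanged and listed as flagged.
    """
    out: list[SeedBankRecord] = []
    flagged: list[str] = []
    for r in records:
        if "season" in r.standardized_flags:
            out.append(r)
            continue
        if is_tropical(r.biome):
            rec = r.replace()
            rec.standardized_flags.add("season")
            out.append(rec)
            continue
        season = assign_season(r)
        if season is None:
            flagged.append(r.record_id)
            out.append(r)
            continue
        ratio = ratios.ratio(r.measure, season)
        if ratio is None:
            flagged.append(r.record_id)
            out.append(r)
            continue
        rec = r.replace(value=r.value * ratio)
        rec.standardized_flags.add("season")
        out.append(rec)
    return out, flagged


def rosner_outliers(
    values: Sequence[float], alpha: float = 0.05, max_k: int | None = None
) -> list[int]:
    """Indices of outliers by the generalized ESD (Rosner) test.

    Up to ``max_k`` (default ceil(5% of n)) candidates are peeled off by
    largest |x - mean| / sd; candidate i is compared against the critical
    value lambda_i from the Student-t quantile at level alpha.  The declared
    outliers are the first i* candidates where i* is the largest i with
    R_i > lambda_i.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    n = len(x)
    if n < 10:
        return []
    k = max_k if max_k is not None else max(1, math.ceil(0.05 * n))
    k = min(k, n - 2)
    work = x.copy()
    idx = np.arange(n)
    stats_seq: list[tuple[float, float, int]] = []
    for i in range(1, k + 1):
        mean = work.mean()
        sd = work.std(ddof=1)
        if sd == 0:
            break
        j = int(np.argmax(np.abs(work - mean)))
        r_i = abs(work[j] - mean) / sd
        p = 1.0 - alpha / (2.0 * (n - i + 1))
        t = stats.t.ppf(p, n - i - 1)
        lam = (n - i) * t / math.sqrt((n - i - 1 + t * t) * (n - i + 1))
        stats_seq.append((r_i, lam, int(idx[j])))
        work = np.delete(work, j)
        idx = np.delete(idx, j)
    n_out = 0
    for i, (r_i, lam, _) in enumerate(stats_seq, start=1):
        if r_i > lam:
            n_out = i
    return [stats_seq[i][2] for i in range(n_out)]


def rosner_cap(
    values: Sequence[float], alpha: float = 0.05, max_k: int | None = None
) -> tuple[np.ndarray, list[int], list[str]]:
    """Cap high-side Rosner outliers at the sample's 95th percentile.

    Returns (capped values, all flagged indices, warnings).  Only flagged
    values above the 95th percentile (linear-interpolation definition,
    computed on the full pre-capping sample) are replaced; low-side outliers
    are flagged but left unchanged.  Vectors with n < 10 pass through with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    if len(x) < 10:
        return x.copy(), [], [f"n={len(x)} < 10: Rosner capping skipped"]
    outliers = rosner_outliers(x, alpha=alpha, max_k=max_k)
    p95 = float(np.percentile(x, 95))
    capped = x.copy()
    for i in outliers:
        if x[i] > p95:
            capped[i] = p95
    return capped, outliers, []


def _ols(y: np.ndarray, X: np.ndarray):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    return model.fit()


def fit_species_area(
    records: Sequence[SeedBankRecord],
    biome: str | None = None,
    alpha: float = 0.05,
    cap: bool = True,
    min_n: int = 10,
) -> BiomeAreaModel:
    """Fit S = C * A^Z by OLS of log(S) on log(A) on diversity records.

    ``biome=None`` pools all biomes.  Zero/negative values are excluded from
    the log fit and counted.  Rosner capping of the values is applied first
    by default.  Requires at least two distinct areas and ``min_n`` usable
    records, otherwise the model is flagged ``insufficient_data``.
    """
    label = biome if biome is not None else "pooled"
    sel = [
        r
        for r in records
        if r.measure == "diversity" and (biome is None or r.biome == biome)
    ]
    values = np.array([r.value for r in sel], dtype=float)
    areas = np.array([r.sample_area_m2 for r in sel], dtype=float)
    if cap and len(values) >= 10:
        values, _, _ = rosner_cap(values, alpha=alpha)
    positive = values > 0
    n_excluded = int((~positive).sum())
    values, areas = values[positive], areas[positive]
    if len(values) < min_n or len(np.unique(areas)) < 2:
        return BiomeAreaModel(
            biome=label, C=None, Z=None, n=len(values), r_squared=None,
            insufficient_data=True, n_excluded_nonpositive=n_excluded,
        )
    fit = _ols(np.log(values), np.log(areas)[:, None])
    return BiomeAreaModel(
        biome=label,
        C=float(np.exp(fit.params[0])),
        Z=float(fit.params[1]),
        n=len(values),
        r_squared=float(fit.rsquared),
        insufficient_data=False,
        n_excluded_nonpositive=n_excluded,
    )


def standardize_area(
    record: SeedBankRecord, model: BiomeAreaModel
) -> tuple[SeedBankRecord, bool]:
    """Rescale a diversity record to the 0.01 m2 reference quadrat.

    value <- value * (0.01 / A)^Z, preserving record-level variation rather
    than replacing values by curve predictions.  Returns (record, applied).
    """
    if record.measure != "diversity":
        raise ValueError("area standardization applies to diversity records")
    if "area" in record.standardized_flags:
        return record, False
    if model.insufficient_data or model.Z is None:
        return record, False
    rec = record.replace(
        value=record.value * (TARGET_AREA_M2 / record.sample_area_m2) ** model.Z
    )
    rec.standardized_flags.add("area")
    return rec, True


def fit_depth_model(
    records: Sequence[SeedBankRecord],
    biome: str | None,
    measure: str,
    min_n: int = 10,
) -> BiomeDepthModel:
    """OLS of log10(value) on the upper and lower depth boundaries.

    The boundaries include 0 cm so they enter untransformed; only the
    response is on the log scale.  Perfectly collinear boundaries (constant
    slice thickness) fall back to a lower-boundary-only model, flagged
    ``reduced_rank``.
    """
    label = biome if biome is not None else "pooled"
    sel = [
        r
        for r in records
        if r.measure == measure and (biome is None or r.biome == biome) and r.value > 0
    ]
    slices = {(r.depth_upper_cm, r.depth_lower_cm) for r in sel}
    if len(sel) < min_n or len(slices) < 2:
        return BiomeDepthModel(
            biome=label, measure=measure, b0=None, b1=None, b2=None,
            n=len(sel), r_squared=None, insufficient_data=True,
        )
    y = np.log10([r.value for r in sel])
    u = np.array([r.depth_upper_cm for r in sel], dtype=float)
    low = np.array([r.depth_lower_cm for r in sel], dtype=float)
    X = np.column_stack([u, low])
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < 3:
        fit = _ols(y, low[:, None])
        return BiomeDepthModel(
            biome=label, measure=measure,
            b0=float(fit.params[0]), b1=0.0, b2=float(fit.params[1]),
            n=len(sel), r_squared=float(fit.rsquared),
            insufficient_data=False, reduced_rank=True,
        )
    fit = _ols(y, X)
    return BiomeDepthModel(
        biome=label, measure=measure,
        b0=float(fit.params[0]), b1=float(fit.params[1]), b2=float(fit.params[2]),
        n=len(sel), r_squared=float(fit.rsquared), insufficient_data=False,
    )


def standardize_depth(
    record: SeedBankRecord, model: BiomeDepthModel
) -> tuple[SeedBankRecord, bool]:
    """Rescale a record from its depth slice (u, l) to the 0-5 cm reference.

    value <- value * 10^(b1*(0 - u) + b2*(5 - l)).  Returns (record, applied).
    """
    if "depth" in record.standardized_flags:
        return record, False
    if model.insufficient_data or model.b1 is None:
        return record, False
    tu, tl = TARGET_DEPTH_CM
    factor = 10.0 ** (
        model.b1 * (tu - record.depth_upper_cm) + model.b2 * (tl - record.depth_lower_cm)
    )
    rec = record.replace(value=record.value * factor)
    rec.standardized_flags.add("depth")
    return rec, True


def density_to_per_m2(record: SeedBankRecord) -> SeedBankRecord:
    """Convert a raw density seed count to seeds per m2 of soil surface.

    Idempotent via the ``density_unit`` flag.  Raises on non-positive area.
    """
    if record.measure != "density":
        raise ValueError("unit conversion applies to density records")
    if "density_unit" in record.standardized_flags:
        return record
    if not (record.sample_area_m2 > 0):
        raise ValueError(f"record {record.record_id}: non-positive sample area")
    rec = record.replace(value=record.value / record.sample_area_m2)
    rec.standardized_flags.add("density_unit")
    return rec


@dataclass
class StandardizationOptions:
    steps: tuple[str, ...] = ("units", "season", "area", "depth")
    season_method: str = "ratio_of_means"
    rosner_alpha: float = 0.05
    rosner_max_k: int | None = None
    cap_before_area_fit: bool = True
    min_n_fit: int = 10
    pooled_fallback: bool = True


@dataclass
class StandardizationResult:
    records: list[SeedBankRecord]
    models: StandardizationModels
    report: dict


def run_standardization(
    records: Sequence[SeedBankRecord],
    options: StandardizationOptions | None = None,
) -> StandardizationResult:
    """Full harmonization chain; never drops a record silently.

    Default order: density unit conversion, winter standardization,
    species-area rescaling of diversity to 0.01 m2, depth rescaling to
    0-5 cm.  Per-biome fits fall back to the pooled fit when a biome has
    insufficient data; all fallbacks and skipped records are reported.
    """
    opts = options or StandardizationOptions()
    current = [r.replace() for r in records]
    models = StandardizationModels()
    report: dict = {"n_input": len(current), "steps": {}}

    for step in opts.steps:
        if step == "units":
            rejected: list[str] = []
            out = []
            n_applied = 0
            for r in current:
                if r.measure != "density":
                    out.append(r)
                    continue
                try:
                    converted = density_to_per_m2(r)
                except ValueError:
                    rejected.append(r.record_id)
                    continue
                n_applied += converted is not r
                out.append(converted)
            current = out
            report["steps"]["units"] = {"applied": n_applied, "rejected": rejected}
        elif step == "season":
            if any(not is_tropical(r.biome) for r in current):
                ratios = fit_season_ratios(current, method=opts.season_method)
            else:  # every record exempt: nothing to fit, exemption still flagged
                ratios = SeasonRatios(
                    ratios={m: {} for m in MEASURES},
                    n_per_season={m: {} for m in MEASURES},
                )
            models.season_ratios = ratios
            current, flagged = apply_season_standardization(current, ratios)
            report["steps"]["season"] = {
                "applied": sum("season" in r.standardized_flags for r in current),
                "unstandardizable": flagged,
            }
        elif step == "area":
            biomes = sorted({r.biome for r in current if r.measure == "diversity"})
            pooled = fit_species_area(
                current, biome=None, alpha=opts.rosner_alpha,
                cap=opts.cap_before_area_fit, min_n=opts.min_n_fit,
            )
            models.area_models["pooled"] = pooled
            fallbacks: list[str] = []
            n_applied = 0
            skipped: list[str] = []
            for b in biomes:
                models.area_models[b] = fit_species_area(
                    current, biome=b, alpha=opts.rosner_alpha,
                    cap=opts.cap_before_area_fit, min_n=opts.min_n_fit,
                )
            out = []
            for r in current:
                if r.measure != "diversity":
                    out.append(r)
                    continue
                model = models.area_models.get(r.biome)
                if (model is None or model.insufficient_data) and opts.pooled_fallback:
                    if r.biome not in fallbacks:
                        fallbacks.append(r.biome)
                    model = pooled
                if model is None or model.insufficient_data:
                    skipped.append(r.record_id)
                    out.append(r)
                    continue
                rec, applied = standardize_area(r, model)
                n_applied += applied
                out.append(rec)
            current = out
            report["steps"]["area"] = {
                "applied": n_applied,
                "skipped": skipped,
                "pooled_fallback_biomes": fallbacks,
            }
        elif step == "depth":
            n_applied = 0
            skipped = []
            fallbacks = []
            for measure in MEASURES:
                models.depth_models[("pooled", measure)] = fit_depth_model(
                    current, None, measure, min_n=opts.min_n_fit
                )
                for b in sorted({r.biome for r in current if r.measure == measure}):
                    models.depth_models[(b, measure)] = fit_depth_model(
                        current, b, measure, min_n=opts.min_n_fit
                    )
            out = []
            for r in current:
                model = models.depth_models.get((r.biome, r.measure))
                if (model is None or model.insufficient_data) and opts.pooled_fallback:
                    key = (r.biome, r.measure)
                    if key not in fallbacks:
                        fallbacks.append(key)
                    model = models.depth_models[("pooled", r.measure)]
                if model is None or model.insufficient_data:
                    skipped.append(r.record_id)
                    out.append(r)
                    continue
                rec, applied = standardize_depth(r, model)
                n_applied += applied
                out.append(rec)
            current = out
            report["steps"]["depth"] = {
                "applied": n_applied,
                "skipped": skipped,
                "pooled_fallback": [list(map(str, k)) for k in fallbacks],
            }
        else:
            raise ValueError(f"unknown standardization step {step!r}")

    report["n_output"] = len(current)
    report["n_rejected"] = report["n_input"] - len(current)
    return StandardizationResult(records=current, models=models, report=report)
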