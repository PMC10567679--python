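"""Synthetic NutNet-like datasets with known ground truth.

The generator emulates a globally replicated nutrient-addition experiment:
each site has a 121-year growing-season water-balance record, >=3 blocks
each containing one Control and one NPK plot, and 4-15 experimental years
of species cover and aboveground biomass.  During growing seasons whose
standardized water balance exceeds a cutoff, community properties deviate
from their normal-season levels in proportion to a per-aspect sensitivity
times |SPEI|; one year later the deviation has shrunk by ``recovery_rate``
(and decays geometrically thereafter).  NPK plots apply multiplicative
treatment effects to the normal-season baselines and may carry distinct
sensitivities.

Every distributional choice here (lognormal abundance ranks, the
donor-to-recipient compositional shift, equal-direction carry-over) is a
declared stand-in for unknown field processes, not an inference about real
grassland data; see the methods note.

The noise-free expectation of every plot-year value is deterministic given
(config, seed) and is rebuilt independently by :func:`expected_truth`,
which evaluates the stability-facet definitions by direct arithmetic —
the parameter-recovery target for the full pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as climate_mod
from .climate import DRY, NORMAL, WET, SeasonClassification, classify, select_events, standardize

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SyntheticDataset",
    "gen_climate_series",
    "gen_dataset",
    "expected_truth",
    "write_dataset",
]

ASPECTS = ("biomass", "richness", "composition")
TREATMENTS = ("Control", "NPK")


def _default_sensitivity() -> dict:
    # proportional deviation per unit |SPEI| during extreme seasons
    return {
        "biomass": {"Control": 0.15, "NPK": 0.15},
        "richness": {"Control": 0.10, "NPK": 0.10},
        "composition": {"Control": 0.10, "NPK": 0.10},
    }


def _default_treatment_effects() -> dict:
    # multiplicative NPK effects on normal-season levels
    return {
        "biomass_gain": 0.25,
        "richness_loss_fraction": 0.20,
        "composition_shift": 0.15,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    The defaults mirror the design of the real experiment this emulates:
    55 sites, 3 blocks per site, per-site experiment durations of 4-15
    years, and a 1901-2021 climate baseline.
    """

    n_sites: int = 55
    n_blocks: int = 3
    #: years of post-treatment measurement per site; None draws 4-15 per site
    n_years_experiment: int | None = None
    n_species_pool: int = 24
    climate_ar1: float = 0.3
    climate_trend: float = 0.0  # water-balance drift, mm per year
    treatment_effects: dict = field(default_factory=_default_treatment_effects)
    sensitivity: dict = field(default_factory=_default_sensitivity)
    recovery_rate: float = 0.5  # fraction of deviation remaining one year later
    noise_sd: float = 0.05  # sd of multiplicative measurement noise (biomass, cover)
    #: sd of the log-normal plot-level multiplier on extreme-season
    #: deviations (response heterogeneity among plots); None -> 2 * noise_sd
    deviation_noise_sd: float | None = None
    seed: int = 0
    # climate scale: water balance in mm
    baseline_years: tuple = (1901, 2021)
    wb_mean: float = 50.0
    wb_scale: float = 100.0
    deviation_cutoff: float = 0.67  # |SPEI| threshold that triggers deviations
    # community structure
    core_fraction: float = 0.6  # fraction of pool always present (carries shifts)
    total_core_cover: float = 80.0
    total_marginal_cover: float = 12.0
    max_shift_fraction: float = 0.45
    biomass_baseline: float = 300.0  # g m^-2 under Control in normal seasons
    lognormal_sigma: float = 1.0  # spread of the species-abundance distribution

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_blocks < 1 or self.n_species_pool < 2:
            raise ValueError("counts must be >= 1 (species pool >= 2)")
        if self.n_years_experiment is not None and not 4 <= self.n_years_experiment <= 15:
            raise ValueError("n_years_experiment must be in 4..15 (>=4 years of measurement)")
        if not abs(self.climate_ar1) < 1:
            raise ValueError("climate_ar1 must satisfy |phi| < 1")
        if not 0 <= self.recovery_rate <= 1:
            raise ValueError("recovery_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.deviation_noise_sd is not None and self.deviation_noise_sd < 0:
            raise ValueError("deviation_noise_sd must be non-negative")
        loss = self.treatment_effects.get("richness_loss_fraction", 0.0)
        if not 0 <= loss < 1:
            raise ValueError("richness_loss_fraction must be in [0, 1)")
        for aspect in ASPECTS:
            for trt in TREATMENTS:
                if self.sensitivity[aspect][trt] < 0:
                    raise ValueError("sensitivities must be non-negative")

    @property
    def dev_noise_sd(self) -> float:
        if self.deviation_noise_sd is None:
            return 2.0 * self.noise_sd
        return self.deviation_noise_sd

    @property
    def n_core(self) -> int:
        return max(2, int(round(self.core_fraction * self.n_species_pool)))

    @property
    def n_marginal(self) -> int:
        return self.n_species_pool - self.n_core


@dataclass
class TruthRecord:
    """Ground truth implied by a :class:`SimulationConfig`.

    ``facets`` holds the exact noise-free facet value per (site, treatment,
    aspect, facet) on the same (log for biomass/richness) scale the
    pipeline stores; the idealized single-event closed forms are exposed
    through :meth:`ideal_resistance` and :meth:`ideal_recovery`.
    """

    config: SimulationConfig
    facets: pd.DataFrame

    def ideal_resistance(self, aspect: str, treatment: str, abs_spei: float = 1.0) -> float:
        """1 / (sensitivity * |SPEI|): resistance when the normal level is uncontaminated."""
        s = self.config.sensitivity[aspect][treatment]
        if s * abs_spei == 0:
            return math.inf
        return 1.0 / (s * abs_spei)

    def ideal_recovery(self) -> float:
        """1 / recovery_rate: recovery when the normal level is uncontaminated."""
        if self.config.recovery_rate == 0:
            return math.inf
        return 1.0 / self.config.recovery_rate

    def effect_log_resistance(self, aspect: str) -> float:
        """Imposed NPK-Control contrast in log resistance for a scalar aspect.

        Sensitivities scale every event's deviation identically, so the
        contrast in log mean resistance is -log(s_NPK / s_Control) up to a
        small contamination term from post-extreme carry-over.
        """
        s = self.config.sensitivity[aspect]
        return -math.log(s["NPK"] / s["Control"])


@dataclass
class SyntheticDataset:
    """Generated experiment: climate + community panel + ground truth."""

    cover: pd.DataFrame
    biomass: pd.DataFrame
    climate: pd.DataFrame
    truth: TruthRecord
    config: SimulationConfig


# ---------------------------------------------------------------------------
# climate


def _site_rng(config: SimulationConfig, site_index: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per (seed, site, purpose)."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(site_index, stream))
    )


def _draw_climate(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    y0, y1 = config.baseline_years
    years = np.arange(y0, y1 + 1)
    n = years.size
    phi = config.climate_ar1
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * math.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + innov[t - 1]
    wb = config.wb_mean + config.wb_scale * z + config.climate_trend * (years - y0)
    return years, wb


def gen_climate_series(config: SimulationConfig, site_index: int) -> tuple[np.ndarray, np.ndarray]:
    """121-year annual growing-season water balance (mm) for one site.

    AR(1) interannual structure with unit marginal variance on the z scale,
    plus a linear drift of ``climate_trend`` mm per year.  Reproducible:
    the stream depends only on (config.seed, site_index).
    """
    return _draw_climate(config, _site_rng(config, site_index, 0))


# ---------------------------------------------------------------------------
# noise-free site profile (shared by the generator and the truth)


@dataclass
class _SiteProfile:
    site_id: str
    years: np.ndarray  # full baseline years
    wb: np.ndarray
    exp_years: np.ndarray
    classification: SeasonClassification  # experimental years only
    deviation: dict  # (treatment, aspect) -> signed per-year deviation
    r_base: dict  # treatment -> baseline richness (int)
    core_base: dict  # treatment -> cover vector (n_core)
    marginal_base: dict  # treatment -> cover vector (n_marginal; 0 = never present)
    species: tuple  # species names, core first then marginal


def _apply_shift(base: np.ndarray, frac: float, n_donor: int) -> np.ndarray:
    """Move ``frac`` of total cover from the donor block to the rest.

    Donors are the first ``n_donor`` (dominant) species; mass is removed
    from donors and added to recipients in proportion to their covers, so
    the total is conserved and no cover goes negative.
    """
    out = base.astype(float).copy()
    total = out.sum()
    donors = out[:n_donor]
    recip = out[n_donor:]
    donor_total = donors.sum()
    recip_total = recip.sum()
    if donor_total == 0 or recip_total == 0 or frac <= 0:
        return out
    moved = min(frac * total, 0.9 * donor_total)
    out[:n_donor] = donors * (1.0 - moved / donor_total)
    out[n_donor:] = recip * (1.0 + moved / recip_total)
    return out


def _build_profile(config: SimulationConfig, site_index: int) -> _SiteProfile:
    rng = _site_rng(config, site_index, 0)
    site_id = f"site{site_index + 1:02d}"

    # climate, retried until the experimental window holds >=1 extreme
    # season (mirrors the site-inclusion criterion of the real experiment)
    if config.n_years_experiment is None:
        n_exp = int(rng.integers(4, 16))
    else:
        n_exp = config.n_years_experiment
    for _attempt in range(200):
        years, wb = _draw_climate(config, rng)
        spei = standardize(wb, years, site_id=site_id)
        exp_years = years[-n_exp:]
        cls = classify(spei, config.deviation_cutoff).restrict(exp_years)
        # the experimental window must hold >=1 extreme season (inclusion
        # criterion) and >=1 normal season (the normal level must exist)
        if np.any(cls.labels != NORMAL) and np.any(cls.labels == NORMAL):
            break
    else:  # pragma: no cover - essentially impossible for n_exp >= 4
        raise RuntimeError(f"no extreme season found for {site_id} after 200 climate draws")

    # signed per-year deviations with geometric carry-over
    sign = {
        "biomass": {DRY: -1.0, WET: +1.0},
        "richness": {DRY: -1.0, WET: -1.0},
        "composition": {DRY: +1.0, WET: +1.0},
    }
    deviation: dict = {}
    for trt in TREATMENTS:
        for aspect in ASPECTS:
            s = config.sensitivity[aspect][trt]
            d = np.zeros(n_exp)
            for t in range(n_exp):
                lab = cls.labels[t]
                if lab != NORMAL:
                    d[t] = sign[aspect][lab] * s * abs(cls.spei[t])
                elif t > 0:
                    d[t] = config.recovery_rate * d[t - 1]
            deviation[(trt, aspect)] = d

    # species pool: lognormal core ranks (always present, carry the
    # compositional shifts) plus small marginal species whose occupancy
    # implements richness dynamics (rarest dropped first)
    n_core, n_marg = config.n_core, config.n_marginal
    core = np.sort(rng.lognormal(0.0, config.lognormal_sigma, n_core))[::-1]
    core = core / core.sum() * config.total_core_cover
    marg = np.sort(rng.lognormal(-1.0, config.lognormal_sigma, n_marg))[::-1]
    marg = marg / marg.sum() * config.total_marginal_cover if n_marg else marg

    loss = config.treatment_effects.get("richness_loss_fraction", 0.0)
    base_shift = config.treatment_effects.get("composition_shift", 0.0)
    n_donor = n_core // 2
    r_base = {
        "Control": config.n_species_pool,
        "NPK": max(n_core, int(round(config.n_species_pool * (1.0 - loss)))),
    }
    core_base = {
        "Control": core,
        "NPK": _apply_shift(core, base_shift, n_donor),
    }
    marginal_base = {}
    for trt in TREATMENTS:
        m = marg.copy()
        m[r_base[trt] - n_core:] = 0.0  # species lost under NPK never occur
        marginal_base[trt] = m

    species = tuple(f"sp{j + 1:02d}" for j in range(config.n_species_pool))
    return _SiteProfile(site_id, years, wb, exp_years, cls, deviation,
                        r_base, core_base, marginal_base, species)


def _richness_from_dev(profile: _SiteProfile, config: SimulationConfig, trt: str,
                       d_rich: np.ndarray) -> np.ndarray:
    """Integer species counts implied by (possibly noisy) richness deviations."""
    r_base = profile.r_base[trt]
    target = np.rint(r_base * (1.0 + d_rich)).astype(int)
    return np.clip(target, config.n_core, r_base)


def _cover_from_dev(profile: _SiteProfile, config: SimulationConfig, trt: str,
                    d_comp: float, n_present: int) -> np.ndarray:
    """Cover vector (core + marginal) for one year given its deviations.

    The compositional deviation moves a fraction of total core cover from
    dominant to subordinate core species; richness dynamics drop marginal
    species rarest-first (nested occupancy).
    """
    n_core = config.n_core
    delta = min(abs(d_comp), config.max_shift_fraction)
    core = _apply_shift(profile.core_base[trt], delta, n_core // 2)
    marg = profile.marginal_base[trt].copy()
    marg[n_present - n_core:] = 0.0
    return np.concatenate([core, marg])


def _expected_cover(profile: _SiteProfile, config: SimulationConfig, trt: str, t: int) -> np.ndarray:
    """Noise-free cover vector for experimental year index t."""
    n_present = _richness_from_dev(
        profile, config, trt, profile.deviation[(trt, "richness")][t : t + 1]
    )[0]
    return _cover_from_dev(
        profile, config, trt, profile.deviation[(trt, "composition")][t], n_present
    )


def _biomass_from_dev(config: SimulationConfig, trt: str, d_bio: np.ndarray) -> np.ndarray:
    gain = config.treatment_effects.get("biomass_gain", 0.0)
    base = config.biomass_baseline * (1.0 + gain if trt == "NPK" else 1.0)
    return base * np.clip(1.0 + d_bio, 0.05, None)


def _expected_biomass(profile: _SiteProfile, config: SimulationConfig, trt: str) -> np.ndarray:
    return _biomass_from_dev(config, trt, profile.deviation[(trt, "biomass")])


# ---------------------------------------------------------------------------
# dataset generation


def gen_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic experiment as long-format tables.

    Each plot draws a log-normal multiplier (sd ``dev_noise_sd``) on every
    extreme-season deviation — plots differ in how strongly they respond
    to the same climate event — and measurement noise (sd ``noise_sd``)
    multiplies biomass and species cover.  Richness dynamics drop marginal
    species rarest-first to match the count implied by the plot's noisy
    deviation.  With ``noise_sd = 0`` (and ``deviation_noise_sd`` unset)
    every value equals its noise-free expectation.  Identical
    (config, seed) gives bit-identical output.
    """
    cover_rows = []
    biomass_rows = []
    climate_rows = []
    n_aspects = len(ASPECTS)
    for i in range(config.n_sites):
        profile = _build_profile(config, i)
        noise_rng = _site_rng(config, i, 1)
        site = profile.site_id
        for year, value in zip(profile.years, profile.wb):
            climate_rows.append((site, int(year), float(value), "water_balance"))

        n_exp = profile.exp_years.size
        for block in range(1, config.n_blocks + 1):
            for trt in TREATMENTS:
                plot = f"b{block}_{'ctl' if trt == 'Control' else 'npk'}"
                if config.dev_noise_sd > 0:
                    eps = np.exp(noise_rng.normal(0.0, config.dev_noise_sd, (n_exp, n_aspects)))
                else:
                    eps = np.ones((n_exp, n_aspects))
                dev = {
                    aspect: profile.deviation[(trt, aspect)] * eps[:, k]
                    for k, aspect in enumerate(ASPECTS)
                }
                biomass_vals = _biomass_from_dev(config, trt, dev["biomass"])
                counts = _richness_from_dev(profile, config, trt, dev["richness"])
                for t, year in enumerate(profile.exp_years):
                    cov = _cover_from_dev(profile, config, trt, dev["composition"][t], counts[t])
                    if config.noise_sd > 0:
                        cov = cov * np.exp(noise_rng.normal(0.0, config.noise_sd, cov.size))
                    for j, sp in enumerate(profile.species):
                        if cov[j] > 0:
                            cover_rows.append(
                                (site, f"B{block}", plot, trt, int(year), sp, float(cov[j]), 1)
                            )
                    bio = biomass_vals[t]
                    if config.noise_sd > 0:
                        bio = bio * math.exp(noise_rng.normal(0.0, config.noise_sd))
                    biomass_rows.append((site, f"B{block}", plot, trt, int(year), float(bio)))

    cover = pd.DataFrame(
        cover_rows,
        columns=["site", "block", "plot", "treatment", "year", "species", "cover", "survey"],
    )
    biomass = pd.DataFrame(
        biomass_rows, columns=["site", "block", "plot", "treatment", "year", "biomass"]
    )
    clim = pd.DataFrame(climate_rows, columns=["site", "year", "value", "kind"])
    return SyntheticDataset(cover, biomass, clim, expected_truth(config), config)


# ---------------------------------------------------------------------------
# ground truth


def _bc(x: np.ndarray, y: np.ndarray) -> float:
    return 1.0 - 2.0 * np.minimum(x, y).sum() / (x.sum() + y.sum())


def _multi_bc(rows: list[np.ndarray]) -> float:
    num_min = num_max = a_sum = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a = np.minimum(rows[i], rows[j]).sum()
            bi = rows[i].sum() - a
            bj = rows[j].sum() - a
            a_sum += a
            num_min += min(bi, bj)
            num_max += max(bi, bj)
    return (num_min + num_max) / (2.0 * a_sum + num_min + num_max)


def expected_truth(config: SimulationConfig) -> TruthRecord:
    """Exact noise-free facet values implied by the configuration.

    Rebuilds each site's deterministic deviation profile and evaluates the
    facet definitions by direct arithmetic (explicit least-squares
    residuals, inline Bray-Curtis sums), independent of the plot-level
    pipeline implementations.  Values are on the stored scale (natural log
    for biomass and richness).  Non-finite facets (e.g. invariability of a
    constant series) are recorded as inf/nan.
    """
    rows = []
    for i in range(config.n_sites):
        profile = _build_profile(config, i)
        cls = profile.classification
        events = select_events(cls)
        normal_mask = cls.labels == NORMAL
        n_exp = profile.exp_years.size
        year_index = {int(y): t for t, y in enumerate(profile.exp_years)}

        for trt in TREATMENTS:
            series = {
                "biomass": _expected_biomass(profile, config, trt),
                "richness": _richness_from_dev(
                    profile, config, trt, profile.deviation[(trt, "richness")]
                ).astype(float),
            }
            covers = [_expected_cover(profile, config, trt, t) for t in range(n_exp)]

            for aspect, v in series.items():
                x = profile.exp_years.astype(float)
                xc = x - x.mean()
                slope = (xc * (v - v.mean())).sum() / (xc * xc).sum()
                resid = v - v.mean() - slope * xc
                sigma = math.sqrt((resid**2).sum() / (n_exp - 1))
                inv = v.mean() / sigma if sigma > 0 else math.inf
                rows.append((profile.site_id, trt, aspect, "invariability", inv))

                yn = v[normal_mask].mean() if normal_mask.any() else math.nan
                per_kind: dict[str, list[float]] = {}
                for year, kind in events.resistance_years:
                    ye = v[year_index[year]]
                    dev = abs(ye - yn)
                    per_kind.setdefault(f"resistance_{kind}", []).append(
                        yn / dev if dev > 0 else math.inf
                    )
                for year_e, year_a, kind in events.recovery_pairs:
                    de = abs(v[year_index[year_e]] - yn)
                    da = abs(v[year_index[year_a]] - yn)
                    if de == 0 and da == 0:
                        val = math.nan
                    elif da == 0:
                        val = math.inf
                    else:
                        val = de / da
                    per_kind.setdefault(f"recovery_{kind}", []).append(val)
                for facet, vals in per_kind.items():
                    finite = [u for u in vals if math.isfinite(u)]
                    rows.append(
                        (profile.site_id, trt, aspect, facet,
                         float(np.mean(finite)) if finite else math.nan)
                    )

            # composition
            rows.append((profile.site_id, trt, "composition", "invariability",
                         1.0 - _multi_bc(covers)))
            ref = np.mean([covers[t] for t in range(n_exp) if normal_mask[t]], axis=0)
            per_kind = {}
            for year, kind in events.resistance_years:
                per_kind.setdefault(f"resistance_{kind}", []).append(
                    1.0 - _bc(covers[year_index[year]], ref)
                )
            for year_e, year_a, kind in events.recovery_pairs:
                sim_e = 1.0 - _bc(covers[year_index[year_e]], ref)
                sim_a = 1.0 - _bc(covers[year_index[year_a]], ref)
                per_kind.setdefault(f"recovery_{kind}", []).append(
                    sim_a / sim_e if sim_e > 0 else math.inf
                )
            for facet, vals in per_kind.items():
                finite = [u for u in vals if math.isfinite(u)]
                rows.append((profile.site_id, trt, "composition", facet,
                             float(np.mean(finite)) if finite else math.nan))

    facets = pd.DataFrame(rows, columns=["site", "treatment", "aspect", "facet", "value"])
    # store biomass/richness on the log scale, like the pipeline
    log_mask = facets["aspect"].isin(["biomass", "richness"])
    with np.errstate(divide="ignore", invalid="ignore"):
        facets.loc[log_mask, "value"] = np.log(facets.loc[log_mask, "value"])
    return TruthRecord(config, facets)


# ---------------------------------------------------------------------------
# output


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the cover/biomass/climate CSVs plus a truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cover": outdir / "cover.csv",
        "biomass": outdir / "biomass.csv",
        "climate": outdir / "climate.csv",
        "truth": outdir / "truth.json",
    }
    dataset.cover.to_csv(paths["cover"], index=False)
    dataset.biomass.to_csv(paths["biomass"], index=False)
    dataset.climate.to_csv(paths["climate"], index=False)
    truth = {
        "config": asdict(dataset.config),
        "facets": dataset.truth.facets.to_dict(orient="records"),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, default=float))
    return paths
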