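"""End-to-end virtual-species experiments: simulate, model, stack, regress.

These drivers wire the whole pipeline together on simulated worlds with
known truth, so recovery of generative parameters (the metabolic-theory
activation energy, species' thermal optima) can be measured.  Problem sizes
are set for a single desk CPU; every stage is seeded from the one master
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .background import build_target_group, sample_background, stratify
from .ensemble import (
    build_ensemble,
    build_member,
    predictor_correlations,
    select_predictor_sets,
)
from .grid import GridSpec
from .macroecology import fit_thermal_regimes
from .predictors import DEFAULT_CANDIDATES, derive_predictors, matchup, rank_predictors
from .prep import apply_open_ocean_mask, bin_presences, filter_records
from .synthetic import (
    EnvironmentConfig,
    biased_effort,
    generate_environment,
    generate_metabolic_pool,
    generate_species_pool,
    sample_occurrences,
    NicheConfig,
)


@dataclass
class PipelineConfig:
    """Desk-scale defaults of the simulation experiments.

    The world is a 40 x 60 cell monthly 1-degree-equivalent grid whose
    temperature field spans the global ocean's -1.8..32 deg C; sampling
    effort concentrates 49% of visits in one basin analogue.  SDM members
    use the GLM path by default (GAM and RF members are available via
    ``algorithm``; richness maps are insensitive to the member algorithm,
    while GLM keeps a 500-species experiment within a single-CPU session).
    """

    n_lat: int = 40
    n_lon: int = 60
    n_species: int = 500
    activation_energy: float = 0.32
    range_width: float = 10.0
    p_max: float = 0.2
    n_samples: int = 5000
    hotspot_share: float = 0.49
    min_presences: int = 24
    ratio: int = 10
    n_sets: int = 5
    set_size: int = 4
    tss_min: float = 0.35
    algorithm: str = "glm"
    rank_algorithms: tuple = ("glm",)
    candidates: tuple = DEFAULT_CANDIDATES
    rf_trees: int = 200
    env: EnvironmentConfig = field(default_factory=EnvironmentConfig)


@dataclass
class PipelineResult:
    regimes: object                 # RegimeFit on annual means
    true_slope: float               # -activation_energy
    n_species_modeled: int
    n_species_skipped: int
    richness_annual: xr.DataArray
    temperature_annual: xr.DataArray
    species_stats: pd.DataFrame     # per-species presences, members, peaks

    @property
    def global_slope(self) -> float:
        return self.regimes.slope("global")


def thermal_response_peak(
    ens_values: np.ndarray, t_values: np.ndarray, bin_width: float = 1.0
) -> float:
    """Temperature at which the mean ensemble value peaks (binned by T)."""
    ok = np.isfinite(ens_values) & np.isfinite(t_values)
    e, t = ens_values[ok], t_values[ok]
    edges = np.arange(np.floor(t.min()), np.ceil(t.max()) + bin_width, bin_width)
    idx = np.clip(np.digitize(t, edges) - 1, 0, edges.size - 2)
    sums = np.bincount(idx, weights=e, minlength=edges.size - 1)
    cnts = np.bincount(idx, minlength=edges.size - 1)
    with np.errstate(invalid="ignore"):
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1), -np.inf)
    return float(edges[int(np.argmax(means))] + bin_width / 2.0)


def simulate_world(config: PipelineConfig, seed: int, metabolic: bool = True):
    """Environment, species pool and raw biased occurrence records."""
    spec = GridSpec(
        n_lat=config.n_lat,
        n_lon=config.n_lon,
        lat_min=-config.n_lat / 2.0,
    )
    rng = np.random.default_rng(seed)
    s_env, s_pool, s_eff, s_occ = rng.integers(2 ** 31, size=4)
    env = generate_environment(spec, config.env, seed=int(s_env))
    if metabolic:
        pool, _c = generate_metabolic_pool(
            config.n_species,
            config.activation_energy,
            env,
            seed=int(s_pool),
            range_width=config.range_width,
            p_max=config.p_max,
        )
    else:
        t = env["T"].values
        t = t[np.isfinite(t)]
        pool = generate_species_pool(
            config.n_species,
            NicheConfig(
                optima={"T": (float(t.min()), float(t.max()))},
                breadths={"T": (2.0, 4.0)},
                p_max=config.p_max,
            ),
            seed=int(s_pool),
        )
    effort = biased_effort(spec, env, config.hotspot_share, seed=int(s_eff))
    records = sample_occurrences(
        pool, env, effort, config.n_samples, seed=int(s_occ)
    )
    env = derive_predictors(env)
    return spec, env, pool, records


def run_pipeline(config: PipelineConfig, seed: int, metabolic: bool = True) -> PipelineResult:
    """Simulate a world and push it through the full diagnostic pipeline.

    Steps: occurrence cleaning and open-ocean masking, monthly 1-degree
    binning, target-group background sampling (T x MLD stratified, 10:1),
    per-species predictor ranking, randomized predictor-set selection,
    member fitting with 4x cross-validation and TSS >= 0.35 retention,
    max-TSS binarization, ensemble averaging, richness stacking, and the
    Boltzmann-axis regime regression of ln richness on 1/kT.
    """
    spec, env, pool, records = simulate_world(config, seed, metabolic)
    records, _rep1 = filter_records(records, env)
    records, _rep2 = apply_open_ocean_mask(records, env)
    presences = bin_presences(records, spec)

    group_map = {sp.species_id: sp.taxon for sp in pool}
    groups = build_target_group(presences, group_map, mode="total")
    counts = presences.counts
    corr = predictor_correlations(env, config.candidates)

    # one stratification per distinct target group (total mode: just one)
    strata_cache = {}
    rng = np.random.default_rng(seed + 1)

    richness_sum = None
    covered = None
    stats = []
    truth = {sp.species_id: sp for sp in pool}
    t_flat = env["T"].values.reshape(-1)
    n_skipped = 0
    for sp_id in counts.index:
        if counts[sp_id] < config.min_presences:
            n_skipped += 1
            continue
        sp_seed = int(rng.integers(2 ** 31))
        group = groups[sp_id]
        gkey = id(group)
        if gkey not in strata_cache:
            strata_cache[gkey] = stratify(group, env)
        strata = strata_cache[gkey]
        bg = sample_background(
            sp_id, presences, group, strata, ratio=config.ratio, seed=sp_seed
        )
        data = matchup(
            presences.for_species(sp_id), bg.table, env, config.candidates
        )
        ranking = rank_predictors(
            data,
            config.candidates,
            seed=sp_seed,
            algorithms=config.rank_algorithms,
            min_presences=config.min_presences,
            rf_trees=config.rf_trees,
        )
        try:
            sets = select_predictor_sets(
                ranking.index, corr, n_sets=config.n_sets,
                set_size=config.set_size, seed=sp_seed,
            )
        except ValueError:
            n_skipped += 1
            continue
        members = []
        for k, pred_set in enumerate(sets):
            kwargs = {"rf_trees": config.rf_trees} if config.algorithm == "rf" else {}
            try:
                members.append(
                    build_member(
                        data, config.algorithm, pred_set,
                        seed=sp_seed + 7 * k + 1, species_id=sp_id, **kwargs,
                    )
                )
            except Exception:
                continue
        ens = build_ensemble(members, env, tss_min=config.tss_min)
        true_opt = truth[sp_id].niche.get("T", (np.nan, np.nan))[0]
        if ens is None:
            n_skipped += 1
            stats.append(
                {"species_id": sp_id, "presences": int(counts[sp_id]),
                 "n_members": 0, "true_optimum": true_opt,
                 "recovered_peak": np.nan}
            )
            continue
        vals = ens.data.values
        if richness_sum is None:
            richness_sum = np.zeros(vals.shape)
            covered = np.zeros(vals.shape, dtype=bool)
        ok = np.isfinite(vals)
        richness_sum[ok] += vals[ok]
        covered |= ok
        stats.append(
            {"species_id": sp_id, "presences": int(counts[sp_id]),
             "n_members": ens.n_members, "true_optimum": true_opt,
             "recovered_peak": thermal_response_peak(
                 vals.reshape(-1), t_flat
             )}
        )

    if richness_sum is None:
        raise RuntimeError("no species could be modeled")
    monthly = xr.DataArray(
        np.where(covered, richness_sum, np.nan),
        coords={"month": env["month"], "lat": env["lat"], "lon": env["lon"]},
        dims=("month", "lat", "lon"),
    )
    richness_annual = monthly.mean("month", skipna=True)
    t_annual = env["T"].mean("month", skipna=True)
    regimes = fit_thermal_regimes(richness_annual.values, t_annual.values)
    stats_df = pd.DataFrame(stats)
    return PipelineResult(
        regimes=regimes,
        true_slope=-config.activation_energy if metabolic else np.nan,
        n_species_modeled=int((stats_df["n_members"] > 0).sum()) if len(stats_df) else 0,
        n_species_skipped=n_skipped,
        richness_annual=richness_annual,
        temperature_annual=t_annual,
        species_stats=stats_df,
    )


def recover_activation_energy(
    seeds, config: PipelineConfig | None = None
) -> dict:
    """Mean recovered global Boltzmann slope over several simulated worlds."""
    config = config or PipelineConfig()
    slopes = []
    n_modeled = []
    for s in seeds:
        res = run_pipeline(config, int(s), metabolic=True)
        slopes.append(res.global_slope)
        n_modeled.append(res.n_species_modeled)
    return {
        "slopes": slopes,
        "mean_slope": float(np.mean(slopes)),
        "true_slope": -config.activation_energy,
        "n_species_modeled": n_modeled,
    }
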