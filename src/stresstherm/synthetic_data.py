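"""Synthetic datasets with the structure the meta-regression assumes.

The generator draws a bird and a mammal phylogeny (pure-birth,
ultrametric, unit height), species masses and relative-RMR categories,
study-level covariates (air temperature, technique, design, age class),
and observation-level latencies and group sizes.  True log response
ratios follow the meta-regression's own generative model — fixed effects
on centred/standardized covariates, i.i.d. species and study intercepts,
phylogenetically correlated species effects, and residual heterogeneity
— and observed ratios add sampling noise with a realistic pooled-SE
distribution.  Body temperatures are then back-computed so that the
effect-size pipeline reproduces the intended observed lRR exactly:
Tb0 ~ Normal(38, 1.7) and Tb1 = Tb0 * exp(lrr).

The default scenario mirrors the analysed sample: 165 observations, 68
studies, 24 species, mean mass ~222 g, mean air temperature ~20 deg C,
with the published coefficient table as the true effect vector.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

import dendropy
import numpy as np

from stresstherm import meta_model
from stresstherm.io_schema import Dataset, ObservationRecord
from stresstherm.phylo import PhyloCov, block_combine, vcov_from_tree

__all__ = [
    "GeneratorScenario",
    "SimulationResult",
    "reference_scenario",
    "null_scenario",
    "simulate_tree",
    "simulate_dataset",
]


@dataclass(frozen=True)
class GeneratorScenario:
    """Study conditions for one simulated dataset."""

    n_species: int = 24
    n_studies: int = 68
    n_obs: int = 165
    # true coefficients, in meta_model.COEF_NAMES order
    beta: tuple[float, ...] = (
        1.67e-2,  # intercept
        7.70e-4,  # air temperature (per deg C)
        4.25e-3,  # ln body mass
        -3.98e-3,  # relative RMR (high)
        -4.00e-4,  # air temp x ln mass
        1.38e-3,  # air temp x relative RMR
        -3.61e-2,  # latency (standardized)
        -5.04e-2,  # latency squared
        4.80e-4,  # technique (thermocouple)
        -6.97e-3,  # age class
    )
    sd_species: float = 1.49e-2
    sd_phylo: float = 1.50e-3
    sd_study: float = 1.0e-2
    sigma: float = 1.5e-2
    # covariate distributions
    air_temp_mean: float = 20.1
    air_temp_sd: float = 10.0
    air_temp_range: tuple[float, float] = (-10.0, 35.0)
    air_within_study_sd: float = 6.0  # spread of air-temp treatments in a study
    air_meas_sd: float = 2.0
    ln_mass_mean: float = 5.403  # ln(222 g)
    ln_mass_sd: float = 1.5
    mass_range: tuple[float, float] = (5.0, 8500.0)
    mass_cv: float = 0.10  # observation-level mass noise / reported CV
    latency_ln_mean: float = 7.6
    latency_ln_sd: float = 1.0
    latency_max: float = 28_800.0
    se_ln_median: float = 0.005  # pooled-SE log-normal median
    se_ln_sd: float = 0.5
    tb0_mean: float = 38.0
    tb0_sd: float = 1.7
    frac_control_design: float = 0.3
    frac_bird: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_obs >= self.n_studies >= 1):
            raise ValueError("need n_obs >= n_studies >= 1")
        for name in ("sd_species", "sd_phylo", "sd_study", "sigma",
                     "air_meas_sd", "mass_cv", "se_ln_sd", "tb0_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def reference_scenario(seed: int = 0, **overrides) -> GeneratorScenario:
    """The default study conditions (published coefficients as truth)."""
    return replace(GeneratorScenario(seed=seed), **overrides)


def null_scenario(seed: int = 0, **overrides) -> GeneratorScenario:
    """All fixed effects zero; group structure and noise unchanged."""
    return replace(
        GeneratorScenario(seed=seed, beta=(0.0,) * len(meta_model.COEF_NAMES)),
        **overrides,
    )


@dataclass
class SimulationResult:
    """A simulated dataset with its generating truth."""

    dataset: Dataset
    truth: dict
    bird_tree: dendropy.Tree
    mammal_tree: dendropy.Tree
    rel_map: dict[str, int]
    phylo: PhyloCov
    resampled: int = 0

    def write(self, outdir) -> dict[str, str]:
        """Emit observations CSV, Newick trees and the truth JSON."""
        import json
        from pathlib import Path

        from stresstherm.io_schema import write_observations

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "observations": str(outdir / "observations.csv"),
            "bird_tree": str(outdir / "birds.nwk"),
            "mammal_tree": str(outdir / "mammals.nwk"),
            "truth": str(outdir / "truth.json"),
        }
        write_observations(self.dataset, paths["observations"])
        self.bird_tree.write(path=paths["bird_tree"], schema="newick")
        self.mammal_tree.write(path=paths["mammal_tree"], schema="newick")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1)
        return paths


def simulate_tree(
    n_tips: int, taxon_class: str, seed: int
) -> dendropy.Tree:
    """Ultrametric pure-birth tree of unit height, deterministic per seed."""
    if n_tips < 1:
        raise ValueError("need at least one tip")
    labels = [f"{taxon_class}_sp{i + 1}" for i in range(n_tips)]
    if n_tips == 1:
        return dendropy.Tree.get(data=f"({labels[0]}:1.0);", schema="newick")
    if n_tips == 2:
        # the pure-birth process starts from two lineages, so a 2-tip
        # tree is a root split of unit height by construction
        return dendropy.Tree.get(
            data=f"({labels[0]}:1.0,{labels[1]}:1.0);", schema="newick"
        )
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    tree.seed_node.edge.length = None  # drop the root stem
    for leaf, label in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = label
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    lo: float, hi: float, size: int,
) -> np.ndarray:
    out = np.empty(size)
    for i in range(size):
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                out[i] = x
                break
        else:  # pragma: no cover - bounds are generous
            out[i] = np.clip(mean, lo, hi)
    return out


def simulate_dataset(scn: GeneratorScenario) -> SimulationResult:
    """Draw one dataset (and its truth record) under the scenario."""
    rng = np.random.default_rng(scn.seed)
    n_bird = min(max(int(round(scn.frac_bird * scn.n_species)), 1),
                 scn.n_species - 1) if scn.n_species > 1 else 1
    n_mammal = scn.n_species - n_bird
    tree_seeds = rng.integers(0, 2**31 - 1, size=2)
    bird_tree = simulate_tree(n_bird, "bird", int(tree_seeds[0]))
    mammal_tree = (
        simulate_tree(n_mammal, "mammal", int(tree_seeds[1]))
        if n_mammal
        else None
    )
    bird_species = sorted(t.label for t in bird_tree.taxon_namespace)
    mammal_species = (
        sorted(t.label for t in mammal_tree.taxon_namespace) if mammal_tree else []
    )
    species = bird_species + mammal_species
    classes = ["bird"] * len(bird_species) + ["mammal"] * len(mammal_species)

    bird_cov = vcov_from_tree(bird_tree, bird_species)
    if mammal_tree is not None:
        mammal_cov = vcov_from_tree(mammal_tree, mammal_species)
        phylo = block_combine(bird_cov, mammal_cov, normalize=True)
    else:
        phylo = bird_cov.normalized()
    C = phylo.matrix

    S, K, n = scn.n_species, scn.n_studies, scn.n_obs
    # species-level attributes
    ln_mass_sp = _truncated_normal(
        rng, scn.ln_mass_mean, scn.ln_mass_sd,
        np.log(scn.mass_range[0]), np.log(scn.mass_range[1]), S,
    )
    rel_rmr_sp = rng.integers(0, 2, size=S)
    rel_map = {sp: int(v) for sp, v in zip(species, rel_rmr_sp)}

    # study-level attributes; every study observes one species, and every
    # species is observed by some study when there are enough studies
    if K >= S:
        study_species = np.concatenate(
            [rng.permutation(S), rng.integers(0, S, size=K - S)]
        )
    else:
        study_species = rng.integers(0, S, size=K)
    study_air = _truncated_normal(
        rng, scn.air_temp_mean, scn.air_temp_sd,
        scn.air_temp_range[0], scn.air_temp_range[1], K,
    )
    # mild study-to-study spread in reported measurement error
    study_air_sd = scn.air_meas_sd * np.clip(
        rng.normal(1.0, 0.25, size=K), 0.25, None
    )
    study_tech = rng.integers(0, 2, size=K)
    study_design = rng.random(K) < scn.frac_control_design
    study_age = rng.choice([-1, 0, 1], size=K, p=[0.15, 0.15, 0.70])

    # observations: each study gets at least one
    obs_study = np.concatenate(
        [np.arange(K), rng.integers(0, K, size=n - K)]
    )
    obs_study.sort()
    sp_idx = study_species[obs_study]

    latency = np.empty(n)
    for i in range(n):
        while True:
            lv = rng.lognormal(scn.latency_ln_mean, scn.latency_ln_sd)
            if lv <= scn.latency_max:
                latency[i] = lv
                break
    n_ind = 1 + rng.poisson(7.0, size=n)

    # true covariates and their observed (noisy) versions; study groups
    # are partly defined by air-temperature treatments, so the true air
    # temperature varies within studies around the study-level centre
    if scn.air_within_study_sd > 0:
        air_true = np.array([
            _truncated_normal(
                rng, study_air[obs_study[i]], scn.air_within_study_sd,
                scn.air_temp_range[0], scn.air_temp_range[1], 1,
            )[0]
            for i in range(n)
        ])
    else:
        air_true = study_air[obs_study]
    air_obs = air_true + rng.normal(0.0, study_air_sd[obs_study])
    lnm_true = ln_mass_sp[sp_idx]
    lnm_obs = lnm_true + rng.normal(0.0, scn.mass_cv, size=n)
    mass_obs = np.exp(lnm_obs)
    mass_sd = scn.mass_cv * mass_obs

    # design matrix from TRUE covariates, centred on their sample means
    air_c = air_true - air_true.mean()
    lnm_c = lnm_true - lnm_true.mean()
    lat_sd = latency.std(ddof=0)
    lat_c = (latency - latency.mean()) / (lat_sd if lat_sd > 0 else 1.0)
    rmr = rel_rmr_sp[sp_idx].astype(float)
    tech = study_tech[obs_study].astype(float)
    age = study_age[obs_study].astype(float)
    X = np.column_stack(
        [np.ones(n), air_c, lnm_c, rmr, air_c * lnm_c, air_c * rmr,
         lat_c, lat_c**2, tech, age]
    )
    beta = np.asarray(scn.beta, dtype=float)

    u_sp = rng.normal(0.0, scn.sd_species, size=S) if scn.sd_species > 0 else np.zeros(S)
    if scn.sd_phylo > 0:
        L = np.linalg.cholesky(C + 1e-10 * np.eye(S))
        u_ph = scn.sd_phylo * (L @ rng.standard_normal(S))
    else:
        u_ph = np.zeros(S)
    u_st = rng.normal(0.0, scn.sd_study, size=K) if scn.sd_study > 0 else np.zeros(K)

    lrr_true = (
        X @ beta
        + u_sp[sp_idx]
        + u_ph[sp_idx]
        + u_st[obs_study]
        + (rng.normal(0.0, scn.sigma, size=n) if scn.sigma > 0 else 0.0)
    )
    se = (
        np.exp(rng.normal(np.log(scn.se_ln_median), scn.se_ln_sd, size=n))
        if scn.se_ln_median > 0
        else np.zeros(n)
    )
    lrr_obs = lrr_true + rng.normal(0.0, 1.0, size=n) * se

    # back-compute temperatures so the pipeline reproduces lrr_obs exactly
    resampled = 0
    tb0 = np.empty(n)
    tb1 = np.empty(n)
    for i in range(n):
        for _ in range(100):
            t0 = rng.normal(scn.tb0_mean, scn.tb0_sd)
            t1 = t0 * np.exp(lrr_obs[i])
            if 0.5 < t0 < 49.5 and 0.5 < t1 < 49.5:
                tb0[i], tb1[i] = t0, t1
                break
            resampled += 1
        else:  # pragma: no cover
            raise RuntimeError("could not back-compute feasible temperatures")

    seasons = ["spring", "summer", "autumn", "winter", "NA"]
    records = []
    group_counter: dict[int, int] = {}
    rootn = np.sqrt(n_ind)
    for i in range(n):
        k = int(obs_study[i])
        group_counter[k] = group_counter.get(k, 0) + 1
        s = int(sp_idx[i])
        # arm dispersions chosen so the pooled SE reproduces se[i]
        sd_resp = 0.5 * se[i] * tb1[i] * rootn[i]
        sd_base = 0.5 * se[i] * tb0[i] * rootn[i]
        records.append(
            ObservationRecord(
                study_id=f"s{k + 1:03d}",
                group_id=f"g{group_counter[k]}",
                species=species[s],
                family=f"fam_{species[s].split('_')[0]}",
                taxon_class=classes[s],
                n_individuals=int(n_ind[i]),
                tb_baseline=float(tb0[i]),
                tb_baseline_sd=float(sd_base),
                tb_response=float(tb1[i]),
                tb_response_sd=float(sd_resp),
                design=(
                    "stressed_vs_control" if study_design[k] else "pre_post"
                ),
                air_temp=float(air_obs[i]),
                air_temp_sd=float(study_air_sd[k]),
                mass=float(mass_obs[i]),
                mass_sd=float(mass_sd[i]),
                latency=float(latency[i]),
                technique="thermocouple" if study_tech[k] else "telemetry",
                age_class=int(study_age[k]),
                sex="mixed",
                season=seasons[int(rng.integers(0, 5))],
                pharma_flag=False,
            )
        )
    dataset = Dataset(records, provenance=f"simulated (seed={scn.seed})")
    truth = {
        "seed": scn.seed,
        "beta": {name: float(b) for name, b in zip(meta_model.COEF_NAMES, beta)},
        "sd_species": scn.sd_species,
        "sd_phylo": scn.sd_phylo,
        "sd_study": scn.sd_study,
        "sigma": scn.sigma,
        "species": species,
        "rel_map": rel_map,
        "lrr_true": lrr_true.tolist(),
        "lrr_obs": lrr_obs.tolist(),
        "se": se.tolist(),
        "centring": {
            "air_mean": float(air_true.mean()),
            "lnm_mean": float(lnm_true.mean()),
            "lat_mean": float(latency.mean()),
            "lat_sd": float(lat_sd),
        },
        "resampled": resampled,
    }
    return SimulationResult(
        dataset=dataset,
        truth=truth,
        bird_tree=bird_tree,
        mammal_tree=mammal_tree if mammal_tree is not None else bird_tree,
        rel_map=rel_map,
        phylo=phylo,
        resampled=resampled,
    )
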