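"""Synthetic cohort generator.

Emulates the data shape of a pre-treatment gut-microbiome immunotherapy
cohort: paired 16S amplicon (s-OTU counts plus phylogeny) and shotgun
(species-level relative abundance) profiles driven by a shared latent
community, HUMAnN-style pathway tables decomposed into per-species
contributions with a metatranscriptomic counterpart on a sample subset, and
proportional-hazards progression-free survival tied to planted features.

The generative model, per sample i and species s:

* latent log-abundance  theta_is = ln a_s + u_ic + N(0, sigma_w), where a_s is
  a heavy-tailed (log-normal) species baseline giving a realistic
  rank-abundance curve, and u_ic is an optional community-type shift creating
  two compositional clusters;
* platform measurements add independent noise to the shared latent value:
  16S counts ~ Multinomial(depth_i, softmax(theta_i + eps16)), shotgun
  relative abundance = softmax(theta_i + eps_shot);
* survival: hazard h_i = h0 * exp( sum_j beta_j clr_ij + gamma' Z_i +
  log-cluster-effect ), exponential event times by inverse transform,
  administrative censoring at the horizon plus a uniform early-dropout
  fraction.

Everything is reproducible from ``config.seed`` via named substreams.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._rng import substream
from .containers import (
    ClrTable,
    FeatureTable,
    StratifiedFunctionTable,
    SurvivalData,
)

_GENUS_POOL = [
    "Bacteroides", "Faecalibacterium", "Prevotella", "Blautia", "Ruminococcus",
    "Streptococcus", "Coprococcus", "Parabacteroides", "Bilophila",
    "Clostridium", "Akkermansia", "Roseburia", "Dorea", "Alistipes",
    "Eubacterium", "Dialister", "Oscillospira", "Sutterella", "Veillonella",
    "Lachnospira",
]


def _default_planted() -> dict[str, float]:
    # three planted species, |log HR| >= 0.8, mixed directions
    return {"sp001": 1.0, "sp002": -1.0, "sp003": 0.8}


def _default_covariate_log_hrs() -> dict[str, float]:
    # progressors tend to be older with lower BMI; other covariates null
    return {"age": 0.03, "bmi": -0.04}


@dataclass
class SyntheticConfig:
    """Generator settings. Defaults mirror the emulated study design:
    27 patients, a 17-sample metatranscriptome subset, per-sample 16S depths
    in 18,368-60,000 reads, follow-up horizon 25 months."""

    n_patients: int = 27
    n_taxa_16s: int = 150
    n_taxa_shotgun: int = 80
    n_pathways: int = 40
    mtx_subset_fraction: float = 17 / 27
    planted_effects: dict[str, float] = field(default_factory=_default_planted)
    platform_noise_sd: float = 0.3
    baseline_hazard_rate: float = 0.01      # events per month (reference patient)
    censoring_horizon: float = 25.0         # months
    dropout_fraction: float = 0.10
    depth_range: tuple[int, int] = (18368, 60000)
    shared_fraction: float = 0.6            # taxa observed on both platforms
    abundance_tail_sd: float = 2.0          # between-species log-normal spread
    within_sample_sd: float = 1.0           # per-sample latent variation
    cluster_separation: float = 2.0         # community-type latent shift (signed)
    cluster_log_hr: float = float(np.log(5))  # hazard multiplier, cluster 2
    cluster_fraction: float = 0.5
    covariate_log_hrs: dict[str, float] = field(default_factory=_default_covariate_log_hrs)
    expression_factor_sd: float = 0.5       # per-pathway RNA/DNA log-sd
    mtx_noise_sd: float = 0.3               # per-cell metatranscriptome noise
    unclassified_species_fraction: float = 0.15  # 16S-only features lacking s__
    detection_limit: float = 1e-5           # shotgun relabund below this reads 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_taxa_16s", "n_taxa_shotgun", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not (0 < self.mtx_subset_fraction <= 1):
            raise ValueError("mtx_subset_fraction must be in (0, 1]")
        if self.mtx_subset_fraction * self.n_patients < 2:
            raise ValueError("metatranscriptome subset must contain at least 2 samples")
        if self.platform_noise_sd < 0:
            raise ValueError("platform_noise_sd must be nonnegative")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline_hazard_rate must be positive")
        if self.censoring_horizon <= 0:
            raise ValueError("censoring_horizon must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    true_log_hr: pd.Series                    # per shotgun/shared feature
    true_cluster_label: pd.Series             # per patient, {1, 2}
    contribution_weights: pd.DataFrame | None  # pathway x species, rows sum 1
    latent_log_abundance: pd.DataFrame         # patients x species (shared latent)
    shared_species: list[str] = field(default_factory=list)
    sotu_to_species: dict[str, str] = field(default_factory=dict)
    prob_16s: pd.DataFrame | None = None       # expected 16S relabund (pre-count)
    prob_shotgun: pd.DataFrame | None = None   # shotgun relabund before closure noise


def _species_names(n: int, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Deterministic species ids sp001.. with genus-structured taxonomy."""
    names, taxonomies = [], []
    for k in range(n):
        genus = _GENUS_POOL[k % len(_GENUS_POOL)]
        sp = f"sp{k + 1:03d}"
        names.append(sp)
        taxonomies.append(
            "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
            f"f__{genus}aceae;g__{genus};s__{genus}_{sp}"
        )
    return names, taxonomies


def _random_tree(leaves: list[str], rng: np.random.Generator) -> TreeNode:
    """Random bifurcating (coalescent-style) tree with exponential lengths."""
    nodes = [f"{name}:{rng.exponential(1.0):.6f}" for name in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = rng.exponential(1.0)
        merged = f"({nodes[i]},{nodes[j]}):{b:.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0]
    newick = newick[: newick.rfind(":")] + ";"
    return TreeNode.read(_io.StringIO(newick))


def generate_taxa_tables(
    config: SyntheticConfig,
) -> tuple[FeatureTable, FeatureTable, TreeNode, GroundTruth]:
    """Paired 16S (counts + tree) and shotgun (relative abundance) tables.

    Taxa present on both platforms share the same latent log-abundance before
    independent platform noise is added, so paired measurements are
    positively correlated, as in real paired 16S/shotgun profiles.
    """
    cfg = config
    rng_lat = substream(cfg.seed, "latent")
    rng_16s = substream(cfg.seed, "platform-16s")
    rng_sg = substream(cfg.seed, "platform-shotgun")
    rng_tree = substream(cfg.seed, "tree")

    n_shared = max(1, int(round(cfg.shared_fraction * min(cfg.n_taxa_16s, cfg.n_taxa_shotgun))))
    n_species = cfg.n_taxa_16s + cfg.n_taxa_shotgun - n_shared
    species, taxonomies = _species_names(n_species, rng_lat)
    shared = species[:n_shared]
    only_16s = species[n_shared: cfg.n_taxa_16s]
    only_sg = species[cfg.n_taxa_16s:]
    species_16s = shared + only_16s
    species_sg = shared + only_sg

    unknown = set(cfg.planted_effects) - set(species)
    if unknown:
        raise ValueError(f"planted feature ids not among generated features: {sorted(unknown)}")

    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    # heavy-tailed species baselines: a few taxa dominate
    base = rng_lat.normal(0.0, cfg.abundance_tail_sd, size=n_species)
    # effects are planted in detectable taxa (as in the emulated analysis,
    # which only tests taxa passing prevalence/abundance screens)
    for feat in cfg.planted_effects:
        k = species.index(feat) if feat in species else -1
        if k >= 0 and base[k] < 0.0:
            base[k] = 0.0
    cluster = (rng_lat.random(cfg.n_patients) < cfg.cluster_fraction).astype(int) + 1
    # community types shift a random half of the taxa, up or down with equal
    # probability (enterotype-like reshuffling of dominance, not a uniform
    # enrichment), which makes the two types separable by composition
    shifted = rng_lat.random(n_species) < 0.5
    signs = np.where(rng_lat.random(n_species) < 0.5, 1.0, -1.0)
    shift = np.where(shifted, cfg.cluster_separation * signs, 0.0)
    theta = (base[None, :]
             + np.where(cluster[:, None] == 2, shift[None, :], 0.0)
             + rng_lat.normal(0.0, cfg.within_sample_sd, size=(cfg.n_patients, n_species)))
    latent = pd.DataFrame(theta, index=patients, columns=species)

    tax_map = dict(zip(species, taxonomies))

    # --- 16S: s-OTUs, multinomial counts at realistic depths
    idx16 = [species.index(s) for s in species_16s]
    eta16 = theta[:, idx16] + rng_16s.normal(0.0, cfg.platform_noise_sd,
                                             size=(cfg.n_patients, len(idx16)))
    prob16 = np.exp(eta16 - eta16.max(axis=1, keepdims=True))
    prob16 /= prob16.sum(axis=1, keepdims=True)
    depths = rng_16s.integers(cfg.depth_range[0], cfg.depth_range[1] + 1,
                              size=cfg.n_patients)
    counts = np.vstack([rng_16s.multinomial(depths[i], prob16[i])
                        for i in range(cfg.n_patients)])
    sotu_ids = [f"sotu{k + 1:04d}" for k in range(len(species_16s))]
    sotu_to_species = dict(zip(sotu_ids, species_16s))
    # some 16S-only features lack species- (and a few genus-) level names
    tax16 = []
    n_only = len(only_16s)
    unclass = rng_16s.random(len(species_16s)) < cfg.unclassified_species_fraction
    unclass[:n_shared] = False  # shared taxa keep full classification
    for k, (sid, sp) in enumerate(zip(sotu_ids, species_16s)):
        t = tax_map[sp]
        if unclass[k]:
            head, _, _ = t.rpartition(";")
            if rng_16s.random() < 0.2:  # occasionally unclassified at genus too
                head = head.rpartition(";")[0] + ";g__"
            t = head + ";s__"
        tax16.append(t)
    table_16s = FeatureTable(
        pd.DataFrame(counts, index=patients, columns=sotu_ids),
        level="s-OTU",
        feature_meta=pd.DataFrame({"taxonomy": tax16}, index=sotu_ids),
    )
    tree = _random_tree(sotu_ids, rng_tree)

    # --- shotgun: species-level relative abundance
    idxsg = [species.index(s) for s in species_sg]
    etasg = theta[:, idxsg] + rng_sg.normal(0.0, cfg.platform_noise_sd,
                                            size=(cfg.n_patients, len(idxsg)))
    probsg = np.exp(etasg - etasg.max(axis=1, keepdims=True))
    probsg /= probsg.sum(axis=1, keepdims=True)
    # shotgun profilers have a detection limit: tiny abundances read as zero
    if cfg.detection_limit > 0:
        probsg[probsg < cfg.detection_limit] = 0.0
        probsg /= probsg.sum(axis=1, keepdims=True)
    table_sg = FeatureTable(
        pd.DataFrame(probsg, index=patients, columns=species_sg),
        level="species",
        feature_meta=pd.DataFrame(
            {"taxonomy": [tax_map[s] for s in species_sg]}, index=species_sg),
    )

    true_log_hr = pd.Series(0.0, index=species)
    for feat, b in cfg.planted_effects.items():
        true_log_hr[feat] = float(b)

    # per-pathway species contribution weights (rows sum to 1)
    rng_fun = substream(cfg.seed, "function-weights")
    pathways = [f"PWY{k + 1:04d}" for k in range(cfg.n_pathways)]
    weights = np.zeros((cfg.n_pathways, len(species_sg)))
    for pi in range(cfg.n_pathways):
        k = int(rng_fun.integers(1, 7))
        contributors = rng_fun.choice(len(species_sg), size=min(k, len(species_sg)),
                                      replace=False)
        w = rng_fun.dirichlet(np.ones(len(contributors)))
        weights[pi, contributors] = w
    contribution_weights = pd.DataFrame(weights, index=pathways, columns=species_sg)

    truth = GroundTruth(
        true_log_hr=true_log_hr,
        true_cluster_label=pd.Series(cluster, index=patients),
        contribution_weights=contribution_weights,
        latent_log_abundance=latent,
        shared_species=shared,
        sotu_to_species=sotu_to_species,
        prob_16s=pd.DataFrame(prob16, index=patients, columns=sotu_ids),
        prob_shotgun=table_sg.values.copy(),
    )
    return table_16s, table_sg, tree, truth


def generate_covariates(config: SyntheticConfig) -> pd.DataFrame:
    """Clinical covariates with marginals matched to the emulated cohort:
    age ~ N(70, 12), BMI ~ N(27.5, 5), 78% male, 56% recent antibiotics,
    2/3 stage IV, metastatic sites 0 / 1-2 / >=3 with probs .41/.33/.26."""
    rng = substream(config.seed, "covariates")
    n = config.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]
    return pd.DataFrame({
        "age": np.round(rng.normal(70.0, 12.0, n), 1),
        "sex": (rng.random(n) < 0.78).astype(int),
        "bmi": np.round(rng.normal(27.5, 5.0, n), 1),
        "stage": (rng.random(n) < 2 / 3).astype(int),
        "met_sites": rng.choice(["0", "1-2", ">=3"], size=n, p=[0.41, 0.33, 0.26]),
        "antibiotics": (rng.random(n) < 0.56).astype(int),
    }, index=patients)


def generate_survival(
    config: SyntheticConfig,
    clr_table: ClrTable,
    ground_truth: GroundTruth,
    covariates: pd.DataFrame | None = None,
) -> SurvivalData:
    """Proportional-hazards event times tied to planted clr features.

    Hazard: h_i = h0 * exp(sum_j beta_j clr_ij + gamma' Z_i + cluster term),
    exponential event times by inverse transform, administrative censoring at
    the horizon plus a uniform early-dropout fraction.
    """
    cfg = config
    rng = substream(cfg.seed, "survival")
    if not np.allclose(clr_table.values.sum(axis=1), 0.0, atol=1e-8):
        raise ValueError("clr rows must be centered")
    if covariates is None:
        covariates = generate_covariates(cfg)
    patients = list(clr_table.values.index)
    covariates = covariates.loc[patients]

    lp = np.zeros(len(patients))
    for feat, b in cfg.planted_effects.items():
        if feat in clr_table.values.columns:
            x = clr_table.values[feat].to_numpy()
            # center across patients so h0 is the rate of the average patient
            lp += b * (x - x.mean())
    gamma = cfg.covariate_log_hrs or {}
    design = pd.DataFrame({
        "age": covariates["age"] - 70.0,     # centered so h0 is the reference rate
        "sex": covariates["sex"],
        "bmi": covariates["bmi"] - 27.5,
        "stage": covariates["stage"],
        "antibiotics": covariates["antibiotics"],
    })
    for name, g in gamma.items():
        if name not in design.columns:
            raise ValueError(f"unknown covariate in covariate_log_hrs: {name!r}")
        lp += g * design[name].to_numpy(dtype=float)
    labels = ground_truth.true_cluster_label.loc[patients].to_numpy()
    lp += np.where(labels == 2, cfg.cluster_log_hr, 0.0)

    hazard = cfg.baseline_hazard_rate * np.exp(lp)
    if np.all(hazard == 0):
        raise ValueError("all-zero hazard: check baseline rate and effects")
    t_event = rng.exponential(1.0 / hazard)
    censor = np.full(len(patients), cfg.censoring_horizon)
    drop = rng.random(len(patients)) < cfg.dropout_fraction
    censor[drop] = rng.uniform(0.0, cfg.censoring_horizon, size=int(drop.sum()))
    censor = np.maximum(censor, 1e-3)
    time = np.maximum(np.minimum(t_event, censor), 0.01)
    event = (t_event <= censor).astype(int)

    frame = covariates.copy()
    frame.insert(0, "event", event)
    frame.insert(0, "time", np.round(time, 4))
    return SurvivalData(frame)


def generate_function_tables(
    config: SyntheticConfig,
    shotgun_table: FeatureTable,
    ground_truth: GroundTruth,
) -> tuple[StratifiedFunctionTable, StratifiedFunctionTable]:
    """HUMAnN-style stratified pathway tables for metagenome (all samples)
    and metatranscriptome (the mtx subset).

    Per-species pathway abundance is weight x species abundance; the pathway
    total is the sum over contributing species; both are closed per sample.
    The metatranscriptome multiplies each pathway by a log-normal expression
    factor and per-cell log-normal noise before re-closure.
    """
    cfg = config
    weights = ground_truth.contribution_weights
    if weights is None:
        raise ValueError("ground truth carries no contribution weights")
    unknown = weights.columns.difference(shotgun_table.values.columns)
    if len(unknown):
        raise ValueError(f"contribution weights reference unknown species: {list(unknown)}")
    rng = substream(cfg.seed, "function-tables")

    A = shotgun_table.values  # samples x species
    patients = list(A.index)
    pathways = list(weights.index)

    strata = {}
    for pw in pathways:
        w = weights.loc[pw]
        for sp in w.index[w > 0]:
            strata[(pw, sp)] = w[sp] * A[sp].to_numpy()
    strat = pd.DataFrame(strata, index=patients)
    strat.columns = pd.MultiIndex.from_tuples(strat.columns, names=["pathway", "species"])
    total = strat.T.groupby(level="pathway").sum().T[pathways]

    # close the metagenome tables per sample
    norm = total.sum(axis=1)
    total_mgx = total.div(norm, axis=0)
    strat_mgx = strat.div(norm, axis=0)
    mgx = StratifiedFunctionTable(total=total_mgx, stratified=strat_mgx)

    n_mtx = int(round(cfg.mtx_subset_fraction * cfg.n_patients))
    n_mtx = max(2, n_mtx)
    subset = sorted(rng.choice(patients, size=n_mtx, replace=False).tolist())
    factors = np.exp(rng.normal(0.0, cfg.expression_factor_sd, size=len(pathways)))
    factor_by_pw = dict(zip(pathways, factors))
    fvec = np.array([factor_by_pw[pw] for pw, _ in strat.columns])
    noise = np.exp(rng.normal(0.0, cfg.mtx_noise_sd,
                              size=(n_mtx, strat.shape[1]))) if cfg.mtx_noise_sd > 0 else 1.0
    strat_mtx = strat.loc[subset] * fvec[None, :] * noise
    total_mtx = strat_mtx.T.groupby(level="pathway").sum().T[pathways]
    norm_mtx = total_mtx.sum(axis=1)
    mtx = StratifiedFunctionTable(
        total=total_mtx.div(norm_mtx, axis=0),
        stratified=strat_mtx.div(norm_mtx, axis=0),
    )
    return mgx, mtx


def cluster_config(seed: int, n_patients: int = 150, **overrides) -> SyntheticConfig:
    """Cluster-linked-hazard study conditions.

    The community-type hazard multiplier (x5 by default) is the only
    microbial survival signal; per-taxon planted effects are switched off so
    the clustering stages see an isolated planted structure.
    """
    return SyntheticConfig(n_patients=n_patients, planted_effects={},
                           seed=seed, **overrides)


def recovery_config(seed: int, n_patients: int = 200, n_noise: int = 60,
                    planted_effects: dict[str, float] | None = None,
                    **overrides) -> SyntheticConfig:
    """Parameter-recovery study conditions.

    Three planted taxa with |log HR| >= 0.8 among ``n_noise``
    survival-neutral taxa; the community-type hazard link is switched off so
    that the planted features are the only microbial survival signal.
    """
    return SyntheticConfig(
        n_patients=n_patients,
        n_taxa_shotgun=3 + n_noise,
        n_taxa_16s=3 + n_noise,
        planted_effects=planted_effects or _default_planted(),
        cluster_log_hr=0.0,
        cluster_separation=0.0,
        seed=seed,
        **overrides,
    )


@dataclass
class SyntheticBundle:
    """Everything one cohort simulation produces."""

    config: SyntheticConfig
    table_16s: FeatureTable
    table_shotgun: FeatureTable
    tree: TreeNode
    survival: SurvivalData
    mgx: StratifiedFunctionTable
    mtx: StratifiedFunctionTable
    truth: GroundTruth


def generate_cohort(config: SyntheticConfig | None = None, **overrides) -> SyntheticBundle:
    """One-call cohort simulation: taxa, tree, survival, function tables."""
    from .compositional import clr_transform

    cfg = config if config is not None else SyntheticConfig(**overrides)
    t16, tsg, tree, truth = generate_taxa_tables(cfg)
    clr = clr_transform(tsg)
    survival = generate_survival(cfg, clr, truth)
    mgx, mtx = generate_function_tables(cfg, tsg, truth)
    return SyntheticBundle(config=cfg, table_16s=t16, table_shotgun=tsg, tree=tree,
                           survival=survival, mgx=mgx, mtx=mtx, truth=truth)
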