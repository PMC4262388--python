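"""Two-species synthetic microarray generator with known ground truth.

The generator emulates the structure of a multi-year collection of
untreated ovary microarrays from two related fish species:

* per-gene baseline log2 intensities spanning roughly 6-14 with a
  transcriptome mean near 8.5;
* per-gene coefficients of variation following an inverse-intensity
  power trend ``cv_g = a * mu_g**(-b) * jitter``, with ``a`` calibrated
  so the transcriptome-average CV hits a target (default 0.05);
* additive batch shifts hitting an independent random subset of genes
  per batch (the "nonsystematic" structure that survives quantile
  normalization), summed over however many batch factors are defined;
* ortholog gene pairs whose intensities and (log) CVs are correlated
  across the two species at configurable gene-level correlations, with
  pathway-level offsets shared between species so pathway averages are
  conserved more strongly than individual genes;
* duplicate probes per gene with probe-specific affinity offsets;
* optionally, raw two-color arrays with an intensity-dependent dye bias
  and correlated channels (shared spot effects).

Biological noise is Gaussian on the log2 scale with standard deviation
``cv_g * mu_g``, so the within-batch CV estimated downstream recovers
``cv_g`` directly.  Every random draw derives from the mandatory seed;
identical configurations yield bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .io_formats import BatchDesign, ExpressionMatrix, OrthologMap, PathwaySet
from .preprocess import TwoColorArray

__all__ = [
    "FactorSpec",
    "SpeciesSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "generate_two_color_arrays",
    "plant_within_batch_effect",
]


@dataclass
class FactorSpec:
    """One batch factor: a named partition of the samples into batches.

    ``layout='contiguous'`` chunks samples in their generation order
    (factors so defined are nested to various degrees, like sampling
    dates nested in experiments); ``'shuffled'`` re-partitions a
    seed-derived permutation of the same samples (crossed factors).
    """

    name: str
    batch_sizes: tuple
    layout: str = "contiguous"

    def __post_init__(self) -> None:
        self.batch_sizes = tuple(int(x) for x in self.batch_sizes)
        if any(x < 1 for x in self.batch_sizes):
            raise ValueError("batch sizes must be >= 1")
        if self.layout not in ("contiguous", "shuffled"):
            raise ValueError(f"unknown layout {self.layout!r}")

    @property
    def n_samples(self) -> int:
        return sum(self.batch_sizes)


def _default_factors() -> tuple:
    # Experiment-like primary factor plus a coarser nested personnel-like factor
    return (FactorSpec("Experiment", (12,) * 8),
            FactorSpec("RNA_Person", (48, 48)))


@dataclass
class SpeciesSpec:
    """Per-species generator settings."""

    name: str
    n_genes: int = 3000
    duplicate_probe_fraction: float = 0.3    # genes carrying a second probe
    mean_intensity: float = 8.5              # log2 transcriptome mean
    intensity_sd: float = 1.5
    intensity_range: tuple = (6.0, 14.0)
    cv_target: float = 0.05                  # transcriptome-average CV
    cv_trend_exponent: float = 1.0           # b in cv = a * mu^-b
    cv_jitter_sigma: float = 0.35            # lognormal jitter on the trend
    probe_offset_sd: float = 0.25            # probe affinity spread (log2)
    factors: tuple = field(default_factory=_default_factors)
    batch_effect_fraction: float = 0.2       # genes hit per batch
    batch_effect_sd: float = 0.3             # shift sd tau (log2)

    def __post_init__(self) -> None:
        if not (0.0 <= self.duplicate_probe_fraction <= 1.0):
            raise ValueError("duplicate_probe_fraction must lie in [0, 1]")
        if not (0.0 <= self.batch_effect_fraction <= 1.0):
            raise ValueError("batch_effect_fraction must lie in [0, 1]")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")
        self.factors = tuple(f if isinstance(f, FactorSpec) else FactorSpec(**f)
                             for f in self.factors)
        sizes = {f.n_samples for f in self.factors}
        if len(sizes) > 1:
            raise ValueError("all factors must partition the same number of samples")

    @property
    def n_samples(self) -> int:
        return self.factors[0].n_samples


@dataclass
class SyntheticConfig:
    """Full two-species generator configuration; the seed is mandatory."""

    seed: int
    species_a: SpeciesSpec = field(default_factory=lambda: SpeciesSpec("PPR"))
    species_b: SpeciesSpec = field(default_factory=lambda: SpeciesSpec("DRE"))
    ortholog_fraction: float = 0.7           # of the smaller gene set
    rho_intensity: float = 0.5               # gene-level cross-species correlation
    rho_cv: float = 0.5
    n_pathways: int = 40
    pathway_size_range: tuple = (5, 30)
    pathway_intensity_sd: float = 1.0        # shared log2 pathway offset
    pathway_cv_sigma: float = 0.25           # shared log pathway CV offset
    two_color: bool = False
    dye_bias_amplitude: float = 0.3
    channel_correlation: float = 0.9
    spot_noise_sd: float = 0.6               # per-spot effect shared across channels

    def __post_init__(self) -> None:
        for name in ("ortholog_fraction",):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("rho_intensity", "rho_cv", "channel_correlation"):
            v = getattr(self, name)
            if not (-1.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if isinstance(self.species_a, dict):
            self.species_a = SpeciesSpec(**self.species_a)
        if isinstance(self.species_b, dict):
            self.species_b = SpeciesSpec(**self.species_b)


@dataclass
class SpeciesTruth:
    gene_ids: list
    mu: np.ndarray                 # baseline log2 intensity per gene
    cv: np.ndarray                 # true per-gene CV
    pathway: list                  # pathway id or None per gene
    probe_ids: list
    probe_gene_index: np.ndarray   # gene index per probe
    probe_offsets: np.ndarray
    batch_effects: dict            # factor -> batch -> {"genes": idx, "shifts": arr}
    sample_ids: list


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery without regenerating."""

    seed: int
    species: dict                  # name -> SpeciesTruth
    ortholog_genes: list
    achieved_rho_intensity: float
    achieved_rho_cv: float
    planted_partition: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def convert(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            raise TypeError(type(obj))
        payload = {
            "seed": self.seed,
            "ortholog_genes": self.ortholog_genes,
            "achieved_rho_intensity": self.achieved_rho_intensity,
            "achieved_rho_cv": self.achieved_rho_cv,
            "planted_partition": self.planted_partition,
            "species": {k: asdict(v) for k, v in self.species.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=convert)


@dataclass
class SyntheticDataset:
    matrix_a: ExpressionMatrix
    matrix_b: ExpressionMatrix
    designs_a: list
    designs_b: list
    ortholog_map: OrthologMap
    pathways: PathwaySet
    truth: SyntheticTruth

    def matrix(self, species: str) -> ExpressionMatrix:
        return self.matrix_a if species == self.matrix_a.species else self.matrix_b

    def designs(self, species: str) -> list:
        return self.designs_a if species == self.matrix_a.species else self.designs_b

    def design(self, species: str, factor: str) -> BatchDesign:
        for d in self.designs(species):
            if d.factor_name == factor:
                return d
        raise KeyError(f"no factor {factor!r} for species {species!r}")


def _bivariate(rng, n, rho):
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n)
    return z1, z2


def _partition_pathways(rng, gene_ids, n_pathways, size_range):
    """Disjoint pathway membership over the ortholog genes."""
    lo, hi = size_range
    order = list(rng.permutation(len(gene_ids)))
    membership = {}
    sets = {}
    cursor = 0
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if cursor + size > len(order):
            break
        pw = f"pw{k:03d}"
        idx = order[cursor:cursor + size]
        sets[pw] = {gene_ids[i] for i in idx}
        for i in idx:
            membership[i] = pw
        cursor += size
    return sets, membership


def _make_samples(spec: SpeciesSpec, rng) -> tuple:
    sample_ids = [f"{spec.name}_s{i:03d}" for i in range(spec.n_samples)]
    designs = []
    for f in spec.factors:
        if f.layout == "shuffled":
            order = [sample_ids[i] for i in rng.permutation(len(sample_ids))]
        else:
            order = sample_ids
        assignment, start = {}, 0
        for k, size in enumerate(f.batch_sizes):
            label = f"{f.name}_b{k:02d}"
            for s in order[start:start + size]:
                assignment[s] = label
            start += size
        designs.append(BatchDesign(f.name, assignment))
    return sample_ids, designs


def _batch_effects(spec: SpeciesSpec, rng) -> dict:
    effects = {}
    for f in spec.factors:
        per_batch = {}
        for k in range(len(f.batch_sizes)):
            label = f"{f.name}_b{k:02d}"
            hit = np.flatnonzero(rng.random(spec.n_genes) < spec.batch_effect_fraction)
            shifts = rng.normal(0.0, spec.batch_effect_sd, size=hit.size)
            per_batch[label] = {"genes": hit, "shifts": shifts}
        effects[f.name] = per_batch
    return effects


def _expand_probes(spec: SpeciesSpec, rng) -> tuple:
    n_dup = int(round(spec.duplicate_probe_fraction * spec.n_genes))
    dup_genes = rng.choice(spec.n_genes, size=n_dup, replace=False)
    gene_index = list(range(spec.n_genes)) + list(np.sort(dup_genes))
    gene_index = np.asarray(gene_index, dtype=int)
    probe_ids = [f"{spec.name}_p{i:05d}" for i in range(gene_index.size)]
    offsets = rng.normal(0.0, spec.probe_offset_sd, size=gene_index.size)
    return probe_ids, gene_index, offsets


def _assemble_matrix(spec: SpeciesSpec, mu, cv, sample_ids, designs, effects,
                     probe_ids, gene_index, probe_offsets, rng) -> ExpressionMatrix:
    n_samples = len(sample_ids)
    shift = np.zeros((spec.n_genes, n_samples))
    for design in designs:
        per_batch = effects[design.factor_name]
        for j, s in enumerate(sample_ids):
            eff = per_batch[design.assignment[s]]
            shift[eff["genes"], j] += eff["shifts"]
    gene_signal = mu[:, None] + shift
    values = gene_signal[gene_index] + probe_offsets[:, None]
    noise_sd = (cv * mu)[gene_index]
    values = values + rng.normal(0.0, 1.0, size=values.shape) * noise_sd[:, None]
    return ExpressionMatrix(probe_ids, sample_ids, values, spec.name)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full two-species dataset with ground truth.

    Cross-species correlations are achieved by construction: the shared
    pathway offsets and the correlated gene-level residuals are combined
    so the *total* gene-level Pearson correlation of intensities (and of
    log CVs) matches the configured rho; the residual correlation needed
    for that is solved analytically and clipped to [-1, 1] if the shared
    pathway component alone already exceeds the target.
    """
    rng = np.random.default_rng([int(config.seed), 0x5EED])
    sa, sb = config.species_a, config.species_b
    if sa.name == sb.name:
        raise ValueError("the two species must have distinct names")

    n_orth = int(round(config.ortholog_fraction * min(sa.n_genes, sb.n_genes)))
    orth_genes = [f"g{i:05d}" for i in range(n_orth)]
    gene_ids_a = orth_genes + [f"{sa.name}_g{i:05d}" for i in range(sa.n_genes - n_orth)]
    gene_ids_b = orth_genes + [f"{sb.name}_g{i:05d}" for i in range(sb.n_genes - n_orth)]

    pathway_sets, membership = _partition_pathways(
        rng, orth_genes, config.n_pathways, config.pathway_size_range)
    pathway_ids = sorted(pathway_sets)
    pw_dmu = {pw: rng.normal(0.0, config.pathway_intensity_sd) for pw in pathway_ids}
    pw_dcv = {pw: rng.normal(0.0, config.pathway_cv_sigma) for pw in pathway_ids}

    # --- intensities ------------------------------------------------------
    # mixture algebra: for ortholog genes, var = v + w*p with v the
    # idiosyncratic and p the shared pathway variance (w = fraction of
    # ortholog genes inside pathways); solving for the idiosyncratic
    # correlation that delivers the configured total rho:
    v = sa.intensity_sd * sb.intensity_sd
    w = (sum(len(s) for s in pathway_sets.values()) / n_orth) if n_orth else 0.0
    p = config.pathway_intensity_sd ** 2
    rho_u = (config.rho_intensity * (v + w * p) - w * p) / v if v > 0 else 0.0
    rho_u = float(np.clip(rho_u, -0.999, 0.999))
    z_a, z_b = _bivariate(rng, n_orth, rho_u)

    def build_mu(spec, gene_ids, z_orth):
        z = np.empty(len(gene_ids))
        z[:n_orth] = z_orth
        z[n_orth:] = rng.standard_normal(len(gene_ids) - n_orth)
        mu = spec.mean_intensity + spec.intensity_sd * z
        for i, g in enumerate(gene_ids[:n_orth]):
            pw = membership.get(i)
            if pw is not None:
                mu[i] += pw_dmu[pw]
        return np.clip(mu, *spec.intensity_range)

    mu_a = build_mu(sa, gene_ids_a, z_a)
    mu_b = build_mu(sb, gene_ids_b, z_b)

    # --- CVs --------------------------------------------------------------
    # log cv = log a - b*log mu + gamma_pathway + eps; the eps correlation
    # needed for the configured total log-cv correlation is solved from the
    # empirical covariance of the deterministic (trend + pathway) parts.
    gamma_a = np.zeros(sa.n_genes)
    gamma_b = np.zeros(sb.n_genes)
    for i in range(n_orth):
        pw = membership.get(i)
        if pw is not None:
            gamma_a[i] = pw_dcv[pw]
            gamma_b[i] = pw_dcv[pw]
    base_a = -sa.cv_trend_exponent * np.log(mu_a) + gamma_a
    base_b = -sb.cv_trend_exponent * np.log(mu_b) + gamma_b
    if n_orth > 1:
        cov_known = float(np.cov(base_a[:n_orth], base_b[:n_orth])[0, 1])
        var_a = float(np.var(base_a[:n_orth], ddof=1)) + sa.cv_jitter_sigma**2
        var_b = float(np.var(base_b[:n_orth], ddof=1)) + sb.cv_jitter_sigma**2
        denom = sa.cv_jitter_sigma * sb.cv_jitter_sigma
        rho_eps = ((config.rho_cv * np.sqrt(var_a * var_b) - cov_known) / denom
                   if denom > 0 else 0.0)
        rho_eps = float(np.clip(rho_eps, -0.999, 0.999))
    else:
        rho_eps = 0.0
    e_a, e_b = _bivariate(rng, n_orth, rho_eps)

    def build_cv(spec, base, e_orth, n_genes):
        eps = np.empty(n_genes)
        eps[:n_orth] = e_orth * spec.cv_jitter_sigma
        eps[n_orth:] = rng.normal(0.0, spec.cv_jitter_sigma, size=n_genes - n_orth)
        raw = np.exp(base + eps)
        return spec.cv_target * raw / raw.mean()   # calibrate a so mean CV = target

    cv_a = build_cv(sa, base_a, e_a, sa.n_genes)
    cv_b = build_cv(sb, base_b, e_b, sb.n_genes)

    ach_rho_i = float(np.corrcoef(mu_a[:n_orth], mu_b[:n_orth])[0, 1]) if n_orth > 1 else np.nan
    ach_rho_c = float(np.corrcoef(np.log(cv_a[:n_orth]), np.log(cv_b[:n_orth]))[0, 1]) if n_orth > 1 else np.nan

    # --- samples, probes, matrices ---------------------------------------
    dataset = {}
    truth_species = {}
    for spec, gene_ids, mu, cv in ((sa, gene_ids_a, mu_a, cv_a), (sb, gene_ids_b, mu_b, cv_b)):
        sample_ids, designs = _make_samples(spec, rng)
        effects = _batch_effects(spec, rng)
        probe_ids, gene_index, offsets = _expand_probes(spec, rng)
        matrix = _assemble_matrix(spec, mu, cv, sample_ids, designs, effects,
                                  probe_ids, gene_index, offsets, rng)
        pathway_of = [membership.get(i) if i < n_orth else None for i in range(spec.n_genes)]
        truth_species[spec.name] = SpeciesTruth(
            gene_ids, mu, cv, pathway_of, probe_ids, gene_index, offsets, effects, sample_ids)
        dataset[spec.name] = (matrix, designs)

    # --- ortholog map (probe level, joined through the shared gene id) ----
    records = []
    ta, tb = truth_species[sa.name], truth_species[sb.name]
    probes_by_gene_a = {}
    for pid, gi in zip(ta.probe_ids, ta.probe_gene_index):
        if gi < n_orth:
            probes_by_gene_a.setdefault(gi, []).append(pid)
    for pid, gi in zip(tb.probe_ids, tb.probe_gene_index):
        if gi < n_orth:
            for pa in probes_by_gene_a.get(gi, []):
                records.append((pa, pid, orth_genes[gi]))
    ortholog_map = OrthologMap(records)

    truth = SyntheticTruth(config.seed, truth_species, orth_genes, ach_rho_i, ach_rho_c)
    matrix_a, designs_a = dataset[sa.name]
    matrix_b, designs_b = dataset[sb.name]
    return SyntheticDataset(matrix_a, matrix_b, designs_a, designs_b,
                            ortholog_map, PathwaySet(pathway_sets), truth)


def plant_within_batch_effect(matrix: ExpressionMatrix, batch_design: BatchDesign,
                              probe_ids, delta: float, partition: dict = None,
                              seed: int = 0):
    """Shift the case half of every batch by ``delta`` on a probe subset.

    ``partition`` maps sample -> "case"/"control" and must split every
    batch (at least one sample of each class per batch); when omitted, a
    seed-derived half split (case = floor(n/2)) is drawn.  Returns the
    modified matrix and the partition actually used, ready to be scored
    against a case/control scan.
    """
    batch_design = batch_design.restrict(matrix.sample_ids)
    unknown = [p for p in probe_ids if p not in set(matrix.probe_ids)]
    if unknown:
        raise ValueError(f"unknown probe id(s): {', '.join(unknown[:5])}")
    if partition is None:
        rng = np.random.default_rng([seed, 0x9A27])
        partition = {}
        for b in batch_design.batches:
            members = sorted(batch_design.samples_in(b))
            order = rng.permutation(len(members))
            n_case = len(members) // 2
            for rank, i in enumerate(order):
                partition[members[i]] = "case" if rank < n_case else "control"
    else:
        for b in batch_design.batches:
            classes = {partition.get(s) for s in batch_design.samples_in(b)}
            if classes != {"case", "control"}:
                raise ValueError(f"partition does not split batch {b!r} into case and control")
    values = matrix.values.copy()
    probe_rows = {p: i for i, p in enumerate(matrix.probe_ids)}
    rows = [probe_rows[p] for p in probe_ids]
    case_cols = [j for j, s in enumerate(matrix.sample_ids) if partition[s] == "case"]
    values[np.ix_(rows, case_cols)] += delta
    out = ExpressionMatrix(matrix.probe_ids, matrix.sample_ids, values, matrix.species)
    return out, dict(partition)


def generate_two_color_arrays(config: SyntheticConfig, n_arrays: int = None):
    """Raw two-color arrays for species B with dye bias and correlated channels.

    Each array hybridizes two consecutive species-B samples (red, green).
    On the log2 scale a spot effect shared between channels (variance
    ``channel_correlation * spot_noise_sd**2``) plus channel-specific
    remainders produce the configured within-pair correlation, and an
    intensity-dependent dye bias ``amplitude * sin(A)`` is applied
    half to each channel with opposite sign.  Backgrounds are positive
    and additive.  Returns (arrays, channel_samples, truth_matrix): the
    channel->sample map feeds straight into channel splitting.
    """
    cfg = SyntheticConfig(**{**asdict(config), "two_color": True}) if not config.two_color else config
    data = generate(cfg)
    matrix = data.matrix_b
    rng = np.random.default_rng([int(cfg.seed), 0x7C01])
    n_pairs = matrix.n_samples // 2 if n_arrays is None else n_arrays
    sd_shared = np.sqrt(cfg.channel_correlation) * cfg.spot_noise_sd
    sd_indiv = np.sqrt(max(1.0 - cfg.channel_correlation, 0.0)) * cfg.spot_noise_sd
    arrays, channel_samples = [], {}
    for k in range(n_pairs):
        s_red, s_green = matrix.sample_ids[2 * k], matrix.sample_ids[2 * k + 1]
        x_red = matrix.values[:, 2 * k].copy()
        x_green = matrix.values[:, 2 * k + 1].copy()
        spot = rng.normal(0.0, sd_shared, size=matrix.n_probes)
        x_red += spot + rng.normal(0.0, sd_indiv, size=matrix.n_probes)
        x_green += spot + rng.normal(0.0, sd_indiv, size=matrix.n_probes)
        a = (x_red + x_green) / 2.0
        bias = cfg.dye_bias_amplitude * np.sin(a)
        x_red += bias / 2.0
        x_green -= bias / 2.0
        bg_red = 10.0 + np.abs(rng.normal(0.0, 2.0, size=matrix.n_probes))
        bg_green = 10.0 + np.abs(rng.normal(0.0, 2.0, size=matrix.n_probes))
        array_id = f"array{k:03d}"
        arrays.append(TwoColorArray(
            array_id, matrix.probe_ids,
            np.exp2(x_red) + bg_red, np.exp2(x_green) + bg_green,
            bg_red, bg_green))
        channel_samples[(array_id, "red")] = s_red
        channel_samples[(array_id, "green")] = s_green
    return arrays, channel_samples, data
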