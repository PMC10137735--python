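"""Seeded generator of complete synthetic diallel datasets with ground truth.

The generator emulates the study conditions this pipeline targets: 8 inbred
Chinese-cabbage-like parents crossed in a complete diallel with 3 missing
cells (53 hybrids), leaf transcriptomes of ~20k genes × 3 replicates per
parent as negative-binomial counts converted to FPKM, and 10 yield-related
traits whose hybrid values carry planted correlations with specific genes'
parental expression and with the parental transcriptome distance.

Heterosis architecture
----------------------
Each parent carries a latent score u_p.  Planted genes load linearly on it
(FPKM mean ∝ 1 + κ·s·u_p, s = ±1), so across hybrids their mid-parent
expression value (MPV) is collinear with the latent mid-parent score
z = standardized(u_female + u_male).  The target trait's mid-parent
heterosis is built as MPH = mean + sd·(c·z + sqrt(1−c²)·noise) with
c = ρ / att, where the attenuation att = mean |corr(z, realized MPV)| over
planted genes is estimated from the generated expression matrix; the
*measured* planted-gene MPV–MPH correlation is therefore ρ in expectation.
A requested ρ exceeding att is infeasible at the configured noise level and
is rejected.  Non-target traits correlate with the realized parental
Euclidean distance instead (coefficient ``distance_coef``).  Hybrid trait
values follow F1 = MP · MPH_ratio/100, with the ratio-scale MPH moments
taken from the field study the generator emulates, which keeps every trait
value positive as the heterosis formulas require.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import DiallelDesign, complete_design, write_design
from .distance import pairwise_distances, distance_lookup
from .enrichment import AnnotationMap
from .expression import ExpressionMatrix, fpkm_matrix
from .traits import TraitTable


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TraitSpec:
    """Moments defining one trait: parent-value distribution and the
    ratio-scale MPH distribution of the hybrids (percent of mid-parent)."""

    name: str
    parent_mean: float
    parent_sd: float
    mph_mean: float
    mph_sd: float


#: The ten yield-related traits with the field study's parent means/SDs and
#: ratio-scale MPH means; MPH SDs use quarter-range where a range is
#: reported and mean/4 otherwise.
DEFAULT_TRAITS: tuple[TraitSpec, ...] = (
    TraitSpec("PGW", 2.13, 0.96, 192.54, 91.85),
    TraitSpec("NOL", 8.63, 2.50, 115.03, 28.76),
    TraitSpec("LOL", 38.36, 8.95, 117.62, 29.41),
    TraitSpec("WOL", 24.40, 5.91, 127.10, 31.78),
    TraitSpec("LHH", 27.25, 6.58, 109.58, 27.40),
    TraitSpec("LHW", 17.76, 2.31, 95.17, 23.79),
    TraitSpec("HW", 1.39, 0.65, 201.78, 103.91),
    TraitSpec("LNH", 34.92, 4.82, 112.08, 28.02),
    TraitSpec("PW", 54.63, 12.06, 122.90, 30.73),
    TraitSpec("PH", 37.08, 6.91, 106.83, 26.71),
)

DEFAULT_PARENTS = ("A", "B", "C", "D", "E", "F", "G", "H")
DEFAULT_MISSING = (("A", "C"), ("F", "G"), ("G", "A"))


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the emulated study's
    conditions (8 parents, 3 missing crosses, 3 replicates, ~20k genes,
    10 traits)."""

    parents: tuple[str, ...] = DEFAULT_PARENTS
    missing: tuple[tuple[str, str], ...] = DEFAULT_MISSING
    n_genes: int = 20000
    n_replicates: int = 3
    # expression level distribution (log2 FPKM) and NB dispersion
    log2_fpkm_mean: float = 3.0
    log2_fpkm_sd: float = 2.0
    planted_log2_fpkm_mean: float = 4.0
    planted_log2_fpkm_sd: float = 1.0
    dispersion: float = 0.05
    parent_effect_sd: float = 0.35  # log2-scale parent-specific deviation, null genes
    # presence/absence variation: a fraction of null genes is silent (zero
    # expression) in a random subset of parents, as in real transcriptomes;
    # this is what the binary distance measures
    silent_gene_fraction: float = 0.2
    silent_rate: float = 0.3
    gene_length_log_mean: float = float(np.log(1500.0))
    gene_length_log_sd: float = 0.4
    library_size_range: tuple[float, float] = (1.5e7, 2.5e7)
    # traits and heterosis architecture
    traits: tuple[TraitSpec, ...] = DEFAULT_TRAITS
    target_trait: str = "PGW"
    n_planted_positive: int = 100
    n_planted_negative: int = 50
    planted_rho: float = 0.6
    planted_loading: float = 0.4
    distance_coef: float = 0.4
    mph_floor: float = 10.0  # ratio-scale floor keeping trait values positive
    # DEG planting: per-parent fraction of genes shifted by ±deg_effect log2
    deg_fraction: float = 0.02
    deg_effect: float = 2.0
    deg_fc_truth: float = 1.0  # |log2 difference| in true means defining a true DEG
    # annotation
    n_terms: int = 200
    terms_per_gene: float = 1.2
    planted_term_coverage: float = 0.7
    planted_term_background: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.planted_rho < 1.0:
            raise SimulationError(f"planted_rho must lie in (-1, 1), got {self.planted_rho}")
        if not -1.0 < self.distance_coef < 1.0:
            raise SimulationError("distance_coef must lie in (-1, 1)")
        for count in (self.n_genes, self.n_replicates, self.n_terms):
            if count <= 0:
                raise SimulationError("all counts must be positive")
        if self.n_planted_positive + self.n_planted_negative > self.n_genes:
            raise SimulationError("planted gene sets exceed the gene universe")

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Small profile for fast test runs (500 genes, 30+20 planted)."""
        defaults = dict(n_genes=500, n_terms=40, n_planted_positive=30,
                        n_planted_negative=20, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """No planted effects anywhere: responses are pure noise."""
        defaults = dict(n_planted_positive=0, n_planted_negative=0,
                        distance_coef=0.0, deg_fraction=0.0, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    planted: pd.DataFrame           # gene, sign (+1/-1), target_rho
    deg_sets: dict[tuple[str, str], frozenset]  # ordered pair -> true DEG genes
    distance_coef: float
    target_trait: str
    enriched_term: str | None
    attenuation: float | None       # measured-MPV attenuation used for planting
    seed: int


@dataclass
class SimulatedDataset:
    design: DiallelDesign
    expression: ExpressionMatrix
    traits: TraitTable
    annotation: AnnotationMap
    truth: TruthTable
    config: SimulationConfig


def _truncated_normal(rng, mean: float, sd: float, size: int, lower: float) -> np.ndarray:
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset (design, expression, traits, annotation) plus
    its ground truth.  Identical configs and seeds give identical outputs."""
    rng = np.random.default_rng(config.seed)
    design = complete_design(config.parents, config.missing)
    parents = list(config.parents)
    n_parents, n_genes, n_reps = len(parents), config.n_genes, config.n_replicates
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene")

    # planted gene sets (disjoint by construction)
    n_pos, n_neg = config.n_planted_positive, config.n_planted_negative
    planted_idx = rng.choice(n_genes, size=n_pos + n_neg, replace=False)
    pos_idx, neg_idx = planted_idx[:n_pos], planted_idx[n_pos:]
    signs = np.zeros(n_genes)
    signs[pos_idx], signs[neg_idx] = 1.0, -1.0
    is_planted = signs != 0

    # baseline log2 FPKM; planted (pathway-like) genes are highly expressed
    base = rng.normal(config.log2_fpkm_mean, config.log2_fpkm_sd, n_genes)
    base[is_planted] = rng.normal(config.planted_log2_fpkm_mean,
                                  config.planted_log2_fpkm_sd, int(is_planted.sum()))

    # parent latent scores drive planted genes; null genes get independent
    # parent-specific deviations, some shifted further as planted DEGs
    u = rng.normal(0.0, 1.0, n_parents)
    delta = rng.normal(0.0, config.parent_effect_sd, (n_genes, n_parents))
    delta[is_planted] = 0.0
    n_deg = int(round(config.deg_fraction * n_genes))
    null_pool = np.flatnonzero(~is_planted)
    for p in range(n_parents):
        if n_deg == 0 or null_pool.size == 0:
            break
        chosen = rng.choice(null_pool, size=min(n_deg, null_pool.size), replace=False)
        delta[chosen, p] += rng.choice([-1.0, 1.0], size=chosen.size) * config.deg_effect

    det_fpkm = np.exp2(base[:, None] + delta)
    loading = np.clip(1.0 + config.planted_loading * signs[is_planted, None] * u[None, :], 0.05, None)
    det_fpkm[is_planted] = np.exp2(base[is_planted, None]) * loading
    # presence/absence variation on a subset of null genes
    variable = (rng.random(n_genes) < config.silent_gene_fraction) & ~is_planted
    silent = variable[:, None] & (rng.random((n_genes, n_parents)) < config.silent_rate)
    det_fpkm[silent] = 0.0
    with np.errstate(divide="ignore"):
        det_log2 = np.log2(det_fpkm)

    # NB counts -> FPKM
    lengths = np.clip(rng.lognormal(config.gene_length_log_mean,
                                    config.gene_length_log_sd, n_genes), 200, 20000).round()
    lib = rng.uniform(*config.library_size_range, n_parents * n_reps)
    sample_ids = [f"{p}_r{j + 1}" for p in parents for j in range(n_reps)]
    parent_of_sample = np.repeat(np.arange(n_parents), n_reps)
    mu = det_fpkm[:, parent_of_sample] * lengths[:, None] * lib[None, :] / 1e9
    shape = 1.0 / config.dispersion
    counts = rng.poisson(rng.gamma(shape, mu / shape))
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    lengths_series = pd.Series(lengths, index=genes, name="length_bp")
    fpkm_df = fpkm_matrix(counts_df, lengths_series)
    sample_map = pd.DataFrame({"parent": [parents[i] for i in parent_of_sample],
                               "replicate": np.tile(np.arange(1, n_reps + 1), n_parents)},
                              index=pd.Index(sample_ids, name="sample"))
    expression = ExpressionMatrix(fpkm=fpkm_df, sample_map=sample_map, counts=counts_df,
                                  gene_lengths=lengths_series,
                                  library_sizes=pd.Series(counts.sum(axis=0), index=sample_ids))

    # hybrid-level structure: latent mid-parent score and realized distances
    profiles = expression.parent_profiles()
    hybrids = [c.hybrid for c in design.crosses]
    parent_pos = {p: i for i, p in enumerate(parents)}
    f_idx = np.array([parent_pos[c.female] for c in design.crosses])
    m_idx = np.array([parent_pos[c.male] for c in design.crosses])
    n_hyb = len(hybrids)

    def standardize(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std()

    dist = pairwise_distances(profiles, transform="identity", tau=0.0)
    lookup = distance_lookup(dist)
    d_vec = np.array([lookup[c.unordered_pair]["euclidean"] for c in design.crosses])
    z_dist = standardize(d_vec)

    attenuation: float | None = None
    c_signal = 0.0
    z_latent = np.zeros(n_hyb)
    if is_planted.any():
        z_latent = standardize(u[f_idx] + u[m_idx])
        mpv = (profiles.to_numpy()[:, f_idx] + profiles.to_numpy()[:, m_idx]) / 2.0
        planted_rows = np.flatnonzero(is_planted)
        cors = []
        for g in planted_rows:
            v = mpv[g]
            if v.std() == 0:
                continue
            cors.append(signs[g] * np.corrcoef(z_latent, v)[0, 1])
        attenuation = float(np.mean(cors))
        c_signal = config.planted_rho / attenuation if attenuation > 0 else np.inf
        if not 0.0 <= c_signal < 1.0:
            raise SimulationError(
                f"target correlation rho={config.planted_rho} is infeasible: measurement "
                f"attenuation of planted mid-parent expression is {attenuation:.3f}, so the "
                f"noise-free signal would need coefficient {c_signal:.3f} >= 1; lower rho, "
                f"raise planted_loading, or reduce dispersion")

    # traits: parents truncated-normal, hybrids via ratio-scale MPH
    trait_names = [t.name for t in config.traits]
    if config.target_trait not in trait_names:
        raise SimulationError(f"target trait {config.target_trait!r} not in traits")
    values = pd.DataFrame(index=pd.Index(list(parents) + hybrids, name="entity"),
                          columns=trait_names, dtype=float)
    for spec in config.traits:
        parent_vals = _truncated_normal(rng, spec.parent_mean, spec.parent_sd,
                                        n_parents, 0.1 * spec.parent_mean)
        noise = rng.normal(0.0, 1.0, n_hyb)
        if spec.name == config.target_trait and is_planted.any():
            signal = c_signal * z_latent + np.sqrt(1.0 - c_signal ** 2) * noise
        elif config.distance_coef != 0.0:
            gamma = config.distance_coef
            signal = gamma * z_dist + np.sqrt(1.0 - gamma ** 2) * noise
        else:
            signal = noise
        mph_ratio = np.clip(spec.mph_mean + spec.mph_sd * signal, config.mph_floor, None)
        mp = (parent_vals[f_idx] + parent_vals[m_idx]) / 2.0
        values.loc[parents, spec.name] = parent_vals
        values.loc[hybrids, spec.name] = mp * mph_ratio / 100.0
    traits = TraitTable(values)

    # annotation: random terms plus one term enriched in the positive planted set
    term_ids = [f"TERM{i:03d}" for i in range(1, config.n_terms + 1)]
    n_assign = rng.poisson(config.terms_per_gene, n_genes)
    terms: dict[str, set[str]] = {t: set() for t in term_ids}
    for g, k in enumerate(n_assign):
        for t in rng.choice(config.n_terms, size=min(k, config.n_terms), replace=False):
            terms[term_ids[t]].add(genes[g])
    enriched_term: str | None = None
    if n_pos > 0:
        members = {genes[g] for g in pos_idx if rng.random() < config.planted_term_coverage}
        members |= {genes[g] for g in range(n_genes)
                    if rng.random() < config.planted_term_background}
        if members:
            enriched_term = "TERM000"
            terms[enriched_term] = members
    terms = {t: m for t, m in terms.items() if m}
    annotation = AnnotationMap(terms=terms, universe=set(genes))

    # ground truth
    planted_df = pd.DataFrame({
        "gene": genes[planted_idx],
        "sign": signs[planted_idx].astype(int),
        "target_rho": config.planted_rho,
    }).sort_values("gene").reset_index(drop=True)
    deg_sets: dict[tuple[str, str], frozenset] = {}
    for female, male in design.ordered_pairs():
        key = tuple(sorted((female, male)))
        if key not in deg_sets:
            with np.errstate(invalid="ignore"):
                # silent-vs-silent yields NaN (no true difference); silent vs
                # expressed yields inf (always a true DEG)
                diff = np.abs(det_log2[:, parent_pos[key[0]]]
                              - det_log2[:, parent_pos[key[1]]])
            deg_sets[key] = frozenset(genes[diff > config.deg_fc_truth])
        deg_sets[(female, male)] = deg_sets[key]
    truth = TruthTable(planted=planted_df, deg_sets=deg_sets,
                       distance_coef=config.distance_coef, target_trait=config.target_trait,
                       enriched_term=enriched_term, attenuation=attenuation, seed=config.seed)
    return SimulatedDataset(design=design, expression=expression, traits=traits,
                            annotation=annotation, truth=truth, config=config)


def simulate_planted_series(n_genes: int, n_planted: int, rho: float, n: int,
                            seed: int) -> tuple[pd.DataFrame, pd.DataFrame, pd.Index]:
    """Exchangeable predictor series with a planted correlation.

    Generates a response of *n* independent observations and *n_genes*
    predictor series; the first *n_planted* are built as
    x = ρ·ỹ + sqrt(1−ρ²)·η (linear-Gaussian), so their expected correlation
    with the response is ρ; the rest are independent noise.  This isolates
    the correlation screen's operating characteristics (power and FDR at a
    given n) from the parent-sharing dependence of a real diallel, where
    hybrid-level observations are not exchangeable.

    Returns (predictors gene × observation, responses observation × 1,
    planted gene index).
    """
    if not -1.0 < rho < 1.0:
        raise SimulationError(f"rho must lie in (-1, 1), got {rho}")
    if n_planted > n_genes:
        raise SimulationError("more planted genes than genes")
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, 1.0, n)
    y_std = (y - y.mean()) / y.std()
    x = rng.normal(0.0, 1.0, (n_genes, n))
    x[:n_planted] = rho * y_std + np.sqrt(1.0 - rho ** 2) * x[:n_planted]
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene")
    obs = [f"h{i:02d}" for i in range(n)]
    predictors = pd.DataFrame(x, index=genes, columns=obs)
    responses = pd.DataFrame({"MPH": y}, index=pd.Index(obs))
    return predictors, responses, genes[:n_planted]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict:
    """Write all tables in the pipeline's TSV dialects plus a manifest with
    the config, seed and file hashes.  Returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_design(dataset.design, outdir / "design.tsv")
    dataset.traits.write_wide(outdir / "traits.tsv")
    dataset.expression.write(outdir / "fpkm.tsv", outdir / "sample_map.tsv")
    if dataset.expression.counts is not None:
        dataset.expression.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene")
        dataset.expression.gene_lengths.to_csv(outdir / "gene_lengths.tsv", sep="\t",
                                               index_label="gene")
    dataset.annotation.write(outdir / "annotation.tsv")
    dataset.truth.planted.to_csv(outdir / "truth_planted.tsv", sep="\t", index=False)
    config_dict = dataclasses.asdict(dataset.config)
    config_dict["traits"] = [dataclasses.asdict(t) for t in dataset.config.traits]
    files = sorted(p.name for p in outdir.glob("*.tsv"))
    manifest = {
        "seed": dataset.config.seed,
        "config": config_dict,
        "attenuation": dataset.truth.attenuation,
        "enriched_term": dataset.truth.enriched_term,
        "hashes": {name: _sha256(outdir / name) for name in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
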