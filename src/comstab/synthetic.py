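"""Synthetic community, environment and coordinate generators with known
ground truth.

The community generator emulates the structure of a two-soil-type mangrove
survey: two groups of samples with distinct dominant taxon classes (hence
distinct alpha diversity), group-specific blocks of positively and
negatively rank-correlated taxa (hence group-specific network cohesion), and
overdispersed sequencing counts. Rank correlation is injected through a
Gaussian copula — block taxa share a latent factor, and each taxon's normal
score is pushed through its own negative-binomial quantile function — so the
marginal count distributions are untouched while the Spearman correlation,
which is what co-occurrence networks measure, is controlled. The latent
equicorrelation r is chosen as r = 2 sin(pi * rho_s / 6) so the copula's
Spearman correlation equals the requested rho_s.

Negative blocks give half their taxa a positive factor loading and half a
negative one: cross-sign pairs are negatively correlated at the requested
magnitude (a block of more than two taxa cannot be mutually negatively
equicorrelated, since that matrix is not positive definite).

The environment generator draws latent scores along a user-specified DAG
(standard-normal exogenous latents; endogenous latents are path-weighted
sums of their parents plus just enough Gaussian noise to stay unit
variance), then emits manifest variables as loading * latent + noise. The
hidden latent scores are returned alongside the observed matrix so that
path-model recovery can be tested against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import EnvMatrix, FeatureTable, SampleMetadata

__all__ = [
    "CorrelationBlock",
    "CommunitySpec",
    "PathTruth",
    "generate_community",
    "generate_env",
    "generate_coordinates",
    "default_community_spec",
    "default_path_truth",
    "default_env_variables",
    "default_site_centers",
    "simulate_study",
]


@dataclass(frozen=True)
class CorrelationBlock:
    """A set of taxa sharing a latent factor.

    ``group`` restricts the block to one sample group (None = all groups);
    ``sign`` +1 gives uniformly positive pairwise correlation, -1 gives
    alternating loadings (negative cross-sign pairs).
    """

    taxa: tuple[int, ...]
    rho: float
    sign: int = 1
    group: str | None = None

    def __post_init__(self):
        if not (0 < self.rho < 1):
            raise ValueError("block |rho| must lie in (0, 1)")
        if self.sign not in (-1, 1):
            raise ValueError("block sign must be +1 or -1")
        if len(self.taxa) < 2:
            raise ValueError("block needs at least 2 taxa")


@dataclass(frozen=True)
class CommunitySpec:
    n_samples_per_group: int
    n_taxa: int
    group_labels: tuple[str, ...]
    dominance_profile: dict[str, tuple[float, ...]]
    correlation_blocks: tuple[CorrelationBlock, ...]
    sequencing_depth: int = 10_000
    dispersion: float = 5.0
    depth_variation_sigma: float = 0.25   # log-sd of per-sample library size
    count_model: str = "negative_binomial"  # or "multinomial"
    seed: int = 0

    def __post_init__(self):
        labels = tuple(self.group_labels)
        object.__setattr__(self, "group_labels", labels)
        object.__setattr__(self, "correlation_blocks", tuple(self.correlation_blocks))
        object.__setattr__(self, "dominance_profile",
                           {g: tuple(v) for g, v in self.dominance_profile.items()})
        if set(self.dominance_profile) != set(labels):
            raise ValueError("dominance_profile must have one vector per group")
        sizes = {len(v) for v in self.dominance_profile.values()}
        if len(sizes) != 1:
            raise ValueError("dominance profiles must share the number of classes")
        used: set[int] = set()
        for blk in self.correlation_blocks:
            if blk.group is not None and blk.group not in labels:
                raise ValueError(f"block group {blk.group!r} not in group labels")
            overlap = used & set(blk.taxa)
            if overlap:
                raise ValueError(f"correlation blocks overlap on taxa {sorted(overlap)}")
            used |= set(blk.taxa)
            if max(blk.taxa) >= self.n_taxa:
                raise ValueError("block taxon index out of range")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def n_classes(self) -> int:
        return len(next(iter(self.dominance_profile.values())))


@dataclass(frozen=True)
class PathTruth:
    """Ground-truth latent path model for the environment generator."""

    latent_names: tuple[str, ...]
    path_matrix: np.ndarray           # strictly lower triangular coefficients
    loadings: dict[str, float] = field(default_factory=dict)   # per-latent loading
    noise_sd: float | None = None     # None: sqrt(1 - loading^2), unit-variance manifests

    def __post_init__(self):
        pm = np.asarray(self.path_matrix, dtype=float)
        L = len(self.latent_names)
        if pm.shape != (L, L) or np.any(np.triu(pm) != 0):
            raise ValueError("path matrix must be strictly lower triangular")
        for lat, lo in self.loadings.items():
            if not (0 < abs(lo) <= 1):
                raise ValueError(f"loading for {lat!r} must lie in (0, 1]")
        object.__setattr__(self, "path_matrix", pm)
        object.__setattr__(self, "latent_names", tuple(self.latent_names))


# ---------------------------------------------------------------------------
# community generation


def _class_assignment(n_taxa: int, n_classes: int) -> np.ndarray:
    """Contiguous, near-equal split of taxa into classes."""
    bounds = np.linspace(0, n_taxa, n_classes + 1).astype(int)
    out = np.empty(n_taxa, dtype=int)
    for c in range(n_classes):
        out[bounds[c]:bounds[c + 1]] = c
    return out


def _latent_scores_for_group(rng, n, m, blocks):
    """Standard-normal matrix with block equicorrelation injected."""
    z = rng.standard_normal((n, m))
    for blk in blocks:
        r = 2.0 * math.sin(math.pi * blk.rho / 6.0)  # Spearman -> latent Pearson
        f = rng.standard_normal(n)
        signs = np.ones(len(blk.taxa))
        if blk.sign < 0:
            signs[1::2] = -1.0
        for s, t in zip(signs, blk.taxa):
            z[:, t] = s * math.sqrt(r) * f + math.sqrt(1.0 - r) * rng.standard_normal(n)
    return z


def generate_community(spec: CommunitySpec):
    """Draw a (FeatureTable, SampleMetadata) pair from a community spec.

    Deterministic given ``spec.seed``. Metadata sites are assigned round-robin
    within each group from the default site table; coordinates are filled by
    :func:`generate_coordinates`.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_taxa
    classes = _class_assignment(m, spec.n_classes)

    sample_ids, groups, tables = [], [], []
    for g in spec.group_labels:
        weights = np.asarray(spec.dominance_profile[g], dtype=float)
        weights = weights / weights.sum()
        # per-taxon log-normal base abundance, rescaled so each taxon class
        # carries its group's dominance weight
        base = rng.lognormal(mean=0.0, sigma=1.0, size=m)
        p = np.empty(m)
        for c in range(spec.n_classes):
            mask = classes == c
            p[mask] = base[mask] / base[mask].sum() * weights[c]
        p = p / p.sum()

        n = spec.n_samples_per_group
        blocks = [blk for blk in spec.correlation_blocks if blk.group in (None, g)]
        z = _latent_scores_for_group(rng, n, m, blocks)
        u = stats.norm.cdf(z)
        # shared per-sample library-size factor: sequencing effort varies
        # across libraries, which couples all taxa of a sample weakly and
        # positively, as in real amplicon data
        sig = spec.depth_variation_sigma
        libsize = np.exp(rng.normal(0.0, sig, n) - sig ** 2 / 2.0) if sig > 0 else np.ones(n)
        mu = (spec.sequencing_depth * libsize)[:, None] * p[None, :]
        k = spec.dispersion
        if spec.count_model == "negative_binomial":
            counts = stats.nbinom.ppf(u, k, k / (k + mu)).astype(float)
        elif spec.count_model == "multinomial":
            # copula-correlated gamma weights, multinomial-resampled to depth
            gamma_w = stats.gamma.ppf(u, a=k, scale=mu / k)
            gamma_w = np.where(gamma_w <= 0, 1e-12, gamma_w)
            probs = gamma_w / gamma_w.sum(axis=1, keepdims=True)
            depths = np.round(spec.sequencing_depth * libsize).astype(int)
            counts = np.array([rng.multinomial(d, pr) for d, pr in zip(depths, probs)], dtype=float)
        else:
            raise ValueError(f"unknown count model {spec.count_model!r}")
        tables.append(counts)
        sample_ids += [f"{g}_{i + 1:03d}" for i in range(n)]
        groups += [g] * n

    values = np.vstack(tables)
    taxon_ids = tuple(f"OTU_{classes[t]}_{t:04d}" for t in range(m))
    ft = FeatureTable(tuple(sample_ids), taxon_ids, values, mode="counts")

    site_table = default_site_centers()
    centers = {s: (lat, lon) for s, (lat, lon, _) in site_table.items()}
    sites = []
    per_group_counter: dict[str, int] = {}
    for k, g in enumerate(groups):
        group_sites = [s for s, (lat, lon, soil) in site_table.items() if soil == g]
        if not group_sites:
            # groups outside the default soil types get one synthetic site
            # each, spaced 1 degree apart along the equator
            group_sites = [f"{g}_site"]
            centers.setdefault(f"{g}_site", (0.0, float(spec.group_labels.index(g))))
        i = per_group_counter.get(g, 0)
        sites.append(group_sites[i % len(group_sites)])
        per_group_counter[g] = i + 1
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": sample_ids, "site": sites, "soil_type": groups,
        "latitude": 0.0, "longitude": 0.0,
    }))
    meta = generate_coordinates(meta, centers, jitter_m=200.0, seed=spec.seed)
    return ft, meta


def generate_coordinates(meta: SampleMetadata, site_centers: dict, jitter_m: float,
                         seed: int = 0) -> SampleMetadata:
    """Place each sample at its site center plus uniform jitter of at most
    ``jitter_m`` meters in each axis. Deterministic given seed."""
    rng = np.random.default_rng(seed)
    lats, lons = [], []
    for site in meta.column("site"):
        if site not in site_centers:
            raise ValueError(f"unknown site label {site!r}")
        lat0, lon0 = site_centers[site]
        dlat = rng.uniform(-jitter_m, jitter_m) / 111_320.0
        dlon = rng.uniform(-jitter_m, jitter_m) / (111_320.0 * math.cos(math.radians(lat0)))
        lats.append(lat0 + dlat)
        lons.append(lon0 + dlon)
    df = meta.frame.copy()
    df["latitude"] = lats
    df["longitude"] = lons
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# environment generation


def _implied_latent_cov(pm: np.ndarray) -> np.ndarray:
    """Covariance of unit-variance latents under the recursive path model."""
    L = pm.shape[0]
    cov = np.eye(L)
    for i in range(L):
        parents = np.flatnonzero(pm[i])
        if parents.size == 0:
            continue
        beta = pm[i, parents]
        explained = beta @ cov[np.ix_(parents, parents)] @ beta
        if explained >= 1.0:
            raise ValueError(f"path coefficients into latent {i} imply variance >= 1")
        for j in range(L):
            if j != i:
                cov[i, j] = cov[j, i] = beta @ cov[parents, j]
    return cov


def generate_env(meta: SampleMetadata, truth: PathTruth, manifest_map: dict[str, list[str]],
                 seed: int = 0, manifest_locations: dict[str, tuple[float, float]] | None = None):
    """Generate (EnvMatrix, latent scores DataFrame) from a latent path model.

    Latents are unit variance: endogenous residual noise is sized as
    sqrt(1 - explained variance), so a path coefficient equals the implied
    latent correlation in the single-parent case. ``manifest_locations``
    optionally maps a manifest name to (mean, scale) for unit-ful output
    (an affine map, so correlations are unchanged).
    """
    names = truth.latent_names
    missing = [lat for lat in names if not manifest_map.get(lat)]
    if missing:
        raise ValueError(f"manifest_map must assign at least one variable per latent: {missing}")
    pm = truth.path_matrix
    cov = _implied_latent_cov(pm)  # validates feasibility
    rng = np.random.default_rng(seed)
    n = len(meta.sample_ids)
    L = len(names)
    scores = np.empty((n, L))
    for i in range(L):
        parents = np.flatnonzero(pm[i])
        if parents.size == 0:
            scores[:, i] = rng.standard_normal(n)
        else:
            beta = pm[i, parents]
            lin = scores[:, parents] @ beta
            resid_var = max(1.0 - float(beta @ cov[np.ix_(parents, parents)] @ beta), 1e-12)
            scores[:, i] = lin + math.sqrt(resid_var) * rng.standard_normal(n)

    cols, data = [], []
    for i, lat in enumerate(names):
        loading = truth.loadings.get(lat, 0.8)
        noise_sd = truth.noise_sd if truth.noise_sd is not None else math.sqrt(max(1.0 - loading ** 2, 0.0))
        for mv in manifest_map[lat]:
            x = loading * scores[:, i] + noise_sd * rng.standard_normal(n)
            if manifest_locations and mv in manifest_locations:
                mean, scale = manifest_locations[mv]
                x = mean + scale * x
            cols.append(mv)
            data.append(x)
    env = EnvMatrix(meta.sample_ids, tuple(cols), np.column_stack(data))
    latent_scores = pd.DataFrame(scores, index=list(meta.sample_ids), columns=list(names))
    return env, latent_scores


# ---------------------------------------------------------------------------
# default study conditions


def default_site_centers() -> dict[str, tuple[float, float, str]]:
    """Three mangrove sampling sites on the southern China coast:
    site -> (latitude, longitude, soil type)."""
    return {
        "LZ": (21.57, 109.75, "clay_loam"),
        "SK": (19.95, 110.56, "sandy"),
        "ZZ": (23.92, 117.41, "sandy"),
    }


def default_community_spec(seed: int = 0) -> CommunitySpec:
    """Two soil-type groups, five taxon classes, 30 samples per group.

    The clay-loam group concentrates over half its abundance on one taxon
    class (strong single-class dominance, hence lower alpha diversity) and is
    cooperative: three positive blocks span its dominant and mid-abundance
    classes, with only a small competitive block. The sandy group is more
    even, with one weaker positive block and a substantial competitive
    (alternating-sign) block — mirroring communities where negative
    associations are relatively more common — which both raises the share of
    its network that collapses under node removal and keeps its cohesion
    below the clay-loam group's.
    """
    return CommunitySpec(
        n_samples_per_group=30,
        n_taxa=60,
        group_labels=("clay_loam", "sandy"),
        dominance_profile={
            "clay_loam": (0.55, 0.20, 0.10, 0.09, 0.06),
            "sandy": (0.25, 0.23, 0.20, 0.17, 0.15),
        },
        correlation_blocks=(
            CorrelationBlock(taxa=tuple(range(0, 12)), rho=0.75, sign=1, group="clay_loam"),
            CorrelationBlock(taxa=tuple(range(12, 24)), rho=0.75, sign=1, group="clay_loam"),
            CorrelationBlock(taxa=tuple(range(24, 36)), rho=0.70, sign=1, group="clay_loam"),
            CorrelationBlock(taxa=tuple(range(36, 42)), rho=0.60, sign=-1, group="clay_loam"),
            CorrelationBlock(taxa=tuple(range(42, 48)), rho=0.60, sign=1, group="sandy"),
            CorrelationBlock(taxa=tuple(range(48, 58)), rho=0.75, sign=-1, group="sandy"),
        ),
        sequencing_depth=10_000,
        dispersion=5.0,
        seed=seed,
    )


def default_env_variables() -> dict[str, list[str]]:
    """Manifest blocks for the two environmental latents."""
    return {
        "soil_properties": ["temperature", "salinity", "pH", "DO", "ORP", "clay", "silt", "sand"],
        "nutrients": ["TOC", "TC", "TIC", "TS", "TN", "TP", "PO4", "SO4", "NO2_N", "NO3_N", "NH4_N"],
    }


def default_manifest_locations() -> dict[str, tuple[float, float]]:
    """Plausible (mean, scale) per environmental variable for unit-ful output."""
    return {
        "temperature": (25.0, 3.0), "salinity": (20.0, 5.0), "pH": (7.0, 0.5),
        "DO": (5.0, 1.0), "ORP": (100.0, 50.0),
        "clay": (30.0, 8.0), "silt": (40.0, 8.0), "sand": (30.0, 10.0),
        "TOC": (15.0, 4.0), "TC": (20.0, 5.0), "TIC": (5.0, 1.5), "TS": (2.0, 0.6),
        "TN": (1.5, 0.4), "TP": (0.8, 0.2), "PO4": (0.3, 0.1), "SO4": (1.5, 0.5),
        "NO2_N": (0.05, 0.02), "NO3_N": (0.5, 0.15), "NH4_N": (0.8, 0.25),
    }


def default_path_truth() -> PathTruth:
    """Soil properties drive nutrients (path 0.5); both latents load 0.8."""
    return PathTruth(
        latent_names=("soil_properties", "nutrients"),
        path_matrix=np.array([[0.0, 0.0], [0.5, 0.0]]),
        loadings={"soil_properties": 0.8, "nutrients": 0.8},
    )


def simulate_study(seed: int = 0):
    """Full synthetic study: community counts, metadata with coordinates, and
    an environmental matrix. Returns (FeatureTable, SampleMetadata, EnvMatrix)."""
    spec = default_community_spec(seed=seed)
    ft, meta = generate_community(spec)
    env, _ = generate_env(meta, default_path_truth(), default_env_variables(),
                          seed=seed + 1, manifest_locations=default_manifest_locations())
    return ft, meta, env
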