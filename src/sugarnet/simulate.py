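"""Synthetic expression data with planted co-expression structure.

Emulates a two-genotype (R: nitrogen-responsive, NR: non-responsive) x two
nitrogen level (10 / 270 mg N per kg sand) x four leaf segment (B0, B, M, P)
factorial with replicated samples, on a variance-stabilized expression scale.
Co-expression modules are planted as noisy linear readouts of a latent
per-module profile, so that network construction, clustering, eigengene-trait
screening and enrichment can all be verified against known ground truth.

Model per planted module m with latent profile :math:`L_m` (standardized to
mean 0, SD 1 across samples):

.. math:: x_{gs} = \\mu_g + a_g L_{ms} + \\varepsilon_{gs}

with gene loadings :math:`a_g \\sim U(0.7, 1)` and noise SD chosen as
:math:`\\sigma_g = a_g \\sqrt{1/\\rho - 1}` so the expected pairwise Pearson
correlation between any two member genes equals the requested
``within_module_cor`` :math:`\\rho` exactly, independent of the loadings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("R", "NR")
NITROGEN_LEVELS = (10, 270)
SEGMENTS = ("B0", "B", "M", "P")

DRIVERS = ("genotype", "nitrogen", "segment", "interaction", "trait_only", "noise")

#: Module label used in the ground truth for unplanted (noise) genes.
NOISE_MODULE = 0


@dataclass(frozen=True)
class PlantedModuleSpec:
    """Specification of one planted co-expression module.

    Parameters
    ----------
    module_id
        Positive integer identifying the module in the ground truth.
    n_genes
        Number of member genes (>= 2).
    driver
        Which experimental factor shifts the latent profile: one of
        ``genotype``, ``nitrogen``, ``segment``, ``interaction`` (genotype x
        nitrogen product), ``trait_only`` (no factor shift; exists to be
        coupled to a trait) or ``noise``.
    effect_size
        Shift of the latent profile between factor levels, in SD units of the
        latent's sample-to-sample noise.
    within_module_cor
        Target expected pairwise Pearson correlation between member genes,
        in (0, 1].
    signed
        If True, gene loadings get a random sign, producing anti-correlated
        members (the network keeps edges by absolute correlation, so such
        modules must be generatable); default all-positive.
    """

    module_id: int
    n_genes: int
    driver: str
    effect_size: float = 2.0
    within_module_cor: float = 0.95
    signed: bool = False

    def __post_init__(self) -> None:
        if self.module_id <= 0:
            raise ValueError("module_id must be a positive integer")
        if self.n_genes < 2:
            raise ValueError("a planted module needs n_genes >= 2")
        if self.driver not in DRIVERS:
            raise ValueError(f"unknown driver {self.driver!r}; expected one of {DRIVERS}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 < self.within_module_cor <= 1.0:
            raise ValueError("within_module_cor must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic expression matrix.

    ``gene_to_module`` maps every gene to its planted module id
    (``NOISE_MODULE`` = 0 for unplanted genes); ``latents`` holds the
    standardized latent profile of each module (modules x samples);
    ``loadings`` the per-gene loading on its module latent;
    ``differential_genes`` the genes truly responsive to nitrogen in each
    within-genotype, within-segment contrast; ``planted_terms`` records
    annotation terms planted into modules by :func:`generate_annotations`.
    """

    gene_to_module: dict[str, int]
    latents: pd.DataFrame
    module_specs: list[PlantedModuleSpec]
    loadings: dict[str, float]
    differential_genes: dict[str, set[str]] = field(default_factory=dict)
    planted_terms: dict[int, str] = field(default_factory=dict)

    def module_members(self, module_id: int) -> list[str]:
        return [g for g, m in self.gene_to_module.items() if m == module_id]

    @property
    def genes(self) -> list[str]:
        return list(self.gene_to_module)


def generate_design(n_replicates: int = 3, seed: int = 0) -> pd.DataFrame:
    """Full factorial genotype x nitrogen x leaf-segment design.

    Three replicates give the study's 2 x 2 x 4 x 3 = 48 samples. ``seed`` is
    accepted for interface uniformity; the design itself is deterministic.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = [
        {
            "sample_id": f"{g}_{n}_{s}_r{r}",
            "genotype": g,
            "nitrogen": n,
            "segment": s,
            "replicate": r,
        }
        for g, n, s, r in itertools.product(
            GENOTYPES, NITROGEN_LEVELS, SEGMENTS, range(1, n_replicates + 1)
        )
    ]
    design = pd.DataFrame(rows)
    if design["sample_id"].duplicated().any():
        raise AssertionError("sample ids must be unique")
    return design


def _driver_code(design: pd.DataFrame, driver: str) -> np.ndarray:
    """Centered contrast coding of a driver; group means differ by 1."""
    g = np.where(design["genotype"].to_numpy() == "R", 0.5, -0.5)
    n = np.where(design["nitrogen"].to_numpy() == NITROGEN_LEVELS[1], 0.5, -0.5)
    if driver == "genotype":
        return g
    if driver == "nitrogen":
        return n
    if driver == "segment":
        idx = np.array([SEGMENTS.index(s) for s in design["segment"]], dtype=float)
        return (idx - 1.5) / 3.0  # extreme segments (B0 vs P) differ by 1
    if driver == "interaction":
        return 2.0 * g * n  # +-0.5; same-sign (R,270)/(NR,10) vs the rest
    return np.zeros(len(design))


def generate_expression(
    design: pd.DataFrame,
    modules: list[PlantedModuleSpec],
    n_noise_genes: int = 200,
    noise_sd: float = 1.0,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a genes x samples expression matrix with planted modules.

    Returns the matrix (float, NaN marks injected missing values) and the
    :class:`SyntheticTruth`. Deterministic given ``seed``.
    """
    if len(design) == 0:
        raise ValueError("design table is empty")
    if not modules and n_noise_genes == 0:
        raise ValueError("nothing to simulate: no modules and no noise genes")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    ids = [s.module_id for s in modules]
    if len(set(ids)) != len(ids):
        raise ValueError("module_ids must be unique")

    rng = np.random.default_rng(seed)
    n_samples = len(design)
    sample_ids = design["sample_id"].tolist()

    gene_to_module: dict[str, int] = {}
    loadings: dict[str, float] = {}
    latent_rows = {}
    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []
    counter = 0

    for spec in modules:
        code = _driver_code(design, spec.driver)
        raw = spec.effect_size * code + rng.standard_normal(n_samples)
        latent = (raw - raw.mean()) / raw.std(ddof=0)
        latent_rows[spec.module_id] = latent

        a = rng.uniform(0.7, 1.0, size=spec.n_genes)
        if spec.signed:
            a *= rng.choice([-1.0, 1.0], size=spec.n_genes)
        # noise SD per gene makes expected pairwise r equal within_module_cor
        sigma = np.abs(a) * np.sqrt(1.0 / spec.within_module_cor - 1.0)
        mu = rng.uniform(4.0, 12.0, size=spec.n_genes)
        block = (
            mu[:, None]
            + a[:, None] * latent[None, :]
            + rng.standard_normal((spec.n_genes, n_samples)) * sigma[:, None]
        )
        for k in range(spec.n_genes):
            gid = f"tg{counter:06d}"
            counter += 1
            gene_ids.append(gid)
            gene_to_module[gid] = spec.module_id
            loadings[gid] = float(a[k])
        blocks.append(block)

    if n_noise_genes:
        mu = rng.uniform(4.0, 12.0, size=n_noise_genes)
        block = mu[:, None] + rng.standard_normal((n_noise_genes, n_samples)) * noise_sd
        for _ in range(n_noise_genes):
            gid = f"tg{counter:06d}"
            counter += 1
            gene_ids.append(gid)
            gene_to_module[gid] = NOISE_MODULE
            loadings[gid] = 0.0
        blocks.append(block)

    values = np.vstack(blocks)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = np.where(mask, np.nan, values)

    X = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    latents = pd.DataFrame(latent_rows, index=sample_ids).T
    latents.index.name = "module_id"

    truth = SyntheticTruth(
        gene_to_module=gene_to_module,
        latents=latents,
        module_specs=list(modules),
        loadings=loadings,
    )
    truth.differential_genes = _true_differentials(truth)
    return X, truth


def _true_differentials(truth: SyntheticTruth) -> dict[str, set[str]]:
    """Genes truly nitrogen-responsive within each genotype x segment contrast."""
    responsive = {
        s.module_id
        for s in truth.module_specs
        if s.driver in ("nitrogen", "interaction") and s.effect_size > 0
    }
    genes = {g for g, m in truth.gene_to_module.items() if m in responsive}
    out = {}
    for g, s in itertools.product(GENOTYPES, SEGMENTS):
        out[f"{g}-{s}-10 vs {g}-{s}-270"] = set(genes)
    return out


def attenuation_noise_sd(loading: float, target_cor: float) -> float:
    """Trait noise SD giving population correlation ``target_cor`` with a
    unit-variance latent loaded at ``loading``: cor = lambda/sqrt(lambda^2+sigma^2)."""
    if not 0.0 < target_cor <= 1.0:
        raise ValueError("target_cor must lie in (0, 1]")
    return abs(loading) * np.sqrt(1.0 / target_cor**2 - 1.0)


TRAIT_NAMES = (
    "genotype",
    "nitrogen",
    "total_chlorophyll",
    "chlorophyll_a",
    "chlorophyll_b",
    "rubisco",
    "pepcase",
)
ASSAY_TRAITS = TRAIT_NAMES[2:]


def default_trait_loadings(modules: list[PlantedModuleSpec]) -> pd.DataFrame:
    """Unit loadings mapping the five assay traits onto the trait-couplable
    modules (drivers ``nitrogen``, ``trait_only``, ``interaction``) in turn."""
    coupled = [s.module_id for s in modules if s.driver in ("nitrogen", "trait_only", "interaction")]
    L = pd.DataFrame(
        0.0, index=list(ASSAY_TRAITS), columns=[s.module_id for s in modules]
    )
    if coupled:
        for i, trait in enumerate(ASSAY_TRAITS):
            L.loc[trait, coupled[i % len(coupled)]] = 1.0
    return L


def generate_traits(
    design: pd.DataFrame,
    truth: SyntheticTruth,
    loadings: pd.DataFrame | None = None,
    trait_noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample trait table: binary genotype/nitrogen plus five assay traits
    (chlorophylls, Rubisco, PEPCase) generated as linear functions of module
    latents plus Gaussian noise.

    ``loadings`` is a traits x modules matrix (columns must match the planted
    module ids); defaults to :func:`default_trait_loadings`.
    """
    if loadings is None:
        loadings = default_trait_loadings(truth.module_specs)
    planted_ids = {s.module_id for s in truth.module_specs}
    if set(loadings.columns) != planted_ids:
        raise ValueError(
            f"loadings columns {sorted(loadings.columns)} do not match planted "
            f"modules {sorted(planted_ids)}"
        )
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=design["sample_id"].tolist())
    out.index.name = "sample_id"
    out["genotype"] = (design["genotype"].to_numpy() == "R").astype(float)
    out["nitrogen"] = (design["nitrogen"].to_numpy() == NITROGEN_LEVELS[1]).astype(float)
    if len(truth.latents):
        lat = truth.latents.loc[:, design["sample_id"]].to_numpy()
    else:
        lat = np.zeros((0, len(design)))
    for trait in loadings.index:
        lam = loadings.loc[trait, truth.latents.index].to_numpy() if len(truth.latents) else np.zeros(0)
        signal = lam @ lat if lam.size else np.zeros(len(design))
        out[trait] = signal + rng.standard_normal(len(design)) * trait_noise_sd
    return out


def generate_annotations(
    truth: SyntheticTruth,
    n_terms: int = 50,
    planted: dict[int, str] | None = None,
    background_rate: float = 0.05,
    coverage: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene -> GO-like term table with enrichment planted in chosen modules.

    Every gene carries each background term independently with probability
    ``background_rate``; a planted term additionally covers ``coverage``
    (>= 0.8) of its module's genes. Returns columns
    ``gene_id, term_id, term_type`` with unique (gene, term) pairs.
    """
    if not 0.0 < background_rate < 1.0:
        raise ValueError("background_rate must lie in (0, 1)")
    if coverage < 0.8:
        raise ValueError("planted coverage must be >= 0.8 to constitute enrichment")
    planted = dict(planted or {})
    known = {s.module_id for s in truth.module_specs}
    for mod in planted:
        if mod not in known:
            raise ValueError(f"planted term mapped to unknown module {mod}")

    rng = np.random.default_rng(seed)
    genes = np.array(truth.genes)
    terms = [f"GO:SYN{i:04d}" for i in range(1, n_terms + 1)]
    module_of = np.array([truth.gene_to_module[g] for g in genes])

    records: list[tuple[str, str]] = []
    for term in terms:
        hit = rng.random(len(genes)) < background_rate
        records.extend((g, term) for g in genes[hit])
    for mod, term in planted.items():
        members = genes[module_of == mod]
        hit = rng.random(len(members)) < coverage
        # guarantee the >=80% coverage contract even at small module sizes
        if hit.mean() < 0.8:
            need = int(np.ceil(0.8 * len(members))) - int(hit.sum())
            hit[np.flatnonzero(~hit)[:need]] = True
        records.extend((g, term) for g in members[hit])
        truth.planted_terms[mod] = term

    ann = pd.DataFrame(records, columns=["gene_id", "term_id"]).drop_duplicates()
    ann["term_type"] = "GO"
    return ann.reset_index(drop=True)


def plant_tap_families(
    genes: list[str], family_probs: dict[str, float], seed: int = 0
) -> pd.DataFrame:
    """Assign one TAP family label per gene by the given probabilities
    (must sum to 1); models e.g. a MYB/MYB-related-dominated module."""
    probs = np.array(list(family_probs.values()), dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("family probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    fams = rng.choice(list(family_probs), size=len(genes), p=probs)
    return pd.DataFrame({"gene_id": genes, "term_id": fams, "term_type": "TAP"})
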