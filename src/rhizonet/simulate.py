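"""Synthetic study generator: communities, traits and zymogram images.

Every downstream stage of the package has a recovery test against ground
truth produced here, so the generators are first-class, deterministic
(pure functions of their arguments including ``seed``) and return both the
data object and a *truth* record.

Community model
---------------
Taxa are partitioned into ``n_modules`` co-occurrence modules plus an
unstructured pool (module id 0). Each module m has one latent factor per
sample, ``z[s, m] ~ N(0, 1)``; a member taxon t with loading ``l_t`` has

    log mu[s, t] = baseline_log_mean + coupling * l_t * z[s, module(t)]

and counts are drawn negative-binomially with mean ``mu`` and
overdispersion ``dispersion`` (variance mu + dispersion·mu²). Taxa in the
same module therefore co-vary with a strength controlled by a single
``coupling`` knob, while ``coupling = 0`` gives exchangeable independent
taxa — the null case used for calibration tests.

Trait model
-----------
A trait linked to module m is ``effect * z[:, m] + N(0, noise_sd)`` per
unit; a trait linked to module 0 is pure noise. Units coincide with
samples (one rhizobox per sample) so association power is a function of
the sample size alone.

Zymogram model
--------------
A branching random-walk root footprint is drawn on a Gaussian-noise
background (``background_mean``, ``background_sd``); root pixels and a set
of planted hotspot patches around root points are elevated by
``hotspot_gain`` grey units. The returned truth carries the root and
hotspot masks for pixelwise recall scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, TraitTable, ValidationError, Zymogram

log = logging.getLogger(__name__)

__all__ = [
    "CommunityTruth",
    "ZymogramTruth",
    "generate_community",
    "generate_traits",
    "generate_zymogram",
    "DEFAULT_TRAIT_POOL",
]

#: trait names used (in order) when the caller does not supply names;
#: drawn from the soil-chemistry / root-morphology / enzyme vocabulary
DEFAULT_TRAIT_POOL = (
    "pH", "TOC", "TN", "NH3-NH4", "NN", "TP", "K", "Na", "Ca", "Zn",
    "Tips", "TRL", "NetA", "MaxD", "MD", "P", "SA", "SRL",
    "ß-Glu", "LAP", "Phos",
)


@dataclass
class CommunityTruth:
    """Ground truth of a generated community."""

    module_of: dict[str, int]
    latent_factors: np.ndarray  # n_samples × n_modules, column m-1 = module m
    loadings: np.ndarray        # per-taxon coupling multiplier
    dispersion: float
    seed: int
    coupling: float = 0.0
    sample_ids: list[str] = field(default_factory=list)

    def members(self, module_id: int) -> list[str]:
        return [t for t, m in self.module_of.items() if m == module_id]


@dataclass
class ZymogramTruth:
    """Ground truth of a generated zymogram image."""

    root_mask: np.ndarray
    hotspot_mask: np.ndarray
    band_width_px: int
    background_mean: float
    background_sd: float
    hotspot_gain: float
    seed: int

    def __post_init__(self) -> None:
        if self.band_width_px < 1:
            raise ValidationError("band_width_px must be ≥ 1")


def _metadata_frame(sample_ids: list[str], condition, one_box_per_sample: bool = True) -> pd.DataFrame:
    site, compartment, treatment = condition
    return pd.DataFrame(
        {
            "site": site,
            "compartment": compartment,
            "treatment": treatment,
            "rhizobox_id": [f"box_{s}" for s in sample_ids]
            if one_box_per_sample
            else [f"box_{i % 3}" for i in range(len(sample_ids))],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def generate_community(
    n_samples: int = 9,
    n_taxa: int = 180,
    n_modules: int = 4,
    coupling: float = 2.0,
    dispersion: float = 0.5,
    seed: int = 0,
    baseline_log_mean: float = np.log(50.0),
    unstructured_frac: float = 0.2,
    condition: tuple[str, str, str] = ("non_urban", "rhizosphere", "untreated"),
    sample_prefix: str = "S",
) -> tuple[AbundanceTable, CommunityTruth]:
    """Generate a genus-level count table with planted co-occurrence modules.

    Defaults mirror one condition of a rhizobox 16S study: nine samples,
    ~180 genera, four modules. Identical arguments (incl. seed) give a
    bit-identical table.
    """
    if n_samples < 1 or n_taxa < 1:
        raise ValidationError("n_samples and n_taxa must be positive")
    if not (1 <= n_modules <= n_taxa):
        raise ValidationError("need n_taxa ≥ n_modules ≥ 1")
    if coupling < 0:
        raise ValidationError("coupling must be ≥ 0")
    rng = np.random.default_rng(seed)

    n_unstructured = int(round(unstructured_frac * n_taxa))
    n_structured = n_taxa - n_unstructured
    if n_structured < n_modules:
        raise ValidationError("too few structured taxa for the requested modules")
    taxa = [f"genus_{i:03d}" for i in range(n_taxa)]
    # round-robin so modules have near-equal sizes; trailing taxa unstructured
    module_of = {}
    for i, t in enumerate(taxa):
        module_of[t] = (i % n_modules) + 1 if i < n_structured else 0

    z = rng.standard_normal((n_samples, n_modules))
    loadings = rng.uniform(0.75, 1.25, size=n_taxa)
    log_mu = np.full((n_samples, n_taxa), baseline_log_mean)
    for j, t in enumerate(taxa):
        m = module_of[t]
        if m > 0:
            log_mu[:, j] += coupling * loadings[j] * z[:, m - 1]
    mu = np.exp(log_mu)

    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    sample_ids = [f"{sample_prefix}{i:02d}" for i in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                             columns=taxa)
    # simple two-phylum annotation so rank aggregation is exercisable
    taxonomy = pd.DataFrame(
        {
            "phylum": [f"phylum_{module_of[t] % 2}" for t in taxa],
            "genus": taxa,
        },
        index=pd.Index(taxa, name="taxon"),
    )
    table = AbundanceTable(
        counts=counts_df,
        metadata=_metadata_frame(sample_ids, condition),
        taxonomy=taxonomy,
    )
    truth = CommunityTruth(
        module_of=module_of,
        latent_factors=z,
        loadings=loadings,
        dispersion=dispersion,
        seed=seed,
        coupling=coupling,
        sample_ids=sample_ids,
    )
    return table, truth


def generate_traits(
    truth: CommunityTruth,
    linked_modules: list[int],
    effect: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    trait_names: list[str] | None = None,
) -> TraitTable:
    """Generate one trait per entry of ``linked_modules``.

    A trait linked to module m equals ``effect × z[:, m] + N(0, noise_sd)``;
    module 0 yields pure noise (a null trait).
    """
    n_modules = truth.latent_factors.shape[1]
    for m in linked_modules:
        if not (0 <= m <= n_modules):
            raise ValidationError(f"unknown module id {m} (have 0..{n_modules})")
    rng = np.random.default_rng(seed)
    if trait_names is None:
        trait_names = [DEFAULT_TRAIT_POOL[i % len(DEFAULT_TRAIT_POOL)]
                       if i < len(DEFAULT_TRAIT_POOL) else f"trait_{i}"
                       for i in range(len(linked_modules))]
    if len(trait_names) != len(linked_modules):
        raise ValidationError("trait_names length must match linked_modules")
    n = truth.latent_factors.shape[0]
    cols = {}
    for name, m in zip(trait_names, linked_modules):
        signal = truth.latent_factors[:, m - 1] * effect if m > 0 else 0.0
        cols[name] = signal + rng.normal(0.0, noise_sd, size=n)
    units = [f"box_{s}" for s in truth.sample_ids] if truth.sample_ids else \
        [f"unit_{i}" for i in range(n)]
    return TraitTable(values=pd.DataFrame(cols, index=pd.Index(units, name="unit_id")))


def _draw_root(shape: tuple[int, int], rng: np.random.Generator,
               n_branches: int = 3) -> np.ndarray:
    """Seeded branching random walk from the top edge: a connected footprint."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    starts = [(0, w // 2)]
    walks = 0
    while starts and walks < 1 + n_branches:
        r, c = starts.pop(0)
        walks += 1
        length = int(h * rng.uniform(0.6, 1.0))
        branch_at = set(rng.integers(5, max(6, length - 1), size=n_branches)) \
            if walks == 1 and length > 6 else set()
        for step in range(length):
            mask[r, c] = True
            if step in branch_at and len(starts) < n_branches:
                starts.append((r, c))
            r += int(rng.random() < 0.8)  # biased downward
            c += int(rng.integers(-1, 2))
            if r >= h:
                break
            c = min(max(c, 1), w - 2)
    return mask


def generate_zymogram(
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    background_mean: float = 100.0,
    background_sd: float = 5.0,
    hotspot_gain: float = 50.0,
    band_width_px: int = 3,
    n_branches: int = 3,
    n_hotspot_patches: int = 6,
    pixel_size: float = 0.01,
) -> tuple[Zymogram, ZymogramTruth]:
    """Generate a membrane image with a known root footprint and hotspots.

    Root pixels and ``n_hotspot_patches`` disk-shaped patches centred on
    random root pixels are elevated by ``hotspot_gain`` over a Gaussian
    background; everything else is pure background noise. The true hotspot
    mask is returned for recall scoring. ``hotspot_gain ≤ 0`` raises a
    warning — the ground truth is then undetectable by design.
    """
    if shape[0] < 32 or shape[1] < 32:
        raise ValidationError("shape must be at least 32×32")
    if hotspot_gain <= 0:
        warnings.warn("hotspot_gain ≤ 0: planted hotspots are undetectable",
                      UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    root = _draw_root(shape, rng, n_branches=n_branches)

    hotspot = root.copy()
    root_px = np.argwhere(root)
    if len(root_px) and n_hotspot_patches > 0:
        centres = root_px[rng.integers(0, len(root_px), size=n_hotspot_patches)]
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        radius = max(band_width_px, 2)
        for (r, c) in centres:
            hotspot |= (yy - r) ** 2 + (xx - c) ** 2 <= radius ** 2

    image = rng.normal(background_mean, background_sd, size=shape)
    image[hotspot] += hotspot_gain
    truth = ZymogramTruth(
        root_mask=root,
        hotspot_mask=hotspot,
        band_width_px=band_width_px,
        background_mean=background_mean,
        background_sd=background_sd,
        hotspot_gain=hotspot_gain,
        seed=seed,
    )
    return Zymogram(image=image, pixel_size=pixel_size, meta={"synthetic": True}), truth
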