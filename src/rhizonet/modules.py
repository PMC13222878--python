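"""Network modules and their associations with soil / root / enzyme traits.

Genera are clustered into modules by seeded Louvain modularity
optimisation on the co-occurrence graph; modules are ranked by node
count (ties by summed degree) and analyses typically keep only the top
four per network. Each module is summarised to a per-sample profile (the
mean of its member genera's z-scored relative abundances), which is then
Spearman-correlated with every trait; only associations with p < 0.01
count as significant. Mantel tests give the matrix-level confirmation,
and the untreated-vs-treated comparison classifies each (module, trait)
pair as newly induced, maintained or missed under the amendment.

Module identity across the two networks of a comparison is established by
maximum-Jaccard matching of member sets, since partitions of different
graphs carry no shared labels of their own.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceTable, CooccurrenceNetwork, TraitTable, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ModulePartition",
    "detect_modules",
    "module_profile",
    "module_profiles",
    "AssociationMatrix",
    "associate",
    "mantel",
    "match_modules",
    "AssociationShift",
    "classify_shift",
    "expand_traits_to_units",
]


@dataclass
class ModulePartition:
    """Node → module assignment with size-based module ranking.

    Module ids are dense from 1, already in rank order: module 1 is the
    largest (ties resolved by summed degree, then by smallest member
    label for full determinism).
    """

    module_of: dict[str, int]
    sizes: dict[int, int]
    algorithm: str
    seed: int

    def members(self, module_id: int) -> list[str]:
        return sorted(t for t, m in self.module_of.items() if m == module_id)

    @property
    def n_modules(self) -> int:
        return len(self.sizes)

    def top(self, n: int = 4) -> list[int]:
        """The n largest module ids (they are rank-ordered already)."""
        return list(range(1, min(n, self.n_modules) + 1))

    def as_series(self) -> pd.Series:
        return pd.Series(self.module_of, name="module").sort_index()


def detect_modules(net: CooccurrenceNetwork | nx.Graph, seed: int = 0) -> ModulePartition:
    """Seeded Louvain community detection, modules ranked by size.

    Deterministic given the seed. Raises on an empty network.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot detect modules in an empty network")
    communities = nx.community.louvain_communities(g, weight=None, seed=seed)
    ranked = sorted(
        communities,
        key=lambda c: (-len(c), -sum(dict(g.degree(c)).values()), min(map(str, c))),
    )
    module_of = {node: i + 1 for i, comm in enumerate(ranked) for node in comm}
    sizes = {i + 1: len(comm) for i, comm in enumerate(ranked)}
    return ModulePartition(module_of=module_of, sizes=sizes,
                           algorithm="louvain", seed=seed)


def module_profile(
    t: AbundanceTable,
    part: ModulePartition,
    module_id: int,
) -> pd.Series:
    """Per-sample summary of one module: mean of z-scored member abundances.

    Member genera's relative abundances are z-scored across samples and
    averaged; a constant member contributes 0. This keeps each member on
    an equal footing regardless of its absolute abundance.
    """
    members = [m for m in part.members(module_id) if m in t.counts.columns]
    if not members:
        raise ValidationError(f"module {module_id} has no taxa in the table")
    rel = t.relative_abundance()[members]
    sd = rel.std(ddof=1)
    z = (rel - rel.mean()) / sd.replace(0.0, np.nan)
    profile = z.fillna(0.0).mean(axis=1)
    profile.name = f"M{module_id}"
    return profile


def module_profiles(
    t: AbundanceTable,
    part: ModulePartition,
    module_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Profiles for several modules (default: top 4), samples × modules."""
    if module_ids is None:
        module_ids = part.top(4)
    return pd.concat([module_profile(t, part, m) for m in module_ids], axis=1)


@dataclass
class AssociationMatrix:
    """Module × trait Spearman grid with a significance flag at ``alpha``."""

    rho: pd.DataFrame
    p: pd.DataFrame
    alpha: float = 0.01
    mantel_results: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha

    def significant_pairs(self) -> set[tuple[str, str]]:
        sig = self.significant
        return {(m, tr) for m in sig.index for tr in sig.columns if sig.loc[m, tr]}


def expand_traits_to_units(traits: TraitTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Map per-rhizobox traits onto samples via metadata ``rhizobox_id``."""
    boxes = metadata["rhizobox_id"].astype(str)
    missing = set(boxes) - set(map(str, traits.values.index))
    if missing:
        raise ValidationError(f"rhizobox id(s) missing from trait table: {sorted(missing)}")
    expanded = traits.values.loc[boxes].copy()
    expanded.index = metadata.index
    return expanded


def associate(
    profiles: pd.DataFrame,
    traits: TraitTable | pd.DataFrame,
    alpha: float = 0.01,
) -> AssociationMatrix:
    """Spearman rho and two-sided p for every (module profile, trait) pair.

    Profiles and traits must be indexed by the same units; missing trait
    values drop pairwise. Requires ≥ 4 complete pairs per correlation.
    """
    trait_df = traits.values if isinstance(traits, TraitTable) else traits
    if list(profiles.index) != list(trait_df.index):
        common = profiles.index.intersection(trait_df.index)
        if len(common) < 4:
            raise ValidationError("fewer than 4 aligned units between profiles and traits")
        profiles = profiles.loc[common]
        trait_df = trait_df.loc[common]
    rho = pd.DataFrame(index=profiles.columns, columns=trait_df.columns, dtype=float)
    p = pd.DataFrame(index=profiles.columns, columns=trait_df.columns, dtype=float)
    for mod in profiles.columns:
        for tr in trait_df.columns:
            pair = pd.concat([profiles[mod], trait_df[tr]], axis=1).dropna()
            if len(pair) < 4:
                raise ValidationError(
                    f"fewer than 4 complete pairs for ({mod}, {tr})")
            r, pv = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho.loc[mod, tr] = float(r)
            p.loc[mod, tr] = float(pv)
    return AssociationMatrix(rho=rho, p=p, alpha=alpha)


def _offdiag(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], 1)
    return d[iu]


def mantel(
    d1: pd.DataFrame | np.ndarray,
    d2: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    r correlates the upper off-diagonal entries; the two-sided p-value
    permutes the rows and columns of the second matrix simultaneously
    (add-one convention). Requires n_perm ≥ 99 and square same-order
    matrices.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("mantel requires two square matrices of equal order")
    if n_perm < 99:
        raise ValidationError("n_perm must be ≥ 99")
    n = a.shape[0]
    x = _offdiag(a)
    observed = float(np.corrcoef(x, _offdiag(b))[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = float(np.corrcoef(x, _offdiag(b[np.ix_(perm, perm)]))[0, 1])
        if abs(r) >= abs(observed):
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return observed, float(p)


def match_modules(
    reference: ModulePartition,
    other: ModulePartition,
    module_ids: list[int] | None = None,
) -> tuple[dict[int, int], dict[int, float]]:
    """Greedy maximum-Jaccard matching of ``other`` modules onto ``reference``.

    Returns (mapping other_id → reference_id, Jaccard score per other_id).
    Needed because partitions of two different networks carry no shared
    labels; Table-style untreated/treated comparisons require one.
    """
    ref_ids = module_ids or reference.top(reference.n_modules)
    oth_ids = module_ids or other.top(other.n_modules)
    scores = []
    for o, r in itertools.product(oth_ids, ref_ids):
        mo, mr = set(other.members(o)), set(reference.members(r))
        union = mo | mr
        j = len(mo & mr) / len(union) if union else 0.0
        scores.append((j, o, r))
    scores.sort(key=lambda s: (-s[0], s[1], s[2]))
    mapping: dict[int, int] = {}
    jaccard: dict[int, float] = {}
    used_ref: set[int] = set()
    for j, o, r in scores:
        if o in mapping or r in used_ref:
            continue
        mapping[o] = r
        jaccard[o] = j
        used_ref.add(r)
    for o in oth_ids:  # unmatched modules keep their own (offset) identity
        if o not in mapping:
            mapping[o] = o
            jaccard[o] = 0.0
    return mapping, jaccard


@dataclass
class AssociationShift:
    """Amendment-induced changes in significant (module, trait) pairs."""

    new: set[tuple[str, str]]
    maintained: set[tuple[str, str]]
    missed: set[tuple[str, str]]

    def counts(self) -> dict[str, int]:
        return {"new": len(self.new), "maintained": len(self.maintained),
                "missed": len(self.missed)}


def classify_shift(
    untreated: AssociationMatrix,
    treated: AssociationMatrix,
) -> AssociationShift:
    """new = significant only under treatment; maintained = both; missed =
    significant only untreated.

    Both matrices must share the same module labelling convention (apply
    :func:`match_modules` first when they come from different networks)
    and the same trait set.
    """
    if set(untreated.p.columns) != set(treated.p.columns):
        raise ValidationError("trait sets differ between the two association matrices")
    u = untreated.significant_pairs()
    t = treated.significant_pairs()
    return AssociationShift(new=t - u, maintained=u & t, missed=u - t)
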