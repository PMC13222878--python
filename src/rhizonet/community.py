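"""Community-level statistics on abundance tables.

Covers the post-denoising steps of a 16S workflow: the 0.005% overall
relative-abundance filter for extremely rare taxa, rank aggregation,
Shannon alpha-diversity (natural log) with Kruskal–Wallis group tests,
Bray–Curtis beta-diversity with a permutation PERMANOVA (Anderson's
pseudo-F), and per-taxon two-group differential abundance (Wilcoxon
rank-sum on relative abundances, Benjamini–Hochberg corrected).

Permutation p-values everywhere use the add-one convention,
p = (1 + #{permuted ≥ observed}) / (1 + n_perm), so p is never exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceTable, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "filter_rare",
    "aggregate_rank",
    "shannon",
    "shannon_per_sample",
    "diversity_test",
    "bray_curtis",
    "PermanovaResult",
    "permanova",
    "differential_abundance",
]


def filter_rare(t: AbundanceTable, threshold_percent: float = 0.005) -> AbundanceTable:
    """Drop taxa whose overall relative abundance falls below the threshold.

    A taxon is retained iff 100 × (taxon total / grand total) ≥
    ``threshold_percent`` — the boundary case is kept. Samples are never
    removed.
    """
    if not (0 <= threshold_percent <= 100):
        raise ValidationError("threshold_percent must be in [0, 100]")
    if t.n_taxa == 0 or t.n_samples == 0:
        raise ValidationError("empty abundance table")
    grand_total = float(t.counts.to_numpy().sum())
    if grand_total == 0:
        raise ValidationError("abundance table has zero grand total")
    taxon_pct = t.counts.sum(axis=0) / grand_total * 100.0
    keep = taxon_pct >= threshold_percent
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_rare: removed %d / %d taxa below %.4g%%",
                 dropped, t.n_taxa, threshold_percent)
    taxonomy = t.taxonomy.loc[t.counts.columns[keep]] if t.taxonomy is not None else None
    return AbundanceTable(counts=t.counts.loc[:, keep].copy(),
                          metadata=t.metadata.copy(), taxonomy=taxonomy)


def aggregate_rank(t: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum counts within taxa sharing a rank label (phylum or genus).

    Taxa without an annotation at the requested rank pool into
    ``"unclassified"``. Column sums are conserved.
    """
    if rank not in ("phylum", "genus"):
        raise ValidationError(f"unknown rank {rank!r}")
    if t.taxonomy is None or rank not in t.taxonomy.columns:
        raise ValidationError(f"abundance table has no {rank!r} annotations")
    labels = t.taxonomy.loc[t.counts.columns, rank]
    labels = labels.fillna("unclassified").replace("", "unclassified")
    agg = t.counts.T.groupby(labels.to_numpy()).sum().T
    agg.index.name = "sample_id"
    return AbundanceTable(counts=agg, metadata=t.metadata.copy(), taxonomy=None)


def shannon(counts: np.ndarray) -> float:
    """Shannon diversity H = −Σ p ln p (nats) of one sample's counts."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative counts")
    total = x.sum()
    if total == 0:
        raise ValidationError("all-zero sample has undefined diversity")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(t: AbundanceTable) -> pd.Series:
    return pd.Series({s: shannon(t.counts.loc[s].to_numpy()) for s in t.sample_ids},
                     name="shannon")


def diversity_test(t: AbundanceTable, factor: str) -> dict:
    """Kruskal–Wallis test of Shannon diversity across the levels of a factor."""
    if factor not in t.metadata.columns:
        raise ValidationError(f"unknown metadata factor {factor!r}")
    h = shannon_per_sample(t)
    groups = [h[t.metadata[factor].astype(str) == lv].to_numpy()
              for lv in sorted(t.metadata[factor].astype(str).unique())]
    if len(groups) < 2:
        raise ValidationError(f"factor {factor!r} has a single level")
    stat, p = stats.kruskal(*groups)
    return {"factor": factor, "H": float(stat), "p_value": float(p),
            "shannon": h}


def bray_curtis(t: AbundanceTable, relative: bool = True) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities, d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ).

    Computed on relative abundances by default (raw counts with
    ``relative=False``). Two all-zero samples have an undefined distance
    and raise an error.
    """
    if t.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    totals = t.counts.sum(axis=1)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValidationError(f"all-zero sample(s) {zero}: Bray–Curtis undefined")
    x = t.relative_abundance().to_numpy() if relative else t.counts.to_numpy().astype(float)
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=t.counts.index, columns=t.counts.index)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    n_groups: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from a squared-distance matrix and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(groups)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutation PERMANOVA on a distance matrix.

    pseudo-F partitions the among/within sum of squares of the distance
    matrix; the p-value permutes group labels with the add-one convention.
    """
    d = np.asarray(d, dtype=float)
    labels = np.asarray([str(g) for g in groups])
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValidationError("distance matrix and group labels are misaligned")
    if n_perm < 99:
        raise ValidationError("n_perm must be ≥ 99")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 members")
    d2 = d**2
    observed = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(labels)) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(observed), p_value=float(p),
                           n_permutations=n_perm, n_groups=len(uniq))


def differential_abundance(
    t: AbundanceTable,
    contrast: str,
    alpha_q: float = 0.05,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-taxon two-group test on relative abundances with BH correction.

    ``contrast`` must have exactly two levels in the table. Returns a
    DataFrame indexed by taxon with columns ``level_a``/``level_b`` means,
    ``direction`` (the enriched level by mean relative abundance),
    ``statistic``, ``p_value``, ``q_value`` and the boolean ``call`` at
    ``alpha_q``. Taxa absent from all samples are skipped with a log entry.
    """
    if contrast not in t.metadata.columns:
        raise ValidationError(f"unknown metadata factor {contrast!r}")
    levels = sorted(t.metadata[contrast].astype(str).unique())
    if len(levels) != 2:
        raise ValidationError(
            f"contrast {contrast!r} must have exactly 2 levels, found {levels}")
    if test != "wilcoxon":
        raise ValidationError(f"unknown test {test!r}")
    rel = t.relative_abundance()
    in_a = (t.metadata[contrast].astype(str) == levels[0]).to_numpy()
    rows = []
    for taxon in t.taxa:
        x = rel[taxon].to_numpy()
        if np.all(t.counts[taxon].to_numpy() == 0):
            log.info("differential_abundance: taxon %r absent everywhere, skipped",
                     taxon)
            continue
        xa, xb = x[in_a], x[~in_a]
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            stat, p = 0.0, 1.0  # constant identical abundances: no evidence
        else:
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({
            "taxon": taxon,
            f"mean_{levels[0]}": float(xa.mean()),
            f"mean_{levels[1]}": float(xb.mean()),
            "direction": levels[0] if xa.mean() > xb.mean() else levels[1],
            "statistic": float(stat),
            "p_value": float(p),
        })
    result = pd.DataFrame(rows).set_index("taxon")
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result["call"] = result["q_value"] < alpha_q
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["call"] = pd.Series(dtype=bool)
    return result
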