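"""Community statistics on fingerprint and tag-sequence tables.

One code path serves both data types: ARISA consensus vectors enter as
relative intensities, tag tables as (relative) sequence counts.  Provides
Bray-Curtis dissimilarities, non-metric multidimensional scaling, the
ANOSIM permutation test with Bonferroni correction, singleton filtering,
rank-level composition summaries, and the shared-OTU resampling analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import MDS

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class TagTable:
    """Sample × OTU sequence counts with per-OTU taxonomy paths.

    ``counts`` is samples (rows) × OTUs (columns), non-negative integers.
    ``taxonomy`` maps OTU id → semicolon-separated path
    (domain;phylum;class;order;family;genus), possibly truncated or
    "unassigned".
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        values = self.counts.values
        if np.any(values < 0) or not np.allclose(values, np.round(values)):
            raise ValueError("counts must be non-negative integers")
        if self.taxonomy is not None:
            missing = set(self.counts.columns) - set(self.taxonomy.index)
            if missing:
                raise ValueError(f"taxonomy missing for OTUs: {sorted(missing)[:5]} ...")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def subset(self, samples: list[str]) -> "TagTable":
        sub = self.counts.loc[samples]
        keep = sub.sum(axis=0) > 0
        sub = sub.loc[:, keep]
        tax = self.taxonomy[sub.columns] if self.taxonomy is not None else None
        return TagTable(sub, tax)

    @classmethod
    def from_tsv(cls, path) -> "TagTable":
        """Read a table with OTU-id rows, sample columns and a final
        ``taxonomy`` column."""
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        taxonomy = None
        if "taxonomy" in df.columns:
            taxonomy = df.pop("taxonomy")
        return cls(df.T, taxonomy)

    def to_tsv(self, path) -> None:
        out = self.counts.T.copy()
        if self.taxonomy is not None:
            out["taxonomy"] = self.taxonomy[out.index]
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Dissimilarity and ordination


def bray_curtis(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between rows.

    BC(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ); rows must be non-negative with
    positive totals.
    """
    if isinstance(matrix, pd.DataFrame):
        index = matrix.index
        values = matrix.values.astype(float)
    else:
        values = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(len(values))
    if np.any(values < 0):
        raise ValueError("negative abundances")
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        bad = list(np.asarray(index)[totals <= 0])
        raise ValueError(f"zero-total rows: {bad}")
    dm = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(dm, index=index, columns=index)


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame
    stress: float
    degenerate: bool = False


def nmds(
    dissimilarity: pd.DataFrame,
    dims: int = 2,
    n_starts: int = 20,
    seed: int | None = None,
) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of n random starts."""
    dm = dissimilarity.values
    n = len(dm)
    if n < 3:
        raise ValueError("need at least 3 samples for an ordination")
    off_diag = dm[~np.eye(n, dtype=bool)]
    if np.allclose(off_diag, off_diag[0]):
        # all-equal dissimilarities: any regular configuration is optimal
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(n, dims))
        return NMDSResult(
            pd.DataFrame(coords, index=dissimilarity.index), 0.0, degenerate=True
        )
    model = MDS(
        n_components=dims,
        metric_mds=False,
        n_init=n_starts,
        init="random",
        metric="precomputed",
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
    )
    coords = model.fit_transform(dm)
    return NMDSResult(
        pd.DataFrame(coords, index=dissimilarity.index), float(model.stress_)
    )


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    grouping: tuple
    corrected_p: float | None = None


def _anosim_r(ranks_condensed: np.ndarray, within: np.ndarray, n: int) -> float:
    r_within = ranks_condensed[within].mean()
    r_between = ranks_condensed[~within].mean()
    M = n * (n - 1) / 2
    return (r_between - r_within) / (M / 2.0)


def anosim(
    dissimilarity: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """ANOSIM rank permutation test.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2, ranks taken over all pairwise dissimilarities (average
    ranks for ties).  p = (1 + #{permuted R ≥ observed}) / (1 + n_perm).
    """
    groups = np.asarray(groups)
    n = len(dissimilarity)
    if len(groups) != n:
        raise ValueError("group labels must match the dissimilarity matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        small = labels[counts < 2]
        raise ValueError(f"groups of size 1 not allowed: {list(small)}")
    condensed = squareform(dissimilarity.values, checks=False)
    ranks = rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    within = groups[iu] == groups[ju]
    observed = _anosim_r(ranks, within, n)
    rng = np.random.default_rng(seed)
    count_ge = 0
    perm = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(perm)
        g = groups[perm]
        r = _anosim_r(ranks, g[iu] == g[ju], n)
        if r >= observed:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return AnosimResult(float(observed), float(p), n_perm, tuple(labels))


def bonferroni(p_values, m_tests: int | None = None):
    """Bonferroni correction: min(1, p·m).  Scalar in → scalar out."""
    scalar = np.isscalar(p_values)
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    m = m_tests if m_tests is not None else len(p)
    if m < 1:
        raise ValueError("m_tests must be >= 1")
    corrected = np.minimum(1.0, p * m)
    return float(corrected[0]) if scalar else corrected


# ---------------------------------------------------------------------------
# Singleton filtering and shared-OTU resampling


@dataclass
class SingletonReport:
    n_otus_before: int
    n_removed: int

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_otus_before if self.n_otus_before else 0.0


def remove_singletons(table: TagTable) -> tuple[TagTable, SingletonReport]:
    """Drop OTUs with a total of exactly one sequence in the whole dataset."""
    totals = table.counts.sum(axis=0)
    keep = totals != 1
    report = SingletonReport(len(totals), int((~keep).sum()))
    if not keep.any():
        raise ValueError("all OTUs are singletons; nothing left after filtering")
    counts = table.counts.loc[:, keep]
    tax = table.taxonomy[counts.columns] if table.taxonomy is not None else None
    return TagTable(counts, tax), report


@dataclass
class SharedOTUResult:
    """Mean shared / unique OTU fractions over resampling iterations.

    Percentages are of the pooled (resampled) OTU list; ``unique_pct``
    maps sample → mean % unique to that sample, ``partial_pct`` covers
    OTUs in more than one but not all samples.  Sequence percentages give
    the share of sequences falling into shared OTUs, computed on the
    resampled counts and, separately, on the full counts.
    """

    shared_pct: float
    unique_pct: dict
    partial_pct: float
    shared_seq_pct: float
    shared_seq_pct_full: float
    resample_depth: int
    n_iterations: int


def _subsample_counts(
    counts: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``depth`` sequences without replacement from a count vector."""
    total = int(counts.sum())
    if depth > total:
        raise ValueError("resampling depth exceeds sample size")
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def shared_otus(
    table: TagTable,
    samples: list[str] | None = None,
    n_resample: int = 1000,
    seed: int | None = None,
) -> SharedOTUResult:
    """Shared / unique OTU fractions under repeated rarefaction.

    Each iteration subsamples every sample, without replacement, down to
    the smallest sample's sequence count, then classifies each pooled OTU
    as shared (present in all samples), unique (exactly one) or partial.
    Reported values are means over iterations, in percent.
    """
    if samples is not None:
        table = table.subset(samples)
    counts = table.counts.values.astype(np.int64)
    names = table.samples
    if len(names) < 2:
        raise ValueError("need at least two samples")
    depths = counts.sum(axis=1)
    if np.any(depths == 0):
        empty = [names[i] for i in np.nonzero(depths == 0)[0]]
        raise ValueError(f"empty samples: {empty}")
    depth = int(depths.min())
    rng = np.random.default_rng(seed)
    n_s = len(names)
    shared_f, partial_f = [], []
    unique_f = np.zeros((n_resample, n_s))
    seq_shared_f, seq_shared_full_f = [], []
    full_total = counts.sum()
    for it in range(n_resample):
        sub = np.vstack([_subsample_counts(counts[i], depth, rng) for i in range(n_s)])
        presence = sub > 0
        occupancy = presence.sum(axis=0)
        pooled = occupancy > 0
        n_pooled = int(pooled.sum())
        shared = occupancy == n_s
        shared_f.append(shared.sum() / n_pooled)
        partial_f.append(((occupancy > 1) & ~shared).sum() / n_pooled)
        for i in range(n_s):
            unique_only = presence[i] & (occupancy == 1)
            unique_f[it, i] = unique_only.sum() / n_pooled
        seq_shared_f.append(sub[:, shared].sum() / sub.sum())
        seq_shared_full_f.append(counts[:, shared].sum() / full_total)
    return SharedOTUResult(
        shared_pct=100.0 * float(np.mean(shared_f)),
        unique_pct={
            names[i]: 100.0 * float(unique_f[:, i].mean()) for i in range(n_s)
        },
        partial_pct=100.0 * float(np.mean(partial_f)),
        shared_seq_pct=100.0 * float(np.mean(seq_shared_f)),
        shared_seq_pct_full=100.0 * float(np.mean(seq_shared_full_f)),
        resample_depth=depth,
        n_iterations=n_resample,
    )


def pairwise_shared_fraction(
    table: TagTable,
    pair: tuple[str, str],
    n_resample: int = 1000,
    seed: int | None = None,
) -> float:
    """Mean % of the pooled OTUs of a sample pair present in both, under
    the same resampling scheme as :func:`shared_otus`."""
    result = shared_otus(table, list(pair), n_resample=n_resample, seed=seed)
    return result.shared_pct


# ---------------------------------------------------------------------------
# Composition summaries


def _rank_of(path: str, rank: str) -> str | None:
    idx = RANKS.index(rank)
    parts = [p.strip() for p in str(path).split(";")]
    if len(parts) <= idx or not parts[idx] or parts[idx].lower() == "unassigned":
        return None
    return parts[idx]


def taxon_composition(
    table: TagTable,
    rank: str = "class",
    top_n: int = 10,
    assigned_only: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Relative sequence abundance aggregated at a taxonomic rank.

    Returns (samples × taxa relative-abundance table, per-sample ranked
    top-n list).  OTUs unassigned at the rank are pooled under
    "unassigned" unless ``assigned_only`` drops them (shrinking the
    denominators), the behaviour used for genus-level summaries.
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy")
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    labels = {otu: _rank_of(table.taxonomy[otu], rank) for otu in table.counts.columns}
    if all(v is None for v in labels.values()):
        raise ValueError(f"no OTU is assigned at rank {rank!r}")
    counts = table.counts.copy()
    if assigned_only:
        keep = [otu for otu, lab in labels.items() if lab is not None]
        counts = counts[keep]
    grouped = counts.T.groupby(
        lambda otu: labels[otu] if labels[otu] is not None else "unassigned"
    ).sum().T
    totals = grouped.sum(axis=1)
    rel = grouped.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    ranked = {
        sample: list(rel.loc[sample].sort_values(ascending=False).index[:top_n])
        for sample in rel.index
    }
    return rel, ranked
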