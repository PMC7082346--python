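"""Post-mapping transcriptome/proteome processing.

Takes a fragment-count matrix (genes x samples, with treatment/time/replicate
metadata and host/phage gene strata) through the normalization chain
counts -> FPKM -> log2 -> per-gene z-score, clusters temporal expression
profiles by Pearson correlation with resampling-based stability, labels
clusters as early/middle/late infection stages, and computes per-gene
fold changes between infected and uninfected cultures after deconvolving
the fraction of cells actually infected.

The infected-culture signal is modelled as a two-component mixture: a
fraction ``f`` of cells are true virocells with expression X_v and the rest
are uninfected background X_U, so the observed mean is
``X_I = f * X_v + (1 - f) * X_U``. Inverting,

    X_v = (X_I - (1 - f) * X_U) / f        (floored at 0)
    log2FC = log2((X_v + eps) / (X_U + eps)),  eps = 1

A gene is over-expressed when log2FC > 0 and under-expressed when < 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

TREATMENTS = ("uninfected", "HP1", "HS2")
STAGES = ("early", "middle", "late")

_PROVENANCE_CHAIN = {
    "fpkm": {"counts"},
    "log2fpkm": {"fpkm"},
    # proteomics protein counts are z-scored directly, without FPKM
    "zscore": {"log2fpkm", "counts"},
}


@dataclass
class CountMatrix:
    """Non-negative integer fragment counts, genes x samples.

    ``samples`` is indexed by sample id with columns treatment
    (uninfected/HP1/HS2), time_min and replicate.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative counts")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("treatment", "time_min", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")


@dataclass
class ExpressionMatrix:
    """Real-valued expression with transform provenance."""

    values: pd.DataFrame
    provenance: str  # counts | fpkm | log2fpkm | zscore
    constant_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.provenance not in ("counts", "fpkm", "log2fpkm", "zscore"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class TemporalClusterAssignment:
    labels: pd.Series  # gene_id -> cluster id (1..k)
    stability: pd.Series  # gene_id -> [0, 1]
    stages: dict[int, str]  # cluster id -> early/middle/late (after staging)
    params: dict
    excluded: list[str] = field(default_factory=list)


@dataclass
class FoldChangeTable:
    log2fc: pd.DataFrame  # genes x times
    f: pd.Series  # infected fraction per time
    direction: pd.DataFrame  # over / under / none


@dataclass
class StrandednessReport:
    table: pd.DataFrame  # per library: fraction, passed, reason

    @property
    def all_passed(self) -> bool:
        return bool(self.table["passed"].all())


def _require_provenance(m: ExpressionMatrix, target: str) -> None:
    if m.provenance not in _PROVENANCE_CHAIN[target]:
        raise ValueError(
            f"cannot derive {target!r} from {m.provenance!r} "
            f"(expected one of {sorted(_PROVENANCE_CHAIN[target])})"
        )


def fpkm(counts: CountMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped fragments.

    ``annotation`` is indexed by gene id with columns length_bp and stratum
    (host/phage). Host and phage genes are normalized separately: each
    stratum's sequencing depth in a sample is the summed counts of that
    stratum's own genes, so phage transcript levels are comparable across
    infections regardless of host background.
    """
    missing = set(counts.values.index) - set(annotation.index)
    if missing:
        raise ValueError(f"genes without annotation: {sorted(missing)[:5]} ...")
    ann = annotation.loc[counts.values.index]
    zero_depth = counts.values.sum(axis=0) == 0
    if zero_depth.any():
        bad = list(counts.values.columns[zero_depth])
        raise ValueError(f"zero library depth in sample(s) {bad}")
    out = pd.DataFrame(
        0.0, index=counts.values.index, columns=counts.values.columns
    )
    for stratum, genes in ann.groupby("stratum").groups.items():
        sub = counts.values.loc[genes]
        depth = sub.sum(axis=0)  # per-sample stratum depth
        if (depth == 0).any():
            quiet = list(depth.index[depth == 0])
            warnings.warn(
                f"stratum {stratum!r} has zero depth in {quiet}; FPKM set to 0"
            )
        kb = ann.loc[genes, "length_bp"].to_numpy()[:, None] / 1e3
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = sub.to_numpy() / kb / (depth.to_numpy()[None, :] / 1e6)
        out.loc[genes] = np.nan_to_num(vals, nan=0.0, posinf=0.0)
    return ExpressionMatrix(out, "fpkm")


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1); the +1 pseudocount keeps zero expression at 0."""
    _require_provenance(m, "log2fpkm")
    if (m.values.values < 0).any():
        raise ValueError("negative expression values")
    return ExpressionMatrix(np.log2(m.values + 1.0), "log2fpkm")


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score (sample sd, n-1); constant rows become 0 and are flagged."""
    _require_provenance(m, "zscore")
    if m.values.shape[1] < 2:
        raise ValueError("z-score needs at least 2 samples per row")
    mu = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=1)
    constant = sd == 0
    sd_safe = sd.where(~constant, 1.0)
    z = m.values.sub(mu, axis=0).div(sd_safe, axis=0)
    z[constant] = 0.0
    return ExpressionMatrix(z, "zscore", constant_rows=list(m.values.index[constant]))


def strandedness(
    reverse_counts: dict[str, int], both_counts: dict[str, int]
) -> StrandednessReport:
    """Per-library reverse-strand fraction with a strict >95% pass threshold."""
    rows = []
    for lib in both_counts:
        rev, both = reverse_counts[lib], both_counts[lib]
        if not 0 <= rev <= both:
            raise ValueError(f"{lib}: need 0 <= reverse <= both")
        if both == 0:
            rows.append((lib, np.nan, False, "no mapped reads"))
        else:
            frac = rev / both
            rows.append((lib, frac, frac > 0.95, ""))
    table = pd.DataFrame(
        rows, columns=["library", "fraction", "passed", "reason"]
    ).set_index("library")
    return StrandednessReport(table)


# ---------------------------------------------------------------------------
# Temporal clustering
# ---------------------------------------------------------------------------


def _pearson_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """1 - Pearson r between gene profiles; undefined pairs get distance 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    return np.clip((dist + dist.T) / 2.0, 0.0, 2.0)


class TemporalClusterer(ClusterMixin, BaseEstimator):
    """Hierarchical clustering of temporal profiles with resampling stability.

    Genes (rows of X) are clustered with average linkage on the
    correlation distance ``1 - Pearson(r)`` between their mean-per-timepoint
    profiles and the tree is cut at ``n_clusters``. Per-gene stability is
    estimated by reclustering ``b_resamples`` random subsets of the
    timepoint columns (``subsample_fraction`` of them, without replacement)
    and recording how often each gene lands with the majority of its final
    cluster.

    Parameters
    ----------
    n_clusters : number of temporal clusters (3 for early/middle/late).
    b_resamples : number of column resamples for the stability score.
    subsample_fraction : fraction of timepoint columns kept per resample.
    random_state : seed; the whole procedure is deterministic given it.

    Attributes
    ----------
    labels_ : cluster id (1..k) per gene.
    stability_ : per-gene co-clustering stability in [0, 1].
    """

    def __init__(
        self,
        n_clusters: int = 3,
        b_resamples: int = 100,
        subsample_fraction: float = 0.75,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.b_resamples = b_resamples
        self.subsample_fraction = subsample_fraction
        self.random_state = random_state

    def _cluster_once(self, profiles: np.ndarray) -> np.ndarray:
        dist = _pearson_distance_matrix(profiles)
        z = linkage(squareform(dist, checks=False), method="average")
        return fcluster(z, t=self.n_clusters, criterion="maxclust")

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (genes x timepoints)")
        n_genes, n_times = X.shape
        if n_genes < self.n_clusters:
            raise ValueError("fewer genes than clusters")
        if n_times < 3:
            raise ValueError("need at least 3 timepoints")
        self.n_features_in_ = n_times
        self.labels_ = self._cluster_once(X)

        rng = np.random.default_rng(self.random_state)
        k_cols = max(3, int(round(self.subsample_fraction * n_times)))
        k_cols = min(k_cols, n_times)
        stable = np.zeros(n_genes)
        members = {c: np.flatnonzero(self.labels_ == c) for c in set(self.labels_)}
        for _ in range(self.b_resamples):
            cols = rng.choice(n_times, size=k_cols, replace=False)
            sub_labels = self._cluster_once(X[:, cols])
            for idx in members.values():
                votes = np.bincount(sub_labels[idx])
                majority = votes.argmax()  # smallest label wins ties
                stable[idx] += sub_labels[idx] == majority
        self.stability_ = stable / max(self.b_resamples, 1)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def mean_time_profiles(
    z: ExpressionMatrix, times: pd.Series | dict
) -> pd.DataFrame:
    """Average replicate columns into one profile column per timepoint."""
    times = pd.Series(times)
    cols_by_time = {
        t: [c for c in z.values.columns if times[c] == t]
        for t in sorted(times.unique())
    }
    return pd.DataFrame(
        {t: z.values[cols].mean(axis=1) for t, cols in cols_by_time.items()}
    )


def temporal_cluster(
    z: ExpressionMatrix,
    n_clusters: int = 3,
    b_resamples: int = 100,
    subsample_fraction: float = 0.75,
    seed: int | None = None,
    times: pd.Series | dict | None = None,
) -> TemporalClusterAssignment:
    """Cluster genes by temporal profile (thin wrapper over TemporalClusterer).

    If ``times`` maps sample columns to timepoints, replicate columns are
    first averaged per timepoint; otherwise each column is taken as one
    timepoint. Genes with zero variance across time carry no temporal
    signal and are excluded with a warning.
    """
    profiles = mean_time_profiles(z, times) if times is not None else z.values
    flat = profiles.std(axis=1) == 0
    excluded = list(profiles.index[flat])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} zero-variance gene(s) from clustering"
        )
        profiles = profiles[~flat]
    est = TemporalClusterer(
        n_clusters=n_clusters,
        b_resamples=b_resamples,
        subsample_fraction=subsample_fraction,
        random_state=seed,
    ).fit(profiles.to_numpy())
    return TemporalClusterAssignment(
        labels=pd.Series(est.labels_, index=profiles.index, name="cluster"),
        stability=pd.Series(est.stability_, index=profiles.index, name="stability"),
        stages={},
        params={
            "n_clusters": n_clusters,
            "B": b_resamples,
            "subsample_fraction": subsample_fraction,
            "seed": seed,
        },
        excluded=excluded,
    )


def assign_stages(
    tc: TemporalClusterAssignment, profiles: pd.DataFrame
) -> TemporalClusterAssignment:
    """Label three clusters early/middle/late by when their centroid peaks.

    Clusters are ranked by the timepoint of their mean-profile maximum;
    ties are broken by which centroid rises (crosses half its range)
    earlier. Identical peak and rise implies indistinguishable clusters and
    raises, leaving the labelling to the analyst.
    """
    cluster_ids = sorted(tc.labels.unique())
    if len(cluster_ids) != 3:
        raise ValueError("stage labels require exactly 3 clusters")
    timepoints = list(profiles.columns)

    def keys(cid: int) -> tuple[int, int]:
        centroid = profiles.loc[tc.labels.index[tc.labels == cid]].mean(axis=0)
        peak = int(np.argmax(centroid.to_numpy()))
        half = centroid.min() + 0.5 * (centroid.max() - centroid.min())
        rise = int(np.argmax(centroid.to_numpy() >= half))
        return peak, rise

    ranked = sorted(cluster_ids, key=lambda cid: keys(cid))
    for a, b in zip(ranked, ranked[1:]):
        if keys(a) == keys(b):
            raise ValueError(
                f"clusters {a} and {b} peak and rise at the same time; "
                "stage labels require manual assignment"
            )
    tc.stages = {cid: stage for cid, stage in zip(ranked, STAGES)}
    _ = timepoints  # stage order is positional over the profile columns
    return tc


# ---------------------------------------------------------------------------
# Fold change and DE set algebra
# ---------------------------------------------------------------------------


def adjusted_fold_change(
    infected_mean: pd.DataFrame,
    control_mean: pd.DataFrame,
    f: pd.Series | dict | float,
    epsilon: float = 1.0,
) -> FoldChangeTable:
    """Infected-fraction-adjusted log2 fold change per gene and timepoint.

    Deconvolves the virocell signal from the observed infected-culture mean
    (see module docstring), then log2FC = log2((X_v + eps)/(X_U + eps)).
    ``f`` is the infected fraction per timepoint column, in (0, 1].
    """
    if list(infected_mean.columns) != list(control_mean.columns) or not (
        infected_mean.index.equals(control_mean.index)
    ):
        raise ValueError("infected and control matrices must align")
    if np.isscalar(f):
        f = pd.Series(float(f), index=infected_mean.columns)
    else:
        f = pd.Series(f).reindex(infected_mean.columns)
    if f.isna().any() or (f <= 0).any() or (f > 1).any():
        raise ValueError("infected fraction f must lie in (0, 1] for every time")
    if (infected_mean.values < 0).any() or (control_mean.values < 0).any():
        raise ValueError("expression means must be non-negative")
    x_v = (infected_mean - control_mean.mul(1.0 - f, axis=1)).div(f, axis=1)
    x_v = x_v.clip(lower=0.0)
    log2fc = np.log2((x_v + epsilon) / (control_mean + epsilon))
    direction = pd.DataFrame(
        np.where(log2fc > 0, "over", np.where(log2fc < 0, "under", "none")),
        index=log2fc.index,
        columns=log2fc.columns,
    )
    return FoldChangeTable(log2fc=log2fc, f=f, direction=direction)


@dataclass
class DePanelSummary:
    de_sets: dict[str, set[str]]
    shared: set[str]
    unique: dict[str, set[str]]
    n_total_genes: int

    def counts(self) -> dict[str, float]:
        out: dict[str, float] = {"n_total_genes": self.n_total_genes}
        for name, s in self.de_sets.items():
            out[f"n_de_{name}"] = len(s)
        out["n_shared"] = len(self.shared)
        out["frac_shared"] = (
            len(self.shared) / self.n_total_genes if self.n_total_genes else 0.0
        )
        for name, s in self.unique.items():
            out[f"n_unique_{name}"] = len(s)
        return out


def classify_de_panel(
    fc_tables: dict[str, FoldChangeTable],
    de_calls: dict[str, set[str]] | None = None,
    abs_log2fc_threshold: float = 1.0,
) -> DePanelSummary:
    """Per-virocell DE gene sets and their overlap.

    Significance calls are external when supplied (``de_calls``); otherwise
    a stand-in threshold on the adjusted |log2FC| (any timepoint) is used.
    Gene universes must agree across virocells.
    """
    universes = [frozenset(fc.log2fc.index) for fc in fc_tables.values()]
    if len(set(universes)) != 1:
        raise ValueError("mismatched gene universes across virocells")
    genes = set(universes[0])
    de_sets: dict[str, set[str]] = {}
    for name, fc in fc_tables.items():
        if de_calls is not None:
            called = set(de_calls[name]) & genes
        else:
            called = set(
                fc.log2fc.index[(fc.log2fc.abs() >= abs_log2fc_threshold).any(axis=1)]
            )
        de_sets[name] = called
    shared = set.intersection(*de_sets.values()) if de_sets else set()
    unique = {
        name: s - set.union(*(o for n, o in de_sets.items() if n != name))
        for name, s in de_sets.items()
    }
    return DePanelSummary(de_sets, shared, unique, len(genes))
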