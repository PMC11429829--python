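"""Permutation nulls, cluster statistics, effect sizes, and behavior.

The statistical surface of the pipeline:

* a *null TRF* per subject, obtained by refitting the encoding model on
  deliberately mismatched envelope/EEG pairings (derangements, so no segment
  keeps its own envelope) and averaging over permutations — the noise floor
  of the method;
* spatiotemporal *cluster-based permutation tests* controlling the multiple
  comparisons across 64 sensors x lags: supra-threshold paired-t samples are
  clustered under scalp adjacency and lag contiguity, cluster sum-t
  statistics are ranked against a Monte-Carlo null of within-subject
  condition-label swaps, two-tailed at 0.025 per tail;
* electrode-wise z-normalized topographies for lateralization/representation
  contrasts (scale-free, so amplitude differences cannot drive topographic
  effects);
* small-sample-corrected Cohen's d with bootstrap confidence intervals;
* signal-detection d-prime for the behavioral control task;
* the minimum-data analysis: detection of the tactile TRF against its null
  from 2..9 minutes of stimulation at a Bonferroni-corrected alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from . import montage
from .envelope import TactileEnvelope
from .trf import DEFAULT_LAMBDA, LaggedStats, LagWindow, TRFModel, _as_arrays

logger = logging.getLogger(__name__)

#: scalp distance (m) under which two electrodes are neighbors; on the
#: idealized geodesic montage this yields a median of 5 neighbors and no
#: isolated channel
DEFAULT_ADJACENCY_THRESHOLD_M = 0.052

#: sentinel replacing an infinite paired-t at a zero-variance cell
T_SENTINEL = 1e6

#: per-tail cluster significance level (two-tailed 0.05)
CLUSTER_P_PER_TAIL = 0.025

#: Bonferroni-corrected per-test alpha for the eight minimum-data tests
MIN_DATA_ALPHA = 0.05 / 8


# ---------------------------------------------------------------------------
# null TRF

@dataclass
class NullTRF:
    """Average of TRFs fit on mismatched envelope/EEG pairings."""

    weights: np.ndarray
    intercept: np.ndarray
    lag_axis_ms: np.ndarray
    n_permutations: int
    scheme: str = "within-condition derangement"
    subject: int | str = 0
    condition: str = ""


def _random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of 0..n-1 with no fixed point."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def make_null_trf(
    segments: list[tuple[TactileEnvelope, object]] | LaggedStats,
    lam: float = DEFAULT_LAMBDA,
    lags: LagWindow | None = None,
    n_permutations: int = 100,
    seed: int | np.random.SeedSequence = 0,
    subject: int | str = 0,
    condition: str = "",
    n_segments: int | None = None,
) -> NullTRF:
    """Null TRF: mean over permutations of mismatched-pairing subject TRFs.

    Each permutation re-pairs every EEG segment with a different
    condition-matched envelope (a derangement, so no segment keeps its own),
    then fits the usual leave-one-out-averaged subject TRF on the shuffled
    pairs. A prebuilt :class:`LaggedStats` may be passed to share cached
    sufficient statistics with other analyses; ``n_segments`` restricts the
    null to the first k segments (minimum-data analysis).
    """
    lags = LagWindow() if lags is None else lags
    if isinstance(segments, LaggedStats):
        stats = segments
    else:
        envs, eeg = _as_arrays(segments)
        stats = LaggedStats(envs, eeg, lags)
    n = stats.n if n_segments is None else n_segments
    if n < 2:
        raise ValueError("null TRF needs at least 2 segments for a derangement")
    rng = np.random.default_rng(seed)
    w_sum = None
    b_sum = None
    for _ in range(n_permutations):
        perm = _random_derangement(n, rng)
        pairs = [(int(perm[j]), j) for j in range(n)]
        w, b = stats.loo_average(pairs, lam)
        w_sum = w if w_sum is None else w_sum + w
        b_sum = b if b_sum is None else b_sum + b
    return NullTRF(
        weights=w_sum / n_permutations,
        intercept=b_sum / n_permutations,
        lag_axis_ms=lags.lag_axis_ms,
        n_permutations=n_permutations,
        subject=subject,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# adjacency

@dataclass
class AdjacencyGraph:
    """Symmetric, irreflexive channel neighborhood on the scalp."""

    matrix: np.ndarray                    # (n_channels, n_channels) bool
    labels: list[str]
    threshold_m: float

    def neighbors(self, label: str) -> list[str]:
        i = self.labels.index(label)
        return [self.labels[j] for j in np.flatnonzero(self.matrix[i])]


def build_adjacency(
    positions: np.ndarray | None = None,
    labels: list[str] | None = None,
    distance_threshold: float = DEFAULT_ADJACENCY_THRESHOLD_M,
) -> AdjacencyGraph:
    """Distance-threshold neighborhood graph on electrode positions.

    Defaults to the idealized 64-channel geodesic montage. Channels left
    isolated under the threshold trigger a warning (they can never join a
    spatial cluster) but not an error.
    """
    if positions is None:
        positions = montage.channel_positions()
        labels = montage.channel_labels()
    if labels is None:
        labels = [f"ch{i}" for i in range(len(positions))]
    dist = squareform(pdist(positions))
    matrix = (dist < distance_threshold) & ~np.eye(len(labels), dtype=bool)
    isolated = np.flatnonzero(matrix.sum(axis=1) == 0)
    if isolated.size:
        logger.warning(
            "isolated channel(s) under threshold %.3g m: %s",
            distance_threshold, [labels[i] for i in isolated],
        )
    return AdjacencyGraph(matrix=matrix, labels=list(labels), threshold_m=distance_threshold)


# ---------------------------------------------------------------------------
# paired t maps and spatiotemporal clusters

@dataclass
class TTestMap:
    """Element-wise paired-t statistics over channels x lags."""

    t: np.ndarray
    df: int
    lag_axis_ms: np.ndarray


def paired_t_map(a: np.ndarray, b: np.ndarray,
                 lag_axis_ms: np.ndarray | None = None) -> TTestMap:
    """Element-wise paired t over the subject axis of (subjects, ch, lags).

    Zero-variance cells would give infinite t; they are capped to a signed
    sentinel and logged.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t needs at least 2 subjects")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = sd == 0
    if np.any(bad):
        logger.warning("zero-variance paired differences at %d cells; t capped", bad.sum())
        t = np.where(bad, np.sign(mean) * T_SENTINEL, t)
        t = np.where(bad & (mean == 0), 0.0, t)
    if lag_axis_ms is None:
        lag_axis_ms = np.arange(a.shape[-1], dtype=float)
    return TTestMap(t=t, df=n - 1, lag_axis_ms=np.asarray(lag_axis_ms, float))


@dataclass
class Cluster:
    """One signed spatiotemporal cluster with its Monte-Carlo p-value."""

    members: list[tuple[int, int]]     # (channel index, lag index within window)
    sign: int
    sum_t: float
    p_value: float

    @property
    def channels(self) -> list[int]:
        return sorted({ch for ch, _ in self.members})

    @property
    def lag_range(self) -> tuple[int, int]:
        lags = [lag for _, lag in self.members]
        return min(lags), max(lags)


@dataclass
class ClusterTestResult:
    """Signed clusters, the Monte-Carlo null, and the test bookkeeping."""

    clusters: list[Cluster]
    n_permutations: int
    alpha: float
    df: int
    t_threshold: float
    lag_axis_ms: np.ndarray
    null_max_sum_t: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]


def _spatiotemporal_graph(channel_adjacency: np.ndarray, n_lags: int) -> sparse.csr_matrix:
    """Node graph over (channel, lag) cells: scalp neighbors at equal lag
    plus lag-contiguous cells within each channel."""
    n_ch = channel_adjacency.shape[0]
    n_nodes = n_ch * n_lags
    rows, cols = [], []
    ch_i, ch_j = np.nonzero(channel_adjacency)
    for lag in range(n_lags):
        rows.append(ch_i * n_lags + lag)
        cols.append(ch_j * n_lags + lag)
    base = np.arange(n_nodes).reshape(n_ch, n_lags)
    rows.append(base[:, :-1].ravel())
    cols.append(base[:, 1:].ravel())
    rows.append(base[:, 1:].ravel())
    cols.append(base[:, :-1].ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(rows.size, dtype=np.int8)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes))


def _find_clusters(tmap: np.ndarray, graph: sparse.csr_matrix, t_threshold: float
                   ) -> list[tuple[np.ndarray, int, float]]:
    """Sign-specific connected components of supra-threshold cells.

    Returns (flat member indices, sign, sum_t) triples.
    """
    n_lags = tmap.shape[1]
    out = []
    flat = tmap.ravel()
    for sign in (1, -1):
        mask = flat * sign > t_threshold
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = graph[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            out.append((members, sign, float(flat[members].sum())))
    return out


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    adjacency: AdjacencyGraph | np.ndarray,
    lag_axis_ms: np.ndarray | None = None,
    lag_window_ms: tuple[float, float] | None = None,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    alpha: float = CLUSTER_P_PER_TAIL,
    seed: int | np.random.SeedSequence = 0,
) -> ClusterTestResult:
    """Paired spatiotemporal cluster-based permutation test.

    ``a`` and ``b`` are (subjects, channels, lags) arrays of matched
    observations (e.g. tactile TRFs vs null TRFs). The observed paired-t map
    is thresholded at the two-tailed sample-level critical value for
    ``cluster_alpha``; supra-threshold cells form sign-specific connected
    clusters under scalp adjacency x lag contiguity, each scored by its
    summed t. The Monte-Carlo null swaps condition labels within random
    subsets of subjects (sign flips of the paired differences) and records
    the maximum |sum t| over clusters per permutation. Cluster p-values
    count the observed statistic, so the smallest attainable p is
    ``1/(n_permutations + 1)``; significance is ``p < alpha`` per tail.

    ``lag_window_ms`` restricts the test to lags within the window (0-400 ms
    for condition-vs-null/control, 50-400 ms for between-condition
    contrasts).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    n_subjects, n_channels, n_lags_full = a.shape
    if lag_axis_ms is None:
        lag_axis_ms = np.arange(n_lags_full, dtype=float)
    lag_axis_ms = np.asarray(lag_axis_ms, float)
    if lag_window_ms is not None:
        keep = np.flatnonzero(
            (lag_axis_ms >= lag_window_ms[0] - 1e-9) & (lag_axis_ms <= lag_window_ms[1] + 1e-9)
        )
        if keep.size == 0:
            raise ValueError(f"empty lag window {lag_window_ms}")
        a = a[:, :, keep]
        b = b[:, :, keep]
        lag_axis_ms = lag_axis_ms[keep]
    n_lags = a.shape[2]
    adj = adjacency.matrix if isinstance(adjacency, AdjacencyGraph) else np.asarray(adjacency, bool)

    df = n_subjects - 1
    t_threshold = float(sps.t.ppf(1 - cluster_alpha / 2, df))
    graph = _spatiotemporal_graph(adj, n_lags)

    d = (a - b).reshape(n_subjects, -1)
    sumsq = np.sum(d**2, axis=0)            # invariant under sign flips

    def t_of(signs: np.ndarray) -> np.ndarray:
        mean = signs @ d / n_subjects
        var = (sumsq / n_subjects - mean**2) * (n_subjects / df)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n_subjects)
        t = np.where(var == 0, np.sign(mean) * T_SENTINEL, t)
        return t.reshape(n_channels, n_lags)

    observed_t = t_of(np.ones(n_subjects))
    observed = _find_clusters(observed_t, graph, t_threshold)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_permutations)
    for p in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n_subjects)
        perm_clusters = _find_clusters(t_of(signs), graph, t_threshold)
        if perm_clusters:
            null_max[p] = max(abs(s) for _, _, s in perm_clusters)

    clusters = []
    for members, sign, sum_t in observed:
        p_val = (1 + int(np.sum(null_max >= abs(sum_t)))) / (n_permutations + 1)
        clusters.append(
            Cluster(
                members=[(int(m // n_lags), int(m % n_lags)) for m in members],
                sign=sign,
                sum_t=sum_t,
                p_value=float(p_val),
            )
        )
    clusters.sort(key=lambda c: -abs(c.sum_t))
    return ClusterTestResult(
        clusters=clusters,
        n_permutations=n_permutations,
        alpha=alpha,
        df=df,
        t_threshold=t_threshold,
        lag_axis_ms=lag_axis_ms,
        null_max_sum_t=null_max,
    )


# ---------------------------------------------------------------------------
# normalized topographies, effect sizes, behavior

def normalize_topographies(trfs: np.ndarray) -> np.ndarray:
    """z-score across electrodes at each (subject, lag).

    Removes per-subject amplitude scale and per-lag offsets, so contrasts of
    the output reflect topography, not amplitude.
    """
    trfs = np.asarray(trfs, float)
    if trfs.ndim != 3 or trfs.shape[1] < 2:
        raise ValueError("expected (subjects, channels>=2, lags)")
    mean = trfs.mean(axis=1, keepdims=True)
    sd = trfs.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero across-channel variance at some (subject, lag)")
    return (trfs - mean) / sd


@dataclass
class EffectSize:
    """Small-sample-corrected Cohen's d with bootstrap 95% CI."""

    d: float
    ci_low: float
    ci_high: float
    n: int


def cohens_d_unbiased(
    a: np.ndarray, b: np.ndarray, n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> EffectSize:
    """Paired Cohen's d with Hedges' small-sample correction and bootstrap CI.

    ``d = mean(a-b)/sd(a-b) * (1 - 3/(4 df - 1))`` with ``df = n - 1``; the
    CI is the percentile interval over ``n_boot`` resamples of subjects
    (``n_boot=0`` skips the bootstrap and returns a degenerate CI at d).
    Nonzero constant differences are an error (d undefined); identical
    inputs give d = 0 by convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be matched 1-D subject vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return EffectSize(d=0.0, ci_low=0.0, ci_high=0.0, n=n)
        raise ValueError("zero-variance paired differences: d undefined")
    correction = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)

    def _d(x: np.ndarray) -> float:
        s = x.std(ddof=1)
        return float(x.mean() / s * correction) if s > 0 else np.nan

    d = _d(diff)
    if n_boot == 0:
        return EffectSize(d=d, ci_low=d, ci_high=d, n=n)
    rng = np.random.default_rng(seed)
    boots = np.array([
        _d(diff[rng.integers(0, n, size=n)]) for _ in range(n_boot)
    ])
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EffectSize(d=d, ci_low=float(lo), ci_high=float(hi), n=n)


@dataclass
class DPrimeResult:
    """Signal-detection sensitivity from the behavioral control task."""

    hit_rate: float
    fa_rate: float
    dprime: float


def dprime(hits: int, misses: int, fas: int, crs: int,
           adjust_extremes: bool = True) -> DPrimeResult:
    """d' = z(hit rate) - z(false-alarm rate).

    Extreme rates (0 or 1) are replaced by ``1/(2N)`` and ``1 - 1/(2N)``
    when ``adjust_extremes`` (otherwise they give infinite d'). Equal rates
    give d' = 0 to machine precision: no sensitivity.
    """
    n_sig = hits + misses
    n_noise = fas + crs
    if n_sig <= 0 or n_noise <= 0:
        raise ValueError("need at least one signal and one noise trial")
    hit_rate = hits / n_sig
    fa_rate = fas / n_noise
    if adjust_extremes:
        hit_rate = min(max(hit_rate, 1 / (2 * n_sig)), 1 - 1 / (2 * n_sig))
        fa_rate = min(max(fa_rate, 1 / (2 * n_noise)), 1 - 1 / (2 * n_noise))
    d = float(sps.norm.ppf(hit_rate) - sps.norm.ppf(fa_rate))
    return DPrimeResult(hit_rate=float(hit_rate), fa_rate=float(fa_rate), dprime=d)


# ---------------------------------------------------------------------------
# minimum-data analysis

#: default summary window: the early contralateral positive response, ms
MIN_DATA_WINDOW_MS = (50.0, 170.0)


def trf_summary_scalar(
    weights: np.ndarray, lag_axis_ms: np.ndarray,
    electrode_indices: np.ndarray, lag_window_ms: tuple[float, float] = MIN_DATA_WINDOW_MS,
) -> float:
    """Mean TRF weight over an electrode set and lag window."""
    keep = (lag_axis_ms >= lag_window_ms[0] - 1e-9) & (lag_axis_ms <= lag_window_ms[1] + 1e-9)
    return float(weights[np.ix_(electrode_indices, np.flatnonzero(keep))].mean())


def minimum_data_analysis(
    subject_stats: list[LaggedStats],
    electrode_set: tuple[str, ...],
    lam: float = DEFAULT_LAMBDA,
    lags: LagWindow | None = None,
    minutes_grid: range = range(2, 10),
    lag_window_ms: tuple[float, float] = MIN_DATA_WINDOW_MS,
    alpha: float = MIN_DATA_ALPHA,
    null_permutations: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Detection of the tactile TRF vs its null from k = 2..9 minutes.

    For each k, the subject TRF and its mismatched-pairing null TRF are fit
    on the first k one-minute segments; the per-subject summary scalar is
    the mean TRF weight over ``electrode_set`` within ``lag_window_ms``.
    Tactile vs null scalars enter a paired t test across subjects (normality
    of the differences is screened with Shapiro-Wilk and logged);
    significance is judged at the Bonferroni-corrected ``alpha``
    (0.05/8 = 0.00625 for the eight tests).

    Returns a DataFrame with one row per k: t, p, significant, shapiro_p.
    """
    lags = LagWindow() if lags is None else lags
    e_idx = montage.channel_index(list(electrode_set))
    max_k = max(minutes_grid)
    for s in subject_stats:
        if s.n < max_k:
            raise ValueError(f"need at least {max_k} segments per subject, got {s.n}")
    root = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    rows = []
    for k in minutes_grid:
        tactile, null = [], []
        for s_i, stats in enumerate(subject_stats):
            pairs = [(i, i) for i in range(k)]
            w, _ = stats.loo_average(pairs, lam)
            tactile.append(trf_summary_scalar(w, lags.lag_axis_ms, e_idx, lag_window_ms))
            nt = make_null_trf(
                stats, lam=lam, lags=lags, n_permutations=null_permutations,
                seed=np.random.SeedSequence(entropy=root.entropy, spawn_key=(s_i, k)),
                n_segments=k,
            )
            null.append(trf_summary_scalar(nt.weights, lags.lag_axis_ms, e_idx, lag_window_ms))
        tactile_arr = np.array(tactile)
        null_arr = np.array(null)
        t_stat, p_val = sps.ttest_rel(tactile_arr, null_arr)
        shapiro_p = float(sps.shapiro(tactile_arr - null_arr).pvalue)
        if shapiro_p < 0.05:
            logger.warning("minimum-data k=%d: differences deviate from normality (p=%.3g)",
                           k, shapiro_p)
        rows.append(dict(
            minutes=k, t=float(t_stat), p=float(p_val),
            significant=bool(p_val < alpha), shapiro_p=shapiro_p,
            mean_tactile=float(tactile_arr.mean()), mean_null=float(null_arr.mean()),
        ))
    return pd.DataFrame(rows)


def cluster_table(result: ClusterTestResult, labels: list[str] | None = None) -> pd.DataFrame:
    """Flat summary of a cluster test: one row per cluster."""
    labels = montage.channel_labels() if labels is None else labels
    rows = []
    for c in result.clusters:
        lo, hi = c.lag_range
        rows.append(dict(
            sign=c.sign,
            sum_t=c.sum_t,
            p_value=c.p_value,
            n_members=len(c.members),
            lag_start_ms=float(result.lag_axis_ms[lo]),
            lag_end_ms=float(result.lag_axis_ms[hi]),
            channels=",".join(labels[ch] for ch in c.channels),
        ))
    return pd.DataFrame(rows, columns=[
        "sign", "sum_t", "p_value", "n_members", "lag_start_ms", "lag_end_ms", "channels",
    ])
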