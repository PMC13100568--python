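"""Nonparametric and mixed-model statistics for lattice-shaped data.

The cluster permutation test runs on any lattice (time, time x freq, 2D gaze
grids, optionally with a channel axis and an explicit channel adjacency);
stratification, circular-shift surrogate correlation, a trial-level mixed
model, and a 2x2 within-subject ANOVA round out the toolbox.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "ClusterResult",
    "StratifiedSelection",
    "cluster_permutation_test",
    "stratify",
    "surrogate_corr",
    "lmm_trial_model",
    "rm_anova_2x2",
    "channel_adjacency",
    "cohens_d",
]


# --------------------------------------------------------------------------- #
# cluster permutation
# --------------------------------------------------------------------------- #


@dataclass
class Cluster:
    mask: np.ndarray
    mass: float
    p: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray
    effect_map: np.ndarray  # Cohen's d
    n_permutations: int
    alpha: float

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p <= self.alpha]

    def significant_mask(self) -> np.ndarray:
        out = np.zeros_like(self.t_map, dtype=bool)
        for c in self.significant:
            out |= c.mask
        return out

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def cohens_d(a: np.ndarray, b: np.ndarray, paired: bool) -> np.ndarray:
    if paired:
        diff = a - b
        sd = diff.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = diff.mean(axis=0) / sd
    else:
        na, nb = a.shape[0], b.shape[0]
        pooled = np.sqrt(
            ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1))
            / (na + nb - 2)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (a.mean(axis=0) - b.mean(axis=0)) / pooled
    return np.nan_to_num(d)


def _t_paired(diff: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff.mean(axis=0) / (sd / np.sqrt(n))
    return np.nan_to_num(t)

def _t_independent(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp * (1 / na + 1 / nb))
    return np.nan_to_num(t)


def _grid_structure(ndim: int) -> np.ndarray:
    # orthogonal neighbours only (4-connectivity in 2D)
    return ndimage.generate_binary_structure(ndim, 1)


def _cluster_masses(t_map, thresh, adjacency):
    """Signed cluster masses and masks.  Returns list of (mask, mass)."""
    out = []
    for sign in (1, -1):
        supra = (sign * t_map) > thresh
        if not supra.any():
            continue
        if adjacency is None:
            labels, n = ndimage.label(supra, structure=_grid_structure(t_map.ndim))
            if n:
                sums = ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1))
                for k in range(1, n + 1):
                    out.append((labels == k, float(sums[k - 1])))
        else:
            out.extend(_graph_clusters(t_map, supra, adjacency))
    return out


def _graph_clusters(t_map, supra, adjacency):
    """Clusters when axis 0 is channels with adjacency matrix ``adjacency`` and
    the remaining axes form a grid."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    shape = t_map.shape
    n_ch = shape[0]
    grid_shape = shape[1:]
    idx = np.flatnonzero(supra.ravel())
    pos = {v: i for i, v in enumerate(idx)}
    rows, cols = [], []

    def flat(ch, grid_flat):
        return ch * int(np.prod(grid_shape)) + grid_flat if grid_shape else ch

    grid_n = int(np.prod(grid_shape)) if grid_shape else 1
    for v in idx:
        ch, g = divmod(v, grid_n)
        # channel neighbours
        for ch2 in np.flatnonzero(adjacency[ch]):
            w = ch2 * grid_n + g
            if w in pos:
                rows.append(pos[v])
                cols.append(pos[w])
        # grid neighbours (orthogonal steps)
        if grid_shape:
            coords = np.unravel_index(g, grid_shape)
            for ax in range(len(grid_shape)):
                for d in (-1, 1):
                    c2 = list(coords)
                    c2[ax] += d
                    if 0 <= c2[ax] < grid_shape[ax]:
                        w = ch * grid_n + int(np.ravel_multi_index(c2, grid_shape))
                        if w in pos:
                            rows.append(pos[v])
                            cols.append(pos[w])
    m = len(idx)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    n_comp, labels = connected_components(graph, directed=False)
    tflat = t_map.ravel()
    out = []
    for k in range(n_comp):
        members = idx[labels == k]
        mask = np.zeros(t_map.size, dtype=bool)
        mask[members] = True
        out.append((mask.reshape(shape), float(tflat[members].sum())))
    return out


def _max_abs_mass(t_map, thresh, adjacency) -> float:
    masses = _cluster_masses(t_map, thresh, adjacency)
    return max((abs(m) for _, m in masses), default=0.0)


def cluster_permutation_test(
    data_a: np.ndarray,
    data_b: np.ndarray,
    paired: bool = True,
    adjacency: np.ndarray | None = None,
    n_perm: int = 500,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int | None = 0,
) -> ClusterResult:
    """Two-tailed cluster-mass permutation test.

    ``data_a``/``data_b``: units x lattice (any number of lattice axes; if
    ``adjacency`` is given, lattice axis 0 is channels).  The cluster-forming
    threshold is the pointwise two-tailed t quantile at ``cluster_alpha``;
    cluster statistic is the summed t (mass); the null is the permutation
    distribution of the maximum absolute mass (sign flips when paired, label
    shuffles otherwise); p values carry the +1 correction.
    """
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("lattice shapes differ")
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired data need equal unit counts")
    if n_perm < int(1 / alpha):
        warnings.warn(f"n_perm={n_perm} cannot resolve p < {1/(n_perm+1):.3g}")
    rng = np.random.default_rng(seed)

    if paired:
        diff = a - b
        df = diff.shape[0] - 1
        t_map = _t_paired(diff)
    else:
        df = a.shape[0] + b.shape[0] - 2
        t_map = _t_independent(a, b)
    thresh = stats.t.ppf(1 - cluster_alpha / 2, df)

    observed = _cluster_masses(t_map, thresh, adjacency)
    effect = cohens_d(a, b, paired)
    if not observed:
        return ClusterResult([], t_map, effect, n_perm, alpha)

    null = np.empty(n_perm)
    if paired:
        n = diff.shape[0]
        for i in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)
            null[i] = _max_abs_mass(_t_paired(diff * signs.reshape((-1,) + (1,) * (diff.ndim - 1))),
                                    thresh, adjacency)
    else:
        pooled = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        for i in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            pa, pb = pooled[perm[:na]], pooled[perm[na:]]
            null[i] = _max_abs_mass(_t_independent(pa, pb), thresh, adjacency)

    clusters = []
    for mask, mass in sorted(observed, key=lambda c: -abs(c[1])):
        p = (1 + np.sum(null >= abs(mass))) / (n_perm + 1)
        clusters.append(Cluster(mask=mask, mass=mass, p=float(p), sign=int(np.sign(mass))))
    return ClusterResult(clusters, t_map, effect, n_perm, alpha)


#: nominal 10-20 electrode positions (mm, flattened scalp projection) for the
#: distance-threshold adjacency; enough for the montages used here.
_POSITIONS_1020 = {
    "Fp1": (-27, 87), "Fp2": (27, 87), "F7": (-71, 51), "F3": (-45, 52),
    "Fz": (0, 54), "F4": (45, 52), "F8": (71, 51), "T7": (-84, 0),
    "C3": (-48, 0), "Cz": (0, 0), "C4": (48, 0), "T8": (84, 0),
    "P7": (-71, -51), "P3": (-45, -52), "Pz": (0, -54), "P4": (45, -52),
    "P8": (71, -51), "O1": (-27, -87), "O2": (27, -87), "POz": (0, -78),
    "Oz": (0, -90), "M1": (-84, -42), "M2": (84, -42), "AFz": (0, 70),
    "FCz": (0, 27),
}


def channel_adjacency(labels, threshold_mm: float = 100.0) -> np.ndarray:
    """Boolean adjacency from a distance threshold on template positions."""
    pos = np.array([_POSITIONS_1020[l] for l in labels], dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = d <= threshold_mm
    np.fill_diagonal(adj, False)
    return adj


# --------------------------------------------------------------------------- #
# stratification
# --------------------------------------------------------------------------- #


@dataclass
class StratifiedSelection:
    kept_a: np.ndarray
    kept_b: np.ndarray
    bin_edges: np.ndarray
    kept_per_bin: np.ndarray  # (n_bins,) counts kept in EACH condition
    summary: dict = field(default_factory=dict)
    empty: bool = False


def stratify(values_a, values_b, n_bins: int = 20, seed: int = 0) -> StratifiedSelection:
    """Equalise two distributions by equal-per-bin subsampling.

    Common bin edges span the pooled range; within each bin
    ``min(count_a, count_b)`` trials are kept from each condition, subsampled
    uniformly with ``seed``.  Zero overlap yields an empty, flagged selection.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    rng = np.random.default_rng(seed)
    edges = np.histogram_bin_edges(np.concatenate([a, b]), bins=n_bins)
    ia = np.clip(np.digitize(a, edges[1:-1]), 0, n_bins - 1)
    ib = np.clip(np.digitize(b, edges[1:-1]), 0, n_bins - 1)
    kept_a, kept_b, per_bin = [], [], np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        idx_a = np.flatnonzero(ia == k)
        idx_b = np.flatnonzero(ib == k)
        m = min(idx_a.size, idx_b.size)
        per_bin[k] = m
        if m == 0:
            continue
        kept_a.append(rng.choice(idx_a, size=m, replace=False))
        kept_b.append(rng.choice(idx_b, size=m, replace=False))
    ka = np.sort(np.concatenate(kept_a)) if kept_a else np.array([], dtype=int)
    kb = np.sort(np.concatenate(kept_b)) if kept_b else np.array([], dtype=int)
    summary = {
        "pre_mean_a": float(a.mean()),
        "pre_mean_b": float(b.mean()),
        "post_mean_a": float(a[ka].mean()) if ka.size else np.nan,
        "post_mean_b": float(b[kb].mean()) if kb.size else np.nan,
        "n_kept": int(ka.size),
    }
    return StratifiedSelection(ka, kb, edges, per_bin, summary, empty=ka.size == 0)


# --------------------------------------------------------------------------- #
# circular-shift surrogate correlation
# --------------------------------------------------------------------------- #


def surrogate_corr(
    x,
    y,
    n_shifts: int = 500,
    seed: int = 0,
    min_shift_frac: float = 0.05,
):
    """Observed Pearson r against a null of circularly shifted copies of y.

    Shift offsets are sampled without replacement from
    ``[ceil(frac*n), n - ceil(frac*n)]``; p carries the +1 correction.
    Returns ``(r_obs, p, r_null)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 10:
        raise ValueError("series must be equal length >= 10")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant series")
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    r_obs = float(np.dot(xz, yz) / n)

    m = int(np.ceil(min_shift_frac * n))
    offsets = np.arange(m, n - m + 1)
    rng = np.random.default_rng(seed)
    if offsets.size > n_shifts:
        offsets = rng.choice(offsets, size=n_shifts, replace=False)
    # r at every circular lag via FFT cross-correlation
    cc = np.fft.irfft(np.fft.rfft(xz) * np.conj(np.fft.rfft(yz)), n=n) / n
    r_null = cc[offsets]
    p = float((1 + np.sum(np.abs(r_null) >= abs(r_obs))) / (offsets.size + 1))
    return r_obs, p, r_null


# --------------------------------------------------------------------------- #
# model contracts (numerics delegated to statsmodels / closed forms)
# --------------------------------------------------------------------------- #


def lmm_trial_model(table: pd.DataFrame):
    """alpha_power ~ state * gaze_dispersion + (1 | subject).

    Returns a dict with fixed-effect estimates, standard errors, p values and
    the converged/singular flags of the underlying solver.
    """
    req = {"alpha_power", "gaze_dispersion", "state", "subject"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    if table["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    if table["state"].nunique() < 2:
        raise ValueError("need >= 2 states")
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "alpha_power ~ state * gaze_dispersion", data=table, groups=table["subject"]
        )
        fit = model.fit(reml=True)
    singular = bool(np.any(np.linalg.eigvalsh(np.atleast_2d(fit.cov_re)) < 1e-10))
    return {
        "estimates": fit.fe_params.to_dict(),
        "se": fit.bse_fe.to_dict(),
        "p_values": fit.pvalues[fit.fe_params.index].to_dict(),
        "converged": bool(fit.converged),
        "singular": singular,
        "result": fit,
    }


def rm_anova_2x2(subject_means: np.ndarray):
    """Classical within-subject 2x2 ANOVA from a (subjects, state, measure)
    array.  Each effect is a 1-df contrast; F = t**2 with df (1, n-1)."""
    x = np.asarray(subject_means, dtype=float)
    if x.ndim != 3 or x.shape[1] != 2 or x.shape[2] != 2:
        raise ValueError("expected subjects x 2 states x 2 measures")
    if not np.isfinite(x).all():
        raise ValueError("missing cells")
    n = x.shape[0]

    def contrast_F(c):
        mean = c.mean()
        sd = c.std(ddof=1)
        if sd == 0:
            return (0.0, 1.0) if mean == 0 else (np.inf, 0.0)
        t = mean / (sd / np.sqrt(n))
        F = t * t
        return float(F), float(stats.f.sf(F, 1, n - 1))

    c_state = x[:, 1, :].mean(axis=1) - x[:, 0, :].mean(axis=1)
    c_measure = x[:, :, 1].mean(axis=1) - x[:, :, 0].mean(axis=1)
    c_inter = (x[:, 1, 1] - x[:, 1, 0]) - (x[:, 0, 1] - x[:, 0, 0])
    out = {}
    for name, c in [("state", c_state), ("measure", c_measure), ("interaction", c_inter)]:
        F, p = contrast_F(c)
        out[name] = {"F": F, "p": p, "df": (1, n - 1)}
    return out
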