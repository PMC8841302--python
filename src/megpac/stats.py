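"""Group statistics: pointwise F/FDR/t on band-power time courses and the
2-D cluster-based permutation test on comodulograms.

The cluster test controls family-wise error over the (phase frequency x
amplitude frequency) grid non-parametrically: per-bin two-sample t values
above the cluster-forming threshold are grouped into 4-connected clusters
separately by sign, each cluster's mass is the sum of its t values, and the
observed masses are referred to the permutation distribution of the maximum
absolute cluster mass under random relabelling of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .containers import Comodulogram

#: 4-neighbourhood (von Neumann) connectivity for 2-D cluster formation
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


# ---------------------------------------------------------------------------
# pointwise band-power statistics


@dataclass
class PointwiseResult:
    f_values: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray            # bins surviving BH-FDR
    undefined: np.ndarray       # bins with zero within-group variance


def pointwise_f_fdr(groups: list[np.ndarray], q: float = 0.05) -> PointwiseResult:
    """One-way F test per time bin across groups, BH-FDR corrected.

    ``groups`` is a list of (subjects x time bins) arrays on a common time
    grid. Bins with zero within-group variance (F undefined) are flagged
    and excluded from the FDR family.
    """
    if len(groups) < 2 or any(g.shape[0] < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    n_bins = groups[0].shape[1]
    if any(g.shape[1] != n_bins for g in groups):
        raise ValueError("groups must share the time grid")
    f_vals = np.full(n_bins, np.nan)
    p_vals = np.full(n_bins, np.nan)
    undefined = np.zeros(n_bins, dtype=bool)
    k = len(groups)
    n_tot = sum(g.shape[0] for g in groups)
    grand = np.vstack(groups).mean(axis=0)
    ssb = sum(g.shape[0] * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    undefined = ssw <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_vals = (ssb / (k - 1)) / (ssw / (n_tot - k))
    p_vals = stats.f.sf(f_vals, k - 1, n_tot - k)
    mask = np.zeros(n_bins, dtype=bool)
    family = ~undefined & np.isfinite(p_vals)
    if family.any():
        rej, _, _, _ = multipletests(p_vals[family], alpha=q, method="fdr_bh")
        mask[family] = rej
    f_vals[undefined] = np.nan
    p_vals[undefined] = np.nan
    return PointwiseResult(f_vals, p_vals, mask, undefined)


def anova_from_summary(means, sds, ns) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from per-group mean/sd/n summaries.

    Algebraically identical to the raw-data ANOVA when the summaries are
    computed from the raw data. Returns (F, p).
    """
    m, s, n = (np.asarray(a, dtype=float) for a in (means, sds, ns))
    k = m.size
    if k < 2 or np.any(n < 2):
        raise ValueError("need >= 2 groups with n >= 2")
    grand = np.sum(n * m) / np.sum(n)
    ssb = np.sum(n * (m - grand) ** 2)
    ssw = np.sum((n - 1) * s**2)
    df_b, df_w = k - 1, int(np.sum(n)) - k
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(stats.f.sf(f, df_b, df_w))


def posthoc_t(group_a: np.ndarray, group_b: np.ndarray, bins: np.ndarray | None = None):
    """Pooled-variance two-sample t per retained time bin.

    Returns (t, p) arrays over the retained bins (all bins when ``bins`` is
    None).
    """
    a, b = np.atleast_2d(group_a), np.atleast_2d(group_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs >= 2 subjects")
    if bins is not None:
        bins = np.asarray(bins)
        if bins.dtype == bool:
            if not bins.any():
                raise ValueError("empty bin mask")
            a, b = a[:, bins], b[:, bins]
        else:
            a, b = a[:, bins], b[:, bins]
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    return np.atleast_1d(t), np.atleast_1d(p)


# ---------------------------------------------------------------------------
# cluster-based permutation test


@dataclass
class ClusterTestResult:
    stat_map: np.ndarray
    cluster_masks: list = field(default_factory=list)       # boolean maps
    cluster_masses: np.ndarray = field(default_factory=lambda: np.empty(0))
    cluster_signs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    null_max_masses: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    cluster_alpha: float = 0.05

    def significant(self, alpha: float = 0.05, sign: int | None = None) -> list:
        """Indices of clusters with p <= alpha (optionally of one sign)."""
        out = []
        for i, p in enumerate(self.p_values):
            if p <= alpha and (sign is None or self.cluster_signs[i] == sign):
                out.append(i)
        return out


def _t_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for stacked (subjects x bins) arrays."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = ((a - ma) ** 2).sum(axis=0)
    vb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (va + vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return np.where(np.isfinite(t), t, 0.0)


def _clusters(t_map: np.ndarray, thresh: float):
    """4-connected suprathreshold clusters, separately by sign."""
    masks, masses, signs = [], [], []
    for sign, sup in ((1, t_map > thresh), (-1, t_map < -thresh)):
        labelled, n = ndimage.label(sup, structure=_CROSS)
        for c in range(1, n + 1):
            mask = labelled == c
            masks.append(mask)
            masses.append(float(t_map[mask].sum()))
            signs.append(sign)
    return masks, np.asarray(masses), np.asarray(signs, dtype=int)


def cluster_permutation(
    group_a: list[Comodulogram] | np.ndarray,
    group_b: list[Comodulogram] | np.ndarray,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | int | None = 0,
) -> ClusterTestResult:
    """Two-sample cluster-based permutation test on 2-D coupling maps.

    Group labels are shuffled ``n_permutations`` times; each shuffle
    contributes its maximum absolute cluster mass to the reference
    distribution, and each observed cluster's p-value is
    ``(1 + #{null >= |mass|}) / (1 + P)`` — the observed labelling counts
    itself, so p can never be zero. All bins subthreshold yields a result
    with zero clusters, not an error.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    a = _stack(group_a)
    b = _stack(group_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs >= 2 subjects")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("comodulogram grids differ between groups")
    rng = np.random.default_rng(rng)
    shape = a.shape[1:]
    na = a.shape[0]
    x = np.concatenate([a, b], axis=0).reshape(a.shape[0] + b.shape[0], -1)
    df = x.shape[0] - 2
    t_crit = stats.t.ppf(1 - cluster_alpha / 2, df)

    t_obs = _t_map(x[:na], x[na:]).reshape(shape)
    masks, masses, signs = _clusters(t_obs, t_crit)

    null = np.zeros(n_permutations)
    idx = np.arange(x.shape[0])
    for p in range(n_permutations):
        perm = rng.permutation(idx)
        t_p = _t_map(x[perm[:na]], x[perm[na:]]).reshape(shape)
        _, m_p, _ = _clusters(t_p, t_crit)
        null[p] = np.max(np.abs(m_p)) if m_p.size else 0.0

    p_values = np.array(
        [(1 + np.sum(null >= abs(m))) / (1 + n_permutations) for m in masses]
    )
    return ClusterTestResult(
        stat_map=t_obs,
        cluster_masks=masks,
        cluster_masses=masses,
        cluster_signs=signs,
        null_max_masses=null,
        p_values=p_values,
        cluster_alpha=cluster_alpha,
    )


def _stack(group) -> np.ndarray:
    if isinstance(group, np.ndarray):
        return np.asarray(group, dtype=float)
    return np.stack([c.values for c in group], axis=0)


def cluster_mean_strength(subject: Comodulogram | np.ndarray, mask: np.ndarray) -> float:
    """Subject-level cluster strength: mean coupling over the cluster bins."""
    values = subject.values if isinstance(subject, Comodulogram) else np.asarray(subject)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape does not match comodulogram")
    if not mask.any():
        raise ValueError("empty cluster mask")
    return float(values[mask].mean())
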