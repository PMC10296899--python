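"""Unsupervised random-forest clustering of complexity features.

The clustering arm stratifies subjects by their multiscale-entropy features
without using the hemodynamic labels:

1. features with a Bayes factor ≥ 3 (moderate evidence or better for a
   group difference) are selected and z-scored;
2. a synthetic reference set is built by independently permuting each
   feature column, destroying the joint structure while keeping marginals;
3. a random forest is trained to discriminate real from reference rows, and
   the proximity of two subjects is the fraction of trees in which they
   land in the same terminal leaf;
4. subjects are partitioned by PAM (k-medoids) on the distance
   √(1 − proximity) for k = 2..k_max;
5. k is chosen by the minimum of a spherical-Gaussian BIC computed in the
   standardized feature space.

The 2×2 cluster-by-group table is then summarized as the relative risk of
low-complexity-cluster members being hemodynamically unstable, with a Katz
log-method 95% CI and a continuity-corrected chi-square p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterAssignment",
    "RelativeRiskResult",
    "select_features",
    "rf_cluster",
    "pam",
    "bic_select_k",
    "contingency",
    "relative_risk",
]


@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray  # 1-based cluster ids, aligned with input rows
    bic_by_k: dict[int, float]
    proximity: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    subjects: list[str] = field(default_factory=list)


@dataclass
class RelativeRiskResult:
    rr: float
    ci95: tuple[float, float]
    p_value: float
    continuity_corrected_cells: bool = False


def select_features(bf_by_feature: dict[str, float],
                    threshold: float = 3.0) -> list[str]:
    """Features whose BF10 meets the moderate-evidence gate, input order.

    Raises when nothing passes — the caller should reconsider the threshold
    rather than cluster on an empty feature set.
    """
    selected = [f for f, bf in bf_by_feature.items() if bf >= threshold]
    if not selected:
        raise ValueError(
            f"no feature reaches BF10 >= {threshold}; review the evidence "
            "threshold before clustering"
        )
    return selected


def pam(dist: np.ndarray, k: int) -> np.ndarray:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Deterministic BUILD + SWAP: greedy medoid seeding followed by
    best-improvement swaps until convergence; ties break to the lowest
    index.  Returns 0-based cluster labels.
    """
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = np.min(dist[:, medoids], axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    # SWAP
    def cost(meds: list[int]) -> float:
        return float(np.min(dist[:, meds], axis=1).sum())

    best_cost = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1:])
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost = c
                    medoids = trial
                    improved = True
    labels = np.argmin(dist[:, medoids], axis=1)
    return labels


def bic_select_k(
    x: np.ndarray, labels_by_k: dict[int, np.ndarray]
) -> tuple[int, dict[int, float]]:
    """Pick k by the minimum spherical-Gaussian classification BIC.

    Each candidate partition is scored as a hard-assignment mixture of
    spherical Gaussians with shared variance and multinomial cluster
    weights:

        BIC(k) = 2·Σ_c n_c·ln(n/n_c) + n·d·ln(2π σ̂²_k) + d·(n−k)
                 + k·(d+1)·ln(n)

    with σ̂²_k = SSE_k / (d·(n−k)) the pooled within-cluster per-dimension
    variance about cluster centroids.  The multinomial assignment term is
    what keeps the criterion from rewarding arbitrary splits of a single
    Gaussian cluster: refitting σ̂² after any balanced split always lowers
    the variance term at small n, and without the assignment cost a
    hard-assignment BIC degenerates into "more clusters is always better".
    Identical partitions submitted under different k differ only through
    the parameter penalty; partitions with zero pooled variance are
    degenerate and skipped.
    """
    if len(labels_by_k) < 2:
        raise ValueError("need at least two candidate partitions")
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    bics: dict[int, float] = {}
    for k, lab in labels_by_k.items():
        sse = 0.0
        assign = 0.0
        for c in np.unique(lab):
            pts = x[lab == c]
            sse += float(((pts - pts.mean(axis=0)) ** 2).sum())
            assign += 2.0 * len(pts) * math.log(n / len(pts))
        if sse <= 0 or n <= k:
            warnings.warn(f"degenerate partition at k={k} (zero variance); "
                          "skipped", stacklevel=2)
            continue
        var = sse / (d * (n - k))
        bics[k] = (assign + n * d * math.log(2.0 * math.pi * var)
                   + d * (n - k) + k * (d + 1) * math.log(n))
    if not bics:
        raise ValueError("all candidate partitions degenerate")
    best = min(sorted(bics), key=lambda k: bics[k])
    return best, bics


def rf_cluster(
    features: pd.DataFrame | np.ndarray,
    k_max: int = 5,
    n_trees: int = 500,
    seed: int = 0,
) -> ClusterAssignment:
    """Unsupervised random-forest clustering (synthetic-contrast method).

    See the module docstring for the construction.  Deterministic given the
    seed; constant feature columns are dropped with a warning.
    """
    from sklearn.ensemble import RandomForestClassifier

    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        subjects = [str(i) for i in features.index]
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
        subjects = [str(i) for i in range(x.shape[0])]
    n = x.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < 2 * k_max:
        raise ValueError("need at least 2*k_max subjects")
    if np.isnan(x).any():
        raise ValueError("missing values in feature matrix")

    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [names[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping constant feature columns: {dropped}",
                      stacklevel=2)
        x, names = x[:, keep], [nm for nm, k_ in zip(names, keep) if k_]
        sd = sd[keep]
    z = (x - x.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    ref = np.column_stack([rng.permutation(z[:, j]) for j in range(z.shape[1])])
    x_train = np.vstack([z, ref])
    y_train = np.concatenate([np.ones(n), np.zeros(n)])
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(rng.integers(2 ** 31)),
        n_jobs=1,
    )
    rf.fit(x_train, y_train)
    leaves = rf.apply(z)  # (n, n_trees)
    proximity = (leaves[:, None, :] == leaves[None, :, :]).mean(axis=2)
    np.fill_diagonal(proximity, 1.0)

    dist = np.sqrt(np.clip(1.0 - proximity, 0.0, None))
    labels_by_k = {k: pam(dist, k) for k in range(2, k_max + 1)}
    if len(labels_by_k) == 1:
        # k_max=2 fixes the dichotomy; BIC still reported for the record
        k_best, bics = bic_select_k(z, {**labels_by_k, 1: np.zeros(n, int)})
        k_best, bics = 2, {2: bics[2]}
    else:
        k_best, bics = bic_select_k(z, labels_by_k)
    return ClusterAssignment(
        k=k_best,
        labels=labels_by_k[k_best] + 1,
        bic_by_k=bics,
        proximity=proximity,
        feature_names=names,
        subjects=subjects,
    )


def contingency(cluster_labels: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """2×2 cluster-by-group counts (rows Cluster 1/2, columns HS/HU)."""
    cluster_labels = np.asarray(cluster_labels)
    groups = np.asarray(groups)
    clusters = np.unique(cluster_labels)
    if clusters.size != 2:
        raise ValueError(
            f"contingency analysis needs exactly two clusters, got "
            f"{clusters.size}"
        )
    if set(np.unique(groups)) != {"HS", "HU"}:
        raise ValueError("groups must contain both HS and HU")
    table = pd.crosstab(pd.Series(cluster_labels, name="cluster"),
                        pd.Series(groups, name="group"))
    table = table.reindex(index=sorted(clusters), columns=["HS", "HU"],
                          fill_value=0)
    return table


def relative_risk(table: pd.DataFrame | np.ndarray) -> RelativeRiskResult:
    """Relative risk of the Cluster-2 outcome for HU vs HS patients.

    The table rows are Cluster 1 (high complexity) and Cluster 2 (low
    complexity), columns HS and HU.  Exposure is group membership (HU
    exposed, HS unexposed) and the outcome is assignment to the
    low-complexity Cluster 2:

        rr = (a/(a+b)) / (c/(c+d))

    with a = HU∩C2, a+b = all HU, c = HS∩C2, c+d = all HS — the Cluster-2
    rate among unstable patients over the Cluster-2 rate among stable ones.
    The CI is exp(ln rr ± 1.96·SE) with the Katz log standard error
    √(1/a − 1/(a+b) + 1/c − 1/(c+d)); the p-value is the
    continuity-corrected chi-square test of the table.  Zero cells get a
    0.5 continuity correction (flagged).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    # rows: cluster 1, cluster 2; columns: HS, HU
    a = t[1, 1]  # HU in cluster 2
    b = t[0, 1]  # HU in cluster 1
    c = t[1, 0]  # HS in cluster 2
    d_ = t[0, 0]  # HS in cluster 1
    corrected = False
    if min(a, b, c, d_) == 0:
        a, b, c, d_ = a + 0.5, b + 0.5, c + 0.5, d_ + 0.5
        corrected = True
    exposed_n = a + b      # HU total
    unexposed_n = c + d_   # HS total
    rr = (a / exposed_n) / (c / unexposed_n)
    se = math.sqrt(1.0 / a - 1.0 / exposed_n + 1.0 / c - 1.0 / unexposed_n)
    zcrit = 1.959963984540054
    ci = (rr * math.exp(-zcrit * se), rr * math.exp(zcrit * se))
    chi2 = stats.chi2_contingency(np.asarray(table, dtype=float),
                                  correction=True)
    return RelativeRiskResult(rr=rr, ci95=ci, p_value=float(chi2.pvalue),
                              continuity_corrected_cells=corrected)
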