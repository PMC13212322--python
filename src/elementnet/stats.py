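"""Permutation-based multivariate community statistics.

PERMANOVA partitions the squared dissimilarities of a distance matrix into
between- and within-group sums of squares:

    SS_total  = sum_{i<j} d_ij^2 / n
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    pseudo-F  = (SS_between/(g-1)) / (SS_within/(n-g)),  R^2 = SS_b/SS_t

PERMDISP (beta-dispersion) embeds the matrix by principal coordinates
(Gower centering; negative-eigenvalue axes enter with negative squared
distance, the standard imaginary-part correction), measures each sample's
distance to its group centroid, and applies a one-way F test to those
distances.  Both tests permute group labels; p = (#{F_perm >= F_obs} + 1) /
(n_perm + 1), so p is floored at 1/(n_perm+1) and exactly reproducible for
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from elementnet.abundance import DissimilarityMatrix


@dataclass
class PermutationTestResult:
    test: str
    statistic: float
    p: float
    n_perm: int
    seed: int
    r_squared: float | None = None

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic, "p": self.p, "n_perm": self.n_perm, "seed": self.seed}
        if self.r_squared is not None:
            d["r_squared"] = self.r_squared
        return d


def _check_labels(d: DissimilarityMatrix, labels) -> np.ndarray:
    labels = pd.Series(labels)
    if not isinstance(labels.index, pd.RangeIndex):  # keyed by sample id
        labels = labels.reindex(d.labels)
    if len(labels) != len(d.labels):
        raise ValueError("label vector length does not match matrix")
    if labels.isna().any():
        raise ValueError("missing group label for some samples")
    groups, counts = np.unique(labels.to_numpy(), return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = groups[counts.argmin()]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    codes = pd.Categorical(labels.to_numpy()).codes.astype(int)
    return codes


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)  # full matrix double-counts pairs
    ss_within = 0.0
    for gcode in range(n_groups):
        mask = codes == gcode
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(d: DissimilarityMatrix, labels, n_perm: int = 9999, seed: int = 0) -> PermutationTestResult:
    """One-factor PERMANOVA with unrestricted label permutations."""
    codes = _check_labels(d, labels)
    n_groups = int(codes.max()) + 1
    d2 = d.values**2
    if d2.sum() == 0:
        raise ValueError("degenerate input: all samples identical (SS_total = 0)")
    f_obs, r2 = _pseudo_f(d2, codes, n_groups)

    rng = np.random.default_rng(seed)
    n = len(codes)
    perms = np.stack([rng.permutation(codes) for _ in range(n_perm)])  # n_perm x n
    # Vectorized within-group SS over all permutations.
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(n_perm)
    for gcode in range(n_groups):
        m = (perms == gcode).astype(float)  # n_perm x n
        ng = m[0].sum()  # group sizes are permutation-invariant
        ss_within += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * ng)
    ss_between = ss_total - ss_within
    f_perm = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    p = (np.sum(f_perm >= f_obs - 1e-12) + 1.0) / (n_perm + 1.0)
    return PermutationTestResult("permanova", float(f_obs), float(p), n_perm, seed, r_squared=float(r2))


def _pcoa_coords(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates split into real and 'imaginary' axes.

    Returns (coords_pos, coords_neg): axes from positive eigenvalues carry
    ordinary squared distance, axes from negative eigenvalues subtract."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    tol = 1e-10 * max(1.0, np.abs(evals).max())
    pos = evals > tol
    neg = evals < -tol
    coords_pos = evecs[:, pos] * np.sqrt(evals[pos])
    coords_neg = evecs[:, neg] * np.sqrt(-evals[neg])
    return coords_pos, coords_neg


def _dispersion_distances(d: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    cp, cn = _pcoa_coords(d)
    z = np.empty(len(codes))
    for gcode in range(n_groups):
        mask = codes == gcode
        cen_p = cp[mask].mean(axis=0)
        cen_n = cn[mask].mean(axis=0) if cn.shape[1] else np.zeros(0)
        d2 = ((cp[mask] - cen_p) ** 2).sum(axis=1)
        if cn.shape[1]:
            d2 = d2 - ((cn[mask] - cen_n) ** 2).sum(axis=1)
        z[mask] = np.sqrt(np.clip(d2, 0.0, None))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_b = sum(((z[codes == g].mean() - grand) ** 2) * (codes == g).sum() for g in range(n_groups))
    ss_w = sum(((z[codes == g] - z[codes == g].mean()) ** 2).sum() for g in range(n_groups))
    if ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / (n_groups - 1)) / (ss_w / (n - n_groups))


def permdisp(d: DissimilarityMatrix, labels, n_perm: int = 999, seed: int = 0) -> PermutationTestResult:
    """Beta-dispersion: F test on distances to group centroids in PCoA space,
    with a label-permutation p-value (distances held fixed, labels shuffled)."""
    codes = _check_labels(d, labels)
    n_groups = int(codes.max()) + 1
    z = _dispersion_distances(d.values, codes, n_groups)
    f_obs = _anova_f(z, codes, n_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _anova_f(z, perm, n_groups) >= f_obs - 1e-12:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    return PermutationTestResult("permdisp", float(f_obs), float(p), n_perm, seed)
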