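"""Fitness and community statistics.

Implements the Malthusian relative-fitness measure

    S = ln(evolved_end / evolved_start) - ln(ancestor_end / ancestor_start),

ancestor-standardization of phenotype measurements, the Jaccard distance on
mutation presence/absence profiles, and a from-scratch one-way permutational
MANOVA in Anderson's distance-based formulation (the statistic computed by
vegan's ``adonis`` for a single factor):

    F = [SS_between / (a - 1)] / [SS_within / (n - a)]

with SS_total = (1/n) * sum_{i<j} d_ij^2 and SS_within the analogous
within-group sums. The permutation p-value uses the (count + 1)/(n_perm + 1)
estimator for sampled permutations, or the exact fraction over all distinct
label assignments (observed included) in exhaustive mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CompetitionAssay",
    "CompetitionResult",
    "PermanovaResult",
    "malthusian_selection",
    "standardize_to_ancestor",
    "jaccard_distance",
    "jaccard_matrix",
    "pseudo_f",
    "permanova",
    "ancestor_baseline_tests",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class CompetitionAssay:
    """Paired start/end CFU counts of an evolved clone and the ancestor."""

    evolved_start: float
    evolved_end: float
    ancestor_start: float
    ancestor_end: float
    environment: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("evolved_start", "evolved_end", "ancestor_start", "ancestor_end"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(
                    f"{name} must be strictly positive and finite (got {v!r}); "
                    "substitute the detection limit for zero counts upstream"
                )


@dataclass(frozen=True)
class CompetitionResult:
    S: float
    environment: str = ""
    replicate: int = 0


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def malthusian_selection(assay: CompetitionAssay) -> CompetitionResult:
    """Relative fitness S as the difference of Malthusian parameters.

    S = 0 means equal fitness; S > 0 means the evolved competitor
    outgrew the ancestor over the assay.
    """
    S = math.log(assay.evolved_end / assay.evolved_start) - math.log(
        assay.ancestor_end / assay.ancestor_start
    )
    return CompetitionResult(S=S, environment=assay.environment,
                             replicate=assay.replicate)


def standardize_to_ancestor(
    values: Sequence[float], ancestor_values: Sequence[float]
) -> np.ndarray:
    """Subtract the ancestor mean, so the ancestral baseline maps to 0."""
    anc = np.asarray(ancestor_values, dtype=float)
    if anc.size == 0:
        raise ValueError("ancestor_values must be non-empty")
    return np.asarray(values, dtype=float) - anc.mean()


def jaccard_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """1 - |intersection| / |union| on binary presence/absence vectors.

    Two all-zero vectors (clone pairs with no mutations) are at distance 0
    by convention, with a warning.
    """
    a_arr = np.asarray(a)
    b_arr = np.asarray(b)
    if a_arr.shape != b_arr.shape or a_arr.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if not (np.isin(a_arr, (0, 1)).all() and np.isin(b_arr, (0, 1)).all()):
        raise ValueError("entries must be binary (0/1)")
    union = np.logical_or(a_arr, b_arr).sum()
    if union == 0:
        warnings.warn(
            "Jaccard distance of two all-zero vectors defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    inter = np.logical_and(a_arr, b_arr).sum()
    return 1.0 - inter / union


def jaccard_matrix(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Jaccard distance matrix over the rows of a binary matrix."""
    arr = np.asarray(X)
    n = arr.shape[0]
    D = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = jaccard_distance(arr[i], arr[j])
    return D


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square matrix")
    if not np.allclose(D, D.T):
        raise ValueError("D must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("D must have a zero diagonal")
    return D


def _ss_terms(D2: np.ndarray, codes: np.ndarray, group_sizes: np.ndarray):
    n = D2.shape[0]
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for g, n_g in enumerate(group_sizes):
        x = (codes == g).astype(float)
        ss_within += x @ D2 @ x / (2.0 * n_g)
    return ss_total, ss_within


def pseudo_f(D: np.ndarray, groups: Sequence) -> float:
    """Distance-based pseudo-F for a one-way design."""
    D = _validate_distance_matrix(D)
    codes, sizes = _encode_groups(groups, D.shape[0])
    return _pseudo_f_from_codes(D**2, codes, sizes)


def _encode_groups(groups: Sequence, n: int) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.Series(list(groups))
    if len(labels) != n:
        raise ValueError("groups length must match the distance matrix")
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    return codes.astype(np.int64), sizes


def _pseudo_f_from_codes(D2: np.ndarray, codes: np.ndarray,
                         sizes: np.ndarray) -> float:
    n = D2.shape[0]
    a = len(sizes)
    ss_total, ss_within = _ss_terms(D2, codes, sizes)
    if ss_total <= 0:
        raise ValueError("degenerate distance matrix: no variance to partition")
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return math.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _f_for_permutations(D2: np.ndarray, perms: np.ndarray,
                        sizes: np.ndarray) -> np.ndarray:
    """Vectorized pseudo-F over a (P, n) array of label-code rows."""
    n = D2.shape[0]
    a = len(sizes)
    ss_total = D2.sum() / (2.0 * n)
    ss_within = np.zeros(perms.shape[0])
    for g, n_g in enumerate(sizes):
        X = (perms == g).astype(float)
        ss_within += np.einsum("pi,ij,pj->p", X, D2, X) / (2.0 * n_g)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):
        return (ss_between / (a - 1)) / (ss_within / (n - a))


def _distinct_assignments(codes: np.ndarray) -> np.ndarray:
    from sympy.utilities.iterables import multiset_permutations

    perms = list(multiset_permutations(codes.tolist()))
    return np.array(perms, dtype=np.int64)


def permanova(
    D: np.ndarray,
    groups: Sequence,
    n_perm: int = 9999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Sampled mode draws ``n_perm`` uniform permutations of the labels (which
    preserves group sizes) and reports p = (#{F_perm >= F_obs} + 1) /
    (n_perm + 1). Exhaustive mode enumerates every distinct assignment of
    labels to samples and reports the exact fraction attaining F >= F_obs,
    with the observed assignment included. Permuted statistics within 1e-12
    of the observed count as >=.
    """
    D = _validate_distance_matrix(D)
    codes, sizes = _encode_groups(groups, D.shape[0])
    D2 = D**2
    f_obs = _pseudo_f_from_codes(D2, codes, sizes)

    if exhaustive:
        perms = _distinct_assignments(codes)
        f_all = _f_for_permutations(D2, perms, sizes)
        count = int(np.sum(f_all >= f_obs - _TIE_TOL))
        return PermanovaResult(
            pseudo_F=f_obs,
            p_value=count / len(perms),
            n_permutations=len(perms),
            exhaustive=True,
        )

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    f_perm = _f_for_permutations(D2, perms, sizes)
    count = int(np.sum(f_perm >= f_obs - _TIE_TOL))
    return PermanovaResult(
        pseudo_F=f_obs,
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        exhaustive=False,
    )


def ancestor_baseline_tests(
    values_by_group: dict[str, Sequence[float]],
    popmean: float = 0.0,
    correction: str = "bonferroni",
    sign_flip: bool = False,
    n_perm: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-sample location tests against the ancestor baseline.

    Thin pass-through to ``scipy.stats.ttest_1samp`` with multiple-testing
    correction via statsmodels; ``sign_flip=True`` adds a sign-flip
    permutation alternative for each group. Plumbing, not a contribution.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    rng = np.random.default_rng(seed)
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        t, p = sps.ttest_1samp(arr, popmean)
        row = {"group": name, "n": arr.size, "mean": arr.mean(),
               "t": float(t), "p_value": float(p)}
        if sign_flip:
            centered = arr - popmean
            obs = abs(centered.mean())
            flips = rng.choice((-1.0, 1.0), size=(n_perm, arr.size))
            perm_means = np.abs((flips * centered).mean(axis=1))
            row["p_sign_flip"] = (np.sum(perm_means >= obs - _TIE_TOL) + 1) / (
                n_perm + 1
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method=correction)[1]
    return out
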