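"""Marker-trait statistics: growth summaries (SGR, CV), regression of
phenotype on allele count with permutation empirical P, BH-FDR,
unrelated-subset sampling and mitochondrial haplotype analysis.

The association statistic is the ordinary-least-squares regression of a
quantitative trait on allele dosage (0/1/2 copies of the A2 allele; 0/1
carriage for haploid haplotypes): slope b_y.x, its t statistic, the
two-sided asymptotic P from the t distribution, and R².  The empirical
P-value is the add-one permutation estimate

    P = (1 + #{ permutations with |t*| >= |t_obs| }) / (K + 1)

with K = 20,000 by default for markers and 10,000 for haplotypes.
Permutations either shuffle the phenotype over all samples (``pooled``)
or only among siblings within each full-sib family (``within_family``),
which preserves family structure under the null.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AssociationResult,
    DegenerateDesignError,
    GenotypeMatrix,
    HaplotypeTable,
    Pedigree,
)


def sgr(bw_a: float, bw_b: float, t_a: float, t_b: float) -> float:
    """Specific growth rate in % per day: 100 * (ln BW_b - ln BW_a)/(t_b - t_a)."""
    if bw_a <= 0 or bw_b <= 0:
        raise ValueError("body weights must be positive")
    if t_b <= t_a:
        raise ValueError("evaluation times must be strictly increasing")
    return 100.0 * (math.log(bw_b) - math.log(bw_a)) / (t_b - t_a)


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation SD/mean (sample SD, ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(x.std(ddof=1) / mean)


def _design(y, dosage, covariates):
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != y.size:
            covariates = covariates.T
        ok = np.isfinite(y) & np.isfinite(dosage) & np.all(np.isfinite(covariates), axis=1)
        return y[ok], dosage[ok], covariates[ok]
    ok = np.isfinite(y) & np.isfinite(dosage)
    return y[ok], dosage[ok], None


def allele_count_regression(
    y: Sequence[float],
    dosage: Sequence[float],
    covariates: Optional[np.ndarray] = None,
    marker: str = "",
    trait: str = "",
) -> AssociationResult:
    """OLS of phenotype on allele count (plus optional covariates).

    Missing pairs are dropped listwise.  Reports slope, t = b/SE(b),
    two-sided asymptotic P with residual degrees of freedom, and the
    model R².  A constant phenotype yields b = 0, t = 0, P = 1; a
    perfectly collinear phenotype yields R² = 1 with the
    ``degenerate_se`` flag set (t reported as +/-inf, P = 0).
    """
    y, x, cov = _design(y, dosage, covariates)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 complete cases")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("allele dosage is constant")

    if cov is None:
        X = np.column_stack([np.ones(n), x])
    else:
        X = np.column_stack([np.ones(n), x, cov])
    p = X.shape[1]
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")

    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return AssociationResult(marker, trait, n, 0.0, 0.0, 1.0, 0.0)

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    r2 = 1.0 - sse / sst
    b = float(beta[1])

    xtx_inv = np.linalg.pinv(X.T @ X)
    if sse <= sst * 1e-12:
        t = math.inf if b > 0 else (-math.inf if b < 0 else 0.0)
        return AssociationResult(
            marker, trait, n, b, t, 0.0 if b != 0 else 1.0, 1.0, degenerate_se=True
        )
    sigma2 = sse / df
    se = math.sqrt(sigma2 * xtx_inv[1, 1])
    t = b / se
    p_asym = 2.0 * stats.t.sf(abs(t), df)
    return AssociationResult(marker, trait, n, b, t, float(p_asym), r2)


def _perm_groups(
    n: int, scheme: str, sample_ids: Optional[Sequence[str]], ped: Optional[Pedigree]
) -> list[np.ndarray]:
    if scheme == "pooled":
        return [np.arange(n)]
    if scheme != "within_family":
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if ped is None or sample_ids is None:
        raise ValueError("within_family scheme requires a pedigree and sample ids")
    fam_of = {s: e.family for s, e in ped.entries.items()}
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(sample_ids):
        groups.setdefault(fam_of.get(s, f"__solo_{s}"), []).append(i)
    return [np.asarray(ix) for ix in groups.values()]


def empirical_p(
    y: Sequence[float],
    dosage: Sequence[float],
    k: int = 20_000,
    scheme: str = "pooled",
    sample_ids: Optional[Sequence[str]] = None,
    ped: Optional[Pedigree] = None,
    covariates: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> tuple[float, AssociationResult]:
    """Permutation empirical P for the allele-count regression.

    Returns ``(p_empirical, observed_result)``; the result carries the
    empirical P and K.  The ``pooled`` scheme permutes the phenotype
    over all samples; ``within_family`` permutes only among siblings of
    the same family (requires ``sample_ids`` aligned with ``y`` and a
    pedigree).  Deterministic for a given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    obs = allele_count_regression(y, dosage, covariates=covariates)
    y_arr, x_arr, cov = _design(y, dosage, covariates)
    n = y_arr.size
    rng = np.random.default_rng(seed)
    groups = _perm_groups(n, scheme, sample_ids, ped)

    obs_t = abs(obs.t)
    if not math.isfinite(obs_t):
        p_emp = 1.0 / (k + 1)
        obs.p_empirical, obs.n_permutations = p_emp, k
        return p_emp, obs

    if cov is None and np.ptp(y_arr) > 0:
        # |t| is monotone in |r|; compare correlations, vectorised
        xc = x_arr - x_arr.mean()
        xnorm = math.sqrt(float(xc @ xc))
        perm_y = np.empty((k, n))
        row = y_arr.copy()
        for i in range(k):
            for g in groups:
                row[g] = row[g][rng.permutation(len(g))]
            perm_y[i] = row
        yc = perm_y - perm_y.mean(axis=1, keepdims=True)
        ynorm = np.sqrt((yc**2).sum(axis=1))
        r_perm = np.abs(yc @ xc) / (ynorm * xnorm)
        yc0 = y_arr - y_arr.mean()
        r_obs = abs(float(yc0 @ xc)) / (math.sqrt(float(yc0 @ yc0)) * xnorm)
        hits = int((r_perm >= r_obs - 1e-15).sum())
    else:
        hits = 0
        row = y_arr.copy()
        for _ in range(k):
            for g in groups:
                row[g] = row[g][rng.permutation(len(g))]
            try:
                t_perm = allele_count_regression(row, x_arr, covariates=cov).t
            except DegenerateDesignError:
                continue
            if abs(t_perm) >= obs_t - 1e-15:
                hits += 1
    p_emp = (hits + 1) / (k + 1)
    obs.p_empirical, obs.n_permutations = p_emp, k
    return p_emp, obs


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values.

    adj_i = min over j >= rank(i) of (m * p_(j) / j), capped at 1.
    Monotone in the order statistics and idempotent.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def sample_unrelated(
    ped: Pedigree,
    genotyped: Iterable[str],
    n_sets: int = 3,
    seed: Optional[int] = None,
) -> list[list[str]]:
    """Draw sets of unrelated individuals: one sibling per family.

    Each of the ``n_sets`` sets samples one genotyped offspring
    uniformly from every family, independently per set, so set size
    equals the number of families (n = 40 in the study design).
    """
    rng = np.random.default_rng(seed)
    genotyped = set(genotyped)
    families = ped.families()
    eligible = {
        fam: [s for s in members if s in genotyped]
        for fam, members in families.items()
    }
    empty = [fam for fam, members in eligible.items() if not members]
    if empty:
        raise ValueError(f"families with no genotyped offspring: {empty[:5]}")
    sets = []
    for _ in range(n_sets):
        sets.append(
            [members[rng.integers(len(members))] for members in eligible.values()]
        )
    return sets


# ---------------------------------------------------------------------------
# mitochondrial haplotypes
# ---------------------------------------------------------------------------


def build_mt_haplotypes(
    gm: GenotypeMatrix,
    marker_order: Sequence[str],
    max_missing: int = 2,
) -> HaplotypeTable:
    """Collapse haploid mitochondrial allele strings into haplotypes.

    Markers are taken in ``marker_order`` (physical position along the
    mitochondrial genome).  Haploid calls are dosage 0 (A1) or 2 (A2);
    het calls are treated as missing.  Samples with complete strings
    define the haplotypes; samples with at most ``max_missing`` missing
    calls are assigned to the unique haplotype consistent with their
    called alleles, otherwise left unassigned.  Frequencies are over
    assigned samples.
    """
    for mid in marker_order:
        if gm.markers[mid].genome != "mito":
            raise ValueError(f"marker {mid} is not mitochondrial")
    calls = gm.calls[list(marker_order)]

    def allele_char(mid: str, dosage: float) -> Optional[str]:
        if pd.isna(dosage) or dosage == 1.0:
            return None
        info = gm.markers[mid]
        return info.a1 if dosage == 0.0 else info.a2

    strings: dict[str, list[Optional[str]]] = {}
    for sample in calls.index:
        strings[sample] = [allele_char(m, calls.at[sample, m]) for m in marker_order]

    complete = {
        s: "".join(chars) for s, chars in strings.items() if None not in chars
    }
    haplotypes = sorted(set(complete.values()))

    assignments: dict[str, Optional[str]] = {}
    for sample, chars in strings.items():
        if sample in complete:
            assignments[sample] = complete[sample]
            continue
        n_missing = sum(c is None for c in chars)
        if n_missing > max_missing:
            assignments[sample] = None
            continue
        compatible = [
            h
            for h in haplotypes
            if all(c is None or c == h[i] for i, c in enumerate(chars))
        ]
        assignments[sample] = compatible[0] if len(compatible) == 1 else None

    assigned = [h for h in assignments.values() if h is not None]
    n_assigned = len(assigned)
    freqs = [assigned.count(h) / n_assigned for h in haplotypes] if n_assigned else []
    return HaplotypeTable(
        marker_order=list(marker_order),
        haplotypes=haplotypes,
        frequencies=freqs,
        assignments=assignments,
    )


def haplotype_association(
    y: Sequence[float],
    carriage: Sequence[int],
    k: int = 10_000,
    seed: Optional[int] = None,
    marker: str = "",
    trait: str = "",
) -> AssociationResult:
    """Regression of phenotype on 0/1 haplotype carriage with empirical P.

    Same regression/permutation contract as the marker analysis; the
    default permutation count is 10,000 for haplotype data.
    """
    _, result = empirical_p(y, carriage, k=k, scheme="pooled", seed=seed)
    result.marker = marker
    result.trait = trait
    return result
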