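"""Phenotype QC, sample pruning, and the five-family association battery.

Trait QC follows the quantitative-sensory-testing protocol being emulated:
individuals reporting severe depression (score > 15) are excluded outright;
then, per trait, extreme outliers beyond +/-2 standard deviations (on the
raw measurement scale) are removed and the survivors natural-log
transformed.  Relatedness is handled by greedy pruning until no pairwise
kinship exceeds 5%.

Association tests are ordinary least squares of a (log) trait on a genetic
dosage term plus eight covariates (sex, age, depression score, five genetic
PCs); the adjusted post-sensitization mechanical threshold additionally
conditions on the pre-sensitization threshold.  Five families of dosage
codings are tested:

  (i)   single-locus dosages at the two focal loci, across all traits and
        the adjusted trait (2 x 7 = 14 tests);
  (ii)  both loci jointly in one model (2 betas);
  (iii) copy counts of each of the four two-locus haplotypes, the fully
        ancestral one recoded as its complement (any-archaic count) so all
        effects point the same way (4 tests);
  (iv)  the sum of archaic alleles over both loci, 0-4 (1 test);
  (v)   archaic-copy counts at each retained admixture-mapping segment.

With 34 retained segments this yields the 55-test battery controlled
study-wide by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from archpain.admixmap import Segment

__all__ = [
    "TRAITS",
    "COVARIATES",
    "AssocResult",
    "BatteryConfig",
    "prepare_phenotypes",
    "kinship_prune",
    "fit_linear_adjusted",
    "haplotype_copy_counts",
    "run_test_battery",
    "bh_threshold",
]

TRAITS = ("PPT", "HPT", "MPT", "WUR", "POST_HPT", "POST_MPT")
COVARIATES = ("sex", "age", "depression", "PC1", "PC2", "PC3", "PC4", "PC5")
FAMILIES = ("single_locus", "joint", "haplotype", "allele_sum", "segment")


@dataclass(frozen=True)
class AssocResult:
    test_id: str
    family: str
    trait: str
    beta: float
    se: float
    p: float
    n: int


@dataclass
class BatteryConfig:
    traits: tuple[str, ...] = TRAITS
    focal_trait: str = "POST_MPT"
    adjust_for: str = "MPT"
    covariates: tuple[str, ...] = COVARIATES
    locus_labels: tuple[str, str] = ("locusA", "locusB")
    fdr_q: float = 0.05


# ---------------------------------------------------------------------------
# phenotype QC
# ---------------------------------------------------------------------------

def prepare_phenotypes(
    raw: pd.DataFrame,
    traits: Sequence[str] = TRAITS,
    sd_mult: float = 2.0,
    depression_cutoff: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trait outlier trimming and log transform, plus depression exclusion.

    Severe-depression individuals (score strictly > ``depression_cutoff``)
    are dropped entirely.  Then, per trait, values outside
    mean +/- ``sd_mult``*SD — both computed on the raw scale over non-missing
    values (sample SD) — are set missing, and survivors are natural-log
    transformed.  Non-positive survivors cannot be logged and are likewise
    excluded.  Every exclusion is logged with sample, trait and reason.
    """
    if raw["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids")
    exclusions: list[dict] = []
    severe = raw["depression"] > depression_cutoff
    for sid in raw.loc[severe, "sample_id"]:
        exclusions.append({"sample_id": sid, "trait": None, "reason": "severe_depression", "value": np.nan})
    out = raw.loc[~severe].copy().reset_index(drop=True)
    for trait in traits:
        vals = out[trait].astype(float)
        obs = vals.dropna()
        if obs.empty:
            continue
        m, sd = obs.mean(), obs.std(ddof=1)
        if np.isnan(sd):
            sd = 0.0
        lo, hi = m - sd_mult * sd, m + sd_mult * sd
        outlier = (vals < lo) | (vals > hi)
        for sid, v in zip(out.loc[outlier, "sample_id"], vals[outlier]):
            exclusions.append({"sample_id": sid, "trait": trait, "reason": "outlier_2sd", "value": v})
        vals[outlier] = np.nan
        nonpos = vals <= 0
        for sid, v in zip(out.loc[nonpos, "sample_id"], vals[nonpos]):
            exclusions.append({"sample_id": sid, "trait": trait, "reason": "nonpositive", "value": v})
        vals[nonpos] = np.nan
        out[trait] = np.log(vals)
    log = pd.DataFrame(exclusions, columns=["sample_id", "trait", "reason", "value"])
    return out, log


def kinship_prune(
    kinship: np.ndarray, sample_ids: Sequence[str], max_kin: float = 0.05
) -> list[str]:
    """Greedy removal until no pairwise kinship exceeds ``max_kin``.

    At each step the individual in the most violating pairs is removed;
    ties broken by larger total kinship, then lexicographic id.
    """
    K = np.asarray(kinship, dtype=float)
    n = len(sample_ids)
    if K.shape != (n, n):
        raise ValueError("kinship matrix shape does not match sample ids")
    if not np.allclose(K, K.T):
        raise ValueError("kinship matrix must be symmetric")
    K = K.copy()
    np.fill_diagonal(K, 0.0)
    active = np.ones(n, dtype=bool)
    removed: list[str] = []
    while True:
        A = K[np.ix_(active, active)]
        if (A <= max_kin).all():
            break
        idx_active = np.flatnonzero(active)
        viol = (A > max_kin).sum(axis=1)
        worst = viol.max()
        cand = np.flatnonzero(viol == worst)
        totals = A[cand].sum(axis=1)
        cand = cand[totals == totals.max()]
        names = [sample_ids[idx_active[c]] for c in cand]
        pick = idx_active[cand[int(np.argmin(names))]]
        active[pick] = False
        removed.append(sample_ids[pick])
    return removed


# ---------------------------------------------------------------------------
# linear model
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        collinear = [names[i] for i in sorted(piv[rank:])]
        raise np.linalg.LinAlgError(f"design matrix rank-deficient; collinear columns: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, pvals, dof


def fit_linear_adjusted(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    dosage_names: Sequence[str] | None = None,
) -> list[dict]:
    """OLS of y on [intercept, dosage term(s), covariates]; complete cases.

    Returns one record per dosage term with ``beta``, ``se``, ``p`` (from
    the t statistic at n - k - 1 df) and the analysed ``n``.
    """
    y = np.asarray(y, dtype=float)
    D = np.asarray(dosage, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    if isinstance(covariates, pd.DataFrame):
        cov_names = list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cov_names = [f"cov{i}" for i in range(C.shape[1])]
    if dosage_names is None:
        dosage_names = [f"dosage{i}" for i in range(D.shape[1])]
    keep = ~(np.isnan(y) | np.isnan(D).any(axis=1) | np.isnan(C).any(axis=1))
    y, D, C = y[keep], D[keep], C[keep]
    n = int(keep.sum())
    X = np.column_stack([np.ones(n), D, C])
    names = ["intercept", *dosage_names, *cov_names]
    beta, se, p, _ = _ols(y, X, names)
    return [
        {"name": dosage_names[i], "beta": float(beta[1 + i]), "se": float(se[1 + i]),
         "p": float(p[1 + i]), "n": n}
        for i in range(D.shape[1])
    ]


def haplotype_copy_counts(alleles1: np.ndarray, alleles2: np.ndarray) -> np.ndarray:
    """Per-individual copy counts of AB/Ab/aB/ab from phased haplotypes.

    Consecutive pairs of rows are the two haplotypes of one individual.
    Returns (n_individuals, 4) with columns in AB, Ab, aB, ab order; rows
    sum to 2.
    """
    a1 = np.asarray(alleles1).reshape(-1, 2)
    a2 = np.asarray(alleles2).reshape(-1, 2)
    code = 2 * (1 - a1) + (1 - a2)  # 0=AB, 1=Ab, 2=aB, 3=ab
    counts = np.stack([(code == k).sum(axis=1) for k in range(4)], axis=1)
    return counts.astype(np.int8)


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

def run_test_battery(
    genotype1: np.ndarray,
    genotype2: np.ndarray,
    hap_counts: np.ndarray,
    segments: Sequence[Segment],
    sample_ids: Sequence[str],
    phenotypes: pd.DataFrame,
    config: BatteryConfig | None = None,
) -> list[AssocResult]:
    """Emit the five association-test families, in order.

    ``genotype1``/``genotype2`` are per-individual 0/1/2 dosages at the two
    focal loci (locus B being the merged linked pair) and ``hap_counts`` the
    (n, 4) AB/Ab/aB/ab copy counts, all aligned to ``sample_ids``; segment
    representative dosages must be aligned to the same order.  Phenotype
    rows are matched on ``sample_id``; individuals absent from the cleaned
    phenotype table are ignored, and remaining missingness is handled by
    per-test listwise deletion (the reported n is per test).
    """
    cfg = config or BatteryConfig()
    phen = phenotypes.set_index("sample_id")
    order = [s for s in sample_ids if s in phen.index]
    sidx = {s: i for i, s in enumerate(sample_ids)}
    rows = np.array([sidx[s] for s in order], dtype=int)
    phen = phen.loc[order]

    g1 = np.asarray(genotype1, dtype=float)[rows]
    g2 = np.asarray(genotype2, dtype=float)[rows]
    hc = np.asarray(hap_counts, dtype=float)[rows]
    cov = phen[list(cfg.covariates)]
    results: list[AssocResult] = []

    def _emit(test_id, family, trait, fit):
        results.append(AssocResult(test_id=test_id, family=family, trait=trait,
                                   beta=fit["beta"], se=fit["se"], p=fit["p"], n=fit["n"]))

    def _fit_one(y_, d_, cov_, name):
        # a monomorphic dosage carries no test: emit a degenerate record
        # (beta undefined, p = 1) instead of aborting the battery
        try:
            return fit_linear_adjusted(y_, d_, cov_, [name])[0]
        except np.linalg.LinAlgError:
            keep = int((~np.isnan(np.asarray(y_, dtype=float))).sum())
            return {"name": name, "beta": float("nan"), "se": float("nan"), "p": 1.0, "n": keep}

    # (i) single-locus: each locus x (6 traits + adjusted focal trait)
    for label, g in zip(cfg.locus_labels, (g1, g2)):
        for trait in cfg.traits:
            fit = _fit_one(phen[trait].to_numpy(), g, cov, label)
            _emit(f"single_{label}_{trait}", "single_locus", trait, fit)
        adj_cov = pd.concat([cov, phen[[cfg.adjust_for]]], axis=1)
        fit = _fit_one(phen[cfg.focal_trait].to_numpy(), g, adj_cov, label)
        _emit(f"single_{label}_{cfg.focal_trait}_adj_{cfg.adjust_for}", "single_locus",
              f"{cfg.focal_trait}_adj", fit)

    # (ii) joint test: both loci in one model
    y = phen[cfg.focal_trait].to_numpy()
    try:
        fits = fit_linear_adjusted(y, np.column_stack([g1, g2]), cov, list(cfg.locus_labels))
    except np.linalg.LinAlgError:
        keep = int((~np.isnan(y)).sum())
        fits = [{"name": lbl, "beta": float("nan"), "se": float("nan"), "p": 1.0, "n": keep}
                for lbl in cfg.locus_labels]
    for fit in fits:
        _emit(f"joint_{fit['name']}", "joint", cfg.focal_trait, fit)

    # (iii) haplotype tests; the fully ancestral haplotype is recoded as its
    # complement (any-archaic count) so the effect direction is shared
    hap_dosages = {"AB": hc[:, 0], "Ab": hc[:, 1], "aB": hc[:, 2], "any_archaic": 2 - hc[:, 3]}
    for name, d in hap_dosages.items():
        fit = _fit_one(y, d, cov, name)
        _emit(f"haplotype_{name}", "haplotype", cfg.focal_trait, fit)

    # (iv) allele sum over both loci, 0..4
    fit = _fit_one(y, g1 + g2, cov, "allele_sum")
    _emit("allele_sum", "allele_sum", cfg.focal_trait, fit)

    # (v) one test per retained introgression segment
    if not segments:
        import warnings

        warnings.warn("no admixture-mapping segments retained; segment family empty")
    for k, seg in enumerate(segments, start=1):
        d = np.asarray(seg.representative_dosage, dtype=float)[rows]
        fit = _fit_one(y, d, cov, f"segment_{k}")
        _emit(f"segment_{k}", "segment", cfg.focal_trait, fit)
    return results


def bh_threshold(pvalues: Sequence[float], q: float = 0.05) -> tuple[float, np.ndarray, int]:
    """Benjamini-Hochberg step-up: study-wide threshold and significant set.

    Returns ``(threshold, significant_mask, k_star)`` where the threshold is
    p(k*), the largest accepted p-value, and the significant set is every
    test with p <= threshold.  With no accepted p-value the threshold is 0
    and the mask empty.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = (np.arange(1, m + 1) * q) / m
    accepted = np.flatnonzero(sorted_p <= crit)
    if accepted.size == 0:
        return 0.0, np.zeros(m, dtype=bool), 0
    k_star = int(accepted[-1] + 1)
    threshold = float(sorted_p[k_star - 1])
    return threshold, p <= threshold, k_star
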