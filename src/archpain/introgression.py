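"""Two-state archaic/modern HMM scan over phased haplotypes.

Each haplotype is modelled as a succession of archaic and modern tracts.
Emissions compare the observed allele against two proxies: under the modern
state the derived-allele probability is the modern-proxy frequency (clipped
to ``[freq_floor, 1-freq_floor]``); under the archaic state it is the
archaic proxy's derived-genotype fraction (0, 1/2 or 1) with a symmetric
error ``emit_error``.  The per-bp transition intensity ``switch_rate`` gives
a switching probability of ``1 - exp(-switch_rate * dbp)`` between adjacent
sites, partitioned between destination states by the stationary prior
``(p_arch_prior, 1 - p_arch_prior)`` so that the prior is the chain's
stationary distribution.

Decoding is done in log space (Viterbi for the state path, forward-backward
for per-site posteriors), so panels of 10^5 sites do not underflow.
Candidate tracts are maximal archaic runs retained only when their mean
per-site archaic posterior exceeds ``posterior_min`` (default 0.99).  Short
spurious tracts are removed by a physical length cutoff calibrated on
African-background chromosomes, which are assumed to carry essentially no
archaic material.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from archpain.sites import SiteRecord

__all__ = [
    "HMMParams",
    "IntrogressionTract",
    "CalibrationResult",
    "emission_logprob",
    "decode_haplotype",
    "decode_panel",
    "call_tracts",
    "apply_length_cutoff",
    "calibrate_length_cutoff",
    "summarize_introgression",
    "tract_frequency_profile",
    "tract_recovery_f1",
]

ARCHAIC, MODERN = 1, 0


@dataclass
class HMMParams:
    p_arch_prior: float = 0.02
    switch_rate: float = 1.0 / 123_000.0
    emit_error: float = 0.01
    freq_floor: float = 0.01
    posterior_min: float = 0.99
    min_tract_len: float | None = None

    def __post_init__(self) -> None:
        for name in ("p_arch_prior", "posterior_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0,1)")
        for name in ("emit_error", "freq_floor"):
            v = getattr(self, name)
            if not (0.0 < v < 0.5):
                raise ValueError(f"{name} must lie in (0, 0.5)")
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be positive")


@dataclass(frozen=True)
class IntrogressionTract:
    hap_id: str
    start_pos: int
    end_pos: int
    n_sites: int
    mean_posterior: float

    def __post_init__(self) -> None:
        if self.end_pos < self.start_pos or self.n_sites < 1:
            raise ValueError("degenerate tract")

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def _derived_probs(sites: Sequence[SiteRecord], params: HMMParams) -> tuple[np.ndarray, np.ndarray]:
    """P(derived | modern) and P(derived | archaic) per site."""
    mod = np.array([s.modern_derived_freq for s in sites])
    gts = [s.archaic_gt for s in sites]
    if any(g is None for g in gts):
        raise ValueError("sites with missing archaic genotype must be removed before decoding")
    arch = np.array(gts, dtype=float) / 2.0
    p_mod = np.clip(mod, params.freq_floor, 1.0 - params.freq_floor)
    p_arch = np.clip(arch, params.emit_error, 1.0 - params.emit_error)
    return p_mod, p_arch


def emission_logprob(site: SiteRecord, allele: int, state: str, params: HMMParams) -> float:
    """log P(observed allele | hidden state) at one site."""
    if site.archaic_gt is None:
        raise ValueError(f"site at {site.pos} has no archaic genotype")
    if state == "modern":
        p = np.clip(site.modern_derived_freq, params.freq_floor, 1.0 - params.freq_floor)
    elif state == "archaic":
        p = np.clip(site.archaic_gt / 2.0, params.emit_error, 1.0 - params.emit_error)
    else:
        raise ValueError(f"unknown state {state!r}")
    return float(np.log(p if allele == 1 else 1.0 - p))


def _log_emissions(
    alleles: np.ndarray, sites: Sequence[SiteRecord], params: HMMParams
) -> np.ndarray:
    """(n_haps, n_sites, 2) log emission array; state axis = (modern, archaic)."""
    p_mod, p_arch = _derived_probs(sites, params)
    a = np.asarray(alleles)
    if a.ndim == 1:
        a = a[None, :]
    le = np.empty((a.shape[0], a.shape[1], 2))
    le[:, :, MODERN] = np.where(a == 1, np.log(p_mod), np.log1p(-p_mod))
    le[:, :, ARCHAIC] = np.where(a == 1, np.log(p_arch), np.log1p(-p_arch))
    return le


def _log_transitions(positions: np.ndarray, params: HMMParams) -> np.ndarray:
    """(n_gaps, 2, 2) log transition matrices between adjacent sites.

    P(i -> j != i) = s * pi_j, P(i -> i) = 1 - s * pi_(1-i), with
    s = 1 - exp(-switch_rate * dbp); stationary distribution is
    (1 - p_arch_prior, p_arch_prior).
    """
    pi = np.array([1.0 - params.p_arch_prior, params.p_arch_prior])
    d = np.diff(np.asarray(positions, dtype=float))
    s = 1.0 - np.exp(-params.switch_rate * d)
    T = np.empty((len(d), 2, 2))
    T[:, MODERN, ARCHAIC] = s * pi[ARCHAIC]
    T[:, ARCHAIC, MODERN] = s * pi[MODERN]
    T[:, MODERN, MODERN] = 1.0 - T[:, MODERN, ARCHAIC]
    T[:, ARCHAIC, ARCHAIC] = 1.0 - T[:, ARCHAIC, MODERN]
    with np.errstate(divide="ignore"):
        return np.log(T)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def decode_panel(
    alleles: np.ndarray, sites: Sequence[SiteRecord], params: HMMParams
) -> tuple[np.ndarray, np.ndarray]:
    """Viterbi paths and archaic posteriors for a stack of haplotypes.

    Vectorised over haplotypes: one pass over sites updates every haplotype
    simultaneously.  Returns ``(paths, posteriors)`` with shapes
    (n_haps, n_sites); posteriors are P(archaic | data) per site.
    """
    if len(sites) == 0:
        raise ValueError("cannot decode over zero sites")
    positions = np.array([s.pos for s in sites], dtype=np.int64)
    le = _log_emissions(alleles, sites, params)
    n_haps, n_sites, _ = le.shape
    lt = _log_transitions(positions, params)
    log_pi = np.log(np.array([1.0 - params.p_arch_prior, params.p_arch_prior]))

    # --- Viterbi ---
    score = log_pi[None, :] + le[:, 0, :]
    back = np.empty((n_sites, n_haps, 2), dtype=np.int8)
    for t in range(1, n_sites):
        cand = score[:, :, None] + lt[t - 1][None, :, :]  # (haps, from, to)
        back[t] = np.argmax(cand, axis=1)
        score = np.max(cand, axis=1) + le[:, t, :]
    paths = np.empty((n_haps, n_sites), dtype=np.int8)
    paths[:, -1] = np.argmax(score, axis=1)
    rows = np.arange(n_haps)
    for t in range(n_sites - 1, 0, -1):
        paths[:, t - 1] = back[t, rows, paths[:, t]]

    # --- forward-backward ---
    fwd = np.empty((n_haps, n_sites, 2))
    fwd[:, 0, :] = log_pi[None, :] + le[:, 0, :]
    for t in range(1, n_sites):
        trans = fwd[:, t - 1, :, None] + lt[t - 1][None, :, :]
        fwd[:, t, :] = _logsumexp2(trans) + le[:, t, :]
    bwd = np.empty((n_haps, n_sites, 2))
    bwd[:, -1, :] = 0.0
    for t in range(n_sites - 2, -1, -1):
        trans = lt[t][None, :, :] + (le[:, t + 1, :] + bwd[:, t + 1, :])[:, None, :]
        bwd[:, t, :] = _logsumexp2(np.swapaxes(trans, 1, 2))
    lp = fwd + bwd
    lp -= _logsumexp_last(lp)[..., None]
    posteriors = np.exp(lp[:, :, ARCHAIC])
    return paths, posteriors


def _logsumexp2(x: np.ndarray) -> np.ndarray:
    """logsumexp over axis 1 of a (..., 2, 2) 'from' axis."""
    m = np.max(x, axis=1)
    return m + np.log(np.sum(np.exp(x - m[:, None, :]), axis=1))


def _logsumexp_last(x: np.ndarray) -> np.ndarray:
    m = np.max(x, axis=-1)
    return m + np.log(np.sum(np.exp(x - m[..., None]), axis=-1))


def decode_haplotype(
    alleles: np.ndarray, sites: Sequence[SiteRecord], params: HMMParams
) -> tuple[np.ndarray, np.ndarray]:
    """Viterbi state path and per-site archaic posterior for one haplotype."""
    paths, post = decode_panel(np.asarray(alleles)[None, :], sites, params)
    return paths[0], post[0]


def sequence_loglik(
    alleles: np.ndarray, sites: Sequence[SiteRecord], params: HMMParams
) -> tuple[float, float]:
    """Total data log-likelihood from the forward and the backward pass.

    The two must agree (up to round-off); both are returned so callers can
    verify the recursion consistency.
    """
    positions = np.array([s.pos for s in sites], dtype=np.int64)
    le = _log_emissions(np.asarray(alleles)[None, :], sites, params)
    lt = _log_transitions(positions, params)
    log_pi = np.log(np.array([1.0 - params.p_arch_prior, params.p_arch_prior]))
    n_sites = le.shape[1]
    fwd = log_pi[None, :] + le[:, 0, :]
    for t in range(1, n_sites):
        fwd = _logsumexp2(fwd[:, :, None] + lt[t - 1][None, :, :]) + le[:, t, :]
    total_fwd = float(_logsumexp_last(fwd)[0])
    bwd = np.zeros((1, 2))
    for t in range(n_sites - 2, -1, -1):
        trans = lt[t][None, :, :] + (le[:, t + 1, :] + bwd)[:, None, :]
        bwd = _logsumexp2(np.swapaxes(trans, 1, 2))
    total_bwd = float(_logsumexp_last(log_pi[None, :] + le[:, 0, :] + bwd)[0])
    return total_fwd, total_bwd


def path_loglik(
    path: np.ndarray, alleles: np.ndarray, sites: Sequence[SiteRecord], params: HMMParams
) -> float:
    """Joint log-likelihood of a given state path and the observed alleles."""
    positions = np.array([s.pos for s in sites], dtype=np.int64)
    le = _log_emissions(np.asarray(alleles)[None, :], sites, params)[0]
    lt = _log_transitions(positions, params)
    log_pi = np.log(np.array([1.0 - params.p_arch_prior, params.p_arch_prior]))
    path = np.asarray(path, dtype=int)
    ll = log_pi[path[0]] + le[0, path[0]]
    for t in range(1, len(path)):
        ll += lt[t - 1, path[t - 1], path[t]] + le[t, path[t]]
    return float(ll)


# ---------------------------------------------------------------------------
# tract assembly and calibration
# ---------------------------------------------------------------------------

def call_tracts(
    path: np.ndarray,
    posteriors: np.ndarray,
    sites: Sequence[SiteRecord],
    params: HMMParams,
    hap_id: str = "hap",
    retention: str = "per_site",
) -> list[IntrogressionTract]:
    """Assemble archaic tracts from the Viterbi path under a >99% rule.

    Two retention interpretations are provided:

    ``per_site`` (default)
        A site is assigned archaic iff the Viterbi state is archaic *and*
        its posterior exceeds ``posterior_min``; maximal runs of such sites
        are tracts.  This trims the soft boundary zone (where the tract's
        exact endpoint is uncertain even though its existence is not) and
        never discards a confidently detected tract for having fuzzy edges.
    ``tract_mean``
        Maximal archaic Viterbi runs are candidate tracts spanning
        first-to-last archaic site; a tract is retained iff its *mean*
        per-site archaic posterior exceeds ``posterior_min``.  Stricter on
        long tracts, whose boundary-uncertainty mass scales with the number
        of edge sites.

    A tract spans its first to its last retained site.  If
    ``params.min_tract_len`` is numeric, shorter tracts are dropped too.
    """
    path = np.asarray(path)
    post = np.asarray(posteriors)
    positions = np.array([s.pos for s in sites], dtype=np.int64)
    if not (len(path) == len(post) == len(positions)):
        raise ValueError("path, posteriors and sites must align")
    if retention not in ("per_site", "tract_mean"):
        raise ValueError("retention must be 'per_site' or 'tract_mean'")
    tracts: list[IntrogressionTract] = []
    if retention == "per_site":
        arch = np.flatnonzero((path == ARCHAIC) & (post > params.posterior_min))
    else:
        arch = np.flatnonzero(path == ARCHAIC)
    if arch.size == 0:
        return tracts
    breaks = np.flatnonzero(np.diff(arch) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [arch.size - 1]])
    for a, b in zip(starts, ends):
        idx = arch[a : b + 1]
        mean_post = float(post[idx].mean())
        if retention == "tract_mean" and mean_post <= params.posterior_min:
            continue
        tract = IntrogressionTract(
            hap_id=hap_id,
            start_pos=int(positions[idx[0]]),
            end_pos=int(positions[idx[-1]]),
            n_sites=int(idx.size),
            mean_posterior=mean_post,
        )
        if params.min_tract_len is not None and tract.length_bp < params.min_tract_len:
            continue
        tracts.append(tract)
    return tracts


def apply_length_cutoff(
    tracts: Sequence[IntrogressionTract], min_len_bp: float
) -> list[IntrogressionTract]:
    """Discard tracts shorter than the calibrated physical cutoff."""
    return [t for t in tracts if t.length_bp >= min_len_bp]


@dataclass(frozen=True)
class CalibrationResult:
    cutoff_bp: float
    achieved: bool
    residual_fraction: float
    discards_all_non_african: bool = False


def calibrate_length_cutoff(
    tracts: Sequence[IntrogressionTract],
    african_hap_ids: set[str],
    region: tuple[int, int],
    tolerance: float = 1e-4,
    grid_step: float = 500.0,
) -> CalibrationResult:
    """Smallest length cutoff leaving <= ``tolerance`` archaic bp on African
    chromosomes.

    African-background chromosomes are assumed archaic-free, so any bp they
    are assigned is an error floor.  The cutoff is searched on a
    ``grid_step`` (default 0.5 kb) grid: the smallest L such that, after
    discarding tracts shorter than L, the archaic fraction of African
    chromosome bp is <= tolerance.  Flags the degenerate case where the
    calibrated cutoff would also discard every non-African tract.
    """
    if not african_hap_ids:
        raise ValueError("calibration requires at least one African-background haplotype")
    region_len = region[1] - region[0] + 1
    total_afr_bp = len(african_hap_ids) * region_len
    afr_lengths = np.array(
        [t.length_bp for t in tracts if t.hap_id in african_hap_ids], dtype=float
    )
    non_afr_lengths = [t.length_bp for t in tracts if t.hap_id not in african_hap_ids]

    if afr_lengths.size == 0:
        return CalibrationResult(cutoff_bp=grid_step, achieved=True, residual_fraction=0.0)

    grid = np.arange(grid_step, afr_lengths.max() + 2 * grid_step, grid_step)
    cutoff, residual, achieved = float(grid[-1]), 1.0, False
    for L in grid:
        kept = afr_lengths[afr_lengths >= L]
        frac = kept.sum() / total_afr_bp
        if frac <= tolerance:
            cutoff, residual, achieved = float(L), float(frac), True
            break
    discards_all = bool(non_afr_lengths) and cutoff > max(non_afr_lengths)
    return CalibrationResult(
        cutoff_bp=cutoff,
        achieved=achieved,
        residual_fraction=residual,
        discards_all_non_african=discards_all,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_introgression(
    tracts: Sequence[IntrogressionTract],
    groups: Mapping[str, set[str]],
    region: tuple[int, int],
):
    """Per-group tract count, mean length (kb, with SE) and % archaic bp.

    The archaic percentage is computed per haplotype (sum of tract lengths /
    region length), then averaged within the group; SE is the standard error
    over haplotypes.  Groups with no haplotypes or a single tract get NaN
    SEs (flagged undefined by NaN).
    """
    import pandas as pd

    region_len = region[1] - region[0] + 1
    by_hap: dict[str, float] = {}
    for t in tracts:
        by_hap[t.hap_id] = by_hap.get(t.hap_id, 0.0) + t.length_bp
    rows = []
    for name, hap_ids in groups.items():
        g_tracts = [t for t in tracts if t.hap_id in hap_ids]
        lengths = np.array([t.length_bp for t in g_tracts], dtype=float) / 1_000.0
        pct = np.array([100.0 * by_hap.get(h, 0.0) / region_len for h in sorted(hap_ids)])
        rows.append(
            {
                "group": name,
                "n_chromosomes": len(hap_ids),
                "n_tracts": len(g_tracts),
                "mean_length_kb": lengths.mean() if lengths.size else 0.0,
                "se_length_kb": lengths.std(ddof=1) / np.sqrt(lengths.size) if lengths.size > 1 else np.nan,
                "mean_pct_archaic": pct.mean() if pct.size else 0.0,
                "se_pct_archaic": pct.std(ddof=1) / np.sqrt(pct.size) if pct.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def tract_frequency_profile(
    tracts: Sequence[IntrogressionTract], n_haplotypes: int, query_positions: np.ndarray
) -> np.ndarray:
    """Fraction of haplotypes carrying a tract over each query position.

    The tract pile-up: count of tracts overlapping each position divided by
    the number of haplotypes.  Implemented by event sorting (O((T+Q) log T)).
    """
    q = np.asarray(query_positions)
    if not tracts:
        return np.zeros(len(q))
    starts = np.sort(np.array([t.start_pos for t in tracts]))
    ends = np.sort(np.array([t.end_pos for t in tracts]))
    n_started = np.searchsorted(starts, q, side="right")
    n_ended = np.searchsorted(ends, q, side="left")
    return (n_started - n_ended) / float(n_haplotypes)


def tract_recovery_f1(
    called: Sequence[IntrogressionTract],
    truth: Mapping[str, list[tuple[int, int]]],
    min_len_bp: float = 0.0,
    min_overlap: float = 0.5,
) -> float:
    """Tract-level F1 of called tracts against ground truth.

    A true tract (length >= ``min_len_bp``) counts as recovered when some
    called tract on the same haplotype covers >= ``min_overlap`` of it; a
    called tract is a true positive when true tracts cover >= ``min_overlap``
    of *its* length.
    """
    true_by_hap = {
        h: [(s, e) for (s, e) in ts if e - s + 1 >= min_len_bp] for h, ts in truth.items()
    }
    n_true = sum(len(ts) for ts in true_by_hap.values())
    called_by_hap: dict[str, list[IntrogressionTract]] = {}
    for t in called:
        called_by_hap.setdefault(t.hap_id, []).append(t)

    def overlap(a, b, c, d):
        return max(0, min(b, d) - max(a, c) + 1)

    recovered = 0
    for h, ts in true_by_hap.items():
        for s, e in ts:
            cov = sum(overlap(s, e, c.start_pos, c.end_pos) for c in called_by_hap.get(h, []))
            if cov >= min_overlap * (e - s + 1):
                recovered += 1
    tp_called = 0
    for h, cs in called_by_hap.items():
        for c in cs:
            cov = sum(overlap(c.start_pos, c.end_pos, s, e) for s, e in true_by_hap.get(h, []))
            if cov >= min_overlap * c.length_bp:
                tp_called += 1
    n_called = len(called)
    if n_true == 0 and n_called == 0:
        return 1.0
    recall = recovered / n_true if n_true else 0.0
    precision = tp_called / n_called if n_called else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
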