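"""Synthetic reference proxies, admixed cohorts, and phenotypes.

No raw study data exists for this analysis, so the pipeline is exercised on
synthetic cohorts that reproduce the statistical structure the downstream
stages assume:

* a reference-proxy site panel at Poisson-spaced positions over a ~4.18 Mb
  region, each site carrying an archaic diploid genotype with depth/FILTER
  annotations and a modern-proxy (African-panel-like) derived-allele
  frequency; a configurable fraction of sites is *archaic-informative*
  (archaic homozygous derived, modern frequency near zero);
* per-haplotype continental ancestry (AFR/EUR/NAM) from a homogeneous
  Markov switch process with per-individual Dirichlet proportions;
* archaic tracts with exponential lengths (mean ~123 kb), generated only
  inside Native-American ancestry intervals and anchored at the focal
  coding loci so that NAM-background allele frequencies and the two-locus
  LD structure match the admixture history being emulated;
* six positive, right-skewed quantitative pain thresholds with sex, age and
  depression covariates and five genetic PCs; the per-allele genetic effect
  (default -0.075 per archaic allele, on the log scale) acts on the
  post-sensitization mechanical threshold.

Everything is drawn from one `numpy.random.Generator`, so an identical
config + seed reproduces the panel, truth and phenotypes byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from archpain.haplotypes import AncestryTract
from archpain.sites import SiteRecord

__all__ = ["SimConfig", "SimTruth", "HaplotypePanel", "simulate_reference_panel", "simulate_cohort"]

TRAITS = ("PPT", "HPT", "MPT", "WUR", "POST_HPT", "POST_MPT")

# log-scale trait baselines (instrument units: kPa, deg C proxy, mN, ratio)
_TRAIT_BASELINE = {"PPT": 5.7, "HPT": 3.8, "MPT": 4.6, "WUR": 0.7, "POST_HPT": 3.7, "POST_MPT": 4.2}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study region: a 4.18 Mb window, ~8776
    sites, three focal loci separated by 73.9 kb and 4.3 kb, archaic-tract
    mean length 123 kb, NAM-background archaic frequencies (0.68, 0.29) at
    the two loci with ~85% of B-carrying chromosomes also carrying A (the
    ratio implied by the observed two-locus haplotype frequencies), and a
    per-allele effect of -0.075 on the log post-sensitization mechanical
    pain threshold.
    """

    n_individuals: int = 1623
    region_start: int = 165_050_001
    region_end: int = 169_230_000
    site_density: float = 8776 / 4_180_000
    ancestry_dirichlet: tuple[float, float, float] = (0.22, 2.48, 2.30)  # AFR, EUR, NAM
    ancestry_switch_rate: float = 5.3e-8
    archaic_freq_nam: float | tuple[float, float] = (0.68, 0.29)
    archaic_co_carriage: float = 0.85
    archaic_tract_mean_len: float = 123_000.0
    focal_positions: tuple[int, int, int] = (167_055_000, 167_128_900, 167_133_200)
    informative_fraction: float = 0.2
    qc_fail_fraction: float = 0.02
    copy_error: float = 0.01
    effect_per_allele: float = -0.075
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": -0.10, "age": -0.004, "depression": -0.01}
    )
    noise_sd: float = 0.65
    sensitization_sd: float = 0.30
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.region_end <= self.region_start:
            raise ValueError("region_end must exceed region_start")
        if self.site_density < 0:
            raise ValueError("site_density must be non-negative")
        for p in self.focal_positions:
            if not (self.region_start <= p <= self.region_end):
                raise ValueError(f"focal position {p} outside region")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        fa, fb = self.archaic_freqs
        if not (0 <= fa <= 1 and 0 <= fb <= 1):
            raise ValueError("archaic_freq_nam must lie in [0,1]")

    @property
    def archaic_freqs(self) -> tuple[float, float]:
        """NAM-background archaic frequency at locus A and locus B."""
        f = self.archaic_freq_nam
        if np.isscalar(f):
            return float(f), float(f)
        return float(f[0]), float(f[1])

    @property
    def region_length(self) -> int:
        return self.region_end - self.region_start + 1


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated cohort."""

    ancestry_tracts: list[AncestryTract]
    archaic_tracts: dict[str, list[tuple[int, int]]]
    focal_dosage: np.ndarray              # individuals x 3 focal loci, 0/1/2
    ancestry_props: np.ndarray            # individuals x (AFR, EUR, NAM)
    true_effects: dict

    def archaic_tracts_flat(self) -> list[tuple[str, int, int]]:
        return [(h, s, e) for h, ts in self.archaic_tracts.items() for (s, e) in ts]


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix (haplotypes x sites)."""

    alleles: np.ndarray
    positions: np.ndarray
    hap_ids: list[str]
    sample_ids: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        if self.alleles.shape != (len(self.hap_ids), len(self.positions)):
            raise ValueError("allele matrix shape does not match hap_ids x positions")

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_ids)

    def hap_owner(self) -> dict[str, str]:
        """hap_id -> sample_id (two haplotypes per individual)."""
        return {h: self.sample_ids[i // 2] for i, h in enumerate(self.hap_ids)}

    def site_index(self, pos: int) -> int:
        i = int(np.searchsorted(self.positions, pos))
        if i >= len(self.positions) or self.positions[i] != pos:
            raise KeyError(f"no site at position {pos}")
        return i

    def alleles_at(self, pos: int) -> np.ndarray:
        return self.alleles[:, self.site_index(pos)]


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def simulate_reference_panel(config: SimConfig, rng: np.random.Generator) -> list[SiteRecord]:
    """Draw a site panel at Poisson-spaced positions with proxy annotations.

    Focal positions are always included as clean, archaic-informative sites
    so the cohort generator and the HMM can anchor on them.
    """
    L = config.region_length
    if config.site_density == 0:
        return []
    n = rng.poisson(config.site_density * L)
    positions = np.unique(rng.integers(config.region_start, config.region_end + 1, size=n))
    positions = np.unique(np.concatenate([positions, np.array(config.focal_positions)]))
    n = len(positions)
    focal_set = set(config.focal_positions)

    informative = rng.random(n) < config.informative_fraction
    mod_freq = np.where(
        informative,
        rng.uniform(0.0, 0.01, size=n),
        rng.uniform(0.05, 0.95, size=n),
    )
    arch_gt = np.where(informative, 2, rng.binomial(2, np.clip(mod_freq, 0, 1)))
    depth = rng.poisson(35, size=n)
    fail = rng.random(n) < config.qc_fail_fraction
    fail_mode = rng.integers(0, 5, size=n)

    records = []
    bases = ("A", "C", "G", "T")
    for i, pos in enumerate(positions):
        pos = int(pos)
        ref, alt = bases[i % 4], bases[(i + 1) % 4]
        is_focal = pos in focal_set
        rec = dict(
            chrom="2",
            pos=pos,
            ref=ref,
            alt=alt,
            archaic_gt=int(arch_gt[i]) if not is_focal else 2,
            archaic_depth=int(depth[i]) if not is_focal else int(max(depth[i], 25)),
            archaic_filter="PASS",
            modern_filter="PASS",
            # the emulated coding variants are archaic-specific: essentially
            # absent from every modern background off-tract
            modern_derived_freq=float(mod_freq[i]) if not is_focal else float(rng.uniform(0.0, 0.002)),
            ancestral_allele_src1=ref,
            ancestral_allele_src2=ref,
            biallelic_in_both=True,
            same_polymorphism=True,
        )
        if fail[i] and not is_focal:
            mode = int(fail_mode[i])
            if mode == 0:
                rec["biallelic_in_both"] = False
            elif mode == 1:
                rec["archaic_depth"] = int(rng.integers(0, 20))
            elif mode == 2:
                rec["archaic_filter"] = "LowQual"
            elif mode == 3:
                rec["ancestral_allele_src2"] = alt
            else:
                rec["same_polymorphism"] = False
        records.append(SiteRecord(**rec))
    return records


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _ancestry_tracts_for_hap(
    hap_id: str, props: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> list[AncestryTract]:
    """Homogeneous Markov switch process along bp; no self-transitions."""
    from archpain.haplotypes import ANCESTRIES

    L = config.region_length
    n_switch = rng.poisson(config.ancestry_switch_rate * L)
    cuts = np.sort(rng.integers(config.region_start + 1, config.region_end + 1, size=n_switch))
    cuts = np.unique(cuts)
    starts = np.concatenate([[config.region_start], cuts])
    ends = np.concatenate([cuts - 1, [config.region_end]])
    state = int(rng.choice(3, p=props))
    tracts = []
    for s, e in zip(starts, ends):
        tracts.append(AncestryTract(hap_id=hap_id, start_pos=int(s), end_pos=int(e), ancestry=ANCESTRIES[state]))
        others = [k for k in range(3) if k != state]
        w = props[others]
        w = w / w.sum() if w.sum() > 0 else np.array([0.5, 0.5])
        state = int(rng.choice(others, p=w))
    # merge consecutive same-ancestry tracts (silent switches)
    merged = [tracts[0]]
    for t in tracts[1:]:
        if t.ancestry == merged[-1].ancestry:
            merged[-1] = AncestryTract(hap_id, merged[-1].start_pos, t.end_pos, t.ancestry)
        else:
            merged.append(t)
    return merged


def _nam_tract_containing(tracts: list[AncestryTract], pos: int) -> AncestryTract | None:
    for t in tracts:
        if t.ancestry == "NAM" and t.start_pos <= pos <= t.end_pos:
            return t
    return None


def _clip(start: float, end: float, tract: AncestryTract) -> tuple[int, int] | None:
    s = max(int(round(start)), tract.start_pos)
    e = min(int(round(end)), tract.end_pos)
    return (s, e) if e >= s else None


def _archaic_tracts_for_hap(
    anc_tracts: list[AncestryTract], config: SimConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Archaic tract placement anchored at the focal loci, inside NAM only.

    Conditional on NAM background, the haplotype carries archaic material at
    locus A with probability f_A and at locus B with probability f_B; a
    fraction ``archaic_co_carriage`` of B-carriers also carry A, realised as
    one long tract spanning both anchors.
    """
    fA, fB = config.archaic_freqs
    p1, p2, p3 = config.focal_positions
    tA = _nam_tract_containing(anc_tracts, p1)
    tB2 = _nam_tract_containing(anc_tracts, p2)
    tB3 = _nam_tract_containing(anc_tracts, p3)
    mean_len = config.archaic_tract_mean_len

    pAB = min(config.archaic_co_carriage * fB, fA, fB)
    pAb = fA - pAB
    paB = fB - pAB

    klass = "none"
    if tA is not None and tB2 is not None:
        u = rng.random()
        if u < pAB:
            klass = "AB"
        elif u < pAB + pAb:
            klass = "Ab"
        elif u < pAB + pAb + paB:
            klass = "aB"
    elif tA is not None:
        if rng.random() < fA:
            klass = "Ab"
    elif tB2 is not None:
        if rng.random() < fB:
            klass = "aB"

    out: list[tuple[int, int]] = []
    if klass == "AB":
        core = p3 - p1
        ext_scale = max((mean_len - core) / 2.0, 1_000.0)
        start = p1 - rng.exponential(ext_scale)
        end = p3 + rng.exponential(ext_scale)
        if tA is tB2:
            iv = _clip(start, end, tA)
            if iv:
                out.append(iv)
        else:  # NAM interrupted between anchors: realise as two nested tracts
            iv1 = _clip(start, tA.end_pos, tA)
            iv2 = _clip(tB2.start_pos, end, tB2)
            out.extend(iv for iv in (iv1, iv2) if iv)
    elif klass == "Ab":
        length = rng.exponential(mean_len)
        start = p1 - rng.random() * length
        end = min(start + length, p2 - 1)  # must not reach locus B
        iv = _clip(start, end, tA)
        if iv:
            out.append(iv)
    elif klass == "aB":
        core = p3 - p2
        total = core + rng.exponential(mean_len)
        start = p2 - rng.random() * (total - core)
        end = max(start + total, p3)
        start = max(start, p1 + 1)  # must not reach locus A
        iv = _clip(start, end, tB2)
        if iv:
            out.append(iv)
    # clip tail at locus-3 tract if B anchors sit in different NAM tracts
    if out and tB2 is not None and tB3 is not None and tB2 is not tB3:
        pass  # p2/p3 are 4.3 kb apart; distinct tracts are vanishingly rare and left as-is
    return out


def simulate_cohort(
    config: SimConfig, sites: Sequence[SiteRecord], rng: np.random.Generator
) -> tuple[HaplotypePanel, SimTruth, pd.DataFrame]:
    """Simulate phased haplotypes, ancestry/archaic truth, and phenotypes."""
    positions = np.array([s.pos for s in sites], dtype=np.int64)
    if len(positions) == 0:
        raise ValueError("no sites supplied")
    if (np.diff(positions) <= 0).any():
        raise ValueError("sites must be sorted with unique positions")
    pos_set = set(positions.tolist())
    for p in config.focal_positions:
        if p not in pos_set:
            raise ValueError(f"focal position {p} not covered by any site")

    n_sites = len(positions)
    n_ind = config.n_individuals
    arch_gt = np.array([0 if s.archaic_gt is None else s.archaic_gt for s in sites], dtype=float)
    f_afr = np.clip(np.array([s.modern_derived_freq for s in sites]), 1e-4, 1 - 1e-4)

    # ancestry-specific modern frequencies: logit-scale jitter keeps rare
    # alleles rare in every ancestry while decorrelating the backgrounds
    logit = np.log(f_afr / (1 - f_afr))
    freq_by_anc = np.empty((3, n_sites))
    freq_by_anc[0] = f_afr
    for k in (1, 2):
        z = logit + rng.normal(0.0, 0.3, size=n_sites)
        freq_by_anc[k] = 1.0 / (1.0 + np.exp(-z))

    props = rng.dirichlet(config.ancestry_dirichlet, size=n_ind)
    sample_ids = [f"ind{i:05d}" for i in range(n_ind)]
    hap_ids = [f"{s}_h{j}" for s in sample_ids for j in (1, 2)]

    anc_code = {"AFR": 0, "EUR": 1, "NAM": 2}
    alleles = np.empty((2 * n_ind, n_sites), dtype=np.int8)
    all_anc_tracts: list[AncestryTract] = []
    archaic: dict[str, list[tuple[int, int]]] = {}
    p_err = config.copy_error

    for i in range(n_ind):
        for j in (0, 1):
            h = 2 * i + j
            hap_id = hap_ids[h]
            anc_tracts = _ancestry_tracts_for_hap(hap_id, props[i], config, rng)
            all_anc_tracts.extend(anc_tracts)
            arc = _archaic_tracts_for_hap(anc_tracts, config, rng)
            archaic[hap_id] = arc

            bounds = np.array([t.start_pos for t in anc_tracts] + [anc_tracts[-1].end_pos + 1])
            anc_idx = np.array([anc_code[t.ancestry] for t in anc_tracts])
            site_anc = anc_idx[np.searchsorted(bounds, positions, side="right") - 1]
            p = freq_by_anc[site_anc, np.arange(n_sites)]
            if arc:
                on = np.zeros(n_sites, dtype=bool)
                for s, e in arc:
                    on |= (positions >= s) & (positions <= e)
                p_arch = arch_gt / 2.0
                p = np.where(on, p_arch * (1 - p_err) + (1 - p_arch) * p_err, p)
            alleles[h] = rng.random(n_sites) < p

    focal_dosage = np.zeros((n_ind, 3), dtype=np.int8)
    for i in range(n_ind):
        for j in (0, 1):
            for k, fp in enumerate(config.focal_positions):
                if any(s <= fp <= e for s, e in archaic[hap_ids[2 * i + j]]):
                    focal_dosage[i, k] += 1

    phen = _simulate_phenotypes(config, props, focal_dosage, sample_ids, rng)
    truth = SimTruth(
        ancestry_tracts=all_anc_tracts,
        archaic_tracts=archaic,
        focal_dosage=focal_dosage,
        ancestry_props=props,
        true_effects={"effect_per_allele": config.effect_per_allele, **config.covariate_effects},
    )
    panel = HaplotypePanel(alleles=alleles, positions=positions, hap_ids=hap_ids, sample_ids=sample_ids)
    return panel, truth, phen


def _simulate_phenotypes(
    config: SimConfig,
    props: np.ndarray,
    focal_dosage: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(sample_ids)
    sex = (rng.random(n) < 0.561).astype(int)  # 1 = female
    age = rng.integers(18, 46, size=n)
    depression = np.minimum(rng.poisson(3.0, size=n), 27)
    severe = rng.random(n) < 0.015
    depression = np.where(severe, rng.integers(16, 28, size=n), depression)

    pcs = np.empty((n, 5))
    pcs[:, 0] = (props[:, 2] - props[:, 2].mean()) * 5 + rng.normal(0, 0.1, n)
    pcs[:, 1] = (props[:, 0] - props[:, 0].mean()) * 5 + rng.normal(0, 0.1, n)
    pcs[:, 2:] = rng.normal(0, 1, (n, 3))

    ce = config.covariate_effects
    cov_term = ce["sex"] * sex + ce["age"] * (age - 30) + ce["depression"] * depression
    allele_sum = focal_dosage[:, 0] + focal_dosage[:, 1]  # locus A + merged locus B
    sensitization = rng.normal(0, config.sensitization_sd, n)

    data = {"sample_id": sample_ids}
    for trait in TRAITS:
        y = _TRAIT_BASELINE[trait] + cov_term + rng.normal(0, config.noise_sd, n)
        if trait in ("MPT", "POST_MPT"):
            y = y + sensitization
        if trait == "POST_MPT":
            y = y + config.effect_per_allele * allele_sum
        data[trait] = np.exp(y)
    data.update(
        sex=sex, age=age, depression=depression,
        **{f"PC{k + 1}": pcs[:, k] for k in range(5)},
    )
    return pd.DataFrame(data)
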