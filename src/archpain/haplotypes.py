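"""Ancestry-aligned haplotype analysis: allele and haplotype frequencies, LD.

Allele frequencies of the focal coding variants are interpretable per
continental ancestry only on *single-ancestry chromosomes* — phased
haplotypes whose local ancestry is uniform (all African, all European, or
all Native American) across the analysed region.  This module partitions
haplotypes by that criterion, counts alleles and two-locus haplotypes on
phased data, and derives the standard LD statistics D, D' and r^2 from the
four haplotype frequencies.

Two-locus haplotypes are coded AB/Ab/aB/ab where A is the derived
(archaic-origin) allele at locus 1 and B at locus 2; when a pair of tightly
linked variants behaves as a single locus (co-occurring on >=99.9% of
chromosomes) `merge_paired_locus` collapses them, reporting rather than
dropping the discordant chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AncestryTract",
    "HaplotypeFreqs",
    "LDStats",
    "MergedLocus",
    "single_ancestry_chromosomes",
    "allele_freq_by_ancestry",
    "haplotype_frequencies",
    "ld_stats",
    "weighted_combined_frequency",
    "merge_paired_locus",
]

ANCESTRIES = ("AFR", "EUR", "NAM")
HAPLOTYPE_CODES = ("AB", "Ab", "aB", "ab")


@dataclass(frozen=True)
class AncestryTract:
    """Half-open-free, 1-based inclusive local-ancestry interval."""

    hap_id: str
    start_pos: int
    end_pos: int
    ancestry: str

    def __post_init__(self) -> None:
        if self.end_pos < self.start_pos:
            raise ValueError("end_pos < start_pos")
        if self.ancestry not in ANCESTRIES:
            raise ValueError(f"unknown ancestry {self.ancestry!r}")

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes; must sum to 1."""

    AB: float
    Ab: float
    aB: float
    ab: float

    def __post_init__(self) -> None:
        total = self.AB + self.Ab + self.aB + self.ab
        if any(f < 0 for f in (self.AB, self.Ab, self.aB, self.ab)):
            raise ValueError("haplotype frequencies must be non-negative")
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.AB, self.Ab, self.aB, self.ab)

    @classmethod
    def normalized(cls, AB: float, Ab: float, aB: float, ab: float) -> "HaplotypeFreqs":
        """Rescale almost-summing inputs (e.g. table values rounded to 3 dp)."""
        total = AB + Ab + aB + ab
        if total <= 0:
            raise ValueError("frequencies must have positive sum")
        return cls(AB=AB / total, Ab=Ab / total, aB=aB / total, ab=ab / total)


@dataclass(frozen=True)
class LDStats:
    D: float
    D_prime: float
    r2: float
    defined: bool = True


@dataclass(frozen=True)
class MergedLocus:
    alleles: np.ndarray          # merged 0/1 per haplotype
    concordance: float           # fraction of chromosomes with equal alleles
    discordant_haps: tuple[int, ...]
    merged: bool                 # True iff concordance >= threshold


def single_ancestry_chromosomes(
    tracts: Sequence[AncestryTract], region: tuple[int, int]
) -> dict[str, set[str]]:
    """Partition haplotypes into uniform-ancestry sets plus a 'mixed' set.

    Each haplotype's tracts must tile ``region`` exactly (no gap, no
    overlap); malformed tilings raise ValueError.
    """
    by_hap: dict[str, list[AncestryTract]] = {}
    for t in tracts:
        by_hap.setdefault(t.hap_id, []).append(t)
    out: dict[str, set[str]] = {a: set() for a in ANCESTRIES}
    out["mixed"] = set()
    for hap_id, ts in by_hap.items():
        ts = sorted(ts, key=lambda t: t.start_pos)
        expected = region[0]
        for t in ts:
            if t.start_pos != expected:
                raise ValueError(
                    f"haplotype {hap_id}: tracts do not tile region "
                    f"(expected start {expected}, got {t.start_pos})"
                )
            expected = t.end_pos + 1
        if expected != region[1] + 1:
            raise ValueError(f"haplotype {hap_id}: tiling ends at {expected - 1}, region ends at {region[1]}")
        ancs = {t.ancestry for t in ts}
        if len(ancs) == 1:
            out[next(iter(ancs))].add(hap_id)
        else:
            out["mixed"].add(hap_id)
    return out


def allele_freq_by_ancestry(
    alleles: np.ndarray,
    hap_ids: Sequence[str],
    site_positions: Sequence[int],
    focal_positions: Sequence[int],
    partition: Mapping[str, set[str]],
):
    """Derived-allele frequency per ancestry class at each focal site.

    Returns a DataFrame indexed by focal position with one column per
    ancestry; empty classes yield NaN (flagged undefined).
    """
    import pandas as pd

    alleles = np.asarray(alleles)
    pos_index = {p: i for i, p in enumerate(site_positions)}
    missing = [p for p in focal_positions if p not in pos_index]
    if missing:
        raise KeyError(f"focal positions absent from panel: {missing}")
    hap_index = {h: i for i, h in enumerate(hap_ids)}
    rows = {}
    for anc in ANCESTRIES:
        ids = partition.get(anc, set())
        idx = [hap_index[h] for h in ids]
        if not idx:
            rows[anc] = [np.nan] * len(focal_positions)
            continue
        sub = alleles[np.asarray(idx, dtype=int)]
        rows[anc] = [float(sub[:, pos_index[p]].mean()) for p in focal_positions]
    return pd.DataFrame(rows, index=list(focal_positions))


def haplotype_frequencies(
    alleles_locus1: np.ndarray, alleles_locus2: np.ndarray
) -> tuple[HaplotypeFreqs, dict[str, int]]:
    """Count the four two-locus haplotypes over phased chromosomes."""
    a1 = np.asarray(alleles_locus1)
    a2 = np.asarray(alleles_locus2)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError("allele vectors must be 1-D and equal length")
    if not (np.isin(a1, (0, 1)).all() and np.isin(a2, (0, 1)).all()):
        raise ValueError("alleles must be phased 0/1 — unphased or missing input rejected")
    n = a1.shape[0]
    counts = {
        "AB": int(((a1 == 1) & (a2 == 1)).sum()),
        "Ab": int(((a1 == 1) & (a2 == 0)).sum()),
        "aB": int(((a1 == 0) & (a2 == 1)).sum()),
        "ab": int(((a1 == 0) & (a2 == 0)).sum()),
    }
    freqs = HaplotypeFreqs(**{k: v / n for k, v in counts.items()})
    return freqs, counts


def ld_stats(hapfreqs: HaplotypeFreqs) -> LDStats:
    """D, D' and r^2 from four haplotype frequencies.

    pA = fAB + fAb, pB = fAB + faB; D = fAB - pA*pB;
    r^2 = D^2 / (pA(1-pA) pB(1-pB));
    D' = |D| / Dmax with Dmax = min(pA(1-pB), (1-pA)pB) for D>0 and
    min(pA*pB, (1-pA)(1-pB)) for D<0; D'=0 at D=0 by continuity.
    A monomorphic locus makes every statistic 0/0: flagged undefined.
    """
    fAB, fAb, faB, _ = hapfreqs.as_tuple()
    pA = fAB + fAb
    pB = fAB + faB
    D = fAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return LDStats(D=D, D_prime=float("nan"), r2=float("nan"), defined=False)
    r2 = D * D / denom
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return LDStats(D=0.0, D_prime=0.0, r2=0.0)
    return LDStats(D=D, D_prime=abs(D) / dmax, r2=r2)


def weighted_combined_frequency(freqs: Sequence[float], ns: Sequence[int]) -> float:
    """Sample-size-weighted pooled frequency across sub-cohorts."""
    if len(freqs) != len(ns):
        raise ValueError("freqs and ns must have equal length")
    if len(freqs) == 0:
        raise ValueError("no groups")
    if any(n <= 0 for n in ns):
        raise ValueError("group sizes must be positive")
    return float(np.dot(freqs, ns) / np.sum(ns))


def merge_paired_locus(
    alleles_a: np.ndarray, alleles_b: np.ndarray, threshold: float = 0.999
) -> MergedLocus:
    """Collapse two near-perfectly linked variants into one locus.

    The pair is merged whenever their phased alleles co-occur on at least
    ``threshold`` of chromosomes; the merged allele is taken from the first
    variant, and discordant chromosomes are reported, not dropped.
    """
    a = np.asarray(alleles_a)
    b = np.asarray(alleles_b)
    if a.shape != b.shape:
        raise ValueError("allele vectors must align")
    agree = a == b
    concordance = float(agree.mean()) if a.size else 1.0
    discordant = tuple(int(i) for i in np.flatnonzero(~agree))
    return MergedLocus(
        alleles=a.copy(),
        concordance=concordance,
        discordant_haps=discordant,
        merged=concordance >= threshold,
    )
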