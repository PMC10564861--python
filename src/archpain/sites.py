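"""Site ascertainment against archaic and modern proxy genomes.

The introgression scan only uses biallelic sites at which the archaic proxy
(a high-coverage Neanderthal genome) is confidently genotyped and the modern
proxy (an African reference panel such as YRI) reports a comparable
polymorphism.  A site survives ascertainment iff it is biallelic in both
sources and passes, in order:

  (i)   archaic sequencing depth >= ``min_depth`` (default 20x);
  (ii)  FILTER == PASS in both the archaic and the modern VCF;
  (iii) the ancestral-allele annotation is consistent across sources;
  (iv)  both VCFs describe the identical polymorphism (same REF/ALT pair).

Rejections are attributed to the *first* failing rule so that the counts
partition the removed set deterministically.

`variant_retention` implements the separate post-imputation retention
predicate applied to cohort genotypes (region window, MAF > 1%, call rate
>= 95%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SiteRecord",
    "AscertainmentResult",
    "ascertain_sites",
    "variant_retention",
    "read_site_records",
    "write_site_table",
]

REJECTION_RULES = (
    "not_biallelic",
    "low_depth",
    "filter_fail",
    "ancestral_mismatch",
    "different_polymorphism",
)


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic site with archaic-proxy QC annotations.

    ``archaic_gt`` counts derived alleles (0/1/2) in the diploid archaic
    proxy; ``modern_derived_freq`` is the derived-allele frequency in the
    modern proxy panel.  ``None`` marks missing annotations, which fail the
    corresponding ascertainment rule rather than raising.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    archaic_gt: int | None = None
    archaic_depth: int = 0
    archaic_filter: str = "PASS"
    modern_filter: str = "PASS"
    modern_derived_freq: float = 0.0
    ancestral_allele_src1: str | None = None
    ancestral_allele_src2: str | None = None
    biallelic_in_both: bool = True
    same_polymorphism: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.modern_derived_freq <= 1.0):
            raise ValueError(f"modern_derived_freq out of [0,1] at pos {self.pos}")
        if self.archaic_gt is not None and self.archaic_gt not in (0, 1, 2):
            raise ValueError(f"archaic_gt must be 0/1/2 or None at pos {self.pos}")


@dataclass
class AscertainmentResult:
    retained: list[SiteRecord]
    rejection_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejection_counts.values())


def _first_failing_rule(rec: SiteRecord, min_depth: int) -> str | None:
    if not rec.biallelic_in_both:
        return "not_biallelic"
    if rec.archaic_gt is None or rec.archaic_depth < min_depth:
        return "low_depth"
    if rec.archaic_filter != "PASS" or rec.modern_filter != "PASS":
        return "filter_fail"
    aa1, aa2 = rec.ancestral_allele_src1, rec.ancestral_allele_src2
    if aa1 is None or aa2 is None or aa1 != aa2:
        return "ancestral_mismatch"
    if not rec.same_polymorphism:
        return "different_polymorphism"
    return None


def ascertain_sites(records: Sequence[SiteRecord], min_depth: int = 20) -> AscertainmentResult:
    """Apply the conjunctive site filter, attributing each rejection.

    ``records`` must be position-sorted.  Idempotent: re-ascertaining the
    retained list changes nothing.
    """
    positions = [r.pos for r in records]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("records must be sorted by strictly increasing position")
    counts = {rule: 0 for rule in REJECTION_RULES}
    retained: list[SiteRecord] = []
    for rec in records:
        rule = _first_failing_rule(rec, min_depth)
        if rule is None:
            retained.append(rec)
        else:
            counts[rule] += 1
    return AscertainmentResult(retained=retained, rejection_counts=counts)


def variant_retention(
    genotypes: np.ndarray,
    positions: Sequence[int],
    region: tuple[int, int],
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
) -> np.ndarray:
    """Post-imputation retention mask over variants.

    ``genotypes`` is individuals x variants with entries in {0,1,2} and NaN
    for missing.  A variant is kept iff its position lies in ``region``
    (1-based inclusive), its minor-allele frequency among called genotypes is
    strictly greater than ``maf_min``, and its call rate is >= ``call_rate_min``.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.size == 0:
        return np.zeros(g.shape[1] if g.ndim == 2 else 0, dtype=bool)
    if g.ndim != 2:
        raise ValueError("genotypes must be 2-D (individuals x variants)")
    pos = np.asarray(positions)
    if pos.shape[0] != g.shape[1]:
        raise ValueError("positions length must match number of variants")
    called = ~np.isnan(g)
    n_called = called.sum(axis=0)
    call_rate = n_called / g.shape[0]
    with np.errstate(invalid="ignore"):
        af = np.nansum(g, axis=0) / np.where(n_called > 0, 2 * n_called, 1)
    af = np.where(n_called > 0, af, 0.0)
    maf = np.minimum(af, 1.0 - af)
    in_region = (pos >= region[0]) & (pos <= region[1])
    return in_region & (maf > maf_min) & (call_rate >= call_rate_min)


# ---------------------------------------------------------------------------
# I/O: proxy VCFs -> SiteRecords, and a TSV site table
# ---------------------------------------------------------------------------

def read_site_records(
    archaic_vcf: str,
    modern_vcf: str,
    region: str | None = None,
    depth_field: str = "DP",
) -> list[SiteRecord]:
    """Join an archaic-proxy VCF with a modern-proxy VCF into SiteRecords.

    The archaic VCF supplies the diploid genotype, FILTER and depth (read
    from FORMAT or INFO ``depth_field``, whichever is present — reference
    datasets differ on where per-site depth lives); the modern VCF supplies
    the alternate-allele frequency (INFO/AF or computed from GTs) and its
    FILTER.  Derived state is polarised by the ancestral-allele (INFO/AA)
    annotation of each source.  Sites absent from either VCF are marked
    non-biallelic-in-both.
    """
    from cyvcf2 import VCF  # deferred: only needed for real-file workflows

    def _iter(path):
        vcf = VCF(path)
        return vcf(region) if region else vcf

    modern: dict[int, tuple] = {}
    for var in _iter(modern_vcf):
        if var.ALT is None or len(var.ALT) != 1:
            continue
        af = var.INFO.get("AF")
        if af is None:
            af = float(var.aaf)
        modern[var.POS] = (var.REF, var.ALT[0], var.FILTER or "PASS", float(af), var.INFO.get("AA"))

    records: list[SiteRecord] = []
    for var in _iter(archaic_vcf):
        if var.ALT is None or len(var.ALT) != 1:
            continue
        m = modern.get(var.POS)
        depth = var.INFO.get(depth_field)
        if depth is None:
            try:
                depth = int(np.nansum(var.format(depth_field)))
            except (TypeError, ValueError, KeyError):
                depth = 0
        gts = var.genotypes[0][:2] if var.genotypes else (None, None)
        n_alt = sum(1 for a in gts if a == 1) if None not in gts and -1 not in gts else None
        aa_arch = var.INFO.get("AA")
        if m is None:
            records.append(
                SiteRecord(
                    chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=var.ALT[0],
                    archaic_gt=n_alt, archaic_depth=int(depth),
                    archaic_filter=var.FILTER or "PASS", modern_filter="PASS",
                    modern_derived_freq=0.0, ancestral_allele_src1=aa_arch,
                    ancestral_allele_src2=None, biallelic_in_both=False,
                )
            )
            continue
        m_ref, m_alt, m_filter, m_af, aa_mod = m
        same_poly = (var.REF, var.ALT[0]) == (m_ref, m_alt)
        # polarise: derived = non-ancestral allele
        ancestral = aa_arch if aa_arch is not None else aa_mod
        if ancestral is not None and ancestral == var.ALT[0]:
            arch_gt = None if n_alt is None else 2 - n_alt
            mod_freq = 1.0 - m_af
        else:
            arch_gt = n_alt
            mod_freq = m_af
        records.append(
            SiteRecord(
                chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=var.ALT[0],
                archaic_gt=arch_gt, archaic_depth=int(depth),
                archaic_filter=var.FILTER or "PASS", modern_filter=m_filter,
                modern_derived_freq=float(np.clip(mod_freq, 0.0, 1.0)),
                ancestral_allele_src1=aa_arch, ancestral_allele_src2=aa_mod,
                biallelic_in_both=True, same_polymorphism=same_poly,
            )
        )
    records.sort(key=lambda r: r.pos)
    return records


def write_site_table(records: Iterable[SiteRecord], path: str) -> None:
    import pandas as pd

    df = pd.DataFrame([vars(r) if not hasattr(r, "__dataclass_fields__") else
                       {k: getattr(r, k) for k in r.__dataclass_fields__} for r in records])
    df.to_csv(path, sep="\t", index=False)
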