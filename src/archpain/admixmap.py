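"""Admixture-mapping segments from called archaic tracts.

Each individual's genotype at each site is recoded as the number of their
two haplotypes carrying a retained archaic tract over that position (0/1/2).
Consecutive sites whose dosage columns are (nearly) identical across all
individuals are then merged into segments: a segment opens at the first
unassigned site, whose column becomes the representative, and each
subsequent site joins while its column differs from the representative in
fewer than ``max_diff_frac`` of individuals.  Comparing against the segment's
first column (rather than the previous site) prevents unbounded drift under
chains of near-identical columns; the adjacent-comparison variant is
available behind ``compare="adjacent"``.

Segments with archaic frequency above ``min_freq`` (default 1%) enter the
association battery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from archpain.introgression import IntrogressionTract

__all__ = ["DosageMatrix", "Segment", "archaic_dosage", "merge_segments", "filter_segments"]


@dataclass
class DosageMatrix:
    """Per-individual archaic-copy counts (individuals x sites)."""

    values: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("dosage shape does not match sample_ids x positions")
        if self.values.size and not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("dosage entries must be 0/1/2")


@dataclass(frozen=True)
class Segment:
    first_site_idx: int
    last_site_idx: int
    start_pos: int
    end_pos: int
    representative_dosage: np.ndarray
    archaic_freq: float

    @property
    def n_sites(self) -> int:
        return self.last_site_idx - self.first_site_idx + 1

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


def archaic_dosage(
    tracts: Sequence[IntrogressionTract],
    positions: Sequence[int],
    hap_owner: Mapping[str, str],
    sample_ids: Sequence[str],
) -> DosageMatrix:
    """Count, per (individual, site), haplotypes with a tract covering the site."""
    pos = np.asarray(positions, dtype=np.int64)
    idx = {s: i for i, s in enumerate(sample_ids)}
    values = np.zeros((len(sample_ids), len(pos)), dtype=np.int8)
    for t in tracts:
        owner = hap_owner.get(t.hap_id)
        if owner is None:
            raise KeyError(f"haplotype {t.hap_id} has no owning individual")
        row = idx[owner]
        lo = np.searchsorted(pos, t.start_pos, side="left")
        hi = np.searchsorted(pos, t.end_pos, side="right")
        values[row, lo:hi] += 1
    if values.size and values.max() > 2:
        raise ValueError("an individual carries >2 overlapping tracts at one site; tracts per haplotype must be non-overlapping")
    return DosageMatrix(values=values, positions=pos, sample_ids=list(sample_ids))


def merge_segments(
    dosage: DosageMatrix, max_diff_frac: float = 0.001, compare: str = "representative"
) -> list[Segment]:
    """Greedy left-to-right merge of near-identical dosage columns.

    A site joins the open segment iff its column is identical to the
    comparison column, or differs in strictly fewer than ``max_diff_frac``
    of individuals.  With ``max_diff_frac=0`` this reduces exactly to
    run-length encoding of identical columns.
    """
    if compare not in ("representative", "adjacent"):
        raise ValueError("compare must be 'representative' or 'adjacent'")
    V = dosage.values
    n_ind, n_sites = V.shape
    if n_sites == 0:
        raise ValueError("need at least one site")
    segments: list[Segment] = []
    start = 0
    ref = V[:, 0]
    for j in range(1, n_sites + 1):
        if j < n_sites:
            cmp_col = ref if compare == "representative" else V[:, j - 1]
            n_diff = int((V[:, j] != cmp_col).sum())
            joins = n_diff == 0 or (n_diff / n_ind) < max_diff_frac
        else:
            joins = False
        if not joins:
            rep = V[:, start].copy()
            segments.append(
                Segment(
                    first_site_idx=start,
                    last_site_idx=j - 1,
                    start_pos=int(dosage.positions[start]),
                    end_pos=int(dosage.positions[j - 1]),
                    representative_dosage=rep,
                    archaic_freq=float(rep.mean()) / 2.0,
                )
            )
            if j < n_sites:
                start = j
                ref = V[:, j]
    return segments


def filter_segments(
    segments: Sequence[Segment], min_freq: float = 0.01
) -> tuple[list[Segment], dict]:
    """Retain segments with archaic frequency strictly above ``min_freq``."""
    kept = [s for s in segments if s.archaic_freq > min_freq]
    summary = {
        "n_retained": len(kept),
        "n_input": len(segments),
        "mean_length_kb": float(np.mean([s.length_bp for s in kept]) / 1_000.0) if kept else 0.0,
    }
    return kept, summary
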