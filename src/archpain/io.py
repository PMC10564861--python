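"""Writers for the pipeline's text artefacts (VCF, BED, TSV, YAML).

All writers stamp the generating seed into a header/comment line so any
artefact can be traced to its configuration.  Coordinates are 1-based
inclusive internally; BED export converts to 0-based half-open.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Sequence

import pandas as pd

from archpain.haplotypes import AncestryTract
from archpain.introgression import IntrogressionTract
from archpain.admixmap import Segment
from archpain.sites import SiteRecord

__all__ = [
    "write_vcf",
    "write_tracts_bed",
    "write_ancestry_bed",
    "write_phenotypes_tsv",
    "write_segments_tsv",
    "write_results_tsv",
    "write_manifest",
]


def write_vcf(panel, sites: Sequence[SiteRecord], path: str, seed: int) -> None:
    """Phased genotypes as VCF 4.2 (GT with '|' separator)."""
    pos_to_site = {s.pos: s for s in sites}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##archpain_seed={seed}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write("##contig=<ID=2>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.sample_ids) + "\n")
        for j, pos in enumerate(panel.positions):
            site = pos_to_site.get(int(pos))
            ref = site.ref if site else "A"
            alt = site.alt if site else "T"
            col = panel.alleles[:, j]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(panel.sample_ids)))
            fh.write(f"2\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_tracts_bed(tracts: Iterable[IntrogressionTract], path: str, seed: int, chrom: str = "2") -> None:
    with open(path, "w") as fh:
        fh.write(f"# archpain introgression tracts; seed={seed}; 0-based half-open\n")
        for t in tracts:
            fh.write(f"{chrom}\t{t.start_pos - 1}\t{t.end_pos}\t{t.hap_id}\t{t.mean_posterior:.6f}\t{t.length_bp}\n")


def write_ancestry_bed(tracts: Iterable[AncestryTract], path: str, seed: int, chrom: str = "2") -> None:
    with open(path, "w") as fh:
        fh.write(f"# archpain ancestry tracts; seed={seed}; 0-based half-open\n")
        for t in tracts:
            fh.write(f"{chrom}\t{t.start_pos - 1}\t{t.end_pos}\t{t.hap_id}\t{t.ancestry}\n")


def write_phenotypes_tsv(phen: pd.DataFrame, path: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# archpain phenotypes; seed={seed}\n")
        phen.to_csv(fh, sep="\t", index=False)


def write_segments_tsv(segments: Sequence[Segment], path: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# archpain admixture-mapping segments; seed={seed}\n")
        fh.write("segment\tfirst_site_idx\tlast_site_idx\tstart_pos\tend_pos\tn_sites\tlength_bp\tarchaic_freq\n")
        for k, s in enumerate(segments, start=1):
            fh.write(
                f"{k}\t{s.first_site_idx}\t{s.last_site_idx}\t{s.start_pos}\t{s.end_pos}\t"
                f"{s.n_sites}\t{s.length_bp}\t{s.archaic_freq:.6f}\n"
            )


def write_results_tsv(results, significant, threshold: float, path: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# archpain association results; seed={seed}; bh_threshold={threshold:.6g}\n")
        fh.write("test_id\tfamily\ttrait\tbeta\tse\tp\tn\tsignificant\n")
        for r, sig in zip(results, significant):
            fh.write(
                f"{r.test_id}\t{r.family}\t{r.trait}\t{r.beta:.6g}\t{r.se:.6g}\t{r.p:.6g}\t{r.n}\t{int(sig)}\n"
            )


def write_manifest(manifest: Mapping, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
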