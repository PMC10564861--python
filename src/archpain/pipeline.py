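"""Configuration-driven end-to-end orchestration.

`run_pipeline` executes the full chain — simulate, ascertain, decode,
calibrate, call tracts, ancestry-aligned haplotype statistics,
admixture-mapping segments, association battery, BH correction — from one
seeded random generator, writes all artefacts, and returns a manifest with
stage-wise record counts and output checksums.  Identical config + seed
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from dataclasses import dataclass, field

import numpy as np

from archpain import io as aio
from archpain.admixmap import archaic_dosage, filter_segments, merge_segments
from archpain.assoc import (
    BatteryConfig,
    bh_threshold,
    haplotype_copy_counts,
    prepare_phenotypes,
    run_test_battery,
)
from archpain.haplotypes import (
    allele_freq_by_ancestry,
    haplotype_frequencies,
    ld_stats,
    merge_paired_locus,
    single_ancestry_chromosomes,
)
from archpain.introgression import (
    HMMParams,
    apply_length_cutoff,
    calibrate_length_cutoff,
    call_tracts,
    decode_panel,
    summarize_introgression,
)
from archpain.simdata import SimConfig, simulate_cohort, simulate_reference_panel
from archpain.sites import ascertain_sites

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    hmm: HMMParams = field(default_factory=HMMParams)
    min_depth: int = 20
    calibration_tolerance: float = 1e-4
    merge_max_diff_frac: float = 0.001
    segment_min_freq: float = 0.01
    fdr_q: float = 0.05
    seed: int = 1234

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        hmm = HMMParams(**raw.pop("hmm", {}))
        cfg = cls(sim=sim, hmm=hmm, **raw)
        cfg.sim.seed = cfg.seed
        return cfg

    def to_yaml(self, path: str) -> None:
        import yaml

        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            return x

        with open(path, "w") as fh:
            yaml.safe_dump(plain(dataclasses.asdict(self)), fh, sort_keys=True)


@dataclass
class PipelineResult:
    sites: list
    panel: object
    truth: object
    tracts_all: list
    tracts: list
    calibration: object
    partition: dict
    summary: object
    hapfreqs: object
    ld_ab: object
    segments_all: list
    segments: list
    phenotypes_clean: object
    exclusions: object
    assoc_results: list
    bh: tuple
    manifest: dict


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    rng = np.random.default_rng(config.seed)
    sim = config.sim
    region = (sim.region_start, sim.region_end)

    # 1-2: reference proxies and site ascertainment
    raw_sites = simulate_reference_panel(sim, rng)
    asc = ascertain_sites(raw_sites, min_depth=config.min_depth)
    sites = asc.retained

    # 3: cohort
    panel, truth, phen_raw = simulate_cohort(sim, sites, rng)

    # 4: HMM scan and tract calling (posterior filter only, pre-cutoff)
    paths, posts = decode_panel(panel.alleles, sites, config.hmm)
    tracts_all = []
    for i, hap_id in enumerate(panel.hap_ids):
        tracts_all.extend(call_tracts(paths[i], posts[i], sites, config.hmm, hap_id=hap_id))

    # 5: length-cutoff calibration on African-background chromosomes
    partition = single_ancestry_chromosomes(truth.ancestry_tracts, region)
    if partition["AFR"]:
        calibration = calibrate_length_cutoff(
            tracts_all, partition["AFR"], region, tolerance=config.calibration_tolerance
        )
        cutoff = calibration.cutoff_bp
    else:  # tiny cohorts may lack African-background chromosomes entirely
        calibration = None
        cutoff = 0.0
    tracts = apply_length_cutoff(tracts_all, cutoff)

    groups = {"all": set(panel.hap_ids), **{a: partition[a] for a in ("AFR", "EUR", "NAM")}}
    summary = summarize_introgression(tracts, groups, region)

    # 6: ancestry-aligned haplotype and LD statistics
    p1, p2, p3 = sim.focal_positions
    a1 = panel.alleles_at(p1)
    merged = merge_paired_locus(panel.alleles_at(p2), panel.alleles_at(p3))
    a2 = merged.alleles
    hapfreqs, hap_counts_chr = haplotype_frequencies(a1, a2)
    ld_ab = ld_stats(hapfreqs)
    anc_freqs = allele_freq_by_ancestry(
        panel.alleles, panel.hap_ids, panel.positions, sim.focal_positions, partition
    )

    # 7: admixture-mapping segments
    dosage = archaic_dosage(tracts, panel.positions, panel.hap_owner(), panel.sample_ids)
    segments_all = merge_segments(dosage, max_diff_frac=config.merge_max_diff_frac)
    segments, seg_summary = filter_segments(segments_all, min_freq=config.segment_min_freq)

    # 8: phenotype QC and association battery
    phen_clean, exclusions = prepare_phenotypes(phen_raw)
    g1 = a1.reshape(-1, 2).sum(axis=1)
    g2 = a2.reshape(-1, 2).sum(axis=1)
    hc = haplotype_copy_counts(a1, a2)
    bat_cfg = BatteryConfig(fdr_q=config.fdr_q, locus_labels=("D1908G_like", "V991L_M932L_like"))
    results = run_test_battery(g1, g2, hc, segments, panel.sample_ids, phen_clean, bat_cfg)
    threshold, significant, k_star = bh_threshold([r.p for r in results], q=config.fdr_q)

    manifest = {
        "seed": config.seed,
        "counts": {
            "sites_simulated": len(raw_sites),
            "sites_retained": len(sites),
            "site_rejections": asc.rejection_counts,
            "individuals": sim.n_individuals,
            "haplotypes": panel.n_haplotypes,
            "tracts_pre_cutoff": len(tracts_all),
            "tracts_post_cutoff": len(tracts),
            "length_cutoff_bp": cutoff,
            "single_ancestry": {a: len(partition[a]) for a in ("AFR", "EUR", "NAM")},
            "mixed_ancestry": len(partition["mixed"]),
            "locus_pair_concordance": merged.concordance,
            "segments_all": len(segments_all),
            "segments_retained": len(segments),
            "phenotype_exclusion_events": len(exclusions),
            "association_tests": len(results),
            "bh_threshold": threshold,
            "bh_significant": int(np.asarray(significant).sum()),
        },
        "outputs": {},
    }
    # stage-count conservation checks
    assert len(sites) + asc.n_rejected == len(raw_sites)
    assert len(tracts) <= len(tracts_all)
    assert sum(s.n_sites for s in segments_all) == len(sites)

    result = PipelineResult(
        sites=sites, panel=panel, truth=truth, tracts_all=tracts_all, tracts=tracts,
        calibration=calibration, partition=partition, summary=summary, hapfreqs=hapfreqs,
        ld_ab=ld_ab, segments_all=segments_all, segments=segments,
        phenotypes_clean=phen_clean, exclusions=exclusions, assoc_results=results,
        bh=(threshold, significant, k_star), manifest=manifest,
    )

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        seed = config.seed
        paths_out = {
            "genotypes.vcf": lambda p: aio.write_vcf(panel, sites, p, seed),
            "tracts.bed": lambda p: aio.write_tracts_bed(tracts, p, seed),
            "ancestry.bed": lambda p: aio.write_ancestry_bed(truth.ancestry_tracts, p, seed),
            "phenotypes.tsv": lambda p: aio.write_phenotypes_tsv(phen_raw, p, seed),
            "segments.tsv": lambda p: aio.write_segments_tsv(segments, p, seed),
            "assoc_results.tsv": lambda p: aio.write_results_tsv(results, significant, threshold, p, seed),
        }
        for name, writer in paths_out.items():
            path = os.path.join(outdir, name)
            writer(path)
            manifest["outputs"][name] = _sha256(path)
        summary.to_csv(os.path.join(outdir, "introgression_summary.tsv"), sep="\t", index=False)
        manifest["outputs"]["introgression_summary.tsv"] = _sha256(
            os.path.join(outdir, "introgression_summary.tsv")
        )
        anc_freqs.to_csv(os.path.join(outdir, "ancestry_allele_freqs.tsv"), sep="\t")
        manifest["outputs"]["ancestry_allele_freqs.tsv"] = _sha256(
            os.path.join(outdir, "ancestry_allele_freqs.tsv")
        )
        aio.write_manifest(manifest, os.path.join(outdir, "manifest.json"))
    return result
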