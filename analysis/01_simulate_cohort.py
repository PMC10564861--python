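"""Simulate the admixed study cohort and write its artefacts.

Generates the reference-proxy site panel, ascertains sites, simulates a
500-individual phased cohort (three-way continental ancestry, archaic
tracts nested in Native-American segments, six pain phenotypes) and writes
genotypes (VCF), truth tracts (BED), phenotypes (TSV) and the run manifest
under results/01_cohort/.
"""

import pathlib

from archpain.pipeline import PipelineConfig, run_pipeline
from archpain.simdata import SimConfig

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "01_cohort"

config = PipelineConfig(sim=SimConfig(n_individuals=500, seed=42), seed=42)
res = run_pipeline(config, outdir=str(OUT))
c = res.manifest["counts"]
print(f"simulated {c['individuals']} individuals over {c['sites_retained']} ascertained sites")
print(f"site rejections by first failing rule: {c['site_rejections']}")
print(
    f"single-ancestry chromosomes: AFR {c['single_ancestry']['AFR']}, "
    f"EUR {c['single_ancestry']['EUR']}, NAM {c['single_ancestry']['NAM']} "
    f"({c['mixed_ancestry']} mixed)"
)
print(f"artefacts in {OUT}")
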