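"""Shared fixtures: small simulated cohorts and site panels.

Everything is generated programmatically from fixed seeds; session scope
keeps the full-density cohort (used by the HMM recovery tests) to a single
simulation per run.
"""

import numpy as np
import pytest

from archpain.simdata import SimConfig, simulate_cohort, simulate_reference_panel
from archpain.sites import SiteRecord, ascertain_sites


def make_sites(positions, archaic_gts, modern_freqs, chrom="2"):
    """Clean SiteRecords from parallel arrays (helper for hand-built panels)."""
    return [
        SiteRecord(
            chrom=chrom, pos=int(p), ref="A", alt="T", archaic_gt=int(g),
            archaic_depth=30, modern_derived_freq=float(f),
            ancestral_allele_src1="A", ancestral_allele_src2="A",
        )
        for p, g, f in zip(positions, archaic_gts, modern_freqs)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """100 individuals at full site density, with ascertained sites and truth."""
    config = SimConfig(n_individuals=100, seed=20240917)
    rng = np.random.default_rng(config.seed)
    sites = ascertain_sites(simulate_reference_panel(config, rng)).retained
    panel, truth, phen = simulate_cohort(config, sites, rng)
    return config, sites, panel, truth, phen


@pytest.fixture(scope="session")
def sparse_cohort():
    """300 individuals at reduced site density (association-scale fixture)."""
    config = SimConfig(n_individuals=300, site_density=400 / 4.18e6, seed=77)
    rng = np.random.default_rng(config.seed)
    sites = ascertain_sites(simulate_reference_panel(config, rng)).retained
    panel, truth, phen = simulate_cohort(config, sites, rng)
    return config, sites, panel, truth, phen
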