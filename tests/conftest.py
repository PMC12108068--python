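"""Shared fixtures: synthetic study data generated once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tealseq import simulate as sim
from tealseq.models import PanelConfig
from tealseq.pipeline import design_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # seeded rng fixtures are deliberately shared across generated inputs
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


def two_species_config(seed: int, n_core: int = 100, n_accessory: int = 0) -> sim.SimConfig:
    """The default desk-scale study: two staphylococcus-like species, eight
    strains each, SNPs at 0.5%, an off-target relative and host background."""
    return sim.SimConfig(
        seed=seed,
        species=[
            sim.SpeciesSimConfig("Se", n_core_genes=n_core, n_accessory_genes=n_accessory),
            sim.SpeciesSimConfig("Sa", n_core_genes=n_core, n_accessory_genes=n_accessory),
        ],
    )


@pytest.fixture(scope="session")
def truth_small():
    """Small pangenome (2 species x 25 genes) with expression truth."""
    cfg = two_species_config(seed=11, n_core=20, n_accessory=5)
    rng = cfg.rng()
    truth = sim.simulate_pangenome(cfg, rng)
    sim.simulate_expression(truth, cfg, rng)
    return truth


@pytest.fixture(scope="session")
def truth_e2e():
    """The end-to-end study pangenome: 2 species x 100 core genes."""
    cfg = two_species_config(seed=7)
    rng = cfg.rng()
    truth = sim.simulate_pangenome(cfg, rng)
    sim.simulate_expression(truth, cfg, rng)
    return truth


@pytest.fixture(scope="session")
def panel_config():
    return PanelConfig(inclusion_min_genomes=5)


def design_for(truth, species_id, arch, config):
    st = truth.species[species_id]
    others = [
        truth.species[o].reference for o in sorted(truth.species) if o != species_id
    ]
    return design_panel(
        st.reference,
        st.cds,
        config,
        arch,
        species_id,
        st.strains,
        truth.offtarget_genomes + others,
        truth.host_transcripts,
    )


@pytest.fixture(scope="session")
def mip_panels(truth_e2e, panel_config):
    """Designed MIP panels for both species of the end-to-end study."""
    return {
        sid: design_for(truth_e2e, sid, "MIP", panel_config)
        for sid in sorted(truth_e2e.species)
    }


@pytest.fixture(scope="session")
def spe_panel_small(truth_small, panel_config):
    return design_for(truth_small, "Se", "SPE", panel_config)


@pytest.fixture(scope="session")
def mip_panel_small(truth_small, panel_config):
    return design_for(truth_small, "Se", "MIP", panel_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
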