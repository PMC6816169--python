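from __future__ import annotations

import pytest

from domortho.core import build_groups, groups_to_domain_pairs
from domortho.extraction import extract_proteome
from domortho.model import Config
from domortho.protein import build_domain_map, project_protein_pairs
from domortho.similarity import all_vs_all, apply_hit_filters
from domortho.synthetic import EvolutionScenario, generate


def run_full(scenario: EvolutionScenario, config: Config | None = None,
             alpha: float = 0.3) -> dict:
    """Run the whole inference chain in memory on a generated scenario."""
    config = config or Config()
    pa, pb, aa, ab, truth = generate(scenario)
    domains_a, report_a = extract_proteome(pa, aa, config)
    domains_b, report_b = extract_proteome(pb, ab, config)
    domains = domains_a + domains_b
    lengths = {d.id: d.length for d in domains}
    species_of = {d.id: d.species for d in domains}
    cross, wa, wb = all_vs_all(domains_a, domains_b)
    cross = apply_hit_filters(cross, lengths, config)
    wa = apply_hit_filters(wa, lengths, config)
    wb = apply_hit_filters(wb, lengths, config)
    groups = build_groups(cross, wa, wb, species_of,
                          scenario.species_a, scenario.species_b)
    domain_map = build_domain_map(domains)
    return {
        "truth": truth,
        "proteomes": (pa, pb),
        "annotations": (aa, ab),
        "domains": (domains_a, domains_b),
        "reports": (report_a, report_b),
        "groups": groups,
        "domain_map": domain_map,
        "domain_pairs": {frozenset((a, b))
                         for a, b, _ in groups_to_domain_pairs(groups)},
        "protein_pairs": {p.key
                          for p in project_protein_pairs(groups, domain_map,
                                                         alpha)},
    }


@pytest.fixture(scope="session")
def zero_divergence_run() -> dict:
    """Identical-sequence two-species scenario: 20 families, 30 proteins,
    no fusion/fission, substitution rate 0."""
    scenario = EvolutionScenario(rng_seed=1, substitution_rate=0.0,
                                 p_fusion=0.0, p_fission=0.0)
    return run_full(scenario)


@pytest.fixture(scope="session")
def diverged_run() -> dict:
    """Same conditions at substitution rate 0.3 per lineage."""
    scenario = EvolutionScenario(rng_seed=1, substitution_rate=0.3,
                                 p_fusion=0.0, p_fission=0.0)
    return run_full(scenario)
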