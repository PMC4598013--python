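import itertools

import numpy as np
import pytest

from hc4n.similarity import co_occurrence_matrix
from hc4n.simulate import (
    PlantedHierarchy,
    SimulationConfig,
    detection_probability,
    plant_hierarchy,
    simulate_ips,
)


def tier_of_pair(h: PlantedHierarchy, p: str, q: str) -> str:
    if h.core_of.get(p, -1) == h.core_of.get(q, -2):
        return "core"
    pc, qc = set(h.complex_of.get(p, ())), set(h.complex_of.get(q, ()))
    if pc & qc:
        return "complex"
    asm = {c: a for a, group in enumerate(h.assembly_complexes) for c in group}
    if {asm[c] for c in pc} & {asm[c] for c in qc}:
        return "assembly"
    return "background"


def tier_means(h: PlantedHierarchy, co) -> dict[str, float]:
    vals: dict[str, list[float]] = {}
    for i, j in itertools.combinations(range(len(co.protein_ids)), 2):
        t = tier_of_pair(h, co.protein_ids[i], co.protein_ids[j])
        vals.setdefault(t, []).append(co.values[i, j])
    return {t: float(np.mean(v)) for t, v in vals.items()}


class TestPlantHierarchy:
    def test_simple_layout(self):
        cfg = SimulationConfig(
            n_cores=2, n_complexes=1, n_assemblies=1, n_shared=0, n_background=0
        )
        h = plant_hierarchy(cfg)
        assert len(h.cores) == 2 and len(h.complexes) == 1
        assert h.complexes[0] >= h.cores[0] | h.cores[1]

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(rng_seed=5)
        assert plant_hierarchy(cfg) == plant_hierarchy(cfg)

    def test_shared_protein_in_both_complexes(self):
        cfg = SimulationConfig(n_shared=1, rng_seed=2)
        h = plant_hierarchy(cfg)
        (s,) = h.shared_proteins
        hosts = [i for i, cx in enumerate(h.complexes) if s in cx]
        assert len(hosts) == 2

    def test_shared_proteins_without_complex_pair_rejected(self):
        cfg = SimulationConfig(n_complexes=1, n_cores=2, n_assemblies=1, n_shared=1)
        with pytest.raises(ValueError, match="shared"):
            plant_hierarchy(cfg)

    def test_shared_proteins_may_share_a_complex_pair(self):
        cfg = SimulationConfig(n_complexes=2, n_cores=2, n_assemblies=1, n_shared=3, rng_seed=0)
        h = plant_hierarchy(cfg)
        assert len(h.shared_proteins) == 3

    def test_probability_ordering_enforced(self):
        with pytest.raises(ValueError, match="p_background < p_assembly"):
            SimulationConfig(p_background=0.5, p_assembly=0.2).validate()


class TestSimulateIps:
    def test_pure_core_limit(self):
        """p_core=1 and every other tier impossible: IPs with a core bait
        contain exactly that core, and within-core co-occurrence is 1."""
        cfg = SimulationConfig(
            n_cores=2, n_complexes=2, n_assemblies=2, proteins_per_core=3,
            attachments_per_complex=1, n_shared=0, n_background=0, n_ips=40,
            p_core=1.0, p_attach=1e-9, p_assembly=1e-10, p_background=0.0,
            rng_seed=0,
        )
        h = plant_hierarchy(cfg)
        m, baits, dropped = simulate_ips(h, cfg)
        occ = m.occupancy
        pidx = {p: i for i, p in enumerate(m.protein_ids)}
        for j, ip in enumerate(m.ip_ids):
            bait = baits[ip]
            if bait in h.core_of:
                core = h.cores[h.core_of[bait]]
                detected = {m.protein_ids[i] for i in np.flatnonzero(occ[:, j])}
                assert detected == set(core)
        co = co_occurrence_matrix(m)
        for core in h.cores:
            present = [p for p in core if p in pidx]
            for p, q in itertools.combinations(present, 2):
                assert co.value(p, q) == 1.0

    def test_no_cross_complex_co_occurrence_without_assembly_link(self):
        cfg = SimulationConfig(
            n_cores=2, n_complexes=2, n_assemblies=2, n_shared=0, n_background=0,
            p_background=0.0, p_assembly=1e-12, p_attach=0.6, n_ips=60, rng_seed=3,
        )
        h = plant_hierarchy(cfg)
        m, _, _ = simulate_ips(h, cfg)
        co = co_occurrence_matrix(m)
        for p in h.complexes[0]:
            for q in h.complexes[1]:
                if p in m.protein_ids and q in m.protein_ids:
                    assert co.value(p, q) == 0.0

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(rng_seed=11, n_ips=50)
        h = plant_hierarchy(cfg)
        m1, b1, _ = simulate_ips(h, cfg)
        m2, b2, _ = simulate_ips(h, cfg)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert b1 == b2

    def test_marginal_detection_probability_matches_tier(self):
        cfg = SimulationConfig(rng_seed=0)
        h = plant_hierarchy(cfg)
        bait = sorted(h.cores[0])[0]
        same_core = sorted(h.cores[0])[1]
        assert detection_probability(h, cfg, bait, same_core) == cfg.p_core
        attachment_host = h.complex_of[bait][0]
        other_assembly_cx = next(
            i for i in range(cfg.n_complexes)
            if i % cfg.n_assemblies != attachment_host % cfg.n_assemblies
        )
        foreign = sorted(h.complexes[other_assembly_cx] - h.complexes[attachment_host])[0]
        assert detection_probability(h, cfg, bait, foreign) == cfg.p_background

    @pytest.mark.parametrize("seed", range(5))
    def test_tier_ordering_of_empirical_co_occurrence(self, seed):
        """core > complex > assembly > background mean co-occurrence, with
        margin, at the default configuration."""
        cfg = SimulationConfig(rng_seed=seed)
        h = plant_hierarchy(cfg)
        m, _, _ = simulate_ips(h, cfg)
        means = tier_means(h, co_occurrence_matrix(m))
        assert means["core"] > means["complex"] + 0.05
        assert means["complex"] > means["assembly"] + 0.05
        assert means["assembly"] > means.get("background", 0.0) + 0.05

    def test_shared_proteins_show_characteristic_pattern(self):
        """A shared protein co-occurs with members of every hosting complex
        well above the cross-complex background."""
        cfg = SimulationConfig(rng_seed=1)
        h = plant_hierarchy(cfg)
        m, _, _ = simulate_ips(h, cfg)
        co = co_occurrence_matrix(m)
        cross = tier_means(h, co)["assembly"]
        for s in h.shared_proteins:
            for cxi in h.complex_of[s]:
                links = [
                    co.value(s, q)
                    for q in h.complexes[cxi]
                    if q != s and q in m.protein_ids
                ]
                assert np.mean(links) > cross

    def test_abundance_kind_produces_nonnegative_reals(self):
        cfg = SimulationConfig(rng_seed=2, data_kind="abundance", n_ips=60)
        h = plant_hierarchy(cfg)
        m, _, _ = simulate_ips(h, cfg)
        assert m.data_kind == "abundance"
        assert (m.values >= 0).all()
        assert not np.all(np.isin(m.values, (0.0, 1.0)))
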