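"""Synthetic bait-prey IP/MS data with a planted multi-level hierarchy.

The generator plants the organizational levels a real bait-prey screen
exhibits: stable complex *cores* of tightly co-detected proteins, complexes
built of cores plus looser *attachments*, *assemblies* of transiently
interacting complexes, proteins *shared* between complexes, and a pool of
background contaminants.  Detection follows the spoke model: in each IP a
bait is pulled down and every other protein is detected with the probability
of the tightest relationship linking it to that bait (same core > same
complex > same assembly > background).  The ordering of these probabilities
is what places the tiers at decreasing empirical co-occurrence, which is the
structure the hierarchical clustering is meant to recover; the ground truth
comes back as one complex catalog per level.

A core is captured as a unit: whether a bait's pull-down reaches a core is
drawn once per core and IP (at the tier probability of the bait-core
relationship), and on success the whole core is detected.  All-or-none
capture is the defining property of a stable core — its members occur
together throughout the data — and it is what places within-core pairs at
the top of the co-occurrence ordering.  Attachments, shared proteins and
contaminants are detected by independent per-protein draws.  Marginally,
every protein is still detected with exactly the probability of its
tightest relationship to the bait.

What is emulated and what is not: the tiered co-occurrence structure,
bait-driven IP composition, core-unit capture, overlap through shared
proteins and contaminant noise are; peptide-level detectability and other
mass-spectrometry noise physics are not — beyond the shared core draw,
detections are independent Bernoulli draws given the bait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hc4n.data_io import ABUNDANCE, OCCURRENCE, ComplexCatalog, IPMSMatrix


@dataclass
class SimulationConfig:
    """Counts, detection probabilities and abundance model for one simulation.

    Defaults describe a desk-scale screen: 8 cores of 3 proteins grouped two
    per complex, 4 complexes with 2 attachments each grouped two per
    assembly, 2 proteins shared between complex pairs, 6 background
    contaminants and 200 IPs — a miniature of the published large screens'
    structure.  The detection probabilities keep the strict tier ordering
    background < assembly < attachment < core.
    """

    n_cores: int = 8
    n_complexes: int = 4
    n_assemblies: int = 2
    proteins_per_core: int = 3
    attachments_per_complex: int = 2
    n_shared: int = 2
    n_background: int = 6
    n_ips: int = 200
    p_core: float = 0.95
    p_attach: float = 0.6
    p_assembly: float = 0.2
    p_background: float = 0.01
    # log-normal abundance model (natural-log scale)
    abundance_mu: float = 2.0
    abundance_sigma: float = 0.5
    tier_factor: dict = field(
        default_factory=lambda: {"core": 1.0, "complex": 0.5, "assembly": 0.2, "background": 0.05}
    )
    data_kind: str = OCCURRENCE
    rng_seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_cores, self.n_complexes, self.n_assemblies,
            self.proteins_per_core, self.attachments_per_complex, self.n_ips,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all structural counts must be >= 1")
        if self.n_shared < 0 or self.n_background < 0:
            raise ValueError("shared/background counts must be >= 0")
        if not (0.0 <= self.p_background < self.p_assembly < self.p_attach < self.p_core <= 1.0):
            raise ValueError(
                "detection probabilities must satisfy "
                "0 <= p_background < p_assembly < p_attach < p_core <= 1"
            )
        if self.n_cores < self.n_complexes:
            raise ValueError("need at least one core per complex")
        if self.n_complexes < self.n_assemblies:
            raise ValueError("need at least one complex per assembly")
        if self.n_shared > 0 and self.n_complexes < 2:
            raise ValueError(
                "shared proteins need at least 2 complexes to be shared between"
            )


@dataclass
class PlantedHierarchy:
    """Ground truth of one simulation.

    ``complex_of`` maps each non-background protein to the complexes hosting
    it (shared proteins map to several); ``core_of`` maps core members to
    their core index.
    """

    cores: list[frozenset[str]]
    complexes: list[frozenset[str]]          # core members + attachments + shared
    assemblies: list[frozenset[str]]         # unions of member complexes
    complex_cores: list[tuple[int, ...]]     # core indices per complex
    assembly_complexes: list[tuple[int, ...]]
    shared_proteins: frozenset[str]
    background_proteins: frozenset[str]
    core_of: dict[str, int]
    complex_of: dict[str, tuple[int, ...]]

    @property
    def all_proteins(self) -> list[str]:
        seen: list[str] = []
        for cx in self.complexes:
            for p in sorted(cx):
                if p not in seen:
                    seen.append(p)
        seen.extend(sorted(self.background_proteins))
        return seen

    def catalog(self, level: str) -> ComplexCatalog:
        """Ground-truth catalog at ``level`` in {'core', 'complex', 'assembly'}."""
        if level == "core":
            return ComplexCatalog({f"core{i}": s for i, s in enumerate(self.cores)})
        if level == "complex":
            return ComplexCatalog({f"complex{i}": s for i, s in enumerate(self.complexes)})
        if level == "assembly":
            return ComplexCatalog({f"assembly{i}": s for i, s in enumerate(self.assemblies)})
        raise ValueError(f"unknown ground-truth level {level!r}")


def plant_hierarchy(cfg: SimulationConfig) -> PlantedHierarchy:
    """Lay out cores, complexes, assemblies, shared and background proteins.

    Deterministic given ``cfg.rng_seed``: cores are assigned to complexes and
    complexes to assemblies round-robin, shared proteins to seeded-random
    complex pairs (several shared proteins may land on the same pair).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    width = 4
    cores: list[frozenset[str]] = []
    counter = 0
    for _ in range(cfg.n_cores):
        members = [f"P{counter + k:0{width}d}" for k in range(cfg.proteins_per_core)]
        counter += cfg.proteins_per_core
        cores.append(frozenset(members))

    complex_cores: list[list[int]] = [[] for _ in range(cfg.n_complexes)]
    for ci in range(cfg.n_cores):
        complex_cores[ci % cfg.n_complexes].append(ci)

    attachments: list[list[str]] = []
    for _ in range(cfg.n_complexes):
        members = [f"A{counter + k:0{width}d}" for k in range(cfg.attachments_per_complex)]
        counter += cfg.attachments_per_complex
        attachments.append(members)

    # shared proteins: each lives in one seeded-random pair of complexes;
    # several shared proteins may join the same pair (the characteristic
    # multi-protein pattern between two complexes)
    pairs = [(i, j) for i in range(cfg.n_complexes) for j in range(i + 1, cfg.n_complexes)]
    pick = rng.choice(len(pairs), size=cfg.n_shared, replace=True) if cfg.n_shared else []
    shared: list[tuple[str, tuple[int, int]]] = []
    for k in sorted(int(x) for x in pick):
        shared.append((f"S{counter:0{width}d}", pairs[k]))
        counter += 1

    background = [f"B{counter + k:0{width}d}" for k in range(cfg.n_background)]

    complexes: list[set[str]] = []
    for cxi in range(cfg.n_complexes):
        members: set[str] = set()
        for ci in complex_cores[cxi]:
            members |= cores[ci]
        members |= set(attachments[cxi])
        complexes.append(members)
    for name, (i, j) in shared:
        complexes[i].add(name)
        complexes[j].add(name)

    assembly_complexes: list[list[int]] = [[] for _ in range(cfg.n_assemblies)]
    for cxi in range(cfg.n_complexes):
        assembly_complexes[cxi % cfg.n_assemblies].append(cxi)
    assemblies = [
        frozenset().union(*(complexes[cxi] for cxi in group)) for group in assembly_complexes
    ]

    core_of = {p: ci for ci, core in enumerate(cores) for p in core}
    complex_of: dict[str, tuple[int, ...]] = {}
    for cxi, members in enumerate(complexes):
        for p in members:
            complex_of[p] = tuple(sorted(set(complex_of.get(p, ())) | {cxi}))

    return PlantedHierarchy(
        cores=cores,
        complexes=[frozenset(s) for s in complexes],
        assemblies=assemblies,
        complex_cores=[tuple(c) for c in complex_cores],
        assembly_complexes=[tuple(a) for a in assembly_complexes],
        shared_proteins=frozenset(name for name, _ in shared),
        background_proteins=frozenset(background),
        core_of=core_of,
        complex_of=complex_of,
    )


def _assembly_of(h: PlantedHierarchy) -> dict[int, int]:
    return {cxi: ai for ai, group in enumerate(h.assembly_complexes) for cxi in group}


def detection_probability(h: PlantedHierarchy, cfg: SimulationConfig, bait: str, prey: str) -> float:
    """Spoke-model detection probability of ``prey`` given ``bait``: the
    probability of the tightest relationship linking the two."""
    if prey == bait:
        return 1.0
    b_cores = {h.core_of[bait]} if bait in h.core_of else set()
    p_cores = {h.core_of[prey]} if prey in h.core_of else set()
    if b_cores & p_cores:
        return cfg.p_core
    b_cx = set(h.complex_of.get(bait, ()))
    p_cx = set(h.complex_of.get(prey, ()))
    if b_cx & p_cx:
        return cfg.p_attach
    asm = _assembly_of(h)
    if {asm[c] for c in b_cx} & {asm[c] for c in p_cx}:
        return cfg.p_assembly
    return cfg.p_background


def core_capture_probability(h: PlantedHierarchy, cfg: SimulationConfig, bait: str, core_index: int) -> float:
    """Probability that one IP with ``bait`` captures core ``core_index`` as
    a unit: the tier probability of the tightest bait-core relationship."""
    if h.core_of.get(bait) == core_index:
        return cfg.p_core
    core_cx = set(h.complex_of[next(iter(h.cores[core_index]))])
    bait_cx = set(h.complex_of.get(bait, ()))
    if core_cx & bait_cx:
        return cfg.p_attach
    asm = _assembly_of(h)
    if {asm[c] for c in core_cx} & {asm[c] for c in bait_cx}:
        return cfg.p_assembly
    return cfg.p_background


def simulate_ips(
    h: PlantedHierarchy, cfg: SimulationConfig
) -> tuple[IPMSMatrix, dict[str, str], list[str]]:
    """Draw the IP/MS matrix.

    Baits cycle round-robin over the non-background proteins and continue
    with seeded-random draws, so every planted protein is a bait at least
    once whenever ``n_ips`` reaches the planted protein count.  Cores are
    captured all-or-none (one draw per core and IP); other proteins are
    drawn independently.  Returns the matrix, the IP -> bait assignment,
    and the proteins dropped for never being detected (possible at low
    probabilities; reported so the ground truth can be restricted
    accordingly).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))
    proteins = h.all_proteins
    planted = [p for p in proteins if p not in h.background_proteins]
    n_p, n_ips = len(proteins), cfg.n_ips
    pidx = {p: i for i, p in enumerate(proteins)}
    loose = [p for p in proteins if p not in h.core_of]  # individually drawn

    # per-bait probability vectors, cached per distinct bait
    core_cache: dict[str, np.ndarray] = {}
    loose_cache: dict[str, np.ndarray] = {}

    def core_probs(bait: str) -> np.ndarray:
        if bait not in core_cache:
            core_cache[bait] = np.array(
                [core_capture_probability(h, cfg, bait, ci) for ci in range(len(h.cores))]
            )
        return core_cache[bait]

    def loose_probs(bait: str) -> np.ndarray:
        if bait not in loose_cache:
            loose_cache[bait] = np.array(
                [detection_probability(h, cfg, bait, p) for p in loose]
            )
        return loose_cache[bait]

    baits: list[str] = []
    for k in range(n_ips):
        if k < len(planted):
            baits.append(planted[k])
        else:
            baits.append(planted[int(rng.integers(len(planted)))])

    occ = np.zeros((n_p, n_ips), dtype=float)
    for j, bait in enumerate(baits):
        captured = rng.random(len(h.cores)) < core_probs(bait)
        for ci, hit in enumerate(captured):
            if hit:
                for p in h.cores[ci]:
                    occ[pidx[p], j] = 1.0
        draw = rng.random(len(loose)) < loose_probs(bait)
        for p, hit in zip(loose, draw):
            if hit:
                occ[pidx[p], j] = 1.0
        occ[pidx[bait], j] = 1.0

    if cfg.data_kind == ABUNDANCE:
        base = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, size=(n_p, n_ips))
        scale = np.zeros((n_p, n_ips))
        tier_p = {
            cfg.p_core: cfg.tier_factor["core"],
            cfg.p_attach: cfg.tier_factor["complex"],
            cfg.p_assembly: cfg.tier_factor["assembly"],
            cfg.p_background: cfg.tier_factor["background"],
        }
        marg_cache: dict[str, np.ndarray] = {}
        for j, bait in enumerate(baits):
            if bait not in marg_cache:
                marg_cache[bait] = np.array(
                    [
                        1.0 if p == bait else tier_p.get(detection_probability(h, cfg, bait, p), 1.0)
                        for p in proteins
                    ]
                )
            scale[:, j] = marg_cache[bait]
        values = occ * base * scale
        kind = ABUNDANCE
    else:
        values = occ
        kind = OCCURRENCE

    detected = (values > 0).any(axis=1)
    dropped = [p for p, d in zip(proteins, detected) if not d]
    keep = [i for i, d in enumerate(detected) if d]
    matrix = IPMSMatrix(
        [proteins[i] for i in keep],
        [f"ip{j:04d}" for j in range(n_ips)],
        values[keep, :],
        kind,
    )
    bait_assignment = {f"ip{j:04d}": baits[j] for j in range(n_ips)}
    return matrix, bait_assignment, dropped
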