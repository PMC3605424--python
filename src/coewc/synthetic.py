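"""Synthetic PPI networks and coupled expression data for testing.

Real interactome hubs fall into two essential classes — *party hubs*, embedded
inside one dense module and co-expressed with its members, and *date hubs*,
bridging several dense modules and co-expressed with one anchor per module —
plus non-essential star-like hubs whose partners are mutually disconnected
singletons (promiscuous or spurious interactors).  The generator plants all
three classes at matched degree on a background of disjoint cliques, so a
ranking measure's ability to separate them can be asserted seed by seed.

Expression profiles follow a shared-latent-factor model: each planted
party/date hub carries an i.i.d. standard-normal latent signal over the
samples, and each of its neighbours mixes that signal with independent noise
at a mixing weight solved so the population correlation with the hub equals
``target_pcc_signal``.  All remaining proteins get independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor, sqrt

import numpy as np

from .io_formats import EssentialSet, ExpressionMatrix, PPINetwork

__all__ = ["SyntheticSpec", "LabeledNetwork", "make_three_clique_toy", "generate", "perturb"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-hub benchmark network.

    Defaults plant 2 party, 2 date and 2 noisy hubs, all of degree 10, on
    twelve disjoint 10-cliques: party hubs adopt one clique each, date hubs
    anchor to one member of each of the ten remaining cliques, and noisy hubs
    get ten fresh pairwise non-adjacent leaves.  Expression has 36 samples
    (the size of a typical yeast metabolic-cycle time course) with a target
    hub–neighbour correlation of 0.8 over noise of s.d. 0.2.
    """

    clique_sizes: tuple[int, ...] = (10,) * 12
    n_party_hubs: int = 2
    n_date_hubs: int = 2
    n_noisy_hubs: int = 2
    noisy_hub_degree: int = 10
    target_pcc_signal: float = 0.8
    noise_sd: float = 0.2
    n_samples: int = 36
    seed: int = 0

    def validate(self) -> None:
        if min((self.n_party_hubs, self.n_date_hubs, self.n_noisy_hubs), default=0) < 0:
            raise ValueError("hub counts must be non-negative")
        if self.n_samples < 3:
            raise ValueError("need at least 3 expression samples")
        if not 0.0 < self.target_pcc_signal <= 1.0:
            raise ValueError("target_pcc_signal must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_noisy_hubs > 0 and self.noisy_hub_degree < 1:
            raise ValueError("noisy_hub_degree must be >= 1")
        if any(c < 3 for c in self.clique_sizes):
            raise ValueError("clique sizes must be >= 3")
        if self.n_party_hubs > len(self.clique_sizes):
            raise ValueError(
                f"{self.n_party_hubs} party hubs need {self.n_party_hubs} "
                f"cliques, only {len(self.clique_sizes)} specified"
            )
        if self.n_date_hubs > 0:
            free = len(self.clique_sizes) - self.n_party_hubs
            want = max(3, self.noisy_hub_degree)
            if free < want:
                raise ValueError(
                    f"date hubs span {want} cliques but only {free} cliques "
                    f"are free of party hubs"
                )
            if self.n_date_hubs > min(self.clique_sizes[self.n_party_hubs:]):
                raise ValueError(
                    "more date hubs than distinct anchor members per clique"
                )


@dataclass(frozen=True)
class LabeledNetwork:
    """A generated network with expression, hub roles and essential labels."""

    network: PPINetwork
    expression: ExpressionMatrix
    essential_ids: frozenset[str]
    hub_roles: dict[str, str]  # protein ID -> party | date | noisy | background

    @property
    def essential_set(self) -> EssentialSet:
        return EssentialSet(self.essential_ids)

    def hubs(self, role: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, r in self.hub_roles.items() if r == role))


def make_three_clique_toy() -> PPINetwork:
    """The motivating toy network for neighbour-weighted scoring.

    Five named nodes A, A1, B, B1, C plus three complete sub-networks of
    sizes 20, 30 and 40 (D, E, F).  C is adjacent to A, B and to exactly one
    member of each clique (D1, E1, F1); A–A1 and B–B1 are pendant edges.
    Under neighbour-CC weighting the C–D1/C–E1/C–F1 edges dominate C's score,
    whereas edge-clustering-based scores favour the sparse A–C/B–C side.
    """
    edges: list[tuple[str, str]] = [
        ("A", "A1"),
        ("B", "B1"),
        ("A", "C"),
        ("B", "C"),
        ("C", "D1"),
        ("C", "E1"),
        ("C", "F1"),
    ]
    for prefix, size in (("D", 20), ("E", 30), ("F", 40)):
        members = [f"{prefix}{i}" for i in range(1, size + 1)]
        edges.extend(
            (members[i], members[j])
            for i in range(size)
            for j in range(i + 1, size)
        )
    return PPINetwork(edges=edges)


def _clique_member(ci: int, j: int) -> str:
    return f"Q{ci:02d}_{j:02d}"


def generate(spec: SyntheticSpec) -> LabeledNetwork:
    """Build a planted-hub network with coupled expression, fully determined
    by ``spec.seed``.

    Party and date hubs are labelled essential (deterministically — the
    planted classes encode the premise that both hub types are essential),
    noisy hubs and background proteins non-essential.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec.n_samples

    edges: list[tuple[str, str]] = []
    roles: dict[str, str] = {}
    # latent_of[pid] = hub whose latent signal pid's profile mixes in
    latent_of: dict[str, str] = {}

    # background cliques
    for ci, size in enumerate(spec.clique_sizes):
        members = [_clique_member(ci, j) for j in range(size)]
        for m in members:
            roles[m] = "background"
        edges.extend(
            (members[i], members[j])
            for i in range(size)
            for j in range(i + 1, size)
        )

    # party hubs: adopt one clique each, adjacent to every member
    for h in range(spec.n_party_hubs):
        hub = f"PARTY{h + 1:02d}"
        roles[hub] = "party"
        size = spec.clique_sizes[h]
        for j in range(size):
            member = _clique_member(h, j)
            edges.append((hub, member))
            latent_of.setdefault(member, hub)

    # date hubs: one anchor member in each of `noisy_hub_degree` cliques that
    # host no party hub (degree matched to the noisy hubs)
    date_cliques = range(
        spec.n_party_hubs, spec.n_party_hubs + max(3, spec.noisy_hub_degree)
    )
    for h in range(spec.n_date_hubs):
        hub = f"DATE{h + 1:02d}"
        roles[hub] = "date"
        for ci in date_cliques:
            anchor = _clique_member(ci, h)
            edges.append((hub, anchor))
            latent_of.setdefault(anchor, hub)

    # noisy hubs: star centres over fresh pairwise non-adjacent leaves
    for h in range(spec.n_noisy_hubs):
        hub = f"NOISY{h + 1:02d}"
        roles[hub] = "noisy"
        for leaf_i in range(spec.noisy_hub_degree):
            leaf = f"{hub}_L{leaf_i + 1:02d}"
            roles[leaf] = "background"
            edges.append((hub, leaf))

    net = PPINetwork(edges=edges, nodes=roles)

    # expression: hub latents first, then profiles in sorted node order so the
    # draw sequence is independent of dict iteration details
    rho, sd = spec.target_pcc_signal, spec.noise_sd
    if rho < 1.0:
        alpha = sd * rho / sqrt(1.0 - rho * rho)
    else:
        alpha = None  # exact copy of the latent
    signal_hubs = sorted(
        p for p, r in roles.items() if r in ("party", "date")
    )
    latents = {hub: rng.standard_normal(s) for hub in signal_hubs}
    profiles: dict[str, np.ndarray] = {hub: latents[hub] for hub in signal_hubs}
    for pid in sorted(roles):
        if pid in profiles:
            continue
        hub = latent_of.get(pid)
        if hub is None:
            profiles[pid] = rng.standard_normal(s)
        elif alpha is None:
            profiles[pid] = latents[hub].copy()
        else:
            profiles[pid] = alpha * latents[hub] + sd * rng.standard_normal(s)

    expr = ExpressionMatrix(n_samples=s, profiles=profiles)
    essential = frozenset(
        p for p, r in roles.items() if r in ("party", "date")
    )
    return LabeledNetwork(
        network=net, expression=expr, essential_ids=essential, hub_roles=roles
    )


def perturb(
    net: PPINetwork, add_frac: float, remove_frac: float, seed: int = 0
) -> PPINetwork:
    """Randomly rewire a network: drop ⌊remove_frac·|E|⌋ edges and insert
    ⌊add_frac·|E|⌋ uniformly chosen non-edges (false negatives / false
    positives of interaction screens).  Node set is preserved.
    """
    if not (0.0 <= add_frac < 1.0 and 0.0 <= remove_frac < 1.0):
        raise ValueError("perturbation fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    edges = sorted(net.edges)
    m = len(edges)
    n_remove = floor(remove_frac * m)
    n_add = floor(add_frac * m)

    keep = set(edges)
    if n_remove:
        for idx in rng.choice(m, size=n_remove, replace=False):
            keep.discard(edges[idx])

    nodes = sorted(net.nodes)
    existing = set(edges)
    added: set[tuple[str, str]] = set()
    max_possible = len(nodes) * (len(nodes) - 1) // 2 - m
    n_add = min(n_add, max_possible)
    while len(added) < n_add:
        i, j = rng.integers(0, len(nodes), size=2)
        if i == j:
            continue
        u, v = nodes[i], nodes[j]
        e = (u, v) if u <= v else (v, u)
        if e not in existing and e not in added:
            added.add(e)
    return PPINetwork(edges=keep | added, nodes=nodes)
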