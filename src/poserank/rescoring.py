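"""Cluster-entropy-corrected free-energy scoring and ligand ranking.

The score of a cluster with lowest member energy E_min (kcal/mol) and
population N is

    ΔG = E_min + (−kT ln N) = E_min − kT ln N,

which rewards heavily populated clusters (many similarly posed ligands) as a
proxy for configurational stability.  At the default T = 298.15 K and
k_B = 0.0019872041 kcal/(mol·K), kT ≈ 0.59248 kcal/mol, so a 91-member
cluster earns −kT ln 91 ≈ −2.67 kcal/mol on top of its raw minimum.  Ligands
are ranked by their best (most negative) cluster ΔG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusteringParams, PoseCluster

#: Boltzmann constant in kcal/(mol·K)
BOLTZMANN_KCAL = 0.0019872041


@dataclass(frozen=True)
class ThermoParams:
    """Temperature (K) and Boltzmann constant (kcal/(mol·K)) for the kT term."""

    temperature: float = 298.15
    boltzmann_k: float = BOLTZMANN_KCAL

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.boltzmann_k <= 0:
            raise ValueError("temperature and boltzmann_k must be positive")

    @property
    def kT(self) -> float:
        """kT in kcal/mol (≈ 0.59248 at 298.15 K)."""
        return self.temperature * self.boltzmann_k


@dataclass(eq=False)
class ScoredCluster(PoseCluster):
    """A PoseCluster annotated with its entropy-corrected free energy."""

    delta_g: float = 0.0
    thermo: ThermoParams = field(default_factory=ThermoParams)


@dataclass
class RescoreReport:
    """Ranked per-ligand cluster summaries — the tool's primary output.

    Within each ligand, clusters are sorted by ΔG ascending (best first);
    ligands are ordered by their best ΔG.
    """

    entries: list[tuple[str, list[ScoredCluster]]]
    ranking_key: str = "delta_g"
    parameters: dict = field(default_factory=dict)


def cluster_free_energy(e_min: float, n: int, thermo: ThermoParams | None = None) -> float:
    """ΔG = e_min − kT·ln(n), kcal/mol.

    ``n`` is the cluster population; n = 1 leaves e_min unchanged (ln 1 = 0).
    """
    thermo = thermo or ThermoParams()
    if n < 1:
        raise ValueError("cluster population n must be >= 1")
    return e_min - thermo.kT * math.log(n)


def invert_free_energy(delta_g: float, n: int, thermo: ThermoParams | None = None) -> float:
    """The e_min implied by a printed (ΔG, N) pair: e_min = ΔG + kT·ln(n)."""
    thermo = thermo or ThermoParams()
    if n < 1:
        raise ValueError("cluster population n must be >= 1")
    return delta_g + thermo.kT * math.log(n)


def score_clusters(
    clusters: list[PoseCluster], thermo: ThermoParams | None = None
) -> list[ScoredCluster]:
    """Annotate each cluster with its ΔG; input order preserved."""
    thermo = thermo or ThermoParams()
    return [
        ScoredCluster(
            member_indices=c.member_indices,
            representative_index=c.representative_index,
            com_representative=c.com_representative,
            n=c.n,
            e_min=c.e_min,
            e_mean=c.e_mean,
            member_energies=dict(c.member_energies),
            delta_g=cluster_free_energy(c.e_min, c.n, thermo),
            thermo=thermo,
        )
        for c in clusters
    ]


def rank_report(
    scored: dict[str, list[ScoredCluster]], parameters: dict | None = None
) -> RescoreReport:
    """Build the ranked report.

    Clusters are sorted by ΔG within each ligand; ligands by their best ΔG,
    ties broken by largest-cluster size descending then ligand id.
    """
    if not scored or any(not v for v in scored.values()):
        raise ValueError("rank_report requires at least one ligand with >= 1 cluster")

    entries = []
    for ligand_id, clusters in scored.items():
        ranked = sorted(clusters, key=lambda c: (c.delta_g, -c.n, c.representative_index))
        entries.append((ligand_id, ranked))
    entries.sort(key=lambda e: (e[1][0].delta_g, -e[1][0].n, e[0]))
    return RescoreReport(entries=entries, ranking_key="delta_g",
                         parameters=dict(parameters or {}))


def cluster_energy_summary(clusters: list[ScoredCluster]) -> dict:
    """Per-cluster rows plus ligand-level aggregates.

    Returns ``{"clusters": [...], "n_clusters", "largest_cluster_size",
    "largest_cluster_spread"}`` where spread is max−min member energy of the
    largest cluster (ties: lowest e_min wins).
    """
    rows = [
        {"n": c.n, "e_min": c.e_min, "e_mean": c.e_mean, "delta_g": c.delta_g}
        for c in clusters
    ]
    largest = max(clusters, key=lambda c: (c.n, -c.e_min))
    energies = list(largest.member_energies.values())
    return {
        "clusters": rows,
        "n_clusters": len(clusters),
        "largest_cluster_size": largest.n,
        "largest_cluster_spread": float(max(energies) - min(energies)),
    }
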