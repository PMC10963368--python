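"""Per-residue interface energy profiling.

Aggregates replicate ΔΔG decompositions, classifies interface hotspots
(mean ΔΔG strictly below -2 kcal/mol by default), builds cumulative
normalized energy profiles along the sequence, compares two subunits'
energy-weighted positional distributions with a two-sample
Kolmogorov-Smirnov test, and groups hotspots into clusters either along
the sequence (single linkage with a residue-gap cutoff) or in the 3D
fold (single linkage over Cα–Cα distances).

Sign conventions: negative ΔΔG is favorable.  Repulsive (positive)
residues keep their sign in totals and cumulative curves, are never
hotspots, and contribute their absolute value to KS mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .datatypes import ComplexStructure, EnergyTable
from .exceptions import ValidationError

HOTSPOT_THRESHOLD = -2.0  # kcal/mol, strict <


def aggregate_replicates(table: EnergyTable) -> EnergyTable:
    """Fill per-residue mean and sample SD (n-1 denominator) in place.

    With a single replicate the SD is reported as 0 and
    ``single_replicate_warning`` is set on the table.
    """
    table.mean = table.replicates.mean(axis=1)
    if table.n_rep < 2:
        table.sd = np.zeros(table.n_residues)
        table.single_replicate_warning = True
    else:
        table.sd = table.replicates.std(axis=1, ddof=1)
    return table


def classify_hotspots(table: EnergyTable,
                      threshold: float = HOTSPOT_THRESHOLD) -> set[int]:
    """Residues whose mean ΔΔG is strictly below ``threshold``."""
    means = table.require_means()
    return {int(r) for r, m in zip(table.residue_index, means) if m < threshold}


@dataclass
class CumulativeProfile:
    """Cumulative normalized interface energy along the sequence.

    ``signed`` is the running sum of signed means divided by the total
    absolute energy (ends at signed_total / normalization, magnitude
    <= 1); ``magnitude`` is the running sum of |mean| on the same scale
    (monotone, ends at exactly 1).  Positions are 1-based codons;
    residues absent from the table contribute zero.
    """

    positions: np.ndarray          # 1..orf_length
    signed: np.ndarray
    magnitude: np.ndarray
    weights: np.ndarray            # per-position |mean ΔΔG|, kcal/mol
    normalization: float           # total |energy|, kcal/mol
    signed_total: float            # sum of signed means, kcal/mol
    orf_length: int = 0

    def __post_init__(self):
        if not self.orf_length:
            self.orf_length = len(self.positions)


def cumulative_profile(table: EnergyTable) -> CumulativeProfile:
    means = table.require_means()
    L = table.orf_length
    per_pos = np.zeros(L)
    per_pos[table.residue_index - 1] = means
    total_abs = float(np.abs(per_pos).sum())
    if total_abs == 0:
        raise ValidationError("all-zero energy table: cannot normalize")
    return CumulativeProfile(
        positions=np.arange(1, L + 1),
        signed=np.cumsum(per_pos) / total_abs,
        magnitude=np.cumsum(np.abs(per_pos)) / total_abs,
        weights=np.abs(per_pos),
        normalization=total_abs,
        signed_total=float(per_pos.sum()),
        orf_length=L,
    )


def _weighted_cdf(positions: np.ndarray, weights: np.ndarray, grid: np.ndarray):
    order = np.argsort(positions)
    p = positions[order]
    c = np.cumsum(weights[order])
    c = c / c[-1]
    idx = np.searchsorted(p, grid, side="right")
    return np.where(idx > 0, c[np.clip(idx - 1, 0, None)], 0.0)


def ks_compare(profile_a: CumulativeProfile, profile_b: CumulativeProfile,
               weighted: bool = True) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test between two subunits'
    energy-weighted positional distributions.

    Each subunit's |ΔΔG| mass over positions normalized to [0, 1]
    (position / orf_length) forms its empirical distribution;
    D = sup |CDF_a - CDF_b| and the two-sided p-value is the asymptotic
    Kolmogorov distribution with weight-effective sample sizes
    n_eff = (Σw)² / Σw².  With ``weighted=False`` every energy-carrying
    residue counts once (raw per-residue alternative).
    """
    out = []
    for prof in (profile_a, profile_b):
        mask = prof.weights > 0
        if not mask.any():
            raise ValidationError("zero total energy mass on one side")
        pos = prof.positions[mask] / prof.orf_length
        w = prof.weights[mask] if weighted else np.ones(mask.sum())
        out.append((pos, w))
    (pa, wa), (pb, wb) = out
    grid = np.union1d(pa, pb)
    d = float(np.max(np.abs(_weighted_cdf(pa, wa, grid) - _weighted_cdf(pb, wb, grid))))
    # effective sample sizes are scale-invariant; normalize to avoid
    # under/overflow in the squared sums for extreme energy magnitudes
    wa_n, wb_n = wa / wa.max(), wb / wb.max()
    na = wa_n.sum() ** 2 / np.sum(wa_n ** 2)
    nb = wb_n.sum() ** 2 / np.sum(wb_n ** 2)
    en = np.sqrt(na * nb / (na + nb))
    p = float(special.kolmogorov(en * d))
    return d, min(max(p, 0.0), 1.0)


@dataclass
class HotspotCluster:
    """A group of hotspot residues, contiguous in sequence or in space."""

    cluster_id: str
    members: list[int]                 # residue indices, sorted
    span: tuple[int, int]              # [start, end] in sequence
    total_energy: float                # sum of member mean ΔΔG, kcal/mol
    kind: str                          # "linear" | "spatial"
    codependent_with: set[str] = field(default_factory=set)


def _make_clusters(groups: list[list[int]], table: EnergyTable,
                   kind: str) -> list[HotspotCluster]:
    by_res = table.mean_by_residue()
    clusters = []
    for members in sorted(groups, key=min):
        members = sorted(members)
        clusters.append(
            HotspotCluster(
                cluster_id=f"{kind[0].upper()}{len(clusters) + 1}",
                members=members,
                span=(members[0], members[-1]),
                total_energy=float(sum(by_res[m] for m in members)),
                kind=kind,
            )
        )
    return clusters


def linear_clusters(hotspots: set[int], table: EnergyTable,
                    cluster_gap: int = 10) -> list[HotspotCluster]:
    """Single-linkage grouping along the sequence: two hotspots share a
    cluster iff their index distance is <= ``cluster_gap`` (transitively)."""
    if not hotspots:
        return []
    ordered = sorted(hotspots)
    groups, current = [], [ordered[0]]
    for res in ordered[1:]:
        if res - current[-1] <= cluster_gap:
            current.append(res)
        else:
            groups.append(current)
            current = [res]
    groups.append(current)
    return _make_clusters(groups, table, "linear")


def spatial_clusters(hotspots: set[int], table: EnergyTable,
                     structure: ComplexStructure,
                     chain_id: str = "A",
                     spatial_cutoff: float = 8.0) -> list[HotspotCluster]:
    """Single-linkage grouping over Cα–Cα distances <= ``spatial_cutoff``;
    clusters may span sequence-distant regions."""
    if not hotspots:
        return []
    ca = structure.ca_map(chain_id)
    missing = sorted(set(hotspots) - set(ca))
    if missing:
        raise ValidationError(
            f"hotspot residues without Cα coordinates: {missing}"
        )
    ordered = sorted(hotspots)
    coords = np.array([ca[r] for r in ordered])
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(spatial_cutoff)), dtype=int)
    n = len(ordered)
    if pairs.size:
        adj = csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = csr_matrix((n, n))
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for res, lab in zip(ordered, labels):
        groups.setdefault(int(lab), []).append(res)
    return _make_clusters(list(groups.values()), table, "spatial")


def cluster_energy_fraction(cluster: HotspotCluster, table: EnergyTable) -> float:
    """|cluster total energy| as a fraction of the subunit's total
    absolute per-residue energy."""
    means = table.require_means()
    denom = float(np.abs(means).sum())
    if denom == 0:
        raise ValidationError("zero total absolute energy")
    if not cluster.members:
        return 0.0
    by_res = table.mean_by_residue()
    missing = [m for m in cluster.members if m not in by_res]
    if missing:
        raise ValidationError(f"cluster members missing from table: {missing}")
    return abs(cluster.total_energy) / denom
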