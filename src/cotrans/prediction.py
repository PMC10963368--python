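"""The onset-prediction model for co-translational complex assembly.

Model: a nascent subunit can engage its partner on the ribosome as soon
as a hotspot-cluster group carrying a qualifying share of the interface
energy has been fully synthesized *and* has cleared the ribosomal exit
tunnel (~35 codons of nascent chain are buried inside the tunnel).
Clusters coupled in the 3D fold — by inter-cluster hydrogen bonds or by
joint spatial clustering — are co-dependent: the interface can only
form once the last cluster of the group is synthesized, so the group
completes at its maximal member residue.  A qualifying group whose
exposure falls too close to the stop codon (within ``margin`` codons)
cannot sustain an on-ribosome interaction window, and the subunit is
predicted to assemble post-translationally instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import hydrogen_bonds
from .datatypes import ComplexStructure, EnergyTable
from .energetics import (
    CumulativeProfile,
    HotspotCluster,
    cumulative_profile,
    ks_compare,
    spatial_clusters,
)
from .exceptions import ValidationError

TUNNEL_LENGTH = 35  # codons of nascent chain buried in the exit tunnel

MODE_NASCENT = "nascent_engaged"
MODE_POST = "post_translational"
MODE_PARTNER = "partner_engager"


def exposure_codon(residue_index: int, tunnel_length: int = TUNNEL_LENGTH) -> int:
    """Codons translated when ``residue_index`` clears the exit tunnel."""
    if residue_index < 1:
        raise ValidationError("residue_index is 1-based (>= 1)")
    return residue_index + tunnel_length


def mark_codependence(clusters: list[HotspotCluster],
                      structure: ComplexStructure,
                      chain_id: str = "A",
                      table: EnergyTable | None = None,
                      hbond_distance: float = 3.5,
                      hbond_angle: float = 120.0,
                      spatial_cutoff: float = 8.0) -> list[HotspotCluster]:
    """Fill ``codependent_with`` on each cluster.

    Clusters i and j are co-dependent iff a hydrogen bond connects their
    member residues, or their members fall in one spatial
    (Cα-single-linkage) cluster.  Co-dependence is symmetric and closed
    transitively.
    """
    n = len(clusters)
    adj = np.zeros((n, n), dtype=bool)
    # spatial co-membership over the union of all cluster members
    if table is not None and n > 1:
        union = {m for c in clusters for m in c.members}
        spatial = spatial_clusters(union, table, structure, chain_id,
                                   spatial_cutoff)
        for sc in spatial:
            members = set(sc.members)
            involved = [i for i, c in enumerate(clusters)
                        if members & set(c.members)]
            for i in involved:
                for j in involved:
                    adj[i, j] = True
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                continue
            if hydrogen_bonds(structure, set(clusters[i].members),
                              set(clusters[j].members), chain_id,
                              hbond_distance, hbond_angle):
                adj[i, j] = adj[j, i] = True
    # transitive closure (Floyd-Warshall on a small boolean matrix)
    np.fill_diagonal(adj, True)
    for k in range(n):
        adj |= adj[:, k:k + 1] & adj[k:k + 1, :]
    for i, c in enumerate(clusters):
        c.codependent_with = {
            clusters[j].cluster_id for j in range(n) if adj[i, j] and j != i
        }
    return clusters


def _closure_groups(clusters: list[HotspotCluster]) -> list[list[int]]:
    """Indices of each cluster's co-dependence group (cluster + closure)."""
    by_id = {c.cluster_id: i for i, c in enumerate(clusters)}
    groups = []
    for i, c in enumerate(clusters):
        group = {i} | {by_id[cid] for cid in c.codependent_with if cid in by_id}
        groups.append(sorted(group))
    return groups


@dataclass
class OnsetPrediction:
    subunit_label: str
    mode: str  # nascent_engaged | post_translational | partner_engager
    predicted_onset_codon: int | None
    governing_clusters: list[str]
    energy_fraction_at_onset: float
    tunnel_length: int
    orf_length: int
    candidates: list[dict] = field(default_factory=list)


def predict_onset(table: EnergyTable,
                  clusters: list[HotspotCluster],
                  orf_length: int | None = None,
                  energy_fraction_f: float = 0.5,
                  tunnel_length: int = TUNNEL_LENGTH,
                  margin: int = TUNNEL_LENGTH) -> OnsetPrediction:
    """Predict whether and when this subunit engages co-translationally.

    Every cluster group (a cluster plus its co-dependent closure)
    completes at its maximal member residue; its candidate onset is the
    exposure codon of that residue.  The predicted onset is the smallest
    candidate over groups whose share of the subunit's total absolute
    energy reaches ``energy_fraction_f``.  The mode is nascent_engaged
    iff that onset is at most ``orf_length - margin``; otherwise (or
    when no group qualifies) the subunit is called post-translational.
    """
    means = table.require_means()
    if table.n_residues == 0:
        raise ValidationError("empty energy table")
    L = int(orf_length) if orf_length is not None else table.orf_length
    total_abs = float(np.abs(means).sum())
    if total_abs == 0:
        raise ValidationError("zero total absolute energy")
    by_res = table.mean_by_residue()

    candidates = []
    for group_idx in _closure_groups(clusters):
        group = [clusters[i] for i in group_idx]
        members = sorted({m for c in group for m in c.members})
        completion = max(members)
        fraction = sum(abs(by_res[m]) for m in members) / total_abs
        candidates.append(
            {
                "cluster_ids": [c.cluster_id for c in group],
                "completion_residue": completion,
                "onset_codon": exposure_codon(completion, tunnel_length),
                "energy_fraction": fraction,
            }
        )

    qualifying = [c for c in candidates if c["energy_fraction"] >= energy_fraction_f]
    if not qualifying:
        return OnsetPrediction(
            subunit_label=table.subunit_label,
            mode=MODE_POST,
            predicted_onset_codon=None,
            governing_clusters=[],
            energy_fraction_at_onset=0.0,
            tunnel_length=tunnel_length,
            orf_length=L,
            candidates=candidates,
        )
    best = min(qualifying, key=lambda c: c["onset_codon"])
    onset = best["onset_codon"]
    nascent = onset <= L - margin
    return OnsetPrediction(
        subunit_label=table.subunit_label,
        mode=MODE_NASCENT if nascent else MODE_POST,
        predicted_onset_codon=onset if nascent else None,
        governing_clusters=best["cluster_ids"],
        energy_fraction_at_onset=best["energy_fraction"],
        tunnel_length=tunnel_length,
        orf_length=L,
        candidates=candidates,
    )


@dataclass
class AsymmetryReport:
    """Contrast of interface-energy distribution between two subunits."""

    balance_point_a: float        # normalized position where |energy| hits 0.5
    balance_point_b: float
    n_half_fraction_a: float      # |energy| share in the N-terminal half
    n_half_fraction_b: float
    ks_d: float
    ks_p: float


def _balance_point(profile: CumulativeProfile) -> float:
    idx = int(np.searchsorted(profile.magnitude, 0.5))
    return float(profile.positions[min(idx, len(profile.positions) - 1)]
                 / profile.orf_length)


def _n_half_fraction(profile: CumulativeProfile) -> float:
    half = (profile.orf_length + 1) // 2  # N-terminal half, codons 1..L/2
    return float(profile.magnitude[half - 1]) if half >= 1 else 0.0


def asymmetry_report(table_a: EnergyTable, table_b: EnergyTable,
                     weighted_ks: bool = True) -> AsymmetryReport:
    prof_a = cumulative_profile(table_a)
    prof_b = cumulative_profile(table_b)
    d, p = ks_compare(prof_a, prof_b, weighted=weighted_ks)
    return AsymmetryReport(
        balance_point_a=_balance_point(prof_a),
        balance_point_b=_balance_point(prof_b),
        n_half_fraction_a=_n_half_fraction(prof_a),
        n_half_fraction_b=_n_half_fraction(prof_b),
        ks_d=d,
        ks_p=p,
    )


@dataclass
class DirectionalityVerdict:
    ambiguous: bool
    engaged_subunit: str | None    # the nascent chain that is bound
    engager_subunit: str | None    # the fully synthesized partner
    onset_codon: int | None
    detail: str
    prediction_a: OnsetPrediction | None = None
    prediction_b: OnsetPrediction | None = None
    asymmetry: AsymmetryReport | None = None


def call_directionality(pred_a: OnsetPrediction, pred_b: OnsetPrediction,
                        asym: AsymmetryReport | None = None) -> DirectionalityVerdict:
    """Heterodimer assembly direction from the two subunit predictions.

    Exactly one nascent_engaged subunit yields a verdict: that subunit
    is the engaged nascent chain, its partner the engager.  Both or
    neither qualifying is reported as ambiguous — no silent tie-break.
    """
    a_nascent = pred_a.mode == MODE_NASCENT
    b_nascent = pred_b.mode == MODE_NASCENT
    if a_nascent == b_nascent:
        which = "both" if a_nascent else "neither"
        return DirectionalityVerdict(
            ambiguous=True,
            engaged_subunit=None,
            engager_subunit=None,
            onset_codon=None,
            detail=f"{which} subunits qualify as nascent-engaged",
            prediction_a=pred_a,
            prediction_b=pred_b,
            asymmetry=asym,
        )
    engaged, engager = (pred_a, pred_b) if a_nascent else (pred_b, pred_a)
    engager.mode = MODE_PARTNER
    return DirectionalityVerdict(
        ambiguous=False,
        engaged_subunit=engaged.subunit_label,
        engager_subunit=engager.subunit_label,
        onset_codon=engaged.predicted_onset_codon,
        detail=(
            f"{engager.subunit_label} engages nascent {engaged.subunit_label} "
            f"from codon {engaged.predicted_onset_codon}"
        ),
        prediction_a=pred_a,
        prediction_b=pred_b,
        asymmetry=asym,
    )
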