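"""Synthetic data with planted ground truth.

Three generators emulate the statistical structure the analysis assumes:

* :func:`gen_footprint_profiles` — Poisson-sampled per-codon footprint
  counts for a translatome/interactome pair with a planted enrichment
  onset and fold.
* :func:`gen_energy_table` — Gaussian-noise per-residue ΔΔG tables with
  planted hotspot clusters over a flat background.
* :func:`gen_toy_complex` — a two-chain backbone toy complex whose
  interface Cα–Cα distances match requested targets, plus an ensemble of
  frames with isotropic Gaussian positional fluctuations (closed-form
  RMSF oracle: per-axis amplitude a gives RMSF a*sqrt(3)).

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datatypes import Atom, Chain, ComplexStructure, EnergyTable, FootprintProfile, Residue, Trajectory
from .exceptions import PlacementError, ValidationError

CA_SPACING = 3.8  # Angstrom between consecutive Cα of an extended chain


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class SerpSimSpec:
    """Conditions for a selective-ribosome-profiling simulation.

    Defaults mirror the strongest experimentally observed case: onset
    after 104 codons with ~300-fold enrichment, two biological
    replicates, and a mean translatome depth of 50 reads per codon.
    """

    orf_length_codons: int = 600
    onset_codon: int = 104
    enrichment_fold: float = 300.0
    baseline_depth: float = 50.0
    library_size: int = 10_000_000
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.orf_length_codons < 1:
            raise ValidationError("orf_length_codons must be >= 1")
        if not 1 <= self.onset_codon <= self.orf_length_codons:
            raise ValidationError("onset_codon must lie within the ORF")
        if self.enrichment_fold < 1:
            raise ValidationError("enrichment_fold must be >= 1")
        if self.baseline_depth <= 0:
            raise ValidationError("baseline_depth must be > 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass
class EnergySimSpec:
    """Conditions for a per-residue interface-energy simulation.

    ``clusters`` is a list of ``(start, end, per_residue_mean)`` spans in
    kcal/mol; defaults plant a single strongly favorable N-terminal
    cluster (residues 60-69 at -8 kcal/mol) in a 178-residue subunit with
    three replicates, matching the replicate structure of per-residue
    decomposition outputs (mean ± SD over n = 3 production runs).
    """

    n_residues: int = 178
    clusters: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(60, 69, -8.0)]
    )
    background_mean: float = 0.0
    noise_sd: float = 0.25
    n_replicates: int = 3
    seed: int = 0
    subunit_label: str = ""

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValidationError("n_residues must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for s, e, _ in self.clusters:
            if not (1 <= s <= e <= self.n_residues):
                raise ValidationError(f"cluster span ({s}, {e}) outside ORF")


@dataclass
class ToyComplexSpec:
    """A two-chain toy complex with targeted interface distances.

    ``interface_pairs`` lists ``(resA, resB, target_CA_distance)``;
    ``fluctuation_amplitudes`` is the per-axis Gaussian displacement SD
    in Angstrom, either a scalar or one value per residue (chain A
    residues first, then chain B).
    """

    n_residues_chain_a: int = 12
    n_residues_chain_b: int = 12
    interface_pairs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(6, 6, 3.9)]
    )
    fluctuation_amplitudes: float | list[float] = 0.5
    n_frames: int = 100
    frame_time_step_ns: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for a, b, d in self.interface_pairs:
            if not (1 <= a <= self.n_residues_chain_a):
                raise ValidationError(f"pair residue {a} outside chain A")
            if not (1 <= b <= self.n_residues_chain_b):
                raise ValidationError(f"pair residue {b} outside chain B")
            if d <= 0:
                raise ValidationError("target distances must be > 0")
        amps = np.atleast_1d(np.asarray(self.fluctuation_amplitudes, dtype=float))
        if np.any(amps < 0):
            raise ValidationError("fluctuation amplitudes must be >= 0")
        n_total = self.n_residues_chain_a + self.n_residues_chain_b
        if amps.size not in (1, n_total):
            raise ValidationError(
                f"need 1 or {n_total} fluctuation amplitudes, got {amps.size}"
            )
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")

    def amplitudes_per_residue(self) -> np.ndarray:
        n_total = self.n_residues_chain_a + self.n_residues_chain_b
        amps = np.atleast_1d(np.asarray(self.fluctuation_amplitudes, dtype=float))
        return np.full(n_total, amps[0]) if amps.size == 1 else amps


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def gen_footprint_profiles(spec: SerpSimSpec) -> list[FootprintProfile]:
    """Simulate translatome/interactome replicate count profiles.

    Translatome counts are Poisson(baseline_depth) at every codon;
    interactome counts are Poisson(baseline_depth * fold(i)) with
    fold(i) = 1 before the onset codon and ``enrichment_fold`` from the
    onset codon on.  All profiles report ``library_size`` as their total
    mapped reads, modeling the ORF as a small part of a large library so
    the interactome/translatome RPM ratio tracks the planted fold.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.orf_length_codons
    fold = np.ones(L)
    fold[spec.onset_codon - 1:] = spec.enrichment_fold
    profiles = []
    for kind, rates in (
        ("translatome", np.full(L, spec.baseline_depth)),
        ("interactome", spec.baseline_depth * fold),
    ):
        for rep in range(1, spec.n_replicates + 1):
            counts = rng.poisson(rates)
            if counts.sum() > spec.library_size:
                raise ValidationError(
                    "library_size smaller than the ORF's own read count; "
                    "increase library_size or lower depth/fold"
                )
            profiles.append(
                FootprintProfile(
                    orf_id="synthetic",
                    sample_kind=kind,
                    replicate_id=rep,
                    counts=counts,
                    total_mapped_reads=spec.library_size,
                )
            )
    return profiles


def gen_energy_table(spec: EnergySimSpec) -> tuple[EnergyTable, dict]:
    """Simulate a per-residue ΔΔG table with planted clusters.

    Returns the table and a ground-truth record with the planted
    per-residue means, the cluster member set, and the fraction of the
    total absolute planted energy carried by each cluster.
    """
    rng = np.random.default_rng(spec.seed)
    planted = np.full(spec.n_residues, spec.background_mean, dtype=float)
    members: set[int] = set()
    for s, e, mean in spec.clusters:
        planted[s - 1:e] = mean
        members.update(range(s, e + 1))
    reps = planted[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_residues, spec.n_replicates)
    )
    table = EnergyTable(
        residue_index=np.arange(1, spec.n_residues + 1),
        replicates=reps,
        chain_id="A",
        subunit_label=spec.subunit_label,
        orf_length=spec.n_residues,
    )
    total_abs = float(np.abs(planted).sum())
    fractions = [
        float(np.abs(planted[s - 1:e]).sum()) / total_abs if total_abs else 0.0
        for s, e, _ in spec.clusters
    ]
    truth = {
        "planted_means": planted,
        "cluster_spans": [(s, e) for s, e, _ in spec.clusters],
        "cluster_members": members,
        "cluster_energy_fractions": fractions,
    }
    return table, truth


_BACKBONE_OFFSETS = {
    # local offsets from Cα; O gets a small z lift so chains are never
    # perfectly planar (keeps least-squares superposition well-posed)
    "N": np.array([-1.20, 0.80, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.20, 0.80, 0.00]),
    "O": np.array([1.45, 1.70, 0.30]),
}
_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _build_chain(chain_id: str, n_residues: int, origin: np.ndarray,
                 flip_y: bool) -> Chain:
    residues = []
    sign = -1.0 if flip_y else 1.0
    for i in range(1, n_residues + 1):
        ca = origin + np.array([(i - 1) * CA_SPACING, 0.0, 0.0])
        atoms = [
            Atom(name, _BACKBONE_ELEMENTS[name],
                 ca + off * np.array([1.0, sign, 1.0]))
            for name, off in _BACKBONE_OFFSETS.items()
        ]
        residues.append(Residue(i, "GLY", atoms))
    return Chain(chain_id, residues)


def _solve_placement(spec: ToyComplexSpec) -> tuple[float, float]:
    """Find chain-B offset (dx, h) matching every interface pair's
    Cα–Cα target distance, or raise :class:`PlacementError`."""
    pairs = spec.interface_pairs
    a0, b0, d0 = pairs[0]

    def residuals(params):
        dx, h = params
        out = []
        for a, b, d in pairs:
            delta_x = (b - a) * CA_SPACING + dx
            out.append(np.hypot(delta_x, h) - d)
        return out

    best = None
    for h0 in (d0, 0.5 * d0):
        sol = least_squares(residuals, x0=[(a0 - b0) * CA_SPACING, h0])
        if best is None or sol.cost < best.cost:
            best = sol
    if np.max(np.abs(best.fun)) > 0.01:
        raise PlacementError(
            "interface pair target distances are mutually inconsistent "
            f"(worst residual {np.max(np.abs(best.fun)):.3f} Angstrom)"
        )
    return float(best.x[0]), float(abs(best.x[1]))


def gen_toy_complex(spec: ToyComplexSpec) -> tuple[ComplexStructure, Trajectory]:
    """Build the toy two-chain complex and its fluctuation ensemble.

    Chains are extended parallel backbones; chain B is rigidly offset so
    each requested interface Cα–Cα distance is met within 0.01 Angstrom.
    Trajectory frames add independent isotropic Gaussian displacements
    with the per-residue amplitudes to every atom of the residue.
    """
    dx, h = _solve_placement(spec)
    chain_a = _build_chain("A", spec.n_residues_chain_a,
                           np.zeros(3), flip_y=False)
    chain_b = _build_chain("B", spec.n_residues_chain_b,
                           np.array([dx, h, 0.0]), flip_y=True)
    structure = ComplexStructure([chain_a, chain_b])

    amps = spec.amplitudes_per_residue()
    atom_amp = np.empty(structure.n_atoms)
    res_counter = 0
    last_key = None
    for i, c, r, _ in structure.iter_atoms():
        key = (c.chain_id, r.index)
        if key != last_key:
            if last_key is not None:
                res_counter += 1
            last_key = key
        atom_amp[i] = amps[res_counter]

    rng = np.random.default_rng(spec.seed)
    ref = structure.coords
    noise = rng.normal(size=(spec.n_frames, structure.n_atoms, 3))
    frames = ref[None, :, :] + noise * atom_amp[None, :, None]
    times = spec.frame_time_step_ns * np.arange(spec.n_frames, dtype=float)
    traj = Trajectory(reference=structure, frames=frames, frame_times=times)
    return structure, traj


def gen_assembly_pair(seed: int = 0, noise_sd: float = 0.25):
    """A heterodimer scenario with a planted assembly direction.

    The "catalytic" subunit (178 residues) carries one N-terminal
    hotspot cluster (residues 60-69 at -8 kcal/mol) holding ~100% of the
    planted interface energy, so its predicted onset is the cluster
    completion (69) plus the exit-tunnel length.  The "auxiliary"
    subunit (390 residues) has a uniform, individually weak profile
    (-0.3 kcal/mol per residue) and should be called the engager.

    Returns ``(catalytic_table, auxiliary_table, truth)`` where truth
    holds the planted onset codon (with the default 35-codon tunnel) and
    direction.
    """
    cat_spec = EnergySimSpec(
        n_residues=178,
        clusters=[(60, 69, -8.0)],
        background_mean=0.0,
        noise_sd=noise_sd,
        n_replicates=3,
        seed=seed,
        subunit_label="catalytic",
    )
    aux_spec = EnergySimSpec(
        n_residues=390,
        clusters=[],
        background_mean=-0.3,
        noise_sd=noise_sd,
        n_replicates=3,
        seed=seed + 1,
        subunit_label="auxiliary",
    )
    cat_table, cat_truth = gen_energy_table(cat_spec)
    aux_table, _ = gen_energy_table(aux_spec)
    truth = {
        "engaged_subunit": "catalytic",
        "engager_subunit": "auxiliary",
        "cluster_completion_residue": 69,
        "onset_codon_tunnel35": 69 + 35,
        "catalytic_truth": cat_truth,
    }
    return cat_table, aux_table, truth
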