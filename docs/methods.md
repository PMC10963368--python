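# Methods

## Coordinate conventions

Residue and codon indices are 1-based and inclusive everywhere, and
residue *i* of a protein corresponds to codon *i* of its ORF. Onsets
are reported as "ribosome position (codons translated)". Footprint
profiles are stored per codon: enrichment is often computed at
nucleotide resolution upstream, but every downstream statement of this
package (onsets, exposure, minimal regions) is in residues, and one
convention avoids a triple-indexing bug class. Coordinates are in Å,
energies in kcal/mol, times in ns, masses in Da.

## SeRP enrichment and onset detection

Each replicate profile is normalized to reads per million mapped reads
(RPM). Replicate reproducibility is the pairwise Pearson correlation of
RPM profiles (the minimum over pairs when more than two replicates
exist); an ORF passes at r ≥ 0.6, inclusive. Coverage requires strictly
more than 64 raw reads summed over replicates in both the interactome
and the translatome. Replicates are averaged on the RPM scale before
the ratio

    ratio[i] = (mean interactome RPM[i] + α) / (mean translatome RPM[i] + α)

with a symmetric pseudocount α = 0.5 RPM, which keeps the ratio finite
and equal to exactly 1 where both samples are empty.

**Stable crossing.** "The position where enrichment stably crosses the
twofold threshold" needs a formal definition; ours: the onset is the
smallest codon *c* with ratio[c] ≥ 2 such that at least a fraction
s = 0.9 of the codons in [c, L] are also ≥ 2. This rejects isolated
noisy spikes while calling a clean step at its first codon. The
detector is monotone in the threshold: raising it never yields an
earlier onset.

## Trajectory statistics

RMSD of a frame against a reference uses the mass-weighted formula
`RMSD = √(Σ mᵢ(Xᵢ−Yᵢ)²/M)` (all mᵢ = 1 and M = N when unweighted)
after proper (det = +1) least-squares Kabsch superposition. Superposition
can be disabled (`superpose=False`) for pre-aligned ensembles or
selections of fewer than three atoms, where a rigid fit is undefined.

RMSF is the per-atom fluctuation about the window-mean position,
`RMSF_i = √⟨(xᵢ−⟨xᵢ⟩)²⟩`, computed after superposing all frames of the
window to the window-mean structure (one pass aligning to the first
frame to form a provisional mean, then a re-alignment to that mean).
The fit selection defaults to all atoms and is independent of the
analysis selection, so the RMSF of a subset equals the subset of the
full-selection RMSF. Per-residue values are the Cα atom's RMSF. An
isotropic Gaussian ensemble with per-axis displacement SD *a* has
RMSF = a√3, which the synthetic trajectory generator uses as a
closed-form oracle.

Equilibration is the earliest time *t* at which the RMSD sample SD over
[t, t + window] drops to the tolerance (defaults: 10 ns window, 0.3 Å),
both config-exposed. Region-restricted RMSF comparison between two
subunits uses an unpaired two-sided t-test over the residues mapped by
an external structural aligner's core-region correspondence; Welch's
unequal-variance variant is the default (the pooled-variance Student
test is a flag), since homologous subunits need not share RMSF
variance.

## Interface energetics

Per-residue ΔΔG tables carry replicate structure (typically n = 3
independent production runs); aggregation reports the arithmetic mean
and sample SD (n−1). Negative ΔΔG is favorable. A **hotspot** is a
residue with mean ΔΔG strictly below −2 kcal/mol. Repulsive (positive)
residues keep their sign in totals, are never hotspots, and contribute
their absolute value to distributional mass.

**Cumulative profile.** Contributions are normalized by the subunit's
total absolute energy Σ|ΔΔG|, and both curves are emitted: the signed
running sum (bounded by ±1) and the magnitude running sum (monotone,
ending at exactly 1). The magnitude curve is the primary display: it
reproduces the steep accrual at hotspot clusters on a bounded scale
comparable across subunits, regardless of sign cancellation.

**KS comparison.** The two-subunit comparison treats each subunit's
|ΔΔG| mass over sequence positions normalized to [0, 1] as an empirical
distribution; D is the supremum of the weighted CDF difference and the
two-sided p-value uses the asymptotic Kolmogorov distribution with
weight-effective sample sizes n_eff = (Σw)²/Σw². The exact construction
of "one observation" is a convention; a raw per-residue alternative
(every energy-carrying residue counted once) is available behind
`weighted=False`.

**Clustering.** Linear clusters are single-linkage groups along the
sequence with an index-gap cutoff (default 10 residues); spatial
clusters are single-linkage connected components over Cα–Cα distances
(default 8 Å). Both partition the hotspot set. The defaults are
package conventions, config-exposed.

## Contacts and hydrogen bonds

Subunit–subunit interface residues use the Cα-within-4-Å-of-partner-Cα
criterion; contacts against an external heavy-atom cloud (e.g. a
ribosome surface) use Cα within 4 Å of any partner heavy atom. Both
cutoffs are inclusive. The two criteria are deliberately separate
operations. Hydrogen bonds are donor/acceptor-agnostic: any N/O heavy
atom pair across the two residue groups within 3.5 Å counts; when the
donor residue carries explicit hydrogens the best D–H···A angle must
also reach 120°. No chemistry perception is attempted.

## The onset-prediction model

A residue becomes available for intermolecular interaction
`tunnel_length` (default 35) codons after its own synthesis — the span
of nascent chain buried in the ribosomal exit tunnel. Clusters coupled
in the 3D fold (inter-cluster hydrogen bonds, or joint membership in
one spatial cluster) are **co-dependent**; co-dependence is symmetric
and transitively closed, and a co-dependent group only completes at its
maximal member residue. For each group, the candidate onset is
`exposure(max member) = max member + tunnel_length`. The predicted
onset is the smallest candidate among groups whose members carry at
least a fraction *f* (default 0.5) of the subunit's total absolute
interface energy. The subunit is called *nascent-engaged* iff that
onset is at most `orf_length − margin` (margin default 35 codons): a
group completing within the final tunnel-length of the ORF cannot
sustain an on-ribosome interaction window.

*f* is the model's single free threshold: the biology says only that
"most" of the interface energy accrues before onset in engaged
subunits, so 0.5 is the natural reading, and it is config-exposed. The
directionality call for a heterodimer names the unique nascent-engaged
subunit as the engaged nascent chain and its partner as the engager;
when both or neither qualify the verdict is reported as ambiguous with
both predictions attached — never a silent tie-break.

The asymmetry report summarizes each subunit's energy balance point
(the normalized position where cumulative |energy| reaches 0.5) and the
N-terminal-half energy fraction, and attaches the KS comparison.

## NAT substrate classification

After initiator-Met processing, NatA substrates start with S/T/A/G/V.
Unprocessed substrates are classified by the residue after Met:
D/E/N/Q → NatB, L/I/F/Y/K → NatC, S/T/A/V/C → NatE; anything else is
"other", with no fallback guessing. Some surveys also list Cys-starting
termini under NatA; this is off by default (`include_cys_nata=True` to
enable). Abundance ratios are log2(light/heavy) with the mutant in the
light channel, plus the summed intensity; zero/negative channels must
be excluded upstream.

## Synthetic data: what it emulates and what it does not

- **Footprint profiles**: independent Poisson counts per codon,
  translatome at `baseline_depth`, interactome stepped by
  `enrichment_fold` from the planted onset codon. All profiles share
  one `library_size` (default 10⁷ reads), modeling the ORF as a small
  slice of a large library so the RPM ratio tracks the planted fold.
  Defaults (onset 104, fold 300, depth 50, L = 600, n = 2 replicates)
  mirror the strongest experimentally characterized engagement. Not
  emulated: overdispersion, sequence-dependent footprint bias, P-site
  offset effects — and, importantly, shared positional structure
  between replicates, so replicate Pearson correlation on synthetic
  translatomes is ≈ 0 by construction and the r ≥ 0.6 QC gate fails
  there. Synthetic pipelines therefore run with the recorded QC
  override, and passing onset tests demonstrates detector correctness,
  not QC behavior on real libraries.
- **Energy tables**: planted cluster/background means plus i.i.d.
  Gaussian replicate noise, matching the mean ± SD over n = 3
  production runs reporting structure. The heterodimer scenario
  (`gen_assembly_pair`) plants a 178-residue engaged subunit with one
  cluster at residues 60–69 (−8 kcal/mol each; completion 69 + 35 =
  onset 104) against a 390-residue uniform partner (−0.3 kcal/mol per
  residue), with 0.25 kcal/mol replicate noise: strong enough that the
  cluster stays above the hotspot threshold, weak enough that the
  uniform partner never sprouts spurious hotspots. No correlated noise
  or conformational substates are modeled.
- **Toy complexes**: two extended parallel backbone chains (N, CA, C, O
  per residue; 3.8 Å Cα spacing) with chain B rigidly offset so every
  requested interface Cα–Cα distance is met within 0.01 Å (mutually
  inconsistent targets raise a placement error). Trajectory frames add
  isotropic Gaussian displacements, giving the a√3 RMSF oracle. No
  force-field realism, bonded constraints, or solvent.

## Numerical choices

- Pseudocount applied on the RPM scale to both ratio terms.
- Sample SD (ddof = 1) throughout; a single-replicate table reports
  SD 0 with a warning flag.
- KS effective sample sizes are computed on max-normalized weights to
  avoid under/overflow for extreme energy magnitudes.
- Kabsch uses SVD with the determinant sign correction; collinear
  point sets (second singular value ≈ 0) are rejected as degenerate.
- PDB altloc: highest occupancy wins, ties keep the first listed;
  insertion codes are rejected (unsupported dialect); round trips are
  exact at the format's 3-decimal coordinate precision.
- Pipeline reports are JSON with sorted keys; identical inputs, config
  and seed give byte-identical reports.

## Validation experiment sizes

The Monte-Carlo experiments backing the validation suite and
`scripts/acceptance.py` use 200 simulation seeds for onset recovery
(600-codon ORFs) and 200 for direction recovery, and 10⁴ frames for the
RMSF closed-form check; these sizes give binomial standard errors well
below the tested margins while keeping the whole run in seconds.

## Known limitations

- ΔΔG tables are consumed, never computed: no PB/GB solvation, no
  docking scores, no electrostatics.
- mmCIF, compressed trajectory formats, and FASTQ-level read processing
  are out of scope; structures enter as PDB v3.3 and profiles as
  processed per-codon counts.
- The onset model treats the tunnel length as a constant offset;
  nascent-chain compaction inside the tunnel, ribosome stalling, and
  chaperone competition are not modeled.
- Whether published onsets count synthesized or tunnel-exposed residues
  is ambiguous in places; the package stores raw codon positions,
  labels onsets explicitly, and leaves the alignment of the two
  conventions to the comparison report.
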