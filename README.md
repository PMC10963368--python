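# cotrans

Analysis toolkit linking per-residue protein–protein interface energy
distributions to the onset and directionality of **co-translational
protein complex assembly**.

Many heterodimeric complexes — the N-terminal acetyltransferases NatA
and NatB are the canonical case — assemble while one subunit is still
being synthesized: the fully folded partner binds the nascent chain as
it emerges from the ribosomal exit tunnel. Selective ribosome profiling
(SeRP) observes this directly as positional enrichment of
interactome over translatome footprints, while per-residue decomposition
of the binding free energy (ΔΔG, MMPBSA-style) shows *why*: a few
"hotspot" residues (ΔΔG < −2 kcal/mol), clustered in sequence or in the
3D fold, anchor the interface, and engagement begins as soon as the
governing hotspot cluster is fully synthesized and has cleared the
~35-residue exit tunnel.

`cotrans` implements both sides of that picture and the model joining
them:

- **serp** — RPM normalization (`rpm[i] = counts[i]·10⁶ / N_mapped`),
  replicate QC (pairwise Pearson r, pass iff r ≥ 0.6), coverage filter
  (> 64 reads in both samples), pseudocounted enrichment ratio
  `(Ī_RPM + α)/(T̄_RPM + α)`, and onset detection: the first codon where
  the ratio stably crosses the twofold threshold.
- **dynamics** — Kabsch superposition, RMSD
  (`√(Σ mᵢ(Xᵢ−Yᵢ)²/M)`), RMSF (`√⟨(xᵢ−⟨xᵢ⟩)²⟩`), equilibration
  detection, and unpaired two-sided t-tests of per-residue RMSF over
  structurally conserved core regions.
- **energetics** — replicate aggregation (mean ± SD), hotspot
  classification, linear and spatial (Cα single-linkage) hotspot
  clustering, cumulative normalized energy profiles, and an
  energy-weighted two-sample Kolmogorov–Smirnov comparison of two
  subunits' positional energy distributions.
- **contacts** — Cα–Cα interface residues (4 Å), Cα-to-heavy-atom
  partner contacts, hydrogen bonds.
- **prediction** — the exit-tunnel onset model: for each co-dependent
  hotspot-cluster group, candidate onset = max member residue +
  tunnel length; the earliest candidate among groups carrying at least a
  fraction *f* of the interface energy is the predicted onset, and the
  heterodimer's assembly direction follows from which subunit qualifies.
- **natclass** — NAT substrate classification of protein N termini
  (NatA/NatB/NatC/NatE) and heavy/light N-terminomics abundance ratios.
- **synthetic** — generators with planted ground truth (Poisson
  footprint profiles, Gaussian-noise energy tables, toy two-chain
  complexes with closed-form RMSF) so every stage is testable.

## Worked example

```python
from cotrans.synthetic import SerpSimSpec, gen_footprint_profiles, gen_assembly_pair
from cotrans.serp import enrichment_profile, detect_onset
from cotrans.energetics import (aggregate_replicates, classify_hotspots,
                                linear_clusters, cluster_energy_fraction)
from cotrans.prediction import predict_onset, asymmetry_report, call_directionality

# SeRP side: footprint profiles with a planted onset at codon 104
profiles = gen_footprint_profiles(SerpSimSpec(seed=1))
trans = [p for p in profiles if p.sample_kind == "translatome"]
inter = [p for p in profiles if p.sample_kind == "interactome"]
prof = enrichment_profile(trans, inter, force=True)
print(f"observed onset: codon {detect_onset(prof)}, "
      f"peak enrichment {prof.peak_fold:.0f}-fold")

# energy side: a heterodimer with an N-terminal hotspot cluster in one subunit
cat, aux, _ = gen_assembly_pair(seed=1)
for table in (cat, aux):
    aggregate_replicates(table)
clusters = linear_clusters(classify_hotspots(cat), cat, cluster_gap=10)
c = clusters[0]
print(f"hotspots: cluster {c.span[0]}-{c.span[1]} ({c.total_energy:.1f} kcal/mol, "
      f"{cluster_energy_fraction(c, cat):.0%} of interface energy)")
pred_cat = predict_onset(cat, clusters)
pred_aux = predict_onset(aux, linear_clusters(classify_hotspots(aux), aux, 10))
verdict = call_directionality(pred_cat, pred_aux, asymmetry_report(cat, aux))
print(f"predicted: {verdict.detail}")
```

prints

```
observed onset: codon 104, peak enrichment 368-fold
hotspots: cluster 60-69 (-80.0 kcal/mol, 83% of interface energy)
predicted: auxiliary engages nascent catalytic from codon 104
```

The SeRP-observed onset (codon 104) and the energy-model prediction
(cluster completion 69 + 35-codon tunnel = 104) agree, and the uniform
partner subunit is correctly called the engager.

A command-line interface mirrors the library
(`cotrans simulate|serp|dynamics|energetics|contacts|predict|natclass|run`);
`cotrans run` executes the whole pipeline and writes a JSON report
comparing predicted against observed onsets.

## Layout

- `src/cotrans/` — the library (`io`, `synthetic`, `serp`, `dynamics`,
  `energetics`, `contacts`, `prediction`, `natclass`, `pipeline`,
  `experiments`, `cli`)
- `tests/` — pytest suite (unit, property-based, and acceptance tests)
- `docs/methods.md` — models, conventions, parameter defaults, and
  known limitations
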