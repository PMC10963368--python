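"""Selective-ribosome-profiling enrichment analysis.

The pipeline per ORF:

1. reads-per-million (RPM) normalization of each replicate profile,
2. replicate reproducibility QC (pairwise Pearson r, pass iff r >= 0.6),
3. coverage filter (strictly more than 64 raw reads in both the
   interactome and the translatome),
4. the pseudocounted interactome/translatome RPM ratio profile,
5. onset detection: the first codon where the ratio stably crosses the
   fold threshold (default twofold), where "stably" means the threshold
   is exceeded over at least a fraction *s* of the remaining ORF
   (default s = 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import FootprintProfile
from .exceptions import ValidationError

MIN_READS = 64
MIN_PEARSON = 0.6


@dataclass
class EnrichmentProfile:
    """Per-codon interactome/translatome enrichment for one ORF."""

    orf_id: str
    ratio: np.ndarray  # finite, > 0 (pseudocount guarantees)
    replicate_pearson_r: float | None
    passed_qc: bool
    qc_reason: str = ""
    peak_fold: float = 0.0
    onset_codon: int | None = None

    @property
    def length(self) -> int:
        return len(self.ratio)


def rpm_normalize(profile: FootprintProfile) -> np.ndarray:
    """Per-codon reads per million mapped reads."""
    if profile.total_mapped_reads <= 0:
        raise ValidationError(
            f"{profile.orf_id}/{profile.sample_kind}: invalid-library "
            "(zero total mapped reads)"
        )
    return profile.counts * 1e6 / profile.total_mapped_reads


def replicate_qc(profiles: list[FootprintProfile],
                 min_pearson: float = MIN_PEARSON) -> tuple[float | None, bool, str]:
    """Pairwise Pearson correlation of replicate RPM profiles.

    Returns ``(r, passed, reason)`` with *r* the minimum over replicate
    pairs.  Passing is inclusive (r >= threshold).  A zero-variance
    replicate leaves r undefined and fails QC with a reason.
    """
    if len(profiles) < 2:
        raise ValidationError("replicate QC needs at least 2 replicates")
    lengths = {p.length for p in profiles}
    if len(lengths) != 1:
        raise ValidationError("replicate profiles must have equal lengths")
    rpms = [rpm_normalize(p) for p in profiles]
    r_min = np.inf
    for i in range(len(rpms)):
        for j in range(i + 1, len(rpms)):
            if np.std(rpms[i]) == 0 or np.std(rpms[j]) == 0:
                return None, False, "zero-variance replicate: r undefined"
            r = stats.pearsonr(rpms[i], rpms[j]).statistic
            r_min = min(r_min, r)
    return float(r_min), bool(r_min >= min_pearson), ""


def coverage_filter(translatome: list[FootprintProfile],
                    interactome: list[FootprintProfile],
                    min_reads: int = MIN_READS) -> bool:
    """True iff both sample kinds have strictly more than ``min_reads``
    raw reads summed over replicates."""
    t_total = sum(int(p.counts.sum()) for p in translatome)
    i_total = sum(int(p.counts.sum()) for p in interactome)
    return t_total > min_reads and i_total > min_reads


def enrichment_profile(translatome: list[FootprintProfile],
                       interactome: list[FootprintProfile],
                       pseudocount: float = 0.5,
                       min_pearson: float = MIN_PEARSON,
                       min_reads: int = MIN_READS,
                       force: bool = False) -> EnrichmentProfile:
    """The pseudocounted mean-RPM ratio profile.

    ratio[i] = (mean interactome RPM[i] + a) / (mean translatome RPM[i] + a)

    Replicates are averaged on the RPM scale before the ratio.  QC
    (replicate correlation in both sample kinds, plus the coverage
    filter) is recorded on the result; with ``force=False`` a QC failure
    still returns the profile but flags it as not passed.
    """
    if not translatome or not interactome:
        raise ValidationError("need at least one profile per sample kind")
    lengths = {p.length for p in translatome} | {p.length for p in interactome}
    if len(lengths) != 1:
        raise ValidationError("translatome/interactome length mismatch")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0 to keep ratios finite")

    r_vals, reasons = [], []
    for kind, group in (("translatome", translatome), ("interactome", interactome)):
        if len(group) >= 2:
            r, ok, reason = replicate_qc(group, min_pearson)
            r_vals.append(r)
            if not ok:
                reasons.append(f"{kind}: " + (reason or f"r={r:.3f} < {min_pearson}"))
    if not coverage_filter(translatome, interactome, min_reads):
        reasons.append(f"coverage: <= {min_reads} reads in a sample kind")
    r_summary = None
    if r_vals:
        finite = [r for r in r_vals if r is not None]
        r_summary = min(finite) if len(finite) == len(r_vals) else None

    mean_t = np.mean([rpm_normalize(p) for p in translatome], axis=0)
    mean_i = np.mean([rpm_normalize(p) for p in interactome], axis=0)
    ratio = (mean_i + pseudocount) / (mean_t + pseudocount)
    return EnrichmentProfile(
        orf_id=translatome[0].orf_id,
        ratio=ratio,
        replicate_pearson_r=r_summary,
        passed_qc=not reasons or force,
        qc_reason="; ".join(reasons),
        peak_fold=float(ratio.max()),
    )


def detect_onset(profile: EnrichmentProfile,
                 threshold: float = 2.0,
                 stability_fraction: float = 0.9) -> int | None:
    """First codon where enrichment stably crosses ``threshold``.

    Onset is the smallest codon c with ratio[c] >= threshold such that
    the fraction of codons in [c, L] with ratio >= threshold is at least
    ``stability_fraction``; ``None`` if no codon qualifies.
    """
    above = profile.ratio >= threshold
    L = len(above)
    if L == 0:
        return None
    # suffix_above[k] = number of above-threshold codons in [k+1, L] (1-based)
    suffix_above = np.cumsum(above[::-1])[::-1]
    suffix_len = np.arange(L, 0, -1)
    ok = above & (suffix_above >= stability_fraction * suffix_len)
    hits = np.nonzero(ok)[0]
    return int(hits[0]) + 1 if hits.size else None


def analyze_orf(translatome: list[FootprintProfile],
                interactome: list[FootprintProfile],
                pseudocount: float = 0.5,
                threshold: float = 2.0,
                stability_fraction: float = 0.9,
                min_pearson: float = MIN_PEARSON,
                min_reads: int = MIN_READS,
                force: bool = False) -> EnrichmentProfile:
    """Convenience wrapper: enrichment profile plus onset detection."""
    prof = enrichment_profile(
        translatome, interactome, pseudocount=pseudocount,
        min_pearson=min_pearson, min_reads=min_reads, force=force,
    )
    if prof.passed_qc:
        prof.onset_codon = detect_onset(prof, threshold, stability_fraction)
    return prof
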