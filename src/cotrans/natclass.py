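"""N-terminal acetyltransferase (NAT) substrate classification and
heavy/light N-terminal peptide abundance ratios.

Classification follows the canonical sequence rules: NatA acetylates
Ser-, Thr-, Ala-, Gly- and Val- N termini after initiator-Met
processing; NatB acetylates Met followed by an acidic residue or
Asn/Gln (MD/ME/MN/MQ); NatC acetylates Met followed by a hydrophobic
residue (ML/MI/MF/MY/MK); NatE substrates start with MS/MT/MA/MV/MC.
Everything else is "other".

Some surveys additionally list Cys-starting N termini as NatA
substrates; that is off by default and available via
``include_cys_nata=True``.
"""

from __future__ import annotations

import math

from .exceptions import ValidationError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

NATA_FIRST = set("STAGV")
NATA_FIRST_WITH_CYS = NATA_FIRST | {"C"}
NATB_SECOND = set("DENQ")
NATC_SECOND = set("LIFYK")
NATE_SECOND = set("STAVC")


def classify_nt(sequence: str, imet_processed: bool,
                include_cys_nata: bool = False) -> str:
    """Classify a mature N-terminal sequence to a NAT substrate class.

    ``imet_processed`` marks N termini whose initiator Met was removed
    by methionine aminopeptidases (the first residue is then not Met).
    Returns one of ``"NatA" | "NatB" | "NatC" | "NatE" | "other"``.
    """
    seq = sequence.strip().upper()
    if len(seq) < 2:
        raise ValidationError("need at least 2 N-terminal residues")
    if seq[0] not in AMINO_ACIDS or seq[1] not in AMINO_ACIDS:
        bad = seq[0] if seq[0] not in AMINO_ACIDS else seq[1]
        raise ValidationError(f"unknown residue letter {bad!r}")
    if imet_processed:
        if seq[0] == "M":
            raise ValidationError(
                "imet_processed N terminus must not start with Met"
            )
        first_set = NATA_FIRST_WITH_CYS if include_cys_nata else NATA_FIRST
        return "NatA" if seq[0] in first_set else "other"
    if seq[0] != "M":
        raise ValidationError(
            "unprocessed N terminus must start with the initiator Met"
        )
    second = seq[1]
    if second in NATB_SECOND:
        return "NatB"
    if second in NATC_SECOND:
        return "NatC"
    if second in NATE_SECOND:
        return "NatE"
    return "other"


def abundance_ratio(intensity_light: float,
                    intensity_heavy: float) -> tuple[float, float]:
    """log2(light/heavy) channel ratio and the summed intensity.

    The light channel carries the mutant sample and the heavy channel
    the wildtype, so positive ratios mean higher abundance in the
    mutant.  Peptides missing a channel must be excluded upstream.
    """
    if intensity_light <= 0 or intensity_heavy <= 0:
        raise ValidationError("channel intensities must be > 0")
    return (
        math.log2(intensity_light / intensity_heavy),
        intensity_light + intensity_heavy,
    )
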