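"""Bundled germline V-heavy references.

One real reference is shipped: the public IGHV3-23*01 V-region nucleotide
sequence, trimmed to 96 codons ending at the conserved FR3 cysteine, with
region windows stated in ungapped 1-based amino-acid coordinates on this
trimmed sequence. Extra germlines and alleles for multi-germline analyses
are synthetic derivatives of this reference and are labelled as such.
"""

from __future__ import annotations

import numpy as np

from ._seqcodes import AA_INDEX, CODONS_BY_AA, translate_nt
from .io_formats import GermlineReference

# IGHV3-23*01 V region, trimmed to the codon of the conserved FR3 Cys.
VH3_23_NT = (
    "GAGGTGCAGCTGTTGGAGTCTGGGGGAGGCTTGGTACAGCCTGGGGGGTCCCTGAGACTC"
    "TCCTGTGCAGCCTCTGGATTCACCTTTAGCAGCTATGCCATGAGCTGGGTCCGCCAGGCT"
    "CCAGGGAAGGGGCTGGAGTGGGTCTCAGCTATTAGTGGTAGTGGTGGTAGCACATACTAC"
    "GCAGACTCCGTGAAGGGCCGGTTCACCATCTCCAGAGACAATTCCAAGAACACGCTGTAT"
    "CTGCAAATGAACAGCCTGAGAGCCGAGGACACGGCCGTATATTACTGT"
)

#: ungapped windows on the 96-aa trimmed translation
VH3_23_WINDOWS = {
    "FR1": (1, 25),
    "CDR1": (26, 33),
    "FR2": (34, 50),
    "CDR2": (51, 58),
    "FR3": (59, 96),
}


def builtin_germline() -> GermlineReference:
    """The bundled VH3-23 reference (allele *01)."""
    return GermlineReference(
        gene_name="VH3-23",
        allele_name="VH3-23*01",
        nt_seq=VH3_23_NT,
        region_windows=dict(VH3_23_WINDOWS),
    )


def synthetic_allele(base: GermlineReference | None = None, position: int = 85, target_aa: str = "N",
                     allele_suffix: str = "*s2") -> GermlineReference:
    """A synthetic allele of the bundled gene: one framework codon replaced.

    Synthetic stand-in for a population allelic variant (no real allele
    sequence is bundled); used to exercise allele masking.
    """
    ref = base or builtin_germline()
    if ref.aa_seq[position - 1] == target_aa:
        raise ValueError("target residue equals the base allele residue")
    codon = CODONS_BY_AA[AA_INDEX[target_aa]][0]
    nt = ref.nt_seq[: 3 * (position - 1)] + codon + ref.nt_seq[3 * position :]
    return GermlineReference(
        gene_name=ref.gene_name,
        allele_name=ref.gene_name + allele_suffix,
        nt_seq=nt,
        region_windows=dict(ref.region_windows),
    )


def synthetic_germline(name: str, n_changes: int = 6, seed: int = 0,
                       base: GermlineReference | None = None) -> GermlineReference:
    """A synthetic germline gene derived from the bundled one.

    Applies ``n_changes`` random coding single-codon replacements at
    framework positions, keeping the region windows. Intended for
    multi-germline tests (clustering, cross-germline correlation), not as
    a biological reference.
    """
    ref = base or builtin_germline()
    rng = np.random.default_rng(seed)
    nt = list(ref.nt_seq)
    fr_pos = ref.fr_positions()
    chosen = rng.choice(fr_pos, size=n_changes, replace=False)
    for p in sorted(int(x) for x in chosen):
        current = ref.aa_seq[p - 1]
        others = [aa for aa in AA_INDEX if aa != current]
        new_aa = others[rng.integers(len(others))]
        codon = CODONS_BY_AA[AA_INDEX[new_aa]][0]
        nt[3 * (p - 1) : 3 * p] = list(codon)
    seq = "".join(nt)
    translate_nt(seq)  # sanity: stays open reading frame
    return GermlineReference(
        gene_name=name,
        allele_name=name + "*01",
        nt_seq=seq,
        region_windows=dict(ref.region_windows),
    )
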