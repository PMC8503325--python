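"""Integer encodings for nucleotides and amino acids used by the vectorised paths.

Codes: nucleotides A=0, C=1, G=2, T=3; amino acids 0..19 in alphabetical
one-letter order A..Y; 20 = untranslatable (stop codon or ambiguity);
21 = gap. Translation uses the standard genetic code.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"  # alanine .. tyrosine, alphabetical
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
NT_ORDER = "ACGT"
NT_INDEX = {nt: i for i, nt in enumerate(NT_ORDER)}

UNTRANSLATABLE = 20  # stop codon, ambiguous base, or partial codon
GAP = 21

# IUPAC nucleotide ambiguity codes accepted on input (beyond ACGT)
IUPAC_NT = set("ACGTRYSWKMBDHVN")

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon index (16*a + 4*b + c over NT codes) -> aa code, 20 for stops
CODON_AA = np.full(64, UNTRANSLATABLE, dtype=np.uint8)
#: list of sense codons per aa code
CODONS_BY_AA: dict[int, list[str]] = {i: [] for i in range(20)}
SENSE_CODONS: list[str] = []

for _a in NT_ORDER:
    for _b in NT_ORDER:
        for _c in NT_ORDER:
            codon = _a + _b + _c
            if codon in _standard.stop_codons:
                continue
            aa = _standard.forward_table[codon]
            idx = 16 * NT_INDEX[_a] + 4 * NT_INDEX[_b] + NT_INDEX[_c]
            CODON_AA[idx] = AA_INDEX[aa]
            CODONS_BY_AA[AA_INDEX[aa]].append(codon)
            SENSE_CODONS.append(codon)

_NT_LUT = np.full(256, 255, dtype=np.uint8)
for _nt, _i in NT_INDEX.items():
    _NT_LUT[ord(_nt)] = _i
    _NT_LUT[ord(_nt.lower())] = _i

_AA_LUT = np.full(256, UNTRANSLATABLE, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _AA_LUT[ord(_aa)] = _i
_AA_LUT[ord("-")] = GAP
_AA_LUT[ord(".")] = GAP


def encode_nt(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes; ambiguity codes become 255."""
    return _NT_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode_nt(codes: np.ndarray) -> str:
    return "".join(NT_ORDER[c] for c in codes)


def encode_aa(seq: str) -> np.ndarray:
    return _AA_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode_aa(codes: np.ndarray) -> str:
    lut = AA_ORDER + "X-"
    return "".join(lut[c] for c in codes)


def translate_codes(nt_codes: np.ndarray) -> np.ndarray:
    """Translate an (..., 3*P) array of nt codes into (..., P) aa codes.

    Any codon containing a non-ACGT base translates to UNTRANSLATABLE.
    """
    if nt_codes.shape[-1] % 3 != 0:
        raise ValueError("nucleotide length not divisible by 3")
    cod = nt_codes.reshape(nt_codes.shape[:-1] + (-1, 3)).astype(np.int64)
    bad = (cod > 3).any(axis=-1)
    idx = 16 * np.clip(cod[..., 0], 0, 3) + 4 * np.clip(cod[..., 1], 0, 3) + np.clip(cod[..., 2], 0, 3)
    aa = CODON_AA[idx]
    aa = np.where(bad, np.uint8(UNTRANSLATABLE), aa)
    return aa


def translate_nt(seq: str) -> str:
    """Translate an in-frame nucleotide string; stops/ambiguities raise."""
    aa = translate_codes(encode_nt(seq))
    if (aa >= UNTRANSLATABLE).any():
        raise ValueError("sequence contains stop codons or ambiguous bases")
    return decode_aa(aa)
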