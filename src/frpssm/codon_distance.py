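"""Minimum nucleotide-substitution distances between codons and residues.

Somatic hypermutation is dominated by single-nucleotide events, so amino
acid substitutions reachable from the germline codon by one nucleotide
change are far more frequent in repertoires than those needing two or
three. These helpers compute the minimum Hamming distance from a source
codon (or any codon of a source residue) to any sense codon of a target
residue, and summarise PSSM scores by that distance class.

Distances are direct Hamming distances: stop codons are excluded as
targets and intermediate states are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seqcodes import AA_INDEX, AA_ORDER, CODON_AA, CODONS_BY_AA, NT_INDEX, UNTRANSLATABLE
from .io_formats import GermlineReference
from .pssm import PSSM


@dataclass(frozen=True)
class CodonDistanceResult:
    source_codon: str | None
    source_aa: str
    target_aa: str
    min_nt: int
    basis: str  # "germline_codon" | "any_source_codon"


def _codon_index(codon: str) -> int:
    try:
        return 16 * NT_INDEX[codon[0]] + 4 * NT_INDEX[codon[1]] + NT_INDEX[codon[2]]
    except (KeyError, IndexError):
        raise ValueError(f"invalid codon {codon!r}") from None


def min_nt_from_codon(codon: str, target_aa: str) -> int:
    """Minimum substitutions converting ``codon`` into any codon of ``target_aa``."""
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"invalid codon {codon!r}")
    idx = _codon_index(codon)
    if CODON_AA[idx] == UNTRANSLATABLE:
        raise ValueError(f"{codon} is not a sense codon")
    if target_aa not in AA_INDEX:
        raise ValueError(f"invalid residue {target_aa!r}")
    best = 3
    for tgt in CODONS_BY_AA[AA_INDEX[target_aa]]:
        d = sum(a != b for a, b in zip(codon, tgt, strict=True))
        best = min(best, d)
    return best


def min_nt_aa_level(source_aa: str, target_aa: str) -> int:
    """Minimum over all source-residue codons of :func:`min_nt_from_codon`."""
    if source_aa not in AA_INDEX:
        raise ValueError(f"invalid residue {source_aa!r}")
    return min(min_nt_from_codon(c, target_aa) for c in CODONS_BY_AA[AA_INDEX[source_aa]])


def aa_distance_table() -> pd.DataFrame:
    """20x20 table of amino-acid-level minimum substitution distances."""
    data = [[min_nt_aa_level(s, t) for t in AA_ORDER] for s in AA_ORDER]
    return pd.DataFrame(data, index=list(AA_ORDER), columns=list(AA_ORDER))


def classify_pssm_entries(pssm: PSSM, germline: GermlineReference) -> pd.DataFrame:
    """One row per unmasked PSSM entry with its germline-codon distance class."""
    if len(germline.nt_seq) != 3 * len(germline.aa_seq):
        raise ValueError("germline nucleotide and amino-acid sequences are out of frame")
    rows = []
    for pos, aa, score in pssm.entries():
        codon = germline.codon(pos)
        rows.append({
            "position": pos,
            "germline_aa": germline.aa_seq[pos - 1],
            "aa": aa,
            "score": score,
            "min_nt": min_nt_from_codon(codon, aa),
        })
    return pd.DataFrame(rows)


def class_score_summary(pssm: PSSM, germline: GermlineReference) -> dict:
    """Mean score and count per 1/2/3-substitution class, with Welch tests.

    P-values are one-tailed (lower class mean greater than the higher
    class's) Welch t-tests between classes. Empty classes report count 0
    and NaN mean.
    """
    df = classify_pssm_entries(pssm, germline)
    summary = {}
    groups = {}
    for k in (1, 2, 3):
        scores = df.loc[df["min_nt"] == k, "score"].to_numpy()
        groups[k] = scores
        summary[k] = {"mean": float(np.mean(scores)) if scores.size else float("nan"),
                      "count": int(scores.size)}
    pvals = {}
    for lo, hi in ((1, 2), (2, 3), (1, 3)):
        a, b = groups[lo], groups[hi]
        if a.size >= 2 and b.size >= 2:
            res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
            pvals[(lo, hi)] = float(res.pvalue)
        else:
            pvals[(lo, hi)] = float("nan")
    return {"classes": summary, "welch_p_greater": pvals}
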