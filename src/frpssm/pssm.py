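"""Position-specific scoring matrices for framework mutations.

The score of amino-acid substitution j at framework position i is

    S_ij = log_1.26( alpha * N_ij / T_i )

where N_ij is the observation count (pseudocount 1 for unobserved,
unmasked substitutions), T_i the number of gap-free sequences at the
position (the sum of all 20 residue counts, wild type included), and
alpha a germline-specific constant that centres the mean score of the
unmasked framework entries at zero. The log base 1.26 follows the
log-odds convention of Dayhoff-style matrices.

Wild-type residues and known allelic variants are masked: they are not
somatic mutations, so they receive no score, but their observations stay
in T_i so that N_ij / T_i remains a true per-sequence mutation frequency.

Centring constant in closed form: with f_ij = N_ij / T_i over the U
unmasked entries, mean S = 0 forces

    log(alpha) = -(1/U) * sum log f_ij   =>   alpha = 1 / geomean(f_ij).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from ._seqcodes import AA_INDEX, AA_ORDER, UNTRANSLATABLE, encode_aa
from .io_formats import GermlineReference

LOG_BASE = 1.26
DEFAULT_MIN_SEQUENCES = 100_000  # depth at which matrices are considered stable


@dataclass
class CountTable:
    """Per-position amino-acid observation counts over framework columns."""

    germline: str
    positions: np.ndarray            # 1-based germline positions, framework only
    counts: np.ndarray               # (P, 20) int64
    totals: np.ndarray               # (P,) gap-free sequence count
    masked: np.ndarray               # (P, 20) bool, wild type + alleles
    region_labels: list[str]
    n_sequences: int
    pseudocounted: np.ndarray = field(default=None)  # (P, 20) bool

    def __post_init__(self) -> None:
        if self.pseudocounted is None:
            self.pseudocounted = np.zeros_like(self.masked)

    def copy(self) -> "CountTable":
        return CountTable(
            self.germline, self.positions.copy(), self.counts.copy(), self.totals.copy(),
            self.masked.copy(), list(self.region_labels), self.n_sequences,
            self.pseudocounted.copy(),
        )


@dataclass
class PSSM:
    germline: str
    positions: np.ndarray
    scores: np.ndarray               # (P, 20) float, NaN at masked cells
    alpha: float
    log_base: float
    n_sequences: int
    region_labels: list[str]
    pseudocounted: np.ndarray
    settings: dict = field(default_factory=dict)

    def score_of(self, position: int, aa: str) -> float:
        i = int(np.nonzero(self.positions == position)[0][0])
        return float(self.scores[i, AA_INDEX[aa]])

    def unmasked(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    def entries(self) -> Iterator[tuple[int, str, float]]:
        for i, p in enumerate(self.positions):
            for j, aa in enumerate(AA_ORDER):
                s = self.scores[i, j]
                if not np.isnan(s):
                    yield int(p), aa, float(s)

    def flat(self) -> np.ndarray:
        """Unmasked scores as a 1-D array (row-major over positions x residues)."""
        return self.scores[self.unmasked()]


def tally_counts(aa_matrix: np.ndarray, ref: GermlineReference,
                 region_filter: str = "FR") -> CountTable:
    """Collapse an aligned amino-acid matrix into per-position counts.

    ``aa_matrix`` is (n, L_aa) of amino-acid codes in germline coordinates
    (see :func:`frpssm.alignment.aligned_aa_matrix`). Gap and
    untranslatable codes are excluded from the totals. With the default
    region filter only FR1/FR2/FR3 columns are kept.
    """
    mask = ref.region_mask
    if region_filter == "FR":
        keep = [p for p in range(1, len(mask) + 1) if mask[p - 1].startswith("FR")]
    elif region_filter == "all":
        keep = list(range(1, len(mask) + 1))
    else:
        raise ValueError(f"unknown region_filter {region_filter!r}")
    positions = np.array(keep, dtype=int)
    counts = np.zeros((len(keep), 20), dtype=np.int64)
    for out_i, p in enumerate(keep):
        col = aa_matrix[:, p - 1]
        counts[out_i] = np.bincount(col[col < UNTRANSLATABLE], minlength=20)
    totals = counts.sum(axis=1)
    return CountTable(
        germline=ref.gene_name,
        positions=positions,
        counts=counts,
        totals=totals,
        masked=np.zeros((len(keep), 20), dtype=bool),
        region_labels=[mask[p - 1] for p in keep],
        n_sequences=aa_matrix.shape[0],
    )


def mask_wt_and_alleles(table: CountTable, germline: GermlineReference,
                        allele_refs: Sequence[GermlineReference] = ()) -> CountTable:
    """Mask wild-type residues and allelic variants from scoring.

    Counts and totals are untouched; the cells are flagged so they are
    skipped when solving alpha and scoring. Idempotent.
    """
    out = table.copy()
    gl = encode_aa(germline.aa_seq)
    for i, p in enumerate(out.positions):
        out.masked[i, gl[p - 1]] = True
    for allele in allele_refs:
        if len(allele.aa_seq) != len(germline.aa_seq):
            raise ValueError(
                f"allele {allele.allele_name} has aa length {len(allele.aa_seq)}, "
                f"gene reference has {len(germline.aa_seq)}"
            )
        al = encode_aa(allele.aa_seq)
        for i, p in enumerate(out.positions):
            out.masked[i, al[p - 1]] = True
    return out


def apply_pseudocounts(table: CountTable) -> CountTable:
    """Replace zero counts of unmasked substitutions with a pseudocount of one."""
    out = table.copy()
    zero = (out.counts == 0) & ~out.masked
    out.counts[zero] = 1
    out.pseudocounted = out.pseudocounted | zero
    return out


def _unmasked_frequencies(table: CountTable) -> np.ndarray:
    if table.masked.all() or len(table.positions) == 0:
        raise ValueError("count table has no unmasked entries")
    if (table.totals <= 0).any():
        raise ValueError("every position needs at least one gap-free observation")
    freq = table.counts / table.totals[:, None]
    return freq[~table.masked]


def solve_alpha(table: CountTable) -> float:
    """Centring constant: reciprocal geometric mean of the unmasked frequencies."""
    f = _unmasked_frequencies(table)
    if (f <= 0).any():
        raise ValueError("apply pseudocounts before solving alpha")
    return float(np.exp(-np.mean(np.log(f))))


def score_matrix(table: CountTable, alpha: float, settings: dict | None = None) -> PSSM:
    """Log-transform the counts into scores; masked cells become NaN."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    freq = table.counts / table.totals[:, None]
    with np.errstate(divide="ignore"):
        scores = np.log(alpha * freq) / np.log(LOG_BASE)
    scores[table.masked] = np.nan
    return PSSM(
        germline=table.germline,
        positions=table.positions.copy(),
        scores=scores,
        alpha=float(alpha),
        log_base=LOG_BASE,
        n_sequences=table.n_sequences,
        region_labels=list(table.region_labels),
        pseudocounted=table.pseudocounted.copy(),
        settings=settings or {},
    )


def build_pssm(aa_matrix: np.ndarray, ref: GermlineReference,
               allele_refs: Sequence[GermlineReference] = (),
               min_sequences: int = DEFAULT_MIN_SEQUENCES,
               region_filter: str = "FR") -> PSSM:
    """Full pipeline: tally, mask, pseudocount, solve alpha, score.

    Emits a warning (not an error) when fewer than ``min_sequences``
    sequences back the matrix — below that depth score displacements
    against a deep repertoire stop shrinking reliably.
    """
    if aa_matrix.shape[0] < min_sequences:
        warnings.warn(
            f"building PSSM from {aa_matrix.shape[0]} sequences "
            f"(below the recommended depth of {min_sequences})",
            stacklevel=2,
        )
    table = tally_counts(aa_matrix, ref, region_filter=region_filter)
    table = mask_wt_and_alleles(table, ref, allele_refs)
    table = apply_pseudocounts(table)
    alpha = solve_alpha(table)
    return score_matrix(
        table, alpha,
        settings={"min_sequences": min_sequences, "region_filter": region_filter,
                  "alleles": [a.allele_name for a in allele_refs]},
    )
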