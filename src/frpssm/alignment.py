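"""Germline assignment, germline-anchored pairwise alignment, column maps.

A repertoire is anchored on its germline: each read is aligned pairwise
(global Needleman-Wunsch with affine gaps) to the common germline rather
than through a progressive MSA of the whole repertoire, which gives the
same column semantics at a fraction of the cost. Columns where the
germline carries a gap are insertion columns; in an ingested MSA they are
dropped when their occupancy is under the threshold (default strictly
below 10%), and in the pairwise path they are private to one read and
dropped directly.

Gap convention: a gap of length g costs ``gap_open + (g-1)*gap_extend``
(penalties given as positive magnitudes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

from ._seqcodes import GAP, encode_aa, encode_nt, translate_codes
from .io_formats import GermlineReference, RepertoireRecord


class UnassignedError(ValueError):
    """Query could not be assigned to any germline above the identity floor."""


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = 5.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_pair(query: str, reference: str, *, match: float = 1.0, mismatch: float = -1.0,
               gap_open: float = 5.0, gap_extend: float = 1.0) -> tuple[str, str, float]:
    """Global affine-gap alignment; returns (query_row, reference_row, score)."""
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(query, reference)[0]
    q_row, r_row = str(aln[0]), str(aln[1])
    return q_row, r_row, float(aln.score)


def align_to_germline(query_nt: str, ref: GermlineReference, *, gap_open: float = 5.0,
                      gap_extend: float = 1.0) -> tuple[str, str]:
    """Align a nucleotide query to the germline frame (query_row, germline_row)."""
    q, g, _ = align_pair(query_nt.upper(), ref.nt_seq, gap_open=gap_open, gap_extend=gap_extend)
    return q, g


def percent_identity(query_row: str, ref_row: str) -> float:
    """Identity over reference non-gap positions, in percent."""
    ref_positions = 0
    matches = 0
    for q, r in zip(query_row, ref_row, strict=True):
        if r != "-":
            ref_positions += 1
            if q == r:
                matches += 1
    return 100.0 * matches / ref_positions


def assign_germline(query_nt: str, refs: Sequence[GermlineReference],
                    min_identity: float = 60.0) -> tuple[str, float]:
    """Assign the germline gene with the highest pairwise nucleotide identity.

    Ties are broken lexicographically by gene name (and reported via the
    returned identity being shared). Raises :class:`UnassignedError` when
    the best identity is below ``min_identity`` percent.
    """
    if not refs:
        raise ValueError("need at least one reference")
    best: tuple[float, str] | None = None
    for ref in sorted(refs, key=lambda r: r.gene_name):
        q, g = align_to_germline(query_nt, ref)
        ident = percent_identity(q, g)
        if best is None or ident > best[0]:
            best = (ident, ref.gene_name)
    ident, gene = best
    if ident < min_identity:
        raise UnassignedError(f"best identity {ident:.2f}% below floor {min_identity}%")
    return gene, ident


@dataclass(frozen=True)
class ColumnInfo:
    column_index: int
    germline_position: int | None  # None for a retained insertion column
    occupancy: float
    region_label: str | None


@dataclass
class AlignedColumnMap:
    columns: list[ColumnInfo]
    dropped_columns: list[int]

    def germline_positions(self) -> list[int]:
        return [c.germline_position for c in self.columns if c.germline_position is not None]


def build_column_map(rows: Sequence[str], germline_row: str, ref: GermlineReference,
                     min_occupancy: float = 0.10) -> AlignedColumnMap:
    """Map MSA columns to germline positions, dropping sparse insertions.

    ``rows`` are gapped amino-acid rows of one MSA (germline row passed
    separately, same length). Columns whose non-gap occupancy across the
    repertoire rows is strictly below ``min_occupancy`` are dropped;
    retained columns are numbered against the germline and labelled with
    the reference region windows.
    """
    if not rows:
        raise ValueError("empty alignment")
    width = len(germline_row)
    if any(len(r) != width for r in rows):
        raise ValueError("aligned rows must all equal the germline row length")
    mat = np.stack([encode_aa(r) for r in rows])
    occupancy = (mat != GAP).mean(axis=0)
    region_mask = ref.region_mask
    columns: list[ColumnInfo] = []
    dropped: list[int] = []
    gl_pos = 0
    for c in range(width):
        is_gl = germline_row[c] != "-"
        if is_gl:
            gl_pos += 1
        if occupancy[c] < min_occupancy:
            dropped.append(c)
            continue
        pos = gl_pos if is_gl else None
        label = region_mask[pos - 1] if pos is not None else None
        columns.append(ColumnInfo(c, pos, float(occupancy[c]), label))
    return AlignedColumnMap(columns, dropped)


def msa_to_matrix(rows: Sequence[str], germline_row: str, ref: GermlineReference,
                  min_occupancy: float = 0.10) -> np.ndarray:
    """Project MSA rows onto germline coordinates -> (n, L_aa) aa-code matrix."""
    cmap = build_column_map(rows, germline_row, ref, min_occupancy)
    n, L = len(rows), len(ref.aa_seq)
    out = np.full((n, L), GAP, dtype=np.uint8)
    enc = np.stack([encode_aa(r) for r in rows])
    for col in cmap.columns:
        if col.germline_position is not None:
            out[:, col.germline_position - 1] = enc[:, col.column_index]
    return out


def aligned_aa_matrix(records: Sequence[RepertoireRecord] | Sequence[str],
                      ref: GermlineReference, *, gap_open: float = 5.0,
                      gap_extend: float = 1.0) -> np.ndarray:
    """Translate repertoire reads in the germline frame -> (n, L_aa) aa codes.

    Reads whose length equals the germline (substitution-only) are
    translated directly; others are aligned pairwise to the germline,
    insertion columns dropped, and deleted or partially covered codons
    reported as gaps. Codons with ambiguous bases or stops translate to
    the untranslatable code and are excluded from tallies downstream.
    """
    seqs = [r.nt_seq if isinstance(r, RepertoireRecord) else r for r in records]
    L_nt, L_aa = len(ref.nt_seq), len(ref.aa_seq)
    out = np.full((len(seqs), L_aa), GAP, dtype=np.uint8)
    fast = [i for i, s in enumerate(seqs) if len(s) == L_nt]
    if fast:
        block = np.stack([encode_nt(seqs[i]) for i in fast])
        out[np.array(fast)] = translate_codes(block)
    for i, s in enumerate(seqs):
        if len(s) == L_nt:
            continue
        q_row, g_row = align_to_germline(s, ref, gap_open=gap_open, gap_extend=gap_extend)
        # walk germline coordinates, collect query codons
        nt_codes = np.full(L_nt, 255, dtype=np.uint8)
        covered = np.zeros(L_nt, dtype=bool)
        gpos = 0
        q_enc = encode_nt(q_row.replace("-", "A"))  # placeholder; gaps tracked below
        for c, (qc, gc) in enumerate(zip(q_row, g_row, strict=True)):
            if gc == "-":
                continue  # insertion column, dropped
            if qc != "-":
                nt_codes[gpos] = q_enc[c]
                covered[gpos] = True
            gpos += 1
        aa = translate_codes(np.where(covered, nt_codes, 255))
        codon_cov = covered.reshape(-1, 3).all(axis=1)
        aa = np.where(codon_cov, aa, np.uint8(GAP))
        out[i] = aa
    return out
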