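"""Antibody-level framework (FR) scores.

An antibody's FR mutations are scored individually against its germline's
PSSM; the score sum is then normalised by the typical score sum of a
repertoire antibody from the same germline with the same mutation count:

    FR = 1                                   for m = 0
    FR = sum_k S_ijk / (c0*m + c1*m^2)       for m > 0

c0 and c1 are fitted per germline by ordinary least squares (no
intercept) of repertoire score sums on (m, m^2), over individual sampled
repertoire antibodies with at least one FR mutation. An FR score of one
means "framework mutations as typical as a randomly sampled repertoire
antibody with the same mutation load"; mutation effects are assumed
additive and independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seqcodes import AA_INDEX, UNTRANSLATABLE, encode_aa
from .alignment import align_pair
from .io_formats import GermlineReference
from .pssm import PSSM


@dataclass
class MutationRecord:
    position: int
    germline_residue: str
    observed_residue: str
    score: float | None = None
    min_nt: int | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.observed_residue == self.germline_residue:
            raise ValueError("observed residue equals the germline residue")


@dataclass
class FRScoreModel:
    germline: str
    c0: float
    c1: float
    fit_sample_size: int

    def denominator(self, m: int) -> float:
        return self.c0 * m + self.c1 * m * m

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "germline": self.germline, "c0": self.c0, "c1": self.c1,
            "fit_sample_size": self.fit_sample_size,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FRScoreModel":
        d = json.loads(Path(path).read_text())
        return cls(d["germline"], float(d["c0"]), float(d["c1"]), int(d["fit_sample_size"]))


def list_fr_mutations(query_aa: str, germline: GermlineReference,
                      pssm: PSSM | None = None) -> list[MutationRecord]:
    """Framework differences between a query amino-acid sequence and its germline.

    The query is globally aligned to the germline amino-acid sequence;
    one record is produced per framework position where the aligned
    residues differ. CDR differences and gapped positions are skipped.
    When a PSSM is given, scores are attached (the PSSM germline must
    match).
    """
    if pssm is not None and pssm.germline != germline.gene_name:
        raise ValueError(f"PSSM is for {pssm.germline}, query germline is {germline.gene_name}")
    if query_aa == germline.aa_seq:
        return []
    q_row, g_row, _ = align_pair(query_aa.upper(), germline.aa_seq)
    region = germline.region_mask
    muts: list[MutationRecord] = []
    gpos = 0
    for qc, gc in zip(q_row, g_row, strict=True):
        if gc == "-":
            continue
        gpos += 1
        if qc in ("-", gc) or qc not in AA_INDEX:
            continue
        label = region[gpos - 1]
        if not label.startswith("FR"):
            continue
        rec = MutationRecord(gpos, gc, qc, region=label)
        if pssm is not None:
            rec.score = pssm.score_of(gpos, qc)
        muts.append(rec)
    return muts


def mutation_loads(aa_matrix: np.ndarray, ref: GermlineReference,
                   pssm: PSSM) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (m, score_sum) per repertoire sequence.

    A residue counts as an FR mutation when it differs from the germline,
    is a real residue (not gap/untranslatable), and carries an unmasked
    PSSM score (allelic-variant residues are masked and therefore not
    counted as mutations, mirroring their removal from the count table).
    """
    fr = ref.fr_positions()
    gl = encode_aa(ref.aa_seq)[fr - 1]
    sub = aa_matrix[:, fr - 1]
    pos_index = {p: i for i, p in enumerate(pssm.positions)}
    rows = np.array([pos_index[p] for p in fr])
    scores = pssm.scores[rows]                        # (F, 20), NaN at masked
    scorable = ~np.isnan(scores)
    is_mut = (sub != gl[None, :]) & (sub < UNTRANSLATABLE)
    is_mut &= scorable[np.arange(len(fr))[None, :], np.clip(sub, 0, 19)]
    safe = np.where(is_mut, sub, 0)
    per_pos = np.where(is_mut, scores[np.arange(len(fr))[None, :], safe], 0.0)
    return is_mut.sum(axis=1), per_pos.sum(axis=1)


def fit_normalization(samples: Sequence[tuple[int, float]], germline: str = "",
                      on_means: bool = False) -> FRScoreModel:
    """Least-squares fit of score sums to c0*m + c1*m^2 (no intercept).

    ``samples`` are (m, score_sum) pairs; antibodies with m = 0 carry no
    constraint and are dropped. ``on_means`` first averages the sums per
    mutation count and fits the per-m means instead of the raw antibodies.
    """
    pts = [(m, s) for m, s in samples if m >= 1]
    if len({m for m, _ in pts}) < 2:
        raise ValueError(
            "need at least two distinct mutation counts m >= 1 to fit c0/c1; "
            "sample more repertoire antibodies"
        )
    if on_means:
        df = pd.DataFrame(pts, columns=["m", "s"]).groupby("m", as_index=False).mean()
        pts = list(df.itertuples(index=False, name=None))
    m = np.array([p[0] for p in pts], dtype=float)
    s = np.array([p[1] for p in pts], dtype=float)
    X = np.column_stack([m, m * m])
    coef, *_ = np.linalg.lstsq(X, s, rcond=None)
    return FRScoreModel(germline=germline, c0=float(coef[0]), c1=float(coef[1]),
                        fit_sample_size=len(pts))


def fit_from_repertoire(aa_matrix: np.ndarray, ref: GermlineReference, pssm: PSSM,
                        n: int = 1000, seed: int | None = None,
                        with_replacement: bool = True, on_means: bool = False) -> FRScoreModel:
    """Fit c0/c1 on a random sample of repertoire antibodies (default 1,000)."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(aa_matrix.shape[0], size=min(n, aa_matrix.shape[0]) if not with_replacement else n,
                     replace=with_replacement)
    m, s = mutation_loads(aa_matrix[idx], ref, pssm)
    return fit_normalization(list(zip(m.tolist(), s.tolist())), germline=ref.gene_name,
                             on_means=on_means)


def fr_score(mutations: Sequence[MutationRecord] | Sequence[float],
             model: FRScoreModel) -> float:
    """Normalised FR score; exactly 1.0 for an unmutated framework."""
    scores = [mu.score if isinstance(mu, MutationRecord) else float(mu) for mu in mutations]
    m = len(scores)
    if m == 0:
        return 1.0
    if any(s is None for s in scores):
        raise ValueError("all mutations must carry a PSSM score")
    denom = model.denominator(m)
    if denom <= 0:
        raise ValueError(
            f"normalisation model for {model.germline or 'this germline'} has a "
            f"non-positive denominator at m={m}; refit on a larger sample"
        )
    return float(np.sum(scores) / denom)


def score_report(queries: Sequence[tuple[str, str]], pssm: PSSM, model: FRScoreModel,
                 germline: GermlineReference) -> pd.DataFrame:
    """Per-antibody report: mutation count, individual scores, FR score.

    ``queries`` are (antibody_id, aa_sequence) pairs; output row order
    follows input order.
    """
    if model.germline and model.germline != germline.gene_name:
        raise ValueError(f"model fitted for {model.germline}, queries are {germline.gene_name}")
    rows = []
    for ab_id, seq in queries:
        muts = list_fr_mutations(seq, germline, pssm)
        scores = [mu.score for mu in muts]
        rows.append({
            "antibody_id": ab_id,
            "germline": germline.gene_name,
            "m": len(muts),
            "mutations": ";".join(f"{mu.germline_residue}{mu.position}{mu.observed_residue}"
                                   for mu in muts),
            "scores": ";".join(f"{s:.2f}" for s in scores),
            "fr_score": fr_score(muts, model),
            "frac_scores_below_zero": (float(np.mean([s < 0 for s in scores]))
                                        if scores else 0.0),
        })
    return pd.DataFrame(rows)
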