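"""Peptide:MHC-II KD fold-change binning of framework-mutation scores.

Given predicted binding affinities (KD, nM) of 15-mer peptide windows
from a mutated antibody and its germline against a panel of HLA-DRB1
alleles, mutated peptides matching a high-affinity germline peptide
(KD < 1,000 nM) are binned by the ratio mutant KD / germline KD:
fold < 0.5 (binding strengthened), 0.5 <= fold <= 2 (unchanged),
fold > 2 (binding weakened). All peptides are additionally tagged by the
germline affinity class. PSSM scores of the mutations each peptide
carries are averaged per allele and bin, and bins are compared by Welch
t-tests over the allele-level means with Benjamini-Hochberg adjustment.

The affinity predictor itself is out of scope; any TSV with columns
(peptide, allele, kd_nM) is accepted.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fr_score import MutationRecord

logger = logging.getLogger(__name__)

HIGH_AFFINITY_NM = 1000.0
FOLD_BINS = ("fold<0.5", "0.5<=fold<=2", "fold>2")
AFFINITY_BINS = ("all_high_affinity_gl", "all_low_affinity_gl")


def window_peptides(aa_seq: str, width: int = 15) -> list[tuple[int, str]]:
    """All consecutive ``width``-mers with 1-based start positions."""
    if len(aa_seq) < width:
        raise ValueError(f"sequence shorter than {width} residues")
    return [(s + 1, aa_seq[s : s + width]) for s in range(len(aa_seq) - width + 1)]


def pair_by_position(mutant_seq: str, germline_seq: str, width: int = 15) -> dict[str, str]:
    """Pair mutant to germline peptides sharing the same start position.

    Both sequences must be in the same (germline) coordinate frame, i.e.
    equal length; the map is mutant peptide -> germline peptide.
    """
    if len(mutant_seq) != len(germline_seq):
        raise ValueError("sequences must be aligned to equal length")
    return {
        mp: gp
        for (_, mp), (_, gp) in zip(window_peptides(mutant_seq, width),
                                    window_peptides(germline_seq, width), strict=True)
    }


def bin_by_fold_change(mutant: pd.DataFrame, germline: pd.DataFrame,
                       pairing: Mapping[str, str]) -> pd.DataFrame:
    """Assign each (mutant peptide, allele) to a KD fold-change bin.

    Input frames carry columns peptide, allele, kd_nM; comparisons are
    made per allele. Output columns: peptide, allele, kd_mut, kd_gl,
    fold, fold_bin (one of the three bins, or NA when the germline
    peptide is not high-affinity), gl_affinity. Mutant peptides absent
    from the pairing are excluded and logged.
    """
    unmatched = sorted(set(mutant["peptide"]) - set(pairing))
    if unmatched:
        logger.warning("excluding %d mutant peptides with no germline partner", len(unmatched))
    mut = mutant[mutant["peptide"].isin(pairing)].copy()
    mut["gl_peptide"] = mut["peptide"].map(pairing)
    gl = germline.rename(columns={"peptide": "gl_peptide", "kd_nM": "kd_gl"})
    df = mut.rename(columns={"kd_nM": "kd_mut"}).merge(
        gl[["gl_peptide", "allele", "kd_gl"]], on=["gl_peptide", "allele"], how="inner")
    df["fold"] = df["kd_mut"] / df["kd_gl"]
    high = df["kd_gl"] < HIGH_AFFINITY_NM
    df["gl_affinity"] = np.where(high, "high", "low")
    fold_bin = pd.Series(pd.NA, index=df.index, dtype="object")
    fold_bin[high & (df["fold"] < 0.5)] = FOLD_BINS[0]
    fold_bin[high & (df["fold"] >= 0.5) & (df["fold"] <= 2)] = FOLD_BINS[1]
    fold_bin[high & (df["fold"] > 2)] = FOLD_BINS[2]
    df["fold_bin"] = fold_bin
    return df[["peptide", "gl_peptide", "allele", "kd_mut", "kd_gl", "fold",
               "fold_bin", "gl_affinity"]]


def peptide_scores(peptides: Sequence[tuple[int, str]],
                   mutations: Sequence[MutationRecord],
                   multi: str = "mean") -> dict[str, float]:
    """Mean PSSM score of the mutations each peptide window covers.

    A window starting at s (1-based, germline coordinates) covers a
    mutation at position p iff s <= p <= s + 14. Windows containing no
    mutation are omitted. ``multi='expand'`` returns one entry per
    (peptide, k) mutation instead of the mean (keys suffixed ``#k``).
    """
    out: dict[str, float] = {}
    for start, pep in peptides:
        covered = [mu.score for mu in mutations
                   if start <= mu.position <= start + len(pep) - 1]
        if not covered:
            continue
        if any(s is None for s in covered):
            raise ValueError("mutations must carry PSSM scores")
        if multi == "mean":
            out[pep] = float(np.mean(covered))
        elif multi == "expand":
            for k, s in enumerate(covered):
                out[f"{pep}#{k}"] = float(s)
        else:
            raise ValueError(f"unknown multi policy {multi!r}")
    return out


def average_and_test(binned: pd.DataFrame, scores: Mapping[str, float]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allele x bin mean PSSM scores, plus Welch tests between bins.

    Returns (means, tests). Means has columns allele, bin, mean_score, n
    over the three fold bins and the two germline-affinity groups; tests
    compares every bin pair by a Welch two-sample t-test over the
    allele-level means with BH-adjusted p-values. Pairs where either bin
    has fewer than two allele means are skipped with a notice.
    """
    df = binned.copy()
    df["score"] = df["peptide"].map(scores)
    df = df.dropna(subset=["score"])
    pieces = []
    fold = df.dropna(subset=["fold_bin"]).rename(columns={"fold_bin": "bin"})
    pieces.append(fold[["allele", "bin", "score"]])
    aff = df.copy()
    aff["bin"] = np.where(aff["gl_affinity"] == "high", AFFINITY_BINS[0], AFFINITY_BINS[1])
    pieces.append(aff[["allele", "bin", "score"]])
    long = pd.concat(pieces, ignore_index=True)
    means = (long.groupby(["allele", "bin"], as_index=False)
                 .agg(mean_score=("score", "mean"), n=("score", "size")))
    groups = {b: g["mean_score"].to_numpy() for b, g in means.groupby("bin")}
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        xa, xb = groups[a], groups[b]
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("skipping test %s vs %s: fewer than 2 allele means", a, b)
            continue
        res = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"bin_a": a, "bin_b": b, "mean_a": float(np.mean(xa)),
                     "mean_b": float(np.mean(xb)), "t": float(res.statistic),
                     "p_raw": float(res.pvalue)})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_adj"] = multipletests(tests["p_raw"], method="fdr_bh")[1]
    return means, tests
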