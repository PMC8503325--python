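"""Repertoire maturation summaries and PSSM comparison analyses.

Covers per-position mutation frequencies, germline-identity summaries,
dN/dS event counting against the germline, Pearson comparisons between
PSSMs (optionally restricted to shared-codon positions or single-
nucleotide-reachable substitutions), UPGMA clustering of PSSMs on the
1 - r distance, and subsampling convergence of PSSM scores.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from skbio.tree import TreeNode

from ._seqcodes import AA_ORDER, UNTRANSLATABLE, encode_aa, encode_nt, translate_codes
from .codon_distance import min_nt_from_codon
from .io_formats import GermlineReference
from .pssm import PSSM, build_pssm


# ---------------------------------------------------------------- maturation

def per_position_frequency(aa_matrix: np.ndarray, ref: GermlineReference) -> pd.DataFrame:
    """Fraction of gap-free sequences mutated at each position, with region means.

    Returns a frame with columns position, region, frequency; region
    averages are attached as ``.attrs['region_means']`` (keys FR, CDR).
    """
    gl = encode_aa(ref.aa_seq)
    valid = aa_matrix < UNTRANSLATABLE
    mutated = valid & (aa_matrix != gl[None, :])
    with np.errstate(invalid="ignore"):
        freq = mutated.sum(axis=0) / valid.sum(axis=0)
    region = ref.region_mask
    df = pd.DataFrame({
        "position": np.arange(1, len(gl) + 1),
        "region": region,
        "frequency": freq,
    })
    is_fr = df["region"].str.startswith("FR")
    df.attrs["region_means"] = {
        "FR": float(df.loc[is_fr, "frequency"].mean()),
        "CDR": float(df.loc[~is_fr, "frequency"].mean()),
        "all": float(df["frequency"].mean()),
    }
    return df


def identity_summary(nt_matrix: np.ndarray, ref: GermlineReference) -> tuple[float, float]:
    """(% of records with >98% germline nt identity, % unmutated records).

    Identity is computed over covered germline positions (codes > 3, e.g.
    padding for ambiguity, are excluded from the denominator); the >98%
    bin is strict and contains the unmutated records.
    """
    gl = encode_nt(ref.nt_seq)
    valid = nt_matrix <= 3
    matches = (nt_matrix == gl[None, :]) & valid
    ident = matches.sum(axis=1) / valid.sum(axis=1)
    over98 = float(np.mean(ident > 0.98) * 100)
    unmut = float(np.mean(ident == 1.0) * 100)
    return over98, unmut


@dataclass
class DnDsResult:
    n_events: int
    s_events: int

    @property
    def ratio(self) -> float:
        return self.n_events / self.s_events if self.s_events else float("nan")


def dn_ds(nt_matrix: np.ndarray, ref: GermlineReference) -> DnDsResult:
    """Nonsynonymous/synonymous event totals versus the germline, per codon.

    A codon differing from germline counts one nonsynonymous event when
    its translation changes, otherwise one synonymous event. Codons hit
    by multiple nucleotide changes still count a single event.
    """
    gl = encode_nt(ref.nt_seq)
    gl_aa = translate_codes(gl)
    aa = translate_codes(nt_matrix)
    diff_codon = (nt_matrix.reshape(nt_matrix.shape[0], -1, 3)
                  != gl.reshape(-1, 3)[None, :, :]).any(axis=2)
    nonsyn = diff_codon & (aa != gl_aa[None, :]) & (aa < UNTRANSLATABLE)
    syn = diff_codon & (aa == gl_aa[None, :])
    return DnDsResult(int(nonsyn.sum()), int(syn.sum()))


# ---------------------------------------------------------------- comparisons

@dataclass
class ComparisonMatrix:
    labels: list[str]
    r: np.ndarray
    shared_codon_restricted: bool = False


def pssm_correlation(p1: PSSM, p2: PSSM, *, shared_codon_only: bool = False,
                     one_nt_only: bool = False, observed_only: bool = False,
                     germline1: GermlineReference | None = None,
                     germline2: GermlineReference | None = None) -> float:
    """Pearson r between two PSSMs over their common unmasked entries.

    ``shared_codon_only`` keeps positions where both germlines carry an
    identical codon; ``one_nt_only`` keeps substitutions one nucleotide
    from the germline codon; ``observed_only`` drops entries that are
    pseudocounts in either matrix. The codon-based restrictions require
    the germline references.
    """
    common = np.intersect1d(p1.positions, p2.positions)
    i1 = np.searchsorted(p1.positions, common)
    i2 = np.searchsorted(p2.positions, common)
    keep = ~np.isnan(p1.scores[i1]) & ~np.isnan(p2.scores[i2])
    if observed_only:
        keep &= ~p1.pseudocounted[i1] & ~p2.pseudocounted[i2]
    if shared_codon_only or one_nt_only:
        if germline1 is None or germline2 is None:
            raise ValueError("codon-based restrictions need both germline references")
        for row, pos in enumerate(common):
            c1, c2 = germline1.codon(int(pos)), germline2.codon(int(pos))
            if shared_codon_only and c1 != c2:
                keep[row] = False
                continue
            if one_nt_only and keep[row].any():
                for j in np.nonzero(keep[row])[0]:
                    aa = AA_ORDER[j]
                    if min_nt_from_codon(c1, aa) != 1 or (
                            germline2 is not germline1 and min_nt_from_codon(c2, aa) != 1):
                        keep[row, j] = False
    a = p1.scores[i1][keep]
    b = p2.scores[i2][keep]
    if a.size < 3:
        raise ValueError("fewer than 3 overlapping unmasked entries")
    return float(pearsonr(a, b).statistic)


def comparison_matrix(pssms: Sequence[PSSM], labels: Sequence[str] | None = None,
                      **corr_kwargs) -> ComparisonMatrix:
    labels = list(labels) if labels is not None else [p.germline for p in pssms]
    k = len(pssms)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = pssm_correlation(pssms[i], pssms[j], **corr_kwargs)
    return ComparisonMatrix(labels, r,
                            shared_codon_restricted=bool(corr_kwargs.get("shared_codon_only")))


def upgma_linkage(dist: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration of a square distance matrix."""
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


def cluster_pssms(matrices: Sequence[PSSM] | ComparisonMatrix,
                  labels: Sequence[str] | None = None, **corr_kwargs) -> str:
    """UPGMA dendrogram of PSSMs on the distance 1 - r; returns Newick."""
    if isinstance(matrices, ComparisonMatrix):
        cm = matrices
    else:
        if len(matrices) < 2:
            raise ValueError("need at least two PSSMs to cluster")
        cm = comparison_matrix(matrices, labels, **corr_kwargs)
    dist = 1.0 - cm.r
    np.fill_diagonal(dist, 0.0)
    Z = upgma_linkage(dist)
    tree = TreeNode.from_linkage_matrix(Z, cm.labels)
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------- subsampling

@dataclass
class SubsampleReport:
    sizes: list[int]
    median_displacement: dict[int, float]
    p975_displacement: dict[int, float]
    reps: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size": self.sizes,
            "median_abs_dS": [self.median_displacement[s] for s in self.sizes],
            "p97.5_abs_dS": [self.p975_displacement[s] for s in self.sizes],
        })


def subsample_convergence(aa_matrix: np.ndarray, ref: GermlineReference,
                          sizes: Sequence[int], reps: int = 3, seed: int = 0,
                          allele_refs: Sequence[GermlineReference] = ()) -> SubsampleReport:
    """Score displacement |S_sub - S_full| across subsampling depths.

    For each size and repetition a uniform subsample without replacement
    is drawn, a PSSM built from it, and the absolute score difference to
    the full-data PSSM collected over entries unmasked in both; the
    median and 97.5th percentile are pooled over repetitions.
    """
    n = aa_matrix.shape[0]
    if max(sizes) > n:
        raise ValueError(f"subsample size {max(sizes)} exceeds available {n}")
    full = build_pssm(aa_matrix, ref, allele_refs, min_sequences=0)
    rng = np.random.default_rng(seed)
    med: dict[int, float] = {}
    hi: dict[int, float] = {}
    for size in sizes:
        disp: list[np.ndarray] = []
        for _ in range(reps):
            idx = rng.choice(n, size=size, replace=False)
            sub = build_pssm(aa_matrix[idx], ref, allele_refs, min_sequences=0)
            both = full.unmasked() & sub.unmasked()
            disp.append(np.abs(sub.scores[both] - full.scores[both]))
        pooled = np.concatenate(disp)
        med[size] = float(np.median(pooled))
        hi[size] = float(np.percentile(pooled, 97.5))
    return SubsampleReport(list(sizes), med, hi, reps, seed)
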