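"""Synthetic somatic-hypermutation repertoires and KD tables with known truth.

The generator emulates the mutational structure of affinity maturation
at the mechanistic level: each sequence descends from the germline by a
number of independent single-nucleotide substitutions drawn from a
mutation-load distribution, at positions drawn from per-site weights,
with replacement bases drawn from a nucleotide substitution-bias matrix
(default transitions favoured 2:1 over transversions, matching the
point-mutation bias of activation-induced cytidine deaminase without
modelling its hotspot motifs). No selection step is simulated, so score
magnitudes of real, selected repertoires are not reproduced — only the
mechanistic structure (single-nucleotide enrichment, per-site rates).

The default mutation load is negative binomial (mean 8 nucleotide
substitutions per 288-nt V segment, shape 2), an overdispersed mixture
of lightly and heavily matured sequences that leaves a few percent of
sequences unmutated, as seen in IgG repertoires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seqcodes import AA_ORDER, CODON_AA, NT_ORDER, UNTRANSLATABLE, encode_nt
from .io_formats import GermlineReference, RepertoireRecord, RepertoireSet
from .pssm import PSSM


def default_bias(transition_weight: float = 2.0) -> np.ndarray:
    """4x4 substitution matrix, rows germline base, transitions favoured."""
    transitions = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T
    bias = np.ones((4, 4))
    np.fill_diagonal(bias, 0.0)
    for a, b in transitions.items():
        bias[a, b] = transition_weight
    return bias / bias.sum(axis=1, keepdims=True)


@dataclass
class MutationLoad:
    """Distribution of nucleotide substitutions per sequence."""

    kind: str = "nb"          # "nb" | "poisson" | "fixed"
    mean: float = 8.0
    shape: float = 2.0        # NB dispersion; ignored otherwise

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mean == 0:
            return np.zeros(n, dtype=np.int64)
        if self.kind == "poisson":
            return rng.poisson(self.mean, size=n)
        if self.kind == "nb":
            p = self.shape / (self.shape + self.mean)
            return rng.negative_binomial(self.shape, p, size=n)
        if self.kind == "fixed":
            return np.full(n, int(round(self.mean)), dtype=np.int64)
        raise ValueError(f"unknown load kind {self.kind!r}")


@dataclass
class SimParams:
    germline: GermlineReference
    n_sequences: int = 10_000
    mutation_load: MutationLoad = field(default_factory=MutationLoad)
    position_weights: np.ndarray | None = None     # per-nt-site relative rates
    substitution_bias: np.ndarray = field(default_factory=default_bias)
    seed: int = 0

    def __post_init__(self) -> None:
        L = len(self.germline.nt_seq)
        if self.position_weights is None:
            self.position_weights = np.ones(L)
        self.position_weights = np.asarray(self.position_weights, dtype=float)
        if len(self.position_weights) != L:
            raise ValueError("position_weights length must match the germline")
        if (self.position_weights < 0).any() or self.position_weights.sum() == 0:
            raise ValueError("position weights must be non-negative, not all zero")
        bias = np.asarray(self.substitution_bias, dtype=float)
        if bias.shape != (4, 4) or (np.diag(bias) != 0).any() or \
                not np.allclose(bias.sum(axis=1), 1.0):
            raise ValueError("substitution bias must be 4x4, zero diagonal, rows summing to 1")
        self.substitution_bias = bias


def simulate_nt_matrix(params: SimParams) -> np.ndarray:
    """Mutated sequences as an (n, L) nucleotide-code matrix.

    Substitution bases are drawn conditional on the germline base at the
    hit site; repeated hits on one site within a sequence overwrite, so
    per-site events stay exactly single-nucleotide relative to germline.
    Stop-creating hits are not filtered here (downstream translation
    skips such codons), keeping the mechanism selection-free.
    """
    rng = np.random.default_rng(params.seed)
    gl = encode_nt(params.germline.nt_seq)
    L = len(gl)
    out = np.tile(gl, (params.n_sequences, 1))
    k = params.mutation_load.sample(params.n_sequences, rng)
    total = int(k.sum())
    if total == 0:
        return out
    seq_idx = np.repeat(np.arange(params.n_sequences), k)
    w = params.position_weights / params.position_weights.sum()
    sites = rng.choice(L, size=total, p=w)
    old = gl[sites]
    cum = params.substitution_bias.cumsum(axis=1)[old]
    new = (rng.random(total)[:, None] < cum).argmax(axis=1)
    out[seq_idx, sites] = new.astype(np.uint8)
    return out


def matrix_to_records(nt_matrix: np.ndarray, prefix: str = "sim") -> list[RepertoireRecord]:
    lut = np.frombuffer(NT_ORDER.encode(), dtype=np.uint8)
    return [
        RepertoireRecord(
            sequence_id=f"{prefix}_{i:06d}", subject_id=prefix, isotype="IgG",
            nt_seq=lut[row].tobytes().decode("ascii"),
        )
        for i, row in enumerate(nt_matrix)
    ]


def simulate_repertoire(params: SimParams) -> RepertoireSet:
    """Simulate a germline-anchored IgG repertoire (deterministic per seed)."""
    return RepertoireSet(
        germline=params.germline,
        records=matrix_to_records(simulate_nt_matrix(params)),
    )


def true_aa_profile(params: SimParams, multi_hit: bool = False,
                    mc_factor: int = 10) -> np.ndarray:
    """Expected per-sequence amino-acid substitution frequencies, (L_aa, 20).

    Single-hit closed form: each codon's nine single-nucleotide
    neighbours are enumerated, weighted by site weight x substitution
    bias x expected load; neighbours translating to a stop contribute
    nothing. With ``multi_hit`` the expectation is instead estimated by
    Monte Carlo at ``mc_factor`` times the configured repertoire size
    under an offset seed.
    """
    gl = encode_nt(params.germline.nt_seq)
    L_aa = len(params.germline.aa_seq)
    if multi_hit:
        mc = replace(params, n_sequences=params.n_sequences * mc_factor,
                     seed=params.seed + 987_654)
        mat = simulate_nt_matrix(mc)
        from ._seqcodes import translate_codes
        aa = translate_codes(mat)
        gl_aa = translate_codes(gl)
        prof = np.zeros((L_aa, 20))
        for p in range(L_aa):
            col = aa[:, p]
            counts = np.bincount(col[col < UNTRANSLATABLE], minlength=20)
            counts[gl_aa[p]] = 0
            prof[p] = counts / len(mat)
        return prof
    w = params.position_weights / params.position_weights.sum()
    mean_load = params.mutation_load.mean
    prof = np.zeros((L_aa, 20))
    for p in range(L_aa):
        codon = gl[3 * p : 3 * p + 3]
        src_aa = CODON_AA[16 * codon[0] + 4 * codon[1] + codon[2]]
        for off in range(3):
            site = 3 * p + off
            for new in range(4):
                if new == codon[off]:
                    continue
                neigh = codon.copy()
                neigh[off] = new
                aa = CODON_AA[16 * neigh[0] + 4 * neigh[1] + neigh[2]]
                if aa == UNTRANSLATABLE or aa == src_aa:
                    continue
                prof[p, aa] += mean_load * w[site] * params.substitution_bias[codon[off], new]
    return prof


def simulate_kd_tables(pssm: PSSM, germline: GermlineReference, *, seed: int = 0,
                       n_alleles: int = 38, n_mutations: int = 12,
                       effect: float = 0.15, noise_sd: float = 0.3,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], dict[str, float]]:
    """Paired germline/mutant KD tables with a planted score-fold coupling.

    Plants ``n_mutations`` framework substitutions into the germline,
    windows both sequences into 15-mers, and draws log-normal germline
    KDs per (peptide, allele). Mutant KDs multiply the germline KD by a
    fold whose log scales with the mean PSSM score of the mutations the
    window carries (positive ``effect``: high-scoring mutations weaken
    MHC-II binding). ``effect=0`` gives identical KDs (fold 1).

    Returns (germline table, mutant table, pairing, peptide scores).
    """
    from .epitope_binning import pair_by_position, peptide_scores, window_peptides
    from .fr_score import MutationRecord

    rng = np.random.default_rng(seed)
    fr_pos = germline.fr_positions()
    chosen = rng.choice(fr_pos, size=min(n_mutations, len(fr_pos)), replace=False)
    seq = list(germline.aa_seq)
    mutations = []
    for p in sorted(int(x) for x in chosen):
        gl_aa = germline.aa_seq[p - 1]
        options = [aa for aa in AA_ORDER if aa != gl_aa and not np.isnan(
            pssm.scores[np.nonzero(pssm.positions == p)[0][0], AA_ORDER.index(aa)])]
        aa = options[rng.integers(len(options))]
        seq[p - 1] = aa
        mutations.append(MutationRecord(p, gl_aa, aa, score=pssm.score_of(p, aa)))
    mutant_seq = "".join(seq)
    gl_windows = window_peptides(germline.aa_seq)
    mut_windows = window_peptides(mutant_seq)
    pairing = pair_by_position(mutant_seq, germline.aa_seq)
    scores = peptide_scores(mut_windows, mutations)
    alleles = [f"DRB1*{i + 1:02d}:01" for i in range(n_alleles)]
    gl_rows, mut_rows = [], []
    for (start, gl_pep), (_, mut_pep) in zip(gl_windows, mut_windows, strict=True):
        for allele in alleles:
            kd_gl = float(np.exp(rng.normal(np.log(800.0), 1.0)))
            pep_score = scores.get(mut_pep, 0.0)
            log_fold = effect * pep_score + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            kd_mut = kd_gl * float(np.exp(log_fold)) if mut_pep != gl_pep else kd_gl
            gl_rows.append({"peptide": gl_pep, "allele": allele, "kd_nM": kd_gl})
            mut_rows.append({"peptide": mut_pep, "allele": allele, "kd_nM": kd_mut})
    return pd.DataFrame(gl_rows), pd.DataFrame(mut_rows), pairing, scores
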