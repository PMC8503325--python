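"""Readers and writers for the package's external representations.

Sequence input is nucleotide FASTA or AIRR Rearrangement TSV; germline
references are nucleotide FASTA with region windows supplied in code or
config; PSSMs are stored as a TSV matrix (rows = framework positions,
columns = the 20 amino acids, masked wild-type/allele cells as NA) with a
JSON sidecar for metadata (alpha, germline, sequence count, settings).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seqcodes import AA_ORDER, IUPAC_NT, translate_nt

PSSM_FORMAT_VERSION = 1

REGION_LABELS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")


class SequenceParseError(ValueError):
    """Malformed sequence input (bad alphabet, empty file, bad record)."""


@dataclass(frozen=True)
class GermlineReference:
    """A germline V-heavy reference: nucleotide sequence plus region windows.

    ``region_windows`` maps FR1/CDR1/FR2/CDR2/FR3 to inclusive 1-based
    amino-acid windows that tile the translated sequence exactly once.
    """

    gene_name: str
    allele_name: str
    nt_seq: str
    region_windows: dict[str, tuple[int, int]]
    aa_seq: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        aa = translate_nt(self.nt_seq)
        if self.aa_seq and self.aa_seq != aa:
            raise ValueError("aa_seq is not the translation of nt_seq")
        object.__setattr__(self, "aa_seq", aa)
        covered = np.zeros(len(aa), dtype=int)
        for label, (lo, hi) in self.region_windows.items():
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r}")
            if not (1 <= lo <= hi <= len(aa)):
                raise ValueError(f"window {label} out of range")
            covered[lo - 1 : hi] += 1
        if not (covered == 1).all():
            raise ValueError("region windows must tile every aa position exactly once")

    @property
    def region_mask(self) -> list[str]:
        """Per-position region label, 1-based position p -> mask[p-1]."""
        mask = [""] * len(self.aa_seq)
        for label, (lo, hi) in self.region_windows.items():
            for p in range(lo, hi + 1):
                mask[p - 1] = label
        return mask

    def region_of(self, position: int) -> str:
        return self.region_mask[position - 1]

    def fr_positions(self) -> np.ndarray:
        mask = self.region_mask
        return np.array([p for p in range(1, len(self.aa_seq) + 1) if mask[p - 1].startswith("FR")])

    def codon(self, position: int) -> str:
        return self.nt_seq[3 * (position - 1) : 3 * position]


@dataclass
class RepertoireRecord:
    sequence_id: str
    subject_id: str
    isotype: str
    nt_seq: str
    v_gene: str | None = None
    ambiguous: bool = False


@dataclass
class RepertoireSet:
    """Records assigned to one germline V-heavy gene."""

    germline: GermlineReference
    records: list[RepertoireRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.v_gene is not None and rec.v_gene != self.germline.gene_name:
                raise ValueError(
                    f"record {rec.sequence_id} assigned to {rec.v_gene}, not {self.germline.gene_name}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.nt_seq for r in self.records]


def normalize_v_gene(v_call: str) -> tuple[str, str | None]:
    """Map an AIRR v_call like ``IGHV3-23*01`` to (``VH3-23``, allele).

    The ``IGH`` prefix is replaced by ``H`` after the V (IGHV -> VH), the
    allele suffix is split off for gene-level grouping, and trailing
    annotations after a comma (multiple assignments) use the first call.
    """
    call = v_call.split(",")[0].strip()
    gene, _, allele = call.partition("*")
    if gene.upper().startswith("IGHV"):
        gene = "VH" + gene[4:]
    return gene, (f"{gene}*{allele}" if allele else None)


def _check_nt_alphabet(seq: str, where: str) -> bool:
    """Return True when ambiguity codes are present; raise outside IUPAC."""
    bad = set(seq) - IUPAC_NT
    if bad:
        raise SequenceParseError(f"{where}: non-IUPAC nucleotide characters {sorted(bad)}")
    return bool(set(seq) - set("ACGT"))


def read_sequences(path: str | Path, format: str = "fasta") -> list[RepertoireRecord]:
    """Read repertoire records from FASTA or AIRR rearrangement TSV.

    FASTA ids are used as sequence ids; AIRR columns ``sequence_id`` and
    ``sequence`` are required, ``v_call``/``isotype``/``subject_id`` are
    honoured when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[RepertoireRecord] = []
    if format == "fasta":
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise SequenceParseError(f"{path}: record {i + 1} has an empty header")
            amb = _check_nt_alphabet(seq, f"{path} record {rec.id}")
            records.append(RepertoireRecord(rec.id, "", "", seq, ambiguous=amb))
    elif format == "airr":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        for col in ("sequence_id", "sequence"):
            if col not in df.columns:
                raise SequenceParseError(f"{path}: AIRR input lacks required column {col!r}")
        for row in df.itertuples(index=False):
            seq = str(row.sequence).upper()
            amb = _check_nt_alphabet(seq, f"{path} record {row.sequence_id}")
            v_gene = None
            if "v_call" in df.columns and getattr(row, "v_call", ""):
                v_gene, _ = normalize_v_gene(str(getattr(row, "v_call")))
            records.append(
                RepertoireRecord(
                    sequence_id=str(row.sequence_id),
                    subject_id=str(getattr(row, "subject_id", "") or ""),
                    isotype=str(getattr(row, "isotype", "") or ""),
                    nt_seq=seq,
                    v_gene=v_gene,
                    ambiguous=amb,
                )
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        raise SequenceParseError(f"{path}: no sequence records found")
    return records


def write_fasta(records: Iterable[RepertoireRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.sequence_id}\n{rec.nt_seq}\n")


def write_airr(records: Iterable[RepertoireRecord], path: str | Path, v_call: str | None = None) -> None:
    rows = [
        {
            "sequence_id": r.sequence_id,
            "sequence": r.nt_seq,
            "v_call": v_call or (r.v_gene or ""),
            "subject_id": r.subject_id,
            "isotype": r.isotype,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pssm(pssm, path: str | Path) -> None:
    """Write a PSSM as <path>.tsv + <path>.json sidecar (6-decimal scores)."""
    from .pssm import PSSM  # local import to avoid a cycle

    assert isinstance(pssm, PSSM)
    if len(pssm.positions) < 1:
        raise ValueError("PSSM has no positions")
    base = Path(path)
    tsv = base.with_suffix(".tsv")
    js = base.with_suffix(".json")
    df = pd.DataFrame(pssm.scores, index=pssm.positions, columns=list(AA_ORDER))
    df.index.name = "position"
    df.round(6).to_csv(tsv, sep="\t", na_rep="NA", float_format="%.6f")
    meta = {
        "format_version": PSSM_FORMAT_VERSION,
        "germline": pssm.germline,
        "alpha": pssm.alpha,
        "log_base": pssm.log_base,
        "n_sequences": int(pssm.n_sequences),
        "region_labels": list(pssm.region_labels),
        "pseudocounted": [
            [int(pssm.positions[i]), AA_ORDER[j]]
            for i, j in zip(*np.nonzero(pssm.pseudocounted), strict=True)
        ],
        "settings": dict(pssm.settings),
    }
    js.write_text(json.dumps(meta, indent=1))


def read_pssm(path: str | Path):
    """Read a PSSM written by :func:`write_pssm`; version mismatch raises."""
    from .pssm import PSSM

    base = Path(path)
    meta = json.loads(base.with_suffix(".json").read_text())
    if meta.get("format_version") != PSSM_FORMAT_VERSION:
        raise ValueError(
            f"incompatible PSSM file version {meta.get('format_version')!r}; "
            f"this build reads version {PSSM_FORMAT_VERSION}"
        )
    df = pd.read_csv(base.with_suffix(".tsv"), sep="\t", index_col="position", na_values="NA")
    positions = df.index.to_numpy(dtype=int)
    scores = df[list(AA_ORDER)].to_numpy(dtype=float)
    pseudo = np.zeros_like(scores, dtype=bool)
    pos_index = {p: i for i, p in enumerate(positions)}
    for p, aa in meta.get("pseudocounted", []):
        pseudo[pos_index[int(p)], AA_ORDER.index(aa)] = True
    return PSSM(
        germline=meta["germline"],
        positions=positions,
        scores=scores,
        alpha=float(meta["alpha"]),
        log_base=float(meta["log_base"]),
        n_sequences=int(meta["n_sequences"]),
        region_labels=list(meta["region_labels"]),
        pseudocounted=pseudo,
        settings=meta.get("settings", {}),
    )


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write an FR-score report table as TSV."""
    report.to_csv(path, sep="\t", index=False)


def read_kd_table(path: str | Path) -> pd.DataFrame:
    """Read a peptide:MHC-II KD table (TSV: peptide, allele, kd_nM)."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "kd_nM"}
    missing = required - set(df.columns)
    if missing:
        raise SequenceParseError(f"{path}: KD table lacks columns {sorted(missing)}")
    if (df["kd_nM"] <= 0).any() or df["kd_nM"].isna().any():
        raise ValueError("kd_nM values must be positive")
    if (df["peptide"].str.len() != 15).any():
        raise ValueError("peptides must be 15-mers")
    return df


def write_kd_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
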