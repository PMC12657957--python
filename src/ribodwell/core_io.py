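"""Domain types and file I/O for codon-resolved ribosome profiling data.

Conventions used throughout the package:

* positions are 0-based codon indices; windows are half-open unless a
  function documents an inclusive range (the significance window does);
* a missing count (un-annotated position) is ``NaN`` in memory and the
  literal ``NA`` in TSV files — never conflated with an observed zero;
* the condition vocabulary is closed: the replete control plus five
  branched-chain amino-acid deprivations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("ribodwell")

# ---------------------------------------------------------------------------
# vocabularies

NUCLEOTIDES = "ACGT"
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

LEU_CODONS = frozenset({"TTA", "TTG", "CTT", "CTC", "CTA", "CTG"})
ILE_CODONS = frozenset({"ATT", "ATC", "ATA"})
VAL_CODONS = frozenset({"GTT", "GTC", "GTA", "GTG"})

CONDITIONS: tuple[str, ...] = ("CTRL", "LEU", "ILE", "VAL", "LEU_ILE", "LEU_ILE_VAL")
CONDITION_INDEX: dict[str, int] = {c: i for i, c in enumerate(CONDITIONS)}

DEPRIVED_CODONS: dict[str, frozenset] = {
    "CTRL": frozenset(),
    "LEU": LEU_CODONS,
    "ILE": ILE_CODONS,
    "VAL": VAL_CODONS,
    "LEU_ILE": LEU_CODONS | ILE_CODONS,
    "LEU_ILE_VAL": LEU_CODONS | ILE_CODONS | VAL_CODONS,
}

MISSING = float("nan")


class CdsParseError(ValueError):
    pass


class ProfileParseError(ValueError):
    pass


class CheckpointError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CodonSequence:
    """An in-frame coding sequence as an ordered run of codon tokens."""

    gene_id: str
    codons: tuple[str, ...]

    def __post_init__(self):
        if len(self.codons) < 1:
            raise CdsParseError(f"{self.gene_id}: empty coding sequence")
        for c in self.codons:
            if len(c) != 3 or any(ch not in NUCLEOTIDES for ch in c):
                raise CdsParseError(f"{self.gene_id}: invalid codon token {c!r}")

    @property
    def n(self) -> int:
        return len(self.codons)

    def token_ids(self) -> np.ndarray:
        return np.array([CODON_INDEX[c] for c in self.codons], dtype=np.int64)


def annotated(p: np.ndarray) -> np.ndarray:
    """Boolean mask of annotated (non-missing) positions of a profile."""
    return ~np.isnan(p)


def _as_profile(values, n: int, what: str) -> np.ndarray:
    p = np.asarray(values, dtype=float)
    if p.shape != (n,):
        raise ValueError(f"{what}: profile length {p.shape} != sequence length {n}")
    if np.any(p[annotated(p)] < 0):
        raise ValueError(f"{what}: negative counts in profile")
    return p


@dataclass
class Sample:
    """One gene in one condition, with paired control and condition profiles.

    ``y_delta`` is derived: the position-wise difference between the
    deprivation-condition profile and the control profile, missing wherever
    either parent is missing.
    """

    seq: CodonSequence
    cond: str
    y_ctrl: np.ndarray
    y_dc: np.ndarray
    replicate: str | None = None
    y_delta: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.cond not in CONDITION_INDEX:
            raise ProfileParseError(f"unknown condition {self.cond!r}")
        self.y_ctrl = _as_profile(self.y_ctrl, self.seq.n, self.seq.gene_id)
        self.y_dc = _as_profile(self.y_dc, self.seq.n, self.seq.gene_id)
        if self.cond == "CTRL":
            both = annotated(self.y_ctrl) & annotated(self.y_dc)
            if not np.array_equal(self.y_ctrl[both], self.y_dc[both]):
                raise ValueError(
                    f"{self.seq.gene_id}: control sample with y_dc != y_ctrl"
                )
        self.refresh_delta()

    def refresh_delta(self):
        delta = self.y_dc - self.y_ctrl  # NaN propagates
        self.y_delta = delta

    @property
    def gene_id(self) -> str:
        return self.seq.gene_id

    def key(self) -> tuple[str, str]:
        return (self.seq.gene_id, self.cond)


@dataclass
class Dataset:
    samples: list[Sample]
    split: dict[tuple[str, str], str] = field(default_factory=dict)
    interp_keys: set = field(default_factory=set)

    def split_of(self, sample: Sample) -> str:
        return self.split.get(sample.key(), "unassigned")

    def subset(self, tag: str) -> list[Sample]:
        return [s for s in self.samples if self.split_of(s) == tag]

    def validate_splits(self):
        seen: dict[str, str] = {}
        for (gene, _), tag in self.split.items():
            if tag in ("train", "val", "test"):
                if gene in seen and seen[gene] != tag:
                    raise ValueError(f"gene {gene} assigned to {seen[gene]} and {tag}")
                seen[gene] = tag


# ---------------------------------------------------------------------------
# sequence and profile I/O


def read_cds_fasta(path) -> list[CodonSequence]:
    """Read in-frame coding sequences from a FASTA file.

    Record identifiers are taken from the header up to the first whitespace.
    A record whose length is not a multiple of three, or that contains a
    non-ACGT character, is rejected with an error naming the record.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if len(s) % 3 != 0:
            raise CdsParseError(
                f"{rec.id}: length {len(s)} not divisible by 3"
            )
        codons = tuple(s[i : i + 3] for i in range(0, len(s), 3))
        try:
            out.append(CodonSequence(rec.id, codons))
        except CdsParseError as e:
            raise CdsParseError(str(e)) from None
    return out


def write_cds_fasta(seqs, path):
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.gene_id}\n{''.join(s.codons)}\n")


PROFILE_COLUMNS = ["gene_id", "condition", "replicate", "position", "count"]


def read_profiles(path, seqs) -> list[Sample]:
    """Read per-replicate footprint profiles from TSV.

    Rows carry (gene_id, condition, replicate, position, count) with 0-based
    codon positions and ``NA`` for missing counts.  Rows are grouped by
    (gene, condition, replicate); unlisted positions are missing.  At this
    stage each record's counts populate ``y_dc`` (for control records also
    ``y_ctrl``); pairing of deprivation profiles with the gene's merged
    control profile happens during preprocessing.
    """
    by_id = {s.gene_id: s for s in seqs}
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "replicate": str})
    missing_cols = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ProfileParseError(f"profile file missing columns {missing_cols}")
    out = []
    skipped = set()
    for (gene, cond, rep), grp in df.groupby(
        ["gene_id", "condition", "replicate"], sort=True
    ):
        if cond not in CONDITION_INDEX:
            raise ProfileParseError(f"{gene}: unknown condition {cond!r}")
        if gene not in by_id:
            if gene not in skipped:
                logger.warning("gene %s has profiles but no sequence; skipped", gene)
                skipped.add(gene)
            continue
        seq = by_id[gene]
        vals = np.full(seq.n, np.nan)
        pos = grp["position"].to_numpy(dtype=int)
        if pos.size and (pos.min() < 0 or pos.max() >= seq.n):
            raise ProfileParseError(
                f"{gene}: position out of range for {seq.n}-codon gene"
            )
        vals[pos] = grp["count"].to_numpy(dtype=float)
        if cond == "CTRL":
            out.append(Sample(seq, cond, vals.copy(), vals, replicate=str(rep)))
        else:
            out.append(
                Sample(seq, cond, np.full(seq.n, np.nan), vals, replicate=str(rep))
            )
    return out


def write_profiles(samples, path):
    """Serialize samples' condition profiles back to the TSV dialect."""
    rows = []
    for s in samples:
        rep = s.replicate if s.replicate is not None else "merged"
        for i, v in enumerate(s.y_dc):
            rows.append(
                (s.gene_id, s.cond, rep, i, "NA" if np.isnan(v) else repr(float(v)))
            )
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# checkpoints


def write_checkpoint(params: dict, config: dict, path):
    """Save model parameters (npz) plus a JSON sidecar with the full config.

    The sidecar records the seed, the architecture, and both vocabularies so
    that a load into a differently configured process fails loudly.
    """
    path = Path(path)
    arrays = {k: np.asarray(v.data if hasattr(v, "data") else v) for k, v in params.items()}
    np.savez(path.with_suffix(".npz"), **arrays)
    side = dict(config)
    side["codon_vocab"] = list(CODONS)
    side["condition_vocab"] = list(CONDITIONS)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(side, fh, indent=1, sort_keys=True)


def read_checkpoint(path) -> tuple[dict, dict]:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        config = json.load(fh)
    for required in ("seed", "codon_vocab", "condition_vocab"):
        if required not in config:
            raise CheckpointError(f"checkpoint config missing field {required!r}")
    if tuple(config.pop("codon_vocab")) != CODONS:
        raise CheckpointError("checkpoint config mismatch: codon_vocab")
    if tuple(config.pop("condition_vocab")) != CONDITIONS:
        raise CheckpointError("checkpoint config mismatch: condition_vocab")
    with np.load(path.with_suffix(".npz")) as npz:
        params = {k: npz[k].copy() for k in npz.files}
    return params, config
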