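"""Replicate merging, normalization, quality filters, and dataset splitting.

Pipeline order (see ``preprocess_dataset``):

1. replicate profiles for each (gene, condition) are depth-scaled and merged;
2. merged profiles are normalized against the gene's average count and
   log(x + 1) transformed;
3. deprivation profiles are paired with the gene's merged control profile;
4. three quality filters drop low-quality samples (long zero runs, excessive
   length, low coverage);
5. genes are sorted by coverage and walked into train/val/test so the well
   annotated genes populate the held-out sets;
6. a per-sample likelihood-ratio test flags deprivation-responsive samples
   for the interpretability set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core_io import DEPRIVED_CODONS, CodonSequence, Dataset, Sample, annotated

logger = logging.getLogger("ribodwell")


@dataclass
class PreprocessConfig:
    max_zero_run: int = 20  # codons; longer observed-zero runs reject the sample
    max_len: int = 2000  # codons
    min_coverage: float = 0.30  # strictly-greater-than threshold
    val_frac: float = 0.05
    test_frac: float = 0.20
    lrt_alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.min_coverage < 1.0:
            raise ValueError("min_coverage must be in (0, 1)")
        if self.val_frac + self.test_frac >= 1.0:
            raise ValueError("val_frac + test_frac must be < 1")


# ---------------------------------------------------------------------------
# per-profile operations


def merge_replicates(profiles: list[np.ndarray]) -> np.ndarray:
    """Depth-scale each replicate (divide by its mean over annotated
    positions) and average the replicates position-wise over non-missing
    values.  Missing only where every replicate is missing."""
    scaled = []
    for i, p in enumerate(profiles):
        p = np.asarray(p, dtype=float)
        ann = annotated(p)
        if not ann.any() or p[ann].mean() == 0.0:
            logger.warning("replicate %d has no usable counts; dropped", i)
            continue
        scaled.append(p / p[ann].mean())
    if not scaled:
        raise ValueError("no usable replicates")
    stack = np.stack(scaled)
    counts = (~np.isnan(stack)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        merged = np.nansum(stack, axis=0) / counts
    merged[counts == 0] = np.nan
    return merged


def normalize_profile(p: np.ndarray) -> np.ndarray:
    """log(x / mean + 1) with the mean taken over annotated positions."""
    p = np.asarray(p, dtype=float)
    ann = annotated(p)
    if not ann.any():
        raise ValueError("all-missing profile")
    m = p[ann].mean()
    if m == 0.0:
        raise ValueError("all annotated counts are zero")
    out = np.full_like(p, np.nan)
    out[ann] = np.log(p[ann] / m + 1.0)
    return out


def compute_coverage(p: np.ndarray) -> float:
    """Fraction of annotated positions with non-zero counts."""
    p = np.asarray(p, dtype=float)
    ann = annotated(p)
    if not ann.any():
        raise ValueError("all-missing profile")
    return float((p[ann] != 0).sum() / ann.sum())


def longest_zero_run(p: np.ndarray) -> int:
    """Longest run of consecutive annotated zero values; missing breaks runs."""
    run = best = 0
    for v in np.asarray(p, dtype=float):
        if v == 0.0:
            run += 1
            best = max(best, run)
        else:  # non-zero or NaN both break the run
            run = 0
    return best


def filter_gene(sample: Sample, cfg: PreprocessConfig):
    """Apply the three quality filters to the sample's condition profile.

    Returns (keep, reason); the reason names the first failing rule in the
    fixed order zero-run, length, coverage.
    """
    if longest_zero_run(sample.y_dc) > cfg.max_zero_run:
        return False, "zero-run"
    if sample.seq.n > cfg.max_len:
        return False, "length"
    if compute_coverage(sample.y_dc) <= cfg.min_coverage:
        return False, "coverage"
    return True, None


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    gene_coverage: dict[str, float], gene_n_samples: dict[str, int], cfg: PreprocessConfig
) -> dict[str, str]:
    """Coverage-sorted alternating walk into train/val/test.

    Genes are sorted by coverage descending (ties by gene_id ascending) and
    assigned in the repeating order train, val, test; once the val (resp.
    test) set holds its sample quota — ``val_frac`` (resp. ``test_frac``) of
    the pre-split sample count — that slot is skipped and the remainder goes
    to train.  All samples of a gene share its split.
    """
    total = sum(gene_n_samples.values())
    quota = {"val": cfg.val_frac * total, "test": cfg.test_frac * total}
    counts = {"train": 0, "val": 0, "test": 0}
    order = ("train", "val", "test")
    genes = sorted(gene_coverage, key=lambda g: (-gene_coverage[g], g))
    out = {}
    c = 0
    for g in genes:
        tag = order[c % 3]
        while tag != "train" and counts[tag] >= quota[tag]:
            c += 1
            tag = order[c % 3]
        out[g] = tag
        counts[tag] += gene_n_samples[g]
        c += 1
    for tag in ("val", "test"):
        if counts[tag] < quota[tag] - max(gene_n_samples.values(), default=0):
            logger.warning("%s quota left short: %d of %.1f", tag, counts[tag], quota[tag])
    return out


# ---------------------------------------------------------------------------
# deprivation response test


def deprivation_lrt(sample: Sample) -> tuple[float, float]:
    """Likelihood-ratio test for a deprivation-specific codon response.

    Gaussian working likelihood on the annotated deprivation-difference
    profile.  Null: one common mean; alternative: separate means for
    positions whose A-site codon encodes a deprived amino acid vs. the rest
    (shared variance, maximum-likelihood estimates).  The statistic
    2*(loglik_alt - loglik_null) = n*log(var_null/var_alt) is referred to a
    chi-square with one degree of freedom.
    """
    if sample.cond == "CTRL":
        raise ValueError("LRT requires a deprivation-condition sample")
    deprived = DEPRIVED_CODONS[sample.cond]
    is_dep = np.array([c in deprived for c in sample.seq.codons])
    ann = annotated(sample.y_delta)
    x = sample.y_delta[ann]
    g = is_dep[ann]
    if g.sum() < 3 or (~g).sum() < 3:
        raise ValueError("need >= 3 annotated positions in each codon group")
    n = x.size
    var0 = np.mean((x - x.mean()) ** 2)
    resid = x.copy()
    resid[g] -= x[g].mean()
    resid[~g] -= x[~g].mean()
    var1 = np.mean(resid**2)
    if var0 == var1:
        return 0.0, 1.0
    if var1 == 0.0:
        return float("inf"), 0.0
    stat = max(0.0, n * np.log(var0 / var1))
    return float(stat), float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# pipeline


def preprocess_dataset(
    seqs: list[CodonSequence], replicate_samples: list[Sample], cfg: PreprocessConfig
):
    """Full preprocessing: merge, normalize, pair, filter, split, LRT.

    Returns (Dataset, filter_report, split_manifest) where the reports are
    pandas DataFrames matching the TSV outputs of the command-line tool.
    """
    by_id = {s.gene_id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise ValueError("duplicate gene_ids; reduce to one transcript per gene upstream")

    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for s in replicate_samples:
        groups.setdefault(s.key(), []).append(s.y_dc)

    merged_norm: dict[tuple[str, str], np.ndarray] = {}
    for key, reps in groups.items():
        merged_norm[key] = normalize_profile(merge_replicates(reps))

    samples: list[Sample] = []
    for (gene, cond), prof in sorted(merged_norm.items()):
        if cond == "CTRL":
            samples.append(Sample(by_id[gene], "CTRL", prof, prof.copy()))
            continue
        ctrl = merged_norm.get((gene, "CTRL"))
        if ctrl is None:
            logger.warning("gene %s lacks a control profile; skipped", gene)
            continue
        samples.append(Sample(by_id[gene], cond, ctrl, prof))

    report_rows = []
    kept: list[Sample] = []
    rejected_length: list[Sample] = []
    for s in samples:
        keep, reason = filter_gene(s, cfg)
        report_rows.append((s.gene_id, s.cond, "keep" if keep else "reject", reason or ""))
        if keep:
            kept.append(s)
        elif reason == "length":
            rejected_length.append(s)
    filter_report = pd.DataFrame(
        report_rows, columns=["gene_id", "condition", "decision", "reason"]
    )

    gene_cov: dict[str, float] = {}
    gene_n: dict[str, int] = {}
    for s in kept:
        cov = compute_coverage(s.y_dc)
        gene_cov[s.gene_id] = max(gene_cov.get(s.gene_id, 0.0), cov)
        gene_n[s.gene_id] = gene_n.get(s.gene_id, 0) + 1
    gene_split = split_dataset(gene_cov, gene_n, cfg)

    ds = Dataset(samples=kept)
    for s in kept:
        ds.split[s.key()] = gene_split[s.gene_id]
    ds.validate_splits()

    # interpretability set: length-rejected samples plus deprivation-responsive ones
    interp_keys = {s.key() for s in rejected_length}
    for s in kept:
        if s.cond == "CTRL":
            continue
        try:
            _, p = deprivation_lrt(s)
        except ValueError:
            continue
        if p <= cfg.lrt_alpha:
            interp_keys.add(s.key())
    ds.interp_keys = interp_keys  # extra set; train/val/test membership unchanged

    manifest = pd.DataFrame(
        sorted((g, gene_split[g], gene_cov[g]) for g in gene_split),
        columns=["gene_id", "split", "coverage"],
    )
    return ds, filter_report, manifest


# ---------------------------------------------------------------------------
# processed-directory round trip (the on-disk form of a Dataset)


def save_processed(ds: Dataset, filter_report: pd.DataFrame, manifest: pd.DataFrame, out_dir):
    """Write merged+normalized profiles, the split manifest and filter report."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in ds.samples:
        for i, v in enumerate(s.y_dc):
            rows.append(
                (s.gene_id, s.cond, "merged", i, "NA" if np.isnan(v) else repr(float(v)))
            )
    pd.DataFrame(
        rows, columns=["gene_id", "condition", "replicate", "position", "count"]
    ).to_csv(out_dir / "profiles.tsv", sep="\t", index=False)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    filter_report.to_csv(out_dir / "filter_report.tsv", sep="\t", index=False)


def load_processed(proc_dir, seqs: list[CodonSequence]) -> Dataset:
    """Rebuild a Dataset from a processed directory (no re-normalization)."""
    from pathlib import Path

    from .core_io import read_profiles

    proc_dir = Path(proc_dir)
    recs = read_profiles(proc_dir / "profiles.tsv", seqs)
    by_id = {s.gene_id: s for s in seqs}
    prof = {(r.gene_id, r.cond): r.y_dc for r in recs}
    samples = []
    for (gene, cond), p in sorted(prof.items()):
        if cond == "CTRL":
            samples.append(Sample(by_id[gene], "CTRL", p, p.copy()))
        elif (gene, "CTRL") in prof:
            samples.append(Sample(by_id[gene], cond, prof[(gene, "CTRL")], p))
    manifest = pd.read_csv(proc_dir / "manifest.tsv", sep="\t")
    gene_split = dict(zip(manifest["gene_id"], manifest["split"]))
    ds = Dataset(samples=samples)
    for s in samples:
        if s.gene_id in gene_split:
            ds.split[s.key()] = gene_split[s.gene_id]
    ds.validate_splits()
    return ds
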