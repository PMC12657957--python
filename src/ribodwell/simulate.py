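"""Synthetic ribosome-profiling generator with planted, recoverable truth.

The generator emulates the data model the rest of the package consumes:
per-gene footprint profiles whose expected (log) intensity at a position is
a sum of the A-site codon's base dwell, context-kernel contributions from
neighboring codons, end-region technical bias, and — under an amino-acid
deprivation — an added stalling effect on the deprived codons.  Observed
replicate counts are the exponentiated intensity scaled by a per-replicate
library depth and multiplicative lognormal noise, with geometric runs of
missing values.

Offset convention: an effect of codon ``c`` at offset ``o`` means a copy of
``c`` located ``o`` codons from the A-site (negative = upstream) changes the
expected count *at the A-site*.

All randomness flows through one ``numpy.random.Generator``; the draw order
is: per-codon base dwells and end-bias loadings, then gene sequences, then
per gene x condition x replicate noise and missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    CONDITIONS,
    DEPRIVED_CODONS,
    SENSE_CODONS,
    CodonSequence,
    Sample,
    write_cds_fasta,
)


def default_condition_effects() -> dict:
    """Planted stalling effects, in added log-dwell at the A-site.

    Valine deprivation is the strongest (1.0), isoleucine intermediate (0.8,
    with an extra upstream effect at offset -4 to give the search a
    long-range determinant), leucine mildest (0.3); combined deprivations
    take the union of their parts.
    """
    eff: dict[str, dict[str, dict[int, float]]] = {c: {} for c in CONDITIONS}
    for c in DEPRIVED_CODONS["VAL"]:
        eff["VAL"][c] = {0: 1.0}
    for c in DEPRIVED_CODONS["ILE"]:
        eff["ILE"][c] = {0: 0.8, -4: 0.4}
    for c in DEPRIVED_CODONS["LEU"]:
        eff["LEU"][c] = {0: 0.3}
    for src in ("LEU", "ILE"):
        for c, d in eff[src].items():
            eff["LEU_ILE"][c] = dict(d)
    for src in ("LEU", "ILE", "VAL"):
        for c, d in eff[src].items():
            eff["LEU_ILE_VAL"][c] = dict(d)
    return eff


def default_context_kernel() -> dict:
    """Mild condition-independent context effects (poly-basic / acidic flavor)."""
    return {"AAA": {-1: 0.4}, "GAA": {-2: 0.3}}


@dataclass
class SimulationConfig:
    n_genes: int = 200
    length_range: tuple[int, int] = (150, 400)
    codon_usage: dict[str, float] | None = None  # None = uniform over sense codons
    base_dwell_sd: float = 0.5  # per-codon base log-dwells drawn N(0, sd)
    context_kernel: dict = field(default_factory=default_context_kernel)
    condition_effects: dict = field(default_factory=default_condition_effects)
    noise_sd: float = 0.3  # lognormal sigma of multiplicative noise
    missing_rate: float = 0.08  # probability a missing run starts at a position
    missing_run_p: float = 0.5  # geometric success prob; mean run = 1/p
    end_bias_amp: tuple[float, float] = (0.15, 0.15)  # at offsets -5 and +3
    n_replicates: int = 2
    depth: float = 50.0  # mean library-depth scale of a replicate
    depth_sd: float = 0.3  # lognormal sigma of the per-replicate depth
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if self.length_range[0] < 30:
            raise ValueError("minimum gene length is 30 codons")


END_BIAS_OFFSETS = (-5, 3)


class Simulator:
    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        rng = self.rng
        self.base_dwell = {
            c: float(rng.normal(0.0, cfg.base_dwell_sd)) for c in SENSE_CODONS
        }
        self.end_bias_loading = [
            {c: float(rng.normal(0.0, 1.0)) for c in SENSE_CODONS}
            for _ in END_BIAS_OFFSETS
        ]

    # -- sequences -----------------------------------------------------------

    def generate_gene(self, gene_id: str) -> CodonSequence:
        """Random in-frame CDS: starts ATG, no internal stops."""
        cfg = self.cfg
        lo, hi = cfg.length_range
        n = int(self.rng.integers(lo, hi + 1))
        if cfg.codon_usage is None:
            weights = np.ones(len(SENSE_CODONS))
        else:
            weights = np.array([cfg.codon_usage.get(c, 0.0) for c in SENSE_CODONS])
        weights = weights / weights.sum()
        body = self.rng.choice(len(SENSE_CODONS), size=n - 1, p=weights)
        codons = ("ATG",) + tuple(SENSE_CODONS[i] for i in body)
        return CodonSequence(gene_id, codons)

    # -- expected intensities --------------------------------------------------

    @staticmethod
    def _add_offset_effect(out: np.ndarray, codon_pos: np.ndarray, offset: int, eff: float):
        """A codon at position j contributes `eff` to the A-site at j - offset."""
        i = codon_pos - offset
        i = i[(i >= 0) & (i < out.size)]
        out[i] += eff

    def expected_log_profile(self, seq: CodonSequence, cond: str) -> np.ndarray:
        """Noise-free expected log intensity per position (the ground truth)."""
        cfg = self.cfg
        codons = np.array(seq.codons)
        out = np.array([self.base_dwell.get(c, 0.0) for c in seq.codons])
        occurrences = {c: np.nonzero(codons == c)[0] for c in set(seq.codons)}
        for codon_map in (cfg.context_kernel, cfg.condition_effects.get(cond, {})):
            for c, offsets in codon_map.items():
                pos = occurrences.get(c)
                if pos is None or pos.size == 0:
                    continue
                for o, e in offsets.items():
                    self._add_offset_effect(out, pos, o, e)
        for amp_idx, o in enumerate(END_BIAS_OFFSETS):
            amp = cfg.end_bias_amp[amp_idx]
            loading = self.end_bias_loading[amp_idx]
            if amp == 0.0:
                continue
            for c, pos in occurrences.items():
                w = loading.get(c, 0.0)
                if w != 0.0:
                    self._add_offset_effect(out, pos, o, amp * w)
        return out

    # -- observed replicates -----------------------------------------------------

    def simulate_replicate(
        self, seq: CodonSequence, cond: str, expected: np.ndarray | None = None
    ) -> np.ndarray:
        cfg = self.cfg
        rng = self.rng
        if expected is None:
            expected = np.exp(self.expected_log_profile(seq, cond))
        # mean-one lognormals: observed counts are unbiased for the expectation
        depth = (
            cfg.depth * rng.lognormal(-0.5 * cfg.depth_sd**2, cfg.depth_sd)
            if cfg.depth_sd > 0
            else cfg.depth
        )
        noise = (
            rng.lognormal(-0.5 * cfg.noise_sd**2, cfg.noise_sd, size=seq.n)
            if cfg.noise_sd > 0
            else 1.0
        )
        vals = expected * depth * noise
        if cfg.missing_rate > 0:
            i = 0
            while i < seq.n:
                if rng.random() < cfg.missing_rate:
                    run = int(rng.geometric(cfg.missing_run_p))
                    vals[i : i + run] = np.nan
                    i += run
                else:
                    i += 1
        return vals

    def simulate_gene_records(self, seq: CodonSequence) -> list[tuple]:
        """Replicate-level records (gene, condition, replicate, values) for all
        six conditions — the raw exchange-format content."""
        rows = []
        for cond in CONDITIONS:
            expected = np.exp(self.expected_log_profile(seq, cond))
            for r in range(self.cfg.n_replicates):
                rows.append(
                    (seq.gene_id, cond, f"r{r + 1}", self.simulate_replicate(seq, cond, expected))
                )
        return rows


def simulate_dataset(cfg: SimulationConfig):
    """Generate sequences plus replicate profile records for all conditions."""
    sim = Simulator(cfg)
    seqs = [sim.generate_gene(f"g{i:04d}") for i in range(cfg.n_genes)]
    records = []
    for seq in seqs:
        records.extend(sim.simulate_gene_records(seq))
    return seqs, records, sim


def records_to_samples(seqs, records) -> list[Sample]:
    """Adapt raw records to per-replicate Samples (as the profile reader does)."""
    by_id = {s.gene_id: s for s in seqs}
    out = []
    for gene, cond, rep, vals in records:
        seq = by_id[gene]
        if cond == "CTRL":
            out.append(Sample(seq, cond, vals.copy(), vals, replicate=rep))
        else:
            out.append(Sample(seq, cond, np.full(seq.n, np.nan), vals, replicate=rep))
    return out


def ground_truth(cfg: SimulationConfig) -> dict:
    """Planted stalling table: per condition the deprived codons, the planted
    effect sizes, and any non-zero planted offsets."""
    truth = {}
    for cond in CONDITIONS:
        eff = cfg.condition_effects.get(cond, {})
        offsets = sorted({o for d in eff.values() for o in d})
        truth[cond] = {
            "deprived_codons": sorted(DEPRIVED_CODONS[cond]),
            "effects": {c: dict(sorted(d.items())) for c, d in sorted(eff.items())},
            "offsets": offsets,
        }
    return truth


def write_simulation(cfg: SimulationConfig, out_dir):
    """Materialize the fixture: FASTA + profile TSV + ground-truth table."""
    import json
    from pathlib import Path

    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs, records, _ = simulate_dataset(cfg)
    write_cds_fasta(seqs, out_dir / "cds.fasta")
    rows = []
    for gene, cond, rep, vals in records:
        for i, v in enumerate(vals):
            rows.append((gene, cond, rep, i, "NA" if np.isnan(v) else repr(float(v))))
    pd.DataFrame(
        rows, columns=["gene_id", "condition", "replicate", "position", "count"]
    ).to_csv(out_dir / "profiles.tsv", sep="\t", index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth(cfg), fh, indent=1)
    return out_dir
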