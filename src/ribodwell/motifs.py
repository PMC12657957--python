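"""Counterfactual codon-motif extraction by beam search, and enrichment tests.

Starting from "fast" windows — 21-codon significance windows whose A-site
sits in a trough of the (difference) profile — the search mutates codons in
silico and keeps the substitutions that most increase the predicted count at
the A-site, measured on an arctangent percentage scale robust to near-zero
baselines.  A width-w beam explores motifs of one, two and three mutations
(w + w^2 + w^3 motifs per window; 155 at the default width 5).  Motifs are
written as [SKIP]-gapped codon strings anchored at their smallest relative
position, and validated by Fisher exact enrichment inside peak significance
windows with Benjamini-Hochberg control across motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .attribute import SW_HALF_WIDTH, find_troughs, find_peaks, significance_window, stall_profile
from .core_io import CODON_INDEX, CODONS, SENSE_CODONS, Sample
from .model import MAAPE_EPS, DwellModel

logger = logging.getLogger("ribodwell")

SENSE_IDS = np.array([CODON_INDEX[c] for c in SENSE_CODONS])


@dataclass
class MutationWindow:
    gene_id: str
    cond: str
    tokens: np.ndarray  # codon token ids, length <= 21
    a_site_offset: int  # 10 when untruncated
    a_site: int  # absolute codon position of the A-site in the CDS
    baseline: float  # model prediction at the A-site, relevant head
    head: str  # "ctrl" or "delta"

    @property
    def width(self) -> int:
        return int(self.tokens.size)


@dataclass(frozen=True)
class Motif:
    mutations: tuple  # ((rel_pos, codon), ...), sorted by position
    score: float  # signed arctan percentage increase vs. the unmutated window
    gene_id: str = ""
    cond: str = ""
    a_site: int = -1

    @property
    def size(self) -> int:
        return len(self.mutations)

    @property
    def canonical(self) -> str:
        return canonicalize_motif(self.mutations)[0]

    @property
    def anchor(self) -> int:
        return self.mutations[0][0]


def canonicalize_motif(mutations) -> tuple[str, int]:
    """[SKIP]-gapped canonical string plus the anchor (smallest position)."""
    muts = sorted(mutations)
    positions = [p for p, _ in muts]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate positions in motif")
    parts = [muts[0][1]]
    for (p_prev, _), (p, c) in zip(muts, muts[1:]):
        parts.extend(["[SKIP]"] * (p - p_prev - 1))
        parts.append(c)
    return " ".join(parts), positions[0]


def parse_motif(canonical: str, anchor: int) -> tuple:
    """Inverse of canonicalize_motif."""
    out = []
    pos = anchor
    for tok in canonical.split(" "):
        if tok != "[SKIP]":
            out.append((pos, tok))
        pos += 1
    return tuple(out)


# ---------------------------------------------------------------------------
# window selection and scoring


def _window_prediction(model: DwellModel, tokens: np.ndarray, cond: str, head: str, a_off: int):
    yc, yd = model.predict_tokens(tokens[None, :], cond)
    return float((yc if head == "ctrl" else yd)[0, a_off])


def select_fast_windows(
    samples: list[Sample], model: DwellModel, per_condition: int, seed: int = 0
) -> list[MutationWindow]:
    """Uniform seeded sample of trough-centred windows for each condition.

    If a condition has fewer qualifying (gene, position) pairs than
    requested, all of them are returned with a warning.
    """
    rng = np.random.default_rng(seed)
    by_cond: dict[str, list] = {}
    for si, s in enumerate(samples):
        for a in find_troughs(stall_profile(s)):
            by_cond.setdefault(s.cond, []).append((si, int(a)))
    out: list[MutationWindow] = []
    for cond in sorted(by_cond):
        pool = by_cond[cond]
        if per_condition <= 0:
            continue
        if len(pool) < per_condition:
            logger.warning(
                "%s: only %d qualifying windows (requested %d)", cond, len(pool), per_condition
            )
            chosen = list(range(len(pool)))
        else:
            chosen = sorted(rng.choice(len(pool), size=per_condition, replace=False))
        for i in chosen:
            si, a = pool[i]
            out.append(make_window(samples[si], a, model))
    return out


def make_window(sample: Sample, a_site: int, model: DwellModel) -> MutationWindow:
    w = significance_window(a_site, sample.seq.n)
    tokens = sample.seq.token_ids()[w]
    a_off = a_site - int(w[0])
    head = "ctrl" if sample.cond == "CTRL" else "delta"
    baseline = _window_prediction(model, tokens, sample.cond, head, a_off)
    return MutationWindow(sample.gene_id, sample.cond, tokens, a_off, a_site, baseline, head)


def mutation_score(y_orig: float, y_mut: float, eps: float = MAAPE_EPS) -> float:
    """Signed arctangent percentage change of the A-site prediction.

    s = sign(y_mut - y_orig) * 100 * arctan(|y_mut - y_orig| / max(|y_orig|, eps));
    only s > 0 counts as a stalling increase.
    """
    d = y_mut - y_orig
    return float(np.sign(d) * 100.0 * np.arctan(abs(d) / max(abs(y_orig), eps)))


# ---------------------------------------------------------------------------
# beam search


def _candidate_scores(
    model: DwellModel, window: MutationWindow, base_tokens: np.ndarray, frozen: set, chunk: int = 2048
):
    """Score every single substitution (sense codons, excluding the current
    codon and frozen positions) of base_tokens; returns (pos, codon, score)."""
    L = base_tokens.size
    cand_tokens, cand_meta = [], []
    for p in range(L):
        if p in frozen:
            continue
        cur = base_tokens[p]
        for cid in SENSE_IDS:
            if cid == cur:
                continue
            t = base_tokens.copy()
            t[p] = cid
            cand_tokens.append(t)
            cand_meta.append((p, CODONS[cid]))
    if not cand_tokens:
        return []
    stacked = np.stack(cand_tokens)
    vals = np.empty(stacked.shape[0])
    for lo in range(0, stacked.shape[0], chunk):
        yc, yd = model.predict_tokens(stacked[lo : lo + chunk], window.cond)
        vals[lo : lo + chunk] = (yc if window.head == "ctrl" else yd)[:, window.a_site_offset]
    return [
        (p, c, mutation_score(window.baseline, float(v)))
        for (p, c), v in zip(cand_meta, vals)
    ]


def beam_search_motifs(
    window: MutationWindow, model: DwellModel, width: int = 5, max_size: int = 3
) -> list[Motif]:
    """Beam search over codon substitutions in the window.

    Level 1 keeps the `width` best single substitutions; each next level
    freezes a beam member's mutations and extends it with the `width` best
    remaining single substitutions.  All levels are returned:
    width + width^2 + ... motifs.  Ties break deterministically on higher
    score, then smaller relative position, then codon lexicographic order.
    """
    a_off = window.a_site_offset

    def top(cands, base_muts):
        key = lambda t: (-t[2], t[0] - a_off, t[1])
        out = []
        for p, c, s in sorted(cands, key=key)[:width]:
            muts = tuple(sorted(base_muts + ((p - a_off, c),)))
            out.append((Motif(muts, s, window.gene_id, window.cond, window.a_site), p, c))
        return out

    results: list[Motif] = []
    beam = [(Motif((), 0.0), window.tokens, frozenset())]
    for _level in range(max_size):
        next_beam = []
        for motif, tokens, frozen in beam:
            cands = _candidate_scores(model, window, tokens, frozen)
            for m, p, c in top(cands, motif.mutations):
                t = tokens.copy()
                t[p] = CODON_INDEX[c]
                next_beam.append((m, t, frozen | {p}))
        beam = next_beam
        results.extend(m for m, _, _ in beam)
    return results


# ---------------------------------------------------------------------------
# enrichment


def _merged_peak_region(sample: Sample) -> np.ndarray:
    """Boolean mask of positions covered by any peak significance window."""
    n = sample.seq.n
    mask = np.zeros(n, dtype=bool)
    for a in find_peaks(stall_profile(sample)):
        mask[max(0, a - SW_HALF_WIDTH) : min(n, a + SW_HALF_WIDTH + 1)] = True
    return mask


def _pattern(canonical: str) -> list[str | None]:
    return [None if tok == "[SKIP]" else tok for tok in canonical.split(" ")]


def motif_enrichment(
    motifs: list[Motif], samples: list[Sample], condition: str, top_n: int = 50
) -> pd.DataFrame:
    """Fisher/BH enrichment of the most frequent motifs inside peak windows.

    For each of the `top_n` most frequent canonical motif strings of the
    condition, occurrences of the gapped pattern ([SKIP] = any codon) are
    counted at every alignment whose span lies fully inside the merged
    peak-window region versus everywhere else; candidate alignment start
    positions are partitioned the same way.  Two-sided Fisher exact p per
    2x2 table; Benjamini-Hochberg q across the tested motifs.
    """
    strings = [m.canonical for m in motifs if m.cond == condition or not m.cond]
    if not strings:
        return pd.DataFrame(
            columns=["motif", "freq", "occ_in", "occ_out", "tot_in", "tot_out", "odds", "p", "q"]
        )
    freq = pd.Series(strings).value_counts()
    tested = sorted(freq.index[:top_n], key=lambda s: (-freq[s], s))

    cond_samples = [s for s in samples if s.cond == condition]
    genes = []
    for s in cond_samples:
        codons = np.array(s.seq.codons)
        genes.append((codons, _merged_peak_region(s)))

    rows = []
    for canon in tested:
        pat = _pattern(canon)
        L = len(pat)
        occ_in = occ_out = tot_in = tot_out = 0
        for codons, region in genes:
            n = codons.size
            if n < L:
                continue
            starts = n - L + 1
            match = np.ones(starts, dtype=bool)
            for off, c in enumerate(pat):
                if c is not None:
                    match &= codons[off : off + starts] == c
            # an alignment is inside when its full span lies in the region
            span_in = np.ones(starts, dtype=bool)
            for off in range(L):
                span_in &= region[off : off + starts]
            tot_in += int(span_in.sum())
            tot_out += int(starts - span_in.sum())
            occ_in += int((match & span_in).sum())
            occ_out += int((match & ~span_in).sum())
        table = [[occ_in, tot_in - occ_in], [occ_out, tot_out - occ_out]]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append((canon, int(freq[canon]), occ_in, occ_out, tot_in, tot_out, odds, p))
    df = pd.DataFrame(
        rows, columns=["motif", "freq", "occ_in", "occ_out", "tot_in", "tot_out", "odds", "p"]
    )
    df["q"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df
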