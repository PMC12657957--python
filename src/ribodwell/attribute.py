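"""Gradient attributions and their aggregation around stalling peaks.

Integrated Gradients explains one scalar model output — a head's prediction
at one A-site — as per-codon contributions: the path integral of the output
gradient along the straight line from a zero embedding to the actual input
embedding, approximated with a Riemann midpoint rule.  Attributions sum over
the embedding axis to one value per codon, and satisfy the completeness
axiom: they add up to f(x) - f(baseline).

Peaks of a profile are positions strictly above mean + 1 sd of the annotated
values; troughs strictly below mean - 1 sd.  Control samples are analyzed on
their footprint profile with the control head; deprivation samples on the
difference profile with the difference head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad
from .core_io import CONDITION_INDEX, Sample, annotated
from .model import DwellModel

SW_HALF_WIDTH = 10  # codons up- and downstream of the A-site
IG_WARP_POWER = 3  # quadrature warp exponent for the integration path


@dataclass
class AttributionVector:
    gene_id: str
    a_site: int
    head: str  # "ctrl" or "delta"
    values: np.ndarray  # per-codon attribution, length = gene length
    explained: float = float("nan")  # f(x) - f(baseline) at this site


@dataclass
class PeakSet:
    gene_id: str
    condition: str
    peaks: np.ndarray
    troughs: np.ndarray
    mean: float
    sd: float


def stall_profile(sample: Sample) -> np.ndarray:
    """Profile on which peaks/troughs are defined: the footprint profile for
    control samples, the deprivation difference for deprived samples."""
    return sample.y_dc if sample.cond == "CTRL" else sample.y_delta


def head_for(sample: Sample) -> str:
    return "ctrl" if sample.cond == "CTRL" else "delta"


def find_peaks(profile: np.ndarray) -> np.ndarray:
    """Annotated positions strictly above mean + 1 sd of annotated values."""
    p = np.asarray(profile, dtype=float)
    ann = annotated(p)
    m, s = p[ann].mean(), p[ann].std()
    with np.errstate(invalid="ignore"):
        return np.nonzero(ann & (p > m + s))[0]


def find_troughs(profile: np.ndarray) -> np.ndarray:
    p = np.asarray(profile, dtype=float)
    ann = annotated(p)
    m, s = p[ann].mean(), p[ann].std()
    with np.errstate(invalid="ignore"):
        return np.nonzero(ann & (p < m - s))[0]


def peak_set(sample: Sample) -> PeakSet:
    p = stall_profile(sample)
    ann = annotated(p)
    return PeakSet(
        sample.gene_id,
        sample.cond,
        find_peaks(p),
        find_troughs(p),
        float(p[ann].mean()),
        float(p[ann].std()),
    )


def significance_window(a_site: int, n: int) -> np.ndarray:
    """Inclusive position range a_site +/- 10, truncated at the CDS edges."""
    return np.arange(max(0, a_site - SW_HALF_WIDTH), min(n - 1, a_site + SW_HALF_WIDTH) + 1)


# ---------------------------------------------------------------------------
# integrated gradients


def integrated_gradients(
    model: DwellModel,
    sample: Sample,
    a_site: int,
    head: str | None = None,
    steps: int = 64,
    chunk: int = 8,
) -> tuple[AttributionVector, float]:
    """IG of one head's output at ``a_site`` w.r.t. the combined per-position
    input embedding, from a zero baseline, with a midpoint Riemann sum.

    Returns the attribution vector and the relative completeness gap
    |sum(attr) - (f(x) - f(0))| / max(|f(x) - f(0)|, 1e-12).
    """
    if not 0 <= a_site < sample.seq.n:
        raise ValueError("a_site out of range")
    if steps < 8:
        raise ValueError("steps must be >= 8")
    head = head or head_for(sample)
    tokens = sample.seq.token_ids()[None, :]
    cond_ids = np.array([CONDITION_INDEX[sample.cond]])
    with no_grad():
        x0 = model.embed(tokens, cond_ids).data  # [1, n, D]

    def head_out(yc, yd):
        return yc if head == "ctrl" else yd

    # Riemann sum with midpoint samples over a warped partition alpha = t^3:
    # the integrand has a boundary layer near the zero baseline (the
    # normalization transition), and the warp concentrates cells there.
    # Weights are the exact cell widths, so they sum to 1 and attributions
    # on a linear model are exact.
    p = IG_WARP_POWER
    k = np.arange(steps)
    alphas = ((k + 0.5) / steps) ** p
    weights = ((k + 1) / steps) ** p - (k / steps) ** p
    grad_sum = np.zeros_like(x0[0], dtype=np.float64)
    for lo in range(0, steps, chunk):
        a = alphas[lo : lo + chunk]
        w = weights[lo : lo + chunk].astype(model.dtype)
        X = Tensor((a[:, None, None] * x0).astype(model.dtype), requires_grad=True)
        yc, yd = model.forward_from_embedding(X)
        out = (head_out(yc, yd)[:, a_site] * Tensor(w)).sum()
        out.backward()
        if not np.all(np.isfinite(X.grad)):
            raise FloatingPointError("non-finite gradients in integrated gradients")
        grad_sum += X.grad.sum(axis=0).astype(np.float64)
    attr = x0[0].astype(np.float64) * grad_sum  # [n, D]
    values = attr.sum(axis=1)

    with no_grad():
        fx = float(head_out(*model.forward_from_embedding(Tensor(x0))).data[0, a_site])
        f0 = float(
            head_out(*model.forward_from_embedding(Tensor(np.zeros_like(x0)))).data[0, a_site]
        )
    delta = fx - f0
    gap = abs(values.sum() - delta) / max(abs(delta), 1e-12)
    return AttributionVector(sample.gene_id, a_site, head, values, delta), gap


# ---------------------------------------------------------------------------
# aggregation


def normalize_in_window(values: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Max-abs normalization of attribution values within a window; signs kept."""
    w = values[window]
    peak = np.abs(w).max()
    return w / peak if peak > 0 else w


def top_salient_positions(attr: AttributionVector, k: int = 5) -> np.ndarray:
    """The k window positions with largest signed normalized attribution,
    reported relative to the A-site (A-site = 0, P-site = -1)."""
    window = significance_window(attr.a_site, attr.values.size)
    norm = normalize_in_window(attr.values, window)
    rel = window - attr.a_site
    order = sorted(range(rel.size), key=lambda i: (-norm[i], rel[i]))
    return rel[order[: min(k, rel.size)]]


def collect_peak_attributions(
    model: DwellModel,
    samples: list[Sample],
    steps: int = 64,
    max_sites: int | None = None,
    seed: int = 0,
):
    """IG at every (or a seeded subsample of) peak A-site of the samples."""
    sites = []
    for si, s in enumerate(samples):
        for a in find_peaks(stall_profile(s)):
            sites.append((si, int(a)))
    if max_sites is not None and len(sites) > max_sites:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(sites), size=max_sites, replace=False)
        sites = [sites[i] for i in sorted(keep)]
    out = []
    for si, a in sites:
        attr, _ = integrated_gradients(model, samples[si], a, steps=steps)
        out.append((samples[si], attr))
    return out


def codonwise_attribution_summary(attributed: list[tuple[Sample, AttributionVector]]) -> dict:
    """Mean of max-normalized attributions per codon over all occurrences of
    that codon inside the analyzed significance windows.  Positive means:
    the codon's presence increases the predicted count (slows the ribosome)."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for sample, attr in attributed:
        window = significance_window(attr.a_site, attr.values.size)
        norm = normalize_in_window(attr.values, window)
        for pos, v in zip(window, norm):
            c = sample.seq.codons[pos]
            sums[c] = sums.get(c, 0.0) + float(v)
            counts[c] = counts.get(c, 0) + 1
    return {c: sums[c] / counts[c] for c in sums}


def salient_position_histogram(
    attributed: list[tuple[Sample, AttributionVector]], k: int = 5
) -> dict[int, int]:
    hist: dict[int, int] = {}
    for _, attr in attributed:
        for rel in top_salient_positions(attr, k):
            hist[int(rel)] = hist.get(int(rel), 0) + 1
    return hist


def codon_mean_counts(samples: list[Sample]) -> dict[str, float]:
    """Per-codon mean of the (delta) profile over A-site occurrences."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for s in samples:
        p = stall_profile(s)
        for i in np.nonzero(annotated(p))[0]:
            c = s.seq.codons[i]
            sums[c] = sums.get(c, 0.0) + float(p[i])
            counts[c] = counts.get(c, 0) + 1
    return {c: sums[c] / counts[c] for c in sums}


def attribution_count_correlation(codon_attr: dict, codon_counts: dict) -> float:
    """Pearson correlation across codons between mean attribution and mean count."""
    from .model import pcc

    common = sorted(set(codon_attr) & set(codon_counts))
    if len(common) < 3:
        raise ValueError("need >= 3 codons with both summaries")
    return pcc([codon_attr[c] for c in common], [codon_counts[c] for c in common])
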