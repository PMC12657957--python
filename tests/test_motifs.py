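import numpy as np
import pytest
from scipy.stats import hypergeom

from ribodwell.core_io import CODON_INDEX, CODONS, SENSE_CODONS, CodonSequence, Sample
from ribodwell.model import ModelConfig, DwellModel, MAAPE_EPS
from ribodwell.motifs import (
    Motif,
    MutationWindow,
    beam_search_motifs,
    canonicalize_motif,
    make_window,
    motif_enrichment,
    mutation_score,
    parse_motif,
    select_fast_windows,
)

NAN = float("nan")


class TestCanonicalization:
    @pytest.mark.parametrize(
        "mutations,expected,anchor",
        [
            ((( -1, "CTG"), (1, "CTT")), "CTG [SKIP] CTT", -1),
            (((0, "GTC"),), "GTC", 0),
            (((-3, "GTC"), (-1, "GTC")), "GTC [SKIP] GTC", -3),
            (((-2, "AAA"), (-1, "GGG"), (3, "TTT")), "AAA GGG [SKIP] [SKIP] [SKIP] TTT", -2),
        ],
    )
    def test_examples(self, mutations, expected, anchor):
        canon, a = canonicalize_motif(mutations)
        assert canon == expected and a == anchor

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError):
            canonicalize_motif(((0, "GTC"), (0, "GTT")))

    def test_round_trip(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 4))
            pos = sorted(rng.choice(np.arange(-10, 11), size=k, replace=False))
            muts = tuple((int(p), CODONS[int(rng.integers(0, 64))]) for p in pos)
            canon, anchor = canonicalize_motif(muts)
            assert parse_motif(canon, anchor) == muts


class TestMutationScore:
    def test_no_change_scores_zero(self):
        assert mutation_score(1.5, 1.5) == 0.0

    def test_near_zero_baseline_saturates(self):
        s = mutation_score(0.0, 1.0)
        assert s == pytest.approx(100 * np.arctan(1.0 / MAAPE_EPS), rel=1e-9)
        assert s == pytest.approx(100 * np.pi / 2, rel=1e-4)

    def test_sign_flips_under_swap(self, rng):
        # the sign construction guarantees the direction reverses on swap;
        # magnitudes differ because the denominator is the original value
        for _ in range(20):
            a, b = rng.normal(size=2)
            if a != b:
                assert np.sign(mutation_score(a, b)) == -np.sign(mutation_score(b, a))

    def test_positive_iff_increase(self):
        assert mutation_score(1.0, 2.0) > 0 > mutation_score(2.0, 1.0)


@pytest.fixture(scope="module")
def beam_model():
    return DwellModel(ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=32, seed=12))


@pytest.fixture(scope="module")
def val_window(beam_model):
    rng = np.random.default_rng(4)
    codons = ("ATG",) + tuple(SENSE_CODONS[i] for i in rng.integers(0, 61, 40))
    vals = np.ones(41)
    vals[20] = 0.0  # trough at the centre
    vals[5] = 30.0
    s = Sample(CodonSequence("g", codons), "VAL", np.ones(41), vals)
    return make_window(s, 20, beam_model)


class TestBeamSearch:
    @pytest.mark.parametrize("width", [1, 2, 5])
    def test_level_counts(self, beam_model, val_window, width):
        motifs = beam_search_motifs(val_window, beam_model, width=width, max_size=3)
        sizes = [m.size for m in motifs]
        assert sizes.count(1) == width
        assert sizes.count(2) == width**2
        assert sizes.count(3) == width**3
        assert len(motifs) == width + width**2 + width**3

    def test_frozen_positions_never_remutated(self, beam_model, val_window):
        for m in beam_search_motifs(val_window, beam_model, width=3, max_size=3):
            positions = [p for p, _ in m.mutations]
            assert len(set(positions)) == len(positions)

    def test_mutations_are_real_substitutions(self, beam_model, val_window):
        w = val_window
        for m in beam_search_motifs(w, beam_model, width=2, max_size=2):
            for rel, codon in m.mutations:
                original = CODONS[w.tokens[rel + w.a_site_offset]]
                assert codon != original
                assert codon in SENSE_CODONS

    def test_level_one_equals_exhaustive_scan(self, beam_model, val_window):
        w = val_window
        # brute force over every single substitution with the same tie rule
        cands = []
        for p in range(w.width):
            for c in SENSE_CODONS:
                if CODON_INDEX[c] == w.tokens[p]:
                    continue
                t = w.tokens.copy()
                t[p] = CODON_INDEX[c]
                yc, yd = beam_model.predict_tokens(t[None, :], w.cond)
                val = float((yc if w.head == "ctrl" else yd)[0, w.a_site_offset])
                cands.append((p - w.a_site_offset, c, mutation_score(w.baseline, val)))
        cands.sort(key=lambda t: (-t[2], t[0], t[1]))
        expected = [((rel, c),) for rel, c, _ in cands[:5]]
        got = [m.mutations for m in beam_search_motifs(w, beam_model, width=5, max_size=1)]
        assert got == expected

    def test_constant_output_model_is_deterministic(self, val_window):
        m = DwellModel(ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=32, seed=1))
        for k in ("head_ctrl_w", "head_delta_w"):
            m.params[k].data[:] = 0.0
        w = make_window(
            Sample(
                CodonSequence("g", val_window_codons()), "VAL", np.ones(41), np.ones(41)
            ),
            20,
            m,
        )
        a = beam_search_motifs(w, m, width=2, max_size=2)
        b = beam_search_motifs(w, m, width=2, max_size=2)
        assert [x.mutations for x in a] == [x.mutations for x in b]
        assert all(x.score == 0.0 for x in a)


def val_window_codons():
    rng = np.random.default_rng(4)
    return ("ATG",) + tuple(SENSE_CODONS[i] for i in rng.integers(0, 61, 40))


class TestWindowSelection:
    def _samples(self, profiles, cond="VAL"):
        out = []
        for i, vals in enumerate(profiles):
            n = len(vals)
            codons = ("ATG",) + tuple(["GAA"] * (n - 1))
            out.append(
                Sample(CodonSequence(f"g{i}", codons), cond, np.ones(n), np.asarray(vals, float))
            )
        return out

    def test_constant_profiles_yield_nothing(self, beam_model):
        samples = self._samples([np.ones(30), np.ones(40)])
        assert select_fast_windows(samples, beam_model, 10, seed=0) == []

    def test_zero_request_empty(self, beam_model):
        samples = self._samples([[1] * 20 + [0] + [1] * 9])
        assert select_fast_windows(samples, beam_model, 0, seed=0) == []

    def test_qualifying_set_matches_exhaustive_oracle(self, beam_model, rng):
        samples = self._samples([rng.random(60) * 4 for _ in range(10)])
        wins = select_fast_windows(samples, beam_model, 10**6, seed=0)
        got = {(w.gene_id, w.a_site) for w in wins}
        # brute-force scan: every annotated position below mean - 1 sd
        expected = set()
        for s in samples:
            d = s.y_delta
            m, sd = np.nanmean(d), np.nanstd(d)
            for a in range(s.seq.n):
                if not np.isnan(d[a]) and d[a] < m - sd:
                    expected.add((s.gene_id, a))
        assert got == expected

    def test_seeded_subsample_reproducible(self, beam_model, rng):
        samples = self._samples([rng.random(60) * 4 for _ in range(6)])
        a = select_fast_windows(samples, beam_model, 3, seed=5)
        b = select_fast_windows(samples, beam_model, 3, seed=5)
        assert [(w.gene_id, w.a_site_offset) for w in a] == [
            (w.gene_id, w.a_site_offset) for w in b
        ]


class TestEnrichment:
    def _dataset(self, rng, n_genes=6, n=120, planted="GTC", plant_in_peaks=True):
        """Genes whose peaks optionally contain the planted codon."""
        samples = []
        for gi in range(n_genes):
            body = [SENSE_CODONS[i] for i in rng.integers(0, 61, n - 1)]
            vals = np.ones(n)
            for peak_at in (30, 70):
                vals[peak_at] = 20.0
                if plant_in_peaks:
                    for off in (-2, 1):
                        body[peak_at + off - 1] = planted
            samples.append(
                Sample(
                    CodonSequence(f"g{gi}", ("ATG",) + tuple(body)),
                    "VAL",
                    np.ones(n),
                    vals,
                )
            )
        return samples

    def _motifs(self, canon, k=60):
        return [Motif(parse_motif(canon, 0), 1.0, cond="VAL") for _ in range(k)]

    def test_planted_motif_enriched_scrambled_not(self, rng):
        samples = self._dataset(rng)
        table = motif_enrichment(
            self._motifs("GTC") + self._motifs("CCC", k=10), samples, "VAL"
        )
        row = table.set_index("motif")
        assert row.loc["GTC", "p"] < 0.05
        assert row.loc["GTC", "odds"] > 1

    def test_uniform_motif_has_no_association(self):
        # the motif matches at every start position, inside and outside peaks
        codons = ("GAA",) * 42
        vals = np.ones(42)
        vals[10] = 50.0  # peak; its window covers positions 0..20
        s = Sample(CodonSequence("g", codons), "VAL", np.ones(42), vals)
        t = motif_enrichment(self._motifs("GAA"), [s], "VAL")
        assert int(t.loc[0, "occ_in"]) == int(t.loc[0, "tot_in"]) == 21
        assert int(t.loc[0, "occ_out"]) == int(t.loc[0, "tot_out"]) == 21
        assert t.loc[0, "p"] == pytest.approx(1.0)

    def test_fisher_p_matches_hypergeometric_oracle(self, rng):
        samples = self._dataset(rng, n_genes=3)
        table = motif_enrichment(self._motifs("GTC"), samples, "VAL").iloc[0]
        a, b = int(table.occ_in), int(table.tot_in) - int(table.occ_in)
        c, d = int(table.occ_out), int(table.tot_out) - int(table.occ_out)
        M, K, N = a + b + c + d, a + c, a + b
        probs = hypergeom.pmf(np.arange(max(0, K + N - M), min(K, N) + 1), M, K, N)
        p_obs = hypergeom.pmf(a, M, K, N)
        expected = probs[probs <= p_obs * (1 + 1e-7)].sum()
        assert table.p == pytest.approx(expected, rel=1e-4)

    def test_bh_qvalues_monotone_in_p_rank(self, rng):
        samples = self._dataset(rng)
        motifs = []
        for canon in ("GTC", "GAA", "CCC", "GTC [SKIP] GTC", "AAA"):
            motifs += self._motifs(canon, k=12)
        table = motif_enrichment(motifs, samples, "VAL").sort_values("p")
        q = table["q"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()
        assert (table["q"] >= table["p"] - 1e-12).all()

    def test_motif_longer_than_gene_counts_zero(self):
        codons = ("ATG", "GAA", "GAA")
        vals = np.array([1.0, 1, 5])
        s = Sample(CodonSequence("g", codons), "VAL", np.ones(3), vals)
        canon = " ".join(["GTC"] + ["[SKIP]"] * 8 + ["GTC"])
        t = motif_enrichment(self._motifs(canon), [s], "VAL")
        assert int(t.loc[0, "occ_in"]) == 0 and int(t.loc[0, "occ_out"]) == 0
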