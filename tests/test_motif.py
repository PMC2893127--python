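import numpy as np
import pytest

from tripeak.motif import (
    PSSM,
    MotifError,
    accept_motif,
    background_frequencies,
    encode,
    extract_site_sequences,
    scan_pvalue,
    score_distribution,
    zoops_em,
)

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(BASES[b] for b in rng.integers(0, 4, n))


def planted_sequences(seed=7, n=50, n_planted=40, length=41, motif="TTCCGGGAA",
                      n_mut=2):
    rng = np.random.default_rng(seed)
    seqs = []
    for i in range(n):
        s = random_seq(rng, length)
        if i < n_planted:
            inst = list(motif)
            for j in rng.choice(len(motif), size=n_mut, replace=False):
                inst[j] = BASES[int(rng.integers(0, 4))]
            p = int(rng.integers(0, length - len(motif) + 1))
            s = s[:p] + "".join(inst) + s[p + len(motif):]
        seqs.append(s)
    return seqs


def hamming_to_either_strand(consensus, motif):
    rc = motif.translate(str.maketrans(BASES, "TGCA"))[::-1]
    return min(
        sum(a != b for a, b in zip(consensus, motif)),
        sum(a != b for a, b in zip(consensus, rc)),
    )


@pytest.fixture(scope="module")
def uniform_pssm():
    return PSSM(np.full((5, 4), 0.25), np.full(4, 0.25))


@pytest.fixture(scope="module")
def sharp_pssm():
    rng = np.random.default_rng(5)
    m = rng.dirichlet(np.full(4, 0.4), size=5)
    m = np.clip(m, 1e-3, None)
    m /= m.sum(axis=1, keepdims=True)
    return PSSM(m, np.array([0.3, 0.2, 0.2, 0.3]))


class TestExtract:
    def _fasta(self, tmp_path, seqs):
        path = tmp_path / "g.fa"
        with open(path, "w") as fh:
            for name, s in seqs.items():
                fh.write(f">{name}\n{s}\n")
        return path

    def test_substring_oracle(self, tmp_path, rng):
        seq = random_seq(rng, 400)
        path = self._fasta(tmp_path, {"chr1": seq})
        out = extract_site_sequences(path, [("r1", "chr1", 100)], flank=20)
        assert out[0].sequence == seq[80:121].upper() and not out[0].clipped

    def test_chromosome_start_clipping_flagged(self, tmp_path, rng):
        path = self._fasta(tmp_path, {"chr1": random_seq(rng, 400)})
        out = extract_site_sequences(path, [("r1", "chr1", 10)], flank=20)
        assert out[0].clipped and len(out[0].sequence) == 31

    def test_empty_input_and_missing_chromosome(self, tmp_path, rng):
        path = self._fasta(tmp_path, {"chr1": random_seq(rng, 100)})
        assert extract_site_sequences(path, []) == []
        with pytest.raises(KeyError):
            extract_site_sequences(path, [("x", "chrNA", 50)])

    def test_n_rich_sequences_dropped(self, tmp_path):
        path = self._fasta(tmp_path, {"chr1": "N" * 200})
        assert extract_site_sequences(path, [("x", "chr1", 100)]) == []


class TestZoopsEm:
    def test_recovers_planted_motif(self):
        res = zoops_em(planted_sequences(), w=9, n_starts=5, seed=1)
        assert hamming_to_either_strand(res.pssm.consensus, "TTCCGGGAA") <= 1
        assert res.fraction_containing >= 0.6

    def test_objective_never_decreases(self):
        res = zoops_em(planted_sequences(seed=9), w=9, n_starts=3, seed=2)
        diffs = np.diff(res.objective_trajectory)
        assert (diffs >= -1e-8).all()

    def test_random_sequences_rarely_claim_a_motif(self):
        below = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            seqs = [random_seq(rng, 41) for _ in range(50)]
            res = zoops_em(seqs, w=9, n_starts=5, seed=seed)
            below += res.fraction_containing < 0.25
        assert below >= 8

    def test_pssm_columns_normalized_and_positive(self):
        res = zoops_em(planted_sequences(seed=3), w=9, n_starts=2, seed=3)
        assert np.allclose(res.pssm.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert (res.pssm.matrix > 0).all()

    def test_width_preconditions(self):
        with pytest.raises(MotifError):
            zoops_em(["ACGTACGT"], w=3)
        with pytest.raises(MotifError):
            zoops_em(["ACGTA"], w=9)


class TestAcceptMotif:
    @pytest.mark.parametrize(
        "fraction, accepted", [(0.589, True), (0.24, False), (0.25, True)]
    )
    def test_acceptance_boundary(self, fraction, accepted):
        res = zoops_em(planted_sequences(seed=1, n=8, n_planted=8), w=9,
                       n_starts=1, seed=1)
        res.fraction_containing = fraction
        assert accept_motif(res) is accepted


class TestScan:
    def test_uniform_pssm_is_null(self, uniform_pssm, rng):
        hit = scan_pvalue(uniform_pssm, random_seq(rng, 60))
        assert hit.best_score == 0.0 and hit.p_site == 1.0 and hit.p_value == 1.0

    def test_null_distribution_integrates_to_one(self, sharp_pssm):
        _, dist = score_distribution(sharp_pssm)
        assert abs(dist.sum() - 1.0) < 1e-6

    def test_site_pvalue_matches_exhaustive_enumeration(self, sharp_pssm):
        # brute force over all 4^5 words under the background
        granularity = 1e-3
        ints = np.rint(
            np.log(sharp_pssm.matrix / sharp_pssm.background) / granularity
        ).astype(int)
        bg = sharp_pssm.background
        words = np.stack(
            np.meshgrid(*[np.arange(4)] * 5, indexing="ij"), axis=-1
        ).reshape(-1, 5)
        scores = ints[np.arange(5), words].sum(axis=1)
        probs = bg[words].prod(axis=1)
        offset, dist = score_distribution(sharp_pssm, granularity)
        for t in np.percentile(scores, [5, 25, 50, 75, 95]).astype(int):
            brute = probs[scores >= t].sum()
            idx = max(t - offset, 0)
            dp = dist[idx:].sum() if idx < dist.size else 0.0
            assert abs(brute - dp) < 1e-3

    def test_planting_consensus_lowers_pvalue(self, rng):
        res = zoops_em(planted_sequences(seed=21), w=9, n_starts=3, seed=4)
        consensus = res.pssm.consensus
        lower = 0
        for trial in range(100):
            trng = np.random.default_rng(500 + trial)
            seq = random_seq(trng, 500)
            pos = int(trng.integers(0, 491))
            with_site = seq[:pos] + consensus + seq[pos + 9:]
            p_plain = scan_pvalue(res.pssm, seq).p_value
            p_plant = scan_pvalue(res.pssm, with_site).p_value
            lower += p_plant < p_plain
        assert lower == 100

    def test_pvalue_monotone_in_best_score(self, sharp_pssm):
        offset, dist = score_distribution(sharp_pssm)
        tails = dist[::-1].cumsum()[::-1]
        assert (np.diff(tails) <= 1e-15).all()

    def test_short_sequence_rejected(self, sharp_pssm):
        with pytest.raises(MotifError):
            scan_pvalue(sharp_pssm, "ACG")


class TestEncoding:
    def test_ambiguous_bases_are_neutral(self):
        codes = encode("ACGTN")
        assert list(codes) == [0, 1, 2, 3, 4]

    def test_background_estimated_from_input(self):
        bg = background_frequencies(["AAAA", "AAAT"])
        assert bg[0] > bg[3] > 0 and abs(bg.sum() - 1) < 1e-12
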