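"""PWM scanning, enrichment z-test, and hypergeometric over-representation."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from isoswitch.errors import FormatError
from isoswitch.motifs import (
    PWMatrix,
    best_hit_score,
    motif_ztest,
    ora_hypergeom,
    plant_motif,
    random_promoters,
    rank_motifs,
    read_jaspar,
    score_promoters,
    synthetic_ccaat_pwm,
    synthetic_pwm_library,
)

JASPAR_BARE = """>SYN0001 NFY_CCAAT
5 5 85 85 5
85 85 5 5 5
5 5 5 5 5
5 5 5 5 85
"""

JASPAR_BRACKETS = """>SYN0001 NFY_CCAAT
A  [ 5 5 85 85 5 ]
C  [ 85 85 5 5 5 ]
G  [ 5 5 5 5 5 ]
T  [ 5 5 5 5 85 ]
"""


def brute_force_best_hit(seq, pwm):
    """Per-offset, per-strand scorer written independently of the
    vectorized path."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    lo = pwm.log_odds
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    best = -math.inf
    for strand_seq in (seq, "".join(comp[b] for b in reversed(seq))):
        for off in range(len(seq) - pwm.width + 1):
            window = strand_seq[off:off + pwm.width]
            if "N" in window:
                continue
            s = sum(lo[code[b], j] for j, b in enumerate(window))
            best = max(best, s)
    if best == -math.inf:
        return float("nan")
    smin, smax = pwm.score_range
    return (best - smin) / (smax - smin)


class TestJasparReader:
    @pytest.mark.parametrize("text", [JASPAR_BARE, JASPAR_BRACKETS],
                             ids=["bare", "brackets"])
    def test_both_dialects(self, tmp_path, text):
        f = tmp_path / "pfm.txt"
        f.write_text(text)
        pwms = read_jaspar(f)
        assert len(pwms) == 1
        assert pwms[0].matrix_id == "SYN0001"
        assert pwms[0].consensus == "CCAAT"

    def test_wrong_row_count_rejected(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text(">M1 X\n1 2 3 4\n1 2 3 4\n")
        with pytest.raises(FormatError):
            read_jaspar(f)


class TestBestHitScore:
    def test_consensus_scores_one(self):
        pwm = synthetic_ccaat_pwm()
        seq = "GATTAG" + pwm.consensus + "GAGTAA"
        assert best_hit_score(seq, pwm) == pytest.approx(1.0)

    def test_all_n_sequence_has_no_valid_window(self):
        assert np.isnan(best_hit_score("N" * 30, synthetic_ccaat_pwm()))

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            best_hit_score("ACG", synthetic_ccaat_pwm())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pwm = synthetic_pwm_library(n_decoys=1, rng=rng)[1]
        seq = "".join(rng.choice(list("ACGTN"), p=[0.23, 0.23, 0.23, 0.23, 0.08], size=20))
        expected = brute_force_best_hit(seq, pwm)
        if np.isnan(expected):
            assert np.isnan(best_hit_score(seq, pwm))
        else:
            assert best_hit_score(seq, pwm) == pytest.approx(expected, abs=1e-12)

    def test_reverse_complement_symmetry(self, rng):
        pwm = synthetic_ccaat_pwm()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            rc = "".join(comp[b] for b in reversed(seq))
            assert best_hit_score(seq, pwm) == pytest.approx(best_hit_score(rc, pwm))


class TestMotifZtest:
    def test_identical_fg_bg_gives_zero(self):
        proms = random_promoters(30, length=60, rng=0)
        scores = score_promoters(proms, [synthetic_ccaat_pwm()]).iloc[:, 0]
        z, p = motif_ztest(list(proms), scores)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_invariant_to_duplicated_background(self):
        proms = random_promoters(40, length=60, rng=1)
        scores = score_promoters(proms, [synthetic_ccaat_pwm()]).iloc[:, 0]
        fg = list(proms)[:8]
        bg = list(proms)
        z1, _ = motif_ztest(fg, scores, bg)
        z2, _ = motif_ztest(fg, scores, bg + bg)
        assert z1 == pytest.approx(z2)

    def test_small_foreground_refused(self):
        proms = random_promoters(20, length=60, rng=2)
        scores = score_promoters(proms, [synthetic_ccaat_pwm()]).iloc[:, 0]
        with pytest.raises(ValueError):
            motif_ztest(list(proms)[:3], scores)

    def test_planted_ccaat_ranks_first(self, rng):
        pwms = synthetic_pwm_library(n_decoys=19, rng=3)
        bg = random_promoters(150, rng=rng)
        fg = plant_motif(random_promoters(40, rng=rng, prefix="FG"), "CCAAT", 370)
        ranking = rank_motifs(list(fg), {**bg, **fg}, pwms)
        assert ranking.index[0] == "NFY_CCAAT"


class TestOra:
    def test_complete_overlap_closed_form(self):
        # study = set = {k genes}: P(overlap = k) = 1/C(N, k)
        universe = [f"g{i}" for i in range(10)]
        study = universe[:4]
        assert ora_hypergeom(study, study, universe) == pytest.approx(1 / math.comb(10, 4))

    def test_disjoint_sets_give_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        assert ora_hypergeom(universe[:3], universe[5:8], universe) == pytest.approx(1.0)

    def test_study_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeom(["x"], ["a"], ["a", "b"])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_univ = 12
        universe = [f"g{i}" for i in range(n_univ)]
        gset = list(rng.choice(universe, 5, replace=False))
        study = list(rng.choice(universe, 4, replace=False))
        k_obs = len(set(study) & set(gset))
        # enumerate all C(12, 4) study sets of the same size
        hits = total = 0
        for combo in combinations(universe, len(study)):
            total += 1
            hits += len(set(combo) & set(gset)) >= k_obs
        assert ora_hypergeom(study, gset, universe) == pytest.approx(hits / total)
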