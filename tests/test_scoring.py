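"""singscore/stingscore against a first-principles rank-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from drugsig.evaluation import spearman_rho
from drugsig.scoring import (StableGenePanel, score_matrix, singscore,
                             stingscore)
from drugsig.signatures import DrugEfficacySignature


def make_signature(up, down, drug="d"):
    return DrugEfficacySignature(drug_id=drug, up_genes=list(up),
                                 down_genes=list(down),
                                 frequencies=pd.DataFrame())


def oracle_singscore(values: dict[str, float], up: list[str],
                     down: list[str]) -> float:
    """Independent reimplementation from first principles: average ranks by
    explicit pairwise enumeration, normalization bounds from the best/worst
    placements of a set of that size."""
    genes = list(values)
    n = len(genes)

    def rank(g):
        below = sum(values[h] < values[g] for h in genes)
        ties = sum(values[h] == values[g] for h in genes)  # includes g
        return below + (ties + 1) / 2

    def directional(members, reverse):
        m = len(members)
        ranks = [(n - rank(g) + 1) if reverse else rank(g) for g in members]
        mean_rank = sum(ranks) / m
        lo = sum(range(1, m + 1)) / m            # set at the very bottom
        hi = sum(range(n - m + 1, n + 1)) / m    # set at the very top
        return (mean_rank - lo) / (hi - lo) - 0.5

    total = 0.0
    if up:
        total += directional(up, reverse=False)
    if down:
        total += directional(down, reverse=True)
    return total


class TestSingscore:
    def test_maximal_and_minimal_up_sets(self):
        profile = pd.Series({"g1": 5.0, "g2": 6.0, "g3": 7.0, "g4": 8.0})
        top = singscore(profile, make_signature(["g3", "g4"], []))
        bottom = singscore(profile, make_signature(["g1", "g2"], []))
        assert top.up_score == pytest.approx(0.5)
        assert bottom.up_score == pytest.approx(-0.5)

    def test_matches_rank_enumeration_oracle(self, rng):
        sig_max = 0.0
        for _ in range(40):
            n = int(rng.integers(10, 60))
            values = rng.normal(size=n)
            if rng.random() < 0.3:  # inject ties
                values = np.round(values, 1)
            genes = [f"g{i}" for i in range(n)]
            profile = pd.Series(values, index=genes)
            picked = rng.choice(genes, size=min(12, n - 1), replace=False)
            up, down = list(picked[:6]), list(picked[6:])
            res = singscore(profile, make_signature(up, down))
            expected = oracle_singscore(dict(zip(genes, values)), up, down)
            sig_max = max(sig_max, abs(res.total_score - expected))
        assert sig_max < 1e-12

    def test_invariant_under_strictly_increasing_transforms(self, rng):
        genes = [f"g{i}" for i in range(40)]
        profile = pd.Series(rng.normal(size=40), index=genes)
        sig = make_signature(genes[:5], genes[5:10])
        base = singscore(profile, sig).total_score
        for transform in (np.exp, lambda x: 3 * x + 7,
                          lambda x: (x - x.min() + 1) ** 3):
            assert singscore(transform(profile), sig).total_score == \
                pytest.approx(base, abs=1e-12)

    def test_swapping_up_and_down_negates_total(self, rng):
        genes = [f"g{i}" for i in range(30)]
        profile = pd.Series(rng.normal(size=30), index=genes)
        a = singscore(profile, make_signature(genes[:4], genes[4:10]))
        b = singscore(profile, make_signature(genes[4:10], genes[:4]))
        assert a.total_score == pytest.approx(-b.total_score)

    def test_bounds_hold_for_random_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            genes = [f"g{i}" for i in range(n)]
            profile = pd.Series(np.round(rng.normal(size=n), 1), index=genes)
            m_up = int(rng.integers(1, n // 2 + 1))
            m_down = int(rng.integers(0, n - m_up)) or 0
            sig = make_signature(genes[:m_up], genes[m_up:m_up + m_down])
            res = singscore(profile, sig)
            assert -1 <= res.total_score <= 1
            assert -0.5 - 1e-12 <= res.up_score <= 0.5 + 1e-12

    def test_missing_signature_genes_dropped_and_counted(self):
        profile = pd.Series({"g1": 1.0, "g2": 2.0, "g3": 3.0})
        res = singscore(profile, make_signature(["g1", "absent"], ["g3"]))
        assert res.n_up_used == 1 and res.n_down_used == 1

    def test_no_signature_genes_present_is_an_error(self):
        profile = pd.Series({"g1": 1.0, "g2": 2.0})
        with pytest.raises(ValueError, match="no signature genes"):
            singscore(profile, make_signature(["x"], ["y"]))


class TestStingscore:
    panel = StableGenePanel([f"a{i}" for i in range(5)])

    def _profile(self, sig_value):
        data = {f"a{i}": 1.0 for i in range(5)}
        data["up1"] = sig_value
        data["other"] = 0.0
        return pd.Series(data)

    def test_gene_above_all_anchors_scores_half(self):
        res = stingscore(self._profile(2.0), make_signature(["up1"], []),
                         self.panel)
        assert res.up_score == pytest.approx(0.5)

    def test_gene_below_all_anchors_scores_minus_half(self):
        res = stingscore(self._profile(0.5), make_signature(["up1"], []),
                         self.panel)
        assert res.up_score == pytest.approx(-0.5)

    def test_gene_tied_with_all_anchors_scores_zero(self):
        res = stingscore(self._profile(1.0), make_signature(["up1"], []),
                         self.panel)
        assert res.up_score == pytest.approx(0.0)

    def test_missing_anchor_is_an_error(self):
        profile = pd.Series({"a0": 1.0, "up1": 2.0})
        with pytest.raises(ValueError, match="anchor genes missing"):
            stingscore(profile, make_signature(["up1"], []), self.panel)


class TestScoreMatrix:
    def test_duplicate_columns_score_identically(self, rng):
        genes = [f"g{i}" for i in range(20)]
        col = rng.normal(size=20)
        expr = pd.DataFrame({"s1": col, "s2": col}, index=genes)
        scored = score_matrix(expr, make_signature(genes[:3], genes[3:6]))
        assert scored.loc["s1", "total_score"] == scored.loc["s2", "total_score"]

    def test_truth_signature_score_tracks_auc(self, cohort, truth_signature):
        scores = score_matrix(cohort.expression, truth_signature)["total_score"]
        rho = spearman_rho(scores.to_numpy(),
                           cohort.response.iloc[:, 0].to_numpy())
        assert rho >= 0.7

    def test_stingscore_bridges_batch_shift_where_singscore_drifts(self):
        from drugsig import simulate
        cfg = simulate.SyntheticConfig(seed=17, n_genes=500, n_samples=50)
        pair = simulate.generate_batch_shifted_pair(cfg, shift=4.0, scale=1.3,
                                                    n_stable=5)
        sig = make_signature(pair.truth.planted_up_genes,
                             pair.truth.planted_down_genes)
        panel = StableGenePanel(pair.stable_genes)
        sting_a = score_matrix(pair.expression_a, sig, "stingscore", panel)
        sting_b = score_matrix(pair.expression_b, sig, "stingscore", panel)
        rho = spearman_rho(sting_a["total_score"].to_numpy(),
                           sting_b["total_score"].to_numpy())
        assert rho >= 0.9
        # whole-transcriptome ranking drifts with the background: the
        # directional components shift by ~0.4 while the anchored ones stay
        naive_a = score_matrix(pair.expression_a, sig)
        naive_b = score_matrix(pair.expression_b, sig)
        naive_shift = abs(naive_a["up_score"].mean() - naive_b["up_score"].mean())
        sting_shift = abs(sting_a["up_score"].mean() - sting_b["up_score"].mean())
        assert naive_shift > 0.2
        assert naive_shift > 10 * sting_shift

    def test_panel_overlapping_signature_rejected(self):
        genes = [f"g{i}" for i in range(10)]
        expr = pd.DataFrame(np.arange(20.0).reshape(10, 2), index=genes)
        sig = make_signature(genes[:2], genes[2:4])
        with pytest.raises(ValueError, match="overlaps"):
            score_matrix(expr, sig, "stingscore", StableGenePanel([genes[0]]))

    def test_per_sample_failure_names_the_sample(self):
        expr = pd.DataFrame({"ok": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="ok"):
            score_matrix(expr, make_signature(["zz"], []))
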