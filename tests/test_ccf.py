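"""CCF posterior model, SNV filters and clonality calls."""

import math

import numpy as np
import pandas as pd
import pytest

from clonarch import ccf
from clonarch.io import MutationRecord, SamplePurity


def _mut(sample="s1", gene="G", alt=20, depth=100, nalt=0, ndepth=60, effect="non_silent"):
    return MutationRecord(
        sample_id=sample,
        gene=gene,
        chromosome="1",
        position=100,
        ref_allele="C",
        alt_allele="T",
        tumor_alt_count=alt,
        tumor_depth=depth,
        normal_alt_count=nalt,
        normal_depth=ndepth,
        effect=effect,
        context_5p="A",
        context_3p="G",
    )


class TestFilterSnvs:
    # the four read-support rules: >=10x both, <=2 germline alt reads,
    # tumor VAF >= 10%, germline VAF <= 2%
    @pytest.mark.parametrize(
        "rec,kept,rule",
        [
            (_mut(alt=5, depth=9), False, "low_tumor_depth"),
            (_mut(ndepth=9), False, "low_normal_depth"),
            (_mut(nalt=3, ndepth=200), False, "high_normal_alt"),
            (_mut(alt=9, depth=100), False, "low_tumor_vaf"),
            (_mut(nalt=2, ndepth=50), False, "high_normal_vaf"),
            (_mut(alt=12, depth=100, nalt=0, ndepth=50), True, None),
            (_mut(alt=10, depth=100), True, None),  # VAF exactly 10% kept
            (_mut(nalt=2, ndepth=100), True, None),  # germline VAF exactly 2% kept
        ],
    )
    def test_each_rule(self, rec, kept, rule):
        out, rep = ccf.filter_snvs([rec])
        assert (len(out) == 1) == kept
        if rule:
            assert rep.as_dict()[rule] == 1

    def test_counts_reported_per_rule(self):
        recs = [_mut(alt=5, depth=9, ndepth=8), _mut()]
        out, rep = ccf.filter_snvs(recs)
        assert rep.n_input == 2 and rep.n_kept == 2 - 1
        # one record trips both depth rules
        assert rep.low_tumor_depth == 1 and rep.low_normal_depth == 1


class TestExcludeLowPurity:
    def test_boundary(self):
        pur = [SamplePurity("a", 0.15, 2.0), SamplePurity("b", 0.20, 2.0), SamplePurity("c", 0.95, 2.0)]
        assert ccf.exclude_low_purity(pur) == ["b", "c"]

    def test_missing_sample_with_mutations_errors(self):
        pur = [SamplePurity("a", 0.5, 2.0)]
        with pytest.raises(ValueError, match="ghost"):
            ccf.exclude_low_purity(pur, mutation_sample_ids=["a", "ghost"])


class TestMultiplicity:
    @pytest.mark.parametrize(
        "vaf,purity,qt,expected",
        [
            (0.5, 1.0, 2, 1),
            (1.0, 1.0, 2, 2),
            # round(0.33 * (1.8 + 0.8) / 0.6) = round(1.43) = 1
            (0.33, 0.6, 3, 1),
            (0.05, 1.0, 2, 1),  # clamped up to 1
            (1.0, 1.0, 4, 4),
        ],
    )
    def test_point_estimate(self, vaf, purity, qt, expected):
        assert ccf.estimate_multiplicity(vaf, purity, qt) == expected

    def test_homozygous_deletion_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="homozygous"):
            assert ccf.estimate_multiplicity(0.3, 0.5, 0) is None


class TestCcfPosterior:
    def test_half_vaf_diploid_is_clonal(self):
        post = ccf.ccf_posterior(50, 100, 1.0, 2, 1)
        assert post.prob_ge_095 > 0.5
        assert post.point_estimate == pytest.approx(1.0, abs=0.02)

    def test_low_vaf_is_subclonal_with_matching_point_estimate(self):
        post = ccf.ccf_posterior(20, 100, 1.0, 2, 1)
        assert post.prob_ge_095 < 0.5
        assert post.point_estimate == pytest.approx(0.4, abs=0.05)

    def test_saturated_counts_concentrate_at_one(self):
        post = ccf.ccf_posterior(1000, 1000, 1.0, 2, 2)
        assert post.prob_ge_095 > 0.99
        assert post.point_estimate == pytest.approx(1.0, abs=1e-3)

    def test_probabilities_sum_to_one_and_tail_matches_mass(self):
        post = ccf.ccf_posterior(30, 80, 0.6, 2, 1)
        assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        grid_mass = post.probabilities[post.grid >= 0.95 - 1e-12].sum()
        assert grid_mass == pytest.approx(post.prob_ge_095, abs=1e-12)

    def test_inconsistent_multiplicity_errors(self):
        # expected VAF at CCF=1 is p*m/denom = 1*3/2 > 1
        with pytest.raises(ValueError, match="multiplicity"):
            ccf.ccf_posterior(50, 100, 1.0, 2, 3)

    def test_oracle_equivalence_on_random_inputs(self):
        """The grid posterior equals an independent brute-force normalization
        (log-binomial via math.lgamma) to within 1e-6 total variation."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            depth = int(rng.integers(20, 500))
            alt = int(rng.integers(0, depth + 1))
            purity = float(rng.uniform(0.2, 1.0))
            q_t = int(rng.integers(1, 5))
            m = int(rng.integers(1, q_t + 1))
            denom = purity * q_t + 2 * (1 - purity)
            if purity * m / denom > 1:
                continue
            post = ccf.ccf_posterior(alt, depth, purity, q_t, m)
            oracle = _oracle_posterior(alt, depth, purity, q_t, m)
            tv = 0.5 * np.abs(post.probabilities - oracle).sum()
            assert tv < 1e-6

    def test_tail_probability_monotone_in_alt(self):
        probs = [ccf.ccf_posterior(a, 100, 0.7, 2, 1).prob_ge_095 for a in range(0, 36)]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


def _oracle_posterior(alt, depth, purity, q_t, m):
    """Independent reimplementation: pure-python log binomial, extended grid,
    super-clonal mass folded into the top reported point."""
    denom = purity * q_t + 2 * (1 - purity)
    v1 = purity * m / denom
    step = 0.01
    n_ext = int(math.floor(1.0 / v1 / step + 1e-9))
    logc = math.lgamma(depth + 1) - math.lgamma(alt + 1) - math.lgamma(depth - alt + 1)
    weights = []
    for i in range(1, n_ext + 1):
        v = min(i * step * v1, 1.0)
        if v in (0.0, 1.0):
            w = v**alt * (1 - v) ** (depth - alt)
            weights.append(w if w > 0 else 0.0)
        else:
            weights.append(math.exp(logc + alt * math.log(v) + (depth - alt) * math.log(1 - v)))
    total = sum(weights)
    probs = [w / total for w in weights]
    out = probs[:100]
    out[-1] += sum(probs[100:])
    return np.array(out)


class TestCallClonality:
    @pytest.mark.parametrize("tail,label", [(0.51, "clonal"), (0.50, "subclonal"), (0.0, "subclonal")])
    def test_strict_threshold(self, tail, label):
        grid = ccf.default_grid()
        probs = np.zeros(100)
        # place `tail` mass at 1.0 and the rest at 0.5
        probs[-1] = tail
        probs[49] = 1 - tail
        post = ccf.CCFPosterior(grid, probs, 0.5, tail)
        assert ccf.call_clonality(post).clonality == label


class TestMultihitExclusion:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "effect", "ccf", "clonality", "prob_ge_095"])

    def test_two_non_silent_in_one_gene_both_removed(self):
        calls = self._calls(
            [
                ("s1", "VHL", "non_silent", 1.0, "clonal", 0.9),
                ("s1", "VHL", "non_silent", 0.4, "subclonal", 0.0),
                ("s1", "BAP1", "non_silent", 1.0, "clonal", 0.9),
            ]
        )
        out = ccf.exclude_multihit_genes(calls)
        assert set(out["gene"]) == {"BAP1"}

    def test_silent_hit_does_not_trigger_exclusion(self):
        calls = self._calls(
            [
                ("s1", "VHL", "non_silent", 1.0, "clonal", 0.9),
                ("s1", "VHL", "silent", 0.4, "subclonal", 0.0),
            ]
        )
        out = ccf.exclude_multihit_genes(calls)
        assert len(out) == 2  # retained; silent SNVs do not count toward the trigger
        gene = ccf.gene_level_calls(out)
        assert len(gene) == 1 and gene.loc[0, "clonality"] == "clonal"

    def test_singleton_genes_untouched_and_per_sample_scope(self):
        calls = self._calls(
            [
                ("s1", "A", "non_silent", 1.0, "clonal", 0.9),
                ("s1", "B", "non_silent", 1.0, "clonal", 0.9),
                ("s1", "C", "non_silent", 1.0, "clonal", 0.9),
                ("s2", "A", "non_silent", 1.0, "clonal", 0.9),
                ("s2", "A", "non_silent", 0.3, "subclonal", 0.0),
            ]
        )
        out = ccf.exclude_multihit_genes(calls)
        assert len(out[out.sample_id == "s1"]) == 3  # s1 keeps everything
        assert len(out[out.sample_id == "s2"]) == 0  # s2's gene A removed

    def test_gene_level_rejects_unresolved_multihit(self):
        calls = self._calls(
            [
                ("s1", "A", "non_silent", 1.0, "clonal", 0.9),
                ("s1", "A", "non_silent", 0.3, "subclonal", 0.0),
            ]
        )
        with pytest.raises(ValueError, match="exclude_multihit"):
            ccf.gene_level_calls(calls)
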