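"""Abundance tables: filtering, member matching, ecology, diversity, Venn."""

import math

import numpy as np
import pandas as pd
import pytest

from polytax.amplicon import (
    AbundanceTable,
    AmpliconParams,
    alpha_diversity,
    ecology_profile,
    filter_low_abundance,
    match_members,
    venn_counts,
    MemberHit,
)
from polytax.seq_core import NucleotideSequence
from polytax.synthetic import SpikeSpec, gen_member_table, mutate


def _table(values: dict, groups: dict, level="OTU") -> AbundanceTable:
    df = pd.DataFrame(values).T  # rows = taxa
    df.columns = list(groups)
    return AbundanceTable(df, groups, level=level)


@pytest.fixture
def toy_table():
    groups = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    values = {
        "otu1": [10.0, 5.0, 0.0, 0.0],
        "otu2": [0.30, 0.20, 0.10, 0.0],
        "otu3": [0.10, 0.05, 0.08, 0.0],
        "otu4": [0.0, 0.0, 4.0, 13.6],
    }
    return _table(values, groups)


class TestTableValidation:
    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            _table({"t": [-1.0]}, {"s1": "A"})

    def test_oversum_rejected(self):
        with pytest.raises(ValueError):
            _table({"t1": [60.0], "t2": [50.0]}, {"s1": "A"})

    def test_missing_group_label_rejected(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["t"])
        with pytest.raises(ValueError):
            AbundanceTable(df, {}, level="OTU")

    def test_tsv_roundtrip(self, toy_table, tmp_path):
        toy_table.to_tsv(tmp_path / "t.tsv", tmp_path / "g.tsv")
        back = AbundanceTable.from_tsv(tmp_path / "t.tsv", tmp_path / "g.tsv")
        pd.testing.assert_frame_equal(back.values, toy_table.values)
        assert back.groups == toy_table.groups


class TestLowAbundanceFilter:
    def test_boundary_kept_low_dropped_idempotent(self, toy_table):
        filtered = filter_low_abundance(toy_table)
        assert "otu2" in filtered.taxa_ids     # max 0.30 >= 0.25
        assert "otu3" not in filtered.taxa_ids  # max 0.10 < 0.25
        twice = filter_low_abundance(filtered)
        pd.testing.assert_frame_equal(twice.values, filtered.values)

    def test_exact_threshold_kept(self):
        t = _table({"t": [0.25]}, {"s1": "A"})
        assert "t" in filter_low_abundance(t).taxa_ids


@pytest.fixture(scope="module")
def member():
    rng = np.random.default_rng(77)
    return NucleotideSequence(
        "memberA", "".join(rng.choice(list("ACGT"), size=420)))


class TestMatchMembers:
    def test_identical_rep_hits_both_levels(self, member):
        rep = NucleotideSequence("otu1", member.residues)
        for level in ("OTU", "ASV"):
            hits = match_members([member], [rep], level=level)
            assert len(hits) == 1
            assert hits[0].member_id == "memberA"

    def test_98pct_variant_only_otu_level(self, member):
        # exactly 8 interior substitutions on 420 nt: 98.1% identity
        res = list(member.residues)
        for pos in range(30, 420 - 30, 45):
            res[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[res[pos]]
        rep = NucleotideSequence("otu1", "".join(res))
        changed = sum(a != b for a, b in zip(member.residues, rep.residues))
        assert 0.97 <= 1 - changed / 420 < 0.99  # construction sanity
        assert len(match_members([member], [rep], level="OTU")) == 1
        assert match_members([member], [rep], level="ASV") == []

    def test_chimeric_rep_fails_asv_coverage(self, member):
        # 290 nt of the member plus a 130-nt foreign tail: only ~69% of
        # the representative aligns, below the 80% ASV coverage rule
        rng = np.random.default_rng(123)
        tail = "".join(rng.choice(list("ACGT"), size=130))
        rep = NucleotideSequence("otu1", member.residues[:290] + tail)
        assert match_members([member], [rep], level="ASV") == []
        # but still a valid OTU-level hit (high local identity)
        assert len(match_members([member], [rep], level="OTU")) == 1

    def test_asv_hits_subset_of_otu_hits(self, member):
        reps = []
        for i, rate in enumerate((0.0, 0.005, 0.02, 0.06)):
            if rate:
                r, _ = mutate(member, rate, seed=10 + i)
                reps.append(NucleotideSequence(f"otu{i}", r.residues))
            else:
                reps.append(NucleotideSequence(f"otu{i}", member.residues))
        otu = {h.taxon_id for h in match_members([member], reps, level="OTU")}
        asv = {h.taxon_id for h in match_members([member], reps, level="ASV")}
        assert asv <= otu

    def test_tie_breaks_to_lexicographic_member(self, member):
        twin = NucleotideSequence("memberB", member.residues)
        rep = NucleotideSequence("otu1", member.residues)
        hits = match_members([twin, member], [rep], level="OTU")
        assert hits[0].member_id == "memberA"

    def test_params_validation(self):
        with pytest.raises(ValueError):
            AmpliconParams(otu_identity=99.5)  # above asv_identity


class TestEcologyProfile:
    def test_prevalence_and_abundance_summary(self, toy_table):
        hits = [MemberHit("mA", "otu1", 100.0, 100.0, "OTU"),
                MemberHit("mB", "otu4", 100.0, 100.0, "OTU")]
        profiles = {p.member_id: p
                    for p in ecology_profile(hits, toy_table)}
        assert profiles["mA"].prevalence == 50.0  # 2 of 4 samples
        assert profiles["mA"].mean_abundance_in_positives == 7.5
        assert profiles["mA"].max_abundance == 10.0
        assert profiles["mB"].max_abundance == 13.6

    def test_member_without_hits_flagged(self, toy_table):
        profiles = ecology_profile([], toy_table, members=["ghost"])
        assert profiles[0].prevalence == 0.0
        assert profiles[0].mean_abundance_in_positives is None

    def test_single_positive_sample_max_equals_mean(self, toy_table):
        hits = [MemberHit("mB", "otu4", 100.0, 100.0, "OTU")]
        # restrict to the one positive group-B sample at 13.6%
        sub = AbundanceTable(toy_table.values[["s4"]], {"s4": "B"})
        p = ecology_profile(hits, sub)[0]
        assert p.max_abundance == p.mean_abundance_in_positives == 13.6

    def test_multiple_taxa_for_one_member_are_summed(self, toy_table):
        hits = [MemberHit("mA", "otu1", 100.0, 100.0, "OTU"),
                MemberHit("mA", "otu2", 99.0, 100.0, "OTU")]
        p = ecology_profile(hits, toy_table)[0]
        assert p.max_abundance == pytest.approx(10.30)

    def test_unknown_taxon_rejected(self, toy_table):
        with pytest.raises(ValueError):
            ecology_profile([MemberHit("m", "nope", 100.0, 100.0, "OTU")],
                            toy_table)


class TestAlphaDiversity:
    def test_uniform_effective_equals_richness(self):
        t = _table({f"t{i}": [25.0] for i in range(4)}, {"s1": "A"})
        d = alpha_diversity(t, "s1")
        assert d.richness == 4
        assert d.shannon_effective == pytest.approx(4.0)

    def test_single_taxon(self):
        t = _table({"t": [100.0]}, {"s1": "A"})
        assert alpha_diversity(t, "s1").shannon_effective == pytest.approx(1.0)

    def test_closed_form_half_quarter_quarter(self):
        t = _table({"a": [50.0], "b": [25.0], "c": [25.0]}, {"s1": "A"})
        d = alpha_diversity(t, "s1")
        assert d.shannon_H == pytest.approx(1.5 * math.log(2))
        assert d.shannon_effective == pytest.approx(2 ** 1.5)

    def test_effective_between_one_and_richness(self, toy_table):
        for s in ("s1", "s2", "s3"):
            d = alpha_diversity(toy_table, s)
            assert 1.0 <= d.shannon_effective <= d.richness + 1e-9

    def test_all_zero_sample_rejected(self):
        t = _table({"t": [0.0]}, {"s1": "A"})
        with pytest.raises(ValueError):
            alpha_diversity(t, "s1")

    def test_unknown_sample_rejected(self, toy_table):
        with pytest.raises(KeyError):
            alpha_diversity(toy_table, "nope")


class TestVennCounts:
    def test_constructed_counts(self):
        groups = {"a1": "A", "a2": "A", "b1": "B"}
        values = {}
        for i in range(5):
            values[f"onlyA{i}"] = [1.0, 0.5, 0.0]
        for i in range(3):
            values[f"onlyB{i}"] = [0.0, 0.0, 1.0]
        for i in range(2):
            values[f"both{i}"] = [1.0, 0.0, 1.0]
        vc = venn_counts(_table(values, groups))
        assert vc.unique == {"A": 5, "B": 3}
        assert vc.shared == 2
        assert vc.total == 10

    def test_identical_composition_all_shared(self):
        t = _table({"t1": [1.0, 1.0], "t2": [2.0, 2.0]},
                   {"s1": "A", "s2": "B"})
        vc = venn_counts(t)
        assert vc.unique == {"A": 0, "B": 0}
        assert vc.shared == vc.total == 2

    def test_disjoint_composition_no_shared(self):
        t = _table({"t1": [1.0, 0.0], "t2": [0.0, 2.0]},
                   {"s1": "A", "s2": "B"})
        vc = venn_counts(t)
        assert vc.shared == 0
        assert vc.unique == {"A": 1, "B": 1}

    def test_single_group_rejected(self):
        t = _table({"t1": [1.0]}, {"s1": "A"})
        with pytest.raises(ValueError):
            venn_counts(t)


class TestPrevalenceRecovery:
    def test_designed_presence_rate_recovered(self):
        # 200 samples at q=0.3: member prevalence from the full pipeline
        # (generation -> matching -> ecology) must fall in the exact
        # binomial 99% interval of 100q.
        from scipy.stats import binom

        q, n = 0.3, 200
        spikes = [SpikeSpec("m1", {"grp": q})]
        fx = gen_member_table({"grp": n}, spikes, n_background_taxa=15,
                              seed=314)
        hits = match_members(fx.member_refs, fx.rep_seqs, level="OTU")
        profile = ecology_profile(hits, fx.table)[0]
        lo = binom.ppf(0.005, n, q) / n * 100
        hi = binom.ppf(0.995, n, q) / n * 100
        assert lo <= profile.prevalence <= hi
        # and it matches the generator's own realized truth exactly
        assert profile.prevalence == pytest.approx(
            fx.truth.expectations["realized_prevalence"]["m1"]["grp"])
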