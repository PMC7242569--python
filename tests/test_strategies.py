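import numpy as np
import pandas as pd
import pytest

from snowniche.diffabund import timepoint_summaries
from snowniche.strategies import (
    build_profiles,
    cluster_profiles,
    contribution_ranking,
    group_abundance,
    label_strategies,
)
from helpers import make_table

TPS = ["SEP", "MAR", "MAY", "JUN"]


def profiles_from_means(means: dict) -> pd.DataFrame:
    """Build a profile frame directly from raw 4-point means."""
    rows = {}
    constant = {}
    for otu, m in means.items():
        m = np.asarray(m, float)
        sd = m.std()
        constant[otu] = sd == 0
        rows[otu] = np.zeros(4) if sd == 0 else (m - m.mean()) / sd
    out = pd.DataFrame.from_dict(rows, orient="index", columns=TPS)
    out["constant"] = pd.Series(constant)
    return out


def table_from_means(means: dict, n_reps=2):
    vals = np.repeat(np.array(list(means.values()), float), n_reps, axis=1)
    return make_table(vals, n_reps=n_reps, otu_ids=list(means))


class TestBuildProfiles:
    def _summaries(self, means):
        return timepoint_summaries(table_from_means(means))

    def test_hand_computed_z_scores(self):
        s = self._summaries({"O1": [0, 2, 0, 0], "O2": [1, 1, 1, 1]})
        prof = build_profiles(s, {"O1", "O2"})
        # deviations [-0.5, 1.5, -0.5, -0.5] scaled by 1/sd, sd = 0.866
        np.testing.assert_allclose(
            prof.loc["O1", TPS].to_numpy(float),
            np.array([-0.5, 1.5, -0.5, -0.5]) / 0.8660254,
            rtol=1e-6,
        )
        row = prof.loc["O1", TPS].to_numpy(float)
        assert row.mean() == pytest.approx(0, abs=1e-9)
        assert row.std() == pytest.approx(1, abs=1e-9)

    def test_constant_profile_flagged_zero_vector(self):
        s = self._summaries({"O1": [1, 1, 1, 1], "O2": [0, 1, 0, 0]})
        prof = build_profiles(s, {"O1", "O2"})
        assert prof.loc["O1", "constant"]
        np.testing.assert_array_equal(prof.loc["O1", TPS].to_numpy(float), 0.0)

    def test_scale_invariance(self):
        s1 = self._summaries({"O1": [0.01, 0.03, 0.02, 0.01]})
        s10 = self._summaries({"O1": [0.1, 0.3, 0.2, 0.1]})
        p1 = build_profiles(s1, {"O1"})
        p10 = build_profiles(s10, {"O1"})
        np.testing.assert_allclose(
            p1.loc["O1", TPS].to_numpy(float),
            p10.loc["O1", TPS].to_numpy(float),
            rtol=1e-9,
        )

    def test_missing_timepoint_raises(self):
        s = self._summaries({"O1": [0, 1, 0, 0]})
        with pytest.raises(ValueError):
            build_profiles(s[s.timepoint != "MAY"], {"O1"})


class TestClusterProfiles:
    def test_three_planted_pairs_recovered(self):
        rng = np.random.default_rng(0)
        means = {}
        for i, peak in enumerate([1, 1, 2, 2, 3, 3]):  # MAR, MAY, JUN pairs
            base = np.full(4, 0.1) + rng.normal(0, 0.01, 4)
            base[peak] += 0.4
            means[f"O{i + 1}"] = base
        prof = profiles_from_means(means)
        cl = cluster_profiles(prof, 3)
        parts = {tuple(sorted(cl.index[cl == c])) for c in set(cl)}
        assert parts == {("O1", "O2"), ("O3", "O4"), ("O5", "O6")}

    def test_identical_profiles_single_cluster(self):
        prof = profiles_from_means({f"O{i}": [0, 1, 0, 0] for i in range(4)})
        cl = cluster_profiles(prof, 1)
        assert set(cl) == {1}

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        means = {f"O{i}": rng.random(4) for i in range(10)}
        prof = profiles_from_means(means)
        cl1 = cluster_profiles(prof, 3)
        shuffled = prof.sample(frac=1, random_state=5)
        cl2 = cluster_profiles(shuffled, 3)
        parts1 = {frozenset(cl1.index[cl1 == c]) for c in set(cl1)}
        parts2 = {frozenset(cl2.index[cl2 == c]) for c in set(cl2)}
        assert parts1 == parts2

    def test_too_many_clusters_rejected(self):
        prof = profiles_from_means({"O1": [0, 1, 0, 0], "O2": [0, 0, 1, 0]})
        with pytest.raises(ValueError, match="k="):
            cluster_profiles(prof, 3)

    def test_constant_profiles_get_sentinel_cluster(self):
        prof = profiles_from_means(
            {"O1": [1, 1, 1, 1], "O2": [0, 1, 0, 0], "O3": [0, 0, 1, 0]}
        )
        cl = cluster_profiles(prof, 2)
        assert cl["O1"] == -1
        assert set(cl[["O2", "O3"]]) == {1, 2}


class TestLabelStrategies:
    def _labelled(self, means, k):
        prof = profiles_from_means(means)
        cl = cluster_profiles(prof, k)
        return label_strategies(cl, prof)

    def test_peak_timepoint_maps_to_strategy(self):
        lab = self._labelled(
            {
                "O1": [-1, 1.5, -0.3, -0.2],
                "O2": [0, 0, 1, 0],
                "O3": [0, 0, 0, 1],
                "O4": [1, 0, 0, 0],
            },
            4,
        )
        assert lab.loc["O1", "strategy"] == "WINTER_ADAPTED"
        assert lab.loc["O2", "strategy"] == "SNOWMELT_SPECIALIST"
        assert lab.loc["O3", "strategy"] == "SPRING_ADAPTED"
        assert lab.loc["O4", "strategy"] == "FALL"

    def test_multiple_clusters_may_share_a_label(self):
        lab = self._labelled(
            {"O1": [0, 0, 0.1, 1], "O2": [0, 0.3, 0, 1.5]}, 2
        )
        assert set(lab["strategy"]) == {"SPRING_ADAPTED"}
        assert len(set(lab["cluster_id"])) == 2

    def test_tie_breaks_toward_later_timepoint(self):
        prof = profiles_from_means({"O1": [0, 1, 0, 1], "O2": [0, 1.01, 0, 1]})
        cl = pd.Series([1, 1], index=["O1", "O2"])
        # centroid MAR and JUN nearly tied; exact tie must pick JUN
        prof.loc["O1", ["MAR", "JUN"]] = [1.0, 1.0]
        prof.loc["O2", ["MAR", "JUN"]] = [1.0, 1.0]
        lab = label_strategies(cl, prof)
        assert (lab["strategy"] == "SPRING_ADAPTED").all()

    def test_constant_cluster_unassigned(self):
        prof = profiles_from_means({"O1": [1, 1, 1, 1], "O2": [0, 1, 0, 0]})
        cl = cluster_profiles(prof, 1)
        lab = label_strategies(cl, prof)
        assert lab.loc["O1", "strategy"] == "UNASSIGNED"
        assert lab.loc["O2", "strategy"] == "WINTER_ADAPTED"


class TestGroupAbundance:
    def _assignment(self, mapping):
        return pd.DataFrame(
            {"cluster_id": 1, "strategy": pd.Series(mapping)}
        )

    def test_single_member_passthrough(self):
        table = table_from_means({"O1": [0.05] * 4, "O2": [0.95] * 4})
        ga = group_abundance(table, self._assignment({"O1": "WINTER_ADAPTED"}))
        np.testing.assert_allclose(ga["group_abundance"], 0.05)

    def test_members_sum(self):
        table = table_from_means(
            {"O1": [0.02] * 4, "O2": [0.03] * 4, "O3": [0.95] * 4}
        )
        ga = group_abundance(
            table, self._assignment({"O1": "WINTER_ADAPTED", "O2": "WINTER_ADAPTED"})
        )
        np.testing.assert_allclose(ga["group_abundance"], 0.05)

    def test_empty_group_is_zero(self):
        table = table_from_means({"O1": [0.5] * 4, "O2": [0.5] * 4})
        assignment = pd.DataFrame(
            {"cluster_id": [1], "strategy": ["SPRING_ADAPTED"]}, index=["OTUX"]
        )
        ga = group_abundance(table, assignment)
        assert (ga["group_abundance"] == 0).all()


class TestContributionRanking:
    def _setup(self, deltas, base=0.1):
        means = {}
        for i, d in enumerate(deltas):
            means[f"O{i + 1}"] = [base, base + d, base, base]
        filler = 1 - (base * len(deltas))  # not a member; keeps columns sane
        means["BG"] = [filler, filler, filler, filler]
        table = table_from_means(means)
        assignment = pd.DataFrame(
            {
                "cluster_id": 1,
                "strategy": pd.Series(
                    {f"O{i + 1}": "WINTER_ADAPTED" for i in range(len(deltas))}
                ),
            }
        )
        return table, assignment

    def test_worked_percentages(self):
        table, assignment = self._setup([0.02, 0.01, 0.01])
        out = contribution_ranking(
            table, assignment, None, "WINTER_ADAPTED", "WINTER",
            "hillslope", "D0_5", top_n=10, rank="otu",
        )
        assert out["pct_contribution"].tolist() == pytest.approx([50, 25, 25])

    def test_single_member_is_100_percent(self):
        table, assignment = self._setup([0.02])
        out = contribution_ranking(
            table, assignment, None, "WINTER_ADAPTED", "WINTER",
            "hillslope", "D0_5", rank="otu",
        )
        assert out["pct_contribution"].iloc[0] == pytest.approx(100)

    def test_negative_contribution_ranked_last(self):
        table, assignment = self._setup([0.03, 0.02, -0.01])
        out = contribution_ranking(
            table, assignment, None, "WINTER_ADAPTED", "WINTER",
            "hillslope", "D0_5", rank="otu",
        )
        assert out["pct_contribution"].tolist() == pytest.approx([75, 50, -25])
        assert out["taxon"].iloc[-1] == "O3"

    def test_contributions_close_to_100_over_all_members(self):
        table, assignment = self._setup([0.03, 0.02, -0.01, 0.005])
        out = contribution_ranking(
            table, assignment, None, "WINTER_ADAPTED", "WINTER",
            "hillslope", "D0_5", top_n=100, rank="otu",
        )
        assert out["pct_contribution"].sum() == pytest.approx(100, abs=1e-9)

    def test_genus_aggregation_uses_lowest_assigned_rank(self):
        table, assignment = self._setup([0.02, 0.01, 0.01])
        taxonomy = pd.DataFrame(
            {
                "domain": "Bacteria",
                "genus": ["GenusA", "GenusA", "unassigned"],
                "family": ["FamA", "FamA", "FamB"],
            },
            index=["O1", "O2", "O3"],
        )[["domain", "family", "genus"]]
        out = contribution_ranking(
            table, assignment, taxonomy, "WINTER_ADAPTED", "WINTER",
            "hillslope", "D0_5", rank="genus",
        )
        assert set(out["taxon"]) == {"GenusA", "FamB"}
        genus_a = out.set_index("taxon").loc["GenusA"]
        assert genus_a["pct_contribution"] == pytest.approx(75)

    def test_zero_group_change_rejected(self):
        table, assignment = self._setup([0.0, 0.0])
        with pytest.raises(ValueError, match="zero|undefined"):
            contribution_ranking(
                table, assignment, None, "WINTER_ADAPTED", "WINTER",
                "hillslope", "D0_5", rank="otu",
            )
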